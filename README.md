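# sedrl — offline deep RL for ICU sedation dosing

`sedrl` re-implements, as a tested and fully synthetic-data-driven
pipeline, a patient-specific sedation-management analysis: an off-policy
deep reinforcement-learning agent that learns joint **propofol +
fentanyl** dosing from logged hourly ICU trajectories, and the
performance-error statistics that compare the learned policy with the
recorded clinician behaviour.

It is written for researchers in clinical machine learning who want a
transparent, dependency-light reference implementation of this class of
analysis — every component, from the prioritized replay buffer to the
backpropagation of the actor-critic networks, is plain numpy and readable
in one sitting.

## The model

Sedation management is cast as an MDP. The state `s_t ∈ R^14` collects
routinely charted measures for hourly window `t` (blood pressures,
respiration rate, heart rate, SpO2, arterial pH, ventilation pressures,
FiO2, PaO2, MAP, age, gender); the action `a_t ∈ R^2_{≥0}` is the
propofol/fentanyl quantity for the window. The reward keeps the two
control variables in their therapeutic bands — Riker Sedation–Agitation
Scale (SAS) in 3–4 and mean arterial pressure (MAP) in 65–85 mmHg — via
two-logistic band terms, and penalizes medication:

    r_t = r_SAS(SAS_t) + r_MAP(MAP_t) − 0.02 · (propofol_t + fentanyl_t),

with `r_MAP(x) = 2/(1+e^−(x−65)) − 2/(1+e^−(x−85)) − 1` and the SAS
analogue centred on 3 and 4, optionally gated on strict improvement of the
combined band error. The policy `a = π(s)` is learned by a deep
deterministic policy gradient (DDPG) agent — actor, critic, and slowly
tracking target copies of both — with prioritized experience replay,
trained **offline** from the logged clinician transitions. Policies are
compared per patient `i` and control variable `c` by the performance error

    PE_ic = (hours outside band / ICU hours) × 100,

its cohort median (MDPE) and mean (MPE), the RMSE of band deviations, and
Welch t-tests on the per-patient vectors.

Real credentialed ICU data is out of scope; a synthetic cohort generator
(heterogeneous log-normal drug sensitivities, mean-reverting SAS/MAP,
agitation expressed in the vitals, and a noisy band-targeting "clinician"
with reassessment holds and overdose episodes) stands in for it. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

`examples/04_train_and_evaluate.py` trains the agent on a miniature
cohort (60 patients × 36 h, 4k updates per discount candidate) and prints:

```
                            learned  clinician
MPE(SAS) %                  10.7       17.8
mean RMSE(SAS)              0.26       0.42
MPE(MAP) %                  17.7       26.7
mean RMSE(MAP)              0.96       1.66
mean total dose                 363        416
Welch p: PE(SAS) 0.0603, PE(MAP) 0.0928, total dose 0.0483
```

Read: the learned policy leaves the sedation band on 10.7% of ICU hours
versus 17.8% under the logged clinician doses, keeps MAP in range more of
the time, and administers less total medication. (Numbers above are from
the example's fixed seed; at this miniature scale the direction, not the
magnitude, is the point.) The other examples demonstrate the reward
surface (`01`), preprocessing (`02`) and the learned transition model with
counterfactual rollouts (`03`).

The full pipeline is also scriptable from the shell:

```bash
sedrl run-all --seed 1 --outdir runs/demo          # generate → … → evaluate
sedrl generate --seed 1 --out cohort.csv           # individual stages
sedrl evaluate --seed 1 --outdir runs/eval
```

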