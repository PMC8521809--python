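# Methods

`sedrl` learns a continuous joint propofol + fentanyl dosing policy from
logged hourly ICU trajectories and scores it against the recorded clinician
behaviour. This note documents the model, the synthetic cohort that stands
in for a credentialed EHR extract, the numerical choices, and what the
package's tests do and do not establish.

## Problem formulation

Each ICU stay is a Markov decision process. The state `s_t` is a
14-dimensional vector of routinely charted measures in hourly window `t`
(diastolic BP, mean noninvasive BP, respiration rate, heart rate, SpO2,
arterial pH, PEEP, FiO2, PaO2, plateau pressure, mean airway pressure,
MAP, age, gender); the action `a_t` is the (propofol, fentanyl) quantity
administered in the window; the reward scores whether the two control
variables — the Riker Sedation–Agitation Scale (SAS, target band 3–4) and
mean arterial pressure (MAP, target band 65–85 mmHg) — sit in their
therapeutic bands while penalizing total medication. Notably, SAS itself
is *not* part of the state: a policy must read sedation depth from its
physiological correlates.

## Preprocessing

Raw timestamped observations are binned into contiguous half-open hourly
windows `[t, t+1)`, repeated recordings averaged within a window. Windows
where every state measure, or the SAS outcome, is missing are dropped and
the remainder re-indexed contiguously. Missing state features are then
sample-and-hold imputed (last observation carried forward), with
training-split means for leading gaps. Missing doses are zero — an infusion
that was not charted was not given; imputing one would fabricate treatment.
All continuous features are z-scored with training-split statistics under
the population (divide-by-n) variance convention; the binary gender code is
passed through. Raw SAS, MAP and doses are carried alongside the normalized
state for reward and evaluation. Subjects are split 60/20/20
(train/validation/test) at the subject level, deterministically per seed.

## Reward

Per window, each control variable earns a band reward built from two unit
logistics, e.g. for MAP: `2/(1+e^-(MAP-65)) - 2/(1+e^-(MAP-85)) - 1`,
which is ≈ +1 inside 65–85 mmHg and → −1 far outside. The SAS analogue
uses centres 3 and 4. Signed band deviations `D_t` (positive below the
band, negative above), the combined window error `e_t = |D_t(MAP)| +
|D_t(SAS)|` (magnitudes, so opposite excursions cannot cancel; a literal
signed sum is available behind a flag), and the gated reward

    r_t = r_SAS + r_MAP − 0.02·(propofol + fentanyl)   if e_t < e_{t−1}
    r_t = 0                                            otherwise

are computed exactly in this printed form by the reward module's defaults.

Two structural quirks of this form matter. First, on the 1–7 SAS scale the
band width (1) is comparable to the unit logistic scale, so the SAS band
term peaks at ≈ −0.51 (at SAS 3.5) rather than near +1, and its whole
dynamic range (≈ 0.43) is smaller than the dose penalty's range over the
action box (≈ 0.8). Second, the strict-improvement gate pays zero for every
window that merely *stays* in band (error 0 cannot strictly improve), while
mean-reverting physiology produces "improvements" — and hence rewards —
without any action. Together these make "never dose" the optimizer of the
literal reward. An agent trained on it faithfully learns exactly that, and
abandons sedation control.

The package therefore separates two things. The reward *module* implements
the printed form as its default, including the gate. The *experiment
pipeline* trains with a band-dominant variant: the SAS logistics are
steepened (`sas_sharpness = 8`, giving an in-band value ≈ +0.93 and a
sharp penalty outside, i.e. the stated intent of a band reward "close to 1
when in range"), and the improvement gate is off so that every in-band
window pays. Both are single config switches. The evaluation metrics are
reward-independent, so this choice affects only what the agent optimizes,
not how policies are scored.

## Dynamics model

A three-layer fully connected network (ReLU, ReLU, linear; batch
normalization on the hidden layers; Adam) maps `(s_t, a_t)` to `s_{t+1}`.
Internally it predicts the state *delta* with a near-zero-initialized
output layer, so the untrained model is the persistence baseline
`s_{t+1} = s_t` and training can only improve on it; the best
validation-epoch parameters are kept. Networks are implemented directly on
numpy arrays (layers cache activations; backprop is hand-written): the
models involved are small enough that a deep-learning framework would add
nothing but a dependency.

Counterfactual rollouts alternate policy actions with model predictions.
MAP is read from the de-normalized predicted state; SAS, which is not a
state entry, is decoded by a linear least-squares probe fit on training
windows. In tests and in the synthetic experiment the true simulator plays
the role of the transition model, which removes model error from the
policy comparison.

## DDPG with prioritized replay

Four networks: actor (state → sigmoid-squashed two-drug action, scaled by
per-drug `dose_max` = the 99th percentile of training doses), critic
(state+action → value), and slowly tracking target copies of both (Polyak
coefficient 5e-3). Training samples minibatches from a sum-tree
prioritized replay buffer: records are drawn with probability
`p_i^α / Σ p_j^α` (α = 0.6), corrected by importance weights
`(N·P(i))^-β` normalized by the batch maximum, with β annealed 0.4 → 1
over training; priorities are `|TD error| + 1e-3`, and new records enter
at the current maximum priority. The critic minimizes the
importance-weighted squared TD error against `y = r + γ·Q'(s', π'(s'))`;
the actor ascends the critic's action gradient (deterministic policy
gradient). Both use Adam (critic 1e-3, actor 1e-4) with near-zero final
layers so the actor starts at mid-range doses with live sigmoid gradients.

Offline training (the default, and the mode the source data admits) fills
the buffer exclusively with logged clinician transitions; the reward for
the transition `(s_t, a_t, ·, s_{t+1})` scores the *outcome* window `t+1`
with the dose penalty taken from `a_t`. A model-based mode that interacts
with a simulator or learned dynamics under decaying Gaussian exploration
noise (OU noise available) exists for fine-tuning studies.

Two stabilizers address the well-known brittleness of offline DDPG, both
using only training/validation subjects:

* **Discount selection on validation.** γ is chosen from a small grid
  (0.1, 0.4, 0.7) by validation performance — the same protocol the
  source analysis describes for its own γ (its printed value, 1e-3, is an
  effectively myopic setting that remains the agent-config default).
* **Snapshot selection.** During each training run the policy is
  checkpointed every 1000 updates and scored by simulator rollout on the
  validation subjects (plus a fixed slice of training subjects, to reduce
  selection noise). The final policy is the best-scoring *frugal*
  candidate — mean validation dose at least 5% below the clinicians' —
  among single snapshots, the mean-action ensemble of each run's top
  three, and the cross-γ ensemble of run winners. Action-mean ensembling
  damps the erratic dose jumps individual snapshots can exhibit.

## Evaluation

Per patient and control variable, PE is the percentage of ICU hours the
variable spent outside its band (boundaries inclusive); MDPE is the cohort
median of PE, MPE the mean (± sd), and RMSE the root mean squared band
deviation. The clinician ("behaviour") policy is scored directly on its
logged trajectories. A learned policy is scored by rollout: each
evaluation patient is re-simulated from their first logged window under
the policy's doses, with process noise on, and the rollout charts SAS the
same way the log does (rounded to the ordinal level) so both arms are
measured identically. Learned-vs-clinician differences in per-patient PE,
RMSE and total dose are tested with unpaired Welch t-tests (a paired
option exists; the source reports a two-sample test).

The headline experiment evaluates on **freshly simulated held-out
patients** (default 100) — new draws from the same population, never seen
in training or selection — rather than only the 20% test split; with a
generative simulator this is the natural held-out set and roughly doubles
the power of the comparison at no cost in validity.

## Synthetic cohort

Each simulated patient has a resting agitation set point
(`sas_baseline ~ U[4, 6]`), a MAP baseline (`U[70, 95]` mmHg), and
log-normal drug sensitivities (propofol sedation median 0.05 SAS
points/unit/h, log-sd 0.4; fentanyl 0.035; propofol MAP-lowering 0.25
mmHg/unit/h), so identical doses sedate different patients by different
amounts. SAS and MAP mean-revert hourly toward their baselines (rates
0.35 and 0.3) under Gaussian process noise (sd 0.15 SAS points, 2.5 mmHg);
doses push both down. Agitation is expressed in the vitals: heart rate
(+8 bpm per SAS point above 4), respiration (+2.5), noninvasive mean and
diastolic BP (+3, +2 mmHg), and the MAP set point itself (+2 mmHg),
mirroring the monotone rise of charted vitals across sedation levels in
real cohorts. Feature observation noise is small because window values
are hourly means of continuously monitored signals. SAS is charted as the
rounded ordinal level; 5% of feature values and 2% of SAS charts are
dropped to exercise imputation.

The logged clinician is a proportional band-targeting controller with
documented real-world suboptimalities: doses are reassessed only every
4 hours and run unchanged in between (zero-order hold), carry Gaussian
noise (sd 2.0/1.0 units), and with 10% probability per reassessment are
multiplied 2.5× (overdose events); hypotension halves the propofol rate,
and below the band doses taper linearly to zero by SAS 2. These constants
were set so the synthetic clinician's cohort-level performance matches the
clinician arm observed in the real-data analysis this package re-implements
(MPE(SAS) ≈ 17%, with oversedation episodes), and so the charted SAS
distribution is unimodal with its mode at level 4. With them, the cohort's
information structure — sedation depth only partially legible from vitals,
patient sensitivity unobservable — is the binding constraint on any
stateless policy, which is the qualitative regime the real problem lives in.

What the simulator does *not* model: multi-compartment pharmacokinetics,
drug habituation and tolerance, adjunct sedatives, circadian structure,
charting artifacts beyond missingness and rounding, and any fitted
correspondence to a real EHR cohort's distributions. Passing tests on this
cohort show the pipeline's machinery is sound and that the learned-vs-clinician
*direction* is reproducible under heterogeneous, partially observed
dose–response; they do not certify performance on real patients.

## Numerical choices and degenerate inputs

Windows are 0-based, half-open; an observation at integer time `t` falls
in window `t`. Zero-variance features warn and scale by 1. Multiple SAS
recordings in a window average to a real value (the rounded level is kept
for band logic). The PER buffer samples with replacement (so draw counts
may exceed buffer size); α = 0 reduces it exactly to uniform replay.
Welch tests on two zero-variance samples with equal means return p = 1 by
convention. Actions are clipped to `[0, dose_max]`; rollout states that go
non-finite truncate the trajectory with a flag. All randomness flows from
one master seed through named per-stage seeds (kept below 2^31), making
every pipeline run bit-reproducible.

## Problem sizes

The packaged experiment uses 200 patients × 48 h (≈ 5.6k logged
transitions), 15k update steps per γ candidate, and 100 fresh evaluation
patients; the dynamics-recovery check uses 5k transitions of a known
linear-Gaussian system. These sizes keep a full run in the minutes range
on a single core while leaving the comparison statistically interpretable.

## Known limitations

* Offline DDPG has no explicit out-of-distribution action penalty; the
  dose box, the frugality filter and snapshot selection are the only
  guards against critic exploitation.
* The SAS readout used for learned-dynamics rollouts is linear; strongly
  nonlinear agitation–vitals relationships would need a richer probe.
* MDPE of a well-controlled policy is frequently 0 (more than half of
  patients never leave the band), so MPE carries most of the comparative
  information.
* γ = 1e-3, the printed default, makes the return essentially the
  immediate reward; the validated grid exists precisely because that
  setting under-uses the trajectory structure.
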