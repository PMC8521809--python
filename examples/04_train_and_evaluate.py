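"""Train the offline dosing agent on a small cohort and score it.

A scaled-down version of the full experiment (60 patients, 36 h, 4k update
steps, single discount value) so it finishes in about a minute: trains the
DDPG + prioritized-replay agent on logged clinician transitions, then
compares learned and clinician policies with the performance-error
statistics on freshly simulated held-out patients.
"""

from sedrl.agent import AgentConfig
from sedrl.pipeline import RunConfig, run_synthetic_experiment

config = RunConfig(
    seed=3,
    n_patients=60,
    horizon_h=36,
    agent=AgentConfig(training_steps=4000, batch_size=128),
    gamma_grid=(0.1, 0.7),
    n_eval_patients=40,
    fit_dynamics_model=False,
)
result = run_synthetic_experiment(config, progress=print)

comp = result["comparison"]
print()
print(f"{'':24s} {'learned':>10s} {'clinician':>10s}")
for var in ("SAS", "MAP"):
    l, c = comp["learned"][var], comp["clinician"][var]
    print(f"MPE({var}) %            {l['MPE_pct']:10.1f} {c['MPE_pct']:10.1f}")
    print(f"mean RMSE({var})        {l['mean_RMSE']:10.2f} {c['mean_RMSE']:10.2f}")
print(f"{'mean total dose':24s} {comp['learned']['mean_total_dose']:10.0f} "
      f"{comp['clinician']['mean_total_dose']:10.0f}")
t = comp["tests"]
print(f"Welch p: PE(SAS) {t['SAS']['PE_p']:.3g}, PE(MAP) {t['MAP']['PE_p']:.3g}, "
      f"total dose {t['total_dose']['p']:.3g}")
print()
print("MPE is the mean percentage of ICU hours outside the therapeutic band")
print("(SAS 3-4, MAP 65-85 mmHg); lower is better. The learned policy should")
print("reduce out-of-band time and total medication relative to the logged")
print("clinician behaviour; at this miniature scale the direction is the")
print("point, not the magnitudes.")
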