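"""Performance-error statistics for dosing policies.

A policy (the logged clinicians' behaviour or a learned agent evaluated by
rollout) yields, for every patient, hourly series of the two control
variables SAS and MAP. Per patient and variable:

* PE — the percentage of ICU hours spent outside the therapeutic band,
* RMSE — root mean squared band deviation over the stay,

and across patients MDPE (median PE), MPE (mean PE +/- sd), mean values and
mean doses. Learned-vs-clinician differences are tested with a two-sample
Welch t-test on the per-patient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .reward import RewardConfig, deviation


@dataclass
class ControlSeries:
    """Hourly values of one control variable for one patient."""

    patient_id: object
    variable: str  # "SAS" or "MAP"
    values: np.ndarray
    ltb: float
    utb: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("series must be a non-empty 1-D array")
        if not self.ltb < self.utb:
            raise ValueError("band requires ltb < utb")

    @property
    def n_hours(self) -> int:
        return self.values.size


def performance_error(series: ControlSeries) -> float:
    """PE = (hours outside [ltb, utb]) / total hours * 100 (inclusive band)."""
    in_range = (series.values >= series.ltb) & (series.values <= series.utb)
    n = series.n_hours
    return float((n - int(in_range.sum())) / n * 100.0)


def mdpe(pe_values) -> float:
    """Median performance error across patients."""
    pe = np.asarray(list(pe_values), dtype=float)
    if pe.size == 0:
        raise ValueError("need at least one patient")
    return float(np.median(pe))


def rmse_patient(series: ControlSeries) -> float:
    """Root mean squared band deviation; zero iff every hour is in range."""
    devs = np.array([deviation(v, series.ltb, series.utb) for v in series.values])
    return float(np.sqrt(np.mean(devs**2)))


def compare_policies(sample_a, sample_b, paired: bool = False):
    """Two-sample t-test on per-patient metric vectors; returns (t, p).

    Welch's unequal-variance test by default; ``paired=True`` switches to a
    paired test on matched patients. Degenerate zero-variance samples with
    equal means return (0, 1) by convention.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two patients per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    if paired:
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PolicyPerformanceReport:
    """Per-patient and cohort-level performance of one policy."""

    policy_name: str
    patient_ids: list
    pe: dict = field(default_factory=dict)  # variable -> (n_patients,) PE %
    rmse: dict = field(default_factory=dict)
    mean_value: dict = field(default_factory=dict)  # per-patient mean of the variable
    propofol_per_hour: np.ndarray | None = None
    fentanyl_per_hour: np.ndarray | None = None
    total_dose: np.ndarray | None = None  # per-patient propofol+fentanyl total

    def summary(self) -> dict:
        """Cohort-level table: MDPE, MPE +/- sd, mean RMSE, means, doses."""
        out = {"policy": self.policy_name, "n_patients": len(self.patient_ids)}
        for var in self.pe:
            pe = self.pe[var]
            out[var] = {
                "MPE_pct": float(np.mean(pe)),
                "MPE_sd": float(np.std(pe)),
                "MDPE_pct": mdpe(pe),
                "mean_RMSE": float(np.mean(self.rmse[var])),
                "mean_value": float(np.mean(self.mean_value[var])),
                "sd_value": float(np.std(self.mean_value[var])),
                "time_in_range_pct": float(100.0 - np.mean(pe)),
            }
        if self.propofol_per_hour is not None:
            out["mean_propofol_per_hour"] = float(np.mean(self.propofol_per_hour))
            out["sd_propofol_per_hour"] = float(np.std(self.propofol_per_hour))
            out["mean_fentanyl_per_hour"] = float(np.mean(self.fentanyl_per_hour))
            out["sd_fentanyl_per_hour"] = float(np.std(self.fentanyl_per_hour))
            out["mean_total_dose"] = float(np.mean(self.total_dose))
        return out


def _series_report(name, ids, sas_list, map_list, dose_list, cfg: RewardConfig):
    report = PolicyPerformanceReport(policy_name=name, patient_ids=list(ids))
    bands = {"SAS": (cfg.sas_ltb, cfg.sas_utb), "MAP": (cfg.map_ltb, cfg.map_utb)}
    values = {"SAS": sas_list, "MAP": map_list}
    for var, (lo, hi) in bands.items():
        pes, rmses, means = [], [], []
        for pid, vals in zip(ids, values[var]):
            series = ControlSeries(pid, var, vals, lo, hi)
            pes.append(performance_error(series))
            rmses.append(rmse_patient(series))
            means.append(float(np.mean(series.values)))
        report.pe[var] = np.array(pes)
        report.rmse[var] = np.array(rmses)
        report.mean_value[var] = np.array(means)
    doses = [np.asarray(d, dtype=float) for d in dose_list]
    report.propofol_per_hour = np.array([d[:, 0].mean() for d in doses])
    report.fentanyl_per_hour = np.array([d[:, 1].mean() for d in doses])
    report.total_dose = np.array([d.sum() for d in doses])
    return report


def evaluate_behavior_policy(trajectories, reward_config: RewardConfig | None = None):
    """Score the logged clinician behaviour directly (no rollout)."""
    cfg = reward_config or RewardConfig()
    trajs = list(trajectories)
    return _series_report(
        "clinician",
        [t.subject_id for t in trajs],
        [t.sas for t in trajs],
        [t.map_mmHg for t in trajs],
        [t.doses for t in trajs],
        cfg,
    )


def evaluate_policy_on_cohort(
    policy,
    trajectories,
    rollout_fn,
    reward_config: RewardConfig | None = None,
    name: str = "learned",
):
    """Score a policy by counterfactual rollout from each patient's start.

    ``rollout_fn(policy, trajectory, horizon) -> (sas, map, doses)`` supplies
    the mechanism — the synthetic simulator stepped with the policy's doses,
    or a learned transition model. Each rollout starts at the patient's first
    observed state and is matched to the logged stay length, so per-patient
    metrics are directly comparable with :func:`evaluate_behavior_policy`.
    """
    cfg = reward_config or RewardConfig()
    trajs = list(trajectories)
    sas_list, map_list, dose_list = [], [], []
    for traj in trajs:
        horizon = traj.n_windows - 1
        if horizon < 1:
            raise ValueError(f"subject {traj.subject_id}: stay too short to roll out")
        sas, map_mmHg, doses = rollout_fn(policy, traj, horizon)
        sas, map_mmHg, doses = np.asarray(sas), np.asarray(map_mmHg), np.asarray(doses)
        if len(sas) != traj.n_windows or len(map_mmHg) != traj.n_windows:
            raise ValueError("rollout horizon does not match the logged stay")
        sas_list.append(sas)
        map_list.append(map_mmHg)
        dose_list.append(doses)
    return _series_report(name, [t.subject_id for t in trajs], sas_list, map_list, dose_list, cfg)


def compare_reports(learned: PolicyPerformanceReport, behavior: PolicyPerformanceReport) -> dict:
    """Learned-vs-clinician comparison table with Welch t-tests.

    Tests are run on per-patient PE and RMSE for each control variable and
    on per-patient total dose; negative t favours the learned policy for
    error metrics and dose.
    """
    out = {"learned": learned.summary(), "clinician": behavior.summary(), "tests": {}}
    for var in learned.pe:
        t_pe, p_pe = compare_policies(learned.pe[var], behavior.pe[var])
        t_rm, p_rm = compare_policies(learned.rmse[var], behavior.rmse[var])
        out["tests"][var] = {
            "PE_t": t_pe,
            "PE_p": p_pe,
            "RMSE_t": t_rm,
            "RMSE_p": p_rm,
        }
    t_d, p_d = compare_policies(learned.total_dose, behavior.total_dose)
    out["tests"]["total_dose"] = {"t": t_d, "p": p_d}
    return out
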