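"""Synthetic ICU sedation cohorts with heterogeneous drug sensitivity.

Stands in for a credentialed EHR extract: each simulated patient has a
baseline agitation level, a baseline mean arterial pressure, and per-drug
sensitivities drawn log-normally so that the same dose sedates different
patients by different amounts (interindividual pharmacodynamic variation).
Hour to hour, SAS and MAP mean-revert to their baselines, are pushed down
by propofol (both) and fentanyl (SAS only, weakly), and carry Gaussian
process noise; agitation leaks into heart rate and respiration rate so the
14-feature state is informative about sedation depth without containing
SAS itself. A noisy proportional "clinician" targets the SAS 3-4 band,
with occasional overdose events so the logged data contain both good and
bad actions for off-policy learning.

The generator emits the same long-format observation table the
preprocessing module reads, with configurable missingness, plus the
per-patient parameters so learned policies can be scored by re-simulating
each patient counterfactually.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    DOSE_COLUMNS,
    FEATURE_NAMES,
    MAP_INDEX,
    N_FEATURES,
    SAS_COLUMN,
)

# typical charted values around the calm/cooperative sedation level
_BASELINE_TEMPLATE = {
    "diastolic_bp": 64.0,
    "nibp_mean": 76.0,
    "resp_rate": 20.0,
    "heart_rate": 88.0,
    "spo2": 97.0,
    "arterial_ph": 7.4,
    "peep": 5.0,
    "fio2": 46.0,
    "pao2": 120.0,
    "plateau_pressure": 18.0,
    "mean_airway_pressure": 7.0,
    "map": 85.0,  # replaced per patient
    "age": 68.0,
    "gender": 0.0,
}
_HR_INDEX = FEATURE_NAMES.index("heart_rate")
_RR_INDEX = FEATURE_NAMES.index("resp_rate")
_NIBP_INDEX = FEATURE_NAMES.index("nibp_mean")
_DBP_INDEX = FEATURE_NAMES.index("diastolic_bp")
_AGE_INDEX = FEATURE_NAMES.index("age")
_GENDER_INDEX = FEATURE_NAMES.index("gender")
_STATIC_INDICES = (_AGE_INDEX, _GENDER_INDEX)

#: agitation -> vitals couplings (per SAS point above/below 4); agitation
#: raises heart rate, respiration and blood pressure, mirroring the
#: monotone trend of charted vitals across sedation levels
_HR_PER_SAS = 8.0
_RR_PER_SAS = 2.5
_NIBP_PER_SAS = 3.0
_DBP_PER_SAS = 2.0
_MAP_PER_SAS = 2.0


@dataclass
class SyntheticPatientParams:
    """Baselines and sensitivities driving one simulated patient."""

    patient_id: object
    baseline: np.ndarray  # 14-feature resting vector
    sas_baseline: float  # unsedated agitation set point, in [4, 6]
    map_baseline: float  # mmHg, in [70, 95]
    k_propofol: float  # SAS points lowered per propofol unit per hour
    k_fentanyl: float  # SAS points lowered per fentanyl unit per hour
    h_propofol: float  # mmHg of MAP lowered per propofol unit per hour
    sas_reversion: float = 0.35
    map_reversion: float = 0.3
    feature_reversion: float = 0.8
    sas_noise_sd: float = 0.15
    map_noise_sd: float = 2.5
    feature_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if min(self.k_propofol, self.k_fentanyl, self.h_propofol) <= 0:
            raise ValueError("drug sensitivities must be positive")


@dataclass
class BehaviorPolicyConfig:
    """Noisy proportional clinician targeting the SAS 3-4 band.

    Inside the band both drugs run at maintenance rates; above the band the
    doses ramp proportionally with agitation; below it they taper linearly
    to zero by SAS 2. Hypotension (MAP below band) halves the propofol
    rate. ``overdose_prob`` injects occasional multiplied doses so logged
    behaviour contains failures as well as successes.
    """

    sas_ltb: float = 3.0
    sas_utb: float = 4.0
    map_ltb: float = 65.0
    maintenance_propofol: float = 6.0
    maintenance_fentanyl: float = 4.0
    gain_propofol: float = 4.0
    gain_fentanyl: float = 1.5
    dose_noise_sd: tuple = (2.0, 1.0)
    overdose_prob: float = 0.1
    overdose_factor: float = 2.5
    hypotension_backoff: float = 0.5
    dose_cap: tuple = (30.0, 20.0)
    #: hours between sedation reassessments; infusions run unchanged in
    #: between (zero-order hold), the main source of clinician over/under-
    #: shoot in the logged data
    reassess_interval_h: int = 4

    def __post_init__(self) -> None:
        if min(self.gain_propofol, self.gain_fentanyl) < 0:
            raise ValueError("gains must be >= 0")


def sample_patient(seed: int, patient_id=None) -> SyntheticPatientParams:
    """Draw one patient's baselines and log-normal drug sensitivities."""
    rng = np.random.default_rng(seed)
    sas_baseline = float(rng.uniform(4.0, 6.0))
    map_baseline = float(rng.uniform(70.0, 95.0))
    baseline = np.array([_BASELINE_TEMPLATE[n] for n in FEATURE_NAMES])
    baseline += rng.normal(0.0, 0.03 * np.abs(baseline))
    baseline[MAP_INDEX] = map_baseline
    baseline[_AGE_INDEX] = float(np.clip(rng.normal(68.0, 12.0), 20.0, 95.0))
    baseline[_GENDER_INDEX] = float(rng.integers(0, 2))
    return SyntheticPatientParams(
        patient_id=patient_id if patient_id is not None else seed,
        baseline=baseline,
        sas_baseline=sas_baseline,
        map_baseline=map_baseline,
        k_propofol=float(rng.lognormal(np.log(0.05), 0.4)),
        k_fentanyl=float(rng.lognormal(np.log(0.035), 0.4)),
        h_propofol=float(rng.lognormal(np.log(0.25), 0.3)),
    )


def step_patient(params: SyntheticPatientParams, state, sas, map_mmHg, action, rng):
    """Advance one hour: mean reversion + dose effects + noise.

    Returns ``(next_state, next_sas, next_map)``; SAS is clipped to [1, 7],
    MAP floored at 30 mmHg. ``rng=None`` gives the noise-free skeleton.
    """
    prop, fent = float(action[0]), float(action[1])
    if prop < 0 or fent < 0:
        raise ValueError("doses must be non-negative")
    noise = (lambda sd, n=None: rng.normal(0.0, sd, n) if rng is not None else (0.0 if n is None else np.zeros(n)))

    sas_next = (
        sas
        + params.sas_reversion * (params.sas_baseline - sas)
        - params.k_propofol * prop
        - params.k_fentanyl * fent
        + noise(params.sas_noise_sd)
    )
    sas_next = float(np.clip(sas_next, 1.0, 7.0))
    map_target = params.map_baseline + _MAP_PER_SAS * (sas_next - 4.0)
    map_next = (
        map_mmHg
        + params.map_reversion * (map_target - map_mmHg)
        - params.h_propofol * prop
        + noise(params.map_noise_sd)
    )
    map_next = float(max(map_next, 30.0))

    state = np.asarray(state, dtype=float)
    target = params.baseline.copy()
    # agitation leaks into heart rate, respiration and blood pressure
    target[_HR_INDEX] += _HR_PER_SAS * (sas_next - 4.0)
    target[_RR_INDEX] += _RR_PER_SAS * (sas_next - 4.0)
    target[_NIBP_INDEX] += _NIBP_PER_SAS * (sas_next - 4.0)
    target[_DBP_INDEX] += _DBP_PER_SAS * (sas_next - 4.0)
    next_state = state + params.feature_reversion * (target - state) + noise(
        params.feature_noise_sd * np.maximum(np.abs(params.baseline) * 0.02, 0.05), N_FEATURES
    )
    next_state[_STATIC_INDICES,] = params.baseline[_STATIC_INDICES,]
    next_state[MAP_INDEX] = map_next
    return next_state, sas_next, map_next


def clinician_behavior(sas, map_mmHg, config: BehaviorPolicyConfig, rng) -> np.ndarray:
    """Noisy band-targeting dose action (propofol, fentanyl)."""
    cfg = config
    if sas > cfg.sas_utb:
        prop = cfg.maintenance_propofol + cfg.gain_propofol * (sas - cfg.sas_utb)
        fent = cfg.maintenance_fentanyl + cfg.gain_fentanyl * (sas - cfg.sas_utb)
    elif sas < cfg.sas_ltb:
        taper = max(0.0, sas - (cfg.sas_ltb - 1.0))  # linear to zero one point below band
        prop = cfg.maintenance_propofol * taper
        fent = cfg.maintenance_fentanyl * taper
    else:
        prop = cfg.maintenance_propofol
        fent = cfg.maintenance_fentanyl
    if map_mmHg < cfg.map_ltb:
        prop *= cfg.hypotension_backoff
    if rng is not None:
        prop += rng.normal(0.0, cfg.dose_noise_sd[0])
        fent += rng.normal(0.0, cfg.dose_noise_sd[1])
        if rng.uniform() < cfg.overdose_prob:
            factor = cfg.overdose_factor
            prop *= factor
            fent *= factor
    return np.clip(np.array([prop, fent]), 0.0, np.asarray(cfg.dose_cap))


@dataclass
class CohortGeneratorConfig:
    """Knobs for the synthetic cohort emitter."""

    behavior: BehaviorPolicyConfig = field(default_factory=BehaviorPolicyConfig)
    feature_missingness: float = 0.05
    sas_missingness: float = 0.02
    record_integer_sas: bool = True  # chart SAS as the ordinal level


def generate_cohort(
    n_patients: int,
    horizon_h: int,
    seed: int,
    config: CohortGeneratorConfig | None = None,
):
    """Simulate a cohort under the clinician behaviour policy.

    Returns ``(observations, params_by_id)``: a long-format table
    (``subject_id, time_h, variable, value``) with injected missingness,
    and each patient's simulator parameters keyed by subject id.
    """
    if n_patients < 1 or horizon_h < 2:
        raise ValueError("need n_patients >= 1 and horizon_h >= 2")
    cfg = config or CohortGeneratorConfig()
    root = np.random.default_rng(seed)
    patient_seeds = root.integers(2**31, size=n_patients)
    rows = []
    params_by_id = {}
    for i in range(n_patients):
        pid = f"P{i:04d}"
        params = sample_patient(int(patient_seeds[i]), patient_id=pid)
        params_by_id[pid] = params
        rng = np.random.default_rng(int(patient_seeds[i]) + 1)
        state = params.baseline + rng.normal(0.0, 0.02 * np.abs(params.baseline))
        sas = float(np.clip(params.sas_baseline + rng.normal(0.0, 0.3), 1.0, 7.0))
        map_mmHg = float(params.map_baseline + rng.normal(0.0, 2.0))
        state[MAP_INDEX] = map_mmHg
        action = None
        hold = max(1, int(cfg.behavior.reassess_interval_h))
        for t in range(horizon_h):
            time = t + 0.5
            charted_sas = round(sas) if cfg.record_integer_sas else sas
            if rng.uniform() >= cfg.sas_missingness:
                rows.append((pid, time, SAS_COLUMN, float(charted_sas)))
            for j, name in enumerate(FEATURE_NAMES):
                if rng.uniform() >= cfg.feature_missingness:
                    rows.append((pid, time, name, float(state[j])))
            # infusion rates are only revisited at reassessment times and
            # run unchanged (zero-order hold) in between
            if action is None or t % hold == 0:
                action = clinician_behavior(sas, map_mmHg, cfg.behavior, rng)
            rows.append((pid, time, DOSE_COLUMNS[0], float(action[0])))
            rows.append((pid, time, DOSE_COLUMNS[1], float(action[1])))
            state, sas, map_mmHg = step_patient(params, state, sas, map_mmHg, action, rng)
    observations = pd.DataFrame(rows, columns=["subject_id", "time_h", "variable", "value"])
    return observations, params_by_id


class SedationSimulator:
    """Stateful wrapper over :func:`step_patient` for one patient.

    Exposes the rollout contract the evaluation and model-based training
    paths expect: ``reset`` to an initial condition, ``step`` with a raw
    dose action, and direct readouts of SAS and MAP.
    """

    def __init__(self, params: SyntheticPatientParams, rng):
        self.params = params
        self.rng = rng
        self.state = None
        self.sas = None
        self.map_mmHg = None

    def reset(self, state=None, sas=None, map_mmHg=None):
        p = self.params
        self.state = np.array(p.baseline if state is None else state, dtype=float)
        self.sas = float(p.sas_baseline if sas is None else sas)
        self.map_mmHg = float(p.map_baseline if map_mmHg is None else map_mmHg)
        self.state[MAP_INDEX] = self.map_mmHg
        return self.state.copy()

    def step(self, action):
        self.state, self.sas, self.map_mmHg = step_patient(
            self.params, self.state, self.sas, self.map_mmHg, action, self.rng
        )
        return self.state.copy(), self.sas, self.map_mmHg


class SedationEnv:
    """Episodic training environment over a population of simulated patients.

    Adapter for the agent's model-based mode: ``reset`` draws a patient and
    returns the z-normalized state; ``step`` applies a raw dose action and
    returns ``(next_state, reward, done)`` with the same outcome-window
    gated reward used for logged transitions. Episodes run for a fixed
    horizon.
    """

    def __init__(self, params_list, stats, reward_config=None, horizon: int = 48, seed: int = 0):
        from .reward import RewardConfig, breakdown_window, compute_reward, deviation, window_error

        self._reward_mod = (breakdown_window, compute_reward, deviation, window_error)
        self.params_list = list(params_list)
        self.stats = stats
        self.reward_config = reward_config or RewardConfig()
        self.horizon = horizon
        self.rng = np.random.default_rng(seed)
        self.dose_max = np.array([30.0, 20.0])
        self._sim = None
        self._t = 0
        self._prev_error = None

    def _error(self, sas, map_mmHg):
        _, _, deviation, window_error = self._reward_mod
        cfg = self.reward_config
        return window_error(
            deviation(map_mmHg, cfg.map_ltb, cfg.map_utb),
            deviation(float(np.clip(sas, 1, 7)), cfg.sas_ltb, cfg.sas_utb),
            signed=cfg.signed_error,
        )

    def reset(self):
        params = self.params_list[self.rng.integers(len(self.params_list))]
        self._sim = SedationSimulator(params, self.rng)
        self._sim.reset(
            sas=float(np.clip(params.sas_baseline + self.rng.normal(0, 0.3), 1, 7)),
            map_mmHg=params.map_baseline + self.rng.normal(0, 2.0),
        )
        self._t = 0
        self._prev_error = self._error(self._sim.sas, self._sim.map_mmHg)
        return self.stats.transform(self._sim.state)

    def step(self, action):
        breakdown_window, compute_reward, *_ = self._reward_mod
        _, sas, map_mmHg = self._sim.step(np.asarray(action, dtype=float))
        bd = breakdown_window(
            float(np.clip(sas, 1, 7)), map_mmHg, float(action[0]), float(action[1]),
            self.reward_config,
        )
        reward = compute_reward(bd, error_prev=self._prev_error, config=self.reward_config)
        self._prev_error = bd.error_t
        self._t += 1
        return self.stats.transform(self._sim.state), reward, self._t >= self.horizon


def make_simulator_rollout_fn(params_by_id, stats, seed: int, chart_sas: bool = True):
    """Rollout mechanism for :func:`sedrl.evaluation.evaluate_policy_on_cohort`.

    Re-simulates each patient with their true generative parameters,
    starting from the first logged window, feeding the policy the
    z-normalized state exactly as in training. Policies take the normalized
    14-vector and return raw (propofol, fentanyl) doses. ``chart_sas``
    records the rounded ordinal SAS level, matching how the logged cohort
    charts sedation, so rollout and logged series are scored identically.
    """

    def rollout_fn(policy, trajectory, horizon):
        params = params_by_id[trajectory.subject_id]
        # process-stable per-patient stream (str hash() is salted per process)
        patient_key = zlib.crc32(str(trajectory.subject_id).encode())
        rng = np.random.default_rng((seed, patient_key))
        sim = SedationSimulator(params, rng)
        raw0 = stats.inverse_transform(trajectory.features[0])
        sim.reset(state=raw0, sas=trajectory.sas[0], map_mmHg=trajectory.map_mmHg[0])
        chart = (lambda s: float(round(s))) if chart_sas else float
        sas_trace = [chart(sim.sas)]
        map_trace = [sim.map_mmHg]
        doses = []
        for _ in range(horizon):
            s_norm = stats.transform(sim.state)
            a = np.asarray(policy(s_norm), dtype=float)
            doses.append(a)
            sim.step(a)
            sas_trace.append(chart(sim.sas))
            map_trace.append(sim.map_mmHg)
        return np.array(sas_trace), np.array(map_trace), np.array(doses)

    return rollout_fn
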