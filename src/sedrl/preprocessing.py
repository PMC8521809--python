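"""Hourly windowing, imputation, normalization and subject-level splits.

Raw input is a long table of timestamped observations per subject
(``subject_id, time_h, variable, value``) or an equivalent wide table with
one row per subject-hour. The pipeline is:

1. ``window_hourly`` — bin each subject's stay into contiguous half-open
   hourly windows [t, t+1), averaging repeated recordings of a variable
   within a window. Doses with no recording are zero (no administration);
   state features with no recording are missing.
2. ``fill_missing`` — drop windows where every state measure, or the SAS
   outcome, is missing; then sample-and-hold (carry the last observed value
   forward) and fall back to training-set means for leading gaps.
3. ``fit_apply_normalizer`` — z-score all continuous features using
   statistics from training subjects only (population variance convention).
   Raw SAS, MAP and doses are retained unscaled for reward and evaluation.
4. ``split_cohort`` — deterministic subject-level 60/20/20 partition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    ALL_VARIABLES,
    CONTINUOUS_INDICES,
    DOSE_COLUMNS,
    FEATURE_NAMES,
    N_FEATURES,
    MAP_INDEX,
    SAS_COLUMN,
)


@dataclass(frozen=True)
class RawObservation:
    """One timestamped recording of a single variable for one subject."""

    subject_id: object
    time: float  # hours from admission, >= 0
    variable: str
    value: float


@dataclass
class PatientTrajectory:
    """Ordered hourly windows of state, doses, SAS and MAP for one ICU stay.

    ``features`` is (T, 14); NaN marks a missing value before imputation.
    ``map_mmHg`` is an unnormalized copy of mean arterial pressure kept for
    reward and evaluation after the state is z-scored.
    """

    subject_id: object
    features: np.ndarray
    sas: np.ndarray
    doses: np.ndarray
    map_mmHg: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.sas = np.asarray(self.sas, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (T, {N_FEATURES})")
        t = self.features.shape[0]
        if t < 1:
            raise ValueError("trajectory must contain at least one window")
        if self.sas.shape != (t,) or self.doses.shape != (t, 2):
            raise ValueError("sas/doses shapes inconsistent with features")
        if np.nanmin(self.doses) < 0:
            raise ValueError("doses must be non-negative")
        if self.map_mmHg is not None:
            self.map_mmHg = np.asarray(self.map_mmHg, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.features.shape[0]

    @property
    def icu_duration_h(self) -> int:
        return self.n_windows

    @property
    def sas_rounded(self) -> np.ndarray:
        """SAS per window rounded to the nearest integer level (band logic)."""
        return np.clip(np.rint(self.sas), 1, 7)


@dataclass
class NormalizationStats:
    """Per-feature train-split mean/std; binary features are passed through."""

    mean: np.ndarray
    std: np.ndarray
    scaled_indices: tuple[int, ...] = CONTINUOUS_INDICES

    def transform(self, features: np.ndarray) -> np.ndarray:
        out = np.array(features, dtype=float, copy=True)
        idx = list(self.scaled_indices)
        out[..., idx] = (out[..., idx] - self.mean[idx]) / self.std[idx]
        return out

    def inverse_transform(self, features: np.ndarray) -> np.ndarray:
        out = np.array(features, dtype=float, copy=True)
        idx = list(self.scaled_indices)
        out[..., idx] = out[..., idx] * self.std[idx] + self.mean[idx]
        return out

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "scaled_indices": list(self.scaled_indices),
            "feature_names": list(FEATURE_NAMES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            scaled_indices=tuple(d["scaled_indices"]),
        )


@dataclass
class CohortSplit:
    """Disjoint subject-level train/validation/test id sets."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split ids must be pairwise disjoint")

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
        }


def window_hourly(observations, subject_id=None) -> PatientTrajectory:
    """Bin one subject's raw observations into hourly mean windows.

    ``observations`` is a sequence of :class:`RawObservation` or a long-format
    DataFrame with columns ``time_h, variable, value`` (and optionally
    ``subject_id``). Window t covers [t, t+1); a variable's window value is
    the arithmetic mean of its recordings in that interval. Missing state
    features and SAS are NaN; missing doses are 0.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations
        if subject_id is None and "subject_id" in df.columns:
            ids = df["subject_id"].unique()
            if len(ids) != 1:
                raise ValueError("DataFrame must contain exactly one subject")
            subject_id = ids[0]
        times = df["time_h"].to_numpy(dtype=float)
        variables = df["variable"].to_numpy()
        values = df["value"].to_numpy(dtype=float)
    else:
        obs = list(observations)
        if subject_id is None and obs:
            subject_id = obs[0].subject_id
        times = np.array([o.time for o in obs], dtype=float)
        variables = np.array([o.variable for o in obs])
        values = np.array([o.value for o in obs], dtype=float)

    if times.size == 0:
        raise ValueError("cannot window an empty observation list")
    if np.any(times < 0):
        raise ValueError("observation times must be >= 0")
    unknown = set(variables) - set(ALL_VARIABLES)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")

    n_windows = int(math.floor(times.max())) + 1
    features = np.full((n_windows, N_FEATURES), np.nan)
    sas = np.full(n_windows, np.nan)
    doses = np.zeros((n_windows, 2))

    hour = np.floor(times).astype(int)
    frame = pd.DataFrame({"hour": hour, "variable": variables, "value": values})
    means = frame.groupby(["hour", "variable"])["value"].mean()
    feat_idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
    dose_idx = {name: j for j, name in enumerate(DOSE_COLUMNS)}
    for (h, var), v in means.items():
        if var == SAS_COLUMN:
            sas[h] = v
        elif var in dose_idx:
            doses[h, dose_idx[var]] = v
        else:
            features[h, feat_idx[var]] = v
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    return PatientTrajectory(subject_id=subject_id, features=features, sas=sas, doses=doses)


def compute_training_means(trajectories) -> np.ndarray:
    """Per-feature mean over all observed (non-missing) training windows."""
    stacked = np.concatenate([t.features for t in trajectories], axis=0)
    if stacked.size == 0:
        raise ValueError("no training windows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(stacked, axis=0)
    return means


def fill_missing(trajectory: PatientTrajectory, training_means) -> PatientTrajectory:
    """Drop uninformative windows, then sample-and-hold + mean imputation.

    Windows where all 14 state measures are missing, or the SAS outcome is
    missing, are removed first and the remaining windows re-indexed
    contiguously. Each remaining gap takes the most recent prior value of
    the same feature; leading gaps take the training-split mean.
    """
    means = np.asarray(training_means, dtype=float)
    if means.shape != (N_FEATURES,):
        raise ValueError(f"training_means must provide all {N_FEATURES} features")
    if np.any(np.isnan(means)):
        missing = [FEATURE_NAMES[i] for i in np.flatnonzero(np.isnan(means))]
        raise ValueError(f"training_means missing features: {missing}")

    keep = ~(np.all(np.isnan(trajectory.features), axis=1) | np.isnan(trajectory.sas))
    if not keep.any():
        raise ValueError(f"subject {trajectory.subject_id}: no informative windows remain")
    feats = trajectory.features[keep].copy()
    sas = trajectory.sas[keep].copy()
    doses = trajectory.doses[keep].copy()

    # sample-and-hold per feature, training-mean fallback for leading gaps
    df = pd.DataFrame(feats).ffill()
    df = df.fillna(pd.Series(means))
    feats = df.to_numpy()
    return PatientTrajectory(
        subject_id=trajectory.subject_id,
        features=feats,
        sas=sas,
        doses=doses,
        map_mmHg=feats[:, MAP_INDEX].copy(),
    )


def fit_apply_normalizer(train_trajectories, all_trajectories):
    """Fit per-feature z-scaling on training windows; apply everywhere.

    Returns ``(NormalizationStats, list of normalized trajectories)`` in the
    order of ``all_trajectories``. Uses the population (divide by n) variance
    convention. Zero-variance features trigger a warning and are scaled by 1.
    The binary gender feature is never scaled.
    """
    train = list(train_trajectories)
    if not train:
        raise ValueError("training trajectories must be non-empty")
    stacked = np.concatenate([t.features for t in train], axis=0)
    if np.any(np.isnan(stacked)):
        raise ValueError("normalizer requires imputed trajectories")
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)  # population convention
    constant = np.flatnonzero(std == 0)
    constant = [i for i in constant if i in CONTINUOUS_INDICES]
    if constant:
        warnings.warn(
            f"zero-variance features scaled by 1: {[FEATURE_NAMES[i] for i in constant]}",
            stacklevel=2,
        )
        std = std.copy()
        std[constant] = 1.0
    std = np.where(std == 0, 1.0, std)
    stats = NormalizationStats(mean=mean, std=std)

    normalized = []
    for traj in all_trajectories:
        if traj.map_mmHg is None:
            map_raw = traj.features[:, MAP_INDEX].copy()
        else:
            map_raw = traj.map_mmHg.copy()
        normalized.append(
            replace(
                traj,
                features=stats.transform(traj.features),
                map_mmHg=map_raw,
                normalized=True,
            )
        )
    return stats, normalized


def split_cohort(subject_ids, seed: int) -> CohortSplit:
    """Deterministic subject-level split, sizes round(0.2 n) for val/test.

    The remainder goes to training, matching 60/20/20 within one subject.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(0.2 * n))
    n_test = int(round(0.2 * n))
    n_train = n - n_val - n_test
    shuffled = [ids[i] for i in order]
    return CohortSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
    )


# ---------------------------------------------------------------------------
# cohort-level convenience + CSV round trip


@dataclass
class PreprocessedCohort:
    """Fully preprocessed cohort: normalized trajectories + split + stats."""

    trajectories: dict
    split: CohortSplit
    stats: NormalizationStats
    training_means: np.ndarray = field(repr=False, default=None)

    def subset(self, ids):
        return [self.trajectories[i] for i in ids if i in self.trajectories]


def preprocess_cohort(raw: pd.DataFrame, seed: int) -> PreprocessedCohort:
    """Run the full windowing/imputation/normalization/split pipeline.

    ``raw`` is a long-format table (``subject_id, time_h, variable, value``)
    covering the whole cohort. Training means and scaling statistics are
    computed on the training split only.
    """
    if {"subject_id", "time_h", "variable", "value"} - set(raw.columns):
        raise ValueError("expected long format columns subject_id,time_h,variable,value")
    windowed = {
        sid: window_hourly(group, subject_id=sid)
        for sid, group in raw.groupby("subject_id", sort=True)
    }
    split = split_cohort(sorted(windowed), seed=seed)
    training_means = compute_training_means([windowed[i] for i in split.train_ids])
    filled = {sid: fill_missing(t, training_means) for sid, t in windowed.items()}
    order = sorted(filled)
    stats, normed = fit_apply_normalizer(
        [filled[i] for i in split.train_ids], [filled[i] for i in order]
    )
    return PreprocessedCohort(
        trajectories=dict(zip(order, normed)),
        split=split,
        stats=stats,
        training_means=training_means,
    )


def read_observations_csv(path) -> pd.DataFrame:
    """Read a cohort observation table, auto-detecting long vs wide layout."""
    df = pd.read_csv(path)
    if "variable" in df.columns:
        return df
    # wide: one row per subject-hour, melt into long
    id_cols = [c for c in ("subject_id", "time_h") if c in df.columns]
    if len(id_cols) != 2:
        raise ValueError("wide format requires subject_id and time_h columns")
    value_cols = [c for c in df.columns if c in ALL_VARIABLES]
    long = df.melt(id_vars=id_cols, value_vars=value_cols, var_name="variable")
    return long.dropna(subset=["value"]).reset_index(drop=True)


def write_preprocessed(cohort: PreprocessedCohort, csv_path, sidecar_path) -> None:
    """Write wide-format CSV of trajectories + JSON sidecar (stats, split)."""
    rows = []
    for sid in sorted(cohort.trajectories):
        traj = cohort.trajectories[sid]
        for t in range(traj.n_windows):
            row = {"subject_id": sid, "hour": t}
            row.update(dict(zip(FEATURE_NAMES, traj.features[t])))
            row[SAS_COLUMN] = traj.sas[t]
            row["map_raw"] = traj.map_mmHg[t]
            row[DOSE_COLUMNS[0]] = traj.doses[t, 0]
            row[DOSE_COLUMNS[1]] = traj.doses[t, 1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    sidecar = {"normalization": cohort.stats.to_dict(), "split": cohort.split.to_dict()}
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
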