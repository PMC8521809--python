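"""One-step patient-state transition model s_{t+1} = f(s_t, a_t).

A three-layer fully connected network (ReLU on the two hidden layers,
linear output, optional batch normalization) maps the concatenated
normalized state and dose action to the next normalized state. Internally
the network predicts the state *delta* and adds the current state back;
vitals change slowly hour to hour, so learning the residual is better
conditioned while the external contract is unchanged.

The fitted model backs counterfactual rollouts of a dosing policy: starting
from a patient's first observed state, policy actions and model predictions
alternate, and per-step SAS/MAP are read from the de-normalized predicted
state for reward and performance-error scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import MAP_INDEX, N_FEATURES
from .nets import MLP, Adam
from .preprocessing import NormalizationStats, PatientTrajectory


@dataclass
class TransitionDataset:
    """Consecutive-window (state+action -> next state) pairs, per subject."""

    inputs: np.ndarray  # (n, 16)
    targets: np.ndarray  # (n, 14)
    subject_ids: np.ndarray  # (n,)

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class DynamicsModelConfig:
    hidden: tuple[int, int] = (64, 64)
    batch_norm: bool = True
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 150
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class DynamicsModel:
    """Trained transition network plus training diagnostics."""

    net: MLP
    config: DynamicsModelConfig
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)


def build_transition_dataset(trajectories) -> TransitionDataset:
    """Pair consecutive windows within each trajectory.

    A patient with T windows contributes exactly T-1 pairs; pairs never
    cross patients, and single-window stays contribute nothing.
    """
    xs, ys, ids = [], [], []
    for traj in trajectories:
        if traj.n_windows < 2:
            continue
        s = traj.features
        a = traj.doses
        xs.append(np.concatenate([s[:-1], a[:-1]], axis=1))
        ys.append(s[1:])
        ids.append(np.full(traj.n_windows - 1, traj.subject_id, dtype=object))
    if not xs:
        return TransitionDataset(
            inputs=np.empty((0, N_FEATURES + 2)),
            targets=np.empty((0, N_FEATURES)),
            subject_ids=np.empty(0, dtype=object),
        )
    return TransitionDataset(
        inputs=np.concatenate(xs), targets=np.concatenate(ys), subject_ids=np.concatenate(ids)
    )


def fit_dynamics(dataset: TransitionDataset, config: DynamicsModelConfig | None = None) -> DynamicsModel:
    """Minimise mean squared one-step prediction error by minibatch Adam.

    A tail fraction of the (shuffled) pairs is held out for the per-epoch
    validation curve. Training aborts with a diagnostic if the loss goes
    non-finite. Fully reproducible given ``config.seed``.
    """
    cfg = config or DynamicsModelConfig()
    if len(dataset) == 0:
        raise ValueError("transition dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    net = MLP(
        (N_FEATURES + 2, *cfg.hidden, N_FEATURES),
        rng=rng,
        batch_norm=cfg.batch_norm,
    )
    # near-zero residual head: the initial model is the persistence
    # baseline s' = s, which training then improves on
    last_linear = [l for l in net.layers if hasattr(l, "W")][-1]
    last_linear.W *= 1e-2
    opt = Adam(net.params, lr=cfg.lr)

    n = len(dataset)
    subjects = np.unique(dataset.subject_ids)
    if len(subjects) > 1:
        # subject-level holdout: validation pairs come from unseen patients
        held = rng.permutation(subjects)[: max(1, int(cfg.val_fraction * len(subjects)))]
        val_mask = np.isin(dataset.subject_ids, held)
        val_idx = np.flatnonzero(val_mask)
        train_idx = np.flatnonzero(~val_mask)
    else:
        order = rng.permutation(n)
        n_val = int(cfg.val_fraction * n)
        val_idx, train_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = dataset.inputs[train_idx], dataset.targets[train_idx]
    x_va, y_va = dataset.inputs[val_idx], dataset.targets[val_idx]
    # residual targets: predict s' - s
    d_tr = y_tr - x_tr[:, :N_FEATURES]
    d_va = y_va - x_va[:, :N_FEATURES]

    model = DynamicsModel(net=net, config=cfg)
    n_tr = x_tr.shape[0]
    best = None  # (val loss, parameter snapshot)
    if len(x_va):
        # score the untrained model (~persistence) so training can only improve
        init_err = net.forward(x_va, training=False) - d_va
        best = (float(np.mean(init_err**2)), net.copy())
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, db = x_tr[idx], d_tr[idx]
            pred = net.forward(xb, training=True)
            err = pred - db
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"dynamics training diverged at epoch {epoch} (loss={loss})"
                )
            net.backward(2.0 * err / err.size)
            opt.step(net.grads)
            losses.append(loss)
        model.train_losses.append(float(np.mean(losses)))
        if len(x_va):
            val_err = net.forward(x_va, training=False) - d_va
            val_loss = float(np.mean(val_err**2))
            model.val_losses.append(val_loss)
            if best is None or val_loss < best[0]:
                best = (val_loss, net.copy())
    if best is not None:
        # keep the best-generalizing epoch, not the last one
        model.net = best[1]
    return model


def predict_next_state(model: DynamicsModel, state: np.ndarray, action: np.ndarray) -> np.ndarray:
    """Deterministic one-step prediction in inference mode.

    Accepts a single (14,)/(2,) pair or batches (n, 14)/(n, 2); the output
    shape mirrors the input.
    """
    s = np.asarray(state, dtype=float)
    a = np.asarray(action, dtype=float)
    single = s.ndim == 1
    s2, a2 = np.atleast_2d(s), np.atleast_2d(a)
    if s2.shape[1] != N_FEATURES or a2.shape[1] != 2 or s2.shape[0] != a2.shape[0]:
        raise ValueError(f"expected (n,{N_FEATURES}) states and (n,2) actions")
    if not (np.all(np.isfinite(s2)) and np.all(np.isfinite(a2))):
        raise ValueError("state/action must be finite")
    delta = model.net.forward(np.concatenate([s2, a2], axis=1), training=False)
    out = s2 + delta
    return out[0] if single else out


@dataclass
class SasReadout:
    """Linear map from raw (de-normalized) state features to SAS.

    SAS is charted alongside the 14 state features but is not itself part of
    the state vector, so model-based rollouts need a readout to score the
    sedation band. Ordinary least squares with intercept is enough: agitation
    is encoded in the simulator (and plausibly in real vitals) through heart
    rate / respiration shifts that a linear probe recovers.
    """

    coef: np.ndarray  # (14,)
    intercept: float

    def __call__(self, raw_state: np.ndarray) -> float:
        value = float(np.asarray(raw_state, dtype=float) @ self.coef + self.intercept)
        return float(np.clip(value, 1.0, 7.0))


def fit_sas_readout(trajectories, stats: NormalizationStats) -> SasReadout:
    """Least-squares SAS probe on the raw features of training windows."""
    xs, ys = [], []
    for traj in trajectories:
        feats = stats.inverse_transform(traj.features) if traj.normalized else traj.features
        xs.append(feats)
        ys.append(traj.sas)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    design = np.column_stack([x, np.ones(len(x))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return SasReadout(coef=beta[:-1], intercept=float(beta[-1]))


@dataclass
class Rollout:
    """Simulated trajectory under a policy and a transition model."""

    states: np.ndarray  # (horizon+1, 14) normalized
    actions: np.ndarray  # (horizon, 2) raw dose units
    sas: np.ndarray  # (horizon+1,) de-normalized
    map_mmHg: np.ndarray  # (horizon+1,)
    truncated: bool = False


def rollout(
    model,
    policy,
    s0: np.ndarray,
    horizon: int,
    stats: NormalizationStats,
    sas_fn=None,
) -> Rollout:
    """Iterate a_t = policy(s_t), s_{t+1} = model prediction for ``horizon`` steps.

    ``model`` is anything with the :func:`predict_next_state` contract — the
    trained network (pass the :class:`DynamicsModel`) or an adapter over the
    synthetic simulator. MAP is de-normalized from the predicted state via
    ``stats``; SAS is not part of the 14-feature state, so a caller who wants
    a SAS trace supplies ``sas_fn(state_raw) -> sas`` (e.g. the simulator's
    readout or a proxy decoder); otherwise NaN is recorded.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    s = np.asarray(s0, dtype=float).copy()
    states = [s.copy()]
    actions = []
    sas_trace = []
    map_trace = []
    truncated = False

    def readout(state_norm):
        raw = stats.inverse_transform(state_norm)
        map_trace.append(float(raw[MAP_INDEX]))
        sas_trace.append(float(sas_fn(raw)) if sas_fn is not None else np.nan)

    readout(s)
    for _ in range(horizon):
        a = np.asarray(policy(s), dtype=float)
        actions.append(a)
        if isinstance(model, DynamicsModel):
            s = predict_next_state(model, s, a)
        else:
            s = np.asarray(model.predict_next_state(s, a), dtype=float)
        if not np.all(np.isfinite(s)):
            truncated = True
            break
        states.append(s.copy())
        readout(s)
    return Rollout(
        states=np.asarray(states),
        actions=np.asarray(actions),
        sas=np.asarray(sas_trace),
        map_mmHg=np.asarray(map_trace),
        truncated=truncated,
    )
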