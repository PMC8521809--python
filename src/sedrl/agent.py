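"""Four-network DDPG learner with prioritized replay for two-drug dosing.

The actor maps the normalized 14-feature patient state to a continuous
propofol/fentanyl action; the critic scores state-action pairs; slowly
tracking target copies of both stabilise the temporal-difference targets.
Training is off-policy: by default the replay buffer is seeded exclusively
with logged clinician transitions (offline mode), so the agent studies the
successes and failures of the behaviour policy without interacting with a
patient. A model-based mode that rolls out through a transition model (or
the synthetic simulator) with exploration noise is available as well.

Internally actions are squashed to [0, 1] per drug by the actor's sigmoid
output and scaled by ``dose_max`` (the 99th percentile of training doses);
the replay buffer and all public interfaces use raw dose units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import N_FEATURES
from .nets import MLP, Adam, soft_update
from .replay import PrioritizedBuffer, TransitionRecord
from .reward import RewardConfig, breakdown_window, compute_reward, deviation, window_error


@dataclass
class AgentConfig:
    """Hyperparameters for the DDPG + PER learner.

    The discount gamma defaults to 1e-3 — an almost myopic setting selected
    on validation performance in the source analysis; it weights the
    immediate windowed reward far above future ones and is freely
    configurable.
    """

    gamma: float = 1e-3
    actor_hidden: tuple = (64, 64)
    critic_hidden: tuple = (64, 64)
    actor_lr: float = 1e-4
    critic_lr: float = 1e-3
    soft_update_coeff: float = 5e-3
    noise_type: str = "gaussian"  # or "ou"
    noise_scale: float = 0.2  # fraction of dose_max
    noise_final: float = 0.02
    replay_capacity: int = 100_000
    batch_size: int = 64
    per_alpha: float = 0.6
    per_beta0: float = 0.4
    per_beta_final: float = 1.0
    priority_floor: float = 1e-3
    training_steps: int = 30_000
    dose_max: tuple | None = None  # per-drug caps; inferred from data if None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.per_alpha < 0 or self.per_beta0 < 0:
            raise ValueError("PER exponents must be >= 0")
        if self.replay_capacity < self.batch_size:
            raise ValueError("replay capacity must cover one batch")


@dataclass
class TrainingLog:
    """Per-update-step diagnostics plus periodic evaluation snapshots."""

    critic_loss: list = field(default_factory=list)
    actor_objective: list = field(default_factory=list)
    batch_reward: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "critic_loss": self.critic_loss,
            "actor_objective": self.actor_objective,
            "batch_reward": self.batch_reward,
            "snapshots": self.snapshots,
        }


class DDPGAgent:
    """Actor/critic pair with target copies and a prioritized buffer."""

    def __init__(self, config: AgentConfig, dose_max=None):
        self.config = config
        dm = dose_max if dose_max is not None else config.dose_max
        if dm is None:
            raise ValueError("dose_max must be provided (config or argument)")
        self.dose_max = np.asarray(dm, dtype=float)
        if self.dose_max.shape != (2,) or np.any(self.dose_max <= 0):
            raise ValueError("dose_max must be two positive caps")
        self.rng = np.random.default_rng(config.seed)
        self.actor = MLP((N_FEATURES, *config.actor_hidden, 2), rng=self.rng, output_activation="sigmoid")
        self.critic = MLP((N_FEATURES + 2, *config.critic_hidden, 1), rng=self.rng)
        # near-zero final layers: actor starts near mid-range doses with live
        # gradients instead of saturated sigmoid corners
        for net in (self.actor, self.critic):
            last = [l for l in net.layers if hasattr(l, "W")][-1]
            last.W *= 1e-2
        self.actor_target = self.actor.copy()
        self.critic_target = self.critic.copy()
        self.actor_opt = Adam(self.actor.params, lr=config.actor_lr)
        self.critic_opt = Adam(self.critic.params, lr=config.critic_lr)
        self.buffer = PrioritizedBuffer(
            capacity=config.replay_capacity,
            alpha=config.per_alpha,
            priority_floor=config.priority_floor,
            seed=int(self.rng.integers(2**31)),
        )
        self._ou_state = np.zeros(2)
        self._step = 0

    # -- acting ------------------------------------------------------------

    def policy(self, state: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode action in raw dose units."""
        unit = self.actor.forward(np.atleast_2d(state), training=False)[0]
        return unit * self.dose_max

    def select_action(self, state: np.ndarray, explore: bool = True) -> np.ndarray:
        """Actor output plus exploration noise, clipped to [0, dose_max]."""
        action = self.policy(state)
        if explore:
            frac = min(self._step / max(self.config.training_steps, 1), 1.0)
            scale = (
                self.config.noise_scale
                + (self.config.noise_final - self.config.noise_scale) * frac
            ) * self.dose_max
            if self.config.noise_type == "ou":
                self._ou_state += 0.15 * (-self._ou_state) + self.rng.normal(0, 1, 2)
                noise = scale * self._ou_state
            else:
                noise = self.rng.normal(0.0, 1.0, size=2) * scale
            action = action + noise
        return np.clip(action, 0.0, self.dose_max)

    # -- updates -----------------------------------------------------------

    def _unit(self, actions: np.ndarray) -> np.ndarray:
        return np.atleast_2d(actions) / self.dose_max

    def critic_td_update(self, records, weights, gamma: float | None = None):
        """Importance-weighted TD regression step; returns (loss, td_errors).

        Targets are y = r + gamma * Q'(s', pi'(s')) with both target
        networks; new priorities are |TD| + floor (written back by the
        caller via the buffer).
        """
        g = self.config.gamma if gamma is None else gamma
        s = np.stack([r.state for r in records])
        a = self._unit(np.stack([r.action for r in records]))
        r = np.array([rec.reward for rec in records])
        s2 = np.stack([rec.next_state for rec in records])
        w = np.asarray(weights, dtype=float)

        a2 = self.actor_target.forward(s2, training=False)
        q2 = self.critic_target.forward(np.concatenate([s2, a2], axis=1), training=False)[:, 0]
        y = r + g * q2
        q = self.critic.forward(np.concatenate([s, a], axis=1), training=True)[:, 0]
        td = q - y
        loss = float(np.mean(w * td**2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"critic TD loss diverged (loss={loss})")
        grad = (2.0 * w * td / len(td))[:, None]
        self.critic.backward(grad)
        self.critic_opt.step(self.critic.grads)
        return loss, td

    def actor_dpg_update(self, states, critic=None) -> float:
        """Deterministic policy-gradient ascent on mean Q(s, pi(s)).

        ``critic`` may be any object with ``value(s, a_unit)`` and
        ``action_gradient(s, a_unit)``; by default the agent's own critic is
        differentiated by backprop. Returns the objective (mean Q).
        """
        s = np.atleast_2d(states)
        n = s.shape[0]
        a_unit = self.actor.forward(s, training=True)
        if critic is None:
            q = self.critic.forward(np.concatenate([s, a_unit], axis=1), training=True)
            objective = float(q.mean())
            if not np.isfinite(objective):
                raise FloatingPointError("actor objective diverged")
            # dQ/da via the critic's input gradient; critic params not stepped
            g_in = self.critic.backward(np.full((n, 1), 1.0 / n))
            g_a = g_in[:, N_FEATURES:]
        else:
            objective = float(np.mean(critic.value(s, a_unit)))
            g_a = critic.action_gradient(s, a_unit) / n
        self.actor.backward(-g_a)  # ascend
        self.actor_opt.step(self.actor.grads)
        return objective

    def soft_update_targets(self, coeff: float | None = None) -> None:
        c = self.config.soft_update_coeff if coeff is None else coeff
        soft_update(self.actor_target, self.actor, c)
        soft_update(self.critic_target, self.critic, c)

    # -- training loops ----------------------------------------------------

    def _beta(self) -> float:
        frac = min(self._step / max(self.config.training_steps, 1), 1.0)
        return self.config.per_beta0 + (self.config.per_beta_final - self.config.per_beta0) * frac

    def _update_once(self, log: TrainingLog) -> None:
        records, weights, indices = self.buffer.sample(self.config.batch_size, beta=self._beta())
        loss, td = self.critic_td_update(records, weights)
        states = np.stack([r.state for r in records])
        objective = self.actor_dpg_update(states)
        self.soft_update_targets()
        self.buffer.update_priorities(indices, td)
        log.critic_loss.append(loss)
        log.actor_objective.append(objective)
        log.batch_reward.append(float(np.mean([r.reward for r in records])))
        self._step += 1


def build_offline_transitions(trajectories, reward_config: RewardConfig | None = None):
    """Turn logged trajectories into gated-reward transition tuples.

    For each consecutive pair of windows (t, t+1) the transition is
    (s_t, a_t, r, s_{t+1}) where the reward scores the *outcome* window t+1:
    band rewards and deviations from SAS/MAP at t+1, the dose penalty from
    a_t, gated on the band error at t+1 strictly improving on the error at t.
    """
    cfg = reward_config or RewardConfig()
    transitions = []
    for traj in trajectories:
        if traj.map_mmHg is None:
            raise ValueError("trajectories must carry raw MAP (preprocess first)")
        errors = [
            window_error(
                deviation(m, cfg.map_ltb, cfg.map_utb),
                deviation(s, cfg.sas_ltb, cfg.sas_utb),
                signed=cfg.signed_error,
            )
            for s, m in zip(traj.sas, traj.map_mmHg)
        ]
        for t in range(traj.n_windows - 1):
            bd = breakdown_window(
                sas=float(np.clip(traj.sas[t + 1], 1.0, 7.0)),
                map_mmHg=float(traj.map_mmHg[t + 1]),
                propofol=float(traj.doses[t, 0]),
                fentanyl=float(traj.doses[t, 1]),
                config=cfg,
            )
            r = compute_reward(bd, error_prev=errors[t], config=cfg)
            transitions.append(
                TransitionRecord(
                    state=traj.features[t].astype(float),
                    action=traj.doses[t].astype(float),
                    reward=float(r),
                    next_state=traj.features[t + 1].astype(float),
                )
            )
    return transitions


def infer_dose_max(trajectories, quantile: float = 0.99) -> np.ndarray:
    """Per-drug action cap from the training data's dose distribution."""
    doses = np.concatenate([t.doses for t in trajectories], axis=0)
    caps = np.quantile(doses, quantile, axis=0)
    return np.maximum(caps, 1e-6)


def train_agent(
    data,
    agent_config: AgentConfig | None = None,
    reward_config: RewardConfig | None = None,
    mode: str = "offline",
    env=None,
    eval_fn=None,
    eval_every: int = 0,
):
    """Run the DDPG training loop; returns (agent, TrainingLog).

    ``mode='offline'`` (default): ``data`` is a list of preprocessed,
    normalized trajectories; the buffer holds exactly their logged
    transitions and no dynamics model is ever queried.

    ``mode='model_based'``: ``env`` provides ``reset() -> s`` and
    ``step(a) -> (s', reward, done)``; trajectories are collected with
    exploration noise, interleaved with updates.

    ``eval_fn(agent) -> dict``, if given, is called every ``eval_every``
    steps and the result stored as a snapshot in the log.
    """
    cfg = agent_config or AgentConfig()
    if mode not in ("offline", "model_based"):
        raise ValueError(f"unknown mode {mode!r}")
    log = TrainingLog()

    if mode == "offline":
        trajectories = list(data)
        if not trajectories:
            raise ValueError("no trajectories to train on")
        dose_max = cfg.dose_max if cfg.dose_max is not None else infer_dose_max(trajectories)
        agent = DDPGAgent(cfg, dose_max=dose_max)
        for rec in build_offline_transitions(trajectories, reward_config):
            agent.buffer.add(rec)
        if len(agent.buffer) < cfg.batch_size:
            raise ValueError("not enough logged transitions for one batch")
        for _ in range(cfg.training_steps):
            agent._update_once(log)
            if eval_fn is not None and eval_every and agent._step % eval_every == 0:
                log.snapshots.append({"step": agent._step, **eval_fn(agent)})
        return agent, log

    if env is None:
        raise ValueError("model_based mode requires an environment")
    dose_max = cfg.dose_max if cfg.dose_max is not None else env.dose_max
    agent = DDPGAgent(cfg, dose_max=dose_max)
    s = env.reset()
    while agent._step < cfg.training_steps:
        a = agent.select_action(s, explore=True)
        s2, r, done = env.step(a)
        agent.buffer.add(TransitionRecord(state=s, action=a, reward=float(r), next_state=s2))
        s = env.reset() if done else s2
        if len(agent.buffer) >= cfg.batch_size:
            agent._update_once(log)
            if eval_fn is not None and eval_every and agent._step % eval_every == 0:
                log.snapshots.append({"step": agent._step, **eval_fn(agent)})
    return agent, log
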