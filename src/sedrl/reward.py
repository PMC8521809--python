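"""Therapeutic-band reward for joint sedation (SAS) and haemodynamic (MAP) control.

The reward issued to the dosing agent in each hourly window combines

* a sigmoid band reward for mean arterial pressure, centred on the
  therapeutic range 65-85 mmHg,
* a sigmoid band reward for the Riker Sedation-Agitation Scale, centred on
  the target band 3-4,
* a linear penalty on the total medication administered (propofol +
  fentanyl, coefficient 0.02),

gated so that the agent is only rewarded when the combined deviation from
both bands strictly improved relative to the previous window; otherwise the
window's reward is zero, penalising a "bad" action.

Note on the SAS band reward: with unit logistic scale and a band of width 1
the two sigmoids overlap heavily, so the in-band value peaks at about -0.51
(at SAS 3.5) rather than near +1. The formula is implemented in that exact
form by default; ``sas_sharpness`` widens the logistic slope for callers who
want the band reward to saturate near 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class RewardConfig:
    """Band edges and penalty weights for the windowed reward.

    ``ltb``/``utb`` are lower/upper target boundaries. ``signed_error``
    switches the window error from the magnitude convention |D_MAP| + |D_SAS|
    (default) to the literal signed sum D_MAP + D_SAS.
    """

    map_ltb: float = 65.0
    map_utb: float = 85.0
    sas_ltb: float = 3.0
    sas_utb: float = 4.0
    dose_penalty_coeff: float = 0.02
    gate_on_improvement: bool = True
    signed_error: bool = False
    sas_sharpness: float = 1.0

    def __post_init__(self) -> None:
        if not self.map_ltb < self.map_utb:
            raise ValueError("MAP band requires ltb < utb")
        if not self.sas_ltb < self.sas_utb:
            raise ValueError("SAS band requires ltb < utb")
        if self.dose_penalty_coeff < 0:
            raise ValueError("dose penalty must be >= 0")
        if self.sas_sharpness <= 0:
            raise ValueError("sas_sharpness must be > 0")


@dataclass
class RewardBreakdown:
    """All intermediate quantities of one window's reward computation."""

    r_map: float
    r_sas: float
    r_dosage: float
    d_map: float
    d_sas: float
    error_t: float
    reward_t: float = field(default=0.0)


def _band_sigmoid(x: float, lo: float, hi: float, k: float = 1.0) -> float:
    # difference of two logistics; peaks midway between the band edges
    return 2.0 / (1.0 + math.exp(-k * (x - lo))) - 2.0 / (1.0 + math.exp(-k * (x - hi))) - 1.0


def r_map(map_mmHg: float) -> float:
    """Band reward 2/(1+e^-(MAP-65)) - 2/(1+e^-(MAP-85)) - 1.

    Close to 1 inside 65-85 mmHg, approaching -1 far outside.
    """
    if not math.isfinite(map_mmHg):
        raise ValueError(f"MAP must be finite, got {map_mmHg!r}")
    return _band_sigmoid(map_mmHg, 65.0, 85.0)


def r_sas(sas: float, sharpness: float = 1.0) -> float:
    """Band reward 2/(1+e^-(SAS-3)) - 2/(1+e^-(SAS-4)) - 1 on the 1-7 scale.

    ``sharpness`` > 1 steepens both logistics so the in-band plateau
    approaches +1; the default reproduces the printed unit-scale form.
    """
    if not (1.0 <= sas <= 7.0):
        raise ValueError(f"SAS must lie in [1, 7], got {sas!r}")
    return _band_sigmoid(sas, 3.0, 4.0, k=sharpness)


def deviation(value: float, ltb: float, utb: float) -> float:
    """Signed deviation from the band: 0 in range, ltb-value below, utb-value above."""
    if not ltb < utb:
        raise ValueError("band requires ltb < utb")
    if value < ltb:
        return ltb - value
    if value > utb:
        return utb - value
    return 0.0


def window_error(d_map: float, d_sas: float, signed: bool = False) -> float:
    """Combined band error for one window.

    Default is the magnitude convention |d_map| + |d_sas| so that opposite
    excursions cannot cancel; ``signed=True`` gives the literal sum.
    """
    if signed:
        return d_map + d_sas
    return abs(d_map) + abs(d_sas)


def breakdown_window(
    sas: float,
    map_mmHg: float,
    propofol: float,
    fentanyl: float,
    config: RewardConfig | None = None,
) -> RewardBreakdown:
    """Compute band rewards, deviations and error for one window (no gate)."""
    cfg = config or RewardConfig()
    d_m = deviation(map_mmHg, cfg.map_ltb, cfg.map_utb)
    d_s = deviation(sas, cfg.sas_ltb, cfg.sas_utb)
    return RewardBreakdown(
        r_map=r_map(map_mmHg),
        r_sas=r_sas(sas, sharpness=cfg.sas_sharpness),
        r_dosage=float(propofol) + float(fentanyl),
        d_map=d_m,
        d_sas=d_s,
        error_t=window_error(d_m, d_s, signed=cfg.signed_error),
    )


def compute_reward(
    breakdown: RewardBreakdown,
    error_prev: float | None,
    config: RewardConfig | None = None,
) -> float:
    """Gated window reward r_SAS + r_MAP - 0.02 * r_dosage.

    The full reward is issued only when this window's band error strictly
    improved on the previous window's (``error_prev``); otherwise the reward
    is 0. With no previous window (``error_prev is None``, the first hour)
    the gate passes. Gating can be disabled via the config flag.
    """
    cfg = config or RewardConfig()
    if cfg.gate_on_improvement and error_prev is not None and not breakdown.error_t < error_prev:
        breakdown.reward_t = 0.0
        return 0.0
    breakdown.reward_t = (
        breakdown.r_sas + breakdown.r_map - cfg.dose_penalty_coeff * breakdown.r_dosage
    )
    return breakdown.reward_t
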