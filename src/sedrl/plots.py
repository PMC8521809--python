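"""Optional figures for policy comparisons (requires matplotlib).

Two views mirror the standard presentation of sedation-control results:
side-by-side boxplots of the achieved SAS / MAP distributions under each
policy with the therapeutic band shaded, and per-patient SAS/MAP traces
comparing the learned policy's rollout with the logged clinician hours.
"""

from __future__ import annotations

import numpy as np


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires the 'plot' extra (matplotlib)") from exc
    return plt


def control_variable_boxplots(learned_values, clinician_values, out_path=None):
    """Boxplots of hourly SAS and MAP under both policies, bands shaded.

    ``learned_values`` / ``clinician_values`` are dicts with keys ``"SAS"``
    and ``"MAP"`` holding concatenated hourly values across patients.
    """
    plt = _require_matplotlib()
    bands = {"SAS": (3.0, 4.0), "MAP": (65.0, 85.0)}
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, var in zip(axes, ("SAS", "MAP")):
        lo, hi = bands[var]
        ax.axhspan(lo, hi, color="tab:green", alpha=0.2, label="target range")
        ax.boxplot(
            [np.asarray(learned_values[var]), np.asarray(clinician_values[var])],
            tick_labels=["learned", "clinician"],
            showfliers=False,
        )
        ax.set_title(var)
        ax.set_ylabel("SAS level" if var == "SAS" else "MAP (mmHg)")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig


def patient_trajectories(patients, out_path=None):
    """SAS and MAP traces for a few patients under both policies.

    ``patients`` is a list of dicts with keys ``id``, ``sas_learned``,
    ``sas_clinician``, ``map_learned``, ``map_clinician`` (hourly arrays).
    """
    plt = _require_matplotlib()
    n = len(patients)
    fig, axes = plt.subplots(2, n, figsize=(4 * n, 6), squeeze=False)
    for j, patient in enumerate(patients):
        for i, var in enumerate(("sas", "map")):
            ax = axes[i][j]
            lo, hi = (3, 4) if var == "sas" else (65, 85)
            ax.axhspan(lo, hi, color="tab:green", alpha=0.2)
            ax.plot(patient[f"{var}_learned"], "-", label="learned")
            ax.plot(patient[f"{var}_clinician"], "--", label="clinician")
            if i == 0:
                ax.set_title(str(patient["id"]))
            ax.set_ylabel(var.upper())
            ax.set_xlabel("hour")
        axes[0][j].legend(fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig
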