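"""Cohort figures: metric histograms and metabolite/action phase planes."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import ParticipantMetrics  # noqa: E402


def enclosed_area(x: np.ndarray, y: np.ndarray) -> float:
    """|shoelace area| of the (closed) trajectory in the phase plane.

    An "out and back" diagonal path encloses ~0 area; a cyclic loop encloses
    a finite one.  The trajectory is closed by joining last to first point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)) / 2.0)


def plot_metric_histograms(metrics: list[ParticipantMetrics], path) -> None:
    """Four-panel histogram figure: the two delays, the peak gap, the nadir gap."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("delay_glucose", "glucose action peak $-$ insulin peak (min)"),
        ("delay_glycerol", "glycerol action peak $-$ insulin peak (min)"),
        ("peak_gap", "glucose $-$ glycerol action peak time (min)"),
        ("nadir_gap", "normalised action difference at nadir"),
    ]
    for ax, (attr, label) in zip(axes.ravel(), panels):
        vals = [getattr(m, attr) for m in metrics]
        ax.hist(vals, bins=12, color="0.4", edgecolor="white")
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel(label)
        ax.set_ylabel("participants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_planes(
    glucose_grid, glucose, XG_values, glycerol_grid, glycerol, Xg_values, path,
    participant_id: str = "",
) -> None:
    """Normalised metabolite vs normalised insulin action, one panel per model."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (g, m, x, label) in zip(
        axes,
        [
            (glucose_grid, glucose, XG_values, "glucose"),
            (glycerol_grid, glycerol, Xg_values, "glycerol"),
        ],
    ):
        m = np.asarray(m, dtype=float)
        x = np.asarray(x, dtype=float)
        mn = m / np.max(np.abs(m))
        xn = x / np.max(x) if np.max(x) > 0 else x
        ax.plot(xn, mn, "-", color="0.2", lw=1.2)
        ax.plot(xn[0], mn[0], "o", color="tab:green", label="t = 0")
        ax.set_xlabel(f"normalised insulin action ({label})")
        ax.set_ylabel(f"normalised {label}")
        ax.set_title(f"{participant_id} {label}".strip())
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
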