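"""Kaplan-Meier figure helpers (time-to-fill and time-to-follow-up)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .survival import KmCurve


def _steps(curve: KmCurve, end: float):
    xs, ys = [0.0], [1.0]
    for t, s in zip(curve.event_times, curve.survival):
        xs += [t, t]
        ys += [ys[-1], s]
    xs.append(end)
    ys.append(ys[-1])
    return xs, ys


def plot_time_to_fill(curve: KmCurve, path: str | Path, end: float = 60.0) -> Path:
    """Survival curve of remaining-unfilled prescriptions over days."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(*_steps(curve, end), drawstyle="default")
    ax.set_xlabel("days from prescription")
    ax.set_ylabel("fraction not yet filled")
    ax.set_ylim(0, 1.02)
    ax.set_xlim(0, end)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_followup_km(
    filled: KmCurve, not_filled: KmCurve, path: str | Path, end: float = 90.0
) -> Path:
    """Per-group survival curves for days until the follow-up visit."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(*_steps(filled, end), label="filled")
    ax.plot(*_steps(not_filled, end), label="not filled")
    ax.set_xlabel("days from index encounter")
    ax.set_ylabel("fraction without follow-up visit")
    ax.set_ylim(0, 1.02)
    ax.set_xlim(0, end)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
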