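"""Trajectory figures: per-group mean curves with fitted power laws."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .models import PowerLawPosterior, power_curve
from .trajectory import records_to_frame

__all__ = ["plot_trajectories", "plot_fit"]

_STYLE = {"CO": dict(color="tab:blue", ls="-"), "HP": dict(color="tab:red", ls="--")}


def plot_fit(
    records: Sequence,
    posterior: Optional[PowerLawPosterior],
    x_field: str,
    ax: plt.Axes,
) -> None:
    df = records_to_frame(records)
    for group, sub in df.groupby("group"):
        means = sub.groupby(x_field)["score"].mean()
        style = _STYLE.get(group, {})
        ax.plot(means.index, means.values, marker="o", lw=0,
                color=style.get("color"), label=f"{group} mean")
        if posterior is not None:
            xs = np.linspace(df[x_field].min(), df[x_field].max(), 100)
            a = posterior.group_mean("a", group)
            b = posterior.group_mean("b", group)
            curves = power_curve(a[:, None], b[:, None], xs[None, :])
            lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
            ax.plot(xs, power_curve(a.mean(), b.mean(), xs),
                    color=style.get("color"), ls=style.get("ls", "-"),
                    label=f"{group} fit")
            ax.fill_between(xs, lo, hi, color=style.get("color"), alpha=0.2)
    ax.set_xlabel(x_field)
    ax.set_ylabel("cosine similarity")
    ax.legend()


def plot_trajectories(
    position_records: Sequence,
    lag_records: Sequence,
    position_posterior: Optional[PowerLawPosterior],
    lag_posterior: Optional[PowerLawPosterior],
    out_dir: str | Path,
) -> list[Path]:
    """Write the position-curve and lag-curve figures; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for records, posterior, x_field, fname in (
        (position_records, position_posterior, "position", "position_trajectory.png"),
        (lag_records, lag_posterior, "lag", "lag_trajectory.png"),
    ):
        if not records:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        plot_fit(records, posterior, x_field, ax)
        path = out_dir / fname
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
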