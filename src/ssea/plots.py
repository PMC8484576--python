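"""Static plots: interaction plots, the 3D state space and its 2D projections.

Every figure gets a sidecar CSV carrying exactly the plotted values, so that
numeric checks run on data rather than pixels.  Rendering is deterministic:
points keep their input order and colors/markers are assigned from fixed
palettes in order of first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .dataset import FactorialDataset, ScaleSpec, SSEAError, transform_scale  # noqa: E402
from .statespace import StateSpacePoint  # noqa: E402

__all__ = ["PlotSpec", "plot_interaction", "plot_statespace"]

PROJECTION_AXES = {
    "projection_g_f1": ("f1", "g"),
    "projection_g_f2": ("f2", "g"),
    "projection_f2_f1": ("f1", "f2"),
}

_MARKERS = ["o", "s", "^", "D", "v", "P", "X", "*"]


@dataclass(frozen=True)
class PlotSpec:
    """What to draw and how to encode the grouping variables."""

    kind: str = "projection_g_f1"
    color_by: str = "unit_id"
    marker_by: str = "context_id"
    control_axis_coord: str = "g"  # partner coordinate for the r00 view
    scale_name: str = "raw"

    def axis_label(self, coord: str) -> str:
        return f"{coord} ({self.scale_name} scale)"


def _sidecar_path(out_path: Path) -> Path:
    return out_path.with_suffix(".csv")


def _points_frame(points: Sequence[StateSpacePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [p.unit_id for p in points],
            "context_id": [p.context_id for p in points],
            "group_id": [p.group_id for p in points],
            "f1": [p.f1 for p in points],
            "f2": [p.f2 for p in points],
            "g": [p.g for p in points],
            "additive": [p.additive for p in points],
            "r00": [p.r00 for p in points],
            "se_g": [p.se_g for p in points],
        }
    )


def _styles(frame: pd.DataFrame, spec: PlotSpec):
    cmap = plt.get_cmap("tab20")
    colors = {
        u: cmap(i % 20) for i, u in enumerate(pd.unique(frame[spec.color_by]))
    }
    markers = {
        c: _MARKERS[i % len(_MARKERS)]
        for i, c in enumerate(pd.unique(frame[spec.marker_by]))
    }
    return colors, markers


def plot_statespace(
    points: Sequence[StateSpacePoint],
    spec: PlotSpec | str = PlotSpec(),
    out_path: str | Path = "statespace.png",
) -> tuple[Path, Path]:
    """Draw a state-space view and write the sidecar coordinate CSV.

    Kinds: ``statespace3d`` (3D scatter with the additive g = 0 plane drawn
    in grey), the three 2D projections ``projection_g_f1`` /
    ``projection_g_f2`` / ``projection_f2_f1``, and ``control_axis`` (the
    reference-treatment response r00 against a chosen coordinate, the
    "fourth axis" view).  Returns (image path, sidecar path).
    """
    if isinstance(spec, str):
        spec = PlotSpec(kind=spec)
    if len(points) == 0:
        raise SSEAError("no points to plot")
    out_path = Path(out_path)
    frame = _points_frame(points)
    frame.to_csv(_sidecar_path(out_path), index=False)
    colors, markers = _styles(frame, spec)

    if spec.kind == "statespace3d":
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
        lim1 = max(abs(frame["f1"]).max(), 1e-9)
        lim2 = max(abs(frame["f2"]).max(), 1e-9)
        xx, yy = np.meshgrid(
            np.linspace(-1.1 * lim1, 1.1 * lim1, 2),
            np.linspace(-1.1 * lim2, 1.1 * lim2, 2),
        )
        ax.plot_surface(xx, yy, np.zeros_like(xx), color="grey", alpha=0.25)
        for _, row in frame.iterrows():
            ax.scatter(
                row["f1"], row["f2"], row["g"],
                color=colors[row[spec.color_by]],
                marker=markers[row[spec.marker_by]],
            )
        ax.set_xlabel(spec.axis_label("f1"))
        ax.set_ylabel(spec.axis_label("f2"))
        ax.set_zlabel(spec.axis_label("g"))
    else:
        if spec.kind == "control_axis":
            xcoord, ycoord = spec.control_axis_coord, "r00"
        elif spec.kind in PROJECTION_AXES:
            xcoord, ycoord = PROJECTION_AXES[spec.kind]
        else:
            raise SSEAError(f"unknown plot kind {spec.kind!r}")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(0.0, color="grey", lw=0.8)
        for _, row in frame.iterrows():
            ax.plot(
                row[xcoord], row[ycoord],
                linestyle="none",
                color=colors[row[spec.color_by]],
                marker=markers[row[spec.marker_by]],
            )
        ax.set_xlabel(spec.axis_label(xcoord))
        ax.set_ylabel(spec.axis_label(ycoord))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path, _sidecar_path(out_path)


def plot_interaction(
    data: FactorialDataset,
    spec: ScaleSpec = ScaleSpec("raw"),
    out_path: str | Path = "interaction.png",
    title: str = "",
) -> tuple[Path, Path]:
    """Draw an interaction plot of the (pooled) 2x2 cell means.

    All rows per driver-level cell of ``data`` are pooled (e.g. replicates
    across females), transformed to the analysis scale, and drawn as one
    line per driver-2 level over the driver-1 levels with standard-error
    bars when a cell has more than one row.  The sidecar CSV holds the
    plotted means, standard errors and per-cell n.
    """
    if len(data) == 0:
        raise SSEAError("empty dataset")
    out_path = Path(out_path)
    rows = []
    for d2 in data.driver2_levels:
        for d1 in data.driver1_levels:
            cell = data.cell(d1, d2)
            if len(cell) == 0:
                raise SSEAError(f"no replicates in cell ({d1!r}, {d2!r})")
            nt = cell["n_trials"].to_numpy() if "n_trials" in cell.columns else None
            y = transform_scale(cell["response"].to_numpy(), spec, n_trials=nt)
            n = len(y)
            se = float(np.std(y, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {"driver1": d1, "driver2": d2, "mean": float(np.mean(y)),
                 "se": se, "n": n}
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(_sidecar_path(out_path), index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.arange(len(data.driver1_levels))
    for d2 in data.driver2_levels:
        sub = frame[frame["driver2"] == d2]
        ax.errorbar(
            x, sub["mean"].to_numpy(), yerr=sub["se"].to_numpy(),
            marker="o", capsize=3, label=str(d2),
        )
    ax.set_xticks(x)
    ax.set_xticklabels(data.driver1_levels)
    ax.set_xlabel("driver 1 level")
    ax.set_ylabel(f"mean response ({spec.name} scale)")
    ax.legend(title="driver 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path, _sidecar_path(out_path)
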