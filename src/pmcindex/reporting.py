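"""Surface matrices, radar series, and release-time timelines.

The *surface* of a policy arranges its nine sub-scored main-indicator
scores as a 3x3 matrix (row-major X1..X9; the sub-less disclosure
indicator, constant at 1, is dropped for symmetry) and renders it as a
surface whose depressions localize the policy's weaknesses.  The radar
series is the per-indicator mean score across policies; the timeline is
the count of policies released per calendar year.

Figure writers are presentation-only: the stored artifacts are the exact
grids and series, and surface smoothing never alters them.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scoring import ScoringError, round2

__all__ = [
    "PolicyMeta",
    "build_surface",
    "radar_series",
    "timeline",
    "plot_surface",
    "plot_radar",
    "plot_timeline",
]


@dataclass(frozen=True)
class PolicyMeta:
    """Identity and provenance of one policy document."""

    pid: str
    title: str
    release_date: date
    agencies: tuple[str, ...]

    def __post_init__(self):
        if not self.agencies:
            raise ValueError(f"policy {self.pid!r} has no issuing agency")


def build_surface(row: Mapping[str, float] | pd.Series | Sequence[float]) -> np.ndarray:
    """3x3 surface matrix from one policy's main-indicator scores.

    Takes the first nine main scores in indicator order (the tenth,
    sub-less disclosure indicator is dropped when present) and places them
    row-major.  Fewer than nine scores is an error.
    """
    if isinstance(row, (pd.Series, Mapping)):
        vals = list(pd.Series(dict(row)).values) if not isinstance(row, pd.Series) else list(row.values)
    else:
        vals = list(row)
    if len(vals) < 9:
        raise ScoringError(f"surface needs at least 9 main scores, got {len(vals)}")
    grid = np.asarray(vals[:9], dtype=float).reshape(3, 3)
    if (grid < 0).any() or (grid > 1).any():
        raise ScoringError("surface cells must lie in [0, 1]")
    return grid


def radar_series(table: pd.DataFrame) -> pd.Series:
    """Mean score per main indicator across all policies in the table.

    Averages are taken unrounded and reported at two decimals; the result
    is invariant to the order of the policy rows.
    """
    if len(table) < 1:
        raise ScoringError("need at least one policy")
    return table.astype(float).mean(axis=0).map(round2)


def _release_year(obj, pid: str) -> int:
    if isinstance(obj, (date, datetime)):
        return obj.year
    try:
        return pd.Timestamp(obj).year
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable release date for policy {pid!r}: {obj!r}") from exc


def timeline(meta: Iterable[PolicyMeta] | pd.DataFrame) -> pd.Series:
    """Policies released per year, zero-filled over the observed span.

    Accepts PolicyMeta records or a DataFrame with ``pid`` and
    ``release_date`` columns.  Counts sum to the number of policies.
    """
    if isinstance(meta, pd.DataFrame):
        records = list(zip(meta["pid"], meta["release_date"]))
    else:
        records = [(m.pid, m.release_date) for m in meta]
    if not records:
        return pd.Series(dtype=int, name="n_policies")
    years = [_release_year(d, pid) for pid, d in records]
    counts = pd.Series(years).value_counts().sort_index()
    full = pd.Series(0, index=range(min(years), max(years) + 1), name="n_policies")
    full.update(counts)
    full.index.name = "year"
    return full.astype(int)


# -- figure writers -------------------------------------------------------


def plot_surface(
    grid: np.ndarray,
    path: str | Path | None = None,
    title: str = "",
    smooth: int = 30,
):
    """Render a 3x3 surface matrix as a smoothed 3-D surface.

    The z-range is fixed to [0, 1] so surfaces of different policies are
    comparable.  Smoothing (bilinear upsampling to ``smooth`` points per
    axis) affects the rendering only.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (3, 3):
        raise ScoringError(f"surface grid must be 3x3, got {grid.shape}")
    base = np.arange(3, dtype=float)
    fine = np.linspace(0, 2, max(smooth, 3))
    # separable bilinear interpolation of the 3x3 grid
    rows = np.array([np.interp(fine, base, grid[i]) for i in range(3)])
    z = np.array([np.interp(fine, base, rows[:, j]) for j in range(rows.shape[1])]).T
    xx, yy = np.meshgrid(fine + 1, fine + 1)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(xx, yy, z, cmap="viridis", vmin=0, vmax=1, antialiased=True)
    ax.set_zlim(0, 1)
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    ax.set_zlabel("score")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_radar(series: pd.Series, path: str | Path | None = None, title: str = ""):
    """Radar chart of per-indicator mean scores (axis range [0, 1])."""
    labels = list(series.index)
    values = list(series.values)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False).tolist()
    values_c = values + values[:1]
    angles_c = angles + angles[:1]
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.plot(angles_c, values_c, "o-", linewidth=1.5)
    ax.fill(angles_c, values_c, alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def plot_timeline(counts: pd.Series, path: str | Path | None = None, title: str = ""):
    """Line chart of policy releases per year."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(counts.index, counts.values, "o-")
    ax.set_xlabel("year")
    ax.set_ylabel("policies released")
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
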