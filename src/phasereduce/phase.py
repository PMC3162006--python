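"""Phase-plane hysteresis analysis.

Under a transient on/off input every pair of (normalized) state trajectories
traces a closed loop in the plane.  The area enclosed by that loop is a
dimensionless measure of timescale separation between the two species: 0
means the pair moves along a single steady-state curve (no separation), 1
means complete separation (the loop fills the unit square).  Areas are
computed with the midpoint (trapezoid-of-ordinates) line integral

    area = | Σ_i ½ (Y_{i+1} + Y_i) (X_{i+1} − X_i) |

over the closed polygonal loop, the shoelace-equivalent rule that is exact
for polygons, needs no uniform spacing, and handles loops that switch
concavity.  Pairwise areas separate empirically into three modes — fast
(area ≤ 0.05), medium (0.05 < area ≤ 0.5) and slow (area > 0.5) — and the
fast direct relationships are the candidates for algebraic reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import NormalizedTimeCourseSet

__all__ = [
    "PhaseLoop",
    "AreaMatrix",
    "SpeedThresholds",
    "loop_area",
    "split_loop_area",
    "pairwise_area_matrix",
    "classify_pairs",
    "classify_area",
    "area_histogram",
    "plot_global_phase_portrait",
]


@dataclass(frozen=True)
class PhaseLoop:
    """Closed normalized phase loop of state ``y_name`` against ``x_name``.

    Points are the combined on+off trajectory; the segment from the last
    point back to the first closes the loop.
    """

    x: np.ndarray
    y: np.ndarray
    x_name: str = "X"
    y_name: str = "Y"

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.x)

    def swapped(self) -> "PhaseLoop":
        return PhaseLoop(self.y, self.x, self.y_name, self.x_name)


@dataclass(frozen=True)
class SpeedThresholds:
    """Trimodal classification cut points on the dimensionless area axis.

    The fast bin is closed above ([0, fast_max]); medium is
    (fast_max, slow_min]; slow is (slow_min, 1].
    """

    fast_max: float = 0.05
    slow_min: float = 0.5

    def __post_init__(self):
        if not (0 < self.fast_max < self.slow_min < 1):
            raise ValueError("need 0 < fast_max < slow_min < 1")


def loop_area(loop: PhaseLoop) -> float:
    """Hysteresis area |∮ y dx| of the closed polygonal loop.

    Invariant under cyclic rotation of the points and under swapping the
    axes.  Self-intersecting loops contribute with signed cancellation
    (use :func:`split_loop_area` to sum sub-loop magnitudes instead).
    """
    if len(loop) < 3:
        raise ValueError("a loop needs at least 3 points")
    x, y = loop.x, loop.y
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("loop coordinates must be finite")
    dx = np.diff(x, append=x[:1])
    ymid = 0.5 * (np.roll(y, -1) + y)
    return float(abs(np.sum(ymid * dx)))


def _segments_cross(p, q, r, s):
    """Proper intersection of open segments pq and rs; returns param u on pq."""
    d1 = q - p
    d2 = s - r
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-15:
        return None
    w = r - p
    u = (w[0] * d2[1] - w[1] * d2[0]) / denom
    v = (w[0] * d1[1] - w[1] * d1[0]) / denom
    if 1e-12 < u < 1 - 1e-12 and 1e-12 < v < 1 - 1e-12:
        return u
    return None


def split_loop_area(loop: PhaseLoop) -> float:
    """Area summing |sub-loop| magnitudes after splitting at self-crossings.

    A figure-eight traced with opposite orientations in its two lobes has
    signed area near zero; this variant detects the first proper segment
    crossing, splits the polygon there, and sums the absolute areas of the
    two sub-loops (recursively).  Quadratic in the number of points, so
    intended for diagnostic use on individual loops.
    """
    if len(loop) < 3:
        raise ValueError("a loop needs at least 3 points")
    pts = np.column_stack([loop.x, loop.y])
    n = len(pts)
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            r, s = pts[j], pts[(j + 1) % n]
            u = _segments_cross(p, q, r, s)
            if u is not None:
                cross = p + u * (q - p)
                a = np.vstack([pts[: i + 1], cross, pts[j + 1:]])
                b = np.vstack([cross, pts[i + 1: j + 1]])
                out = 0.0
                for part in (a, b):
                    if len(part) >= 3:
                        out += split_loop_area(
                            PhaseLoop(part[:, 0], part[:, 1],
                                      loop.x_name, loop.y_name))
                return out
    return loop_area(loop)


@dataclass
class AreaMatrix:
    """Symmetric matrix of pairwise hysteresis areas.

    ``matrix`` is a square DataFrame over the non-static state names with a
    zero diagonal; ``excluded`` lists states dropped as static.
    """

    matrix: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        m = self.matrix
        if list(m.index) != list(m.columns):
            raise ValueError("matrix must be square with matching labels")
        if not np.allclose(m.to_numpy(), m.to_numpy().T):
            raise ValueError("area matrix must be symmetric")

    @property
    def states(self) -> list[str]:
        return list(self.matrix.columns)

    def area(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])

    def pairs(self) -> dict[tuple[str, str], float]:
        return {tuple(sorted((a, b))): self.area(a, b)
                for a, b in combinations(self.states, 2)}

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)

    def to_long_csv(self, path, classes: Mapping | None = None,
                    direct_pairs: Iterable[tuple[str, str]] | None = None) -> None:
        direct = {tuple(sorted(p)) for p in (direct_pairs or ())}
        rows = []
        for (a, b), ar in sorted(self.pairs().items()):
            rows.append({
                "state_a": a, "state_b": b, "area": ar,
                "class": (classes or {}).get((a, b), ""),
                "direct_flag": (a, b) in direct,
            })
        pd.DataFrame(rows).to_csv(path, index=False)


def pairwise_area_matrix(ntc: NormalizedTimeCourseSet) -> AreaMatrix:
    """Hysteresis areas of every unordered pair of non-static states."""
    names = ntc.states
    if len(names) < 2:
        raise ValueError("need at least 2 non-static states for pair analysis")
    n = len(names)
    mat = np.zeros((n, n))
    traces = {s: ntc[s] for s in names}
    for i, j in combinations(range(n), 2):
        a = loop_area(PhaseLoop(traces[names[i]], traces[names[j]],
                                names[i], names[j]))
        mat[i, j] = mat[j, i] = a
    return AreaMatrix(
        matrix=pd.DataFrame(mat, index=names, columns=names),
        excluded=list(ntc.static_states),
    )


def classify_area(area: float, thresholds: SpeedThresholds = SpeedThresholds()) -> str:
    if area <= thresholds.fast_max:
        return "fast"
    if area <= thresholds.slow_min:
        return "medium"
    return "slow"


def classify_pairs(
    am: AreaMatrix,
    thresholds: SpeedThresholds = SpeedThresholds(),
    direct_pairs: Iterable[tuple[str, str]] | None = None,
):
    """Label every pair fast/medium/slow.

    Returns ``(all_classes, direct_classes)`` where ``direct_classes`` is the
    restriction to the given direct pairs (None if none were given).  Direct
    pairs involving static (excluded) states are silently absent.
    """
    classes = {pair: classify_area(a, thresholds)
               for pair, a in am.pairs().items()}
    if direct_pairs is None:
        return classes, None
    direct = {tuple(sorted(p)) for p in direct_pairs}
    return classes, {p: c for p, c in classes.items() if p in direct}


def area_histogram(am: AreaMatrix, bin_width: float = 0.05) -> pd.DataFrame:
    """Histogram of pairwise areas over [0, 1]: columns bin_left, bin_right,
    count.  Counts sum to the number of pairs."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    areas = np.array(list(am.pairs().values()))
    if len(areas) == 0:
        raise ValueError("empty area matrix")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    if edges[-1] < max(1.0, areas.max()):
        edges = np.append(edges, max(1.0, areas.max()) + 1e-12)
    counts, edges = np.histogram(areas, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
    })


def plot_global_phase_portrait(ntc: NormalizedTimeCourseSet,
                               am: AreaMatrix | None = None,
                               path=None):
    """Grid of per-pair normalized loops with the area printed above each
    panel.  Returns the matplotlib figure; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = ntc.states
    pairs = list(combinations(names, 2))
    if am is None:
        am = pairwise_area_matrix(ntc)
    ncol = min(6, max(1, int(np.ceil(np.sqrt(len(pairs))))))
    nrow = int(np.ceil(len(pairs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for ax, (a, b) in zip(axes.flat, pairs):
        ax.set_axis_on()
        ax.plot(ntc[a], ntc[b], lw=0.8)
        ax.set_title(f"{b} vs {a}\narea={am.area(a, b):.3f}", fontsize=7)
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
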