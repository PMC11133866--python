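"""Piecewise-linear trajectory models through 2-D affective space.

The observed transform-condition response traces a 16-point path through
the plane spanned by corrugator (x, negative affect) and zygomaticus
(y, positive affect) percent-of-baseline reactivity. Three hypothesised
trajectories connect the observed start and end points:

* ``neutral`` (L-shape): positive affect falls first (vertical segment at
  the starting corrugator level), then negative affect rises (horizontal
  segment) — the path passes through a neutral state;
* ``mixed`` (inverse step): negative affect rises first (horizontal
  segment at the starting zygomaticus level), then positive affect falls
  — the path passes through a mixed-emotion state;
* ``valence`` (diagonal): both change concurrently along the straight
  line between the endpoints.

For a piecewise family the *vertex* v in 2..15 is the indexed path point
sitting at the corner: points 1..v are equally spaced on the first
segment, points v..16 on the second. Fit quality is the mean squared
Euclidean deviation (MSD) between corresponding model and observed
points, averaged over the 14 interior points (the endpoints are anchored
to the data and deviate by zero). The model/vertex with the smallest MSD
wins; ties break toward the smaller vertex, then family order neutral <
mixed < valence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .design import BIN_WIDTH_MS, N_BINS
from .synth import load_group_means

FAMILIES = ("neutral", "mixed", "valence")
VERTEX_RANGE = range(2, N_BINS)  # 2..15


@dataclass(frozen=True)
class Path2D:
    """Ordered 16-point path: x = corrugator, y = zygomaticus (percent)."""

    points: np.ndarray
    role: str = "observed"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.shape != (N_BINS, 2):
            raise ValueError(f"Path2D requires shape ({N_BINS}, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("Path2D points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]


def observed_transform_path(
    cells: Optional[pd.DataFrame] = None, condition: str = "transform"
) -> Path2D:
    """Observed path from group means: point i = (corrugator_i, zygomaticus_i).

    With ``cells`` given, per-bin across-participant means of that cells
    table are used; otherwise the packaged printed group means.
    """
    coords = {}
    for muscle in ("corrugator", "zygomaticus"):
        if cells is None:
            df = load_group_means(muscle)
            sub = df[df["condition"] == condition].sort_values("bin")
            series = sub.set_index("bin")["mean"]
        else:
            sub = cells[(cells["condition"] == condition) & (cells["muscle"] == muscle)]
            series = sub.groupby("bin")["score"].mean().sort_index()
        if len(series) != N_BINS or series.isna().any():
            raise ValueError(f"observed path needs all {N_BINS} bins for {muscle}")
        coords[muscle] = series.to_numpy()
    return Path2D(np.column_stack([coords["corrugator"], coords["zygomaticus"]]))


def _segment(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return a[None, :] + t * (b - a)[None, :]


def build_model_path(
    family: str,
    anchor_start: np.ndarray,
    anchor_end: np.ndarray,
    vertex: Optional[int] = None,
) -> Path2D:
    """Model path of 16 points anchored at the observed endpoints.

    ``neutral``: corner at (start.x, end.y) — vertical then horizontal.
    ``mixed``: corner at (end.x, start.y) — horizontal then vertical.
    ``valence``: straight segment, 16 equally spaced points (no vertex).
    """
    a = np.asarray(anchor_start, float)
    b = np.asarray(anchor_end, float)
    if family == "valence":
        if vertex is not None:
            raise ValueError("valence trajectory takes no vertex")
        return Path2D(_segment(a, b, N_BINS), role="model")
    if family not in ("neutral", "mixed"):
        raise ValueError(f"unknown trajectory family {family!r}")
    if vertex is None or vertex not in VERTEX_RANGE:
        raise ValueError(f"vertex must lie in {VERTEX_RANGE.start}..{VERTEX_RANGE.stop - 1}")
    corner = np.array([a[0], b[1]]) if family == "neutral" else np.array([b[0], a[1]])
    pts = np.empty((N_BINS, 2))
    pts[:vertex] = _segment(a, corner, vertex)
    pts[vertex - 1 :] = _segment(corner, b, N_BINS - vertex + 1)
    return Path2D(pts, role="model")


def msd(
    model: "Path2D | np.ndarray", observed: "Path2D | np.ndarray", interior_only: bool = True
) -> float:
    """Mean squared Euclidean deviation between corresponding points.

    Averaged over the interior points by default: with endpoint anchoring
    the first and last deviations are identically zero and carry no
    information about the path shape. Accepts :class:`Path2D` or plain
    (n, 2) arrays of equal length.
    """
    mp = model.points if isinstance(model, Path2D) else np.asarray(model, float)
    op = observed.points if isinstance(observed, Path2D) else np.asarray(observed, float)
    if mp.shape != op.shape:
        raise ValueError("paths must have equal length")
    d2 = ((mp - op) ** 2).sum(axis=1)
    return float(d2[1:-1].mean() if interior_only else d2.mean())


@dataclass(frozen=True)
class TrajectoryFit:
    """Model-comparison table plus the winning family/vertex."""

    table: pd.DataFrame
    best_family: str
    best_vertex: Optional[int]
    best_msd: float

    def family_minimum(self, family: str) -> float:
        sub = self.table[self.table["family"] == family]
        if sub.empty:
            raise KeyError(f"no rows for family {family!r}")
        return float(sub["msd"].min())


def fit_all(observed: Path2D, anchors: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> TrajectoryFit:
    """Score every candidate trajectory against the observed path.

    Evaluates the neutral and mixed families at every vertex 2..15 plus
    the valence diagonal, all anchored at the observed endpoints (or
    explicit ``anchors``). Rows are ordered family-then-vertex.
    """
    a, b = anchors if anchors is not None else (observed.start, observed.end)
    rows = []
    for family in ("neutral", "mixed"):
        for v in VERTEX_RANGE:
            model = build_model_path(family, a, b, vertex=v)
            rows.append({"family": family, "vertex": v, "msd": msd(model, observed)})
    rows.append(
        {"family": "valence", "vertex": None, "msd": msd(build_model_path("valence", a, b), observed)}
    )
    table = pd.DataFrame(rows)

    order = {f: i for i, f in enumerate(FAMILIES)}
    ranked = sorted(
        table.itertuples(index=False),
        key=lambda r: (r.msd, N_BINS if pd.isna(r.vertex) else r.vertex, order[r.family]),
    )
    best = ranked[0]
    return TrajectoryFit(
        table=table,
        best_family=best.family,
        best_vertex=None if pd.isna(best.vertex) else int(best.vertex),
        best_msd=float(best.msd),
    )


def vertex_time_ms(vertex: int) -> int:
    """Time of a vertex index on the regulation grid (bin i -> i*500 ms)."""
    return vertex * BIN_WIDTH_MS


def jittered_path(
    family: str,
    anchor_start: np.ndarray,
    anchor_end: np.ndarray,
    vertex: Optional[int],
    jitter_sd: float,
    rng: np.random.Generator,
) -> Path2D:
    """Model path with Gaussian jitter on the interior points.

    Utility for model-recovery simulations: endpoints stay exact so the
    anchoring policy of :func:`fit_all` applies unchanged.
    """
    base = build_model_path(family, anchor_start, anchor_end, vertex=vertex).points.copy()
    noise = rng.normal(0.0, jitter_sd, size=base.shape)
    noise[0] = noise[-1] = 0.0
    return Path2D(base + noise, role="observed")
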