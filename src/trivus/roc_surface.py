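"""True class fractions, the ROC surface grid, and ellipsoidal confidence regions.

At a cut-point pair (c1, c2) with c1 <= c2 the three true class fractions
(TCFs) — the three-class analogue of specificity and sensitivity — are

    TCF1 = P(T <= c1 | class 1)        correct classification of class 1
    TCF2 = P(c1 < T <= c2 | class 2)   correct classification of class 2
    TCF3 = P(T > c2 | class 3)         correct classification of class 3

estimated by normalized sums of the corrected disease matrix. Sweeping
(c1, c2) over all admissible pairs traces the ROC surface in the unit cube;
the useless-test surface is the triangle plane with vertices (1,0,0),
(0,1,0), (0,0,1), and the volume under the surface is the VUS.

The cut-point interval convention is half-open, right-closed: TCF1 uses
``<= c1``, TCF2 uses ``(c1, c2]``, TCF3 uses ``> c2`` — with full data the
three regions partition the line, so the indicator rows of each subject
contribute to exactly one fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_prep import PreparedDataset
from .estimators import CorrectedDisease
from .inference import ModelSpec, _as_dhat, _fit_and_estimate, _one_bootstrap

__all__ = [
    "TCFPoint",
    "SurfaceGrid",
    "EllipsoidRegion",
    "tcf_at",
    "surface_grid",
    "surface_volume",
    "ellipsoid_region",
    "export_obj",
]


@dataclass
class TCFPoint:
    """True class fractions at one cut-point pair."""

    c1: float
    c2: float
    tcf1: float
    tcf2: float
    tcf3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tcf1, self.tcf2, self.tcf3])


@dataclass
class SurfaceGrid:
    """ROC surface evaluated on a cut-point grid (admissible pairs c1 <= c2)."""

    c1_grid: np.ndarray
    c2_grid: np.ndarray
    points: pd.DataFrame  # long format: c1, c2, tcf1, tcf2, tcf3
    method: str

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


@dataclass
class EllipsoidRegion:
    """Ellipsoidal confidence region for the TCF vector at a fixed cut pair.

    The region is { x : (x - center)' cov^{-1} (x - center) <= radius2 }
    with radius2 the chi-square(3) quantile at the confidence level and the
    covariance estimated by bootstrap over replicated TCF vectors.
    """

    center: np.ndarray
    covariance: np.ndarray
    radius2: float
    level: float
    degenerate: bool = False
    _inv: np.ndarray = field(default=None, repr=False)

    def mahalanobis2(self, x: np.ndarray) -> float:
        if self._inv is None:
            try:
                self._inv = np.linalg.inv(self.covariance)
            except np.linalg.LinAlgError:
                self._inv = np.linalg.pinv(self.covariance)
        d = np.asarray(x, dtype=float) - self.center
        return float(d @ self._inv @ d)

    def contains(self, x: np.ndarray) -> bool:
        return self.mahalanobis2(x) <= self.radius2


def tcf_at(dhat, test_values: np.ndarray, c1: float, c2: float) -> TCFPoint:
    """Estimate the three true class fractions at cut-points (c1, c2)."""
    if c1 > c2:
        raise ValueError("cut-points must satisfy c1 <= c2")
    d = _as_dhat(dhat)
    t = np.asarray(test_values, dtype=float)
    col = d.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError(f"each corrected-disease column needs positive sum, got {col}")
    tcf1 = float(d[t <= c1, 0].sum() / col[0])
    tcf2 = float(d[(t > c1) & (t <= c2), 1].sum() / col[1])
    tcf3 = float(d[t > c2, 2].sum() / col[2])
    return TCFPoint(c1=float(c1), c2=float(c2), tcf1=tcf1, tcf2=tcf2, tcf3=tcf3)


def _default_grid(t: np.ndarray) -> np.ndarray:
    lo, hi = t.min(), t.max()
    pad = max(1.0, hi - lo)
    return np.concatenate(([lo - pad], np.unique(t), [hi + pad]))


def surface_grid(
    dhat,
    test_values: np.ndarray,
    grid_size: int | None = None,
    c1_grid: np.ndarray | None = None,
    c2_grid: np.ndarray | None = None,
) -> SurfaceGrid:
    """Evaluate the ROC surface on a grid of cut-point pairs.

    Default grids are the unique observed test values augmented with
    below-minimum and above-maximum sentinels, so the surface reaches all
    three unit-cube corner vertices. ``grid_size`` instead requests an
    evenly spaced grid spanning slightly beyond the observed range.
    """
    d = _as_dhat(dhat)
    t = np.asarray(test_values, dtype=float)
    if c1_grid is None or c2_grid is None:
        if grid_size is not None:
            if grid_size < 2:
                raise ValueError("grid_size must be >= 2")
            lo, hi = t.min(), t.max()
            pad = max(1.0, hi - lo)
            g = np.linspace(lo - pad, hi + pad, grid_size)
        else:
            g = _default_grid(t)
        c1_grid = c1_grid if c1_grid is not None else g
        c2_grid = c2_grid if c2_grid is not None else g
    c1_grid = np.sort(np.asarray(c1_grid, dtype=float))
    c2_grid = np.sort(np.asarray(c2_grid, dtype=float))
    if c1_grid.size == 0 or c2_grid.size == 0:
        raise ValueError("cut-point grids must be non-empty")

    col = d.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError("each corrected-disease column needs positive sum")
    # cumulative class masses below each grid point: vectorized over the grid
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    cum = np.vstack([np.zeros(3), np.cumsum(ds, axis=0)])
    pos1 = np.searchsorted(ts, c1_grid, side="right")
    pos2 = np.searchsorted(ts, c2_grid, side="right")
    mass1_le = cum[pos1, 0] / col[0]            # P_hat(T <= c1 | 1)
    mass2_le1 = cum[pos1, 1] / col[1]
    mass2_le2 = cum[pos2, 1] / col[1]
    mass3_gt = 1.0 - cum[pos2, 2] / col[2]      # P_hat(T > c2 | 3)

    rows = []
    for i, a in enumerate(c1_grid):
        for j, b in enumerate(c2_grid):
            if a > b:
                continue
            rows.append(
                (a, b, mass1_le[i], mass2_le2[j] - mass2_le1[i], mass3_gt[j])
            )
    points = pd.DataFrame(rows, columns=["c1", "c2", "tcf1", "tcf2", "tcf3"])
    method = dhat.method if isinstance(dhat, CorrectedDisease) else "array"
    return SurfaceGrid(c1_grid=c1_grid, c2_grid=c2_grid, points=points, method=method)


def surface_volume(grid: SurfaceGrid, dhat, test_values: np.ndarray) -> float:
    """Numerically integrate the surface height TCF2 over (TCF1, TCF3).

    The volume under the ROC surface equals the integral of the correct
    class-2 fraction against the product measure of class-1 and class-3
    test-value distributions on the admissible region; the Riemann sum here
    uses the per-cut increments of TCF1 and decrements of TCF3 as the cell
    measures. A cross-check for :func:`~trivus.inference.vus_point`, which
    is exact.
    """
    d = _as_dhat(dhat)
    t = np.asarray(test_values, dtype=float)
    col = d.sum(axis=0)
    g1, g2 = grid.c1_grid, grid.c2_grid
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    cum = np.vstack([np.zeros(3), np.cumsum(ds, axis=0)])
    pos1 = np.searchsorted(ts, g1, side="right")
    pos2 = np.searchsorted(ts, g2, side="right")
    f1 = cum[pos1, 0] / col[0]                  # TCF1 along c1 grid
    f2_1 = cum[pos1, 1] / col[1]
    f2_2 = cum[pos2, 1] / col[1]
    s3 = 1.0 - cum[pos2, 2] / col[2]            # TCF3 along c2 grid
    w1 = np.diff(np.concatenate(([0.0], f1)))   # class-1 mass entering at c1[i]
    w3 = -np.diff(np.concatenate((s3, [0.0])))  # class-3 mass leaving at c2[j]
    vol = 0.0
    for i in range(g1.size):
        if w1[i] == 0:
            continue
        j0 = np.searchsorted(g2, g1[i], side="left")
        h = np.clip(f2_2[j0:] - f2_1[i], 0.0, None)
        vol += w1[i] * float(np.sum(w3[j0:] * h))
    return vol


def ellipsoid_region(
    data: PreparedDataset,
    method: str,
    model_spec: ModelSpec | None = None,
    c1: float = 0.0,
    c2: float = 0.0,
    level: float = 0.95,
    B: int = 250,
    seed: int = 0,
) -> EllipsoidRegion:
    """Bootstrap ellipsoidal confidence region for (TCF1, TCF2, TCF3).

    The center is the plug-in TCF estimate at (c1, c2); the covariance is
    the sample covariance of the TCF vector over ``B`` bootstrap replicates
    (resampling subjects and refitting the nuisance models each time); the
    squared radius is the chi-square(3 df) quantile at ``level``. A
    numerically singular covariance is flagged and handled through the
    pseudo-inverse.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if c1 > c2:
        raise ValueError("cut-points must satisfy c1 <= c2")
    spec = model_spec or ModelSpec()
    dh = _fit_and_estimate(data, method, spec)
    center = tcf_at(dh, data.test, c1, c2).as_array()
    reps = np.empty((B, 3))
    for r in range(B):
        _, dh_b, boot = _one_bootstrap(data, method, spec, seed + 1 + r)
        reps[r] = tcf_at(dh_b, boot.test, c1, c2).as_array()
    cov = np.cov(reps, rowvar=False)
    degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-12) < 3)
    radius2 = float(stats.chi2.ppf(level, df=3))
    inv = np.linalg.pinv(cov) if degenerate else np.linalg.inv(cov)
    return EllipsoidRegion(
        center=center,
        covariance=cov,
        radius2=radius2,
        level=level,
        degenerate=degenerate,
        _inv=inv,
    )


def export_obj(grid: SurfaceGrid, path) -> None:
    """Write the surface as a triangulated OBJ mesh in TCF coordinates.

    Vertices are the (tcf1, tcf3, tcf2) points of the admissible cut-point
    pairs; triangles connect neighbouring pairs on the (c1, c2) lattice.
    """
    pts = grid.points
    index = {}
    lines = []
    for row in pts.itertuples(index=False):
        index[(row.c1, row.c2)] = len(index) + 1  # OBJ is 1-based
        lines.append(f"v {row.tcf1:.6f} {row.tcf3:.6f} {row.tcf2:.6f}")
    g1, g2 = grid.c1_grid, grid.c2_grid
    for i in range(g1.size - 1):
        for j in range(g2.size - 1):
            quad = [
                index.get((g1[i], g2[j])),
                index.get((g1[i + 1], g2[j])),
                index.get((g1[i + 1], g2[j + 1])),
                index.get((g1[i], g2[j + 1])),
            ]
            if None in quad:
                continue
            a, b, c, d_ = quad
            lines.append(f"f {a} {b} {c}")
            lines.append(f"f {a} {c} {d_}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
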