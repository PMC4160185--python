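"""Geometry and summaries of the 2-D coordination space.

A coordination strategy is a point (relative phase, normalized range).
Bow changes fall inside the string-crossing band exactly when
|delta_phi| <= arcsin(r) under the sinusoidal model; that curve bounds
the grey region of the coordination-space plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CoordinationPoint:
    delta_phi_deg: float
    r: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must be in [0, 1], got {self.r}")


def boundary_phase(r: float | np.ndarray) -> float | np.ndarray:
    """Phase magnitude (degrees) at which a bow change sits on the band edge."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0.0) or np.any(r_arr > 1.0):
        raise ValueError("r must be in [0, 1]")
    out = np.degrees(np.arcsin(r_arr))
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def classify_inside(point: CoordinationPoint) -> bool:
    """True iff the bow change falls within the string-crossing band."""
    return abs(point.delta_phi_deg) <= boundary_phase(point.r)


@dataclass(frozen=True)
class CoverageEllipse:
    """Covariance-based ellipse containing a given fraction of the data."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation_deg: float
    coverage: float
    _cov_inv: np.ndarray = field(repr=False, default=None)
    _scale2: float = field(repr=False, default=0.0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = xy - np.asarray(self.center)
        m2 = np.einsum("ij,jk,ik->i", d, self._cov_inv, d)
        return m2 <= self._scale2

    @property
    def axis_ratio(self) -> float:
        a, b = self.semi_axes
        return min(a, b) / max(a, b)


def coverage_ellipse(points: np.ndarray, coverage: float = 0.68) -> CoverageEllipse:
    """Ellipse from the sample mean and covariance, scaled to ``coverage``.

    The radius is scaled by the square root of the chi-square(2) quantile
    so that, for bivariate normal data, the requested fraction of the
    distribution falls inside.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[0] / evals[1] < 1e-12:
        raise ValueError(
            "degenerate covariance (points collinear or identical); cannot "
            "construct a coverage ellipse"
        )
    scale2 = float(stats.chi2.ppf(coverage, df=2))
    semi = np.sqrt(evals[::-1]) * np.sqrt(scale2)  # major first
    major_vec = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])))
    return CoverageEllipse(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        orientation_deg=orientation,
        coverage=coverage,
        _cov_inv=np.linalg.inv(cov),
        _scale2=scale2,
    )


def distribution_summary(values: np.ndarray) -> dict[str, float]:
    """Median and 10th/90th percentiles (linear-interpolation convention)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values")
    p10, med, p90 = np.percentile(vals, [10, 50, 90])
    return {"median": float(med), "p10": float(p10), "p90": float(p90)}


# ---------------------------------------------------------------------- #
# plotting


def plot_coordination_space(
    points: np.ndarray | None = None,
    ellipses: list[CoverageEllipse] | None = None,
    ax=None,
    r_max: float = 1.0,
):
    """Coordination-space plot with the inside-band region shaded grey."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as _MplEllipse

    if ax is None:
        _, ax = plt.subplots()
    r_grid = np.linspace(0.0, r_max, 200)
    lim = boundary_phase(r_grid)
    ax.fill_betweenx(r_grid, -lim, lim, color="0.85", zorder=0)
    if points is not None:
        pts = np.atleast_2d(points)
        ax.plot(pts[:, 0], pts[:, 1], "o", ms=3, color="k", zorder=2)
    for ell in ellipses or []:
        ax.add_patch(
            _MplEllipse(
                ell.center,
                2 * ell.semi_axes[0],
                2 * ell.semi_axes[1],
                angle=ell.orientation_deg,
                fill=False,
                lw=1.2,
                zorder=3,
            )
        )
    ax.set_xlabel("relative phase (deg)")
    ax.set_ylabel("normalized range")
    ax.set_ylim(0, r_max)
    return ax
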