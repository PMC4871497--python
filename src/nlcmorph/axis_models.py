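"""Canal axis models built from per-slice centroid sequences.

The canal axis is modelled as a parametric curve s(z) = (x(z), y(z), z)
over the extended depth domain [z1 - delta/2, zp + delta/2], which spans
the outer faces of the first and last canal slices.  Two families are
supported:

* the *polygonal* axis: linear segments joining the centroids, extended
  from the two extreme centroids along the terminal segment directions
  to the outer delimiting planes;
* *polynomial* axes of degree 2, 3 or 4: x(z) and y(z) fitted
  separately by least squares,

      x(z) = a0 + a1 z + a2 z^2 + a3 z^3 + a4 z^4
      y(z) = b0 + b1 z + b2 z^2 + b3 z^3 + b4 z^4

  with goodness of fit assessed by the squared Pearson correlation
  between fitted and observed coordinate values (identical to the
  coefficient of determination for least-squares fits with intercept).

Conditioning: fits are computed internally on z rescaled to [-1, 1]
about mid-domain and the coefficients mapped back to raw z, because raw
powers of depths up to ~70 mm are ill-conditioned.  Reported
coefficients are always in raw z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numpy.polynomial import Polynomial

__all__ = [
    "CentroidSequence",
    "PolynomialAxis",
    "PolygonalAxis",
    "FitReport",
    "fit_polynomial_axis",
    "build_polygonal_axis",
    "evaluate_axis",
    "tangent_at",
    "goodness_of_fit",
    "axis_table",
]

_DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class CentroidSequence:
    """Ordered canal centroids (c_1 ... c_p) with constant z-step delta."""

    points: np.ndarray
    delta: float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (p, 3)")
        if pts.shape[0] < 3:
            raise ValueError("need at least 3 centroids")
        dz = np.diff(pts[:, 2])
        if np.any(dz <= 0) or not np.allclose(dz, self.delta, atol=1e-6):
            raise ValueError("z must increase in constant steps of delta")

    @property
    def p(self) -> int:
        return self.points.shape[0]

    @property
    def z1(self) -> float:
        return float(self.points[0, 2])

    @property
    def zp(self) -> float:
        return float(self.points[-1, 2])

    @property
    def domain(self) -> tuple[float, float]:
        """Extended domain spanning the outer delimiting planes."""
        return (self.z1 - self.delta / 2.0, self.zp + self.delta / 2.0)

    @classmethod
    def from_segmentation(cls, seg) -> "CentroidSequence":
        return cls(points=seg.centroid_array(), delta=seg.geometry.slice_spacing_delta)


def _pearson_r2(fitted: np.ndarray, observed: np.ndarray, tol: float = 1e-12) -> float:
    """Squared Pearson correlation of fitted vs observed values.

    Degenerate case: if the observed (or fitted) values have ~zero
    variance the correlation is 0/0; we report 1.0 when the residuals
    are also ~zero (a perfect constant fit) and 0.0 otherwise.
    """
    fo = fitted - fitted.mean()
    oo = observed - observed.mean()
    denom = math.sqrt(float(fo @ fo) * float(oo @ oo))
    scale = max(1.0, float(np.abs(observed).max()))
    if denom <= tol * scale * scale:
        sse = float(((fitted - observed) ** 2).sum())
        return 1.0 if sse <= (tol * scale) ** 2 * len(observed) else 0.0
    r = float(fo @ oo) / denom
    return min(1.0, r * r)


@dataclass(frozen=True)
class PolynomialAxis:
    """Least-squares polynomial axis of degree 2, 3 or 4.

    Coefficients are in raw z, ascending order (a0 first).
    """

    degree: int
    a_coeffs: np.ndarray
    b_coeffs: np.ndarray
    domain: tuple[float, float]
    r2_x: float
    r2_y: float
    n_points: int

    def __post_init__(self):
        object.__setattr__(self, "a_coeffs", np.asarray(self.a_coeffs, dtype=float))
        object.__setattr__(self, "b_coeffs", np.asarray(self.b_coeffs, dtype=float))

    def _check_domain(self, z: float):
        lo, hi = self.domain
        if not (lo - _DOMAIN_TOL <= z <= hi + _DOMAIN_TOL):
            raise ValueError(f"z={z} outside axis domain [{lo}, {hi}]")

    def __call__(self, z: float) -> np.ndarray:
        self._check_domain(z)
        return np.array(
            [
                float(np.polynomial.polynomial.polyval(z, self.a_coeffs)),
                float(np.polynomial.polynomial.polyval(z, self.b_coeffs)),
                z,
            ]
        )

    def derivative(self, z) -> tuple[np.ndarray, np.ndarray]:
        """(x'(z), y'(z)); accepts scalars or arrays, no domain check."""
        da = np.polynomial.polynomial.polyder(self.a_coeffs)
        db = np.polynomial.polynomial.polyder(self.b_coeffs)
        return (
            np.polynomial.polynomial.polyval(z, da),
            np.polynomial.polynomial.polyval(z, db),
        )

    def tangent(self, z: float) -> np.ndarray:
        self._check_domain(z)
        dx, dy = self.derivative(z)
        v = np.array([float(dx), float(dy), 1.0])
        return v / np.linalg.norm(v)

    def coeffs_highest_first(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient layout used in published axis-model tables."""
        return self.a_coeffs[::-1].copy(), self.b_coeffs[::-1].copy()

    def to_record(self) -> dict:
        a_hi, b_hi = self.coeffs_highest_first()
        rec = {"degree": self.degree, "r2_x": self.r2_x, "r2_y": self.r2_y,
               "z_min": self.domain[0], "z_max": self.domain[1],
               "n_slices": self.n_points}
        for k, v in enumerate(a_hi):
            rec[f"a{self.degree - k}"] = float(v)
        for k, v in enumerate(b_hi):
            rec[f"b{self.degree - k}"] = float(v)
        return rec


@dataclass(frozen=True)
class PolygonalAxis:
    """Piecewise-linear axis through the centroids plus two extensions.

    ``vertices`` holds p + 2 points: the extension endpoint on the lower
    outer plane, the p centroids, and the endpoint on the upper plane.
    """

    vertices: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))

    @property
    def segment_directions(self) -> np.ndarray:
        d = np.diff(self.vertices, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def _check_domain(self, z: float):
        lo, hi = self.domain
        if not (lo - _DOMAIN_TOL <= z <= hi + _DOMAIN_TOL):
            raise ValueError(f"z={z} outside axis domain [{lo}, {hi}]")

    def __call__(self, z: float) -> np.ndarray:
        self._check_domain(z)
        zs = self.vertices[:, 2]
        z = min(max(z, zs[0]), zs[-1])
        j = int(np.searchsorted(zs, z, side="right")) - 1
        j = min(max(j, 0), len(zs) - 2)
        z0, z1 = zs[j], zs[j + 1]
        t = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        return self.vertices[j] * (1 - t) + self.vertices[j + 1] * t

    def tangent(self, z: float) -> np.ndarray:
        """Unit direction of the segment containing z.

        Exactly at an interior vertex the tangent is the renormalised
        mean of the two adjacent segment directions.
        """
        self._check_domain(z)
        zs = self.vertices[:, 2]
        dirs = self.segment_directions
        interior = zs[1:-1]
        hit = np.nonzero(np.isclose(interior, z, atol=1e-12))[0]
        if hit.size:
            j = int(hit[0])  # vertex j+1 joins segments j and j+1
            v = dirs[j] + dirs[j + 1]
            return v / np.linalg.norm(v)
        zc = min(max(z, zs[0]), zs[-1])
        j = int(np.searchsorted(zs, zc, side="right")) - 1
        j = min(max(j, 0), len(dirs) - 1)
        return dirs[j]


AxisModel = Union[PolynomialAxis, PolygonalAxis]


def fit_polynomial_axis(centroids: CentroidSequence, degree: int) -> PolynomialAxis:
    """Fit x(z) and y(z) separately by least squares.

    Requires p >= degree + 1 points.  Fitting runs on z rescaled to
    [-1, 1]; the returned coefficients are mapped back to raw z.
    """
    if degree not in (2, 3, 4):
        raise ValueError("degree must be 2, 3 or 4")
    p = centroids.p
    if p <= degree:
        raise ValueError(f"{p} centroids cannot determine a degree-{degree} fit")
    z = centroids.points[:, 2]
    lo, hi = centroids.domain

    coeffs = []
    r2 = []
    for coord in (0, 1):
        v = centroids.points[:, coord]
        fit = Polynomial.fit(z, v, deg=degree)  # fitted in scaled window
        raw = fit.convert().coef
        if raw.size < degree + 1:  # trailing zero coefficients trimmed
            raw = np.pad(raw, (0, degree + 1 - raw.size))
        fitted = np.polynomial.polynomial.polyval(z, raw)
        coeffs.append(raw)
        r2.append(_pearson_r2(fitted, v))

    return PolynomialAxis(
        degree=degree,
        a_coeffs=coeffs[0],
        b_coeffs=coeffs[1],
        domain=(lo, hi),
        r2_x=r2[0],
        r2_y=r2[1],
        n_points=p,
    )


def build_polygonal_axis(centroids: CentroidSequence) -> PolygonalAxis:
    """Join the centroids with linear segments and extend to the outer planes.

    The extensions continue the first and last segment directions until
    they intersect the planes z = z1 - delta/2 and z = zp + delta/2.
    """
    pts = centroids.points
    lo, hi = centroids.domain

    d_first = pts[1] - pts[0]
    d_last = pts[-1] - pts[-2]
    for name, d in (("first", d_first), ("last", d_last)):
        if abs(d[2]) < 1e-12:
            raise ValueError(f"{name} segment is parallel to the slice planes")

    t_lo = (lo - pts[0, 2]) / d_first[2]
    t_hi = (hi - pts[-1, 2]) / d_last[2]
    v_lo = pts[0] + t_lo * d_first
    v_hi = pts[-1] + t_hi * d_last
    vertices = np.vstack([v_lo, pts, v_hi])
    return PolygonalAxis(vertices=vertices, domain=(lo, hi))


def evaluate_axis(axis: AxisModel, z: float) -> np.ndarray:
    """Point (x(z), y(z), z) on the model curve."""
    return axis(z)


def tangent_at(axis: AxisModel, z: float) -> np.ndarray:
    """Unit tangent of the model curve at depth z."""
    return axis.tangent(z)


@dataclass(frozen=True)
class FitReport:
    """Goodness-of-fit diagnostics for one polynomial axis.

    For each coordinate: r^2 (squared Pearson correlation of fitted vs
    observed), the Fisher Z transform of r, the 95% confidence interval
    of r from the normal approximation with standard error
    1/sqrt(p - 3), the implied lower bound of r^2, and a sufficiency
    flag (lower r^2 bound >= 0.95).  With p <= 3 the interval is
    undefined and the flag is None (indeterminate).
    """

    r2_x: float
    r2_y: float
    fisher_z_x: float
    fisher_z_y: float
    r_ci_x: Optional[tuple[float, float]]
    r_ci_y: Optional[tuple[float, float]]
    r2_lower_x: Optional[float]
    r2_lower_y: Optional[float]
    sufficient_x: Optional[bool]
    sufficient_y: Optional[bool]


def _fisher_ci(r: float, n: int, z_crit: float = 1.959963984540054):
    r = min(r, 1.0 - 1e-15)
    zr = math.atanh(r)
    if n <= 3:
        return zr, None, None, None
    se = 1.0 / math.sqrt(n - 3)
    lo, hi = math.tanh(zr - z_crit * se), math.tanh(zr + z_crit * se)
    r2_lower = lo * lo if lo > 0 else 0.0
    return zr, (lo, hi), r2_lower, r2_lower >= 0.95


def goodness_of_fit(axis: PolynomialAxis, centroids: CentroidSequence) -> FitReport:
    """Fisher-Z based sufficiency assessment of a fitted axis."""
    n = centroids.p
    rx = math.sqrt(max(axis.r2_x, 0.0))
    ry = math.sqrt(max(axis.r2_y, 0.0))
    zx, cix, lox, okx = _fisher_ci(rx, n)
    zy, ciy, loy, oky = _fisher_ci(ry, n)
    return FitReport(
        r2_x=axis.r2_x,
        r2_y=axis.r2_y,
        fisher_z_x=zx,
        fisher_z_y=zy,
        r_ci_x=cix,
        r_ci_y=ciy,
        r2_lower_x=lox,
        r2_lower_y=loy,
        sufficient_x=okx,
        sufficient_y=oky,
    )


def axis_table(models: dict) -> "pandas.DataFrame":
    """Tabulate fitted axes (one row per subject) in the published
    axis-model layout: r2_x, x-coefficients highest degree first, r2_y,
    y-coefficients, extended z-range and slice count."""
    import pandas as pd

    rows = []
    for subject, axis in models.items():
        a_hi, b_hi = axis.coeffs_highest_first()
        row = {"subject": subject, "r2_x": axis.r2_x}
        row.update({f"x_c{axis.degree - k}": float(v) for k, v in enumerate(a_hi)})
        row["r2_y"] = axis.r2_y
        row.update({f"y_c{axis.degree - k}": float(v) for k, v in enumerate(b_hi)})
        row["z_min"], row["z_max"] = axis.domain
        row["n_slices"] = axis.n_points
        rows.append(row)
    return pd.DataFrame(rows)
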