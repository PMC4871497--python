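"""Synthetic CT phantoms of curved bony canals with known geometry.

A phantom is a tube whose centreline is a polynomial curve
(x(z), y(z), z) of degree <= 4, with a circular cross-section of radius
r(z) orthogonal to the axis, surrounded by a bone wall of constant
thickness, embedded in a background medium.  The tube is rasterised
into a voxel grid by supersampled occupancy (4 samples per voxel edge
by default, i.e. 64 sub-samples per voxel), which emulates the partial
volume effect at boundaries; optional i.i.d. Gaussian HU noise emulates
CT quantum noise.

Membership of a sample point is decided by its distance to the local
tangent line of the axis at the sample's depth — exact for straight
tubes, and accurate for the gently curved axes used in validation
(curvature radius >> tube radius).  The analytic ground truth
(centroids, axial areas pi r^2 / cos beta, arc length, volume
integral of pi r^2 ds) uses the same tube definition, so recovery
errors measure the imaging pipeline, not the phantom model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ct_io import CTVolume, VoxelGeometry
from .morphometry import MorphometryResult

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "ground_truth_morphometry",
    "radius_constant",
    "radius_taper",
    "radius_waist",
]


def radius_constant(r: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant lumen radius r mm."""
    return lambda z: np.full_like(np.asarray(z, dtype=float), r)


def radius_taper(r0: float, r1: float, z0: float, z1: float) -> Callable:
    """Linear taper from r0 at z0 to r1 at z1."""
    def f(z):
        z = np.asarray(z, dtype=float)
        t = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
        return r0 + (r1 - r0) * t
    return f


def radius_waist(r_end: float, r_min: float, z0: float, z1: float, z_waist: float) -> Callable:
    """Smooth waist: radius dips to r_min at z_waist, r_end at both ends.

    Piecewise-quadratic in z, so the minimum position is exactly z_waist.
    """
    def f(z):
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        left = z <= z_waist
        t = np.where(left, (z - z_waist) / (z0 - z_waist), (z - z_waist) / (z1 - z_waist))
        t = np.clip(t, 0.0, 1.0)
        out = r_min + (r_end - r_min) * t * t
        return out
    return f


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic canal.

    ``x_coeffs``/``y_coeffs`` are raw-z polynomial coefficients in
    ascending order (constant first), degree <= 4.  The canal occupies
    slices ``first_slice .. last_slice`` inclusive; beyond those, solid
    bone caps the tube so that slice-tracking terminates.
    """

    x_coeffs: Sequence[float]
    y_coeffs: Sequence[float]
    radius_profile: Callable[[np.ndarray], np.ndarray]
    first_slice: int
    last_slice: int
    n_slices: int
    shape_rc: tuple[int, int] = (64, 64)
    pixel_spacing: float = 0.3
    delta: float = 0.625
    wall_thickness: float = 1.0
    # thin lacrimal walls show depressed HU (well below cortical bone);
    # lumen/wall defaults straddle the 300 HU segmentation threshold at
    # their mid-level so partial-volume boundary voxels split evenly
    hu_lumen: float = -50.0
    hu_wall: float = 650.0
    hu_background: float = -1000.0
    noise_sd: float = 0.0
    seed: int = 0
    supersample: int = 4
    subject_id: str = "phantom"

    def __post_init__(self):
        self.x_coeffs = np.asarray(self.x_coeffs, dtype=float)
        self.y_coeffs = np.asarray(self.y_coeffs, dtype=float)
        if len(self.x_coeffs) > 5 or len(self.y_coeffs) > 5:
            raise ValueError("axis polynomials must have degree <= 4")
        if not (0 <= self.first_slice <= self.last_slice < self.n_slices):
            raise ValueError("canal slice range must lie inside the grid")
        if self.wall_thickness < self.pixel_spacing:
            raise ValueError("wall thickness must be >= one pixel spacing")

    # --- axis helpers ---------------------------------------------------

    def axis_point(self, z):
        z = np.asarray(z, dtype=float)
        return (
            np.polynomial.polynomial.polyval(z, self.x_coeffs),
            np.polynomial.polynomial.polyval(z, self.y_coeffs),
            z,
        )

    def axis_derivative(self, z):
        z = np.asarray(z, dtype=float)
        dx = np.polynomial.polynomial.polyval(z, np.polynomial.polynomial.polyder(self.x_coeffs))
        dy = np.polynomial.polynomial.polyval(z, np.polynomial.polynomial.polyder(self.y_coeffs))
        return dx, dy

    def cos_beta(self, z):
        dx, dy = self.axis_derivative(z)
        return 1.0 / np.sqrt(1.0 + dx * dx + dy * dy)

    @property
    def canal_p(self) -> int:
        return self.last_slice - self.first_slice + 1

    @property
    def z_lo(self) -> float:
        """Lower outer delimiting plane of the canal."""
        return self.first_slice * self.delta - self.delta / 2.0

    @property
    def z_hi(self) -> float:
        return self.last_slice * self.delta + self.delta / 2.0


@dataclass
class GroundTruth:
    """Analytic truth accompanying a generated phantom."""

    spec: PhantomSpec
    centroids: np.ndarray           # (p, 3) true axis points at canal slice z's
    axial_areas: np.ndarray         # pi r^2 / cos beta per canal slice, mm^2
    orthogonal_areas: np.ndarray    # pi r^2 per canal slice, mm^2
    arc_length: float               # over the extended domain, mm
    volume: float                   # integral pi r^2 ds between the outer planes, mm^3

    def lumen_mask(self, slice_index: int) -> np.ndarray:
        """Analytic lumen membership of voxel centres in one slice."""
        spec = self.spec
        n_rows, n_cols = spec.shape_rc
        ps = spec.pixel_spacing
        z = slice_index * spec.delta
        xs = np.arange(n_cols) * ps
        ys = np.arange(n_rows) * ps
        X, Y = np.meshgrid(xs, ys)
        d = _distance_to_axis(spec, X.ravel(), Y.ravel(), np.full(X.size, z))
        r = spec.radius_profile(np.full(X.size, z))
        return (d <= r).reshape(n_rows, n_cols)


def _distance_to_axis(spec: PhantomSpec, x, y, z):
    """Distance of points to the local tangent line of the axis."""
    cx, cy, _ = spec.axis_point(z)
    dxdz, dydz = spec.axis_derivative(z)
    # unit tangent (dxdz, dydz, 1)/norm
    norm = np.sqrt(1.0 + dxdz * dxdz + dydz * dydz)
    tx, ty, tz = dxdz / norm, dydz / norm, 1.0 / norm
    px, py, pz = x - cx, y - cy, 0.0  # sample z equals the param z
    dot = px * tx + py * ty
    qx, qy, qz = px - dot * tx, py - dot * ty, -dot * tz
    return np.sqrt(qx * qx + qy * qy + qz * qz)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterise the tube into a HU grid and return it with its truth.

    Occupancy of lumen and wall is evaluated on a ``supersample``^3
    sub-grid per voxel and averaged; HU is the occupancy-weighted blend
    of lumen, wall and background levels.  Gaussian noise (sd in HU) is
    added with the spec's seed; noise_sd = 0 yields a deterministic
    volume.
    """
    n_rows, n_cols = spec.shape_rc
    ps = spec.pixel_spacing
    s = spec.supersample

    # sub-sample offsets within one voxel, centred
    off = (np.arange(s) + 0.5) / s - 0.5
    ox = off * ps
    oz = off * spec.delta

    xs = np.arange(n_cols) * ps
    ys = np.arange(n_rows) * ps

    # check the canal stays inside the grid
    z_dense = np.linspace(spec.z_lo, spec.z_hi, 201)
    cx, cy, _ = spec.axis_point(z_dense)
    r_dense = spec.radius_profile(z_dense) + spec.wall_thickness
    margin_bad = (
        (cx - r_dense < 0) | (cx + r_dense > xs[-1])
        | (cy - r_dense < 0) | (cy + r_dense > ys[-1])
    )
    if margin_bad.any():
        z_bad = float(z_dense[margin_bad][0])
        raise ValueError(
            f"canal exits the grid near z={z_bad:.3f} mm "
            f"(first offending slice ~{int(round(z_bad / spec.delta))})"
        )

    vox = np.full((spec.n_slices, n_rows, n_cols), spec.hu_background, dtype=float)

    X0, Y0 = np.meshgrid(xs, ys)  # (rows, cols)
    for i in range(spec.n_slices):
        z0 = i * spec.delta
        lum_acc = np.zeros((n_rows, n_cols))
        wall_acc = np.zeros((n_rows, n_cols))
        for dz in oz:
            z = z0 + dz
            in_canal_z = spec.z_lo <= z <= spec.z_hi
            for dyy in ox:
                for dxx in ox:
                    d = _distance_to_axis(
                        spec,
                        (X0 + dxx).ravel(),
                        (Y0 + dyy).ravel(),
                        np.full(X0.size, z),
                    ).reshape(n_rows, n_cols)
                    r = float(spec.radius_profile(np.array([z]))[0])
                    wall_hit = d <= r + spec.wall_thickness
                    if in_canal_z:
                        lum_hit = d <= r
                        lum_acc += lum_hit
                        wall_acc += wall_hit & ~lum_hit
                    else:
                        wall_acc += wall_hit  # capped end: solid bone plug
        total = s ** 3
        lum = lum_acc / total
        wal = wall_acc / total
        bg = 1.0 - lum - wal
        vox[i] = bg * spec.hu_background + lum * spec.hu_lumen + wal * spec.hu_wall

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox += rng.normal(0.0, spec.noise_sd, size=vox.shape)

    geometry = VoxelGeometry.uniform(ps, spec.delta, spec.n_slices, slice_thickness=spec.delta)
    volume = CTVolume(voxels=vox, geometry=geometry, subject_id=spec.subject_id)

    truth = _make_ground_truth(spec)
    return volume, truth


def _make_ground_truth(spec: PhantomSpec, n_quad: int = 200_001) -> GroundTruth:
    z_slices = (spec.first_slice + np.arange(spec.canal_p)) * spec.delta
    cx, cy, cz = spec.axis_point(z_slices)
    centroids = np.column_stack([cx, cy, cz])
    r = spec.radius_profile(z_slices)
    cosb = spec.cos_beta(z_slices)
    orth = math.pi * r * r
    axial = orth / cosb

    # arc length over the extended domain and tube volume between outer
    # planes, by dense trapezoidal quadrature (independent of scipy.quad)
    zq = np.linspace(spec.z_lo, spec.z_hi, n_quad)
    dx, dy = spec.axis_derivative(zq)
    speed = np.sqrt(1.0 + dx * dx + dy * dy)
    arc = float(np.trapezoid(speed, zq))
    rq = spec.radius_profile(zq)
    vol = float(np.trapezoid(math.pi * rq * rq * speed, zq))

    return GroundTruth(
        spec=spec,
        centroids=centroids,
        axial_areas=axial,
        orthogonal_areas=orth,
        arc_length=arc,
        volume=vol,
    )


def ground_truth_morphometry(spec: PhantomSpec) -> MorphometryResult:
    """Analytic/high-resolution-numeric twin of the pipeline's result.

    Computed independently of the imaging pipeline: lengths by dense
    quadrature on the true axis, areas from pi r(z)^2 and the true
    cos beta(z), volume as the tube integral of pi r^2 ds.
    """
    truth = _make_ground_truth(spec)
    p = spec.canal_p
    delta = spec.delta

    # polygonal truth: segments through the true centroids + extensions
    pts = truth.centroids
    d_first = pts[1] - pts[0]
    d_last = pts[-1] - pts[-2]
    v_lo = pts[0] + (spec.z_lo - pts[0, 2]) / d_first[2] * d_first
    v_hi = pts[-1] + (spec.z_hi - pts[-1, 2]) / d_last[2] * d_last
    verts = np.vstack([v_lo, pts, v_hi])
    polyg_len = float(np.linalg.norm(np.diff(verts, axis=0), axis=1).sum())

    lo_pt = np.array(spec.axis_point(np.array([spec.z_lo]))).ravel()
    hi_pt = np.array(spec.axis_point(np.array([spec.z_hi]))).ravel()
    exl = float(np.linalg.norm(hi_pt - lo_pt))

    axial_profile = list(zip(truth.centroids[:, 2], truth.axial_areas))
    orth_profile = list(zip(truth.centroids[:, 2], truth.orthogonal_areas))

    def _min(profile):
        areas = np.array([a for _, a in profile])
        zs = np.array([z for z, _ in profile])
        j = int(np.argmin(areas))
        return float(areas[j]), float(zs[j])

    min_ax, z_min_ax = _min(axial_profile)
    min_or, z_min_or = _min(orth_profile)

    res = MorphometryResult(
        Vol=truth.volume,
        AxL=p * delta,
        ExL=exl,
        PolygL=polyg_len,
        Polyn2L=truth.arc_length,
        Polyn3L=truth.arc_length,
        Polyn4L=truth.arc_length,
        SecA=float(np.mean(truth.axial_areas)),
        SecPolygA=float(np.mean(truth.orthogonal_areas)),
        SecPolyn2A=float(np.mean(truth.orthogonal_areas)),
        SecPolyn3A=float(np.mean(truth.orthogonal_areas)),
        SecPolyn4A=float(np.mean(truth.orthogonal_areas)),
        MinSecA=min_ax,
        MinSecPolygA=min_or,
        MinSecPolyn2A=min_or,
        MinSecPolyn3A=min_or,
        MinSecPolyn4A=min_or,
        MinSecD=abs(z_min_ax - spec.z_lo),
        MinSecPolygD=abs(z_min_or - spec.z_lo),
        MinSecPolyn2D=abs(z_min_or - spec.z_lo),
        MinSecPolyn3D=abs(z_min_or - spec.z_lo),
        MinSecPolyn4D=abs(z_min_or - spec.z_lo),
        subject_id=spec.subject_id,
    )
    return res
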