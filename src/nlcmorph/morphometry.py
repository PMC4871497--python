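"""Canal morphometry: lengths, cross-sectional areas, volume.

Six length estimators are provided: the axial length (distance between
the outer faces of the delimiting slices), the end-to-end length
(distance between the axis endpoints on those outer planes), the
polygonal path length and arc lengths of the degree-2/3/4 polynomial
axes.  Cross-sectional areas come in an axial flavour (pixel-count area
in the CT plane, A_k) and orthogonal flavours per axis model, computed
either by projection

    A_k_perp = A_k * cos(beta_k)

where beta_k is the angle between the axis tangent and the scanner
z-axis, or directly by reslicing the volume in the plane orthogonal to
the axis and re-segmenting.  The projection is valid when the canal
path does not change abruptly; the reslice route is the reference and a
warning is emitted when the two disagree by more than 10% at any slice.

Volume is pure voxel summation: masked voxel count times voxel volume.
No end-wedge correction is applied at the canal ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy import integrate, ndimage

from .axis_models import (
    AxisModel,
    CentroidSequence,
    PolygonalAxis,
    PolynomialAxis,
    build_polygonal_axis,
    fit_polynomial_axis,
)
from .ct_io import CTVolume, voxel_volume
from .segmentation import CanalSegmentation, SegmentationParams

__all__ = [
    "MorphometryResult",
    "axial_length",
    "end_to_end_length",
    "polygonal_length",
    "polynomial_length",
    "axial_area_profile",
    "orthogonal_area_profile",
    "resliced_orthogonal_area",
    "mean_sectional_area",
    "min_sectional_area",
    "min_area_depth",
    "canal_volume",
    "compute_all",
]

#: canonical column order of the morphometric variables
VARIABLE_NAMES = [
    "Vol",
    "AxL", "ExL", "PolygL", "Polyn2L", "Polyn3L", "Polyn4L",
    "SecA", "SecPolygA", "SecPolyn2A", "SecPolyn3A", "SecPolyn4A",
    "MinSecA", "MinSecPolygA", "MinSecPolyn2A", "MinSecPolyn3A", "MinSecPolyn4A",
    "MinSecD", "MinSecPolygD", "MinSecPolyn2D", "MinSecPolyn3D", "MinSecPolyn4D",
]


@dataclass
class MorphometryResult:
    """The 21 axis/area variables plus voxel-summation volume, per canal.

    Lengths in mm, areas in mm^2, Vol in mm^3.  Variables whose axis
    model is underdetermined for the available slice count are None.
    """

    Vol: float
    AxL: float
    ExL: Optional[float] = None
    PolygL: Optional[float] = None
    Polyn2L: Optional[float] = None
    Polyn3L: Optional[float] = None
    Polyn4L: Optional[float] = None
    SecA: Optional[float] = None
    SecPolygA: Optional[float] = None
    SecPolyn2A: Optional[float] = None
    SecPolyn3A: Optional[float] = None
    SecPolyn4A: Optional[float] = None
    MinSecA: Optional[float] = None
    MinSecPolygA: Optional[float] = None
    MinSecPolyn2A: Optional[float] = None
    MinSecPolyn3A: Optional[float] = None
    MinSecPolyn4A: Optional[float] = None
    MinSecD: Optional[float] = None
    MinSecPolygD: Optional[float] = None
    MinSecPolyn2D: Optional[float] = None
    MinSecPolyn3D: Optional[float] = None
    MinSecPolyn4D: Optional[float] = None
    subject_id: str = ""
    laterality: str = ""

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "laterality": self.laterality}
        row.update({name: getattr(self, name) for name in VARIABLE_NAMES})
        return row


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def axial_length(seg: CanalSegmentation) -> float:
    """Distance between the external planes of the delimiting slices: p * delta."""
    return seg.n_slices * seg.geometry.slice_spacing_delta


def end_to_end_length(axis: AxisModel) -> float:
    """Distance between the axis points on the two outer delimiting planes."""
    lo, hi = axis.domain
    return float(np.linalg.norm(axis(hi) - axis(lo)))


def polygonal_length(axis: PolygonalAxis) -> float:
    """Sum of segment lengths, extensions included."""
    return float(np.linalg.norm(np.diff(axis.vertices, axis=0), axis=1).sum())


def polynomial_length(axis: PolynomialAxis, epsabs: float = 1e-3) -> float:
    """Arc length of the polynomial curve over its extended domain.

    Adaptive quadrature of sqrt(1 + x'(z)^2 + y'(z)^2) with absolute
    tolerance ``epsabs`` mm (default 1e-3).
    """
    lo, hi = axis.domain

    def speed(z):
        dx, dy = axis.derivative(z)
        return np.sqrt(1.0 + dx * dx + dy * dy)

    val, _ = integrate.quad(speed, lo, hi, epsabs=epsabs, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# areas
# ---------------------------------------------------------------------------

def axial_area_profile(seg: CanalSegmentation) -> list[tuple[float, float]]:
    """Per-slice (z, A_k) pixel-count areas, ordered by z."""
    return [(float(r.centroid[2]), float(r.axial_area)) for r in seg.regions]


def orthogonal_area_profile(
    seg: CanalSegmentation, axis: AxisModel
) -> list[tuple[float, float, float]]:
    """Per-slice (z, A_k_perp, cos beta_k) by the projection method.

    cos(beta_k) is the z-component of the unit tangent at the slice z.
    A canal doubling back (tangent with non-positive z-component) makes
    the projection ill-defined and is rejected.
    """
    out = []
    for z, a_k in axial_area_profile(seg):
        t = axis.tangent(z)
        cosb = float(t[2])
        if cosb <= 0:
            raise ValueError(
                f"axis tangent has non-positive z-component at z={z}; "
                "the canal doubles back and the projection method is invalid"
            )
        out.append((z, a_k * cosb, cosb))
    return out


def _inplane_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ez = np.array([0.0, 0.0, 1.0])
    u = np.cross(t, ez)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = u / nu
    v = np.cross(t, u)
    return u, v / np.linalg.norm(v)


def resliced_orthogonal_area(
    volume: CTVolume,
    axis: AxisModel,
    z_k: float,
    params: SegmentationParams | None = None,
    fov_mm: float = 20.0,
    core_mm: float = 4.0,
) -> Optional[float]:
    """Directly measure A_k_perp by oblique reslicing.

    Builds the plane through the axis point at ``z_k`` orthogonal to the
    tangent there, samples HU on a regular in-plane grid by trilinear
    interpolation, segments the canal in the resliced image seeded at
    the axis point, and returns the pixel-count area in mm^2.

    Raises when the central ``core_mm`` of the plane exits the volume;
    returns None when segmentation fails on the reslice (distinct from
    a zero area).
    """
    params = params or SegmentationParams()
    volume.require_validated()
    geo = volume.geometry
    centre = axis(z_k)
    t = axis.tangent(z_k)
    u, v = _inplane_basis(t)

    h = min(geo.pixel_spacing_row, geo.pixel_spacing_col)
    n = int(np.ceil(fov_mm / h)) | 1  # odd so the centre is a grid node
    offs = (np.arange(n) - n // 2) * h
    A, B = np.meshgrid(offs, offs, indexing="xy")
    if t[2] > 1.0 - 1e-8:
        # orthogonal plane coincides with the axial plane: snap the grid
        # to the voxel lattice so sampling reduces to the original pixels
        centre = centre.copy()
        centre[0] = round(centre[0] / geo.pixel_spacing_col) * geo.pixel_spacing_col
        centre[1] = round(centre[1] / geo.pixel_spacing_row) * geo.pixel_spacing_row
        u, v = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    pts = centre[None, None, :] + A[..., None] * u[None, None, :] + B[..., None] * v[None, None, :]

    # mm -> fractional voxel indices
    idx = np.empty_like(pts)
    idx[..., 0] = pts[..., 2] / geo.slice_spacing_delta          # slice
    idx[..., 1] = pts[..., 1] / geo.pixel_spacing_row            # row
    idx[..., 2] = pts[..., 0] / geo.pixel_spacing_col            # col
    shape = np.array(volume.shape, dtype=float)

    core = (np.abs(A) <= core_mm / 2) & (np.abs(B) <= core_mm / 2)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    if not np.all(inside[core]):
        raise ValueError(
            f"resliced plane at z={z_k} exits the volume within its central "
            f"{core_mm} mm core (grid shape {volume.shape})"
        )

    hu = ndimage.map_coordinates(
        volume.voxels,
        [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
        order=3,
        mode="constant",
        cval=-1000.0,
    ).reshape(n, n)

    # segment the reslice: enclosed sub-threshold component at the centre
    from .segmentation import _candidate_components_spacing

    cands = _candidate_components_spacing(hu, h, h, params)
    if not cands:
        return None
    c = (n // 2) * h  # in-plane mm coordinate of the plane centre
    best, best_d = None, np.inf
    for cand in cands:
        if cand["mask"][n // 2, n // 2]:
            best, best_d = cand, 0.0
            break
        d = float(np.hypot(*(cand["centroid_xy"] - c)))
        if d < best_d:
            best, best_d = cand, d
    if best is None or best_d > params.max_centroid_jump_mm:
        return None
    return float(best["area"])


def mean_sectional_area(profile) -> float:
    """Arithmetic mean of the per-slice sectional areas."""
    areas = [entry[1] for entry in profile]
    if not areas:
        raise ValueError("empty area profile")
    return float(np.mean(areas))


def min_sectional_area(profile) -> tuple[float, float]:
    """Smallest sectional area and its z (ties -> first slice in z order).

    Profiles are ordered by ascending z with the cranial end first by
    the default orientation convention, so the tie-break selects the
    cranial-most slice.
    """
    if not profile:
        raise ValueError("empty area profile")
    areas = np.array([entry[1] for entry in profile])
    zs = np.array([entry[0] for entry in profile])
    j = int(np.argmin(areas))  # argmin returns the first minimum
    return float(areas[j]), float(zs[j])


def min_area_depth(
    z_at_min: float, seg: CanalSegmentation, cranial_end: str = "low-z"
) -> float:
    """Craniocaudal distance from the minimum-area slice to the orbital
    (cranial) outer delimiting plane."""
    geo = seg.geometry
    delta = geo.slice_spacing_delta
    z_lo = seg.first_slice * delta - delta / 2.0
    z_hi = seg.last_slice * delta + delta / 2.0
    if cranial_end not in {"low-z", "high-z"}:
        raise ValueError("cranial_end must be 'low-z' or 'high-z'")
    z_outer = z_lo if cranial_end == "low-z" else z_hi
    return abs(z_at_min - z_outer)


def canal_volume(seg: CanalSegmentation) -> float:
    """Voxel-summation volume: total masked voxel count x voxel volume."""
    total = sum(r.pixel_count for r in seg.regions)
    return total * voxel_volume(seg.geometry)


# ---------------------------------------------------------------------------
# the full variable set
# ---------------------------------------------------------------------------

def compute_all(
    volume: CTVolume | None,
    seg: CanalSegmentation,
    cranial_end: str = "low-z",
    area_method: str = "projection",
    params: SegmentationParams | None = None,
    reslice_warn_tol: float = 0.10,
) -> MorphometryResult:
    """Compute every morphometric variable the segmentation supports.

    Degree-d polynomial variables require p >= d + 1 slices; an
    infeasible model's variables are left as None.  ``area_method`` is
    ``"projection"`` (default, A_k cos beta_k) or ``"reslice"`` (direct
    oblique re-segmentation; requires ``volume``).  With the projection
    method and a supplied volume, a warning is emitted if reslicing
    disagrees with the projection by more than ``reslice_warn_tol``
    at any slice of the degree-3 axis.
    """
    if area_method not in {"projection", "reslice"}:
        raise ValueError("area_method must be 'projection' or 'reslice'")
    if area_method == "reslice" and volume is None:
        raise ValueError("reslice area method requires the CT volume")

    cents = CentroidSequence.from_segmentation(seg)
    p = cents.p

    result = MorphometryResult(
        Vol=canal_volume(seg),
        AxL=axial_length(seg),
        laterality=seg.laterality,
    )

    ax_profile = axial_area_profile(seg)
    result.SecA = mean_sectional_area(ax_profile)
    min_a, z_min = min_sectional_area(ax_profile)
    result.MinSecA = min_a
    result.MinSecD = min_area_depth(z_min, seg, cranial_end)

    models: dict[str, AxisModel] = {"Polyg": build_polygonal_axis(cents)}
    for deg in (2, 3, 4):
        if p >= deg + 1:
            models[f"Polyn{deg}"] = fit_polynomial_axis(cents, deg)

    # end-to-end: straight distance between the canal central points on the
    # outer delimiting planes, i.e. the polygonal extension endpoints
    result.ExL = end_to_end_length(models["Polyg"])

    for name, axis in models.items():
        if isinstance(axis, PolygonalAxis):
            length = polygonal_length(axis)
        else:
            length = polynomial_length(axis)
        setattr(result, f"{name}L", length)

        if area_method == "projection":
            profile = orthogonal_area_profile(seg, axis)
        else:
            profile = []
            for z, _a in ax_profile:
                a_perp = resliced_orthogonal_area(volume, axis, z, params)
                if a_perp is None:
                    raise ValueError(f"reslice segmentation failed for {name} at z={z}")
                profile.append((z, a_perp))
        setattr(result, f"Sec{name}A", mean_sectional_area(profile))
        min_a, z_min = min_sectional_area(profile)
        setattr(result, f"MinSec{name}A", min_a)
        setattr(result, f"MinSec{name}D", min_area_depth(z_min, seg, cranial_end))

    if area_method == "projection" and volume is not None and "Polyn3" in models:
        # cross-check projection validity on interior slices; the outermost
        # slices abut the canal openings where an oblique reslice leaves the
        # canal and the comparison is meaningless
        axis3 = models["Polyn3"]
        for z, a_proj, _ in orthogonal_area_profile(seg, axis3)[1:-1]:
            try:
                a_res = resliced_orthogonal_area(volume, axis3, z, params)
            except ValueError:
                continue
            if a_res is not None and a_proj > 0 and abs(a_res - a_proj) / a_proj > reslice_warn_tol:
                warnings.warn(
                    f"projection and reslice orthogonal areas disagree by "
                    f">{reslice_warn_tol:.0%} at z={z:.3f} "
                    f"({a_proj:.2f} vs {a_res:.2f} mm^2); the canal path may "
                    "bend abruptly there",
                    stacklevel=2,
                )
                break

    result.subject_id = getattr(volume, "subject_id", "") if volume is not None else ""
    return result
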