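"""Seeded, slice-tracked segmentation of a bony canal lumen.

The canal lumen is a low-attenuation channel enclosed by a thin,
sometimes inhomogeneous bone wall.  Plain global thresholding fails on
such walls, so each slice is segmented with a priori knowledge: the
bone mask (HU above a bone threshold) is morphologically closed to seal
sub-voxel wall gaps, and the lumen is the 8-connected sub-threshold
component that contains (or lies nearest to) a seed point and is fully
enclosed by bone, i.e. does not touch the image border.  Candidate
regions must fall inside an anatomically plausible area window.

Across slices, the canal is tracked with the previous centroid as the
seed; tracking terminates when no admissible component exists or the
mask overlap with the previous slice collapses, which bounds the canal
to a contiguous slice range.

All thresholds live in :class:`SegmentationParams`; defaults were tuned
on synthetic phantoms (see :mod:`nlcmorph.phantom`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, VoxelGeometry

__all__ = [
    "SegmentationParams",
    "RegionSlice",
    "CanalSegmentation",
    "segment_slice",
    "segment_canal",
    "region_centroid",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for lumen segmentation.

    Attributes
    ----------
    bone_hu
        HU threshold separating bone wall from lumen content, HU.
    min_area_mm2, max_area_mm2
        Admissible axial-area window for a canal region, mm^2.
    max_centroid_jump_mm
        Maximum in-plane centroid displacement between consecutive
        slices during tracking, mm.
    min_overlap
        Minimum ratio |mask_k .. mask_{k-1}| / min(areas) for tracking
        to continue.
    closing_radius_mm
        Radius of the structuring element used to close gaps in the
        bone wall, mm.
    fill_holes
        Fill interior holes of the lumen mask before area counting.
    """

    bone_hu: float = 300.0
    min_area_mm2: float = 0.5
    max_area_mm2: float = 120.0
    max_centroid_jump_mm: float = 3.0
    min_overlap: float = 0.25
    closing_radius_mm: float = 0.6
    fill_holes: bool = True

    @classmethod
    def from_config(cls, path: str | Path) -> "SegmentationParams":
        """Load parameters from a plain ``key = value`` text file."""
        kwargs = {}
        fields = {f for f in cls.__dataclass_fields__}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise KeyError(f"unknown segmentation parameter {key!r}")
            value = value.strip()
            kwargs[key] = value.lower() in {"1", "true", "yes"} if key == "fill_holes" else float(value)
        return cls(**kwargs)


@dataclass
class RegionSlice:
    """One segmented canal region in one axial slice."""

    slice_index: int
    mask: np.ndarray
    axial_area: float
    centroid: np.ndarray
    pixel_count: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.centroid = np.asarray(self.centroid, dtype=float)


@dataclass
class CanalSegmentation:
    """Ordered stack of segmented canal regions for one laterality."""

    laterality: str
    regions: list
    geometry: VoxelGeometry

    def __post_init__(self):
        idx = [r.slice_index for r in self.regions]
        if len(idx) < 3:
            raise ValueError("a canal needs >=3 segmented slices")
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError(f"slice indices not contiguous: {idx}")

    @property
    def first_slice(self) -> int:
        return self.regions[0].slice_index

    @property
    def last_slice(self) -> int:
        return self.regions[-1].slice_index

    @property
    def n_slices(self) -> int:
        return len(self.regions)

    def centroid_array(self) -> np.ndarray:
        return np.vstack([r.centroid for r in self.regions])

    def label_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary label grid of the full volume shape."""
        lab = np.zeros(shape, dtype=np.uint8)
        for r in self.regions:
            lab[r.slice_index] = r.mask
        return lab

    def export_nifti(self, shape: tuple[int, int, int], path: str | Path) -> Path:
        import nibabel as nib

        geo = self.geometry
        lab = self.label_volume(shape)
        # voxel axes (x, y, z) = (col, row, slice)
        affine = np.diag(
            [geo.pixel_spacing_col, geo.pixel_spacing_row, geo.slice_spacing_delta, 1.0]
        )
        img = nib.Nifti1Image(np.transpose(lab, (2, 1, 0)), affine)
        path = Path(path)
        nib.save(img, path)
        return path

    def export_png_masks(self, directory: str | Path) -> list[Path]:
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = []
        for r in self.regions:
            p = directory / f"{self.laterality}_slice_{r.slice_index:04d}.png"
            Image.fromarray((r.mask.astype(np.uint8)) * 255).save(p)
            out.append(p)
        return out


def region_centroid(
    region_mask: np.ndarray, geometry: VoxelGeometry, slice_index: int
) -> np.ndarray:
    """Unweighted centroid of a binary region in physical mm.

    The arithmetic mean of the member-pixel physical centres; z is the
    physical z of the slice.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("empty mask has no centroid")
    rows, cols = np.nonzero(region_mask)
    x = cols.mean() * geometry.pixel_spacing_col
    y = rows.mean() * geometry.pixel_spacing_row
    z = slice_index * geometry.slice_spacing_delta
    return np.array([x, y, z])


def _candidate_components_spacing(
    hu_slice: np.ndarray,
    ps_row: float,
    ps_col: float,
    params: SegmentationParams,
) -> list[dict]:
    """Enclosed sub-threshold components within the admissible area window.

    The bone mask is morphologically closed to seal wall gaps before
    connectivity analysis; the boundary ring of lumen pixels that the
    closing converts to bone is then reclaimed by geodesic dilation of
    each component within the raw sub-threshold field, limited to the
    closing radius, so the closing fixes topology without shrinking the
    pixel-count area.
    """
    bone = hu_slice >= params.bone_hu
    lumen_raw = ~bone
    r_px = max(1, int(round(params.closing_radius_mm / min(ps_row, ps_col))))
    yy, xx = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
    disk = (xx * xx + yy * yy) <= r_px * r_px
    bone_closed = ndimage.binary_closing(bone, structure=disk)
    lumen_field = ~bone_closed
    labels, n = ndimage.label(lumen_field, structure=_EIGHT)
    out = []
    if n == 0:
        return out
    border = np.zeros_like(lumen_field, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(labels[border])) - {0}
    pixel_area = ps_row * ps_col
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue  # touches image border: not enclosed by bone
        mask = labels == lab
        for _ in range(r_px):  # reclaim the closing-lost boundary ring
            grown = ndimage.binary_dilation(mask, structure=_EIGHT) & lumen_raw
            if grown.sum() == mask.sum():
                break
            mask = grown
        if (mask & border).any():
            continue
        if params.fill_holes:
            mask = ndimage.binary_fill_holes(mask)
        count = int(mask.sum())
        area = count * pixel_area
        if not (params.min_area_mm2 <= area <= params.max_area_mm2):
            continue
        rows, cols = np.nonzero(mask)
        cxy = np.array([cols.mean() * ps_col, rows.mean() * ps_row])
        out.append({"mask": mask, "area": area, "count": count, "centroid_xy": cxy})
    return out


def _candidate_components(
    hu_slice: np.ndarray, geometry: VoxelGeometry, params: SegmentationParams
) -> list[dict]:
    return _candidate_components_spacing(
        hu_slice, geometry.pixel_spacing_row, geometry.pixel_spacing_col, params
    )


def segment_slice(
    volume: CTVolume,
    slice_index: int,
    seed,
    params: SegmentationParams | None = None,
) -> Optional[RegionSlice]:
    """Segment the canal lumen in one axial slice.

    ``seed`` is either an (x, y) mm pair or the :class:`RegionSlice` of
    the previous slice, whose centroid is used as the seed.  Returns the
    enclosed low-HU component containing the seed, or the nearest such
    component within the centroid-jump window; ``None`` when no
    admissible component exists (e.g. a degenerate all-bone slice).
    """
    params = params or SegmentationParams()
    geo = volume.geometry
    if not (0 <= slice_index < geo.n_slices):
        raise IndexError(f"slice index {slice_index} out of range")
    if isinstance(seed, RegionSlice):
        seed_xy = np.asarray(seed.centroid[:2], dtype=float)
        prev_mask = seed.mask
    else:
        seed_xy = np.asarray(seed, dtype=float)
        prev_mask = None
    hu = volume.voxels[slice_index]
    n_rows, n_cols = hu.shape
    if not (
        0 <= seed_xy[0] <= (n_cols - 1) * geo.pixel_spacing_col
        and 0 <= seed_xy[1] <= (n_rows - 1) * geo.pixel_spacing_row
    ):
        raise ValueError(f"seed {tuple(seed_xy)} lies outside the image extent")

    cands = _candidate_components(hu, geo, params)
    if not cands:
        return None

    seed_col = int(round(seed_xy[0] / geo.pixel_spacing_col))
    seed_row = int(round(seed_xy[1] / geo.pixel_spacing_row))

    chosen = None
    for c in cands:
        if c["mask"][seed_row, seed_col]:
            chosen = c
            break
    if chosen is None:
        # nearest candidate centroid within the tracking jump window;
        # ties: smaller displacement, then smaller area difference to prev
        prev_area = prev_mask.sum() * geo.pixel_area if prev_mask is not None else None
        scored = []
        for c in cands:
            d = float(np.hypot(*(c["centroid_xy"] - seed_xy)))
            if d > params.max_centroid_jump_mm:
                continue
            da = abs(c["area"] - prev_area) if prev_area is not None else 0.0
            scored.append((d, da, c))
        if not scored:
            return None
        scored.sort(key=lambda t: (t[0], t[1]))
        chosen = scored[0][2]

    centroid = region_centroid(chosen["mask"], geo, slice_index)
    return RegionSlice(
        slice_index=slice_index,
        mask=chosen["mask"],
        axial_area=chosen["area"],
        centroid=centroid,
        pixel_count=chosen["count"],
    )


def _overlap_ratio(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    return inter / max(1, min(a.sum(), b.sum()))


def segment_canal(
    volume: CTVolume,
    laterality: str = "right",
    params: SegmentationParams | None = None,
    seed: tuple[float, float] | None = None,
) -> CanalSegmentation:
    """Find and track the canal through consecutive axial slices.

    The initial region is detected in a laterality window (the left or
    right half of the image split at the mid-column) unless an explicit
    (x, y) mm seed is given; the detection slice is the one whose best
    in-window candidate has the largest area.  From there the canal is
    tracked slice-to-slice in both z directions using the previous
    centroid as seed, stopping when segmentation fails or mask overlap
    drops below ``params.min_overlap``.
    """
    if laterality not in {"left", "right"}:
        raise ValueError("laterality must be 'left' or 'right'")
    params = params or SegmentationParams()
    volume.require_validated()
    geo = volume.geometry
    n_slices, n_rows, n_cols = volume.shape
    mid_x = (n_cols - 1) * geo.pixel_spacing_col / 2.0

    def in_window(cxy) -> bool:
        if seed is not None:
            return True
        return cxy[0] <= mid_x if laterality == "left" else cxy[0] >= mid_x

    # detection pass
    best = None  # (area, slice_index, candidate)
    for i in range(n_slices):
        for c in _candidate_components(volume.voxels[i], geo, params):
            if not in_window(c["centroid_xy"]):
                continue
            if seed is not None:
                d = float(np.hypot(*(c["centroid_xy"] - np.asarray(seed))))
                if d > params.max_centroid_jump_mm:
                    continue
            if best is None or c["area"] > best[0]:
                best = (c["area"], i, c)
    if best is None:
        win = f"user seed {seed}" if seed is not None else (
            f"{laterality} half-image window (x {'<=' if laterality == 'left' else '>='} {mid_x:.1f} mm)"
        )
        raise ValueError(f"no canal region found in any slice within the {win}")

    _, i0, c0 = best
    start = RegionSlice(
        slice_index=i0,
        mask=c0["mask"],
        axial_area=c0["area"],
        centroid=region_centroid(c0["mask"], geo, i0),
        pixel_count=c0["count"],
    )

    def track(direction: int) -> list[RegionSlice]:
        out = []
        prev = start
        i = i0 + direction
        while 0 <= i < n_slices:
            nxt = segment_slice(volume, i, prev, params)
            if nxt is None:
                break
            if _overlap_ratio(nxt.mask, prev.mask) < params.min_overlap:
                break
            jump = np.hypot(*(nxt.centroid[:2] - prev.centroid[:2]))
            if jump > params.max_centroid_jump_mm:
                break
            out.append(nxt)
            prev = nxt
            i += direction
        return out

    down = track(-1)
    up = track(+1)
    regions = list(reversed(down)) + [start] + up
    return CanalSegmentation(laterality=laterality, regions=regions, geometry=geo)
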