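"""Smoothed 3-D surface mesh of the canal from the segmented contours.

The per-slice binary masks are turned into per-slice 2-D signed
distance fields (positive inside), linearly resampled along z to a
near-isotropic grid — which morphs contours smoothly between slices —
optionally Gaussian-smoothed, and the zero level set extracted with
marching cubes.  The stack is padded with background on all sides
first, so the extracted surface is closed (the canal ends are capped at
the outer delimiting planes) and therefore watertight.

With ``smoothing = 0`` no resampling or filtering is applied and the
mesh is the exact blocky union of the voxels, whose enclosed volume
equals the voxel-summation volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["CanalMesh", "build_surface", "export_mesh"]


@dataclass
class CanalMesh:
    """Triangle mesh of one canal in physical mm coordinates."""

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str = ""
    laterality: str = ""

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def volume(self) -> float:
        """Enclosed volume by the divergence theorem, mm^3."""
        return float(abs(self.as_trimesh().volume))

    @property
    def area(self) -> float:
        return float(self.as_trimesh().area)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)


def _signed_distance_2d(mask: np.ndarray, spacing_rc: tuple[float, float]) -> np.ndarray:
    """Signed distance field, positive inside the mask, mm."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing_rc)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing_rc)
    return inside - outside


def build_surface(seg, smoothing: float = 0.5) -> CanalMesh:
    """Extract a smoothed isosurface mesh from a canal segmentation.

    Parameters
    ----------
    seg : CanalSegmentation
    smoothing
        Gaussian kernel width as a multiple of the (in-plane) voxel
        size; 0 disables smoothing and z-interpolation entirely and
        returns the exact voxel-boundary mesh.  The default 0.5 was
        calibrated on cylinder phantoms: it removes staircase artefacts
        while keeping the enclosed volume within ~2% of the voxel sum.
    """
    regions = seg.regions
    if len(regions) < 3:
        raise ValueError("surface reconstruction needs >=3 region slices")
    geo = seg.geometry
    ps_r, ps_c = geo.pixel_spacing_row, geo.pixel_spacing_col
    delta = geo.slice_spacing_delta

    # crop to the stack bounding box with a one-voxel margin
    rows = np.concatenate([np.nonzero(r.mask)[0] for r in regions])
    cols = np.concatenate([np.nonzero(r.mask)[1] for r in regions])
    r0, r1 = rows.min() - 1, rows.max() + 2
    c0, c1 = cols.min() - 1, cols.max() + 2
    r0, c0 = max(r0, 0), max(c0, 0)
    stack = np.stack([r.mask[r0:r1, c0:c1] for r in regions]).astype(bool)

    i0 = regions[0].slice_index
    origin = np.array([c0 * ps_c, r0 * ps_r, i0 * delta])

    if smoothing == 0:
        import trimesh

        # exact voxel union; grid indexed (slice, row, col) -> (x, y, z)
        enc = trimesh.voxel.encoding.DenseEncoding(np.transpose(stack, (2, 1, 0)))
        tf = np.diag([ps_c, ps_r, delta, 1.0])
        tf[:3, 3] = origin
        vg = trimesh.voxel.VoxelGrid(enc, transform=tf)
        mesh = vg.as_boxes()
        return CanalMesh(
            vertices=np.asarray(mesh.vertices),
            faces=np.asarray(mesh.faces),
            laterality=seg.laterality,
        )

    # in-plane background margin so the lateral surface closes
    stack = np.pad(stack, ((0, 0), (1, 1), (1, 1)), mode="constant")
    sdf = np.stack([_signed_distance_2d(sl, (ps_r, ps_c)) for sl in stack])
    # z-pad with the negative magnitude of the end-slice fields: interior
    # points flip sign so the linear interpolation crosses zero exactly
    # halfway (a flat cap on each outer delimiting plane), while exterior
    # points stay outside
    sdf = np.concatenate([-np.abs(sdf[:1]), sdf, -np.abs(sdf[-1:])])

    # resample z to near-isotropic by linear interpolation of the SDF
    zoom_z = max(1.0, delta / min(ps_r, ps_c))
    n_z = sdf.shape[0]
    sdf_iso = ndimage.zoom(sdf, (zoom_z, 1.0, 1.0), order=1)
    # zoom maps the first/last samples onto each other, so the effective
    # output spacing follows from the realised grid size
    dz_iso = delta * (n_z - 1) / (sdf_iso.shape[0] - 1)

    sigma_mm = smoothing * min(ps_r, ps_c)
    sdf_iso = ndimage.gaussian_filter(
        sdf_iso, sigma=(sigma_mm / dz_iso, sigma_mm / ps_r, sigma_mm / ps_c)
    )

    from skimage import measure

    verts, faces, _, _ = measure.marching_cubes(
        sdf_iso, level=0.0, spacing=(dz_iso, ps_r, ps_c)
    )
    # marching-cubes axes are (slice, row, col) = (z, y, x); padding
    # shifted everything by one voxel
    xyz = np.column_stack([verts[:, 2], verts[:, 1], verts[:, 0]])
    xyz -= np.array([ps_c, ps_r, delta])
    xyz += origin
    return CanalMesh(vertices=xyz, faces=faces, laterality=seg.laterality)


def export_mesh(mesh: CanalMesh, fmt: str, path: str | Path) -> Path:
    """Write the mesh as binary STL, ascii PLY or OBJ."""
    fmt = fmt.lower()
    if fmt not in {"stl", "ply", "obj"}:
        raise ValueError(f"unknown mesh format {fmt!r}; use stl, ply or obj")
    tm = mesh.as_trimesh()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        data = tm.export(file_type=fmt)
    if isinstance(data, str):
        path.write_text(data)
    else:
        path.write_bytes(data)
    return path
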