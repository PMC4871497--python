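"""CT volume input/output and physical-geometry bookkeeping.

A CT volume is a stack of axial slices.  All downstream morphometry is
carried out in physical millimetre coordinates, so this module owns the
voxel-to-mm calibration: in-plane pixel spacing, the inter-slice spacing
``delta`` (the z-difference between consecutive Image Position (Patient)
tags) and the orientation cosines.  Coordinate convention:

* x grows with the column index times the column pixel spacing
  (sagittal direction),
* y grows with the row index times the row pixel spacing (coronal),
* z grows with the slice index times ``delta`` (depth),
* the origin (0, 0, 0) mm is the geometrical centre of the upper-left
  voxel of the first slice.

Volumes read from disk must pass :func:`check_tag_consistency` before
volumetry is trusted; the checks mirror the geometric tag errors that
have been reported in clinical DICOM archives (slice-location vs
image-position disagreement, non-canonical orientation cosines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGeometry",
    "CTVolume",
    "ConsistencyReport",
    "read_dicom_series",
    "write_dicom_series",
    "read_sidecar",
    "write_sidecar",
    "check_tag_consistency",
    "index_to_physical",
    "voxel_volume",
]

CANONICAL_COSINES = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

#: tolerance for agreement of consecutive slice-position differences, mm
_POSITION_TOL = 1e-6


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical calibration of a CT voxel grid.

    Parameters
    ----------
    pixel_spacing_row, pixel_spacing_col
        In-plane spacing in mm (DICOM Pixel Spacing is (row, col)).
    slice_thickness
        Nominal slab thickness of each slice, mm.
    slice_spacing_delta
        z-distance between consecutive slice positions, mm.  This is the
        quantity used as voxel depth and as the centroid z-step.
    image_positions
        (n_slices, 3) array of per-slice Image Position (Patient), mm.
    orientation_cosines
        Six direction cosines of the in-plane axes.
    """

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_thickness: float
    slice_spacing_delta: float
    image_positions: np.ndarray
    orientation_cosines: tuple = CANONICAL_COSINES

    def __post_init__(self):
        object.__setattr__(
            self, "image_positions", np.asarray(self.image_positions, dtype=float)
        )
        if self.pixel_spacing_row <= 0 or self.pixel_spacing_col <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.slice_spacing_delta <= 0:
            raise ValueError("slice spacing delta must be positive")
        if self.image_positions.ndim != 2 or self.image_positions.shape[1] != 3:
            raise ValueError("image_positions must be (n_slices, 3)")

    @property
    def n_slices(self) -> int:
        return self.image_positions.shape[0]

    @property
    def pixel_area(self) -> float:
        """In-plane area of one pixel, mm^2."""
        return self.pixel_spacing_row * self.pixel_spacing_col

    @classmethod
    def uniform(
        cls,
        pixel_spacing: float | tuple[float, float],
        delta: float,
        n_slices: int,
        slice_thickness: float | None = None,
        origin: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "VoxelGeometry":
        """Build a regular geometry with equally spaced slices."""
        if np.isscalar(pixel_spacing):
            ps_row = ps_col = float(pixel_spacing)
        else:
            ps_row, ps_col = map(float, pixel_spacing)
        origin = np.asarray(origin, dtype=float)
        positions = np.tile(origin, (n_slices, 1))
        positions[:, 2] += delta * np.arange(n_slices)
        return cls(
            pixel_spacing_row=ps_row,
            pixel_spacing_col=ps_col,
            slice_thickness=delta if slice_thickness is None else slice_thickness,
            slice_spacing_delta=delta,
            image_positions=positions,
        )


@dataclass
class CTVolume:
    """A CT voxel grid in Hounsfield units with its physical geometry.

    ``voxels`` is indexed (slice, row, col).  HU values must be finite.
    """

    voxels: np.ndarray
    geometry: VoxelGeometry
    subject_id: str = ""
    validated: bool = False

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array (slice, row, col)")
        if self.voxels.shape[0] != self.geometry.n_slices:
            raise ValueError(
                f"grid has {self.voxels.shape[0]} slices but geometry lists "
                f"{self.geometry.n_slices}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def require_validated(self):
        if not self.validated:
            raise ValueError(
                "volume has not passed the geometric tag-consistency check; "
                "run check_tag_consistency first"
            )


@dataclass
class ConsistencyReport:
    """Outcome of the geometric DICOM tag checks.

    ``pair_records`` holds, per consecutive slice pair, the spacing from
    the slice-location tag, the spacing from image positions, and a
    pass/fail flag.  ``orientation_ok`` records whether the direction
    cosines are the canonical axial ones.  Failures are reported, never
    raised; downstream volumetry refuses unvalidated volumes instead.
    """

    pair_records: list = field(default_factory=list)
    orientation_ok: bool = True
    spacing_uniform: bool = True
    gap_or_overlap: bool = False

    @property
    def passed(self) -> bool:
        return (
            self.orientation_ok
            and self.spacing_uniform
            and all(rec["ok"] for rec in self.pair_records)
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.pair_records)


def check_tag_consistency(
    volume: CTVolume,
    per_slice_locations: Sequence[float] | None = None,
    tol: float = _POSITION_TOL,
) -> ConsistencyReport:
    """Verify geometric DICOM tags agree with each other.

    Checks, for every consecutive slice pair, that the difference in the
    slice-location tag equals the difference in the third component of
    the image-position tag; that the spacing is uniform; and that the
    orientation cosines describe the canonical axial frame.  On overall
    pass the volume is flagged ``validated``.
    """
    geo = volume.geometry
    z = geo.image_positions[:, 2]
    dz = np.diff(z)
    report = ConsistencyReport()

    report.orientation_ok = np.allclose(
        geo.orientation_cosines, CANONICAL_COSINES, atol=1e-6
    )
    report.spacing_uniform = bool(
        np.all(np.abs(dz - geo.slice_spacing_delta) <= tol)
    )
    # gap/overlap between slabs: spacing differs from nominal thickness
    report.gap_or_overlap = abs(geo.slice_spacing_delta - geo.slice_thickness) > tol

    if per_slice_locations is not None:
        locs = np.asarray(per_slice_locations, dtype=float)
        if locs.shape[0] != geo.n_slices:
            raise ValueError("per_slice_locations must align with slices")
        dloc = np.diff(locs)
        for k, (a, b) in enumerate(zip(dloc, dz)):
            report.pair_records.append(
                {
                    "pair": (k, k + 1),
                    "location_spacing": float(a),
                    "position_spacing": float(b),
                    "ok": bool(abs(a - b) <= tol),
                }
            )
    else:
        for k, b in enumerate(dz):
            report.pair_records.append(
                {
                    "pair": (k, k + 1),
                    "location_spacing": float("nan"),
                    "position_spacing": float(b),
                    "ok": bool(abs(b - geo.slice_spacing_delta) <= tol),
                }
            )

    volume.validated = report.passed
    return report


def index_to_physical(
    geometry: VoxelGeometry, slice_i: int, row: int, col: int
) -> np.ndarray:
    """Map a voxel index triple to mm coordinates.

    The origin is the centre of voxel (0, 0, 0); x follows columns,
    y follows rows, z follows slices.
    """
    n = geometry.n_slices
    if not (0 <= slice_i < n):
        raise IndexError(f"slice index {slice_i} outside [0, {n})")
    if row < 0 or col < 0:
        raise IndexError("negative row/col index")
    return np.array(
        [
            col * geometry.pixel_spacing_col,
            row * geometry.pixel_spacing_row,
            slice_i * geometry.slice_spacing_delta,
        ]
    )


def voxel_volume(geometry: VoxelGeometry, report: ConsistencyReport | None = None) -> float:
    """Physical volume of one voxel, mm^3.

    The depth is the inter-slice spacing delta (base area x depth).  The
    nominal slice thickness may stand in for the depth only when the
    consistency report confirms there are neither gaps nor overlap, in
    which case the two agree anyway; when they disagree and the report
    flags a gap/overlap the spacing delta takes precedence.
    """
    base = geometry.pixel_spacing_row * geometry.pixel_spacing_col
    depth = geometry.slice_spacing_delta
    if report is not None and report.gap_or_overlap and not report.spacing_uniform:
        raise ValueError(
            "cannot determine voxel depth: slice spacing is non-uniform "
            f"(delta={geometry.slice_spacing_delta} mm) and disagrees with "
            f"slice thickness ({geometry.slice_thickness} mm)"
        )
    return base * depth


# ---------------------------------------------------------------------------
# DICOM series I/O
# ---------------------------------------------------------------------------

_MANDATORY_TAGS = {
    "PixelSpacing": "(0028,0030)",
    "SliceThickness": "(0018,0050)",
    "ImagePositionPatient": "(0020,0032)",
    "ImageOrientationPatient": "(0020,0037)",
}


def read_dicom_series(directory: str | Path, subject_id: str | None = None) -> CTVolume:
    """Read a single-frame CT DICOM series into a :class:`CTVolume`.

    Slices are sorted ascending by the third component of Image Position
    (Patient); rescale slope/intercept is applied so voxel values are in
    HU.  Files from mixed series, or files missing a mandatory geometry
    tag, are rejected.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        datasets.append((p, ds))
    if len(datasets) < 2:
        raise ValueError(f"{directory} does not contain >=2 readable DICOM slices")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed series identifiers in {directory}: {sorted(uids)}")

    for p, ds in datasets:
        for tag, code in _MANDATORY_TAGS.items():
            if getattr(ds, tag, None) is None:
                raise ValueError(f"{p.name}: missing mandatory geometry tag {tag} {code}")

    datasets.sort(key=lambda t: float(t[1].ImagePositionPatient[2]))

    slices = []
    positions = []
    locations = []
    for _, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
        positions.append([float(v) for v in ds.ImagePositionPatient])
        locations.append(float(getattr(ds, "SliceLocation", ds.ImagePositionPatient[2])))

    ds0 = datasets[0][1]
    positions = np.asarray(positions)
    dz = np.diff(positions[:, 2])
    delta = float(np.median(dz))
    geometry = VoxelGeometry(
        pixel_spacing_row=float(ds0.PixelSpacing[0]),
        pixel_spacing_col=float(ds0.PixelSpacing[1]),
        slice_thickness=float(ds0.SliceThickness),
        slice_spacing_delta=delta,
        image_positions=positions,
        orientation_cosines=tuple(float(v) for v in ds0.ImageOrientationPatient),
    )
    vol = CTVolume(
        voxels=np.stack(slices),
        geometry=geometry,
        subject_id=subject_id or str(getattr(ds0, "PatientID", directory.name)),
    )
    vol._slice_locations = locations  # kept for the consistency check
    return vol


def write_dicom_series(volume: CTVolume, directory: str | Path) -> list[Path]:
    """Export a volume as one CT DICOM file per axial slice.

    HU values are stored as int16 with identity rescale so integer grids
    round-trip bit-exactly.  Used to exercise the reader on phantoms.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    geo = volume.geometry
    series_uid = generate_uid()
    study_uid = generate_uid()
    paths = []
    for i in range(geo.n_slices):
        sl = np.round(volume.voxels[i]).astype(np.int16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.PatientID = volume.subject_id or "PHANTOM"
        ds.PatientName = volume.subject_id or "PHANTOM"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [float(v) for v in geo.image_positions[i]]
        ds.ImageOrientationPatient = [float(v) for v in geo.orientation_cosines]
        ds.SliceLocation = float(geo.image_positions[i, 2])
        ds.PixelSpacing = [geo.pixel_spacing_row, geo.pixel_spacing_col]
        ds.SliceThickness = geo.slice_thickness
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = sl.tobytes()

        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Sidecar raw + text format (simple test/export interchange)
# ---------------------------------------------------------------------------

def write_sidecar(volume: CTVolume, basepath: str | Path) -> tuple[Path, Path]:
    """Write a volume as a raw ``.npy`` grid plus a JSON geometry descriptor."""
    basepath = Path(basepath)
    npy = basepath.with_suffix(".npy")
    meta = basepath.with_suffix(".json")
    np.save(npy, volume.voxels)
    geo = volume.geometry
    meta.write_text(
        json.dumps(
            {
                "subject_id": volume.subject_id,
                "pixel_spacing_row": geo.pixel_spacing_row,
                "pixel_spacing_col": geo.pixel_spacing_col,
                "slice_thickness": geo.slice_thickness,
                "slice_spacing_delta": geo.slice_spacing_delta,
                "image_positions": geo.image_positions.tolist(),
                "orientation_cosines": list(geo.orientation_cosines),
            },
            indent=2,
        )
    )
    return npy, meta


def read_sidecar(basepath: str | Path) -> CTVolume:
    """Read a volume written by :func:`write_sidecar`."""
    basepath = Path(basepath)
    voxels = np.load(basepath.with_suffix(".npy"))
    info = json.loads(basepath.with_suffix(".json").read_text())
    geometry = VoxelGeometry(
        pixel_spacing_row=info["pixel_spacing_row"],
        pixel_spacing_col=info["pixel_spacing_col"],
        slice_thickness=info["slice_thickness"],
        slice_spacing_delta=info["slice_spacing_delta"],
        image_positions=np.asarray(info["image_positions"]),
        orientation_cosines=tuple(info["orientation_cosines"]),
    )
    return CTVolume(voxels=voxels, geometry=geometry, subject_id=info.get("subject_id", ""))
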