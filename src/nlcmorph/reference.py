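"""Published reference values used for verification.

``REFERENCE_AXIS_MODELS`` reproduces the published table of degree-3
axis models for the right nasolacrimal canal of six randomly selected
subjects: r^2 per coordinate, polynomial coefficients (highest degree
first, raw z, 4 printed decimals), the extended z-range and the slice
count.  ``COHORT`` holds the published cohort-level slice-count and
axial-length statistics.  delta is 0.625 mm throughout (the
acquisition's slice spacing).

The original per-subject centroid sequences are supplementary data
that are not redistributable here, so
:func:`synthetic_centroid_sequence` constructs a SYNTHETIC stand-in
sequence per subject that is exactly consistent with the printed model
row; see its docstring.
"""

from __future__ import annotations

import numpy as np

from .axis_models import CentroidSequence

__all__ = [
    "DELTA_MM",
    "REFERENCE_AXIS_MODELS",
    "COHORT",
    "synthetic_centroid_sequence",
    "mean_axial_length_from_slice_counts",
]

DELTA_MM = 0.625

#: published degree-3 axis models, one row per subject.
#: coefficients are highest-degree-first for x(z) then y(z), raw z, mm.
REFERENCE_AXIS_MODELS = {
    23: {"r2_x": 0.9975, "x": (0.0301, -0.4251, -2.8260, 50.8315),
         "r2_y": 0.9979, "y": (0.0157, -0.3379, 1.5002, 66.6736),
         "z_min": 7.8125, "z_max": 12.1875, "n_slices": 7},
    26: {"r2_x": 0.9964, "x": (-0.0050, 0.1820, -2.6980, 35.6230),
         "r2_y": 0.9115, "y": (-0.0039, 0.0870, -0.5902, 76.6122),
         "z_min": 1.5625, "z_max": 14.6875, "n_slices": 21},
    17: {"r2_x": 0.9964, "x": (-0.0036, 0.7154, -47.4757, 1103.3619),
         "r2_y": 0.9583, "y": (0.0016, -0.2846, 16.4710, -225.7000),
         "z_min": 54.6875, "z_max": 67.8125, "n_slices": 21},
    29: {"r2_x": 0.9967, "x": (-0.0047, 0.2812, -6.0968, 70.5200),
         "r2_y": 0.9130, "y": (0.0014, -0.0614, 0.8964, 73.6686),
         "z_min": 10.9375, "z_max": 23.4375, "n_slices": 20},
    19: {"r2_x": 0.9993, "x": (0.0001, 0.0678, -3.1991, 49.9476),
         "r2_y": 0.9602, "y": (-0.0008, 0.0618, -1.2999, 78.7241),
         "z_min": 10.3125, "z_max": 20.3125, "n_slices": 16},
    # the x-intercept is printed with a European thousands separator
    # ("1.001.4566") in the source table; read as 1001.4566
    13: {"r2_x": 0.9898, "x": (-0.0424, 3.5863, -101.5361, 1001.4566),
         "r2_y": 0.9798, "y": (-0.0029, 0.2722, -8.3017, 166.9721),
         "z_min": 23.4375, "z_max": 30.9375, "n_slices": 12},
}

#: published cohort statistics (18 subjects, 36 canals)
COHORT = {
    "right_slice_count_mean": 16.39,
    "right_slice_count_range": (7, 21),
    "left_slice_count_mean": 16.44,
    "left_slice_count_range": (6, 22),
    "axl_mean_mm": 10.26,
    "axl_median_mm": 10.63,
    "axl_sd_mm": 2.66,
    "volume_mean_mm3": 215.19,
}


def mean_axial_length_from_slice_counts(
    mean_counts=(COHORT["right_slice_count_mean"], COHORT["left_slice_count_mean"]),
    delta: float = DELTA_MM,
) -> float:
    """Cohort mean axial length implied by the mean slice counts.

    AxL = p * delta per canal, so the cohort mean AxL is the mean slice
    count (averaged over the two sides) times delta.
    """
    return float(np.mean(mean_counts) * delta)


def synthetic_centroid_sequence(subject: int, coord: str = "both", seed: int = 0):
    """SYNTHETIC stand-in for a subject's supplementary centroid sequence.

    The original centroid sequences cannot be redistributed, so this
    builds a sequence that is exactly consistent with the published
    degree-3 model row: centroids are placed at the canal slice depths
    z_i = z_min + delta/2 + i*delta, coordinate values are the printed
    polynomial evaluated at z_i plus a pseudo-random residual vector
    projected orthogonal to the degree-3 design space (so a degree-3
    least-squares refit returns the printed coefficients unchanged) and
    scaled so the squared Pearson correlation of fitted vs observed
    equals the printed r^2.  The construction uses plain QR projection,
    independent of the package's fitting code.

    Returns a :class:`CentroidSequence` (``coord="both"``) or the raw
    (z, values) arrays for a single coordinate.
    """
    row = REFERENCE_AXIS_MODELS[subject]
    p = row["n_slices"]
    z = row["z_min"] + DELTA_MM / 2.0 + DELTA_MM * np.arange(p)

    design = np.vander(z, 4, increasing=True)  # 1, z, z^2, z^3
    q, _ = np.linalg.qr(design)

    def coord_values(key: str, r2: float, sub_seed: int) -> np.ndarray:
        coeffs_hi = np.asarray(row[key], dtype=float)
        exact = np.polyval(coeffs_hi, z)
        rng = np.random.default_rng((seed, subject, sub_seed))
        e = rng.standard_normal(p)
        e -= q @ (q.T @ e)                      # orthogonal to design space
        norm = np.linalg.norm(e)
        if norm < 1e-12:
            raise RuntimeError("degenerate residual draw")
        e /= norm
        ss_model = float(((exact - exact.mean()) ** 2).sum())
        sse = ss_model * (1.0 - r2) / r2
        return exact + e * np.sqrt(sse)

    x = coord_values("x", row["r2_x"], 1)
    y = coord_values("y", row["r2_y"], 2)
    if coord == "x":
        return z, x
    if coord == "y":
        return z, y
    return CentroidSequence(points=np.column_stack([x, y, z]), delta=DELTA_MM)
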