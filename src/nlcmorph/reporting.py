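"""Cohort-level descriptive output and result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .morphometry import VARIABLE_NAMES, MorphometryResult

__all__ = ["results_frame", "descriptive_stats"]


def results_frame(results: list[MorphometryResult]) -> pd.DataFrame:
    """One row per canal, columns in the canonical variable order."""
    return pd.DataFrame([r.to_row() for r in results])


def descriptive_stats(results: list[MorphometryResult]) -> pd.DataFrame:
    """Per-variable mean, SD (n-1), median and quartiles.

    Quartiles use linear interpolation between closest ranks.  With a
    single canal the SD is undefined and reported as NaN.
    """
    if not results:
        raise ValueError("no results to summarise")
    frame = results_frame(results)
    rows = []
    for name in VARIABLE_NAMES:
        vals = frame[name].dropna().astype(float).to_numpy()
        if vals.size == 0:
            continue
        rows.append(
            {
                "variable": name,
                "n": int(vals.size),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                "p25": float(np.percentile(vals, 25)),
                "p50": float(np.percentile(vals, 50)),
                "p75": float(np.percentile(vals, 75)),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
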