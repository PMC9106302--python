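"""Enhancer-blocking insulator strength from reporter flow cytometry.

Transfected cells carry an enhancer flanked by EGFP (behind the candidate
insulator) and mCherry (reference).  Per replicate, the median
log2(mCherry/EGFP) summarizes how strongly the tested fragment blocks the
enhancer; strengths are expressed on the spacer/gypsy scale: the neutral
spacer's mean log2 ratio maps to 0% and the gypsy insulator's to 100%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "median_log2_ratio",
    "insulator_strength",
    "strength_table",
]


def median_log2_ratio(cells: pd.DataFrame) -> pd.DataFrame:
    """Per (fragment, replicate) median of log2(mCherry/EGFP).

    Cells with non-positive intensities are dropped; their count is attached
    as ``result.attrs['n_dropped']``.  Even cell counts use the midpoint
    median.
    """
    required = {"fragment", "replicate", "egfp", "mcherry"}
    if missing := required - set(cells.columns):
        raise ValueError(f"cell table missing columns {sorted(missing)}")
    ok = (cells["egfp"] > 0) & (cells["mcherry"] > 0)
    n_dropped = int((~ok).sum())
    sub = cells[ok]
    ratio = np.log2(sub["mcherry"].to_numpy() / sub["egfp"].to_numpy())
    out = (
        sub.assign(log2_ratio=ratio)
        .groupby(["fragment", "replicate"], sort=True)["log2_ratio"]
        .median()
        .reset_index()
        .rename(columns={"log2_ratio": "median_log2_ratio"})
    )
    out.attrs["n_dropped"] = n_dropped
    return out


def insulator_strength(test_medians, spacer_medians, gypsy_medians):
    """Replicate strengths as percentage of the gypsy insulator.

    strength_r = 100 × (median_r − mean(spacer)) / (mean(gypsy) − mean(spacer)).
    Negative strengths and strengths above 100 are reported as-is.
    """
    test = np.asarray(test_medians, dtype=float)
    spacer = float(np.mean(spacer_medians))
    gypsy = float(np.mean(gypsy_medians))
    if gypsy == spacer:
        raise ValueError("degenerate normalization: gypsy mean equals spacer mean")
    return 100.0 * (test - spacer) / (gypsy - spacer)


def strength_table(cells: pd.DataFrame, spacer: str = "spacer",
                   gypsy: str = "gypsy") -> pd.DataFrame:
    """Full pipeline from a cell table to per-fragment strengths.

    Returns one row per fragment with per-replicate strengths, replicate
    mean and SD; the gypsy control averages exactly 100 and the spacer
    exactly 0 by construction.
    """
    med = median_log2_ratio(cells)
    for ctrl in (spacer, gypsy):
        if ctrl not in set(med["fragment"]):
            raise ValueError(f"control fragment {ctrl!r} missing")
    spacer_m = med.loc[med["fragment"] == spacer, "median_log2_ratio"]
    gypsy_m = med.loc[med["fragment"] == gypsy, "median_log2_ratio"]
    rows = []
    for frag, grp in med.groupby("fragment", sort=True):
        s = insulator_strength(grp["median_log2_ratio"], spacer_m, gypsy_m)
        rows.append({
            "fragment": frag,
            "n_replicates": len(s),
            "strengths": list(np.round(s, 6)),
            "mean_strength": float(np.mean(s)),
            "sd_strength": float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
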