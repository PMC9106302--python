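"""ChIP-peak / boundary / annotation integration and comparison statistics.

Conventions follow the peak-table semantics of differential-binding output:
each peak carries a summit position (best position within the peak region)
and an occupancy value (best log2 fold change over the depleted control).
Boundaries are single bins; their position is the bin start coordinate.
All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChipPeakSet",
    "AggregationMatrix",
    "assign_occupancy",
    "promoter_proximity",
    "motif_overlap",
    "intron_location",
    "aggregate_around_anchors",
    "wilcoxon_rank_sum",
    "contingency_enrichment",
    "overlap_fraction_summary",
]


@dataclass
class ChipPeakSet:
    """Peak summits, regions and occupancy values.

    ``table`` columns: name, start, end, summit, occupancy.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"start", "end", "summit", "occupancy"}
        if missing := required - set(t.columns):
            raise ValueError(f"peak table missing columns {sorted(missing)}")
        if len(t) and not ((t["start"] < t["end"]).all()
                           and (t["summit"] >= t["start"]).all()
                           and (t["summit"] < t["end"]).all()):
            raise ValueError("peak summits must lie within [start, end)")

    @property
    def summits(self) -> np.ndarray:
        return self.table["summit"].to_numpy()

    @classmethod
    def from_truth(cls, peaks: pd.DataFrame, half_width: int = 250) -> "ChipPeakSet":
        """Build a peak set from the generator's planted peak table
        (columns pos/occupancy), with symmetric regions around summits."""
        t = pd.DataFrame({
            "name": [f"peak{k}" for k in range(len(peaks))],
            "start": np.maximum(peaks["pos"].to_numpy() - half_width, 0),
            "end": peaks["pos"].to_numpy() + half_width + 1,
            "summit": peaks["pos"].to_numpy(),
            "occupancy": peaks["occupancy"].to_numpy(),
        })
        return cls(t)


@dataclass
class AggregationMatrix:
    """Ranked anchors × offset bins, with a per-column summary row.

    ``values``: (n_anchors, n_cols); ``summary``: per-column mean (score /
    occupancy tracks) or percentage (presence tracks); ``central``: the
    summary over the 3 central columns (±2 kb at 2-kb bins).
    """

    kind: str
    values: np.ndarray
    summary: np.ndarray
    central: float
    offsets_bp: np.ndarray


def assign_occupancy(boundary_positions_bp: np.ndarray, peaks: ChipPeakSet,
                     window: int = 2000) -> pd.DataFrame:
    """Flag boundaries with a peak summit within ±``window`` bp.

    Position convention: the boundary coordinate passed in (bin start for
    2-kb boundary bins).  The nearest qualifying peak is linked (ties break
    toward the lower summit coordinate).
    """
    pos = np.asarray(boundary_positions_bp)
    summits = peaks.summits
    occupied = np.zeros(pos.size, dtype=bool)
    nearest = np.full(pos.size, -1, dtype=int)
    for k, p in enumerate(pos):
        if summits.size == 0:
            break
        d = np.abs(summits - p)
        j = int(np.argmin(d))  # argmin -> first (lowest-coordinate) on ties
        if d[j] <= window:
            occupied[k] = True
            nearest[k] = j
    return pd.DataFrame({
        "position": pos,
        "occupied": occupied,
        "peak_index": nearest,
    })


def promoter_proximity(peaks: ChipPeakSet, tss: pd.DataFrame,
                       window: int = 200,
                       min_rpkm: float = 0.0) -> np.ndarray:
    """True for peaks whose summit lies within ±``window`` bp of an actively
    transcribed TSS (RPKM > ``min_rpkm``); False otherwise (promoter-distal).
    """
    active = tss[tss["rpkm"] > min_rpkm]
    if len(active) == 0:
        import warnings

        warnings.warn("no transcribed TSS; all peaks classified distal")
        return np.zeros(len(peaks.table), dtype=bool)
    tpos = np.sort(active["pos"].to_numpy())
    out = np.zeros(len(peaks.table), dtype=bool)
    for k, s in enumerate(peaks.summits):
        j = np.searchsorted(tpos, s)
        best = min(
            (abs(s - tpos[i]) for i in (j - 1, j) if 0 <= i < tpos.size),
            default=np.inf,
        )
        out[k] = best <= window
    return out


def motif_overlap(peaks: ChipPeakSet, motifs: pd.DataFrame) -> np.ndarray:
    """True for peaks whose region shares >= 1 bp with any motif interval
    (half-open intervals)."""
    starts = peaks.table["start"].to_numpy()
    ends = peaks.table["end"].to_numpy()
    ms = motifs["start"].to_numpy()
    me = motifs["end"].to_numpy()
    out = np.zeros(len(starts), dtype=bool)
    for k in range(len(starts)):
        out[k] = bool(np.any((starts[k] < me) & (ms < ends[k])))
    return out


def intron_location(peaks: ChipPeakSet, exons: pd.DataFrame,
                    introns: pd.DataFrame) -> np.ndarray:
    """True for peaks whose summit falls inside at least one intron and
    inside no exon of any (possibly overlapping) gene model."""
    es, ee = exons["start"].to_numpy(), exons["end"].to_numpy()
    is_, ie = introns["start"].to_numpy(), introns["end"].to_numpy()
    out = np.zeros(len(peaks.table), dtype=bool)
    for k, s in enumerate(peaks.summits):
        in_intron = bool(np.any((is_ <= s) & (s < ie)))
        in_exon = bool(np.any((es <= s) & (s < ee)))
        out[k] = in_intron and not in_exon
    return out


def aggregate_around_anchors(anchors_bp: np.ndarray,
                             track,
                             kind: str,
                             arm_length: int,
                             half_width: int = 25_000,
                             bin_size: int = 2000) -> AggregationMatrix:
    """Stack a track in ``bin_size`` bins over ±``half_width`` around ranked
    anchors.

    ``kind``:
      * ``"score"`` — ``track`` is a per-bin array sampled at each offset bin;
      * ``"presence"`` — ``track`` is an array of feature positions (bp);
        cell = 1 if any feature falls in the offset bin; summary row is the
        percentage of anchors with the feature present;
      * ``"occupancy"`` — ``track`` is (positions, values); cell = value of
        the strongest feature in the bin, NaN if none.

    Anchors too close to the arm ends get NaN padding, excluded from the
    summary.  The central enrichment is the summary over the three central
    columns (±2 kb for 2-kb bins); for presence tracks it is the percentage
    of anchors with a feature in any central column.
    """
    anchors_bp = np.asarray(anchors_bp)
    n_side = half_width // bin_size
    n_cols = 2 * n_side + 1
    offsets = (np.arange(n_cols) - n_side) * bin_size
    vals = np.full((anchors_bp.size, n_cols), np.nan)

    if kind == "presence":
        feat = np.sort(np.asarray(track))
    elif kind == "occupancy":
        fpos = np.asarray(track[0])
        fval = np.asarray(track[1])
    elif kind == "score":
        profile = np.asarray(track, dtype=float)
    else:
        raise ValueError("kind must be score, presence or occupancy")

    for a, anchor in enumerate(anchors_bp):
        for c, off in enumerate(offsets):
            lo = anchor + off
            hi = lo + bin_size
            if lo < 0 or hi > arm_length:
                continue  # padded with NaN
            if kind == "score":
                vals[a, c] = profile[lo // bin_size]
            elif kind == "presence":
                j = np.searchsorted(feat, lo)
                vals[a, c] = 1.0 if (j < feat.size and feat[j] < hi) else 0.0
            else:
                sel = (fpos >= lo) & (fpos < hi)
                if sel.any():
                    vals[a, c] = fval[sel].max()

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        if kind == "presence":
            summary = np.nanmean(vals, axis=0) * 100.0
            central_cols = vals[:, n_side - 1:n_side + 2]
            row_any = np.nanmax(central_cols, axis=1)
            central = float(np.nanmean(row_any) * 100.0)
        else:
            summary = np.nanmean(vals, axis=0)
            central = float(np.nanmean(summary[n_side - 1:n_side + 2]))
    return AggregationMatrix(kind=kind, values=vals, summary=summary,
                             central=central, offsets_bp=offsets)


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the statistic for the first group in the R ``wilcox.test``
    convention (the Mann-Whitney U of group_a: the number of (a, b) pairs
    with a > b, counting ties as 1/2).  The p-value is exact for small
    tie-free samples and otherwise uses the normal approximation with
    continuity correction and tie-corrected variance, again matching R.
    Two identical groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # degenerate: every value identical
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def contingency_enrichment(table) -> np.ndarray:
    """Per-cell log10(observed / expected) of an r×c contingency table,
    with expected_ij = rowsum_i × colsum_j / total.  Zero observed gives
    -inf; cells in zero rows/columns are NaN."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("table sum must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    out = np.full(t.shape, np.nan)
    ok = expected > 0
    with np.errstate(divide="ignore"):
        out[ok] = np.log10(t[ok] / expected[ok])
    return out


def overlap_fraction_summary(overlapping: int, total: int) -> int:
    """Printed-percentage convention: round(100 × overlapping / total),
    half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= overlapping <= total:
        raise ValueError("overlapping must lie in [0, total]")
    x = 100.0 * overlapping / total
    return int(np.floor(x + 0.5))
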