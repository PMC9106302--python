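"""Hi-C pair processing: fusion-read splitting, pair filtering, binning,
low-coverage masking, ICE balancing and replicate-correlation QC.

Pairs are tab-separated records (see :data:`boundarykit.synthetic.PAIR_COLUMNS`)
held in a pandas DataFrame; one chromosome arm is modelled at a time, trans
contacts are dropped with a counter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "split_fusion_read",
    "filter_pairs",
    "bin_pairs",
    "mask_low_coverage",
    "ice_balance",
    "ice_normalize",
    "downsample_pairs",
    "replicate_correlation",
]

# re-ligated 4-cutter junction patterns; a fusion read is split at the 6-mer
# midpoint so each side keeps its reconstituted half-site
FUSION_PATTERNS = ("GTATAC", "TTATAA", "GTATAA", "TTATAC")

REJECT_NON_UNIQUE = "i:non_unique"
REJECT_MISMATCH = "ii:indel_or_mismatch"
REJECT_CLOSE_OPPOSITE = "iii:close_opposite"
REJECT_DUPLICATE = "iv:duplicate"


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome arm.

    ``counts`` is the raw (or expectation) matrix, ``mask`` flags valid bins
    (True = valid) and ``normalized`` holds the ICE-balanced matrix with NaN
    on masked rows/columns.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray | None = None
    normalized: np.ndarray | None = None
    n_trans_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def arm_length(self) -> int:
        return self.n_bins * self.bin_size

    def bins(self) -> pd.DataFrame:
        """Bin table, 0-based half-open."""
        starts = np.arange(self.n_bins) * self.bin_size
        return pd.DataFrame({
            "chrom": self.chrom,
            "start": starts,
            "end": starts + self.bin_size,
        })

    def marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def split_fusion_read(read: str, max_len: int = 60) -> list[str]:
    """Split a read at every re-ligation junction, left to right.

    The four 6-mer junction patterns are cut at their midpoint so each side
    keeps its reconstituted half-site; occurrences are non-overlapping and
    processed left to right; every emitted sub-read is truncated to
    ``max_len`` nt from its 5' end.  An empty read gives an empty list.
    """
    if not read:
        return []
    pieces = []
    start = 0
    i = 0
    n = len(read)
    while i <= n - 6:
        if read[i:i + 6] in FUSION_PATTERNS:
            pieces.append(read[start:i + 3])
            start = i + 3
            i += 6
        else:
            i += 1
    pieces.append(read[start:])
    return [p[:max_len] for p in pieces]


def filter_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four rejection rules in order; return (kept, rejected).

    (i) either mate maps non-uniquely; (ii) either mate has an indel or more
    than two mismatches; (iii) mates on the same chromosome on opposite
    strands less than 2 kb apart (undigested religation product); (iv) exact
    PCR duplicate — both mates share (chrom, pos, strand) with a previously
    seen pair, mate order ignored.  Each rejected record is tagged with its
    first matching rule in a ``reason`` column.
    """
    required = {"chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
                "unique1", "unique2", "mismatches1", "mismatches2",
                "indel1", "indel2"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"malformed pair records, missing columns: {sorted(missing)}")
    if len(pairs) == 0:
        empty = pairs.copy()
        rej = pairs.copy()
        rej["reason"] = pd.Series(dtype=object)
        return empty, rej

    r1 = ~(pairs["unique1"].to_numpy(bool) & pairs["unique2"].to_numpy(bool))
    r2 = (pairs["mismatches1"].to_numpy() > 2) | (pairs["mismatches2"].to_numpy() > 2) \
        | pairs["indel1"].to_numpy(bool) | pairs["indel2"].to_numpy(bool)
    r3 = (pairs["chrom1"].to_numpy() == pairs["chrom2"].to_numpy()) \
        & (pairs["strand1"].to_numpy() != pairs["strand2"].to_numpy()) \
        & (np.abs(pairs["pos1"].to_numpy() - pairs["pos2"].to_numpy()) < 2000)

    # duplicates detected among records surviving rules i-iii, on the
    # mate-order-invariant key; the first occurrence is kept
    m1 = list(zip(pairs["chrom1"], pairs["pos1"], pairs["strand1"]))
    m2 = list(zip(pairs["chrom2"], pairs["pos2"], pairs["strand2"]))
    keys = [tuple(sorted((a, b))) for a, b in zip(m1, m2)]
    survivors = ~(r1 | r2 | r3)
    # a record only counts as "previously seen" via earlier surviving copies
    seen: set = set()
    r4 = np.zeros(len(pairs), dtype=bool)
    for k, (key, ok) in enumerate(zip(keys, survivors)):
        if not ok:
            continue
        if key in seen:
            r4[k] = True
        else:
            seen.add(key)

    reason = np.full(len(pairs), "", dtype=object)
    reason[r4] = REJECT_DUPLICATE
    reason[r3] = REJECT_CLOSE_OPPOSITE
    reason[r2] = REJECT_MISMATCH
    reason[r1] = REJECT_NON_UNIQUE

    rejected = pairs[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]
    kept = pairs[reason == ""].copy()
    return kept, rejected


def bin_pairs(pairs: pd.DataFrame, bin_size: int, arm_length: int,
              chrom: str | None = None) -> ContactMatrix:
    """Bin filtered cis pairs into a raw symmetric contact matrix.

    Trans pairs (either mate off the modelled arm) are dropped with a
    counter.  The in-matrix total (upper triangle, diagonal once) equals the
    kept cis pair count.
    """
    if arm_length <= 0 or bin_size <= 0 or arm_length % bin_size:
        raise ValueError("arm_length must be a positive multiple of bin_size")
    n = arm_length // bin_size
    counts = np.zeros((n, n))
    if chrom is None:
        chrom = pairs["chrom1"].iloc[0] if len(pairs) else "chr?"

    if len(pairs):
        cis = (pairs["chrom1"] == chrom) & (pairs["chrom2"] == chrom)
        n_trans = int((~cis).sum())
        sub = pairs[cis]
        p1 = sub["pos1"].to_numpy()
        p2 = sub["pos2"].to_numpy()
        if len(sub) and (p1.min() < 0 or p2.min() < 0
                         or p1.max() >= arm_length or p2.max() >= arm_length):
            raise ValueError("pair position beyond arm")
        b1 = p1 // bin_size
        b2 = p2 // bin_size
        i = np.minimum(b1, b2)
        j = np.maximum(b1, b2)
        np.add.at(counts, (i, j), 1)
        counts = counts + np.triu(counts, 1).T
    else:
        n_trans = 0

    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts,
                         n_trans_dropped=n_trans)


def mask_low_coverage(matrix: ContactMatrix) -> np.ndarray:
    """Valid-bin mask: drop zero-marginal bins plus the ceil(5%) of nonzero
    bins with the smallest marginals (ties broken toward the lower index).

    The mask (True = valid) is stored on the matrix and returned.
    """
    marg = matrix.marginals()
    valid = marg > 0
    n_nonzero = int(valid.sum())
    if n_nonzero == 0:
        warnings.warn("all bins have zero coverage; everything masked")
        matrix.mask = valid
        return valid
    k = math.ceil(0.05 * n_nonzero)
    nz_idx = np.flatnonzero(valid)
    order = np.lexsort((nz_idx, marg[nz_idx]))  # by marginal, then index
    valid[nz_idx[order[:k]]] = False
    matrix.mask = valid
    return valid


def ice_balance(counts: np.ndarray, valid: np.ndarray, tol: float = 1e-6,
                max_iter: int = 1000) -> np.ndarray:
    """Iterative correction of a symmetric matrix over the valid bins.

    Rows/columns are repeatedly divided by their (mean-scaled) marginals
    until the coefficient of variation of valid marginals drops below
    ``tol``; the result is rescaled so the mean valid marginal equals 1, and
    masked rows/columns are NaN.
    """
    if int(valid.sum()) < 2:
        raise ValueError("at least 2 valid bins required for balancing")
    m = counts[np.ix_(valid, valid)].astype(float).copy()
    converged = False
    for _ in range(max_iter):
        marg = m.sum(axis=1)
        mean = marg.mean()
        if mean == 0:
            raise ValueError("degenerate matrix: zero marginals within mask")
        cv = marg.std() / mean
        if cv < tol:
            converged = True
            break
        b = marg / mean
        m /= np.outer(b, b)
    if not converged:
        marg = m.sum(axis=1)
        cv = marg.std() / marg.mean()
        if cv >= tol:
            warnings.warn(f"ICE did not converge: final marginal CV {cv:.3g}")
    m /= m.sum(axis=1).mean()

    out = np.full_like(counts, np.nan, dtype=float)
    out[np.ix_(valid, valid)] = m
    return out


def ice_normalize(matrix: ContactMatrix, tol: float = 1e-6,
                  max_iter: int = 1000) -> ContactMatrix:
    """Mask (if not already masked) and ICE-balance a contact matrix in
    place; returns the same object with ``normalized`` set."""
    if matrix.mask is None:
        mask_low_coverage(matrix)
    matrix.normalized = ice_balance(matrix.counts, matrix.mask, tol=tol,
                                    max_iter=max_iter)
    return matrix


def downsample_pairs(pairs: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of n records without replacement, deterministic under
    seed, input order preserved."""
    if n > len(pairs):
        raise ValueError(f"cannot downsample {len(pairs)} pairs to {n}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pairs), size=n, replace=False))
    return pairs.iloc[idx].reset_index(drop=True)


def replicate_correlation(mat_a: ContactMatrix, mat_b: ContactMatrix,
                          max_dist: int = 1_000_000) -> float:
    """Pearson r between two balanced matrices over upper-triangle entries at
    genomic distance 0 < d < max_dist, restricted to jointly valid bins."""
    if mat_a.n_bins != mat_b.n_bins or mat_a.bin_size != mat_b.bin_size:
        raise ValueError("matrices must share bin grid")
    if mat_a.normalized is None or mat_b.normalized is None:
        raise ValueError("matrices must be ICE-normalized first")
    valid = mat_a.mask & mat_b.mask
    n = mat_a.n_bins
    i, j = np.triu_indices(n, k=1)
    sel = ((j - i) * mat_a.bin_size < max_dist) & valid[i] & valid[j]
    va = mat_a.normalized[i[sel], j[sel]]
    vb = mat_b.normalized[i[sel], j[sel]]
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 usable entries for correlation")
    r, _ = stats.pearsonr(va[ok], vb[ok])
    return float(r)
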