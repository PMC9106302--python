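"""A/B compartment calling from balanced contact matrices.

The balanced map is converted to observed-over-expected (per-diagonal
expectation over valid bins, clipped at the 99.9th percentile), the Pearson
correlation matrix of its columns is formed, and the leading eigenvector —
sign-oriented so it correlates positively (Spearman) with TSS density and
then mean-centered — splits bins into A (positive) and B (negative)
compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hic import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "observed_over_expected",
    "compartment_eigenvector",
]


@dataclass
class CompartmentTrack:
    """Per-bin eigenvector values (zero-centered over defined bins) and
    A/B labels; masked or dropped bins carry NaN / None."""

    values: np.ndarray
    labels: np.ndarray  # object array of 'A', 'B' or None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def observed_over_expected(matrix: ContactMatrix,
                           clip_quantile: float | None = 0.999) -> np.ndarray:
    """Observed-over-expected transform of a balanced matrix.

    expected(d) is the mean balanced contact over valid bin pairs at genomic
    distance d; O/E values are clipped from above at the ``clip_quantile``
    quantile of defined entries (None disables clipping).  Entries are NaN
    where a bin is masked or expected(d) is zero.
    """
    if matrix.normalized is None:
        raise ValueError("matrix must be ICE-normalized first")
    valid = matrix.mask
    if valid is None or not valid.any():
        raise ValueError("no valid bins")
    norm = matrix.normalized
    n = matrix.n_bins
    oe = np.full((n, n), np.nan)
    for d in range(n):
        diag = np.diagonal(norm, offset=d)
        pair_valid = valid[: n - d] & valid[d:]
        if not pair_valid.any():
            continue
        vals = diag[pair_valid]
        expected = np.nanmean(vals)
        if not np.isfinite(expected) or expected <= 0:
            continue
        idx = np.flatnonzero(pair_valid)
        oe[idx, idx + d] = diag[idx] / expected
        oe[idx + d, idx] = oe[idx, idx + d]
    if clip_quantile is not None:
        finite = oe[np.isfinite(oe)]
        if finite.size:
            cap = np.quantile(finite, clip_quantile)
            np.clip(oe, None, cap, out=oe)
    return oe


def compartment_eigenvector(oe: np.ndarray, tss_counts: np.ndarray,
                            regions: list[tuple[int, int]] | None = None
                            ) -> CompartmentTrack:
    """First eigenvector of the O/E correlation matrix, TSS-oriented.

    The Pearson correlation matrix of O/E columns is computed over bins with
    defined values (zero-variance columns dropped with a counter); its
    leading eigenvector is sign-flipped so the Spearman correlation with the
    per-bin TSS count is non-negative, then mean-centered over defined bins.
    ``regions`` optionally splits the arm into independently analyzed
    [start, end) bin ranges whose eigenvectors are sign-oriented per region
    and centered only after merging.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    tss_counts = np.asarray(tss_counts, dtype=float)
    if tss_counts.shape[0] != n:
        raise ValueError("tss_counts must have one entry per bin")

    if regions is None:
        regions = [(0, n)]

    values = np.full(n, np.nan)
    for start, end in regions:
        sub = oe[start:end, start:end]
        sub_tss = tss_counts[start:end]
        ev = _region_eigenvector(sub, sub_tss)
        values[start:end] = ev

    defined = np.isfinite(values)
    if defined.any():
        values[defined] -= values[defined].mean()
    labels = np.empty(n, dtype=object)
    labels[:] = None
    labels[defined & (values > 0)] = "A"
    labels[defined & (values < 0)] = "B"
    return CompartmentTrack(values=values, labels=labels)


def _region_eigenvector(oe: np.ndarray, tss_counts: np.ndarray) -> np.ndarray:
    n = oe.shape[0]
    out = np.full(n, np.nan)
    defined = np.isfinite(oe).any(axis=0)
    if defined.sum() < 3:
        raise ValueError("O/E must be defined on at least 3 bins")
    sub = oe[np.ix_(defined, defined)]
    # neutral fill of residual NaN cells with their column mean, then drop
    # zero-variance columns before correlating
    col_mean = np.nanmean(sub, axis=0)
    nan_r, nan_c = np.where(~np.isfinite(sub))
    if nan_r.size:
        sub = sub.copy()
        sub[nan_r, nan_c] = col_mean[nan_c]
    var = sub.var(axis=0)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance bins")
    sub = sub[np.ix_(keep, keep)]
    if sub.shape[0] < 3:
        raise ValueError("fewer than 3 usable bins after dropping")

    corr = np.corrcoef(sub, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    ev = eigvec[:, -1]  # largest eigenvalue

    idx = np.flatnonzero(defined)[keep]
    rho, _ = stats.spearmanr(ev, tss_counts[idx])
    if np.isfinite(rho) and rho < 0:
        ev = -ev
    elif not np.isfinite(rho) or rho == 0:
        warnings.warn("Spearman correlation with TSS counts is zero or "
                      "undefined; eigenvector sign left unchanged")
    out[idx] = ev
    return out
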