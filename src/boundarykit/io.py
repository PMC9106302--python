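"""Plain-text readers/writers for the pipeline's interchange formats.

Pairs are tab-separated records; matrices are sparse bin-bin-count triplets
with a BED3 bin-table sidecar; profiles are bedGraph; boundary sets are BED
with the mean insulation score in the score column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .hic import ContactMatrix
from .insulation import BoundarySet

__all__ = [
    "write_pairs", "read_pairs",
    "write_matrix", "read_matrix",
    "write_bedgraph", "write_boundaries", "read_boundaries",
    "write_mask",
]


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: ContactMatrix, prefix) -> None:
    """Write <prefix>.triplets.tsv (bin1, bin2, count; upper triangle) and
    <prefix>.bins.bed (chrom, start, end)."""
    prefix = Path(prefix)
    i, j = np.nonzero(np.triu(matrix.counts))
    pd.DataFrame({"bin1": i, "bin2": j, "count": matrix.counts[i, j]}).to_csv(
        prefix.with_suffix(".triplets.tsv"), sep="\t", index=False)
    matrix.bins().to_csv(prefix.with_suffix(".bins.bed"), sep="\t",
                         index=False, header=False)


def read_matrix(prefix) -> ContactMatrix:
    prefix = Path(prefix)
    bins = pd.read_csv(prefix.with_suffix(".bins.bed"), sep="\t",
                       names=["chrom", "start", "end"])
    trip = pd.read_csv(prefix.with_suffix(".triplets.tsv"), sep="\t")
    n = len(bins)
    counts = np.zeros((n, n))
    counts[trip["bin1"], trip["bin2"]] = trip["count"]
    counts = np.triu(counts) + np.triu(counts, 1).T
    bin_size = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    return ContactMatrix(chrom=str(bins["chrom"].iloc[0]), bin_size=bin_size,
                         counts=counts)


def write_bedgraph(values: np.ndarray, bin_size: int, chrom: str, path) -> None:
    """Per-bin track as bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    idx = np.flatnonzero(ok)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": idx * bin_size,
        "end": (idx + 1) * bin_size,
        "value": values[idx],
    })
    df.to_csv(path, sep="\t", index=False, header=False)


def write_boundaries(bset: BoundarySet, chrom: str, path) -> None:
    bset.to_frame(chrom).to_csv(path, sep="\t", index=False, header=False)


def read_boundaries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       names=["chrom", "start", "end", "score"])


def write_mask(mask: np.ndarray, bin_size: int, chrom: str, path) -> None:
    """Masked (invalid) bins as BED intervals."""
    idx = np.flatnonzero(~np.asarray(mask, dtype=bool))
    pd.DataFrame({
        "chrom": chrom,
        "start": idx * bin_size,
        "end": (idx + 1) * bin_size,
    }).to_csv(path, sep="\t", index=False, header=False)
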