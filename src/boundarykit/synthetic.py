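"""Synthetic chromosome-arm data with planted ground truth.

Generates distance-decaying Hi-C contact maps with planted contact-domain
boundaries of tunable insulation strength, compartment checkerboards, pair
records with controlled contaminants, ChIP peaks at or away from planted
boundaries, TSS/motif/gene annotations and reporter cell populations.  Every
generator is deterministic under its seed, and the noiseless expectation
matrix is exposed so downstream statistics can be checked analytically.

Generative model for the contact map: the expected contact between bins i, j
on one arm is

    e_ij  ∝  (|i - j| + 1)^(-alpha)                      (distance decay)
            × Π f_b  over planted boundaries b with i < b <= j
            × contrast  if bins i and j share a compartment label

with counts drawn independently Poisson(e_ij) on the upper triangle and
mirrored.  A boundary factor f in (0, 1] multiplies every contact crossing
the border between bin b-1 and bin b, so f is a single interpretable
insulation-strength parameter; f = 1 means no boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "GenomeAnnotation",
    "InvalidConfigError",
    "PlacementError",
    "make_annotation",
    "plant_truth",
    "expected_matrix",
    "simulate_matrix",
    "simulate_pairs",
    "perturb_truth",
    "simulate_reporter_cells",
]


class InvalidConfigError(ValueError):
    """Raised for degenerate or inconsistent generator configuration."""


class PlacementError(RuntimeError):
    """Raised when planted features cannot satisfy their spacing constraints."""


# mean restriction-site spacing of a single 4-cutter landscape; two merged
# enzyme landscapes give the combined mean spacing MEAN_SITE_SPACING / 2
MEAN_SITE_SPACING = 512

PAIR_COLUMNS = [
    "read_id",
    "chrom1", "pos1", "strand1", "frag1",
    "chrom2", "pos2", "strand2", "frag2",
    "unique1", "unique2",
    "mismatches1", "mismatches2",
    "indel1", "indel2",
    "truth",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated chromosome arm.

    Parameters
    ----------
    arm_length : int
        Arm length in bp; must be a positive multiple of ``bin_size``.
    bin_size : int
        Bin size in bp (2 kb by default, the working resolution).
    n_boundaries : int
        Number of planted contact-domain boundaries.
    insulation_factors : tuple of float, optional
        Per-boundary multiplicative factor f in (0, 1]; default 0.5 each.
    decay_exponent : float
        alpha in the contact decay d(s) ∝ s^-alpha.
    compartment_block_size : int
        Compartment block size in bins; 0 disables compartment structure.
    compartment_contrast : float
        Same-compartment contact multiplier, >= 1.
    sequencing_depth : int
        Expected total cis pair count on the arm.
    duplicate_rate, nonunique_rate, mismatch_rate, religation_rate : float
        Contaminant injection rates for ``simulate_pairs`` (fractions of the
        genuine pair count).
    visibility_sd : float
        Log-normal sigma of the per-bin technical visibility bias v_i
        (mappability/GC/fragment density); contacts scale as v_i v_j, the
        rank-one bias ICE removes.  0 disables the bias layer.
    invisible_fraction : float
        Fraction of bins with near-zero visibility (unmappable regions the
        low-coverage mask is meant to catch).
    min_boundary_spacing : int
        Minimum spacing between planted boundaries, in bins.
    peak_fraction_at_boundary : float
        Fraction of planted boundaries receiving a ChIP peak within ±2 kb.
    n_decoy_peaks : int
        Number of decoy peaks planted away from every boundary.
    seed : int
        Master seed; identical (config, seed) gives bit-identical outputs.
    """

    arm_length: int
    bin_size: int = 2000
    n_boundaries: int = 10
    insulation_factors: tuple[float, ...] | None = None
    decay_exponent: float = 1.0
    compartment_block_size: int = 0
    compartment_contrast: float = 1.0
    sequencing_depth: int = 500_000
    duplicate_rate: float = 0.0
    nonunique_rate: float = 0.0
    mismatch_rate: float = 0.0
    religation_rate: float = 0.0
    visibility_sd: float = 0.45
    invisible_fraction: float = 0.02
    min_boundary_spacing: int = 20
    peak_fraction_at_boundary: float = 0.8
    n_decoy_peaks: int = 20
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm_length <= 0 or self.bin_size <= 0:
            raise InvalidConfigError("arm_length and bin_size must be positive")
        if self.arm_length % self.bin_size != 0:
            raise InvalidConfigError("bin_size must divide arm_length")
        if self.n_boundaries < 0:
            raise InvalidConfigError("n_boundaries must be >= 0")
        factors = self.factors
        if len(factors) != self.n_boundaries:
            raise InvalidConfigError(
                "insulation_factors length must equal n_boundaries")
        if np.any((factors <= 0) | (factors > 1)):
            raise InvalidConfigError("insulation_factors must lie in (0, 1]")
        if self.sequencing_depth < 0:
            raise InvalidConfigError("sequencing_depth must be >= 0")
        if self.visibility_sd < 0:
            raise InvalidConfigError("visibility_sd must be >= 0")
        for name in ("duplicate_rate", "nonunique_rate", "mismatch_rate",
                     "religation_rate", "peak_fraction_at_boundary",
                     "invisible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.compartment_contrast < 1.0:
            raise InvalidConfigError("compartment_contrast must be >= 1")
        if self.compartment_block_size < 0:
            raise InvalidConfigError("compartment_block_size must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.arm_length // self.bin_size

    @property
    def factors(self) -> np.ndarray:
        if self.insulation_factors is None:
            return np.full(self.n_boundaries, 0.5)
        return np.asarray(self.insulation_factors, dtype=float)


@dataclass
class GenomeAnnotation:
    """Restriction landscape, TSSs, motif occurrences and gene models."""

    chrom: str
    arm_length: int
    restriction_sites: np.ndarray          # sorted bp positions
    tss: pd.DataFrame                      # pos, strand, rpkm
    motifs: dict[str, pd.DataFrame]        # name -> (start, end) half-open
    genes: pd.DataFrame                    # gene_id, start, end, strand
    exons: pd.DataFrame                    # gene_id, start, end
    introns: pd.DataFrame                  # gene_id, start, end

    def fragment_index(self, pos: np.ndarray | int) -> np.ndarray | int:
        """Restriction fragment index containing bp position(s).

        Fragment k spans [site_k, site_{k+1}) with sentinel sites at 0 and
        arm_length.
        """
        edges = self.fragment_edges
        idx = np.searchsorted(edges, pos, side="right") - 1
        return idx

    @property
    def fragment_edges(self) -> np.ndarray:
        sites = self.restriction_sites
        edges = [0]
        edges.extend(int(s) for s in sites if 0 < s < self.arm_length)
        edges.append(self.arm_length)
        return np.unique(np.asarray(edges))


@dataclass
class SyntheticTruth:
    """Planted ground truth for one arm."""

    boundary_bins: np.ndarray              # strictly increasing bin indices
    boundary_factors: np.ndarray           # per-boundary f in (0, 1]
    compartment_labels: np.ndarray | None  # 'A'/'B' per bin, or None
    peaks: pd.DataFrame                    # pos, occupancy, at_boundary
    mutant_edits: list = field(default_factory=list)
    reporter_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary_bins)
        if b.size and not np.all(np.diff(b) > 0):
            raise InvalidConfigError("boundary bins must be strictly increasing")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic sub-streams per generator
    return np.random.default_rng([config.seed, stream])


def make_annotation(config: SyntheticConfig,
                    truth: SyntheticTruth | None = None) -> GenomeAnnotation:
    """Draw the annotation layer: restriction sites (two merged four-cutter
    landscapes, combined mean spacing 256 bp), TSSs with RPKM (a fraction
    silent), motif occurrences for three named motif classes and simple
    exon/intron gene models.

    If a ``truth`` with compartment labels is given, TSS placement is biased
    4:1 toward A-compartment bins (the A compartment is the
    transcription-associated one)."""
    rng = _rng(config, 0)
    L = config.arm_length

    sites = []
    for _ in range(2):  # two independent enzymes
        pos = 0
        enzyme_sites = []
        while True:
            pos += rng.geometric(1.0 / MEAN_SITE_SPACING)
            if pos >= L:
                break
            enzyme_sites.append(pos)
        sites.append(np.asarray(enzyme_sites, dtype=int))
    restriction_sites = np.unique(np.concatenate(sites))

    n_tss = max(1, L // 5000)
    if truth is not None and truth.compartment_labels is not None:
        bin_w = np.where(truth.compartment_labels == "A", 4.0, 1.0)
        bins = rng.choice(config.n_bins, size=n_tss, p=bin_w / bin_w.sum())
        tss_pos = np.sort(bins * config.bin_size
                          + rng.integers(0, config.bin_size, n_tss))
    else:
        tss_pos = np.sort(rng.integers(0, L, n_tss))
    rpkm = rng.lognormal(mean=1.0, sigma=1.5, size=n_tss)
    silent = rng.random(n_tss) < 0.3
    rpkm[silent] = 0.0
    tss = pd.DataFrame({
        "pos": tss_pos,
        "strand": rng.choice(["+", "-"], n_tss),
        "rpkm": rpkm,
    })

    motifs = {}
    for name in ("CTCF", "Su(Hw)", "BEAF-32"):
        n_m = max(1, L // 20_000)
        starts = np.sort(rng.integers(0, max(1, L - 20), n_m))
        lengths = rng.integers(8, 20, n_m)
        motifs[name] = pd.DataFrame(
            {"start": starts, "end": np.minimum(starts + lengths, L)})

    genes, exons, introns = [], [], []
    gpos, gid = 0, 0
    while gpos < L - 4000:
        g_start = gpos + int(rng.integers(500, 3000))
        g_len = int(rng.integers(2000, 12_000))
        g_end = min(g_start + g_len, L)
        if g_end - g_start < 1500:
            break
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(
            np.arange(g_start + 100, g_end - 100), size=2 * (n_ex - 1),
            replace=False))
        edges = np.concatenate([[g_start], cuts, [g_end]])
        name = f"gene{gid}"
        genes.append((name, g_start, g_end, "+" if rng.random() < 0.5 else "-"))
        for k in range(n_ex):
            exons.append((name, int(edges[2 * k]), int(edges[2 * k + 1])))
        for k in range(n_ex - 1):
            introns.append((name, int(edges[2 * k + 1]), int(edges[2 * k + 2])))
        gpos = g_end
        gid += 1

    return GenomeAnnotation(
        chrom=config.chrom,
        arm_length=L,
        restriction_sites=restriction_sites,
        tss=tss,
        motifs=motifs,
        genes=pd.DataFrame(genes, columns=["gene_id", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "start", "end"]),
        introns=pd.DataFrame(introns, columns=["gene_id", "start", "end"]),
    )


def plant_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Place boundaries with enforced minimum spacing, alternate compartment
    labels in blocks, and plant ChIP peaks at a configurable fraction of
    boundaries (within ±2 kb) plus decoys elsewhere."""
    rng = _rng(config, 1)
    n_bins = config.n_bins
    n_b = config.n_boundaries
    spacing = config.min_boundary_spacing

    if n_b == 0:
        bins = np.asarray([], dtype=int)
    else:
        # enforce minimum spacing via the order-statistics trick: sample from
        # a shrunken range, then re-inflate with the fixed gaps
        margin = spacing
        free = n_bins - 2 * margin - (n_b - 1) * spacing
        if free <= 0:
            raise PlacementError(
                f"cannot place {n_b} boundaries with spacing {spacing} "
                f"on {n_bins} bins")
        raw = np.sort(rng.choice(free, size=n_b, replace=False))
        bins = raw + margin + np.arange(n_b) * spacing

    if config.compartment_block_size > 0:
        block = config.compartment_block_size
        labels = np.where((np.arange(n_bins) // block) % 2 == 0, "A", "B")
    else:
        labels = None

    peak_rows = []
    for b in bins:
        if rng.random() < config.peak_fraction_at_boundary:
            pos = int(np.clip(b * config.bin_size + rng.integers(-2000, 2001),
                              0, config.arm_length - 1))
            occ = float(rng.lognormal(mean=1.0, sigma=0.5))
            peak_rows.append((pos, occ, True))
    boundary_bp = bins * config.bin_size
    placed = 0
    attempts = 0
    while placed < config.n_decoy_peaks and attempts < 50 * max(1, config.n_decoy_peaks):
        attempts += 1
        pos = int(rng.integers(0, config.arm_length))
        if boundary_bp.size and np.min(np.abs(pos - boundary_bp)) <= 4000:
            continue  # keep decoys clear of boundaries
        occ = float(rng.lognormal(mean=0.5, sigma=0.5))
        peak_rows.append((pos, occ, False))
        placed += 1
    peaks = pd.DataFrame(peak_rows, columns=["pos", "occupancy", "at_boundary"])
    peaks = peaks.sort_values("pos", ignore_index=True)

    return SyntheticTruth(
        boundary_bins=bins,
        boundary_factors=config.factors.copy(),
        compartment_labels=labels,
        peaks=peaks,
    )


def bin_visibility(config: SyntheticConfig) -> np.ndarray:
    """Per-bin technical visibility v_i: log-normal spread plus a small
    unmappable fraction at v ~ 0.02, normalized to mean 1.  Deterministic
    under the config seed."""
    n = config.n_bins
    if config.visibility_sd == 0 and config.invisible_fraction == 0:
        return np.ones(n)
    rng = _rng(config, 4)
    sd = config.visibility_sd
    v = rng.lognormal(mean=-sd * sd / 2.0, sigma=sd, size=n)
    invisible = rng.random(n) < config.invisible_fraction
    v[invisible] *= 0.02
    return v / v.mean()


def expected_matrix(truth: SyntheticTruth, config: SyntheticConfig) -> np.ndarray:
    """Noise-free expectation e_ij.

    The depth scale is anchored on the decay-only baseline (the unstructured
    map with no boundaries, compartments or biases sums to
    ``sequencing_depth`` over the upper triangle), so planted boundary
    factors and compartment contrast translate into exact contact ratios.
    """
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    e = (d + 1.0) ** (-config.decay_exponent)

    total = np.triu(e).sum()
    if total > 0 and config.sequencing_depth > 0:
        e *= config.sequencing_depth / total

    for b, f in zip(truth.boundary_bins, truth.boundary_factors):
        # boundary b is the border between bins b-1 and b
        e[:b, b:] *= f
        e[b:, :b] *= f

    if truth.compartment_labels is not None and config.compartment_contrast > 1:
        same = truth.compartment_labels[:, None] == truth.compartment_labels[None, :]
        e[same] *= config.compartment_contrast

    v = bin_visibility(config)
    e *= np.outer(v, v)
    return e


def _sample_counts(truth: SyntheticTruth, config: SyntheticConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Poisson counts on the upper triangle, mirrored to a symmetric matrix."""
    e = expected_matrix(truth, config)
    upper = np.triu(rng.poisson(e))
    counts = upper + np.triu(upper, 1).T
    return counts


def simulate_matrix(truth: SyntheticTruth, config: SyntheticConfig,
                    noise: bool = True):
    """Binned contact map for the planted truth.

    With ``noise=False`` the (continuous) expectation matrix is returned as
    the count field, which makes every downstream statistic analytically
    checkable.  Returns a :class:`boundarykit.hic.ContactMatrix`.
    """
    from .hic import ContactMatrix

    if noise:
        counts = _sample_counts(truth, config, _rng(config, 2)).astype(float)
    else:
        counts = expected_matrix(truth, config)
    return ContactMatrix(chrom=config.chrom, bin_size=config.bin_size,
                         counts=counts)


def simulate_pairs(truth: SyntheticTruth, config: SyntheticConfig,
                   annotation: GenomeAnnotation | None = None) -> pd.DataFrame:
    """Pair records sampled from the expectation matrix.

    Positions are jittered uniformly within bins and assigned to restriction
    fragments; contaminants (PCR duplicates, non-unique mappings, >2-mismatch
    reads, opposite-orientation religation pairs < 2 kb apart) are injected at
    the configured rates and labelled in the ``truth`` column so filters can
    be tested exactly.  The genuine records, binned, reproduce the matrix
    drawn by :func:`simulate_matrix` under the same seed bit for bit.
    """
    if config.sequencing_depth <= 0:
        raise InvalidConfigError("sequencing_depth must be positive for pairs")
    if annotation is None:
        annotation = make_annotation(config)

    counts = _sample_counts(truth, config, _rng(config, 2))
    rng = _rng(config, 3)
    bs = config.bin_size
    chrom = config.chrom

    iu, ju = np.triu_indices(config.n_bins)
    c = counts[iu, ju]
    nz = c > 0
    bin1 = np.repeat(iu[nz], c[nz])
    bin2 = np.repeat(ju[nz], c[nz])
    n_pairs = bin1.size

    pos1 = bin1 * bs + rng.integers(0, bs, n_pairs)
    pos2 = bin2 * bs + rng.integers(0, bs, n_pairs)
    strand1 = rng.choice(["+", "-"], n_pairs)
    strand2 = rng.choice(["+", "-"], n_pairs)
    # genuine close pairs keep equal strands so they survive the
    # opposite-orientation religation filter
    close = np.abs(pos1 - pos2) < 2000
    strand2 = np.where(close, strand1, strand2)

    df = pd.DataFrame({
        "read_id": [f"read{k}" for k in range(n_pairs)],
        "chrom1": chrom, "pos1": pos1, "strand1": strand1,
        "frag1": annotation.fragment_index(pos1),
        "chrom2": chrom, "pos2": pos2, "strand2": strand2,
        "frag2": annotation.fragment_index(pos2),
        "unique1": True, "unique2": True,
        "mismatches1": 0, "mismatches2": 0,
        "indel1": False, "indel2": False,
        "truth": "ok",
    })

    extras = []
    rid = n_pairs

    def _base_sample(rate: int) -> pd.DataFrame:
        k = rng.binomial(n_pairs, rate) if n_pairs else 0
        if k == 0:
            return df.iloc[0:0].copy()
        rows = df.iloc[rng.integers(0, n_pairs, k)].copy().reset_index(drop=True)
        return rows

    dup = _base_sample(config.duplicate_rate)
    dup["truth"] = "duplicate"
    extras.append(dup)

    nonuni = _base_sample(config.nonunique_rate)
    if len(nonuni):
        nonuni["unique1"] = rng.random(len(nonuni)) < 0.5
        nonuni["unique2"] = ~nonuni["unique1"].to_numpy()
        nonuni["truth"] = "nonunique"
    extras.append(nonuni)

    mm = _base_sample(config.mismatch_rate)
    if len(mm):
        mm["mismatches1"] = 3
        mm["truth"] = "mismatch"
    extras.append(mm)

    relig = _base_sample(config.religation_rate)
    if len(relig):
        p1 = rng.integers(0, config.arm_length - 2000, len(relig))
        off = rng.integers(50, 1999, len(relig))
        relig["pos1"], relig["pos2"] = p1, p1 + off
        relig["strand1"], relig["strand2"] = "+", "-"
        relig["frag1"] = annotation.fragment_index(relig["pos1"].to_numpy())
        relig["frag2"] = annotation.fragment_index(relig["pos2"].to_numpy())
        relig["truth"] = "religation"
    extras.append(relig)

    for ex in extras:
        if len(ex) and ex["truth"].iloc[0] != "duplicate":
            ex["read_id"] = [f"read{rid + k}" for k in range(len(ex))]
            rid += len(ex)

    out = pd.concat([df, *extras], ignore_index=True)
    # contaminants interleaved deterministically
    order = rng.permutation(len(out))
    return out.iloc[order].reset_index(drop=True)


def perturb_truth(truth: SyntheticTruth,
                  edits: Sequence[tuple[int, float | None]]) -> SyntheticTruth:
    """Mutant truth: per edit (boundary index, new factor) weaken the
    boundary, or remove it with new factor None (f -> 1.0)."""
    factors = truth.boundary_factors.copy()
    applied = []
    for idx, new_f in edits:
        if not 0 <= idx < len(factors):
            raise IndexError(f"unknown boundary index {idx}")
        f = 1.0 if new_f is None else float(new_f)
        if not 0 < f <= 1:
            raise InvalidConfigError("edited factor must lie in (0, 1]")
        factors[idx] = f
        applied.append((idx, new_f))
    return SyntheticTruth(
        boundary_bins=truth.boundary_bins.copy(),
        boundary_factors=factors,
        compartment_labels=(None if truth.compartment_labels is None
                            else truth.compartment_labels.copy()),
        peaks=truth.peaks.copy(),
        mutant_edits=list(truth.mutant_edits) + applied,
        reporter_truth=dict(truth.reporter_truth),
    )


# reporter simulation constants: log2(mCherry/EGFP) of the neutral spacer and
# the full gypsy insulator
SPACER_BASELINE = 0.0
GYPSY_OFFSET = 2.0


def simulate_reporter_cells(true_strength: float, n_cells: int,
                            noise_sd: float, seed: int,
                            fragment: str = "test", replicate: int = 1,
                            baseline: float = SPACER_BASELINE,
                            gypsy_offset: float = GYPSY_OFFSET) -> pd.DataFrame:
    """Per-cell EGFP/mCherry intensities for one transfection replicate.

    Each cell's log2(mCherry/EGFP) is baseline + (true_strength/100) × the
    gypsy offset + Normal(0, noise_sd); EGFP intensities are log-normal.
    """
    if n_cells < 1:
        raise InvalidConfigError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    log2_ratio = (baseline + true_strength / 100.0 * gypsy_offset
                  + rng.normal(0.0, noise_sd, n_cells))
    egfp = rng.lognormal(mean=6.0, sigma=0.4, size=n_cells)
    mcherry = egfp * np.exp2(log2_ratio)
    return pd.DataFrame({
        "fragment": fragment,
        "replicate": replicate,
        "egfp": egfp,
        "mcherry": mcherry,
    })
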