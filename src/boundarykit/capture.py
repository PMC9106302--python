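"""Capture-C style viewpoint profiles and differential tracks.

A viewpoint is a restriction fragment; informative pairs are deduplicated
pairs with at least one mate on the viewpoint fragment or one of its two
neighbours.  Counts are accumulated in nominal 1-kb bins whose edges are
snapped to the nearest restriction site, so every restriction fragment lies
in exactly one bin; bins closer than 2 kb or farther than 100 kb from the
viewpoint fragment are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CaptureProfile",
    "snap_bin_edges",
    "select_viewpoint_pairs",
    "build_profile",
    "differential_profile",
]


@dataclass
class CaptureProfile:
    """Per-bin interaction counts around one viewpoint.

    ``bins``: DataFrame (start, end, excluded); counts of excluded bins are
    kept for bookkeeping but carry the ``excluded`` flag; ``library_size``
    is the informative pair count.
    """

    viewpoint: tuple[int, int]      # fragment interval [start, end)
    bins: pd.DataFrame
    counts: np.ndarray
    library_size: int

    @property
    def retained(self) -> np.ndarray:
        return ~self.bins["excluded"].to_numpy()


def snap_bin_edges(arm_length: int, sites: np.ndarray,
                   nominal: int = 1000) -> np.ndarray:
    """Bin edges on a nominal grid snapped to the nearest restriction site;
    degenerate (empty) bins are merged."""
    sites = np.asarray(sites)
    inner = np.arange(nominal, arm_length, nominal)
    if sites.size:
        j = np.searchsorted(sites, inner)
        snapped = []
        for e, k in zip(inner, j):
            cands = [sites[i] for i in (k - 1, k) if 0 <= i < sites.size]
            snapped.append(min(cands, key=lambda s: abs(s - e)) if cands else e)
    else:
        snapped = list(inner)
    edges = np.unique(np.concatenate([[0], snapped, [arm_length]]))
    return edges


def _fragment_intervals(arm_length: int, sites: np.ndarray) -> np.ndarray:
    edges = np.unique(np.concatenate([[0], sites[(sites > 0) & (sites < arm_length)],
                                      [arm_length]]))
    return edges


def select_viewpoint_pairs(pairs: pd.DataFrame, viewpoint_fragment: int,
                           n_fragments: int) -> pd.DataFrame:
    """Deduplicated pairs with >= 1 mate on the viewpoint restriction
    fragment or either immediate neighbour fragment."""
    if not 0 <= viewpoint_fragment < n_fragments:
        raise ValueError(f"viewpoint fragment {viewpoint_fragment} not in site table")
    frags = {viewpoint_fragment}
    if viewpoint_fragment > 0:
        frags.add(viewpoint_fragment - 1)
    if viewpoint_fragment < n_fragments - 1:
        frags.add(viewpoint_fragment + 1)

    m1 = list(zip(pairs["chrom1"], pairs["pos1"], pairs["strand1"]))
    m2 = list(zip(pairs["chrom2"], pairs["pos2"], pairs["strand2"]))
    keys = [tuple(sorted((a, b))) for a, b in zip(m1, m2)]
    dedup = ~pd.Series(keys).duplicated().to_numpy()
    informative = (pairs["frag1"].isin(frags) | pairs["frag2"].isin(frags)).to_numpy()
    return pairs[dedup & informative].reset_index(drop=True)


def build_profile(informative: pd.DataFrame, viewpoint_fragment: int,
                  arm_length: int, sites: np.ndarray,
                  bin_nominal: int = 1000, near: int = 2000,
                  far: int = 100_000) -> CaptureProfile:
    """Count, per restriction-site-snapped bin, the pairs with one end on
    the viewpoint (or neighbour) fragment and the other end on a fragment
    overlapping the bin; flag bins closer than ``near`` or farther than
    ``far`` from the viewpoint fragment as excluded."""
    sites = np.asarray(sites)
    frag_edges = _fragment_intervals(arm_length, sites)
    vp_start = int(frag_edges[viewpoint_fragment])
    vp_end = int(frag_edges[viewpoint_fragment + 1])

    edges = snap_bin_edges(arm_length, sites, bin_nominal)
    starts, ends = edges[:-1], edges[1:]

    counts = np.zeros(starts.size)
    vp_frags = {viewpoint_fragment}
    if viewpoint_fragment > 0:
        vp_frags.add(viewpoint_fragment - 1)
    if viewpoint_fragment + 2 < frag_edges.size:
        vp_frags.add(viewpoint_fragment + 1)

    f1 = informative["frag1"].to_numpy()
    f2 = informative["frag2"].to_numpy()
    p1 = informative["pos1"].to_numpy()
    p2 = informative["pos2"].to_numpy()
    # the non-viewpoint end of each pair (for double-viewpoint pairs, mate 2)
    other_pos = np.where(np.isin(f1, list(vp_frags)), p2, p1)
    # each fragment lies in exactly one snapped bin; bin of the other end
    idx = np.searchsorted(edges, other_pos, side="right") - 1
    idx = np.clip(idx, 0, starts.size - 1)
    np.add.at(counts, idx, 1)

    # distance from bin to the viewpoint fragment interval
    gap = np.maximum.reduce([
        vp_start - ends, starts - vp_end, np.zeros(starts.size, dtype=int)])
    excluded = (gap < near) | (gap > far)

    bins = pd.DataFrame({"start": starts, "end": ends, "excluded": excluded})
    return CaptureProfile(viewpoint=(vp_start, vp_end), bins=bins,
                          counts=counts, library_size=int(len(informative)))


def differential_profile(profiles_a: list[CaptureProfile],
                         profiles_b: list[CaptureProfile],
                         pseudocount_cpm: float = 0.5) -> np.ndarray:
    """Per-bin log2 fold change between two replicate groups.

    Counts are scaled to counts-per-million by library size, averaged within
    each group, and compared as log2((mean_a + c)/(mean_b + c)) with
    pseudo-count c in CPM units.  Swapping the groups negates the track
    exactly.  Excluded bins give NaN.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("at least one replicate per condition")
    ref = profiles_a[0].bins
    for p in profiles_a + profiles_b:
        if len(p.bins) != len(ref) or not np.array_equal(
                p.bins["start"].to_numpy(), ref["start"].to_numpy()):
            raise ValueError("replicate profiles must share the bin grid")

    def group_mean(group):
        cpm = [p.counts / max(p.library_size, 1) * 1e6 for p in group]
        return np.mean(cpm, axis=0)

    mean_a = group_mean(profiles_a)
    mean_b = group_mean(profiles_b)
    # difference of logs so that swapping conditions negates the track
    # bit-exactly
    lfc = np.log2(mean_a + pseudocount_cpm) - np.log2(mean_b + pseudocount_cpm)
    retained = profiles_a[0].retained
    for p in profiles_a + profiles_b:
        retained = retained & p.retained
    lfc = np.where(retained, lfc, np.nan)
    return lfc
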