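"""Physical insulation scoring and contact-domain boundary calling.

For a window of w bins, binSignal_i is the average balanced contact frequency
between the w bins upstream and the w bins downstream of bin i (a w×w
diamond).  The physical insulation score is

    score_i = log2( binSignal_i / local average of binSignal over the
                    window i - w/2 < j < i + w/2 )

so a uniform map scores 0 everywhere and lower scores indicate stronger
boundaries.  Boundaries are strict local minima of the score with
score <= -0.1, called at each of several window sizes (20/40/80/160 kb by
default), merged across windows, harmonized across genotypes and classified
in mutants as lost / weaker / intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import ContactMatrix

__all__ = [
    "DEFAULT_WINDOWS_BP",
    "BOUNDARY_SCORE_CUTOFF",
    "DELTA_WEAKER_CUTOFF",
    "InsulationProfile",
    "BoundarySet",
    "bin_signal",
    "insulation_score",
    "insulation_profile",
    "call_boundaries",
    "merge_windows",
    "call_boundary_set",
    "harmonize_genotypes",
    "classify_boundaries",
    "delta_insulation",
]

DEFAULT_WINDOWS_BP = (20_000, 40_000, 80_000, 160_000)
BOUNDARY_SCORE_CUTOFF = -0.1   # boundaries with score > -0.1 are ignored
DELTA_WEAKER_CUTOFF = 0.01     # mutant minus WT score >= 0.01 -> "weaker"
BOUNDARY_FILTER_PVALUE = 0.05  # rank-sum depletion filter on candidates


@dataclass
class InsulationProfile:
    """Per-bin binSignal and insulation score at one window size."""

    window_bins: int
    bin_size: int
    bin_signal: np.ndarray
    score: np.ndarray

    @property
    def window_bp(self) -> int:
        return self.window_bins * self.bin_size


@dataclass
class BoundarySet:
    """Merged-window boundaries for one genotype on one arm."""

    bin_size: int
    positions: np.ndarray          # boundary bin indices
    scores: np.ndarray             # mean-window score at each position
    mean_profile: np.ndarray       # full per-bin mean-window score track
    window_profiles: dict[int, InsulationProfile] = field(default_factory=dict)

    def to_frame(self, chrom: str = "chrSim") -> pd.DataFrame:
        starts = self.positions * self.bin_size
        return pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": starts + self.bin_size,
            "score": self.scores,
        })


def bin_signal(matrix: ContactMatrix, w: int) -> np.ndarray:
    """binSignal at window w: mean balanced contact between the w bins
    upstream and w bins downstream of each bin; NaN within w bins of the arm
    ends or where the whole diamond is masked."""
    if matrix.normalized is None:
        raise ValueError("matrix must be ICE-normalized first")
    n = matrix.n_bins
    if w < 1 or 2 * w > n:
        raise ValueError(f"window {w} bins does not fit a {n}-bin arm")
    norm = matrix.normalized
    bs = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        block = norm[i - w:i, i:i + w]
        if np.any(np.isfinite(block)):
            bs[i] = np.nanmean(block)
    return bs


def insulation_score(bin_signal_values: np.ndarray, w: int) -> np.ndarray:
    """log2 of binSignal over its local average on a window of size w
    (exclusive bounds i - w/2 < j < i + w/2, undefined bins excluded from the
    average); NaN where binSignal is undefined or the local average is
    non-positive or empty."""
    bs = np.asarray(bin_signal_values, dtype=float)
    n = bs.size
    score = np.full(n, np.nan)
    half = w / 2.0
    for i in range(n):
        if not np.isfinite(bs[i]) or bs[i] <= 0:
            continue
        lo = max(0, math.floor(i - half) + 1)
        hi = min(n - 1, math.ceil(i + half) - 1)
        window = bs[lo:hi + 1]
        window = window[np.isfinite(window)]
        if window.size == 0:
            continue
        local = window.mean()
        if local <= 0:
            continue
        score[i] = np.log2(bs[i] / local)
    return score


def insulation_profile(matrix: ContactMatrix, window_bp: int) -> InsulationProfile:
    """binSignal + score at one window size given in bp."""
    if window_bp % matrix.bin_size:
        raise ValueError("window must be a multiple of the bin size")
    w = window_bp // matrix.bin_size
    bs = bin_signal(matrix, w)
    return InsulationProfile(window_bins=w, bin_size=matrix.bin_size,
                             bin_signal=bs, score=insulation_score(bs, w))


def _strict_minima(values: np.ndarray) -> np.ndarray:
    """Strict local minima of a track with NaN gaps; plateaus resolve to the
    leftmost bin."""
    values = np.asarray(values, dtype=float)
    n = values.size
    out = []
    i = 0
    while i < n:
        if not np.isfinite(values[i]):
            i += 1
            continue
        # run of equal consecutive defined values
        j = i
        while j + 1 < n and np.isfinite(values[j + 1]) and values[j + 1] == values[i]:
            j += 1
        left_ok = i - 1 >= 0 and np.isfinite(values[i - 1]) and values[i - 1] > values[i]
        right_ok = j + 1 < n and np.isfinite(values[j + 1]) and values[j + 1] > values[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return np.asarray(out, dtype=int)


def call_boundaries(score: np.ndarray,
                    threshold: float = BOUNDARY_SCORE_CUTOFF) -> np.ndarray:
    """Candidate boundary bins: strict local minima of the score profile
    (plateaus resolved to the leftmost bin) with score <= threshold."""
    score = np.asarray(score, dtype=float)
    mins = _strict_minima(score)
    return mins[score[mins] <= threshold]


def detect_boundaries(profile: InsulationProfile,
                      threshold: float = BOUNDARY_SCORE_CUTOFF) -> np.ndarray:
    """Per-window boundary candidates: strict local minima of binSignal
    whose insulation score is defined and <= threshold.

    Detection runs on binSignal (the diamond mean) rather than on the score:
    balancing widens strong dips beyond the small-window local-average span,
    which carves spurious twin minima into the score track, while the
    binSignal minimum stays on the boundary bin.  The score keeps its role
    as the strength measure and cutoff.
    """
    mins = _strict_minima(profile.bin_signal)
    sc = profile.score[mins]
    return mins[np.isfinite(sc) & (sc <= threshold)]


def depletion_filter(candidates: np.ndarray, oe: np.ndarray, w: int,
                     alpha: float = BOUNDARY_FILTER_PVALUE,
                     min_log2_depletion: float = BOUNDARY_SCORE_CUTOFF
                     ) -> np.ndarray:
    """Statistical pruning of boundary candidates at one window size.

    For each candidate bin i, the distance-normalized (observed/expected)
    contacts in the w×w cross-boundary diamond are compared to the
    within-domain contacts of the two flanking triangles.  A candidate is
    kept only if the cross-boundary contacts are (a) significantly depleted
    (one-sided Wilcoxon rank-sum, p < ``alpha``) and (b) depleted by at
    least the boundary-defining magnitude: log2 of the diamond/domain mean
    contact ratio <= ``min_log2_depletion`` (the same -0.1 cutoff the score
    filter uses — with thousands of cells per window, significance alone
    would also pass percent-level balancing artifacts around masked bins).
    Distance normalization removes the trivial decay difference between the
    two contact sets.
    """
    from scipy.stats import mannwhitneyu

    n = oe.shape[0]
    kept = []
    for i in candidates:
        lo, hi = i - w, i + w
        if lo < 0 or hi > n:
            continue
        inter = oe[lo:i, i:hi].ravel()
        up = oe[lo:i, lo:i][np.triu_indices(w, k=1)]
        down = oe[i:hi, i:hi][np.triu_indices(w, k=1)]
        intra = np.concatenate([up, down])
        inter = inter[np.isfinite(inter)]
        intra = intra[np.isfinite(intra)]
        if inter.size < 3 or intra.size < 3:
            continue
        if not (inter.mean() > 0 and intra.mean() > 0):
            continue
        if np.log2(inter.mean() / intra.mean()) > min_log2_depletion:
            continue
        _, p = mannwhitneyu(inter, intra, alternative="less",
                            method="asymptotic")
        if p < alpha:
            kept.append(i)
    return np.asarray(kept, dtype=int)


def _snap_to_anchors(candidates: np.ndarray, anchors: np.ndarray,
                     radius: int, score: np.ndarray) -> np.ndarray:
    """Relocalize candidates to the nearest anchor within ``radius`` bins,
    but only downhill — a move must strictly lower the insulation score.
    Candidates with no improving anchor in range keep their position.

    Large windows localize a dip a couple of bins off; the smallest window's
    binSignal minima serve as the high-resolution anchors.  The downhill
    condition stops a genuine detection from being dragged off a boundary
    that happens to flank a masked bin (and therefore cannot anchor).
    """
    if anchors.size == 0 or candidates.size == 0:
        return candidates
    out = []
    for c in candidates:
        k = int(np.argmin(np.abs(anchors - c)))
        a = int(anchors[k])
        improves = (np.isfinite(score[a])
                    and (not np.isfinite(score[c]) or score[a] < score[c]))
        out.append(a if abs(a - c) <= radius and improves else int(c))
    return np.unique(np.asarray(out, dtype=int))


def merge_windows(profiles: dict[int, InsulationProfile],
                  candidates: dict[int, np.ndarray] | None = None,
                  threshold: float = BOUNDARY_SCORE_CUTOFF,
                  proximity_bp: int = 2000,
                  mode: str = "union") -> BoundarySet:
    """Merge per-window boundary candidates into one BoundarySet.

    Candidates from all windows are pooled (``mode="union"``, the default; an
    ``"intersection"`` mode keeps bins called at every window), chained
    groups of boundary bins within ``proximity_bp`` of each other (interval
    gap: two 2-kb bins separated by at most one bin are within 2 kb) are
    collapsed to the bin with the lowest mean-window score, the per-boundary
    score is the mean of the per-window scores at that bin over defined
    windows, and boundaries with mean score > threshold are filtered out.
    """
    if not profiles:
        raise ValueError("at least one window profile required")
    bin_size = next(iter(profiles.values())).bin_size
    n = next(iter(profiles.values())).score.size
    if candidates is None:
        candidates = {w: call_boundaries(p.score, threshold)
                      for w, p in profiles.items()}

    stack = np.vstack([p.score for p in profiles.values()])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_profile = np.nanmean(stack, axis=0)

    sets = [set(c.tolist()) for c in candidates.values()]
    if mode == "union":
        pooled = sorted(set().union(*sets))
    elif mode == "intersection":
        pooled = sorted(set.intersection(*sets)) if sets else []
    else:
        raise ValueError("mode must be 'union' or 'intersection'")

    # interval-gap proximity: bins i < j are within proximity_bp when the
    # gap between their intervals, (j - i - 1) * bin_size, is <= proximity_bp
    prox_bins = max(1, proximity_bp // bin_size + 1)
    positions, scores = [], []
    group: list[int] = []
    for pos in pooled + [None]:
        if pos is not None and (not group or pos - group[-1] <= prox_bins):
            group.append(pos)
            continue
        if group:
            g = np.asarray(group)
            s = mean_profile[g]
            best = g[int(np.nanargmin(s))]  # leftmost wins ties via argmin
            if np.isfinite(mean_profile[best]) and mean_profile[best] <= threshold:
                positions.append(best)
                scores.append(mean_profile[best])
        group = [pos] if pos is not None else []

    return BoundarySet(bin_size=bin_size,
                       positions=np.asarray(positions, dtype=int),
                       scores=np.asarray(scores, dtype=float),
                       mean_profile=mean_profile,
                       window_profiles=dict(profiles))


def call_boundary_set(matrix: ContactMatrix,
                      windows_bp: tuple[int, ...] = DEFAULT_WINDOWS_BP,
                      threshold: float = BOUNDARY_SCORE_CUTOFF,
                      mode: str = "union",
                      filter_alpha: float | None = BOUNDARY_FILTER_PVALUE
                      ) -> BoundarySet:
    """Full per-genotype pipeline: insulation profiles at every window size,
    per-window boundary calls with the rank-sum depletion filter, merge
    across windows and -0.1 filtering on the mean score.

    ``filter_alpha=None`` disables the statistical filter (bare local
    minima + score threshold only).
    """
    profiles = {w: insulation_profile(matrix, w) for w in windows_bp}
    candidates = {w: _strict_minima(p.bin_signal) for w, p in profiles.items()}

    # snap every window's detections onto the smallest window's binSignal
    # minima at clean bins (not masked and not flanking a masked bin): the
    # smallest window localizes sharpest, and minima manufactured by
    # balancing artifacts around coverage holes are excluded as anchors, so
    # hole-displaced twin detections of one boundary land on the same bin
    w_small = min(windows_bp)
    anchors = _strict_minima(profiles[w_small].bin_signal)
    if matrix.mask is not None:
        hole = ~matrix.mask
        near_hole = np.convolve(hole.astype(int), np.ones(3, dtype=int),
                                mode="same") > 0
        clean_anchors = anchors[~near_hole[anchors]]
        if clean_anchors.size:
            anchors = clean_anchors
    candidates = {
        w: _snap_to_anchors(c, anchors, radius=profiles[w].window_bins // 2,
                            score=profiles[w].score)
        for w, c in candidates.items()
    }

    # filters evaluated at the final (snapped) positions
    candidates = {
        w: c[np.isfinite(profiles[w].score[c])
             & (profiles[w].score[c] <= threshold)]
        for w, c in candidates.items()
    }
    if filter_alpha is not None:
        from .compartments import observed_over_expected

        oe = observed_over_expected(matrix, clip_quantile=None)
        candidates = {
            w: depletion_filter(c, oe, profiles[w].window_bins, filter_alpha)
            for w, c in candidates.items()
        }
    return merge_windows(profiles, candidates=candidates,
                         threshold=threshold, mode=mode)


def harmonize_genotypes(boundary_sets: dict[str, BoundarySet],
                        proximity_bp: int = 2000) -> pd.DataFrame:
    """Cross-genotype consensus boundary table.

    Boundaries pooled over genotypes are chained into groups (successive
    positions within ``proximity_bp``); each group is replaced by the single
    position minimizing the global insulation score — the sum, over the
    genotypes that called a boundary in the group, of that genotype's
    mean-window score at the candidate position (ties -> leftmost).  Each
    such genotype is marked present at the consensus position with its own
    score re-read there.

    Returns a DataFrame with columns ``position`` (bin index) plus
    ``{genotype}_present`` and ``{genotype}_score``.
    """
    if not boundary_sets:
        raise ValueError("no boundary sets given")
    genotypes = list(boundary_sets)
    bin_size = boundary_sets[genotypes[0]].bin_size
    for bset in boundary_sets.values():
        if bset.bin_size != bin_size:
            raise ValueError("all sets must share the bin size")

    pooled = sorted({(int(p), g) for g, bset in boundary_sets.items()
                     for p in bset.positions})
    prox_bins = max(1, proximity_bp // bin_size + 1)  # interval-gap proximity

    rows = []
    group: list[tuple[int, str]] = []

    def _flush(group):
        if not group:
            return
        g_pos = sorted({p for p, _ in group})
        g_geno = sorted({g for _, g in group}, key=genotypes.index)
        best_pos, best_global = None, np.inf
        for p in g_pos:  # ascending -> leftmost wins ties
            vals = [boundary_sets[g].mean_profile[p] for g in g_geno]
            glob = float(np.nansum(vals))
            if glob < best_global:
                best_global, best_pos = glob, p
        row = {"position": best_pos}
        for g in genotypes:
            present = g in g_geno
            row[f"{g}_present"] = present
            row[f"{g}_score"] = (float(boundary_sets[g].mean_profile[best_pos])
                                 if present else np.nan)
        rows.append(row)

    for item in pooled + [None]:
        if item is not None and (not group or item[0] - group[-1][0] <= prox_bins):
            group.append(item)
            continue
        _flush(group)
        group = [item] if item is not None else []
    _flush(group)

    cols = ["position"] + [f"{g}_{k}" for g in genotypes for k in ("present", "score")]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("position", ignore_index=True)


def classify_boundaries(consensus: pd.DataFrame, wt: str, mutant: str,
                        delta_cutoff: float = DELTA_WEAKER_CUTOFF) -> pd.DataFrame:
    """Label every WT-present consensus boundary as lost / weaker / intact.

    lost: absent in the mutant; otherwise delta = mutant score - WT score,
    weaker if delta >= ``delta_cutoff`` and intact if delta < ``delta_cutoff``
    (reinforced boundaries count as intact).  Boundaries absent in WT are
    excluded; their count is attached as ``result.attrs['n_excluded']``.
    """
    for g in (wt, mutant):
        if f"{g}_present" not in consensus.columns:
            raise ValueError(f"genotype {g!r} missing from consensus table")
    wt_present = consensus[f"{wt}_present"].to_numpy(bool)
    excluded = int((~wt_present).sum())
    sub = consensus[wt_present].copy()

    mut_present = sub[f"{mutant}_present"].to_numpy(bool)
    delta = sub[f"{mutant}_score"].to_numpy() - sub[f"{wt}_score"].to_numpy()
    label = np.where(~mut_present, "lost",
                     np.where(delta >= delta_cutoff, "weaker", "intact"))
    out = pd.DataFrame({
        "position": sub["position"].to_numpy(),
        "wt_score": sub[f"{wt}_score"].to_numpy(),
        "mutant_score": sub[f"{mutant}_score"].to_numpy(),
        "delta": np.where(mut_present, delta, np.nan),
        "label": label,
    })
    out.attrs["n_excluded"] = excluded
    return out


def delta_insulation(wt_profile: np.ndarray,
                     mutant_profile: np.ndarray) -> np.ndarray:
    """Per-bin differential track: mutant mean-window score minus WT;
    undefined values propagate."""
    wt_profile = np.asarray(wt_profile, dtype=float)
    mutant_profile = np.asarray(mutant_profile, dtype=float)
    if wt_profile.shape != mutant_profile.shape:
        raise ValueError("profiles must share the bin grid")
    return mutant_profile - wt_profile
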