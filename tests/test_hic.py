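"""Pair processing, binning, masking, balancing and QC contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boundarykit import (split_fusion_read, filter_pairs, bin_pairs,
                         mask_low_coverage, ice_balance, ice_normalize,
                         downsample_pairs, replicate_correlation,
                         SyntheticConfig, plant_truth, simulate_matrix)
from boundarykit.hic import ContactMatrix, FUSION_PATTERNS

from conftest import random_symmetric_matrix


def make_pair(pos1, pos2, strand1="+", strand2="+", chrom="chr2L",
              unique=True, mismatches=0, indel=False, read_id="r"):
    return {
        "read_id": read_id,
        "chrom1": chrom, "pos1": pos1, "strand1": strand1, "frag1": 0,
        "chrom2": chrom, "pos2": pos2, "strand2": strand2, "frag2": 0,
        "unique1": unique, "unique2": True,
        "mismatches1": mismatches, "mismatches2": 0,
        "indel1": indel, "indel2": False,
        "truth": "ok",
    }


class TestSplitFusionRead:
    def test_long_read_without_junction_trimmed_to_60(self):
        read = "A" * 80
        assert split_fusion_read(read) == ["A" * 60]

    def test_single_junction_split_at_midpoint(self):
        read = "AAAA" + "GTATAC" + "TTTT"
        assert split_fusion_read(read) == ["AAAAGTA", "TACTTTT"]

    def test_empty_read(self):
        assert split_fusion_read("") == []

    @pytest.mark.parametrize("pattern", FUSION_PATTERNS)
    def test_each_pattern_splits(self, pattern):
        sub = split_fusion_read("CCCC" + pattern + "GGGG")
        assert len(sub) == 2
        assert sub[0] == "CCCC" + pattern[:3]
        assert sub[1] == pattern[3:] + "GGGG"

    def test_planted_junction_oracle(self):
        # 1000 random junction-free reads with k planted junctions give
        # 1000 + k sub-reads in total
        rng = np.random.default_rng(0)
        total_subreads = 0
        total_planted = 0
        for _ in range(1000):
            while True:
                segs = ["".join(rng.choice(list("ACG"), size=rng.integers(8, 20)))
                        for _ in range(rng.integers(1, 4))]
                k = len(segs) - 1
                read = segs[0]
                for s in segs[1:]:
                    read += str(rng.choice(FUSION_PATTERNS)) + s
                # junction-free segments over {A,C,G} cannot create patterns
                # (all patterns contain T), but flanks could; re-check
                n_hits = sum(read.count(p) for p in FUSION_PATTERNS)
                if n_hits == k:
                    break
            total_subreads += len(split_fusion_read(read))
            total_planted += k
        assert total_subreads == 1000 + total_planted

    def test_max_length_enforced(self):
        read = "A" * 100 + "GTATAC" + "C" * 100
        for sub in split_fusion_read(read):
            assert len(sub) <= 60


class TestFilterPairs:
    def test_twelve_record_fixture_keeps_seven(self):
        rows = [make_pair(1000 + 5000 * k, 50_000 + 5000 * k,
                          read_id=f"good{k}") for k in range(7)]
        rows.append(make_pair(1000, 50_000, read_id="dup1"))       # dup of good0
        rows.append(make_pair(6000, 55_000, read_id="dup2"))       # dup of good1
        rows.append(make_pair(100, 200, unique=False, read_id="multi"))
        rows.append(make_pair(100, 200, mismatches=3, read_id="mm"))
        rows.append(make_pair(10_000, 11_500, strand2="-", read_id="close"))
        kept, rejected = filter_pairs(pd.DataFrame(rows))
        assert len(kept) == 7
        counts = rejected["reason"].value_counts().to_dict()
        assert counts == {"iv:duplicate": 2, "i:non_unique": 1,
                          "ii:indel_or_mismatch": 1, "iii:close_opposite": 1}

    def test_opposite_strand_within_2kb_rejected(self):
        kept, rejected = filter_pairs(pd.DataFrame(
            [make_pair(10_000, 11_500, strand2="-")]))
        assert len(kept) == 0
        assert rejected["reason"].iloc[0] == "iii:close_opposite"

    def test_opposite_strand_beyond_2kb_kept(self):
        kept, _ = filter_pairs(pd.DataFrame(
            [make_pair(10_000, 12_500, strand2="-")]))
        assert len(kept) == 1

    def test_empty_stream(self):
        empty = pd.DataFrame(columns=list(make_pair(0, 0).keys()))
        kept, rejected = filter_pairs(empty)
        assert len(kept) == 0 and len(rejected) == 0

    def test_first_matching_rule_wins(self):
        # non-unique AND high-mismatch -> tagged with rule (i)
        row = make_pair(0, 10_000, unique=False, mismatches=5)
        _, rejected = filter_pairs(pd.DataFrame([row]))
        assert rejected["reason"].iloc[0] == "i:non_unique"

    def test_completeness_partition(self):
        rng = np.random.default_rng(1)
        rows = [make_pair(int(rng.integers(0, 90_000)),
                          int(rng.integers(0, 90_000)),
                          strand2=rng.choice(["+", "-"]),
                          unique=bool(rng.random() > 0.1),
                          mismatches=int(rng.integers(0, 4)),
                          read_id=f"r{k}")
                for k in range(300)]
        df = pd.DataFrame(rows)
        kept, rejected = filter_pairs(df)
        assert len(kept) + len(rejected) == len(df)
        assert set(kept["read_id"]) | set(rejected["read_id"]) == set(df["read_id"])


class TestBinPairs:
    def test_simple_binning(self):
        df = pd.DataFrame([make_pair(1000, 5000)])
        mat = bin_pairs(df, 2000, 20_000, "chr2L")
        assert mat.counts[0, 2] == 1 and mat.counts[2, 0] == 1

    def test_diagonal_counted_once(self):
        df = pd.DataFrame([make_pair(8100, 8900)])
        mat = bin_pairs(df, 2000, 20_000, "chr2L")
        assert mat.counts[4, 4] == 1
        assert np.triu(mat.counts).sum() == 1

    def test_conservation(self):
        cfg = SyntheticConfig(arm_length=200_000, n_boundaries=2,
                              sequencing_depth=10_000, seed=4)
        from boundarykit import simulate_pairs
        pairs = simulate_pairs(plant_truth(cfg), cfg)
        kept, _ = filter_pairs(pairs)
        mat = bin_pairs(kept, cfg.bin_size, cfg.arm_length, cfg.chrom)
        assert np.triu(mat.counts).sum() == len(kept)

    def test_out_of_range_raises(self):
        df = pd.DataFrame([make_pair(1000, 25_000)])
        with pytest.raises(ValueError, match="beyond arm"):
            bin_pairs(df, 2000, 20_000, "chr2L")

    def test_trans_pairs_dropped_with_counter(self):
        rows = [make_pair(1000, 5000), make_pair(1000, 5000)]
        rows[1]["chrom2"] = "chr3R"
        mat = bin_pairs(pd.DataFrame(rows), 2000, 20_000, "chr2L")
        assert mat.n_trans_dropped == 1
        assert np.triu(mat.counts).sum() == 1


class TestMaskLowCoverage:
    def test_quoted_rule_arithmetic(self):
        # 20 bins: one zero-marginal, one weakest nonzero; ceil(0.05*19)=1
        n = 20
        counts = np.zeros((n, n))
        for k in range(2, n):
            counts[k, k] = 10
        counts[1, 1] = 1
        mat = ContactMatrix(chrom="c", bin_size=2000, counts=counts)
        mask = mask_low_coverage(mat)
        assert not mask[0] and not mask[1]
        assert mask[2:].all()

    def test_equal_marginals_lowest_index_masked(self):
        n = 40
        mat = ContactMatrix(chrom="c", bin_size=2000, counts=np.ones((n, n)))
        mask = mask_low_coverage(mat)
        k = int(np.ceil(0.05 * n))
        assert (~mask[:k]).all() and mask[k:].all()

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 30
            counts = random_symmetric_matrix(n, rng, 0, 3)
            counts[rng.random(n) < 0.2, :] = 0
            counts = np.minimum(counts, counts.T)
            mat = ContactMatrix(chrom="c", bin_size=2000, counts=counts)
            mask = mask_low_coverage(mat)
            marg = counts.sum(0)
            nonzero = np.flatnonzero(marg > 0)
            k = int(np.ceil(0.05 * nonzero.size)) if nonzero.size else 0
            order = sorted(nonzero, key=lambda i: (marg[i], i))
            expected_invalid = set(np.flatnonzero(marg == 0)) | set(order[:k])
            assert set(np.flatnonzero(~mask)) == expected_invalid


def sinkhorn_oracle(m, tol=1e-13, iters=200_000):
    """Alternating row/column normalization (independent of ice_balance)."""
    x = m.astype(float).copy()
    for _ in range(iters):
        r = x.sum(axis=1, keepdims=True)
        x = x / r
        c = x.sum(axis=0, keepdims=True)
        x = x / c
        if np.abs(x.sum(axis=1) - 1).max() < tol:
            break
    return x


class TestIce:
    def test_balanced_fixed_point(self):
        n = 30
        mat = np.ones((n, n))
        valid = np.ones(n, bool)
        out = ice_balance(mat, valid)
        marg = out.sum(axis=1)
        assert np.nanstd(marg) / np.nanmean(marg) < 1e-6
        assert np.allclose(out, out[0, 0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        m = random_symmetric_matrix(40, rng)
        valid = np.ones(40, bool)
        a = ice_balance(m, valid)
        b = ice_balance(7.0 * m, valid)
        assert np.allclose(a, b, atol=1e-9)

    def test_marginals_equal_and_match_sinkhorn(self):
        rng = np.random.default_rng(4)
        m = random_symmetric_matrix(50, rng)
        valid = np.ones(50, bool)
        out = ice_balance(m, valid, tol=1e-12, max_iter=100_000)
        marg = out.sum(axis=1)
        assert np.std(marg) / np.mean(marg) < 1e-6
        oracle = sinkhorn_oracle(m)
        # same balanced matrix up to the symmetric normalization scale
        ratio = out / oracle
        assert np.nanmax(np.abs(ratio - ratio[0, 0])) < 1e-8

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        m = random_symmetric_matrix(40, rng)
        valid = np.ones(40, bool)
        once = ice_balance(m, valid, tol=1e-10, max_iter=10_000)
        twice = ice_balance(once, valid, tol=1e-10, max_iter=10_000)
        assert np.nanmax(np.abs(twice - once)) < 1e-9

    def test_masked_bins_nan(self, balanced_matrix):
        norm = balanced_matrix.normalized
        invalid = ~balanced_matrix.mask
        assert np.isnan(norm[invalid, :]).all()
        assert np.isnan(norm[:, invalid]).all()

    def test_too_few_valid_bins_raises(self):
        with pytest.raises(ValueError):
            ice_balance(np.ones((5, 5)), np.array([True] + [False] * 4))


class TestDownsample:
    def test_full_sample_identity(self):
        df = pd.DataFrame([make_pair(k, k + 5000, read_id=f"r{k}")
                           for k in range(10)])
        out = downsample_pairs(df, 10, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_empty_sample(self):
        df = pd.DataFrame([make_pair(0, 5000)])
        assert len(downsample_pairs(df, 0, seed=1)) == 0

    def test_deterministic(self):
        df = pd.DataFrame([make_pair(k, k + 5000, read_id=f"r{k}")
                           for k in range(100)])
        a = downsample_pairs(df, 30, seed=9)
        b = downsample_pairs(df, 30, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_oversample_raises(self):
        df = pd.DataFrame([make_pair(0, 5000)])
        with pytest.raises(ValueError):
            downsample_pairs(df, 2, seed=1)


class TestReplicateCorrelation:
    def _two_replicates(self, seed_a, seed_b, depth=300_000):
        cfg_a = SyntheticConfig(arm_length=500_000, n_boundaries=5,
                                sequencing_depth=depth, seed=seed_a)
        truth = plant_truth(cfg_a)
        mat_a = ice_normalize(simulate_matrix(truth, cfg_a))
        from dataclasses import replace
        cfg_b = replace(cfg_a, seed=seed_b)
        # same truth, same biases (seed enters only the Poisson draw stream)
        import boundarykit.synthetic as syn
        counts_b = syn._sample_counts(truth, cfg_a, np.random.default_rng([seed_b, 2]))
        mat_b = ice_normalize(ContactMatrix(chrom=cfg_a.chrom,
                                            bin_size=cfg_a.bin_size,
                                            counts=counts_b.astype(float)))
        return mat_a, mat_b

    def test_self_correlation_is_one(self, balanced_matrix):
        r = replicate_correlation(balanced_matrix, balanced_matrix)
        assert r == pytest.approx(1.0)

    def test_matches_flatten_oracle(self):
        mat_a, mat_b = self._two_replicates(1, 2)
        r = replicate_correlation(mat_a, mat_b)
        valid = mat_a.mask & mat_b.mask
        vals_a, vals_b = [], []
        n = mat_a.n_bins
        for i in range(n):
            for j in range(i + 1, n):
                if (j - i) * mat_a.bin_size < 1_000_000 and valid[i] and valid[j]:
                    a, b = mat_a.normalized[i, j], mat_b.normalized[i, j]
                    if np.isfinite(a) and np.isfinite(b):
                        vals_a.append(a)
                        vals_b.append(b)
        oracle = stats.pearsonr(vals_a, vals_b)[0]
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r > 0.5  # replicates of one expectation correlate strongly
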