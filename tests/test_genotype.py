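"""Bin-genotyper checks: aa x bb selection, depth floor, window typing,
bin merging, segregation tests and line/bin filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rilmap.genotype import (
    AA, AB, BB, MISSING,
    GenotyperParams, SNPCallSet,
    apply_depth_filter, call_line_genotypes, chisq_pvalue, filter_bins,
    filter_lines, merge_into_bins, segregation_chisq, select_aaxbb,
    type_window,
)
from rilmap.simulate import SimConfig, breed_ril_population, observe_genotypes


def make_callset(calls, p1=None, p2=None, depths=None, chrom=None, pos=None, recoded=False):
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    snps = pd.DataFrame(
        {
            "chrom": np.zeros(n_snps, int) if chrom is None else chrom,
            "pos": np.arange(1, n_snps + 1) * 1000 if pos is None else pos,
            "p1": np.full(n_snps, AA, np.int8) if p1 is None else np.asarray(p1, np.int8),
            "p2": np.full(n_snps, BB, np.int8) if p2 is None else np.asarray(p2, np.int8),
        }
    )
    return SNPCallSet(
        snps=snps,
        calls=calls,
        depths=None if depths is None else np.asarray(depths),
        line_ids=[f"L{i}" for i in range(n_lines)],
        recoded=recoded,
    )


class TestSelectAaxBb:
    def test_parental_patterns(self):
        # columns: aa x bb kept, het parent dropped, monomorphic dropped,
        # missing parent dropped, bb x aa kept with recoding
        cs = make_callset(
            calls=[[AA, AA, AA, AA, AA], [BB, BB, BB, BB, BB]],
            p1=[AA, AB, AA, MISSING, BB],
            p2=[BB, BB, AA, BB, AA],
        )
        out, report = select_aaxbb(cs)
        assert out.n_snps == 2
        assert sorted(report.removals["reason"]) == ["monomorphic", "parent_het", "parent_missing"]
        # first kept SNP unchanged; second (bb x aa) flipped onto parent-1 basis
        assert list(out.calls[:, 0]) == [AA, BB]
        assert list(out.calls[:, 1]) == [BB, AA]
        assert out.recoded

    def test_het_and_missing_calls_survive_recoding(self):
        cs = make_callset(calls=[[AB, MISSING]], p1=[BB, BB], p2=[AA, AA])
        out, _ = select_aaxbb(cs)
        assert list(out.calls[0]) == [AB, MISSING]


class TestDepthFilter:
    def test_boundary_at_min_depth(self):
        cs = make_callset(
            calls=[[AA, AA], [BB, BB]],
            depths=[[3, 4], [4, 3]],
        )
        out, _ = apply_depth_filter(cs, 4)
        assert out.calls[0, 0] == MISSING and out.calls[0, 1] == AA
        assert out.calls[1, 0] == BB and out.calls[1, 1] == MISSING

    def test_zero_floor_is_identity(self):
        cs = make_callset(calls=[[AA, BB]], depths=[[1, 1]])
        out, rep = apply_depth_filter(cs, 0)
        assert np.array_equal(out.calls, cs.calls) and rep.n_removed == 0

    def test_all_missing_snps_dropped(self):
        cs = make_callset(calls=[[AA, AA]], depths=[[2, 9]])
        out, rep = apply_depth_filter(cs, 4)
        assert out.n_snps == 1 and rep.n_removed == 1


class TestWindowTyping:
    def test_exhaustive_truth_table(self):
        # every feasible (aa, bb) composition of a 15-SNP window
        for aa in range(16):
            for bb in range(16 - aa):
                expected = AA if aa > 11 else (BB if bb > 11 else AB)
                assert type_window(aa, bb) == expected

    def test_smoothing_against_brute_force(self, rng):
        params = GenotyperParams()
        calls = rng.choice([AA, AB, BB, MISSING], size=(4, 40), p=[0.45, 0.05, 0.45, 0.05])
        cs = make_callset(calls, recoded=True)
        got = call_line_genotypes(cs, params)
        w, thr, half = params.window_size, params.window_threshold, params.window_size // 2
        for i in range(4):
            window_types = [
                type_window(
                    int(np.sum(calls[i, j : j + w] == AA)),
                    int(np.sum(calls[i, j : j + w] == BB)),
                    thr,
                )
                for j in range(40 - w + 1)
            ]
            for s in range(40):
                j = min(max(s - half, 0), len(window_types) - 1)
                assert got[i, s] == window_types[j], (i, s)

    def test_short_chromosome_is_single_window(self):
        calls = np.full((1, 5), AA, dtype=np.int8)
        cs = make_callset(calls, recoded=True)
        got = call_line_genotypes(cs, GenotyperParams(window_size=15, window_threshold=11))
        # 5 aa in the only window is not > 11, so everything types ab
        assert np.all(got == AB)

    def test_high_error_tolerance_on_simulated_data(self):
        # dense SNPs, 1% per-read error, depth 10: >=99% of smoothed calls
        # match the truth (the window absorbs isolated miscalls)
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=[100.0],
                       chrom_lengths_bp=[20_000_000], n_snps_per_chrom=2000,
                       n_lines=50, seed=31)
        pop = breed_ril_population(cfg)
        callset, _ = observe_genotypes(pop, 10.0, 0.01, 0.0, np.random.default_rng(32))
        recoded, _ = select_aaxbb(callset)
        smoothed = call_line_genotypes(recoded, GenotyperParams())
        agree = np.mean(smoothed == pop.genotypes)
        assert agree >= 0.99


class TestMergeIntoBins:
    def test_identical_vectors_merge_to_one_bin(self):
        cs = make_callset(np.tile([[AA], [BB]], (1, 4)), recoded=True)
        assert len(merge_into_bins(cs)) == 1

    def test_single_switch_splits_runs(self):
        calls = np.array([[AA, AA, BB, BB], [AA, AA, AA, AA]], dtype=np.int8)
        bins = merge_into_bins(make_callset(calls, recoded=True))
        assert len(bins) == 2
        assert bins.bins[0].start_bp == 1000 and bins.bins[0].end_bp == 2000

    def test_all_distinct_vectors_keep_all_snps(self):
        calls = np.array([[AA, AB, BB]], dtype=np.int8)
        assert len(merge_into_bins(make_callset(calls, recoded=True))) == 3

    def test_matches_run_enumeration_oracle(self, rng):
        calls = rng.choice([AA, BB], size=(6, 80)).astype(np.int8)
        chrom = np.repeat([0, 1], 40)
        pos = np.concatenate([np.arange(1, 41), np.arange(1, 41)]) * 500
        cs = make_callset(calls, chrom=chrom, pos=pos, recoded=True)
        got = len(merge_into_bins(cs))
        expected = 0
        for c in (0, 1):
            idx = np.flatnonzero(chrom == c)
            expected += 1 + sum(
                1
                for k in range(1, len(idx))
                if not np.array_equal(calls[:, idx[k]], calls[:, idx[k - 1]])
            )
        assert got == expected

    def test_idempotent_on_bin_vectors(self, rng):
        calls = rng.choice([AA, BB], size=(5, 60)).astype(np.int8)
        cs = make_callset(calls, recoded=True)
        bins = merge_into_bins(cs)
        rebinned = make_callset(
            bins.matrix(),
            pos=[b.start_bp for b in bins.bins],
            chrom=[b.chromosome for b in bins.bins],
            recoded=True,
        )
        assert len(merge_into_bins(rebinned)) == len(bins)


class TestSegregation:
    def test_balanced_counts(self):
        chi2, p = segregation_chisq(50, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_paper_scale_chi_square_p_value(self):
        assert chisq_pvalue(0.0548) == pytest.approx(0.8149, abs=5e-5)

    def test_distorted_counts_flagged(self):
        chi2, p = segregation_chisq(120, 55)
        assert chi2 == pytest.approx(65**2 / 175)
        assert p < 0.01

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            segregation_chisq(0, 0)


class TestFilterBins:
    def _binset(self, spans_and_counts, n_lines=175):
        calls_cols = []
        pos = []
        chrom = []
        for k, (span, (n_aa, n_bb)) in enumerate(spans_and_counts):
            vec = np.array(
                [AA] * n_aa + [BB] * n_bb + [MISSING] * (n_lines - n_aa - n_bb),
                dtype=np.int8,
            )
            calls_cols += [vec, vec.copy()]
            pos += [1, span]                 # inclusive span = end - start + 1
            chrom += [k, k]                  # each bin on its own chromosome
        calls = np.stack(calls_cols, axis=1)
        cs = make_callset(calls, chrom=np.array(chrom), pos=np.array(pos), recoded=True)
        return merge_into_bins(cs)

    def test_length_and_distortion_rules(self):
        binset = self._binset(
            [
                (8_000, (50, 50)),      # too short
                (10_001, (50, 50)),     # boundary: kept ("longer than" 10 kb)
                (20_000, (120, 55)),    # distorted (p < 0.01)
            ]
        )
        out, report = filter_bins(binset, GenotyperParams())
        assert len(out) == 1 and out.bins[0].span_bp == 10_001
        assert sorted(report.removals["reason"]) == ["segregation_distortion", "too_short"]
        assert report.n_in == report.n_kept + report.n_removed


class TestFilterLines:
    def test_threshold_rule(self):
        n = 200
        clean = np.full(n, AA, np.int8)
        dirty = clean.copy()
        dirty[:6] = AB  # 3% heterozygous
        cs = make_callset(np.stack([clean, dirty]).reshape(2, n), recoded=True)
        out, report = filter_lines(cs, 0.02)
        assert out.line_ids == ["L0"]
        assert list(report.removals["line_id"]) == ["L1"]

    def test_simulated_contamination_always_removed(self):
        """All 15 contaminated lines of a 190-line population are dropped;
        lines in the natural residual-heterozygosity tail go with them."""
        cfg = SimConfig(n_chromosomes=2, chrom_lengths_cM=[80.0] * 2,
                       chrom_lengths_bp=[15_000_000] * 2, n_snps_per_chrom=500,
                       n_lines=190, seed=41)
        pop = breed_ril_population(cfg)
        callset, contaminated = observe_genotypes(
            pop, 20.0, 0.001, 0.01, np.random.default_rng(42),
            contaminated_line_fraction=15 / 190, contamination_het_rate=0.05,
        )
        recoded, _ = select_aaxbb(callset)
        out, report = filter_lines(recoded, 0.02)
        kept = set(out.line_ids)
        assert len(contaminated) == 15
        assert all(pop.line_ids[i] not in kept for i in contaminated)
        assert out.n_lines <= 175
        # the dropped set beyond the contaminated lines is the het tail
        extra = set(report.removals["line_id"]) - {pop.line_ids[i] for i in contaminated}
        het_frac = (recoded.calls == AB).sum(axis=1) / (recoded.calls != MISSING).sum(axis=1)
        assert all(het_frac[pop.line_ids.index(l)] > 0.02 for l in extra)

    def test_all_lines_dropped_is_an_error(self):
        cs = make_callset(np.full((2, 50), AB, np.int8), recoded=True)
        with pytest.raises(ValueError):
            filter_lines(cs, 0.02)


class TestBreakpointRecovery:
    def test_noiseless_bins_match_true_crossovers(self, noiseless_pop):
        """On error-free calls, raw-run merging reproduces every
        marker-visible crossover and nothing else."""
        pop = noiseless_pop
        cs, _ = observe_genotypes(pop, 30.0, 0.0, 0.0, np.random.default_rng(51))
        recoded, _ = select_aaxbb(cs)
        bins = merge_into_bins(recoded)
        chrom_arr = pop.markers["chrom"].to_numpy()
        cm = pop.markers["cM"].to_numpy()
        bp = pop.markers["pos_bp"].to_numpy()
        for c in range(3):
            idx = np.flatnonzero(chrom_arr == c)
            sub = [b for b in bins.bins if b.chromosome == c]
            # bin boundaries: gaps between consecutive bins in bp
            bounds = {(sub[k].end_bp, sub[k + 1].start_bp) for k in range(len(sub) - 1)}
            # oracle: for each line, a boundary between adjacent markers
            # exists iff the true genotype (from the mosaics) changes there
            expected = set()
            for line in range(pop.n_lines):
                g = pop.genotypes[line, idx]
                for k in np.flatnonzero(g[1:] != g[:-1]):
                    expected.add((int(bp[idx[k]]), int(bp[idx[k + 1]])))
            assert bounds == expected
            # and each boundary interval contains a true crossover (cM)
            for k in range(len(idx) - 1):
                if (int(bp[idx[k]]), int(bp[idx[k + 1]])) in bounds:
                    lo, hi = cm[idx[k]], cm[idx[k + 1]]
                    assert any(
                        np.any((pop.breakpoints(line, c) > lo) & (pop.breakpoints(line, c) <= hi))
                        for line in range(pop.n_lines)
                    )


@settings(max_examples=30, deadline=None)
@given(
    aa=st.integers(min_value=0, max_value=15),
    bb=st.integers(min_value=0, max_value=15),
    thr=st.integers(min_value=1, max_value=14),
)
def test_window_typing_never_emits_both_homozygotes(aa, bb, thr):
    if aa + bb > 15:
        aa, bb = aa % 8, bb % 8
    t = type_window(aa, bb, thr)
    assert t in (AA, AB, BB)
    if t == AA:
        assert aa > thr
    if t == BB:
        assert bb > thr
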