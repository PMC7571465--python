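"""ICIM scanner checks: stepwise cofactor selection, phenotype adjustment,
the EM interval scan, permutation thresholds and QTL calling."""

import numpy as np
import pytest

from rilmap.qtl import (
    MapData, ScanParams,
    adjust_phenotype, call_qtl, code_markers, compute_pve, interval_scan,
    permutation_threshold, scan_trait, stepwise_select,
)
from rilmap.simulate import (
    QTLSpec, SimConfig, breed_ril_population, simulate_phenotypes,
    truth_bins_and_map,
)


def _population(n_chrom=3, n_snps=30, n_lines=175, seed=71, qtl=None, length=90.0):
    cfg = SimConfig(
        n_chromosomes=n_chrom,
        chrom_lengths_cM=[length] * n_chrom,
        chrom_lengths_bp=[20_000_000] * n_chrom,
        n_snps_per_chrom=n_snps,
        n_lines=n_lines,
        qtl_specs=qtl or [],
        seed=seed,
    )
    return breed_ril_population(cfg)


@pytest.fixture(scope="module")
def qtl40():
    """One QTL at 43 cM on the second chromosome, target PVE 40%."""
    spec = QTLSpec(1, 43.0, 1.0, 40.0, "R")
    pop = _population(qtl=[spec], seed=72)
    pheno = simulate_phenotypes(pop, [spec], np.random.default_rng(73))
    binset, gmap = truth_bins_and_map(pop)
    return pop, MapData.from_binset(gmap, binset), pheno["R"].to_numpy(), spec


class TestScanParams:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(pin=0.5, pout=0.1)
        with pytest.raises(ValueError):
            ScanParams(step_cM=0.0)
        with pytest.raises(ValueError):
            ScanParams(n_permutations=10)

    def test_pout_defaults_to_twice_pin(self):
        assert ScanParams(pin=0.004).pout == pytest.approx(0.008)


class TestStepwise:
    def test_phenotype_equal_to_marker_coding(self, qtl40):
        _, md, _, _ = qtl40
        y = md.coded[:, 17].copy()
        sel, coefs = stepwise_select(md.coded, y)
        assert 17 in sel
        resid = y - md.coded[:, sel] @ coefs - (y - md.coded[:, sel] @ coefs).mean()
        assert float(resid @ resid) == pytest.approx(0.0, abs=1e-16)

    def test_null_phenotype_selects_almost_nothing(self, qtl40):
        _, md, _, _ = qtl40
        picked = []
        rng = np.random.default_rng(74)
        for _ in range(10):
            sel, _ = stepwise_select(md.coded, rng.normal(size=md.coded.shape[0]))
            picked.append(len(sel))
        assert np.mean(picked) <= 2

    def test_qtl_neighbourhood_selected(self, qtl40):
        pop, md, y, spec = qtl40
        sel, _ = stepwise_select(md.coded, y)
        lg = md.gmap.groups[spec.chromosome]
        offset = md.lg_slices[lg.id].start
        qpos = spec.position_cM - (pop.markers[pop.markers["chrom"] == 1]["cM"].iloc[0])
        dists = np.abs(lg.positions_cM - qpos)
        near = {offset + k for k in np.argsort(dists)[:3]}
        assert near & set(sel)

    def test_zero_variance_phenotype_is_an_error(self, qtl40):
        _, md, _, _ = qtl40
        with pytest.raises(ValueError):
            stepwise_select(md.coded, np.ones(md.coded.shape[0]))


class TestAdjustment:
    def test_no_cofactors_is_identity(self):
        y = np.arange(5.0)
        X = np.ones((5, 3))
        assert np.array_equal(adjust_phenotype(y, X, [], np.array([]), set()), y)

    def test_released_cofactor_leaves_phenotype_whole(self):
        y = np.arange(5.0)
        X = np.column_stack([np.array([1, -1, 1, -1, 1.0]), np.zeros(5)])
        out = adjust_phenotype(y, X, [0], np.array([2.0]), released={0})
        assert np.array_equal(out, y)

    def test_distant_cofactor_subtracted_by_hand(self):
        # five-line toy: y_adj = y - b*x checked against direct arithmetic
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        x = np.array([1.0, -1.0, 1.0, 1.0, -1.0])
        X = x[:, None]
        out = adjust_phenotype(y, X, [0], np.array([0.7]), released=set())
        assert np.allclose(out, [3 - 0.7, 1 + 0.7, 4 - 0.7, 1 - 0.7, 5 + 0.7])


class TestIntervalScan:
    def test_noise_free_marker_phenotype_peaks_at_marker(self, qtl40):
        _, md, _, _ = qtl40
        y = md.coded[:, 40].astype(float)  # exactly a marker's coding
        params = ScanParams(step_cM=0.5, n_permutations=100)
        profile, _ = interval_scan(md, y[None, :], params)
        lg = md.gmap.groups[1]
        marker_cm = lg.positions_cM[40 - md.lg_slices[lg.id].start]
        peak = profile.iloc[int(profile["lod"].idxmax())]
        assert peak["lod"] >= 10
        assert peak["lg"] == lg.id
        assert abs(peak["cM"] - marker_cm) <= params.step_cM

    def test_marker_coincident_lod_equals_regression(self):
        # fully informative genotypes: the mixture collapses to the
        # two-class regression, so the LODs must agree to 1e-6
        pop = _population(n_chrom=1, n_snps=10, n_lines=120, seed=75)
        binset, gmap = truth_bins_and_map(pop)
        md = MapData.from_binset(gmap, binset)
        keep = np.all(np.isin(md.genotypes, (0, 2)), axis=1)
        md2 = MapData.from_binset(gmap, binset)
        md2.genotypes = md.genotypes[keep]
        md2.coded = code_markers(md2.genotypes)
        rng = np.random.default_rng(76)
        y = md2.coded[:, 4] * 0.8 + rng.normal(0, 1.0, size=md2.coded.shape[0])
        params = ScanParams(step_cM=0.1, n_permutations=100)
        profile, _ = interval_scan(md2, y[None, :], params)
        pos = gmap.groups[0].positions_cM[4]
        row = profile.iloc[(profile["cM"] - pos).abs().idxmin()]
        x = md2.coded[:, 4]
        n = len(y)
        rss1 = np.sum((y - np.poly1d(np.polyfit(x, y, 1))(x)) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        reg_lod = n / 2 * np.log10(rss0 / rss1)
        assert row["lod"] == pytest.approx(reg_lod, abs=1e-6)

    def test_lod_invariant_under_shift_and_scale(self, qtl40):
        _, md, y, _ = qtl40
        params = ScanParams(step_cM=2.0, n_permutations=100)
        p1, _ = interval_scan(md, y[None, :], params)
        p2, _ = interval_scan(md, (5.0 + 3.0 * y)[None, :], params)
        assert np.allclose(p1["lod"], p2["lod"], atol=1e-6)
        assert np.allclose(p2["additive"], 3.0 * p1["additive"], atol=1e-6)

    def test_lod_nonnegative_everywhere(self, qtl40):
        _, md, y, _ = qtl40
        profile, _ = interval_scan(md, y[None, :], ScanParams(step_cM=1.0, n_permutations=100))
        assert (profile["lod"] >= 0).all()


class TestPermutationThreshold:
    def test_deterministic_under_seed(self, qtl40):
        _, md, y, _ = qtl40
        params = ScanParams(step_cM=2.0, n_permutations=100, seed=5)
        t1 = permutation_threshold(md, y, params, np.random.default_rng(5))
        t2 = permutation_threshold(md, y, params, np.random.default_rng(5))
        assert t1 == t2

    def test_alpha_one_gives_minimum(self, qtl40):
        _, md, y, _ = qtl40
        base = ScanParams(step_cM=2.0, n_permutations=100, seed=6)
        loose = ScanParams(step_cM=2.0, n_permutations=100, alpha=1.0, seed=6)
        t_min = permutation_threshold(md, y, loose, np.random.default_rng(6))
        t_05 = permutation_threshold(md, y, base, np.random.default_rng(6))
        assert t_min <= t_05


class TestCallsAndPVE:
    def test_threshold_above_max_gives_empty_result(self, qtl40):
        _, md, y, _ = qtl40
        profile, _ = interval_scan(md, y[None, :], ScanParams(step_cM=1.0, n_permutations=100))
        assert call_qtl(profile, profile["lod"].max() + 1, md) == []

    def test_single_qtl_recovered(self, qtl40):
        pop, md, y, spec = qtl40
        params = ScanParams(step_cM=0.5, n_permutations=200, seed=7)
        profile, threshold, results = _scan(md, y, params)
        assert len(results) == 1
        q = results[0]
        lg = md.gmap.groups[spec.chromosome]
        assert q.lg == lg.id
        cm0 = pop.markers[pop.markers["chrom"] == spec.chromosome]["cM"].iloc[0]
        assert abs(q.peak_cM - (spec.position_cM - cm0)) < 5.0
        assert abs(q.pve - 40.0) <= 10.0
        assert q.lod >= q.threshold
        assert q.ci_lo_cM <= q.peak_cM <= q.ci_hi_cM

    def test_two_qtl_on_distinct_groups(self):
        specs = [QTLSpec(0, 30.0, 1.0, 30.0, "R"), QTLSpec(2, 60.0, 1.0, 30.0, "R")]
        pop = _population(qtl=specs, seed=81)
        pheno = simulate_phenotypes(pop, specs, np.random.default_rng(82))
        binset, gmap = truth_bins_and_map(pop)
        md = MapData.from_binset(gmap, binset)
        params = ScanParams(step_cM=0.5, n_permutations=200, seed=8)
        _, _, results = _scan(md, pheno["R"].to_numpy(), params)
        assert {q.lg for q in results} >= {"LG1", "LG3"}

    def test_pve_of_noise_free_marker_phenotype_is_100(self, qtl40):
        _, md, _, _ = qtl40
        y = md.coded[:, 12].astype(float)
        assert compute_pve(y, float(np.var(y))) == pytest.approx(100.0)

    def test_pve_rejects_zero_variance(self):
        with pytest.raises(ValueError):
            compute_pve(np.ones(5), 0.0)


def _scan(md, y, params):
    """Cofactors + scan + threshold + calls, without rebuilding MapData."""
    sel, coefs = stepwise_select(md.coded, y, params.pin, params.pout)
    profile, _ = interval_scan(
        md, y[None, :], params, cofactors=[(sel, coefs)],
        total_variance=np.array([y.var()]),
    )
    threshold = permutation_threshold(md, y, params, np.random.default_rng(params.seed))
    return profile, threshold, call_qtl(profile, threshold, md, "R")


def test_scan_trait_end_to_end(qtl40):
    pop, md, y, spec = qtl40
    binset, gmap = truth_bins_and_map(pop)
    params = ScanParams(step_cM=1.0, n_permutations=100, seed=9)
    profile, threshold, results = scan_trait(gmap, binset, y, params, "R")
    assert threshold > 0
    assert len(results) >= 1
    assert results[0].trait == "R" and results[0].name == "qR.1"
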