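import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ailqtl import qtl_scan as qs
from ailqtl import synthetic_data as sd
from ailqtl.core_io import GenotypeMatrix


def _matrix_from_codes(codes, positions=None, chrom="1"):
    """Build a GenotypeMatrix from a (markers x individuals) array."""
    codes = np.asarray(codes, dtype=float)
    m, n = codes.shape
    positions = positions or [(k + 1) * 1_000_000 for k in range(m)]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": positions},
        index=pd.Index([f"m{k}" for k in range(m)], name="marker"),
    )
    calls = pd.DataFrame(codes, index=markers.index, columns=[f"i{j}" for j in range(n)])
    return GenotypeMatrix(markers, calls)


def _phenos(values, individuals=None, **extra):
    individuals = individuals or [f"i{j}" for j in range(len(values))]
    return pd.DataFrame({"t": np.asarray(values, dtype=float), **extra}, index=individuals)


class TestInformativeMarkers:
    def test_monomorphic_marker_removed(self):
        g = _matrix_from_codes([[2, 2, 2, 2], [0, 1, 2, 1]])
        kept, log = qs.informative_markers(g)
        assert list(kept.markers.index) == ["m1"]
        assert log.iloc[0]["reason"] == "monomorphic"

    def test_planted_monomorphic_subset_exactly_removed(self, rng):
        codes = rng.integers(0, 3, size=(100, 30)).astype(float)
        mono = rng.choice(100, size=10, replace=False)
        codes[mono] = 2.0
        g = _matrix_from_codes(codes)
        kept, log = qs.informative_markers(g)
        assert set(log["marker"]) == {f"m{k}" for k in mono}
        assert kept.n_markers == 90

    def test_high_missingness_removed_and_all_removed_errors(self):
        codes = np.array([[0, 1, np.nan, np.nan], [2, 2, 2, 2]])
        g = _matrix_from_codes(codes)
        with pytest.raises(ValueError):
            qs.informative_markers(g, max_missing_fraction=0.25)


class TestScreenCovariates:
    def test_self_association_included(self, rng):
        y = rng.normal(size=100)
        ph = _phenos(y, cand=y)
        included, p = qs.screen_covariates(ph, "t", ["cand"])
        assert included == ["cand"]
        assert p["cand"] < 1e-10

    def test_independent_candidate_usually_excluded(self):
        excluded = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            ph = _phenos(r.normal(size=400), cand=r.normal(size=400))
            included, _ = qs.screen_covariates(ph, "t", ["cand"])
            if not included:
                excluded += 1
        assert excluded >= 45

    def test_constant_candidate_excluded_with_warning(self, caplog):
        ph = _phenos([1.0, 2.0, 3.0, 4.0], cand=[1, 1, 1, 1])
        with caplog.at_level("WARNING"):
            included, p = qs.screen_covariates(ph, "t", ["cand"])
        assert included == []
        assert np.isnan(p["cand"])

    def test_categorical_candidate_uses_group_f_test(self, rng):
        grp = np.repeat(["a", "b"], 50)
        y = rng.normal(size=100) + (grp == "a") * 2.0
        ph = _phenos(y, subfamily=grp)
        included, p = qs.screen_covariates(ph, "t", ["subfamily"])
        assert included == ["subfamily"]


class TestScan:
    def test_perfect_fit_caps_lod(self):
        codes = np.array([[0, 0, 1, 1, 2, 2]], dtype=float)
        g = _matrix_from_codes(codes)
        ph = _phenos(codes[0])
        curve = qs.scan(g, ph, "t")
        assert curve["lod"].iloc[0] == qs.ScanConfig().lod_cap

    def test_marker_with_one_class_gets_missing_lod(self):
        g = _matrix_from_codes([[1, 1, 1, 1, 1, 1], [0, 0, 1, 1, 2, 2]])
        ph = _phenos([1.0, 2.0, 1.5, 2.5, 1.0, 2.0])
        curve = qs.scan(g, ph, "t")
        assert np.isnan(curve["lod"].iloc[0])
        assert np.isfinite(curve["lod"].iloc[1])

    def test_null_trait_stays_below_genomewide_threshold(self, ail_cohort):
        # independent phenotype: the simpleM/Bonferroni threshold should hold
        exceed = 0
        meff = qs.simple_m(ail_cohort, 820)
        thr = qs.bonferroni_lod_threshold(0.05, meff)
        for seed in range(5):
            r = np.random.default_rng(seed)
            ph = pd.DataFrame(
                {"t": r.normal(size=len(ail_cohort.individuals))}, index=ail_cohort.individuals
            )
            curve = qs.scan(ail_cohort, ph, "t")
            if curve["lod"].max(skipna=True) >= thr:
                exceed += 1
        assert exceed <= 1

    def test_lod_invariant_to_affine_trait_rescaling(self, small_cohort, rng):
        ph = pd.DataFrame(
            {"t": rng.normal(size=len(small_cohort.individuals))},
            index=small_cohort.individuals,
        )
        ph2 = ph.assign(t=ph["t"] * 37.0 - 5.0)
        c1 = qs.scan(small_cohort, ph, "t")
        c2 = qs.scan(small_cohort, ph2, "t")
        assert np.allclose(c1["lod"], c2["lod"], equal_nan=True)

    def test_covariate_absorbs_its_own_variance(self, small_cohort, rng):
        n = len(small_cohort.individuals)
        litter = rng.integers(4, 13, size=n)
        y = 0.5 * litter + rng.normal(size=n)
        ph = pd.DataFrame({"t": y, "litter_size": litter}, index=small_cohort.individuals)
        with_cov = qs.scan(small_cohort, ph, "t", covariates=["litter_size"])
        assert with_cov["n"].iloc[0] == n


class TestSimpleM:
    def test_independent_markers_keep_nearly_all_dimensions(self, rng):
        codes = rng.binomial(2, 0.5, size=(40, 2000)).astype(float)
        g = _matrix_from_codes(codes)
        meff = qs.simple_m(g, window=40)
        assert 0.9 * 40 <= meff <= 40

    def test_duplicated_marker_collapses_to_one(self):
        row = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=float)
        g = _matrix_from_codes(np.tile(row, (10, 1)))
        assert qs.simple_m(g, window=10) == 1

    def test_windowed_meff_matches_direct_eigen_oracle(self, small_cohort):
        window, C = 25, 0.995
        # independent oracle: eigendecomposition per window, re-implemented here
        expected = 0
        calls = small_cohort.calls
        for lo in range(0, len(calls), window):
            block = calls.iloc[lo : lo + window].to_numpy()
            R = np.corrcoef(block)
            eig = np.sort(np.linalg.eigvalsh(R))[::-1]
            eig = np.clip(eig, 0, None)
            cum = np.cumsum(eig) / eig.sum()
            expected += int(np.searchsorted(cum, C) + 1)
        assert qs.simple_m(small_cohort, window=window, C=C) == expected

    def test_never_exceeds_marker_count(self, small_cohort):
        assert qs.simple_m(small_cohort, window=10) <= small_cohort.n_markers


class TestThresholds:
    def test_published_meff_reproduces_printed_thresholds(self):
        assert qs.bonferroni_lod_threshold(0.05, 849) == pytest.approx(4.23, abs=0.005)
        assert qs.bonferroni_lod_threshold(0.01, 849) == pytest.approx(4.93, abs=0.005)

    def test_no_correction_limit(self):
        assert qs.bonferroni_lod_threshold(0.05, 1) == pytest.approx(1.30, abs=0.005)

    @given(
        alpha=st.floats(0.001, 0.2),
        meff1=st.integers(1, 5000),
        meff2=st.integers(1, 5000),
    )
    def test_threshold_monotone_in_meff_and_alpha(self, alpha, meff1, meff2):
        lo, hi = sorted((meff1, meff2))
        assert qs.bonferroni_lod_threshold(alpha, hi) >= qs.bonferroni_lod_threshold(alpha, lo)
        assert qs.bonferroni_lod_threshold(alpha / 2, meff1) > qs.bonferroni_lod_threshold(
            alpha, meff1
        )


class TestLodDropInterval:
    def test_hand_walked_example(self):
        curve = pd.DataFrame(
            {
                "marker": [f"m{k}" for k in range(7)],
                "chrom": "1",
                "pos": [k * 1_000_000 for k in range(1, 8)],
                "lod": [1, 3, 6, 8, 6.4, 6.6, 2],
                "n": 100,
            }
        )
        start, top, stop, top_marker, top_lod = qs.lod_drop_interval(curve, "1", drop=1.5)
        assert (start, top, stop) == (3_000_000, 4_000_000, 5_000_000)
        assert top_marker == "m3"
        assert top_lod == 8

    def test_single_marker_chromosome(self):
        curve = pd.DataFrame(
            {"marker": ["m0"], "chrom": "1", "pos": [5_000_000], "lod": [7.0], "n": 50}
        )
        start, top, stop, *_ = qs.lod_drop_interval(curve, "1")
        assert start == top == stop == 5_000_000

    def test_peak_at_first_marker_clamps_start(self):
        curve = pd.DataFrame(
            {
                "marker": [f"m{k}" for k in range(4)],
                "chrom": "1",
                "pos": [1_000_000 * (k + 1) for k in range(4)],
                "lod": [8.0, 5.0, 3.0, 1.0],
                "n": 50,
            }
        )
        start, top, stop, *_ = qs.lod_drop_interval(curve, "1")
        assert (start, top) == (1_000_000, 1_000_000)
        assert stop == 2_000_000

    def test_tie_broken_toward_lower_position(self):
        curve = pd.DataFrame(
            {
                "marker": ["a", "b", "c"],
                "chrom": "1",
                "pos": [1_000_000, 2_000_000, 3_000_000],
                "lod": [2.0, 8.0, 8.0],
                "n": 50,
            }
        )
        _, top, _, top_marker, _ = qs.lod_drop_interval(curve, "1")
        assert top == 2_000_000 and top_marker == "b"

    def test_all_missing_chromosome_rejected(self):
        curve = pd.DataFrame(
            {"marker": ["m0"], "chrom": "1", "pos": [1], "lod": [np.nan], "n": 0}
        )
        with pytest.raises(ValueError):
            qs.lod_drop_interval(curve, "1")


class TestGenotypeEffects:
    def test_phenotype_equal_to_code_gives_unit_deltas_and_full_variance(self):
        codes = np.array([[0, 0, 1, 1, 2, 2]], dtype=float)
        g = _matrix_from_codes(codes)
        eff = qs.genotype_effects(g, _phenos(codes[0]), "t", "m0")
        assert (eff.mean_s1, eff.mean_het, eff.mean_s2) == (2.0, 1.0, 0.0)
        assert eff.d_s1_het == 1.0 and eff.d_s1_s2 == 2.0
        assert eff.var_explained == pytest.approx(100.0)

    def test_independent_phenotype_explains_little_variance(self, ail_cohort):
        marker = ail_cohort.markers.index[50]
        low = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            ph = pd.DataFrame(
                {"t": r.normal(size=len(ail_cohort.individuals))},
                index=ail_cohort.individuals,
            )
            if qs.genotype_effects(ail_cohort, ph, "t", marker).var_explained < 3.0:
                low += 1
        assert low >= 45

    def test_large_sample_delta_approaches_twice_additive_effect(self, rng):
        n = 10_000
        codes = rng.binomial(2, 0.5, size=(1, n)).astype(float)
        g = _matrix_from_codes(codes)
        y = 0.5 * codes[0] + rng.normal(0, 1, n)
        eff = qs.genotype_effects(g, _phenos(y), "t", "m0")
        assert eff.d_s1_s2 == pytest.approx(1.0, abs=0.1)


class TestNonparametricCheck:
    def test_normal_residuals_skip_kruskal(self, rng):
        codes = rng.binomial(2, 0.5, size=(1, 200)).astype(float)
        g = _matrix_from_codes(codes)
        y = codes[0] + rng.normal(0, 1, 200)
        res = qs.nonparametric_check(g, _phenos(y), "t", "m0")
        assert res["residual_normality_p"] >= 0.05
        assert np.isnan(res["kruskal_wallis_p"])
        assert res["confirmed"] is True

    def test_heavy_tailed_noise_confirmed_by_rank_test(self):
        confirmed = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            codes = r.binomial(2, 0.5, size=(1, 300)).astype(float)
            g = _matrix_from_codes(codes)
            y = 1.5 * codes[0] + r.standard_t(df=2, size=300)
            res = qs.nonparametric_check(g, _phenos(y), "t", "m0")
            if res["confirmed"]:
                confirmed += 1
        assert confirmed >= 18

    def test_kruskal_statistic_matches_hand_rank_formula(self, rng):
        # classes (1,2), (3,4), (5,6): ranks 1..6, H = 12/42 * 16 = 4.571...
        codes = np.array([[0, 0, 1, 1, 2, 2]], dtype=float)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        h, p = stats.kruskal(y[:2], y[2:4], y[4:])
        n = 6
        rank_means = [1.5, 3.5, 5.5]
        h_hand = 12 / (n * (n + 1)) * sum(2 * (rm - 3.5) ** 2 for rm in rank_means)
        assert h == pytest.approx(h_hand)
        g = _matrix_from_codes(codes)
        res = qs.nonparametric_check(
            g, _phenos(y), "t", "m0", normality_alpha=1.0
        )  # force the rank test
        assert res["kruskal_wallis_p"] == pytest.approx(p)


class TestTwoStageScan:
    def test_degenerate_full_equals_selected_gives_identical_estimates(self, small_cohort):
        marker = small_cohort.markers.index[20]
        ph = sd.simulate_phenotypes(
            small_cohort, [sd.QtlSpec(marker, "t", additive_effect=2.0, noise_sd=0.5)], seed=1
        )
        ivs = qs.two_stage_scan(small_cohort, small_cohort, ph, "t")
        assert len(ivs) == 1
        eff1 = qs.genotype_effects(small_cohort, ph, "t", ivs[0].top_marker)
        assert ivs[0].d_s1_s2 == pytest.approx(eff1.d_s1_s2)
        assert ivs[0].confirmed

    def test_no_planted_qtl_usually_yields_empty_list(self, small_cohort):
        empty = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            ph = pd.DataFrame(
                {"t": r.normal(size=len(small_cohort.individuals))},
                index=small_cohort.individuals,
            )
            if not qs.two_stage_scan(small_cohort, small_cohort, ph, "t"):
                empty += 1
        assert empty >= 9

    def test_missing_stage_two_marker_flagged_unconfirmed(self, small_cohort):
        marker = small_cohort.markers.index[20]
        ph = sd.simulate_phenotypes(
            small_cohort, [sd.QtlSpec(marker, "t", additive_effect=2.0, noise_sd=0.5)], seed=1
        )
        other = small_cohort.subset_markers([small_cohort.markers.index[0]])
        ivs = qs.two_stage_scan(small_cohort, other, ph, "t")
        assert len(ivs) == 1 and not ivs[0].confirmed
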