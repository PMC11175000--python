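"""Correlation, ICC, kappa and the test-retest report, each checked against
an independent oracle (hand formulas, a manual ANOVA decomposition, sklearn)."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dietscore as ds
from dietscore.errors import DegenerateDataError, DomainError
from dietscore.reliability import (
    CADE_RANGE,
    CORRELATION_SCALE,
    LANDIS_KOCH,
    BandScale,
    TestRetestPair,
    classify_band,
    cohen_kappa,
    icc,
    pair_profiles,
    pearson_with_ci,
    reliability_report,
    spearman,
)

from conftest import make_compliant_profile


class TestPearsonSpearman:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert pearson_with_ci(x, [2 * v + 1 for v in x]).estimate == pytest.approx(1.0)
        assert spearman(x, [v**3 for v in x]).estimate == pytest.approx(1.0)

    def test_pearson_matches_hand_formula(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        hand = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
        assert pearson_with_ci(x, y).estimate == pytest.approx(hand, abs=1e-12)

    def test_spearman_is_pearson_on_midranks(self, rng):
        from scipy.stats import rankdata

        x = rng.integers(0, 5, size=60).astype(float)  # ties force mid-ranks
        y = x + rng.normal(size=60)
        expected = pearson_with_ci(rankdata(x), rankdata(y)).estimate
        assert spearman(x, y).estimate == pytest.approx(expected, abs=1e-12)

    def test_fisher_interval_brackets_estimate_and_covers_truth(self, rng):
        # nominal 95% coverage: check the CI contains rho on most replicates
        rho, hits = 0.6, 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=60)
            y = rho * x + math.sqrt(1 - rho**2) * r.normal(size=60)
            est = pearson_with_ci(x, y)
            assert est.ci_low < est.estimate < est.ci_high
            hits += est.ci_low <= rho <= est.ci_high
        assert hits >= 85

    def test_short_or_constant_vectors_rejected(self):
        with pytest.raises(DomainError):
            pearson_with_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            pearson_with_ci([1.0] * 10, list(range(10)))


def _icc_anova_oracle(arr):
    """ICC(2,1) from the two-way ANOVA mean squares, written out directly."""
    n, k = arr.shape
    grand = arr.mean()
    ms_rows = k * ((arr.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((arr.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)


class TestIcc:
    def test_identical_administrations_give_one(self):
        arr = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc(arr).estimate == pytest.approx(1.0)

    def test_permuted_administrations_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        est = icc(np.column_stack([x, rng.permutation(x)]))
        assert abs(est.estimate) < 0.15

    def test_recovers_variance_ratio(self):
        # subject sd^2 = 3, error sd^2 = 1 -> ICC = 0.75
        rng = np.random.default_rng(7)
        subject = rng.normal(scale=math.sqrt(3.0), size=500)
        arr = subject[:, None] + rng.normal(size=(500, 2))
        est = icc(arr)
        assert est.estimate == pytest.approx(0.75, abs=0.05)
        assert est.ci_low < est.estimate < est.ci_high

    def test_matches_manual_anova_decomposition(self):
        rng = np.random.default_rng(11)
        arr = rng.normal(size=(40, 2)) + rng.normal(size=(40, 1))
        assert icc(arr).estimate == pytest.approx(_icc_anova_oracle(arr), abs=1e-9)

    def test_shape_and_degenerate_guards(self):
        with pytest.raises(DomainError):
            icc(np.zeros((10, 3)))
        with pytest.raises(DomainError):
            icc(np.zeros((3, 2)))
        with pytest.raises(DegenerateDataError):
            icc(np.ones((10, 2)))


class TestCohenKappa:
    @pytest.mark.parametrize("weights", [None, "linear", "quadratic"])
    def test_perfect_agreement_is_one(self, weights):
        a = ["small", "standard", "large", "standard"] * 5
        est = cohen_kappa(a, list(a), weights=weights, n_boot=0)
        assert est.estimate == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, size=1000)
        b = rng.integers(0, 3, size=1000)
        assert abs(cohen_kappa(a, b, n_boot=0).estimate) < 0.1

    def test_hand_worked_three_by_three_table(self):
        # contingency counts [[20,5,0],[10,30,5],[0,10,20]], n = 100
        a = [0] * 25 + [1] * 45 + [2] * 30
        b = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 30 + [2] * 5 + [1] * 10 + [2] * 20
        po = (20 + 30 + 20) / 100
        pe = (0.25 * 0.30) + (0.45 * 0.45) + (0.30 * 0.25)
        expected = (po - pe) / (1 - pe)
        est = cohen_kappa(a, b, n_boot=0)
        assert est.estimate == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weights", [None, "linear", "quadratic"])
    def test_matches_sklearn(self, weights, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 4, size=300)
        b = np.clip(a + rng.integers(-1, 2, size=300), 0, 3)
        ref = cohen_kappa_score(a, b, weights=weights)
        est = cohen_kappa(a, b, weights=weights, n_boot=0)
        assert est.estimate == pytest.approx(ref, abs=1e-12)

    def test_symmetric_in_raters(self, rng):
        a = rng.integers(0, 3, size=100)
        b = rng.integers(0, 3, size=100)
        k1 = cohen_kappa(a, b, weights="linear", n_boot=0).estimate
        k2 = cohen_kappa(b, a, weights="linear", n_boot=0).estimate
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_two_categories_weighted_equals_simple(self, rng):
        a = rng.integers(0, 2, size=200)
        b = rng.integers(0, 2, size=200)
        simple = cohen_kappa(a, b, n_boot=0).estimate
        for w in ("linear", "quadratic"):
            assert cohen_kappa(a, b, weights=w, n_boot=0).estimate == pytest.approx(simple)

    def test_quadratic_kappa_tracks_pearson_on_codes(self):
        # with matched marginals, quadratic kappa is close to the Pearson
        # correlation of the category codes (classical equivalence)
        rng = np.random.default_rng(17)
        rho = 0.7
        x = rng.normal(size=5000)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=5000)
        cuts = [-0.8, 0.0, 0.8]
        a, b = np.digitize(x, cuts), np.digitize(y, cuts)
        r_codes = pearson_with_ci(a.astype(float), b.astype(float)).estimate
        est = cohen_kappa(a, b, weights="quadratic", n_boot=0)
        assert est.estimate == pytest.approx(r_codes, abs=0.02)

    def test_bootstrap_ci_brackets_estimate_and_is_seed_stable(self, rng):
        a = rng.integers(0, 3, size=120)
        b = np.clip(a + rng.integers(-1, 2, size=120), 0, 2)
        e1 = cohen_kappa(a, b, weights="linear", n_boot=300, seed=42)
        e2 = cohen_kappa(a, b, weights="linear", n_boot=300, seed=42)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)
        assert e1.ci_low <= e1.estimate <= e1.ci_high

    def test_rating_outside_domain_rejected(self):
        with pytest.raises(DomainError, match="huge"):
            cohen_kappa(["small", "huge"], ["small", "small"], categories=["small", "large"], n_boot=0)


class TestBands:
    @pytest.mark.parametrize(
        "value,scale,expected",
        [
            (0.85, LANDIS_KOCH, "almost perfect"),
            (0.8, LANDIS_KOCH, "almost perfect"),
            (0.5, CORRELATION_SCALE, "moderate"),
            (0.39, CORRELATION_SCALE, "poor"),
            (0.6, CADE_RANGE, "acceptable"),
            (0.5, CADE_RANGE, "acceptable"),
            (0.49, CADE_RANGE, "below acceptable"),
            (0.71, CADE_RANGE, "above acceptable"),
            (1.0, CADE_RANGE, "above acceptable"),
        ],
    )
    def test_probe_values(self, value, scale, expected):
        assert classify_band(value, scale) == expected

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_monotone_step_function(self, value):
        label = classify_band(value, LANDIS_KOCH)
        rank = LANDIS_KOCH.labels.index(label)
        higher = classify_band(min(1.0, value + 0.05), LANDIS_KOCH)
        assert LANDIS_KOCH.labels.index(higher) >= rank

    def test_out_of_range_and_bad_scale_rejected(self):
        with pytest.raises(DomainError):
            classify_band(1.5, LANDIS_KOCH)
        with pytest.raises(DomainError):
            BandScale(name="bad", cuts=(0.5, 0.4), labels=("a", "b", "c"))
        with pytest.raises(DomainError):
            BandScale(name="bad", cuts=(0.5,), labels=("a",))


def _synthetic_pairs(n, seed, tau=None, portion_switch_p=None, behavior_flip_p=None):
    from dietscore.synthetic import CohortSpec, RetestNoise, generate_cohort

    kwargs = {}
    defaults = RetestNoise()
    kwargs["tau"] = defaults.tau if tau is None else tau
    kwargs["portion_switch_p"] = (
        defaults.portion_switch_p if portion_switch_p is None else portion_switch_p
    )
    kwargs["behavior_flip_p"] = (
        defaults.behavior_flip_p if behavior_flip_p is None else behavior_flip_p
    )
    return generate_cohort(CohortSpec(n=n, seed=seed, retest=RetestNoise(**kwargs)))


class TestPairProfiles:
    def test_matches_by_id_and_drops_incomplete(self, schema):
        t0 = [make_compliant_profile(schema, rid) for rid in ("A", "B", "C")]
        t1 = [make_compliant_profile(schema, rid) for rid in ("B", "C", "D")]
        pairs = pair_profiles(t0, t1)
        assert [p.respondent_id for p in pairs] == ["B", "C"]

    def test_mismatched_ids_rejected(self, schema):
        with pytest.raises(DomainError):
            TestRetestPair(
                "A", make_compliant_profile(schema, "A"), make_compliant_profile(schema, "B")
            )


class TestReliabilityReport:
    def test_identical_administrations_give_unit_reliability(self, schema):
        pairs = _synthetic_pairs(30, seed=1, tau=0.0, portion_switch_p=0.0, behavior_flip_p=0.0)
        rep = reliability_report(pairs, schema, stratify_by_age=False, n_boot=0)
        varying = rep.frequency.dropna(subset=["pearson_r"])
        assert len(varying) > 20
        assert np.allclose(varying["pearson_r"], 1.0)
        assert np.allclose(varying["icc"], 1.0, atol=1e-9)
        assert (rep.portion.dropna(subset=["kappa"])["kappa"] == 1.0).all()

    def test_item_n_counts_only_complete_pairs(self, schema):
        pairs = _synthetic_pairs(10, seed=2)
        for p in pairs[:3]:
            del p.t1.frequencies["pasta"]
        rep = reliability_report(pairs, schema, stratify_by_age=False, n_boot=0)
        pasta = rep.frequency.set_index("item").loc["pasta"]
        assert pasta["n"] == 7

    def test_mean_attenuation_matches_analytic_prediction(self, schema):
        # the lognormal jitter model predicts r = 1/sqrt(1 + v (1 + mu^2/s^2))
        # per item; compare the observed mean across items with the prediction
        from dietscore.synthetic import expected_retest_correlation

        pairs = _synthetic_pairs(400, seed=9, portion_switch_p=0.0, behavior_flip_p=0.0)
        rep = reliability_report(pairs, schema, stratify_by_age=False, n_boot=0)
        tab = rep.frequency.dropna(subset=["pearson_r"])
        tab = tab[tab["t0_sd"] > 0.5]  # analytic formula is exact pre-rounding
        from dietscore.synthetic import RetestNoise

        tau = RetestNoise().tau
        predicted = [
            expected_retest_correlation(row.t0_mean, row.t0_sd, tau)
            for row in tab.itertuples()
        ]
        assert np.mean(tab["pearson_r"]) == pytest.approx(np.mean(predicted), abs=0.1)

    def test_stratified_report_covers_both_strata(self, schema):
        pairs = _synthetic_pairs(120, seed=4)
        rep = reliability_report(pairs, schema, stratify_by_age=True, n_boot=0)
        assert set(rep.frequency["stratum"]) == {"young_adults", "adults_elderly"}

    def test_small_stratum_skipped_with_warning(self, schema):
        pairs = _synthetic_pairs(40, seed=6)
        young = [p for p in pairs if ds.age_stratum(p.t0.age_years) == "young_adults"][:2]
        older = [p for p in pairs if ds.age_stratum(p.t0.age_years) == "adults_elderly"][:6]
        rep = reliability_report(young + older, schema, stratify_by_age=True, min_n=5, n_boot=0)
        assert set(rep.frequency["stratum"]) == {"adults_elderly"}
        assert any("young_adults" in w for w in rep.warnings)

    def test_same_seed_gives_identical_bootstrap_intervals(self, schema):
        pairs = _synthetic_pairs(40, seed=8)
        r1 = reliability_report(pairs, schema, stratify_by_age=False, n_boot=50, seed=3)
        r2 = reliability_report(pairs, schema, stratify_by_age=False, n_boot=50, seed=3)
        assert r1.portion.equals(r2.portion)

    def test_bands_attached_to_every_scored_row(self, schema):
        pairs = _synthetic_pairs(30, seed=10)
        rep = reliability_report(pairs, schema, stratify_by_age=False, n_boot=0)
        freq_ok = rep.frequency.dropna(subset=["pearson_r"])
        assert set(freq_ok["band"]) <= set(CADE_RANGE.labels)
        portion_ok = rep.portion.dropna(subset=["kappa"])
        assert set(portion_ok["band"]) <= set(LANDIS_KOCH.labels)
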