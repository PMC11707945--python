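import numpy as np
import pytest
from scipy import stats

from mpjunction import (InsufficientDataError, PairedMeasurements, analyze_agreement,
                        bland_altman, bland_altman_repeated, coefficient_of_repeatability,
                        icc_agreement)


def paired(g1, g2, clusters=None, units=""):
    g1 = np.asarray(g1, float)
    return PairedMeasurements(np.arange(len(g1)), g1, np.asarray(g2, float),
                              cluster_ids=None if clusters is None else np.asarray(clusters),
                              units=units)


class TestBlandAltman:
    def test_textbook_differences(self):
        m = paired([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])  # differences −1, 0, 1
        r = bland_altman(m)
        assert r.bias == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(1.0)
        assert r.loa_lower == pytest.approx(-1.96)
        assert r.loa_upper == pytest.approx(1.96)

    def test_zero_variance_collapses_loa_to_bias(self):
        r = bland_altman(paired([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]))  # all differences 1
        assert r.bias == r.loa_lower == r.loa_upper == 1.0
        assert r.pct_within_loa == 100.0

    def test_loa_ci_closed_form(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.2, 30)
        r = bland_altman(paired(d, np.zeros(30)))
        n, sd = 30, np.std(d, ddof=1)
        half = stats.t.ppf(0.975, n - 1) * sd * np.sqrt(1 / n + 1.96 ** 2 / (2 * (n - 1)))
        assert r.loa_lower_ci == pytest.approx((r.loa_lower - half, r.loa_lower + half))
        assert r.loa_upper_ci == pytest.approx((r.loa_upper - half, r.loa_upper + half))

    def test_simulated_bias_and_loa_recovery(self):
        # differences ~ N(0.37, sd) chosen so LOA ≈ [−0.98, 1.73]
        mu, sd = 0.37, (1.73 - -0.98) / (2 * 1.96)
        rng = np.random.default_rng(11)
        d = rng.normal(mu, sd, 3000)
        r = bland_altman(paired(d, np.zeros_like(d)))
        assert r.bias == pytest.approx(mu, abs=3 * sd / np.sqrt(3000))
        assert r.loa_lower == pytest.approx(-0.98, abs=0.1)
        assert r.loa_upper == pytest.approx(1.73, abs=0.1)

    def test_antisymmetry_under_grader_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(10, 3, 40), rng.normal(10, 3, 40)
        r1, r2 = bland_altman(paired(a, b)), bland_altman(paired(b, a))
        assert r1.bias == pytest.approx(-r2.bias)
        assert r1.loa_lower == pytest.approx(-r2.loa_upper)
        assert r1.loa_upper == pytest.approx(-r2.loa_lower)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            paired([1.0], [1.0])


class TestICC:
    def test_perfect_agreement(self):
        a = np.array([1.0, 5.0, 9.0, 2.0])
        assert icc_agreement(paired(a, a.copy())) == 1.0

    def test_null_independent_noise(self):
        rng = np.random.default_rng(3)
        m = paired(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert abs(icc_agreement(m)) < 0.1

    def test_variance_component_ratio(self):
        # unit SD 3, rater-error SD 1 → ICC → 9/10
        rng = np.random.default_rng(4)
        u = rng.normal(0, 3, 3000)
        m = paired(u + rng.normal(0, 1, 3000), u + rng.normal(0, 1, 3000))
        assert icc_agreement(m) == pytest.approx(0.9, abs=0.02)

    def test_zero_total_variance_undefined(self):
        assert np.isnan(icc_agreement(paired([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])))

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(5, 2, 50), rng.normal(5, 2, 50)
        base = icc_agreement(paired(a, b))
        assert icc_agreement(paired(a + 7, b + 7)) == pytest.approx(base)
        assert icc_agreement(paired(a * 3, b * 3)) == pytest.approx(base)

    def test_matches_pingouin_oracle(self):
        """ICC(A,1) against an independent implementation (pingouin ICC2)."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        u = rng.normal(20, 4, 25)
        g1 = u + rng.normal(0.5, 1.0, 25)   # grader 1 biased: absolute agreement penalizes
        g2 = u + rng.normal(0.0, 1.0, 25)
        df = pd.DataFrame({
            "targets": np.tile(np.arange(25), 2),
            "raters": np.repeat(["g1", "g2"], 25),
            "scores": np.concatenate([g1, g2]),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores").set_index("Type").loc["ICC(A,1)", "ICC"]
        assert icc_agreement(paired(g1, g2)) == pytest.approx(float(ref), abs=1e-9)


class TestCoR:
    def test_identical_graders_zero(self):
        assert coefficient_of_repeatability(paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 0.0

    def test_closed_form_limit(self):
        rng = np.random.default_rng(8)
        u = rng.normal(0, 5, 5000)
        m = paired(u + rng.normal(0, 1, 5000), u + rng.normal(0, 1, 5000))
        assert coefficient_of_repeatability(m) == pytest.approx(1.96 * np.sqrt(2), rel=0.03)

    def test_location_invariance_and_scale_linearity(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 2, 40), rng.normal(0, 2, 40)
        base = coefficient_of_repeatability(paired(a, b))
        assert coefficient_of_repeatability(paired(a + 11, b + 11)) == pytest.approx(base)
        assert coefficient_of_repeatability(paired(a * 2, b * 2)) == pytest.approx(2 * base)

    def test_both_conventions_reported(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 2, 40), rng.normal(0, 2, 40)
        r = analyze_agreement(paired(a, b))
        assert r.cor == pytest.approx(coefficient_of_repeatability(paired(a, b)))
        assert r.cor_sd_diff == pytest.approx(1.96 * np.std(a - b, ddof=1))

    def test_estimator_consistency_with_n(self):
        # absolute error of ICC and CoR shrinks as n grows (fixed seed)
        errs_icc, errs_cor = [], []
        for n in (30, 300, 3000):
            rng = np.random.default_rng(100)
            u = rng.normal(0, 3, n)
            m = paired(u + rng.normal(0, 1, n), u + rng.normal(0, 1, n))
            errs_icc.append(abs(icc_agreement(m) - 0.9))
            errs_cor.append(abs(coefficient_of_repeatability(m) - 1.96 * np.sqrt(2)))
        assert errs_icc[0] > errs_icc[2] and errs_cor[0] > errs_cor[2]


class TestRepeatedMeasures:
    def test_variance_component_recovery(self):
        rng = np.random.default_rng(21)
        n_cluster, m = 30, 68
        a = rng.normal(0, 20, n_cluster)            # σ_a = 20 μm eye effect
        d = (a[:, None] + rng.normal(0, 30, (n_cluster, m))).ravel()  # σ_e = 30 μm
        clusters = np.repeat(np.arange(n_cluster), m)
        r = bland_altman_repeated(paired(d, np.zeros_like(d), clusters, units="um"))
        assert r.sigma_cluster == pytest.approx(20.0, rel=0.15)
        assert r.sigma_error == pytest.approx(30.0, rel=0.15)
        assert r.loa_upper - r.loa_lower == pytest.approx(2 * 1.96 * np.hypot(20, 30), rel=0.15)

    def test_all_equal_differences_collapse(self):
        d = np.full(40, 3.0)
        r = bland_altman_repeated(paired(d + 1, np.ones_like(d), np.repeat(np.arange(4), 10)))
        assert r.bias == r.loa_lower == r.loa_upper == 3.0

    def test_one_observation_per_cluster_equals_plain(self):
        rng = np.random.default_rng(30)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        plain = bland_altman(paired(a, b))
        rep = bland_altman_repeated(paired(a, b, np.arange(20)))
        assert rep.bias == plain.bias
        assert rep.loa_lower == plain.loa_lower and rep.loa_upper == plain.loa_upper

    def test_single_cluster_falls_back_with_warning(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        r = bland_altman_repeated(paired(a, b, np.zeros(20, int)))
        assert "single cluster" in " ".join(r.warnings)
        assert r.bias == pytest.approx(np.mean(a - b))

    def test_no_cluster_effect_approaches_plain_loa(self):
        # with zero true between-cluster variance the repeated-measures LOA
        # converge to the plain pooled-difference LOA
        rng = np.random.default_rng(32)
        d = rng.normal(0.2, 1.0, 50 * 40)
        clusters = np.repeat(np.arange(50), 40)
        rep = bland_altman_repeated(paired(d, np.zeros_like(d), clusters))
        plain = bland_altman(paired(d, np.zeros_like(d)))
        assert rep.loa_lower == pytest.approx(plain.loa_lower, abs=0.05)
        assert rep.loa_upper == pytest.approx(plain.loa_upper, abs=0.05)
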