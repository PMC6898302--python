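"""Agreement, reproducibility, ICC, cluster-bootstrap correlation, AROC."""

import numpy as np
import pytest

import nflmd
from nflmd.agreement import VisitSeries


def make_series(eye, pid, nfl, vf, times=None, stage=None):
    nfl = np.asarray(nfl, float)
    times = np.arange(len(nfl)) * 0.5 if times is None else np.asarray(times, float)
    return VisitSeries(eye_id=eye, participant_id=pid, times=times,
                       nfl_md=nfl, vf_md=np.asarray(vf, float), stage=stage)


class TestDifferenceByStage:
    def test_identical_parameters_zero_everywhere(self):
        s = [make_series(f"e{i}", f"p{i}", [0, -1, -2], [0, -1, -2], stage="stage1_early")
             for i in range(4)]
        rep = nflmd.difference_by_stage(s)
        assert rep.stage_mean["stage1_early"] == 0.0
        assert rep.stage_sd["stage1_early"] == 0.0
        assert rep.bias == 0.0 and rep.loa_low == rep.loa_high == 0.0

    def test_constant_offset(self):
        s = [make_series(f"e{i}", f"p{i}", [2, 1, 0], [0, -1, -2], stage="stage2_moderate")
             for i in range(3)]
        rep = nflmd.difference_by_stage(s)
        assert rep.stage_mean["stage2_moderate"] == pytest.approx(2.0)
        assert rep.stage_sd["stage2_moderate"] == pytest.approx(0.0)
        assert rep.bias == pytest.approx(2.0)

    def test_three_eye_hand_oracle(self):
        # hand-computed: per-eye mean differences 1.0, 2.0, -0.5
        s = [
            make_series("e1", "p1", [1, 2], [0, 1], stage="stage1_early"),
            make_series("e2", "p2", [3, 1], [1, -1], stage="stage1_early"),
            make_series("e3", "p3", [0, -1], [0.5, -0.5], stage="stage3_severe"),
        ]
        rep = nflmd.difference_by_stage(s)
        assert rep.stage_mean["stage1_early"] == pytest.approx(1.5)
        assert rep.stage_mean["stage3_severe"] == pytest.approx(-0.5)
        # stage1 visit-level diffs: 1,1,2,2 about mean 1.5 -> RMS 0.5
        assert rep.stage_sd["stage1_early"] == pytest.approx(0.5)
        # Bland-Altman over eye means (1.0, 2.0, -0.5)
        means = np.array([1.0, 2.0, -0.5])
        assert rep.bias == pytest.approx(means.mean())
        assert rep.loa_high == pytest.approx(means.mean() + 1.96 * means.std(ddof=1))

    def test_bland_altman_limits_identity(self):
        rng = np.random.default_rng(0)
        s = [make_series(f"e{i}", f"p{i}", rng.normal(size=4), rng.normal(size=4))
             for i in range(30)]
        rep = nflmd.difference_by_stage(s)
        assert rep.loa_low == pytest.approx(rep.bias - 1.96 * rep.sd_of_differences)
        assert rep.loa_high == pytest.approx(rep.bias + 1.96 * rep.sd_of_differences)


class TestRmsResidualReproducibility:
    def test_perfect_linear_series_zero(self):
        s = [make_series("e", "p", [0, -0.5, -1.0, -1.5], [0, 0, 0, 0])]
        assert nflmd.rms_residual_reproducibility(s, "nfl_md") == pytest.approx(0.0)

    def test_closed_form_four_point_oracle(self):
        # y = (0, 1, 0, 1) at t = (0, .5, 1, 1.5): OLS slope 0.4, intercept 0.2
        t = np.array([0, 0.5, 1.0, 1.5])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        coef = np.polyfit(t, y, 1)
        rss = np.sum((y - np.polyval(coef, t)) ** 2)
        expected = np.sqrt(rss / 2)  # n - 2 denominator
        s = [make_series("e", "p", y, y, times=t)]
        assert nflmd.rms_residual_reproducibility(s, "nfl_md") == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("sigma", [0.23, 0.7])
    def test_recovers_noise_sd(self, sigma):
        s = nflmd.simulate_visit_series(500, noise_sd=sigma, slope=-0.5, seed=9)
        est = nflmd.rms_residual_reproducibility(s, "nfl_md")
        assert est == pytest.approx(sigma, rel=0.05)

    def test_short_series_excluded(self):
        s = [make_series("e1", "p1", [0, 1], [0, 1]),
             make_series("e2", "p2", [0, 1, 2, 3], [0, 0, 0, 0])]
        with pytest.warns(UserWarning, match="fewer than 3"):
            est = nflmd.rms_residual_reproducibility(s, "nfl_md")
        assert est == pytest.approx(0.0, abs=1e-9)


class TestIcc:
    def test_identical_repeats(self):
        m = np.tile(np.arange(6, dtype=float)[:, None], (1, 3)) + 10
        assert nflmd.icc_repeatability(m) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(500, 2))  # no between-eye variance
        assert abs(nflmd.icc_repeatability(m)) < 0.1

    def test_matches_anova_mean_squares_oracle(self):
        m = np.array([
            [9.0, 10.0, 11.0],
            [6.0, 6.5, 7.5],
            [8.0, 8.5, 8.0],
            [7.0, 6.0, 5.0],
            [10.0, 11.5, 12.0],
            [6.0, 7.0, 8.0],
        ])
        n, k = m.shape
        grand = m.mean()
        msr = k * np.sum((m.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((m.mean(axis=0) - grand) ** 2) / (k - 1)
        sst = np.sum((m - grand) ** 2)
        mse = (sst - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert nflmd.icc_repeatability(m) == pytest.approx(icc21, abs=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            nflmd.icc_repeatability(np.ones((6, 2)))


class TestClusteredCorrelation:
    def test_perfect_correlation_degenerate_ci(self):
        x = np.linspace(0, 1, 20)
        res = nflmd.clustered_correlation(x, x, np.arange(20), n_boot=200, seed=1)
        assert res.estimate == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)

    def test_singleton_clusters_match_relabeled_bootstrap(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        a = nflmd.clustered_correlation(x, y, np.arange(40), n_boot=300, seed=7)
        b = nflmd.clustered_correlation(x, y, [f"id{i}" for i in range(40)],
                                        n_boot=300, seed=7)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            nflmd.clustered_correlation(np.ones(20), np.arange(20), np.arange(20))

    def test_ci_coverage(self):
        # scaled-down coverage check: CI should cover the true rho in most runs
        rho, n, reps = 0.7, 150, 40
        rng = np.random.default_rng(12)
        cov = np.array([[1, rho], [rho, 1]])
        hits = 0
        for r in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = nflmd.clustered_correlation(xy[:, 0], xy[:, 1], np.arange(n),
                                              n_boot=300, seed=r)
            hits += res.ci_low <= rho <= res.ci_high
        assert hits / reps >= 0.85


class TestCompareCorrelations:
    def test_antisymmetric_in_inputs(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=60)
        xa = y + rng.normal(scale=0.5, size=60)
        xb = y + rng.normal(scale=2.0, size=60)
        pid = np.repeat(np.arange(30), 2)
        ab = nflmd.compare_correlations(xa, xb, y, pid, n_boot=400, seed=8)
        ba = nflmd.compare_correlations(xb, xa, y, pid, n_boot=400, seed=8)
        assert ab.difference == pytest.approx(-ba.difference)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.ci_low == pytest.approx(-ba.ci_high)

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=200)
        xa = y + rng.normal(scale=0.3, size=200)
        xb = rng.normal(size=200)
        res = nflmd.compare_correlations(xa, xb, y, np.arange(200),
                                         n_boot=500, seed=9)
        assert res.difference > 0.5
        assert res.p_value < 0.05


class TestArocSensitivity:
    def test_complete_separation(self):
        r = nflmd.aroc_sensitivity([-10, -9, -8, -7, -6], [0, 1, 2, 3, 4])
        assert r.aroc == 1.0

    def test_identical_distributions(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=400)
        r = nflmd.aroc_sensitivity(v[:200], v[200:])
        assert r.aroc == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cases = np.round(rng.normal(-2, 2, size=rng.integers(5, 25)), 1)
        controls = np.round(rng.normal(0, 2, size=rng.integers(5, 25)), 1)
        r = nflmd.aroc_sensitivity(cases, controls)
        wins = sum((c < u) + 0.5 * (c == u) for c in cases for u in controls)
        assert r.aroc == pytest.approx(wins / (len(cases) * len(controls)), abs=1e-12)

    def test_invariant_under_monotone_transform(self, model):
        # same eyes in µm and in dB must give the same AROC
        rng = np.random.default_rng(14)
        N, f = 100.0, 45.0
        cases_um = rng.uniform(50, 95, size=30)
        controls_um = rng.uniform(85, 120, size=30)
        to_db = lambda t: nflmd.to_decibel(t, N, f)
        a_um = nflmd.aroc_sensitivity(cases_um, controls_um).aroc
        a_db = nflmd.aroc_sensitivity([to_db(t) for t in cases_um],
                                      [to_db(t) for t in controls_um]).aroc
        assert a_um == pytest.approx(a_db, abs=1e-12)

    def test_sensitivities_at_cutoffs(self):
        cut = nflmd.DiagnosticCutoffs(cutoff95=-1.0, cutoff99=-2.0,
                                      scale_used="native", parameter_kind="nfl_md")
        cases = np.array([-3.0, -1.5, -0.5, -2.5, -4.0])
        r = nflmd.aroc_sensitivity(cases, np.zeros(5), cut)
        assert r.sensitivity95 == pytest.approx(4 / 5)
        assert r.sensitivity99 == pytest.approx(3 / 5)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            nflmd.aroc_sensitivity([], [1, 2, 3, 4, 5])


def test_mcnemar_paired_flags():
    a = np.array([True] * 30 + [False] * 10)
    b = np.array([True] * 20 + [False] * 20)
    p = nflmd.mcnemar_sensitivity(a, b)
    assert 0 <= p <= 1
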