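"""Decibel transform, weighted logarithmic average, and quadratic calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nflmd
from nflmd.decibel import CalibrationModel, fit_calibration


class TestToDecibel:
    def test_reference_thickness_is_zero(self):
        assert nflmd.to_decibel(100.0, 100.0, 45.0) == 0.0

    @pytest.mark.parametrize("t", [45.0, 44.0, 10.0, 0.0])
    def test_at_or_below_floor_clamps(self, t):
        assert nflmd.to_decibel(t, 100.0, 45.0) == -12.8

    def test_five_percent_thinning(self):
        # t = 0.95 N, f = 0.45 N: 10*log10(0.50/0.55)
        assert nflmd.to_decibel(95.0, 100.0, 45.0) == pytest.approx(-0.41, abs=0.005)

    def test_above_reference_positive(self):
        assert nflmd.to_decibel(110.0, 100.0, 45.0) > 0

    def test_reference_not_above_floor_errors(self):
        with pytest.raises(ValueError, match="reference must exceed floor"):
            nflmd.to_decibel(50.0, 45.0, 45.0)

    def test_negative_floor_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            nflmd.to_decibel(50.0, 100.0, -1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(db=st.floats(-12.7, 6.0), N=st.floats(60, 160), f_frac=st.floats(0.0, 0.6))
    def test_roundtrip_inverse(self, db, N, f_frac):
        # t = f + (N - f) * 10^(dB/10) recovers the thickness when unclamped
        f = f_frac * N
        t = f + (N - f) * 10.0 ** (db / 10.0)
        assert nflmd.to_decibel(t, N, f) == pytest.approx(db, abs=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(t1=st.floats(30, 150), t2=st.floats(30, 150))
    def test_monotone_in_thickness(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert nflmd.to_decibel(lo, 100.0, 45.0) <= nflmd.to_decibel(hi, 100.0, 45.0)


class TestProfileToDecibel:
    def test_reference_profile_all_zero(self, model, reference_profile):
        db = nflmd.profile_to_decibel(reference_profile, model)
        assert np.allclose(db.as_array(), 0.0)

    def test_one_sector_at_floor(self, model, reference_profile):
        thick = dict(reference_profile.thickness)
        thick["IT1"] = nflmd.floor_value("IT1", reference_profile.axial_length, model)
        prof = nflmd.SectorProfile("e", thick, reference_profile.age,
                                   reference_profile.axial_length)
        db = nflmd.profile_to_decibel(prof, model)
        assert db["IT1"] == -12.8
        assert all(db[s] == pytest.approx(0.0, abs=1e-9)
                   for s in nflmd.SECTOR_ORDER if s != "IT1")

    def test_uniform_thinning_five_percent(self, model):
        # thinning relative to each sector's own reference is uniform in dB
        age, axlen = 50.0, 23.6
        thick = {s: 0.95 * nflmd.reference_thickness(s, age, axlen, model)
                 for s in nflmd.SECTOR_ORDER}
        db = nflmd.profile_to_decibel(
            nflmd.SectorProfile("e", thick, age, axlen), model)
        assert np.allclose(db.as_array(), 10 * np.log10(0.50 / 0.55), atol=1e-9)

    def test_error_names_sector(self, model):
        bad = nflmd.NormativeModel(model.coefficients, floor_fraction=0.0,
                                   db_floor_clamp=-12.8)
        # an extreme axial length drives one sector's reference non-positive
        thick = {s: 100.0 for s in nflmd.SECTOR_ORDER}
        prof = nflmd.SectorProfile("e", thick, age=50.0, axial_length=60.0)
        with pytest.raises(ValueError, match="sector"), pytest.warns(UserWarning):
            nflmd.profile_to_decibel(prof, bad)

    def test_os_profile_mirrored_at_ingest(self, model):
        age, axlen = 55.0, 24.0
        thick = {s: nflmd.reference_thickness(s, age, axlen, model)
                 for s in nflmd.SECTOR_ORDER}
        thick["ST1"] *= 0.6  # native-OS superotemporal dip
        prof = nflmd.SectorProfile("os-eye", thick, age, axlen, laterality="OS")
        # after mirroring the dip sits on IT1 in OD orientation
        assert prof.thickness["IT1"] == pytest.approx(thick["ST1"])


class TestWeightedLogAverage:
    def test_constant_profile(self, weights):
        db = nflmd.DecibelProfile({s: -3.7 for s in nflmd.SECTOR_ORDER})
        assert nflmd.weighted_log_average(db, weights) == pytest.approx(-3.7, abs=1e-12)

    def test_single_clamped_sector_with_known_weight(self):
        w = {s: (52.0 - 7.64) / 15 for s in nflmd.SECTOR_ORDER}
        w["IT1"] = 7.64
        scheme = nflmd.WeightScheme(w, source="interpolated")
        loss = {s: 0.0 for s in nflmd.SECTOR_ORDER}
        loss["IT1"] = -12.8
        wla = nflmd.weighted_log_average(nflmd.DecibelProfile(loss), scheme)
        assert wla == pytest.approx(7.64 * -12.8 / 52.0, abs=1e-12)
        assert wla == pytest.approx(-1.881, abs=5e-4)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_loop_oracle(self, weights, seed):
        rng = np.random.default_rng(seed)
        loss = {s: float(rng.uniform(-12.8, 3.0)) for s in nflmd.SECTOR_ORDER}
        db = nflmd.DecibelProfile(loss)
        oracle = sum(weights[s] * loss[s] for s in nflmd.SECTOR_ORDER) / 52.0
        assert nflmd.weighted_log_average(db, weights) == pytest.approx(oracle, rel=1e-12)

    def test_linearity_in_profile(self, weights):
        rng = np.random.default_rng(3)
        a = {s: float(rng.uniform(-5, 1)) for s in nflmd.SECTOR_ORDER}
        b = {s: float(rng.uniform(-5, 1)) for s in nflmd.SECTOR_ORDER}
        mix = {s: 0.3 * a[s] + 0.7 * b[s] for s in nflmd.SECTOR_ORDER}
        wa = nflmd.weighted_log_average(nflmd.DecibelProfile(a), weights)
        wb = nflmd.weighted_log_average(nflmd.DecibelProfile(b), weights)
        wm = nflmd.weighted_log_average(nflmd.DecibelProfile(mix), weights)
        assert wm == pytest.approx(0.3 * wa + 0.7 * wb, abs=1e-12)


class TestNflMd:
    def test_zero_fixed_point(self):
        assert nflmd.nfl_md(0.0) == 0.0

    @pytest.mark.parametrize("wla,expected", [
        (-1.881, -1.89),     # focal-loss worked example
        (1.1488, 0.89),      # upper normal-variation bound
    ])
    def test_known_values(self, wla, expected):
        assert nflmd.nfl_md(wla) == pytest.approx(expected, abs=0.005)

    def test_monotone_on_operating_range(self):
        x = np.linspace(-12.8, 3.0, 400)
        y = nflmd.nfl_md(x)
        assert np.all(np.diff(y) > 0)

    def test_warns_outside_range(self):
        with pytest.warns(UserWarning, match="operating range"):
            nflmd.nfl_md(-20.0)

    def test_non_monotone_coefficients_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CalibrationModel(b1=0.1, b2=-0.075)


class TestEndToEndMonotonicity:
    @pytest.mark.parametrize("sector", nflmd.SECTOR_ORDER)
    def test_thicker_sector_never_lowers_nfl_md(self, model, weights, sector):
        age, axlen = 60.0, 24.0
        base = {s: 0.7 * nflmd.reference_thickness(s, age, axlen, model)
                for s in nflmd.SECTOR_ORDER}
        mds = []
        for factor in (0.4, 0.6, 0.8, 1.0, 1.2):
            thick = dict(base)
            thick[sector] = factor * nflmd.reference_thickness(sector, age, axlen, model)
            db = nflmd.profile_to_decibel(
                nflmd.SectorProfile("e", thick, age, axlen), model)
            mds.append(nflmd.nfl_md(nflmd.weighted_log_average(db, weights)))
        assert np.all(np.diff(mds) >= 0)


class TestFitCalibration:
    def _data(self, n=60, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-10, 2, size=n)
        y = 0.864 * x - 0.075 * x**2 + rng.normal(0, noise, size=n)
        pid = np.repeat([f"p{i}" for i in range(n // 2)], 2)
        return x, y, pid

    def test_noiseless_recovery(self):
        x, y, pid = self._data()
        fit = fit_calibration(x, y, pid)
        assert fit.model.b1 == pytest.approx(0.864, abs=1e-10)
        assert fit.model.b2 == pytest.approx(-0.075, abs=1e-10)

    def test_noisy_recovery_within_sampling_error(self):
        x, y, pid = self._data(n=500, noise=0.5, seed=1)
        fit = fit_calibration(x, y, pid)
        X = np.column_stack([x, x**2])
        cov = 0.5**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert abs(fit.model.b1 - 0.864) < 3 * se[0]
        assert abs(fit.model.b2 + 0.075) < 3 * se[1]

    def test_folds_partition_participants_not_eyes(self):
        x, y, pid = self._data(n=100, noise=0.3, seed=2)
        fit = fit_calibration(x, y, pid, n_folds=5)
        for p in np.unique(pid):
            folds = np.unique(fit.fold_assignment[pid == p])
            assert folds.size == 1  # both eyes of a participant share a fold

    def test_out_of_fold_predictions_exclude_own_participant(self):
        # refitting without fold k by hand must reproduce fold k's coefficients
        x, y, pid = self._data(n=100, noise=0.3, seed=3)
        fit = fit_calibration(x, y, pid, n_folds=5)
        for k, fm in enumerate(fit.fold_models):
            train = fit.fold_assignment != k
            X = np.column_stack([x[train], x[train]**2])
            beta, *_ = np.linalg.lstsq(X, y[train], rcond=None)
            assert fm.b1 == pytest.approx(beta[0], abs=1e-10)
            assert fm.b2 == pytest.approx(beta[1], abs=1e-10)
            test = ~train
            assert np.allclose(fit.oof_predictions[test], fm(x[test]))

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration(np.zeros(20), np.zeros(20), np.arange(20))

    def test_too_few_eyes(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_calibration([1, 2, 3], [1, 2, 3], ["a", "b", "c"])


def test_diffuse_loss_db_five_percent():
    assert nflmd.diffuse_loss_db(0.05) == pytest.approx(-0.22, abs=0.005)
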