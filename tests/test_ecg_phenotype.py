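import numpy as np
import pandas as pd
import pytest

from calmkit.ecg_phenotype import (
    QtcModel,
    arrhythmia_score,
    bvt_incidence,
    fit_qtc_exponent,
    qtc,
    signal_average,
)
from calmkit.synthetic_data import gen_beats


def _beat(n=100, fid=40, amp=1.0, rng=None, noise=0.0):
    w = np.zeros(n)
    w[fid] = amp
    w[fid - 2 : fid + 3] += 0.3 * amp
    if noise and rng is not None:
        w += rng.normal(0, noise, n)
    return w


class TestSignalAverage:
    def test_identical_beats_reproduce_one_beat(self):
        beat = _beat()
        avg = signal_average([beat] * 5)
        assert np.allclose(avg, beat)

    def test_single_beat_identity(self):
        beat = _beat()
        assert np.allclose(signal_average([beat]), beat)

    def test_noise_reduced_by_sqrt_n(self):
        rng = np.random.default_rng(0)
        n_beats, sigma = 64, 0.05
        beats = [_beat(rng=rng, noise=sigma) for _ in range(n_beats)]
        avg = signal_average(beats)
        resid = avg - _beat()
        # residual SD ~ sigma/sqrt(N); allow a factor-2 band
        assert np.std(resid) < 2 * sigma / np.sqrt(n_beats)

    def test_alignment_on_shifted_copies(self):
        beat = _beat()
        shifted = [np.roll(beat, k) for k in (-3, 0, 4)]
        avg = signal_average(shifted)
        assert avg.max() == pytest.approx(beat.max())

    def test_min_fiducial(self):
        beat = -_beat()
        avg = signal_average([beat, np.roll(beat, 2)], fiducial="min")
        assert avg.min() == pytest.approx(beat.min())


class TestQtcExponent:
    def test_noiseless_power_law_inversion(self):
        rng = np.random.default_rng(1)
        rr = rng.uniform(80, 200, 50)
        qt = 40.0 * (rr / rr.mean()) ** 0.5
        model = fit_qtc_exponent(rr, qt)
        assert model.exponent_n == pytest.approx(0.5, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0)

    def test_constant_qt_gives_zero_exponent(self):
        rr = np.linspace(80, 200, 30)
        model = fit_qtc_exponent(rr, np.full(30, 42.0))
        assert model.exponent_n == pytest.approx(0.0, abs=1e-12)

    def test_recovery_on_noisy_generated_beats(self):
        beats = gen_beats(45.0, 0.575, (80, 200), 200, cv=0.03, seed=5)
        model = fit_qtc_exponent(beats["rr_ms"].to_numpy(), beats["qt_ms"].to_numpy())
        assert abs(model.exponent_n - 0.575) <= 0.03

    def test_qt_unit_scale_changes_intercept_only(self):
        rng = np.random.default_rng(2)
        rr = rng.uniform(80, 200, 60)
        qt = 40.0 * (rr / rr.mean()) ** 0.4 * np.exp(rng.normal(0, 0.02, 60))
        a = fit_qtc_exponent(rr, qt)
        with pytest.warns(UserWarning, match="QT >= RR"):  # scaled QT exceeds RR
            b = fit_qtc_exponent(rr, qt * 10.0)
        assert b.exponent_n == pytest.approx(a.exponent_n, abs=1e-12)
        assert b.intercept_ln_ms == pytest.approx(a.intercept_ln_ms + np.log(10.0))

    def test_zero_rr_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_qtc_exponent(np.full(10, 120.0), np.full(10, 40.0))


class TestQtc:
    def test_identity_at_reference_rate(self):
        model = QtcModel(0.5, 120.0, 0.0, 1.0)
        assert qtc(40.0, 120.0, model) == pytest.approx(40.0)

    def test_zero_exponent_is_no_correction(self):
        model = QtcModel(0.0, 120.0, 0.0, 1.0)
        rr = np.array([80.0, 120.0, 200.0])
        assert np.allclose(qtc(np.full(3, 40.0), rr, model), 40.0)

    def test_correction_flattens_noiseless_power_law(self):
        rng = np.random.default_rng(3)
        rr = rng.uniform(80, 200, 100)
        qt = 40.0 * (rr / rr.mean()) ** 0.575
        model = fit_qtc_exponent(rr, qt)
        corrected = qtc(qt, rr, model)
        assert corrected.max() / corrected.min() - 1 < 1e-9


def _events(rows):
    return pd.DataFrame(rows, columns=["t_start_s", "type", "duration_s"])


class TestArrhythmiaScore:
    WINDOW = (0.0, 60.0)

    def test_empty_log_scores_1(self):
        assert arrhythmia_score(_events([]), self.WINDOW) == 1

    def test_isolated_pvcs_score_1(self):
        ev = _events([(5.0, "pvc", 0.0), (30.0, "pvc", 0.0)])
        assert arrhythmia_score(ev, self.WINDOW) == 1

    def test_pvc_rate_above_10_per_min_scores_2(self):
        ev = _events([(float(i * 5), "pvc", 0.0) for i in range(11)])
        assert arrhythmia_score(ev, self.WINDOW) == 2

    def test_bigeminy_scores_2(self):
        assert arrhythmia_score(_events([(10.0, "bigeminy", 0.0)]), self.WINDOW) == 2

    def test_couplet_beats_bigeminy(self):
        ev = _events([(10.0, "bigeminy", 0.0), (20.0, "couplet", 0.0)])
        assert arrhythmia_score(ev, self.WINDOW) == 3

    @pytest.mark.parametrize("duration, expected", [(5.0, 4), (3.0, 4), (15.0, 4), (2.0, 1), (20.0, 1)])
    def test_nsvt_duration_bounds(self, duration, expected):
        ev = _events([(10.0, "nsvt", duration)])
        assert arrhythmia_score(ev, self.WINDOW) == expected

    def test_monotone_adding_events_never_lowers_score(self):
        pool = [
            (5.0, "pvc", 0.0),
            (6.0, "bigeminy", 0.0),
            (7.0, "couplet", 0.0),
            (8.0, "nsvt", 5.0),
        ]
        prev = 1
        for k in range(1, len(pool) + 1):
            score = arrhythmia_score(_events(pool[:k]), self.WINDOW)
            assert score >= prev
            prev = score

    def test_events_outside_window_warned_and_ignored(self):
        ev = _events([(120.0, "nsvt", 5.0)])
        with pytest.warns(UserWarning):
            assert arrhythmia_score(ev, self.WINDOW) == 1


class TestBvtIncidence:
    def test_no_bvt_anywhere(self):
        logs = [_events([]) for _ in range(4)]
        assert bvt_incidence(logs) == (0, 4)

    def test_every_animal_affected(self):
        logs = [_events([(1.0, "bvt", 6.0)]) for _ in range(3)]
        assert bvt_incidence(logs) == (3, 3)

    def test_counts_animals_not_episodes(self):
        # 5 of 9 animals with at least one qualifying episode; repeats in one
        # animal must not inflate the count
        affected = [_events([(1.0, "bvt", 4.0), (9.0, "bvt", 20.0)]) for _ in range(5)]
        clean = [_events([(1.0, "bvt", 2.0)]) for _ in range(2)] + [_events([])] * 2
        assert bvt_incidence(affected + clean) == (5, 9)

    def test_short_episodes_do_not_count(self):
        logs = [_events([(1.0, "bvt", 2.9)])]
        assert bvt_incidence(logs) == (0, 1)
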