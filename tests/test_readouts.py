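"""Interval integrals, switch ratio, transcription delay, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import her4jakstat as h
from her4jakstat.readouts import CASEIN_MRNA, NUCLEAR_STAT_DIMER

from conftest import make_trajectory


class TestIntegrateInterval:
    def test_constant_profile(self):
        t = np.linspace(0, 48, 481)
        tr = make_trajectory(t, {CASEIN_MRNA: np.full_like(t, 2.0)})
        assert h.integrate_interval(tr, CASEIN_MRNA, 0, 12) == pytest.approx(24.0)

    def test_linear_ramp(self):
        t = np.linspace(0, 48, 4801)
        tr = make_trajectory(t, {CASEIN_MRNA: t})
        assert h.integrate_interval(tr, CASEIN_MRNA, 0, 4) == pytest.approx(8.0)

    def test_interval_additivity_on_model(self, baseline_traj):
        parts = sum(h.integrate_interval(baseline_traj, CASEIN_MRNA, a, b)
                    for a, b in h.INTERVALS)
        total = h.integrate_interval(baseline_traj, CASEIN_MRNA, 0.0, 48.0)
        assert parts == pytest.approx(total, rel=1e-9)

    def test_out_of_grid_interval_rejected(self, baseline_traj):
        with pytest.raises(ValueError):
            h.integrate_interval(baseline_traj, CASEIN_MRNA, 0.0, 100.0)


class TestSwitchRatio:
    def test_equal_window_integrals_give_unity(self):
        t = np.linspace(0, 48, 9601)
        conc = np.where(t <= 12.0, 3.0, 1.0)
        tr = make_trajectory(t, {CASEIN_MRNA: conc})
        assert h.switch_ratio(tr) == pytest.approx(1.0, rel=1e-2)

    def test_early_only_expression_gives_large_ratio(self):
        t = np.linspace(0, 48, 9601)
        conc = np.where(t <= 12.0, 5.0, 1e-9)
        tr = make_trajectory(t, {CASEIN_MRNA: conc})
        assert h.switch_ratio(tr) > 100.0

    def test_zero_late_expression_rejected(self):
        t = np.linspace(0, 48, 481)
        conc = np.where(t <= 10.0, 5.0, 0.0)
        tr = make_trajectory(t, {CASEIN_MRNA: conc})
        with pytest.raises(ValueError, match="denominator"):
            h.switch_ratio(tr)

    def test_invert_convention_is_reciprocal(self, baseline_traj):
        r = h.switch_ratio(baseline_traj)
        assert h.switch_ratio(baseline_traj, invert=True) == pytest.approx(1.0 / r)


class TestTranscriptionDelay:
    @staticmethod
    def _gauss(t, mu, sigma=0.5):
        return np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    def test_gaussian_peaks_three_hours_apart(self):
        t = np.linspace(0, 48, 4801)
        tr = make_trajectory(t, {
            NUCLEAR_STAT_DIMER: self._gauss(t, 1.0),
            CASEIN_MRNA: self._gauss(t, 4.0),
        })
        assert h.transcription_delay(tr) == pytest.approx(3.0, abs=1e-3)

    def test_identical_profiles_give_zero(self):
        t = np.linspace(0, 48, 4801)
        y = self._gauss(t, 5.0)
        tr = make_trajectory(t, {NUCLEAR_STAT_DIMER: y, CASEIN_MRNA: y.copy()})
        assert h.transcription_delay(tr) == pytest.approx(0.0, abs=1e-9)

    def test_subgrid_resolution_via_quadratic_fit(self):
        # peaks at 1.03 and 4.17 h on a 0.1-h grid: interpolation must beat
        # the raw grid resolution
        t = np.linspace(0, 48, 481)
        tr = make_trajectory(t, {
            NUCLEAR_STAT_DIMER: self._gauss(t, 1.03),
            CASEIN_MRNA: self._gauss(t, 4.17),
        })
        assert h.transcription_delay(tr) == pytest.approx(3.14, abs=0.02)

    def test_monotone_profile_flagged(self):
        t = np.linspace(0, 48, 481)
        tr = make_trajectory(t, {NUCLEAR_STAT_DIMER: self._gauss(t, 5.0),
                                 CASEIN_MRNA: t})
        with pytest.raises(h.NoPeakError, match="peak"):
            h.transcription_delay(tr)


class TestNormalization:
    def test_fold_change(self):
        assert h.normalize_to_control(4.0, 2.0) == pytest.approx(2.0)
        assert h.normalize_to_control(7.3, 7.3) == pytest.approx(1.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            h.normalize_to_control(1.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(v=st.floats(0.01, 1e3), c=st.floats(0.01, 1e3), s=st.floats(0.01, 1e3))
    def test_scale_invariance(self, v, c, s):
        a = h.normalize_to_control(v, c)
        b = h.normalize_to_control(v * s, c * s)
        assert a == pytest.approx(b, rel=1e-9)


class TestDoseTrend:
    @pytest.mark.parametrize("values,expected", [
        ([10.0, 8.0, 6.0], -1),
        ([6.0, 8.0, 10.0], +1),
        ([5.0, 5.0, 5.0], 0),
        ([5.0, 5.0 + 1e-9, 5.0], 0),  # within deadband
    ])
    def test_sign_of_slope(self, values, expected):
        assert h.dose_trend(values, [10.0, 20.0, 50.0]) == expected

    def test_robust_to_non_monotone_middle_dose(self):
        assert h.dose_trend([10.0, 11.0, 4.0], [10.0, 20.0, 50.0]) == -1

    def test_needs_three_doses(self):
        with pytest.raises(ValueError):
            h.dose_trend([1.0, 2.0], [10.0, 20.0])


class TestEnsembleSummary:
    def test_mean_and_sd(self):
        s = h.ensemble_summary([1.0, 3.0])
        assert s["mean"] == pytest.approx(2.0)
        assert s["sd"] == pytest.approx(np.sqrt(2.0))
        assert s["sem"] == pytest.approx(1.0)
        assert s["n"] == 2

    def test_identical_members_have_zero_sd(self):
        assert h.ensemble_summary([4.0] * 5)["sd"] == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            h.ensemble_summary([1.0])


class TestModelReadouts:
    def test_readout_set_consistency(self, baseline_traj):
        r = h.compute_readouts(baseline_traj)
        assert r.integral_total_0_48 == pytest.approx(
            r.integral_0_12 + r.integral_12_24 + r.integral_24_48, rel=1e-9)
        assert r.integral_0_12 >= 0 and r.switch_ratio > 0

    def test_delay_increases_as_export_rate_drops(self, full_net):
        delays = []
        for mult in (1.0, 0.5, 0.2, 0.1):
            tr = h.run_timecourse(
                full_net, 20.0, output_step=0.02,
                params={"kR45": full_net.parameters["kR45"] * mult})
            delays.append(h.transcription_delay(tr))
        assert all(b > a for a, b in zip(delays, delays[1:]))

    def test_delay_non_increasing_in_import_rate(self, full_net):
        delays = []
        for mult in (0.1, 0.3, 1.0, 3.0):
            tr = h.run_timecourse(
                full_net, 20.0, output_step=0.02,
                params={"kR15": full_net.parameters["kR15"] * mult})
            delays.append(h.transcription_delay(tr))
        assert all(b <= a + 0.02 for a, b in zip(delays, delays[1:]))
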