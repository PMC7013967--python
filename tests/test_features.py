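import numpy as np
import pytest

from wristrig.features import (
    combine_axes,
    count_cogwheel_artefacts,
    detect_peaks,
    mean_angular_velocity,
    mean_peak,
    window_features,
)
from wristrig.signal import extract_flexion_samples

from conftest import make_arcade, make_flexion_window
from oracles import oracle_peaks


class TestDetectPeaks:
    def test_single_peak(self):
        ps = detect_peaks([0, 1, 3, 1, 0], margin=0.2)
        assert list(ps.peak_values) == [3]
        assert list(ps.peak_indices) == [2]

    def test_all_zero(self):
        assert len(detect_peaks(np.zeros(50), margin=0.2)) == 0

    def test_empty(self):
        assert len(detect_peaks([], margin=0.2)) == 0

    def test_sub_margin_ripple_is_one_peak(self):
        """±0.1 ripple on a single arcade stays one peak at a 0.2 margin."""
        arcade = make_arcade(10.0, 80)
        ripple = 0.1 * np.sin(np.arange(80) * 2.5)
        ps = detect_peaks(arcade + ripple, margin=0.2)
        assert len(ps) == 1

    def test_supra_margin_dip_splits_peak(self):
        x = np.concatenate([make_arcade(5.0, 20), [0.0], make_arcade(7.0, 20)])
        ps = detect_peaks(x, margin=0.2)
        assert len(ps) == 2

    def test_peaks_confirmed_by_flanking_valleys(self):
        ps = detect_peaks([0, 2, 0.5, 3, 0, 1, 0.9, 1.05, 0], margin=0.2)
        # every peak is bracketed by valleys in index order
        assert len(ps.valley_indices) == len(ps) + 1
        for k, p in enumerate(ps.peak_indices):
            assert ps.valley_indices[k] < p < ps.valley_indices[k + 1]

    def test_matches_independent_oracle(self):
        """Hysteresis scan equals the persistence-merge oracle on random signals."""
        rng = np.random.default_rng(2024)
        for trial in range(120):
            n = int(rng.integers(5, 300))
            if trial % 2:
                x = np.abs(np.cumsum(rng.normal(0, 1, n)))
            else:
                t = np.linspace(0, rng.uniform(1, 4) * np.pi, n)
                x = np.abs(np.sin(t)) * rng.uniform(1, 20) + np.abs(rng.normal(0, 0.3, n))
            margin = float(rng.uniform(0.05, 1.5))
            got = sorted(detect_peaks(x, margin).peak_indices.tolist())
            want = sorted(i for i, _ in oracle_peaks(x, margin))
            assert got == want


class TestMeans:
    def test_mean_angular_velocity(self):
        assert mean_angular_velocity([2.0, 4.0]) == 3.0
        assert mean_angular_velocity([]) == 0.0

    def test_mean_peak(self):
        ps = detect_peaks([0, 10, 0, 20, 0], margin=0.2)
        assert mean_peak(ps) == 15.0
        assert mean_peak(detect_peaks([], 0.2)) == 0.0

    def test_two_arcade_window_against_direct_computation(self, two_arcade_window):
        f = window_features(two_arcade_window)
        y = two_arcade_window.axis("y")
        flex = -y[y < 0]
        assert f.mu_omega == pytest.approx(flex.mean())
        rect = np.where(y < 0, -y, 0.0)
        expected_peaks = [v for _, v in oracle_peaks(rect, 0.2)]
        assert f.mu_peak == pytest.approx(np.mean(expected_peaks))
        assert f.mu_peak > f.mu_omega


class TestCogwheel:
    @staticmethod
    def _flexion_from(magnitude_arcades):
        y = []
        for arc in magnitude_arcades:
            y.extend(-np.asarray(arc))
            y.append(1.0)  # positive gap separates arcades
        return extract_flexion_samples(np.asarray(y))

    def test_smooth_arcade_has_none(self):
        fl = self._flexion_from([make_arcade(10.0, 50)])
        assert count_cogwheel_artefacts(fl, dip_threshold=0.2) == 0

    def test_single_interior_dip(self):
        arc = make_arcade(10.0, 50)
        arc[24:27] -= 0.4  # dip depth 2x threshold
        fl = self._flexion_from([arc])
        assert count_cogwheel_artefacts(fl, dip_threshold=0.2) == 1

    def test_one_dip_per_arcade_sums(self):
        arcs = []
        for amp in (8.0, 12.0):
            arc = make_arcade(amp, 50)
            arc[24:27] -= 0.5
            arcs.append(arc)
        fl = self._flexion_from(arcs)
        assert count_cogwheel_artefacts(fl, dip_threshold=0.2) == 2

    def test_scale_invariance_with_threshold(self):
        """delta is invariant under joint scaling of signal and threshold."""
        rng = np.random.default_rng(7)
        arc = make_arcade(10.0, 60) + np.abs(rng.normal(0, 0.3, 60))
        fl = self._flexion_from([arc])
        base = count_cogwheel_artefacts(fl, dip_threshold=0.2)
        for k in (0.5, 3.0, 10.0):
            fl_k = self._flexion_from([k * arc])
            assert count_cogwheel_artefacts(fl_k, dip_threshold=0.2 * k) == base


class TestCombineAxes:
    def test_pythagorean_triple(self):
        omega = {"x": [3.0], "y": [4.0], "z": [0.0]}
        assert combine_axes(omega, ("x", "y"))[0] == pytest.approx(5.0)

    def test_single_axis_is_magnitude_with_y_sign(self):
        omega = {"x": [0.0], "y": [-4.0], "z": [0.0]}
        assert combine_axes(omega, ("y",))[0] == pytest.approx(-4.0)

    def test_sign_follows_y(self):
        omega = {"x": [3.0, 3.0], "y": [-4.0, 4.0], "z": [0.0, 0.0]}
        out = combine_axes(omega, ("x", "y", "z"))
        assert np.allclose(out, [-5.0, 5.0])

    def test_random_fixture_matches_norm(self):
        rng = np.random.default_rng(3)
        omega = {a: rng.normal(0, 10, 100) for a in "xyz"}
        out = combine_axes(omega, ("x", "y", "z"))
        want = np.sqrt(sum(omega[a] ** 2 for a in "xyz"))
        assert np.allclose(np.abs(out), want)

    def test_unknown_axis(self):
        with pytest.raises((ValueError, KeyError)):
            combine_axes({"y": [1.0]}, ("w",))

    def test_empty_axes(self):
        with pytest.raises(ValueError):
            combine_axes({"y": [1.0]}, ())


class TestFeatureProperties:
    def test_amplitude_linearity(self):
        """mu_omega and mu_peak are linear in the arcade amplitude."""
        base = make_flexion_window([10.0, 20.0])
        f1 = window_features(base)
        for k in (0.5, 2.0, 7.0):
            fk = window_features(make_flexion_window([10.0 * k, 20.0 * k]))
            assert fk.mu_omega == pytest.approx(k * f1.mu_omega, rel=1e-9)
            assert fk.mu_peak == pytest.approx(k * f1.mu_peak, rel=1e-9)

    def test_mu_peak_dominates_mu_omega_on_arcade_family(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            amps = rng.uniform(1.0, 30.0, rng.integers(1, 5))
            f = window_features(make_flexion_window(list(amps)))
            assert f.mu_peak >= f.mu_omega
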