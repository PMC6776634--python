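"""Contact geometry, oscillation fitting and moduli extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinamech import mechanics as mech
from retinamech import synth
from retinamech.errors import (
    DuplicateLocationError,
    InsufficientDataError,
    InvalidParameterError,
    NoContactError,
)

from conftest import make_oscillation


def fft_bin_fit(t, y, f_hz):
    """Independent oracle: DFT coefficient at the drive-frequency bin.

    Valid only for uniformly sampled, integer-period, noise-free segments.
    """
    n = len(t)
    k = int(round(f_hz * n * (t[1] - t[0])))
    coef = np.fft.rfft(y)[k]
    amplitude = 2.0 * np.abs(coef) / n
    phase = np.angle(coef) + np.pi / 2  # cos-phase -> sin-phase convention
    return amplitude, phase


class TestContactGeometry:
    @pytest.mark.parametrize(
        "radius, depth, expected_a",
        [(125.0, 20.0, 50.0), (57.0, 15.0, np.sqrt(855.0)), (57.0, 0.0, 0.0)],
    )
    def test_hertz_contact_radius(self, radius, depth, expected_a):
        assert mech.contact_radius(radius, depth) == pytest.approx(expected_a)

    def test_contact_area_hand_value(self):
        assert mech.contact_area(125.0, 20.0) == pytest.approx(7853.98, abs=0.01)

    def test_negative_depth_rejected(self):
        with pytest.raises(InvalidParameterError):
            mech.contact_radius(125.0, -1.0)

    @pytest.mark.parametrize(
        "load, radius, depth, pressure, strain",
        [
            (0.0, 125.0, 20.0, 0.0, 0.4),
            (0.3, 125.0, 20.0, 38.197, 0.4),
            (5.0, 125.0, 30.0, 424.413, np.sqrt(30.0 / 125.0)),
        ],
    )
    def test_trial_pressure_and_strain(self, load, radius, depth, pressure, strain):
        p, e = mech.trial_pressure_strain(load, radius, depth)
        assert p == pytest.approx(pressure, rel=1e-4)
        assert e == pytest.approx(strain, rel=1e-9)


class TestModuli:
    def fit(self, phase):
        return mech.OscillationFit(
            frequency_hz=1.0, f0_un=0.12, h0_um=0.3, phase_lag_rad=phase,
            mean_depth_um=15.0, residual_rms_un=0.0,
        )

    def test_hand_arithmetic(self):
        # F0/h0 = 0.4 N/m, phi = pi/3, a = 30 um
        area = np.pi * 30.0**2
        kp = mech.storage_modulus(self.fit(np.pi / 3), area)
        kpp = mech.loss_modulus(self.fit(np.pi / 3), area)
        assert kp == pytest.approx(3333.33, rel=1e-4)
        assert kpp == pytest.approx(5773.50, rel=1e-4)
        assert mech.loss_tangent(kp, kpp) == pytest.approx(np.tan(np.pi / 3), rel=1e-12)

    def test_pure_viscous_and_pure_elastic_limits(self):
        area = np.pi * 30.0**2
        assert mech.storage_modulus(self.fit(np.pi / 2), area) == pytest.approx(0.0, abs=1e-9)
        assert mech.loss_modulus(self.fit(0.0), area) == pytest.approx(0.0, abs=1e-12)

    def test_loss_tangent_degenerate(self):
        assert mech.loss_tangent(3.0, 0.0) == 0.0
        assert mech.loss_tangent(2.0, 2.0) == 1.0
        with pytest.raises(InvalidParameterError):
            mech.loss_tangent(0.0, 1.0)

    @given(
        stiffness=st.floats(0.01, 100.0),
        phase=st.floats(1e-3, np.pi / 2 - 1e-3),
        area=st.floats(10.0, 1e5),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_loss_tangent_equals_tan_phase(self, stiffness, phase, area):
        """K"/K' reduces to tan(phi) independently of stiffness and geometry."""
        fit = mech.OscillationFit(1.0, stiffness * 0.3, 0.3, phase, 15.0, 0.0)
        kp = mech.storage_modulus(fit, area)
        kpp = mech.loss_modulus(fit, area)
        assert mech.loss_tangent(kp, kpp) == pytest.approx(np.tan(phase), rel=1e-12)

    def test_amplitude_and_area_scaling(self):
        area = np.pi * 30.0**2
        base = self.fit(np.pi / 4)
        doubled = mech.OscillationFit(1.0, 0.24, 0.6, np.pi / 4, 15.0, 0.0)
        assert mech.storage_modulus(doubled, area) == pytest.approx(
            mech.storage_modulus(base, area), rel=1e-12
        )
        assert mech.storage_modulus(base, 2 * area) == pytest.approx(
            mech.storage_modulus(base, area) / np.sqrt(2), rel=1e-12
        )


class TestOscillationFit:
    def test_identity_case_scaled_load(self):
        t, depth, _ = make_oscillation(1.0, phase=0.0)
        load = 3.0 * (depth - 15.0) + 0.4
        fit = mech.fit_oscillation(t, depth, load, 1.0)
        assert fit.phase_lag_rad == pytest.approx(0.0, abs=1e-9)
        assert fit.f0_un / fit.h0_um == pytest.approx(3.0, rel=1e-9)

    @pytest.mark.parametrize("phase", [np.pi / 3, 0.1, 1.2])
    def test_known_phase_recovered(self, phase):
        t, depth, load = make_oscillation(2.0, phase=phase)
        fit = mech.fit_oscillation(t, depth, load, 2.0)
        assert fit.phase_lag_rad == pytest.approx(phase, rel=1e-6)
        assert fit.f0_un == pytest.approx(0.12, rel=1e-6)
        assert fit.h0_um == pytest.approx(0.3, rel=1e-6)

    def test_agrees_with_fft_bin_oracle(self):
        """Least-squares extraction == DFT bin on integer-period segments."""
        rng = np.random.default_rng(42)
        fs, n = 500.0, 1400
        for _ in range(25):
            k = int(rng.integers(3, 60))
            f = k * fs / n  # exactly k periods over the n-sample segment
            phase = rng.uniform(0.0, np.pi / 2)
            f0 = rng.uniform(0.01, 1.0)
            t, depth, load = make_oscillation(f, n_periods=k, fs_hz=fs, f0=f0, phase=phase)
            assert len(t) == n
            fit = mech.fit_oscillation(t, depth, load, f)
            amp_h, ph_h = fft_bin_fit(t, depth, f)
            amp_f, ph_f = fft_bin_fit(t, load, f)
            assert fit.h0_um == pytest.approx(amp_h, rel=1e-6)
            assert fit.f0_un == pytest.approx(amp_f, rel=1e-6)
            lag = np.angle(np.exp(1j * (ph_f - ph_h)))
            assert fit.phase_lag_rad == pytest.approx(lag, rel=1e-6, abs=1e-9)

    def test_short_segment_rejected(self):
        t, depth, load = make_oscillation(1.0, n_periods=2)
        with pytest.raises(InsufficientDataError):
            mech.fit_oscillation(t, depth, load, 1.0)

    def test_phase_noise_within_10_mrad(self):
        """5 nm deflection noise, 10 periods: phase recovered within 0.01 rad."""
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(50):
            t, depth, load = make_oscillation(1.0, n_periods=10, phase=0.3)
            noise = rng.normal(0, 0.005, len(t))
            fit = mech.fit_oscillation(t, depth - noise, load + 0.45 * noise, 1.0)
            errs.append(abs(fit.phase_lag_rad - 0.3))
        assert max(errs) < 0.01


class TestContactDetection:
    def test_flat_zero_load_raises(self):
        n = 2000
        trace = mech.IndentationTrace(
            time_s=np.arange(n) / 200.0,
            piezo_um=np.linspace(-4, 0, n),
            deflection_um=np.zeros(n),
            load_un=np.zeros(n),
            probe_radius_um=57.0,
            spring_constant_n_per_m=0.45,
            segment_labels=np.full(n, "approach", dtype=object),
        )
        with pytest.raises(NoContactError):
            mech.detect_contact_point(trace)

    def test_noise_free_contact_within_one_sample(self, clean_trace):
        t_c, _ = mech.detect_contact_point(clean_trace)
        truth = clean_trace.meta["contact_time_s"]
        assert abs(t_c - truth) <= 1.5 / clean_trace.fs_hz

    def test_refined_contact_under_load_noise(self, retina_tissue, sweep_protocol):
        """Hertz-regression refinement recovers contact within 0.5 s (1 um)
        at 0.01 uN load noise, where threshold crossing alone is ~2 s late."""
        errs = []
        for seed in range(20):
            tr = synth.simulate_indentation_trace(
                sweep_protocol, retina_tissue, 57.0, noise_sd_um=0.01 / 0.45, seed=seed
            )
            t_thr, _ = mech.detect_contact_point(tr)
            assert t_thr >= tr.meta["contact_time_s"] - 1.5 / tr.fs_hz  # never early
            errs.append(abs(mech.refine_contact_hertz(tr, t_thr) - tr.meta["contact_time_s"]))
        assert max(errs) < 0.5


class TestTraceAnalysis:
    def test_sls_closed_loop_noise_free(self, clean_trace, retina_tissue):
        vm = mech.analyze_trace(clean_trace)
        for f, kp, kpp in zip(vm.frequencies_hz, vm.k_storage_pa, vm.k_loss_pa):
            assert kp == pytest.approx(retina_tissue.k_storage(f), rel=0.01)
            assert kpp == pytest.approx(retina_tissue.k_loss(f), rel=0.01)

    def test_storage_modulus_monotone_in_frequency(self, clean_trace):
        vm = mech.analyze_trace(clean_trace)
        order = np.argsort(vm.frequencies_hz)
        ks = np.array(vm.k_storage_pa)[order]
        assert np.all(np.diff(ks) >= 0)

    def test_map_single_trace_gives_three_rows(self, retina_tissue, sweep_protocol):
        tr = synth.simulate_indentation_trace(
            sweep_protocol, retina_tissue, 57.0, seed=0, location_xy_um=(0.0, 0.0)
        )
        df = mech.build_indentation_map([tr])
        assert len(df) == 3
        assert set(df.columns) == {
            "x_um", "y_um", "freq_hz", "k_storage_pa", "k_loss_pa", "tan_phi"
        }

    def test_map_duplicate_location_rejected(self, retina_tissue, sweep_protocol):
        trs = [
            synth.simulate_indentation_trace(
                sweep_protocol, retina_tissue, 57.0, seed=s, location_xy_um=(0.0, 0.0)
            )
            for s in range(2)
        ]
        with pytest.raises(DuplicateLocationError):
            mech.build_indentation_map(trs)


class TestFrequencyStats:
    def _map(self, groups):
        rows = []
        for f, vals in groups.items():
            for v in vals:
                rows.append(
                    {"x_um": 0, "y_um": 0, "freq_hz": f,
                     "k_storage_pa": v, "k_loss_pa": v / 5, "tan_phi": 0.2}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_h_zero(self):
        df = self._map({0.1: [1.0] * 5, 1.0: [1.0] * 5, 10.0: [1.0] * 5})
        rep = mech.frequency_sweep_stats(df)
        assert rep["k_storage"]["kruskal_h"] == 0.0
        assert rep["k_storage"]["kruskal_p"] == 1.0

    def test_too_few_locations_rejected(self):
        df = self._map({0.1: [1.0, 2.0], 1.0: [1.0, 2.0, 3.0]})
        with pytest.raises(InsufficientDataError):
            mech.frequency_sweep_stats(df)

    def test_strong_alternative_detected(self):
        rng = np.random.default_rng(0)
        df = self._map(
            {f: rng.normal(m, 0.1 * m, 30) for f, m in ((0.1, 700), (1.0, 1200), (10.0, 1700))}
        )
        rep = mech.frequency_sweep_stats(df)
        assert rep["k_storage"]["kruskal_p"] < 0.0005
        assert rep["k_storage"]["significant"]["0.0005"]
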