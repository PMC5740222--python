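import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpetsim import (ML_PER_MIN, PEAK_FLOW_ML_MIN, InflowWaveform,
                     WaveformError, autoregulate, inflow_to_flux,
                     synthesize_inflow, territory_fluxes, default_waveforms)
from mpetsim.geometry import TERRITORIES


class TestSynthesis:
    @pytest.mark.parametrize("peak", [540.6, 77.3, 129.2, 449.9])
    def test_peak_calibration_exact(self, peak):
        w = synthesize_inflow(peak)
        assert w.peak_ml_min == pytest.approx(peak, rel=1e-3)
        assert (w.flows >= 0).all()
        assert (np.diff(w.times) > 0).all()

    def test_degenerate_mean_to_peak_one_is_constant(self):
        w = synthesize_inflow(300.0, mean_to_peak=1.0)
        assert np.all(w.flows == 300.0 * ML_PER_MIN)

    def test_cycle_mean_matches_request(self):
        w = synthesize_inflow(500.0, mean_to_peak=0.6, period=1.0,
                              n_cycles=4, samples_per_cycle=400)
        assert w.mean / w.peak == pytest.approx(0.6, rel=0.02)

    def test_infeasible_mean_rejected(self):
        with pytest.raises(WaveformError):
            synthesize_inflow(500.0, mean_to_peak=0.05)

    @pytest.mark.parametrize("peak, period", [(-1, 1), (0, 1), (100, 0)])
    def test_nonpositive_arguments_rejected(self, peak, period):
        with pytest.raises(WaveformError):
            synthesize_inflow(peak, period=period)

    def test_published_peaks_table(self):
        assert PEAK_FLOW_ML_MIN[("control", "high")]["ICA_L"] == 540.6
        assert PEAK_FLOW_ML_MIN[("control", "low")]["VA_L"] == 77.3
        assert PEAK_FLOW_ML_MIN[("mci", "high")]["ICA_R"] == 460.2
        ws = default_waveforms("control", "low")
        peaks = {w.territory: w.peak_ml_min for w in ws}
        assert peaks["ICA_L"] == pytest.approx(324.3, rel=1e-3)


class TestAutoregulation:
    def test_inactive_above_floor(self):
        w = synthesize_inflow(400.0, mean_to_peak=0.5)
        out = autoregulate(w, baseline_floor=0.5 * w.flows.min())
        assert np.abs(out.flows / w.flows - 1).max() < 1e-3

    def test_zero_input_recovers_floor(self):
        times = np.linspace(0, 60, 601)
        w = InflowWaveform("ICA_L", times, np.zeros_like(times))
        F = 2.0e-6
        out = autoregulate(w, baseline_floor=F, gain=1.0, tau=2.0)
        assert out.flows[-1] == pytest.approx(F, rel=1e-6)
        assert (out.flows >= F).all()

    def test_zero_gain_is_pointwise_clamp(self):
        w = synthesize_inflow(300.0, mean_to_peak=0.5)
        F = 0.8 * w.flows.max()
        out = autoregulate(w, baseline_floor=F, gain=0.0)
        assert np.array_equal(out.flows, np.maximum(w.flows, F))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(0.0, 5.0),
           st.floats(0.0, 10.0))
    def test_floor_invariant_for_any_input(self, seed, gain, tau):
        rng = np.random.default_rng(seed)
        times = np.linspace(0, 10, 101)
        flows = np.abs(rng.normal(2e-6, 2e-6, size=times.shape))
        w = InflowWaveform("VA_L", times, flows)
        F = 1.5e-6
        out = autoregulate(w, baseline_floor=F, gain=gain, tau=tau)
        assert (out.flows >= F - 1e-18).all()

    def test_negative_tau_rejected(self):
        w = synthesize_inflow(300.0)
        with pytest.raises(WaveformError):
            autoregulate(w, 0.0, tau=-1.0)


class TestBoundaryFlux:
    def test_flux_is_flow_over_area(self, shell_mesh):
        w = synthesize_inflow(600.0, territory="ICA_L")
        tf = inflow_to_flux(w, shell_mesh)
        t = 0.123
        assert tf.flux(t) * tf.area == pytest.approx(float(w(t)), rel=1e-14)

    def test_four_territory_conservation(self, shell_mesh):
        waves = default_waveforms("control", "high")
        fx = territory_fluxes(waves, shell_mesh)
        for t in (0.0, 0.3, 0.77):
            total_in = sum(tf.flux(t) * tf.area for tf in fx.values())
            total_q = sum(float(w(t)) for w in waves)
            assert total_in == pytest.approx(total_q, rel=1e-14)

    def test_unknown_territory_rejected(self, shell_mesh):
        w = synthesize_inflow(300.0, territory="ICA_L")
        w.territory = "AORTA"
        with pytest.raises(WaveformError):
            inflow_to_flux(w, shell_mesh)

    def test_missing_territory_rejected(self, shell_mesh):
        waves = default_waveforms("control", "high")[:3]
        with pytest.raises(WaveformError, match="missing"):
            territory_fluxes(waves, shell_mesh)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        w = synthesize_inflow(444.0, territory="VA_R", activity="low")
        f = tmp_path / "va_r.csv"
        w.to_csv(f)
        w2 = InflowWaveform.from_csv(f, "VA_R", activity="low")
        assert np.allclose(w2.flows, w.flows)
        assert np.allclose(w2.times, w.times)

    def test_missing_column_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("time_s,flow\n0,1\n")
        with pytest.raises(WaveformError):
            InflowWaveform.from_csv(f, "ICA_L")
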