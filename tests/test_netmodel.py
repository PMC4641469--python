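"""Rate-network model: transfers, depressing drive, dynamics, dissociation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oddball.netmodel import (CoupledModelParams, DepressionParams,
                              PairwiseModelParams, ToneTrainProtocol,
                              clamp_transfer, pv_transfer,
                              run_coupled_experiment, run_pairwise_experiment,
                              simulate_coupled, simulate_pairwise,
                              som_transfer, summarize_model_effects,
                              thalamic_drive)


class TestTransfers:
    def test_clamp_identity_inside_range(self):
        assert clamp_transfer(0.5, -1.0, 1.75) == 0.5

    def test_clamp_limits(self):
        assert clamp_transfer(5.0, -1.0, 1.75) == 1.75
        assert clamp_transfer(-2.0, -1.0, 1.75) == -1.0

    def test_clamp_bad_limits_rejected(self):
        with pytest.raises(ValueError):
            clamp_transfer(0.0, 1.0, 1.0)

    def test_pv_logistic_values(self):
        assert pv_transfer(9.0) == 0.5  # midpoint at theta
        assert pv_transfer(0.0) == pytest.approx(1 / (1 + np.exp(2.7)),
                                                 rel=1e-9)
        assert pv_transfer(1e4) == pytest.approx(1.0)

    def test_som_tanh_values(self):
        assert som_transfer(0.0) == 0.0
        assert som_transfer(3.0) == pytest.approx(np.tanh(1.0))
        assert som_transfer(1e4) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(-100, 100))
    def test_transfer_ranges(self, r):
        assert 0.0 < pv_transfer(r) < 1.0
        if r >= 0:
            # mathematically < 1; float64 saturates to exactly 1 for large r
            assert 0.0 <= som_transfer(r) <= 1.0


class TestThalamicDrive:
    def test_quiescent_conductance_stays_full(self):
        proto = ToneTrainProtocol(pre_ms=300.0)
        times, drive, g = thalamic_drive(proto, dt=0.1)
        pre = times < 300.0
        assert np.all(drive[pre] == 0.0)
        assert np.allclose(g[pre], 1.0)

    def test_constant_gate_fixed_point_closed_form(self):
        """g* = (1/Tg) / (1/Tg + r/Tr) = 0.00881 for r = 3."""
        dep = DepressionParams()
        assert dep.steady_state(3.0) == pytest.approx(0.00881, abs=2e-5)
        # independent check: Euler integration under a held gate
        g, dt = 1.0, 0.05
        for _ in range(int(30000 / dt)):
            g += dt * ((1.0 - g) / 3000.0 - g * 3.0 / 80.0)
        assert g == pytest.approx(dep.steady_state(3.0), rel=1e-3)

    def test_adaptation_of_tone_peaks(self):
        proto = ToneTrainProtocol()
        times, drive, g = thalamic_drive(proto, dt=0.1)
        peaks = [drive[(times >= on) & (times < on + 400)].max()
                 for on in proto.onsets]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))
        assert peaks[3] < peaks[0]

    def test_conductance_bounded(self):
        times, drive, g = thalamic_drive(ToneTrainProtocol(n_tones=8), dt=0.1)
        assert np.all(g > 0.0) and np.all(g <= 1.0)

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            thalamic_drive(ToneTrainProtocol(), dt=0.0)
        with pytest.raises(ValueError):
            thalamic_drive(ToneTrainProtocol(), dt=2.0)


class TestPairwiseDynamics:
    def test_no_input_stays_at_fixed_point(self):
        params = PairwiseModelParams.pv()
        proto = ToneTrainProtocol(n_tones=1, pre_ms=400.0)
        tr = simulate_pairwise(params, proto, dt=0.1)
        pre = tr.times < 350.0
        assert np.ptp(tr["E"][pre]) < 1e-6
        assert np.ptp(tr["I"][pre]) < 1e-6

    def test_excitatory_adaptation_across_tones(self):
        tr = simulate_pairwise(PairwiseModelParams.pv(), ToneTrainProtocol(),
                               dt=0.1)
        base = tr["E"][tr.times < 150].mean()
        peaks = [max(tr["E"][(tr.times >= on) & (tr.times < on + 150)]) - base
                 for on in tr.protocol.onsets]
        assert peaks[3] < peaks[0]

    def test_dt_halving_convergence(self):
        proto = ToneTrainProtocol(light_tone=4)
        a = simulate_pairwise(PairwiseModelParams.pv(), proto, dt=0.1)
        b = simulate_pairwise(PairwiseModelParams.pv(), proto, dt=0.05)
        eb = b["E"][::2][:a["E"].size]
        scale = np.abs(a["E"]).max()
        assert np.abs(a["E"] - eb).max() / scale < 1e-3


class TestCoupledDynamics:
    def test_som_activity_never_negative(self):
        tr = simulate_coupled(CoupledModelParams(), ToneTrainProtocol(),
                              dt=0.1, light_target="none")
        assert tr["SOM"].min() >= -1e-9

    def test_light_target_none_matches_no_light(self):
        p = CoupledModelParams()
        a = simulate_coupled(p, ToneTrainProtocol(light_tone=None), 0.1, "none")
        b = simulate_coupled(p, ToneTrainProtocol(light_tone=4), 0.1, "none")
        assert np.array_equal(a["E"], b["E"])

    def test_pv_suppressed_during_pv_light(self):
        p = CoupledModelParams()
        off = simulate_coupled(p, ToneTrainProtocol(light_tone=None), 0.1, "none")
        on = simulate_coupled(p, ToneTrainProtocol(light_tone=4), 0.1, "PV")
        win = off.protocol.light_window() or (1300, 1550)
        proto = ToneTrainProtocol(light_tone=4)
        lo, hi = proto.light_window()
        m = (off.times >= lo) & (off.times < lo + 90)  # pre-tone light span
        assert on["PV"][m].mean() < off["PV"][m].mean()

    def test_bad_light_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_coupled(CoupledModelParams(), ToneTrainProtocol(), 0.1,
                             light_target="VIP")


class TestSummaries:
    def test_off_deviant_peak_normalized_to_one(self):
        tr = simulate_pairwise(PairwiseModelParams.pv(), ToneTrainProtocol(),
                               dt=0.1)
        s = summarize_model_effects(tr, tr, tr)
        assert s["deviant_off"] == 1.0
        assert s["delta_deviant"] == 0.0  # off traces used as on: null light

    def test_pairwise_dissociation(self):
        pv = run_pairwise_experiment("PV", dt=0.1)
        som = run_pairwise_experiment("SOM", dt=0.1)
        assert pv["delta_standard"] > 0 and pv["delta_deviant"] > 0
        assert (0.5 <= pv["delta_deviant"] / pv["delta_standard"] <= 2.0)
        assert som["delta_standard"] > 0
        assert abs(som["delta_deviant"]) < 0.2 * som["delta_standard"]

    def test_coupled_dissociation_with_and_without_som_to_pv(self):
        for include in (True, False):
            p = CoupledModelParams(include_som_to_pv=include)
            pv = run_coupled_experiment("PV", dt=0.1, params=p)
            som = run_coupled_experiment("SOM", dt=0.1, params=p)
            assert pv["delta_standard"] > 0 and pv["delta_deviant"] > 0
            assert 0.5 <= pv["delta_deviant"] / pv["delta_standard"] <= 2.0
            assert som["delta_standard"] > 0
            assert abs(som["delta_deviant"]) < 0.2 * som["delta_standard"]
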