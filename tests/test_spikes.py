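"""Spike-train statistics: windows, PSTH, SSA index, inclusion, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oddball import (attach_light_schedule, build_oddball_pair, make_scenario,
                     simulate_spike_trains)
from oddball.scenarios import ScenarioRates
from oddball.spikes import (_positions_relative, _signed_rank_one_sided,
                            apply_inclusion_criteria, count_tone_windows,
                            evoked_rate, light_effect_summary, matched_subsets,
                            normalization_reference, percent_change_of_means,
                            pool_strong_weak, post_event_timecourse, psth,
                            ssa_index, ssa_summary)


class TestEvokedRate:
    def test_counts_only_inside_half_open_window(self):
        assert evoked_rate([5, 20, 60], 0, 50) == 40.0  # 2 spikes / 50 ms
        assert evoked_rate([5, 20, 60], 0, 100) == 30.0  # interneuron window
        assert evoked_rate([], 0, 50) == 0.0

    def test_boundary_spike_belongs_to_later_window(self):
        assert evoked_rate([50.0], 0, 50) == 0.0
        assert evoked_rate([50.0], 50, 50) == 20.0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            evoked_rate([1.0], 0, 0)


class TestPsth:
    def test_single_spike_single_trial(self):
        edges, rates = psth([[12.0]], bin_ms=5, t_range=(0, 50))
        assert rates[2] == 200.0  # 1 spike / 5 ms
        assert rates.sum() == 200.0

    def test_uniform_rate_recovered(self):
        rng = np.random.default_rng(0)
        r_hz, n_trials = 80.0, 4000
        trials = [np.sort(rng.uniform(0, 50, rng.poisson(r_hz * 0.05)))
                  for _ in range(n_trials)]
        _, rates = psth(trials, bin_ms=5, t_range=(0, 50))
        se = np.sqrt(r_hz / (n_trials * 0.005))
        assert np.all(np.abs(rates - r_hz) < 3 * se)

    def test_empty_input_gives_zeros(self):
        _, rates = psth([], bin_ms=5, t_range=(0, 50))
        assert np.all(rates == 0) and rates.size == 10

    def test_indivisible_bin_rejected(self):
        with pytest.raises(ValueError):
            psth([[1.0]], bin_ms=7, t_range=(0, 50))


class TestSSAIndex:
    def test_complete_adaptation_is_one(self):
        assert ssa_index(5, 5, 0, 0) == 1.0

    def test_no_adaptation_is_zero(self):
        assert ssa_index(7, 3, 7, 3) == 0.0

    def test_arithmetic_example(self):
        assert ssa_index(10, 8, 5, 4) == pytest.approx(9 / 27)

    def test_all_zero_rates_flagged_undefined(self):
        assert np.isnan(ssa_index(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1e3), min_size=4, max_size=4))
    def test_bounded_and_antisymmetric(self, rates):
        d_a, d_b, s_a, s_b = rates
        v = ssa_index(d_a, d_b, s_a, s_b)
        if np.isnan(v):
            return
        assert -1.0 <= v <= 1.0
        assert ssa_index(s_a, s_b, d_a, d_b) == pytest.approx(-v, abs=1e-12)


class TestInclusionCriteria:
    def test_responsive_pv_neurons_included(self, pv_flat_counts):
        inc = apply_inclusion_criteria(pv_flat_counts)
        # deviant 10 Hz vs spontaneous 2 Hz over ~200 trials: ample power
        assert inc["included"].all()
        assert inc["included_both"].all()

    def test_silent_neuron_excluded(self, oddball_pair, light):
        silent = ScenarioRates(name="control", table={
            "spontaneous": (0.0, 0.0), "standard": (0.0, 0.0),
            "deviant": (0.0, 0.0), "equal": (0.0, 0.0)})
        sts = simulate_spike_trains(silent, oddball_pair, light, 3, 4, seed=0)
        inc = apply_inclusion_criteria(count_tone_windows(sts))
        assert not inc["included"].any()
        assert inc["reason"].str.contains("Hz").all()

    def test_null_neuron_rejection_rate_controlled(self):
        """Deviant rate == spontaneous: criterion (i) rejects at <= alpha."""
        rng = np.random.default_rng(1)
        n_sim, n_trials, hits = 400, 200, 0
        for _ in range(n_sim):
            ev = rng.poisson(0.5, n_trials)
            sp = rng.poisson(0.5, n_trials)
            hits += _signed_rank_one_sided(ev, sp) < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert hits / n_sim <= 0.05 + 3 * se


class TestNormalization:
    def test_self_normalization_is_one(self, pv_flat_spikes, pv_flat_counts):
        refs = normalization_reference(pv_flat_spikes, pv_flat_counts,
                                       reference="mean_deviant_off")
        from oddball.spikes import mean_rate
        for tone in ("A", "B"):
            rates = mean_rate(pv_flat_counts, tone=tone, condition="deviant",
                              light=False)
            sub = refs[refs["tone"] == tone].sort_values("neuron")
            assert np.allclose(sub["reference_hz"].to_numpy(), rates)

    def test_peak_reference_at_least_mean(self, pv_flat_spikes, pv_flat_counts):
        peak = normalization_reference(pv_flat_spikes, pv_flat_counts,
                                       reference="max_5ms_bin_deviant_off")
        mean = normalization_reference(pv_flat_spikes, pv_flat_counts,
                                       reference="mean_deviant_off")
        assert np.all(peak["reference_hz"].to_numpy()
                      >= mean["reference_hz"].to_numpy() - 1e-9)

    def test_unknown_reference_rejected(self, pv_flat_spikes, pv_flat_counts):
        with pytest.raises(ValueError):
            normalization_reference(pv_flat_spikes, pv_flat_counts,
                                    reference="median")

    def test_percent_change_invariant_to_reference(self, pv_flat_spikes,
                                                   pv_flat_counts):
        """Scale invariance: both references give the same percent changes
        up to the unit weighting they induce (exact for this homogeneous
        population within Monte-Carlo error)."""
        a = light_effect_summary(pv_flat_counts, pv_flat_spikes,
                                 reference="max_5ms_bin_deviant_off")
        b = light_effect_summary(pv_flat_counts, pv_flat_spikes,
                                 reference="mean_deviant_off")
        for cond in ("spontaneous", "standard", "deviant"):
            pa = a.table.loc[cond, "pct_change"]
            pb = b.table.loc[cond, "pct_change"]
            assert pa == pytest.approx(pb, abs=6.0)


class TestLightEffectSummary:
    def test_pv_flat_recovers_table_percent_changes(self, pv_flat_counts,
                                                    pv_flat_spikes):
        les = light_effect_summary(pv_flat_counts, pv_flat_spikes)
        expected = {"spontaneous": 185.0, "standard": 102.0, "deviant": 56.0}
        for cond, pct in expected.items():
            assert les.table.loc[cond, "pct_change"] == pytest.approx(pct,
                                                                      abs=12)
        assert (les.table["difference"]
                == les.table["mean_on"] - les.table["mean_off"]).all()

    def test_empty_population_rejected(self, pv_flat_counts, pv_flat_spikes):
        empty = pd.DataFrame({"neuron": [], "tone": [], "included": []})
        with pytest.raises(ValueError):
            light_effect_summary(pv_flat_counts, pv_flat_spikes, empty)


class TestSSASummary:
    def test_population_index_matches_table(self, pv_flat_counts):
        ssa = ssa_summary(pv_flat_counts)
        # table-implied: off (10-5.42)/15.42, on (15.6-10.95)/26.55
        assert ssa.population.loc[False, "mean_index"] == pytest.approx(
            0.2970, abs=0.02)
        assert ssa.population.loc[True, "mean_index"] == pytest.approx(
            0.1751, abs=0.04)
        assert ssa.per_neuron["index"].between(-1, 1).all()


class TestTimecourse:
    def test_position_bookkeeping_on_handmade_sequence(self):
        """Hand-enumerated positions on a tiny role pattern."""
        roles = np.array(["standard"] * 4 + ["deviant"] + ["standard"] * 6)
        lit = np.zeros(11, dtype=bool)
        lit[4] = True  # the deviant is lit; following standards still count
        pos = _positions_relative(roles, lit, "deviant")
        assert list(pos[0]) == [4]
        assert list(pos[-1]) == [3]
        assert list(pos[1]) == [5] and list(pos[4]) == [8]
        # now light a standard: its successor is excluded
        lit2 = np.zeros(11, dtype=bool)
        lit2[5] = True  # first post-deviant standard lit
        pos2 = _positions_relative(roles, lit2, "deviant")
        assert 6 not in pos2.get(2, [])

    def test_flat_scenario_ratios_are_unity(self, pv_flat_counts):
        df = post_event_timecourse(pv_flat_counts, event="deviant")
        std_off = df[(df["position"] > 0) & (~df["light"])]
        assert np.allclose(std_off["norm"], 1.0, atol=0.09)

    def test_dynamic_t1_elevation(self, oddball_pair, light):
        sts = simulate_spike_trains(make_scenario("PV", "dynamic"),
                                    oddball_pair, light, 40, 4, seed=21)
        df = post_event_timecourse(count_tone_windows(sts), event="deviant")
        t1 = df[(df["position"] == 1) & (~df["light"])]["norm"].iloc[0]
        t3 = df[(df["position"] == 3) & (~df["light"])]["norm"].iloc[0]
        assert t1 == pytest.approx(1.60, abs=0.08)
        assert t3 == pytest.approx(1.00, abs=0.06)

    def test_light_event_positions(self, pv_flat_counts):
        df = post_event_timecourse(pv_flat_counts, event="light")
        t0 = df[(df["position"] == 0) & (df["light"])]
        t3 = df[(df["position"] == 3) & (~df["light"])]
        # lit standards respond at the light-on rate, T3 at the off rate
        assert t0["norm"].iloc[0] == pytest.approx(10.95 / 5.42, abs=0.15)
        assert t3["norm"].iloc[0] == pytest.approx(1.0, abs=0.05)


class TestMatchedSubsets:
    def test_identical_groups_fully_matched(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        i1, i2, msg = matched_subsets(x, x.copy())
        assert len(i1) == len(i2) == 4
        assert "full groups" in msg

    def test_disjoint_ranges_give_empty_subsets(self):
        i1, i2, msg = matched_subsets(np.arange(5.0), np.arange(100.0, 105.0))
        assert i1.size == 0 and i2.size == 0
        assert "overlap" in msg

    def test_overlapping_gaussians_matched_within_tolerance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 3, 200)
        b = rng.normal(12, 3, 250)
        i1, i2, _ = matched_subsets(a, b, tol=0.05)
        assert i1.size >= 20
        scale = np.mean(np.abs(np.concatenate([a, b])))
        assert abs(a[i1].mean() - b[i2].mean()) <= 0.05 * scale
        assert abs(a[i1].std() - b[i2].std()) <= 0.05 * scale


class TestStrongWeakPooling:
    def test_pooling_and_tie_break(self):
        peaks = pd.DataFrame({
            "neuron": [0, 0, 1, 1, 2],
            "tone": ["A", "B", "A", "B", "A"],
            "peak_hz": [12.0, 8.0, 6.0, 6.0, 9.0],
        })
        out = pool_strong_weak(peaks)
        assert len(out) == 2  # neuron 2 lacks tone B -> skipped
        assert out.set_index("neuron").loc[0, "strong_tone"] == "A"
        assert out.set_index("neuron").loc[1, "strong_tone"] == "A"  # tie -> A

    def test_symmetric_scenario_pools_balance(self, pv_flat_spikes,
                                              pv_flat_counts):
        refs = normalization_reference(pv_flat_spikes, pv_flat_counts)
        refs = refs.rename(columns={"reference_hz": "peak_hz"})
        out = pool_strong_weak(refs)
        # generator is tone-symmetric: neither tone dominates strongly
        frac_a = (out["strong_tone"] == "A").mean()
        assert 0.1 <= frac_a <= 0.9


def test_percent_change_of_means_exact_proportionality():
    off = np.array([1.0, 2.0, 3.0, 4.0])
    pct, se = percent_change_of_means(2 * off, off)
    assert pct == pytest.approx(100.0)
    assert se == pytest.approx(0.0, abs=1e-9)
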