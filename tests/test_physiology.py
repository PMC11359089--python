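"""STP event model, spatial scaling, stimulus battery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synaptome_sd as sd
from synaptome_sd.physiology import (FACILITATION_CAP, GRID_SHAPE,
                                     normalize_size_profiles)


def brute_force_amplitudes(times, params, scale=None):
    """Independent oracle: explicit loop over all preceding-spike pairs."""
    scale = scale or sd.ScaleFactors()
    a_d = params.a_d0 * scale.s_ad
    tau_d = params.tau_d0 * scale.s_td
    a_f = params.a_f0 * scale.s_af
    tau_f = params.tau_f0 * scale.s_tf
    out = []
    for k, t_k in enumerate(times):
        dep = fac = 0.0
        for i in range(k):
            dt = t_k - times[i]
            if tau_d > 0:
                dep += a_d * np.exp(-dt / tau_d)
            if tau_f > 0:
                fac += a_f * np.exp(-dt / tau_f)
            fac += params.a_s0 * np.exp(-dt / params.tau_s0)
        a_td = max(1.0 - dep, 0.0)
        a_tf = min(1.0 + fac, params.cap)
        out.append(a_tf * a_td)
    return np.array(out)


def random_train(rng, max_events=30):
    n = rng.integers(1, max_events)
    return np.cumsum(rng.uniform(0.5, 80.0, n))


def random_params(rng):
    return sd.STPParams(
        a_d0=rng.uniform(0, 0.8), tau_d0=rng.uniform(20, 800),
        a_f0=rng.uniform(0, 0.8), tau_f0=rng.uniform(10, 300),
        a_s0=rng.uniform(0, 0.3), tau_s0=rng.uniform(100, 2000))


# ---------------------------------------------------------------------------
# EPSP kernel
# ---------------------------------------------------------------------------

class TestEpspKernel:
    def test_zero_at_origin_and_at_infinity(self):
        p = sd.STPParams()
        assert sd.epsp_kernel(0.0, p) == 0.0
        assert sd.epsp_kernel(1e5, p) == pytest.approx(0.0, abs=1e-12)

    def test_peak_time_matches_closed_form_and_grid_search(self):
        p = sd.STPParams()
        t_star = sd.epsp_peak_time(p)
        assert t_star == pytest.approx(0.930, abs=1e-3)
        grid = np.linspace(0, 20, 200001)
        assert grid[np.argmax(sd.epsp_kernel(grid, p))] == pytest.approx(
            t_star, abs=1e-3)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            sd.STPParams(tau1=0.4, tau2=3.0)
        with pytest.raises(ValueError):
            sd.epsp_kernel(-1.0, sd.STPParams())


# ---------------------------------------------------------------------------
# Event amplitudes
# ---------------------------------------------------------------------------

class TestSimulateAmplitudes:
    def test_single_spike_is_unit(self):
        series = sd.simulate_amplitudes(sd.SpikeTrain("x", np.array([5.0])))
        assert series.a_e.tolist() == [1.0]

    def test_depression_only_is_non_increasing(self):
        p = sd.STPParams(a_d0=0.4, a_f0=0.0, a_s0=0.0)
        series = sd.simulate_amplitudes(
            sd.SpikeTrain("x", np.arange(20) * 10.0), p)
        assert np.all(np.diff(series.a_e) <= 0)

    def test_facilitation_saturates_exactly_at_cap(self):
        p = sd.STPParams(a_d0=0.0, a_f0=0.5, a_s0=0.5)
        series = sd.simulate_amplitudes(
            sd.SpikeTrain("x", np.arange(100) * 1.0), p)
        assert series.a_tf.max() == FACILITATION_CAP

    def test_matches_brute_force_oracle_on_random_trains(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            times = random_train(rng)
            params = random_params(rng)
            scale = sd.ScaleFactors(*rng.uniform(0.05, 1.0, 4))
            got = sd.simulate_amplitudes(
                sd.SpikeTrain("r", times), params, scale).a_e
            want = brute_force_amplitudes(times, params, scale)
            assert np.allclose(got, want, atol=1e-12, rtol=0)

    def test_isolated_spike_recovers_to_unit(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            params = random_params(rng)
            base = random_train(rng)
            gap = 60.0 * max(params.tau_d0, params.tau_f0, params.tau_s0)
            times = np.append(base, base[-1] + gap)
            series = sd.simulate_amplitudes(sd.SpikeTrain("r", times), params)
            assert series.a_e[-1] == pytest.approx(1.0, abs=1e-6)

    @given(a_d0=st.floats(0, 0.9), bump=st.floats(0.01, 0.5))
    @settings(max_examples=40, derandomize=True)
    def test_stronger_depression_never_raises_amplitudes(self, a_d0, bump):
        times = sd.SpikeTrain("x", np.arange(12) * 15.0)
        lo = sd.simulate_amplitudes(times, sd.STPParams(a_d0=a_d0)).a_e
        hi = sd.simulate_amplitudes(
            times, sd.STPParams(a_d0=min(a_d0 + bump, 1.0))).a_e
        assert np.all(hi <= lo + 1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_bounds_hold_for_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        series = sd.simulate_amplitudes(
            sd.SpikeTrain("r", random_train(rng)), random_params(rng))
        assert np.all(series.a_td >= 0) and np.all(series.a_td <= 1)
        assert np.all(series.a_tf >= 1) and np.all(series.a_tf <= FACILITATION_CAP)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            sd.SpikeTrain("x", np.array([0.0, 5.0, 5.0]))


class TestSimulateTrace:
    def test_trace_decays_after_last_event(self):
        train = sd.SpikeTrain("x", np.array([0.0, 10.0]))
        t, v = sd.simulate_trace(train, dt=0.1, pad=60.0)
        peak = np.abs(v).max()
        assert abs(v[-1]) < 1e-3 * peak

    def test_single_spike_peaks_at_kernel_argmax(self):
        p = sd.STPParams()
        train = sd.SpikeTrain("x", np.array([7.0]))
        t, v = sd.simulate_trace(train, p, dt=0.01)
        assert t[np.argmax(v)] == pytest.approx(7.0 + sd.epsp_peak_time(p),
                                                abs=0.01)

    def test_linearity_in_event_amplitudes(self):
        # with doubled per-event amplitudes the trace doubles; emulate by
        # comparing a no-STP train against itself summed twice
        train = sd.SpikeTrain("x", np.array([0.0, 30.0, 60.0]))
        p = sd.STPParams(a_d0=0.0, a_f0=0.0, a_s0=0.0)
        t, v = sd.simulate_trace(train, p, dt=0.5)
        assert np.allclose(2 * v, v + v)


# ---------------------------------------------------------------------------
# Spatial normalization and grids
# ---------------------------------------------------------------------------

def two_group_profiles(span_a=2.0, span_b=4.0):
    base = np.full((4, 4), 10.0)
    ramp_a = np.tile(np.linspace(0, span_a, 4)[None, :], (4, 1))
    ramp_b = np.tile(np.linspace(0, span_b, 4)[None, :], (4, 1))
    col = np.tile(np.linspace(0, 1.0, 4)[:, None], (1, 4))
    return {
        "A": {"psd95": base + ramp_a + col, "sap102": base + ramp_a + col},
        "B": {"psd95": base + ramp_b + col, "sap102": base + ramp_b + col},
    }


class TestNormalizeSizeProfiles:
    def test_hand_example_spans_two_and_four(self):
        factors = normalize_size_profiles(two_group_profiles(2.0, 4.0))
        assert factors["A"][("psd95", "radial")] == pytest.approx(0.0)
        assert factors["B"][("psd95", "radial")] == pytest.approx(0.5)

    def test_identical_groups_all_zero(self):
        prof = two_group_profiles(3.0, 3.0)
        factors = normalize_size_profiles(prof)
        for g in prof:
            assert all(v == pytest.approx(0.0) for v in factors[g].values())

    def test_factors_bounded_on_random_profiles(self):
        rng = np.random.default_rng(200)
        for _ in range(50):
            prof = {
                g: {p: rng.uniform(0.5, 2.0, (4, 4)) for p in ("psd95", "sap102")}
                for g in ("ZT6", "ZT6SD", "ZT11")
            }
            factors = normalize_size_profiles(prof)
            for g in prof:
                assert all(0.0 <= v <= 1.0 for v in factors[g].values())

    def test_zero_span_everywhere_rejected(self):
        flat = {g: {"psd95": np.full((4, 4), 1.0), "sap102": np.full((4, 4), 1.0)}
                for g in ("A", "B")}
        with pytest.raises(ValueError, match="degenerate"):
            normalize_size_profiles(flat)


class TestBuildGrid:
    def test_grid_has_121_synapses(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        assert grid.shape == GRID_SHAPE
        assert grid.n_synapses == 121

    def test_identical_group_profiles_give_identical_grids(self, profiles):
        mats = {g: profiles.group_matrices["ZT6"] for g in ("ZT6", "ZT6SD")}
        same = sd.SpatialSizeProfiles(group_matrices=mats,
                                      baselines=profiles.baselines)
        g1, g2 = sd.build_grid(same, "ZT6"), sd.build_grid(same, "ZT6SD")
        for name in ("s_ad", "s_td", "s_af", "s_tf"):
            assert np.array_equal(getattr(g1, name), getattr(g2, name))

    def test_uniform_baseline_gives_uniform_grid(self, profiles):
        flat = sd.SpatialSizeProfiles(
            group_matrices=profiles.group_matrices,
            baselines={p: np.full(GRID_SHAPE, 0.8) for p in ("psd95", "sap102")})
        grid = sd.build_grid(flat, "ZT6SD")
        for name in ("s_ad", "s_td", "s_af", "s_tf"):
            arr = getattr(grid, name)
            assert np.ptp(arr) == 0.0

    def test_missing_group_rejected(self, profiles):
        with pytest.raises(KeyError):
            sd.build_grid(profiles, "ZT99")


# ---------------------------------------------------------------------------
# Stimuli, response maps, battery
# ---------------------------------------------------------------------------

class TestBuildStimulus:
    def test_theta_train_default(self):
        train = sd.build_stimulus("theta_train")
        assert len(train) == 10
        assert np.allclose(np.diff(train.times), 200.0)

    def test_ripple_is_faster_than_gamma(self):
        swr = np.diff(sd.build_stimulus("sharp_wave_ripple").times).min()
        gamma = np.diff(sd.build_stimulus("gamma_train").times).min()
        assert swr < gamma

    @pytest.mark.parametrize("name", sd.PATTERN_NAMES)
    def test_all_patterns_strictly_increasing(self, name):
        times = sd.build_stimulus(name).times
        assert np.all(np.diff(times) > 0)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(KeyError):
            sd.build_stimulus("delta_wave")


class TestSimulateGridAndCompare:
    def test_single_spike_map_is_all_ones(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        train = sd.SpikeTrain("single", np.array([0.0]))
        out = sd.simulate_grid(grid, train)
        assert np.allclose(out.values, 1.0)
        assert out.n == 121

    def test_uniform_grid_gives_constant_map(self):
        ones = np.ones(GRID_SHAPE)
        grid = sd.SynapseGrid("u", 0.7 * ones, 0.7 * ones, 0.7 * ones, 0.7 * ones)
        out = sd.simulate_grid(grid, sd.build_stimulus("gamma_train"))
        assert np.ptp(out.values) == pytest.approx(0.0, abs=1e-12)

    def test_depression_only_sum_below_event_count(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        p = sd.STPParams(a_d0=0.4, a_f0=0.0, a_s0=0.0)
        out = sd.simulate_grid(grid, sd.build_stimulus("theta_train"), p)
        assert np.all(out.values < 10.0)

    def test_compare_identical_maps(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        m = sd.simulate_grid(grid, sd.build_stimulus("theta_burst"))
        metrics = sd.compare_maps(m, m)
        assert metrics["ed_spatial"] == 0.0
        assert metrics["ed_intensity"] == 0.0
        assert metrics["ks_stat"] == 0.0
        assert metrics["ks_p"] == 1.0
        assert metrics["n"] == 121

    def test_scaled_map_has_zero_spatial_distance(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        m = sd.simulate_grid(grid, sd.build_stimulus("gamma_burst"))
        doubled = sd.ResponseMap(m.group, m.pattern, 2 * m.values)
        metrics = sd.compare_maps(m, doubled)
        assert metrics["ed_spatial"] == pytest.approx(0.0, abs=1e-9)
        assert metrics["ed_intensity"] > 0

    def test_dimension_mismatch_rejected(self):
        a = sd.ResponseMap("a", "p", np.ones((11, 11)))
        b = sd.ResponseMap("b", "p", np.ones((4, 4)))
        with pytest.raises(ValueError):
            sd.compare_maps(a, b)


class TestPatternBattery:
    def test_default_battery_corrects_five_tests(self, profiles):
        table = sd.run_pattern_battery(
            sd.build_grid(profiles, "ZT6SD"), sd.build_grid(profiles, "ZT6"))
        assert len(table) == 5
        assert set(table["pattern"]) == set(sd.PATTERN_NAMES)
        assert np.allclose(
            table["ks_p_adj"],
            np.asarray(sd.bh_adjust(table["ks_p"].to_numpy())))

    def test_identical_grids_yield_no_significant_pattern(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        table = sd.run_pattern_battery(grid, grid)
        assert (table["ks_p_adj"] < 0.05).sum() == 0
        assert np.allclose(table["ed_intensity"], 0.0)

    def test_psd95_only_difference_is_detected(self, profiles):
        g_ctrl = sd.build_grid(profiles, "ZT6")
        g_alt = sd.SynapseGrid(
            "alt", np.clip(g_ctrl.s_ad * 0.6, 0, 1),
            np.clip(g_ctrl.s_td * 0.6, 0, 1), g_ctrl.s_af, g_ctrl.s_tf)
        table = sd.run_pattern_battery(g_alt, g_ctrl)
        assert (table["ed_intensity"] > 0).any()

    def test_battery_is_bit_reproducible(self, profiles):
        ga, gb = sd.build_grid(profiles, "ZT6SD"), sd.build_grid(profiles, "ZT6")
        t1 = sd.run_pattern_battery(ga, gb)
        t2 = sd.run_pattern_battery(ga, gb)
        assert t1.equals(t2)

    def test_empty_pattern_list_rejected(self, profiles):
        grid = sd.build_grid(profiles, "ZT6")
        with pytest.raises(ValueError):
            sd.run_pattern_battery(grid, grid, patterns=[])
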