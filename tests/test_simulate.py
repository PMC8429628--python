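import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autobilayer.errors import InvalidParameterError
from autobilayer.simulate import (
    AcquisitionStream,
    AcquisitionStreamSpec,
    ChannelScenario,
    NoiseSpec,
    draw_dwell_sequence,
    list_presets,
    load_preset,
    render_trace,
    sample_channel_count,
    simulate_gating,
)


def ztp_pmf(k: int, lam: float) -> float:
    """Independent oracle: zero-truncated Poisson pmf by direct evaluation."""
    return (lam ** k * math.exp(-lam) / math.factorial(k)) / (1.0 - math.exp(-lam))


class TestDwellSequence:
    def test_zero_duration_empty(self):
        assert draw_dwell_sequence(50.0, 50.0, 0.0, 0) == []

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            draw_dwell_sequence(0.0, 50.0, 1.0, 0)
        with pytest.raises(InvalidParameterError):
            draw_dwell_sequence(50.0, -1.0, 1.0, 0)
        with pytest.raises(InvalidParameterError):
            draw_dwell_sequence(50.0, 50.0, -1.0, 0)

    def test_alternating_states(self):
        dwells = draw_dwell_sequence(50.0, 50.0, 10.0, 1)
        states = [s for s, _ in dwells]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert all(d > 0 for _, d in dwells)

    def test_covers_duration(self):
        dwells = draw_dwell_sequence(20.0, 80.0, 5.0, 7)
        assert sum(d for _, d in dwells) >= 5.0

    def test_fraction_open_converges(self):
        # symmetric 50/50 ms kinetics: stationary open fraction 0.5
        dwells = draw_dwell_sequence(50.0, 50.0, 1000.0, 3)
        total = sum(d for _, d in dwells)
        open_time = sum(d for s, d in dwells if s == 1)
        assert open_time / total == pytest.approx(0.5, abs=0.02)

    def test_mean_open_dwell_within_5pct(self):
        dwells = draw_dwell_sequence(50.0, 50.0, 100.0, 11)
        opens = [d for s, d in dwells if s == 1]
        assert len(opens) >= 500
        assert np.mean(opens) * 1000.0 == pytest.approx(50.0, rel=0.05)

    def test_dwell_means_converge(self):
        dwells = draw_dwell_sequence(30.0, 70.0, 400.0, 5)
        opens = [d for s, d in dwells if s == 1]
        closed = [d for s, d in dwells if s == 0]
        assert len(opens) >= 1000 and len(closed) >= 1000
        assert np.mean(opens) * 1000.0 == pytest.approx(30.0, rel=0.05)
        assert np.mean(closed) * 1000.0 == pytest.approx(70.0, rel=0.05)


class TestChannelCount:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_always_at_least_one(self, seed):
        assert sample_channel_count(0.6, seed) >= 1

    def test_invalid_lambda(self):
        with pytest.raises(InvalidParameterError):
            sample_channel_count(0.0, 0)
        with pytest.raises(InvalidParameterError):
            sample_channel_count(-1.0, 0)

    def test_small_lambda_limit(self):
        # P(count=1 | >=1) -> 1 as lambda -> 0+
        draws = [sample_channel_count(1e-4, s) for s in range(200)]
        assert all(d == 1 for d in draws)

    def test_pmf_matches_truncated_poisson(self, rng):
        # brute-force summation oracle vs empirical frequencies at lambda=0.6
        lam = 0.6
        n = 40_000
        draws = np.array([sample_channel_count(lam, rng) for _ in range(n)])
        for k in (1, 2, 3):
            expect = ztp_pmf(k, lam)
            se = math.sqrt(expect * (1 - expect) / n)
            assert np.mean(draws == k) == pytest.approx(expect, abs=5 * se)
        # frozen oracle values (direct summation): P(1)~0.7298, P(2)~0.2189
        assert ztp_pmf(1, lam) == pytest.approx(0.7298, abs=5e-4)
        assert ztp_pmf(2, lam) == pytest.approx(0.2189, abs=5e-4)

    def test_printed_split_approximated(self):
        # lambda = 0.6 approximates the observed single/double split
        # (multiple-channel mass is 5%, the closest a truncated Poisson gets)
        lam = 0.6
        p1, p2 = ztp_pmf(1, lam), ztp_pmf(2, lam)
        assert p1 == pytest.approx(0.71, abs=0.03)
        assert p2 == pytest.approx(0.20, abs=0.03)
        assert 0.0 < 1 - p1 - p2 < 0.10


class TestScenario:
    def test_kinetics_completion(self):
        sc = ChannelScenario("x", 100.0, open_prob=0.85, mean_open=100.0)
        assert sc.mean_closed == pytest.approx(100.0 * 0.15 / 0.85)
        sc2 = ChannelScenario("x", 100.0, mean_open=30.0, mean_closed=70.0)
        assert sc2.open_prob == pytest.approx(0.3)

    def test_inconsistent_kinetics_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChannelScenario("x", 100.0, open_prob=0.9, mean_open=50.0, mean_closed=50.0)

    def test_underdetermined_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChannelScenario("x", 100.0, open_prob=0.5)

    def test_unitary_current(self):
        sc = ChannelScenario("x", 103.6, open_prob=0.5, mean_open=50.0)
        assert sc.unitary_current(100.0) == pytest.approx(10.36)
        assert sc.unitary_current(-100.0) == pytest.approx(-10.36)


class TestRenderTrace:
    def test_zero_conductance_zero_trace(self, no_noise):
        sc = ChannelScenario("null", 0.0, open_prob=0.5, mean_open=50.0,
                             fixed_channel_count=1)
        tr = render_trace(sc, 100.0, 1.0, no_noise, 1000.0, 0)
        assert np.allclose(tr.samples, 0.0)

    def test_open_level_amplitude(self, simple_scenario, no_noise):
        tr = render_trace(simple_scenario, 100.0, 5.0, None, 1000.0, 0)
        levels = np.unique(tr.samples)
        assert set(np.round(levels, 9)) <= {0.0, 10.0}
        assert 10.0 in np.round(levels, 9)  # some opening in 5 s

    def test_sign_symmetry(self, simple_scenario):
        tr = render_trace(simple_scenario, -100.0, 5.0, None, 1000.0, 0)
        assert set(np.round(np.unique(tr.samples), 9)) <= {-10.0, 0.0}

    def test_noiseless_samples_are_level_multiples(self, e71a):
        scenario, _ = e71a
        sc = scenario.with_channels(3)
        tr = render_trace(sc, 80.0, 5.0, None, 1000.0, 4)
        u = sc.unitary_current(80.0)
        ks = tr.samples / u
        assert np.allclose(ks, np.round(ks), atol=1e-9)
        assert ks.max() <= 3

    def test_seed_reproducibility(self, e71a):
        scenario, noise = e71a
        a = render_trace(scenario, 100.0, 2.0, noise, 10_000.0, 42)
        b = render_trace(scenario, 100.0, 2.0, noise, 10_000.0, 42)
        assert np.array_equal(a.samples, b.samples)

    def test_invalid_duration(self, simple_scenario):
        with pytest.raises(InvalidParameterError):
            render_trace(simple_scenario, 100.0, 0.0, None, 1000.0, 0)

    def test_fraction_open_converges_in_rendered_counts(self, simple_scenario):
        counts = simulate_gating(simple_scenario, 1000.0, 100.0, 2)
        assert counts.mean() == pytest.approx(0.5, abs=0.02)


class TestNoise:
    def test_rms_level(self, rng):
        from autobilayer.simulate import render_noise
        ns = NoiseSpec(baseline_rms=0.5, drift_rate=0.0, spike_rate=0.0)
        x = render_noise(100_000, 1000.0, ns, rng)
        assert x.std() == pytest.approx(0.5, rel=0.02)

    def test_drift_is_linear_in_absolute_time(self, rng):
        from autobilayer.simulate import render_noise
        ns = NoiseSpec(baseline_rms=0.0, drift_rate=0.2, spike_rate=0.0)
        x = render_noise(1000, 1000.0, ns, rng, t_offset=10.0)
        assert x[0] == pytest.approx(2.0)
        assert x[-1] == pytest.approx(2.0 + 0.2 * 0.999)

    def test_invalid_rms(self):
        with pytest.raises(InvalidParameterError):
            NoiseSpec(baseline_rms=-1.0)


class TestPresets:
    def test_all_presets_present(self):
        names = list_presets()
        assert {"kcsa_e71a_decane", "kcsa_e71a_hexadecane",
                "kcsa_wt_control", "kcsa_wt_tea"} <= set(names)

    @pytest.mark.parametrize("name,g", [
        ("kcsa_e71a_decane", 103.6),
        ("kcsa_e71a_hexadecane", 127.6),
        ("kcsa_wt_control", 90.2),
        ("kcsa_wt_tea", 52.2),
    ])
    def test_preset_conductances(self, name, g):
        scenario, noise = load_preset(name)
        assert scenario.conductance_g == g
        assert scenario.reversal_E == 0.0
        assert noise.baseline_rms == 0.5

    def test_unknown_preset(self):
        with pytest.raises(InvalidParameterError):
            load_preset("does_not_exist")


class TestAcquisitionStream:
    def _spec(self, scenario, noise, **kw):
        return AcquisitionStreamSpec(
            contact_depth=2600.0, formation_depth=2650.0,
            scenario=scenario, noise=noise, **kw)

    def test_no_transient_before_contact_depth(self, wt_control, no_noise):
        scenario, _ = wt_control
        stream = AcquisitionStream(self._spec(scenario, no_noise), seed=0)
        chunk = stream.read(2.0, 0.0, 520.0)  # stays well above contact depth
        assert np.abs(chunk.samples).max() < 1.0

    def test_transient_onset_at_depth_over_speed(self, wt_control, no_noise):
        # descent at 260 µm/s, contact at 2600 µm -> transient onset at t = 10 s
        scenario, _ = wt_control
        stream = AcquisitionStream(self._spec(scenario, no_noise), seed=0)
        chunk = stream.read(11.0, 0.0, 11.0 * 260.0)
        onset_idx = int(np.argmax(np.abs(chunk.samples) >= 100.0))
        assert onset_idx / chunk.rate == pytest.approx(10.0, abs=1e-6)

    def test_no_channels_between_contact_and_formation(self, wt_control, no_noise):
        scenario, _ = wt_control
        stream = AcquisitionStream(self._spec(scenario, no_noise), seed=0)
        stream.read(10.0, 0.0, 2600.0)
        stream.read(10.0, 2600.0, None)  # pause; transient decays
        chunk = stream.read(5.0, 2640.0, None)
        assert np.abs(chunk.samples).max() < 1.0

    def test_gated_current_beyond_formation(self, wt_control, no_noise):
        scenario, _ = wt_control
        sc = scenario.with_channels(1)
        stream = AcquisitionStream(self._spec(sc, no_noise), seed=3, voltage=-60.0)
        stream.read(10.0, 0.0, 2600.0)
        stream.read(10.0, 2600.0, None)
        chunk = stream.read(10.0, 2650.0, None)
        u = sc.unitary_current(-60.0)
        assert np.isclose(chunk.samples, u, atol=1e-6).any()
        assert np.isclose(chunk.samples, 0.0, atol=1e-6).any()

    def test_rupture_produces_sustained_current(self, wt_control, no_noise):
        scenario, _ = wt_control
        spec = self._spec(scenario, no_noise, rupture_depth=2700.0)
        stream = AcquisitionStream(spec, seed=0)
        stream.read(10.0, 0.0, 2600.0)
        chunk = stream.read(3.0, 2700.0, None)
        assert (np.abs(chunk.samples) >= 100.0).all()

    def test_degenerate_formation_equals_contact(self, wt_control, no_noise):
        scenario, _ = wt_control
        sc = scenario.with_channels(1)
        spec = AcquisitionStreamSpec(contact_depth=2600.0, formation_depth=2600.0,
                                     scenario=sc, noise=no_noise)
        stream = AcquisitionStream(spec, seed=5, voltage=-60.0)
        stream.read(10.0, 0.0, 2600.0)
        stream.read(10.0, 2600.0, None)
        chunk = stream.read(10.0, 2600.0, None)
        assert np.isclose(chunk.samples, sc.unitary_current(-60.0), atol=1e-6).any()

    def test_formation_before_contact_rejected(self, wt_control, no_noise):
        scenario, _ = wt_control
        with pytest.raises(InvalidParameterError):
            AcquisitionStreamSpec(contact_depth=2600.0, formation_depth=2500.0,
                                  scenario=scenario, noise=no_noise)

    def test_stream_reproducibility(self, wt_control):
        scenario, noise = wt_control
        chunks = []
        for _ in range(2):
            stream = AcquisitionStream(self._spec(scenario, noise), seed=9)
            stream.read(10.0, 0.0, 2600.0)
            chunks.append(stream.read(5.0, 2650.0, None))
        assert np.array_equal(chunks[0].samples, chunks[1].samples)
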