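import numpy as np
import pytest

from fcsbind import (BindingDiffusionParams, GroundTruth, ObservationVolume,
                     SimulationConfig, attach_tcspc, add_drift, diffusion_acf,
                     autocorrelate, expected_particle_count, get_preset,
                     simulate_binding_trace, simulate_diffusion_trace,
                     simulate_photon_trace)
from fcsbind.correlate import DecayPatternSet
from fcsbind.traces import PhotonTrace


class TestPresets:
    def test_condition_means(self):
        w = get_preset("water")
        assert (w.params.N, w.params.D, w.params.koff) == (48.0, 3.5, 35.0)
        assert w.params.kon_star == pytest.approx(1.725, rel=5e-3)
        c = get_preset("cryptogein")
        assert (c.params.N, c.params.D, c.params.koff) == (32.0, 8.4, 35.0)
        assert c.params.kon_star == pytest.approx(4.63, rel=5e-3)

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("mock-condition")

    def test_particle_count_tracks_occupancy(self):
        truth = get_preset("water")
        cfg = SimulationConfig()
        n = expected_particle_count(truth, cfg)
        box = cfg.resolved_box(truth.volume)
        v_box = 8 * box[0] * box[1] * box[2]
        assert n == round(48.0 * v_box / truth.volume.effective_volume_um3())


class TestValidation:
    def test_dt_invariant_enforced(self):
        truth = get_preset("cryptogein")  # limit ~2.9e-4 s from the waist
        with pytest.raises(ValueError, match="does not resolve"):
            simulate_binding_trace(SimulationConfig(dt=5e-4, duration=1.0), truth)

    def test_box_minimum_enforced(self, volume):
        truth = get_preset("water")
        cfg = SimulationConfig(box_half_widths=(0.5, 0.5, 1.0), duration=0.1)
        with pytest.raises(ValueError, match="5x"):
            simulate_binding_trace(cfg, truth)

    def test_brightness_positive(self):
        with pytest.raises(ValueError, match="brightness"):
            simulate_binding_trace(SimulationConfig(brightness=0.0, duration=0.1),
                                   get_preset("water"))

    def test_trapping_sink_rejected(self, volume):
        with pytest.raises(ValueError):
            BindingDiffusionParams(N=5, D=1.0, kon_star=1.0, koff=0.0)

    def test_diffusion_trace_requires_zero_kon(self):
        with pytest.raises(ValueError, match="kon_star = 0"):
            simulate_diffusion_trace(SimulationConfig(duration=0.1),
                                     get_preset("water"))


class TestDegenerateSystems:
    def test_zero_particles_gives_silent_trace(self, small_truth):
        cfg = SimulationConfig(duration=0.5, dt=2e-4, seed=3, n_particles=0)
        tr = simulate_binding_trace(cfg, small_truth)
        assert tr.counts.sum() == 0

    def test_static_emitter_is_poisson(self, volume):
        """One pinned particle at the beam centre: i.i.d. Poisson(b dt)."""
        truth = GroundTruth(BindingDiffusionParams(N=1, D=0.0, kon_star=0.0,
                                                   koff=35.0), volume, "pinned")
        b, dt = 20_000.0, 2e-4
        cfg = SimulationConfig(duration=20.0, dt=dt, seed=11, n_particles=1,
                               brightness=b)
        tr = simulate_binding_trace(cfg, truth,
                                    initial_positions=np.zeros((1, 3)))
        lam = b * dt
        n = tr.counts.size
        assert abs(tr.counts.mean() - lam) < 5 * np.sqrt(lam / n)
        # Fano factor of a Poisson stream is 1
        assert tr.counts.var() / tr.counts.mean() == pytest.approx(1.0, abs=0.05)


class TestDeterminismAndStationarity:
    def test_identical_seed_identical_trace(self, small_truth):
        cfg = SimulationConfig(duration=2.0, dt=2e-4, seed=42)
        a = simulate_binding_trace(cfg, small_truth)
        b = simulate_binding_trace(cfg, small_truth)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_different_seed_different_trace(self, small_truth):
        a = simulate_binding_trace(SimulationConfig(duration=2.0, seed=1), small_truth)
        b = simulate_binding_trace(SimulationConfig(duration=2.0, seed=2), small_truth)
        assert not np.array_equal(a.counts, b.counts)

    def test_mean_intensity_matches_detection_profile(self, volume):
        """<I> = b N / 2^{3/2}: occupancy weighted by the Gaussian profile."""
        truth = GroundTruth(BindingDiffusionParams(N=5.0, D=3.5, kon_star=0.5,
                                                   koff=35.0), volume, "t")
        b = 5000.0
        expected = b * 5.0 / 2**1.5
        rates = []
        for seed in range(10):
            cfg = SimulationConfig(duration=3.0, dt=5e-4, seed=seed, brightness=b)
            rates.append(simulate_binding_trace(cfg, truth).mean_rate())
        rates = np.array(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expected) < 5 * se

    def test_stationary_halves(self, small_diffusion_trace):
        c = small_diffusion_trace.counts
        h = c.size // 2
        a, b = c[:h], c[h:2 * h]
        # occupancy fluctuations dominate; estimate SE from coarse blocks
        blocks = c[:c.size // 20 * 20].reshape(20, -1).mean(axis=1)
        se = blocks.std(ddof=1) / np.sqrt(10)
        assert abs(a.mean() - b.mean()) < 3 * se * np.sqrt(2)


class TestAcfConsistency:
    def test_diffusion_trace_acf_matches_closed_form(self, small_truth,
                                                     small_diffusion_trace):
        """Module-level oracle: simulated ACF equals the theory curve."""
        curve = autocorrelate(small_diffusion_trace)
        p = small_truth.params
        theory = diffusion_acf(curve.lags, p.N, p.D, small_truth.volume)
        sel = (curve.lags <= 0.05) & np.isfinite(curve.stderr) & (curve.stderr > 0)
        resid = (curve.G - theory)[sel] / curve.stderr[sel]
        # every lag within 3 segment-SE, allowing one marginal excursion
        assert np.sum(np.abs(resid) > 3) <= 1


class TestBindingKinetics:
    def test_symmetric_rates_give_half_bound(self, volume, rng):
        """Two-state Markov chain at kon* = koff sits at 50% bound."""
        from fcsbind.simulate import _geometric_steps
        dt, k = 1e-3, 10.0
        p = float(-np.expm1(-k * dt))
        # simulate one long alternating chain with geometric holding times
        steps_free = _geometric_steps(rng, p, 20_000)
        steps_bound = _geometric_steps(rng, p, 20_000)
        frac = steps_bound.sum() / (steps_free.sum() + steps_bound.sum())
        se = 0.5 / np.sqrt(20_000)
        assert abs(frac - 0.5) < 4 * se

    def test_water_preset_bound_fraction(self, rng):
        """Geometric holding times reproduce kon*/(kon*+koff) occupancy."""
        from fcsbind.simulate import _geometric_steps
        p = get_preset("water").params
        dt = 2e-4
        p_on = float(-np.expm1(-p.kon_star * dt))
        p_off = float(-np.expm1(-p.koff * dt))
        free = _geometric_steps(rng, p_on, 5000)
        bound = _geometric_steps(rng, p_off, 5000)
        frac = bound.sum() / (free.sum() + bound.sum())
        expected = p.bound_fraction
        se = np.sqrt(expected * (1 - expected) / 5000) * 3  # crude cycle-level SE
        assert abs(frac - expected) < 3 * se

    def test_no_binding_limit_matches_diffusion_seed_handling(self, small_truth):
        """kon* = 0 through the binding path equals the diffusion path."""
        cfg = SimulationConfig(duration=1.0, dt=2e-4, seed=5)
        a = simulate_binding_trace(cfg, small_truth)
        b = simulate_diffusion_trace(cfg, small_truth)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestDrift:
    def test_zero_amplitude_identity(self, small_diffusion_trace):
        out = add_drift(small_diffusion_trace, 0.0, 20.0)
        np.testing.assert_array_equal(out.counts, small_diffusion_trace.counts)

    def test_amplitude_one_rejected(self, small_diffusion_trace):
        with pytest.raises(ValueError, match="negative intensity"):
            add_drift(small_diffusion_trace, 1.0, 20.0)

    def test_mean_preserved(self, small_diffusion_trace):
        out = add_drift(small_diffusion_trace, 0.2, 5.0)
        rel = abs(out.counts.mean() / small_diffusion_trace.counts.mean() - 1)
        assert rel < 0.2**2 / 2 + 0.01

    def test_short_period_warns(self, small_diffusion_trace):
        with pytest.warns(UserWarning, match="not separable"):
            add_drift(small_diffusion_trace, 0.1, 0.5)


class TestAttachTcspc:
    def test_single_pattern_histogram(self, rng):
        pattern = np.array([[0.5, 0.3, 0.15, 0.05]])
        times = np.sort(rng.random(100_000))
        tr = PhotonTrace(times, 1.0)
        out = attach_tcspc(tr, pattern, np.array([1.0]), seed=0)
        hist = np.bincount(out.microtimes, minlength=4) / out.n_photons
        from scipy.stats import chisquare
        stat, p = chisquare(np.bincount(out.microtimes, minlength=4),
                            pattern[0] * out.n_photons)
        assert p > 0.01

    def test_two_class_mixture_marginal(self, rng):
        patterns = np.array([[0.8, 0.2], [0.3, 0.7]])
        times = np.sort(rng.random(50_000))
        tr = PhotonTrace(times, 1.0)
        out = attach_tcspc(tr, patterns, np.array([0.5, 0.5]), seed=1)
        frac_bin0 = np.mean(out.microtimes == 0)
        se = np.sqrt(0.55 * 0.45 / out.n_photons)
        assert abs(frac_bin0 - 0.55) < 4 * se

    def test_empty_trace_unchanged(self):
        tr = PhotonTrace(np.empty(0), 1.0)
        out = attach_tcspc(tr, np.array([[1.0, 0.0]]), np.array([1.0]), seed=0)
        assert out.n_photons == 0

    def test_unnormalised_pattern_warns(self, rng):
        tr = PhotonTrace(np.sort(rng.random(10)), 1.0)
        with pytest.warns(UserWarning, match="normalis"):
            attach_tcspc(tr, np.array([[2.0, 2.0]]), np.array([1.0]), seed=0)

    def test_negative_pattern_rejected(self, rng):
        tr = PhotonTrace(np.sort(rng.random(10)), 1.0)
        with pytest.raises(ValueError):
            attach_tcspc(tr, np.array([[1.2, -0.2]]), np.array([1.0]), seed=0)


def test_photon_trace_mode_consistent_with_binned(small_truth):
    """Time-tag mode carries the same counts as the binned simulation."""
    cfg = SimulationConfig(duration=1.0, dt=2e-4, seed=9)
    binned = simulate_binding_trace(cfg, small_truth)
    photons = simulate_photon_trace(cfg, small_truth)
    assert photons.n_photons == binned.counts.sum()
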