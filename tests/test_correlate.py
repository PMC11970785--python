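import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcsbind import (autocorrelate, detrend, direct_acf, flcs_weights,
                     apply_flcs, attach_tcspc, bin_photons)
from fcsbind.correlate import CorrelationCurve, DecayPatternSet
from fcsbind.traces import BinnedTrace, PhotonTrace


class TestFlcsWeights:
    def test_single_component_identity(self):
        pattern = DecayPatternSet(np.array([[0.5, 0.3, 0.2]]))
        W = flcs_weights(pattern, np.array([500.0, 300.0, 200.0]))
        np.testing.assert_allclose(W, 1.0, atol=1e-10)

    def test_orthonormality_on_two_component_example(self):
        ps = DecayPatternSet(np.array([[0.8, 0.2], [0.3, 0.7]]))
        W = flcs_weights(ps, np.array([0.55, 0.45]))
        np.testing.assert_allclose(W @ ps.patterns.T, np.eye(2), atol=1e-10)

    def test_weights_match_explicit_inversion(self):
        """Hand-rolled 2x2 solve as an independent linear-algebra oracle."""
        M = np.array([[0.8, 0.3], [0.2, 0.7]])  # bins x components
        h = np.array([0.55, 0.45])
        A = M.T @ np.diag(1 / h) @ M
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
        expected = Ainv @ M.T @ np.diag(1 / h)
        ps = DecayPatternSet(M.T)
        W = flcs_weights(ps, h)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_dependent_patterns_raise_with_pair_named(self):
        ps = DecayPatternSet(np.array([[0.6, 0.4], [0.6, 0.4]]),
                             labels=("gfp", "copy"))
        with pytest.raises(np.linalg.LinAlgError, match="gfp.*copy"):
            flcs_weights(ps, np.array([0.6, 0.4]))

    def test_empty_bins_dropped_with_warning(self):
        ps = DecayPatternSet(np.array([[0.5, 0.3, 0.2], [0.1, 0.4, 0.5]]))
        with pytest.warns(UserWarning, match="empty TCSPC bins"):
            W = flcs_weights(ps, np.array([100.0, 0.0, 80.0]))
        assert np.all(W[:, 1] == 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_orthonormality_property(self, seed):
        """W M = I for random well-conditioned pattern sets."""
        rng = np.random.default_rng(seed)
        n_comp = rng.integers(2, 4)
        n_bins = rng.integers(n_comp + 1, 12)
        P = rng.dirichlet(np.ones(n_bins), size=n_comp)
        ps = DecayPatternSet(P)
        frac = rng.dirichlet(np.ones(n_comp))
        h = frac @ P
        try:
            W = flcs_weights(ps, h)
        except np.linalg.LinAlgError:
            return  # randomly collinear draw: correctly refused
        np.testing.assert_allclose(W @ P.T, np.eye(n_comp), atol=1e-8)


class TestApplyFlcs:
    @pytest.fixture(scope="class")
    def two_class_trace(self):
        rng = np.random.default_rng(5)
        times = np.sort(rng.random(200_000) * 10.0)
        tr = PhotonTrace(times, 10.0)
        patterns = DecayPatternSet(np.array([[0.8, 0.2], [0.3, 0.7]]),
                                   labels=("signal", "background"))
        tagged = attach_tcspc(tr, patterns, np.array([0.7, 0.3]), seed=2)
        return tagged, patterns

    def test_mixture_share_recovered(self, two_class_trace):
        tagged, patterns = two_class_trace
        h = np.bincount(tagged.microtimes, minlength=2).astype(float)
        W = flcs_weights(patterns, h)
        filtered = apply_flcs(tagged, W, "signal", patterns, bin_width=1e-3)
        unfiltered = bin_photons(tagged, 1e-3)
        share = filtered.counts.mean() / unfiltered.counts.mean()
        se = np.sqrt(0.7 * 0.3 / tagged.n_photons) * 3  # photon-level scatter
        assert share == pytest.approx(0.7, abs=max(3 * se, 0.01))

    def test_pure_background_rejected_to_zero(self):
        rng = np.random.default_rng(6)
        times = np.sort(rng.random(50_000))
        patterns = DecayPatternSet(np.array([[0.8, 0.2], [0.3, 0.7]]))
        tagged = attach_tcspc(PhotonTrace(times, 1.0), patterns,
                              np.array([0.0, 1.0]), seed=3)
        h = np.bincount(tagged.microtimes, minlength=2).astype(float)
        W = flcs_weights(patterns, h)
        comp0 = apply_flcs(tagged, W, 0, bin_width=1e-3)
        se = np.abs(W).max() * np.sqrt(tagged.n_photons) / comp0.counts.size
        assert abs(comp0.counts.mean()) < 3 * se

    def test_missing_microtimes_rejected(self):
        tr = PhotonTrace(np.array([0.1, 0.2]), 1.0)
        with pytest.raises(ValueError, match="micro-times"):
            apply_flcs(tr, np.ones((1, 2)), 0, bin_width=0.1)


class TestDetrend:
    def test_constant_trace_unchanged(self):
        tr = BinnedTrace(np.full(30_000, 7.0), 1e-3)
        out = detrend(tr, 3.0)
        np.testing.assert_allclose(out.counts, 7.0, atol=1e-9)

    def test_linear_ramp_flattened_in_interior(self):
        n = 60_000
        t = np.arange(n) * 1e-3
        tr = BinnedTrace(10.0 + 0.1 * t, 1e-3)
        out = detrend(tr, 3.0)
        w_half = 1500
        interior = out.counts[w_half:-w_half]
        assert np.ptp(interior) < 1e-6 * np.ptp(tr.counts)

    def test_global_mean_preserved_exactly(self, small_diffusion_trace):
        out = detrend(small_diffusion_trace, 3.0)
        assert out.counts.mean() == pytest.approx(
            small_diffusion_trace.counts.mean(), rel=1e-12)

    def test_window_validation(self):
        tr = BinnedTrace(np.ones(1000), 1e-3)
        with pytest.raises(ValueError, match="shorter than the trace"):
            detrend(tr, 2.0)
        with pytest.raises(ValueError, match="10 bins"):
            detrend(tr, 5e-3)


class TestAutocorrelate:
    def test_white_noise_uncorrelated(self, rng):
        tr = BinnedTrace(rng.poisson(20.0, 100_000).astype(float), 1e-4)
        curve = autocorrelate(tr)
        ok = np.isfinite(curve.stderr) & (curve.stderr > 0)
        z = np.abs(curve.G[ok]) / curve.stderr[ok]
        # segment SEs are themselves noisy (10 segments): allow a couple of
        # marginal 4-sigma excursions among ~250 lags, none gross
        assert np.sum(z > 4) <= 2
        assert np.all(z < 8)

    def test_alternating_counts_hand_computed(self):
        """(2,0,2,0,...): symmetric normalisation gives G(d)=-1, G(2d)=+1."""
        tr = BinnedTrace(np.tile([2.0, 0.0], 512), 1.0)
        g = direct_acf(tr.counts, [1, 2])
        assert g[0] == pytest.approx(-1.0, abs=1e-9)
        assert g[1] == pytest.approx(1.0, abs=1e-2)  # edge terms decay as 1/n

    def test_multitau_equals_direct_at_first_level(self, rng):
        """The multiple-tau grid must agree with the O(n^2) oracle exactly."""
        counts = rng.poisson(5.0, 10_000).astype(float)
        tr = BinnedTrace(counts, 1e-3)
        curve = autocorrelate(tr, n_segments=0)
        first = curve.lags <= 32 * 1e-3
        expected = direct_acf(counts, np.arange(1, first.sum() + 1))
        np.testing.assert_allclose(curve.G[first], expected, atol=1e-10)

    def test_multitau_rebinned_levels_match_direct_on_rebinned(self, rng):
        counts = rng.poisson(5.0, 16_384).astype(float)
        tr = BinnedTrace(counts, 1e-3)
        curve = autocorrelate(tr, n_segments=0)
        # level 1: lags 17..32 in units of the doubled bin width
        reb = 0.5 * (counts[0::2] + counts[1::2])
        lags_lvl1 = np.arange(17, 33)
        expected = direct_acf(reb, lags_lvl1)
        sel = np.isin(np.round(curve.lags / 2e-3), lags_lvl1) \
            & (curve.lags > 32 * 1e-3)
        np.testing.assert_allclose(curve.G[sel], expected, atol=1e-10)

    def test_photon_path_equals_binned_path(self, rng):
        times = np.sort(rng.random(5000) * 2.0)
        ph = PhotonTrace(times, 2.0)
        c1 = autocorrelate(ph, bin_width=1e-3, n_segments=0)
        c2 = autocorrelate(bin_photons(ph, 1e-3), n_segments=0)
        np.testing.assert_allclose(c1.G, c2.G, atol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            autocorrelate(BinnedTrace(np.zeros(1000), 1e-3))

    def test_long_lag_trimmed_with_warning(self, rng):
        tr = BinnedTrace(rng.poisson(5.0, 5000).astype(float), 1e-3)
        with pytest.warns(UserWarning, match="trimming"):
            curve = autocorrelate(tr, tau_max=4.0)
        assert curve.lags[-1] <= 0.5 + 1e-9

    def test_floor_and_decay_for_stationary_traces(self, rng):
        """G >= -1 always; G near zero at the largest lags."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            tr = BinnedTrace(r.poisson(8.0, 50_000).astype(float), 1e-3)
            curve = autocorrelate(tr)
            assert np.all(curve.G >= -1.0)
            tail = curve.lags > curve.lags[-1] / 4
            assert np.abs(curve.G[tail]).max() < 0.05


class TestCurveIO:
    def test_round_trip(self, tmp_path, rng):
        tr = BinnedTrace(rng.poisson(5.0, 20_000).astype(float), 1e-3)
        curve = autocorrelate(tr)
        p = tmp_path / "curve.tsv"
        curve.write(p)
        back = CorrelationCurve.read(p)
        np.testing.assert_allclose(back.lags, curve.lags)
        np.testing.assert_allclose(back.G, curve.G)
        np.testing.assert_allclose(back.stderr[np.isfinite(curve.stderr)],
                                   curve.stderr[np.isfinite(curve.stderr)])
        assert back.meta["normalisation"] == "symmetric"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([0.0, 1.0]), np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            CorrelationCurve(np.array([2.0, 1.0]), np.array([1.0, 0.5]))
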