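"""Brownian-dynamics photon-trace generator for diffusion plus binding.

Particles diffuse in a periodic box enclosing the Gaussian observation
volume, switch between a mobile (free) and an immobile (bound) state with
pseudo-first-order rates kon* (bind) and koff (unbind), and emit photons
with a Poisson law whose rate is brightness x MDE(position), where

    MDE(x, y, z) = exp(-2 (x^2 + y^2)/w0^2 - 2 z^2/z0^2).

This is the generative counterpart of the fitted autocorrelation model:
binding sites are spatially uniform and unsaturable, so no site positions
are stored, and the ground-truth molecule number N in the effective volume
V_eff = pi^{3/2} w0^2 z0 maps exactly to the simulated particle count via
n = N * V_box / V_eff.

Numerics
--------
* State switching uses geometric waiting times, which reproduce per-step
  Bernoulli switching with probabilities 1 - exp(-k dt) exactly.
* Far from the focus the emission rate is below 1e-5 of peak and particles
  take multi-step Brownian jumps (variance 2 D n dt), with a 3-sigma
  re-entry margin to the emission ellipsoid; this is statistically exact
  for the emitted trace up to grazing trajectories whose emission is below
  the cutoff.
* Gaussian increments are drawn in large numpy batches and consumed by a
  resumable numba kernel; all randomness derives from the configuration
  seed, so identical configurations give bit-identical traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import BindingDiffusionParams, ObservationVolume, concentration_from_n, \
    kon_to_kon_star
from .traces import BinnedTrace, PhotonTrace, photons_from_binned

_MDE_CUT = 11.5  # emission ignored below exp(-11.5) ~ 1e-5 of peak
_JUMP_SIGMAS = 3.0


@dataclass(frozen=True)
class GroundTruth:
    """Generator ground truth: model parameters plus volume geometry."""

    params: BindingDiffusionParams
    volume: ObservationVolume = field(default_factory=ObservationVolume)
    preset_name: str = "custom"


def _preset(name: str, N: float, D: float, kon_uM: float, koff: float) -> GroundTruth:
    vol = ObservationVolume()
    c = concentration_from_n(N, vol)
    kon_star = kon_uM * 1e6 * c  # kon in 1/M/s times molar concentration
    return GroundTruth(BindingDiffusionParams(N=N, D=D, kon_star=kon_star, koff=koff),
                       vol, name)


#: Named experimental-condition presets (reported condition means).
#: kon* is derived from kon and the concentration of N molecules in the
#: pi^{3/2} effective volume: ~1.73 1/s (water), ~4.63 1/s (cryptogein).
PRESETS: dict[str, GroundTruth] = {
    "water": _preset("water", N=48.0, D=3.5, kon_uM=3.5, koff=35.0),
    "cryptogein": _preset("cryptogein", N=32.0, D=8.4, kon_uM=14.1, koff=35.0),
}


def get_preset(name: str) -> GroundTruth:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical settings of one simulated acquisition.

    box_half_widths : (hx, hy, hz) in um; must be >= 5 * (w0, w0, z0) so
        that periodic-image artifacts stay small.
    brightness : photons/s per molecule at beam centre (in-cell two-photon
        GFP scale; default 5000).
    dt : time step and finest bin width, s.
    duration : acquisition length, s.
    seed : master seed; every random stream derives from it.
    n_particles : optional override of the particle count (default: derived
        from the ground-truth N).
    drift_amplitude, drift_period : optional multiplicative sinusoidal
        intensity drift (applied via :func:`add_drift`).
    background_rate : optional flat background, photons/s.
    """

    box_half_widths: tuple[float, float, float] | None = None
    brightness: float = 5000.0
    dt: float = 2e-4
    duration: float = 60.0
    seed: int = 0
    n_particles: int | None = None
    drift_amplitude: float = 0.0
    drift_period: float = 20.0
    background_rate: float = 0.0

    def resolved_box(self, volume: ObservationVolume) -> tuple[float, float, float]:
        box = self.box_half_widths
        if box is None:
            box = (5.0 * volume.w0, 5.0 * volume.w0, 5.0 * volume.z0)
        box = tuple(float(h) for h in box)
        min_box = (5.0 * volume.w0, 5.0 * volume.w0, 5.0 * volume.z0)
        if any(h < m * (1 - 1e-9) for h, m in zip(box, min_box)):
            raise ValueError(
                f"box_half_widths {box} below the 5x(w0, w0, z0) minimum {min_box}; "
                "boundary effects would not be negligible")
        return box

    def dt_limit(self, truth: GroundTruth) -> float:
        """Largest dt resolving both waist crossing and state switching."""
        lims = [np.inf]
        p = truth.params
        if p.D > 0:
            lims.append(truth.volume.w0**2 / (20.0 * p.D))
        rate = p.kon_star + p.koff
        if p.kon_star > 0 and rate > 0:
            lims.append(1.0 / (20.0 * rate))
        return float(min(lims))


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _trace_kernel(n_steps, dt, D, p_on, p_off, bx, by, bz, sc_xy, sc_z,
                  xs, ys, zs, bnd, sws, ks, p0, norm, intensity):
    """Resumable per-particle propagation; returns (next particle, normals used)."""
    sig = math.sqrt(2.0 * D * dt)
    rcut = math.sqrt(_MDE_CUT)
    inv_jump = 1.0 / (2.0 * _JUMP_SIGMAS * _JUMP_SIGMAS * D * dt) if D > 0 else 0.0
    nb = norm.shape[0]
    ib = 0
    n_part = xs.shape[0]
    for p in range(p0, n_part):
        x = xs[p]; y = ys[p]; z = zs[p]
        bound = bnd[p] == 1
        sw = sws[p]; k = ks[p]
        while k < n_steps:
            if ib + 3 > nb:
                xs[p] = x; ys[p] = y; zs[p] = z
                bnd[p] = 1 if bound else 0
                sws[p] = sw; ks[p] = k
                return p, ib
            ux = x * sc_xy; uy = y * sc_xy; uz = z * sc_z
            m = ux * ux + uy * uy + uz * uz
            if bound:
                kend = k + sw
                if kend > n_steps:
                    kend = n_steps
                if m < _MDE_CUT:
                    e = math.exp(-m)
                    for j in range(k, kend):
                        intensity[j] += e
                sw -= (kend - k)
                k = kend
                if sw == 0:
                    bound = False
                    sw = 1 + np.int64(math.log(np.random.random()) / math.log(1.0 - p_on)) \
                        if p_on > 0 else n_steps
            else:
                if m < _MDE_CUT:
                    intensity[k] += math.exp(-m)
                    n_jump = 1
                else:
                    sm = math.sqrt(m)
                    gap = 0.9 * math.sqrt(x * x + y * y + z * z) * (1.0 - rcut / sm)
                    n_jump = np.int64(gap * gap * inv_jump) if D > 0 else (n_steps - k)
                    if n_jump < 1:
                        n_jump = 1
                    if n_jump > sw:
                        n_jump = sw
                    if k + n_jump > n_steps:
                        n_jump = n_steps - k
                s = sig * math.sqrt(np.float64(n_jump))
                x += norm[ib] * s; y += norm[ib + 1] * s; z += norm[ib + 2] * s
                ib += 3
                if x > bx:
                    x -= 2 * bx
                elif x < -bx:
                    x += 2 * bx
                if y > by:
                    y -= 2 * by
                elif y < -by:
                    y += 2 * by
                if z > bz:
                    z -= 2 * bz
                elif z < -bz:
                    z += 2 * bz
                k += n_jump
                sw -= n_jump
                if sw == 0:
                    bound = True
                    sw = 1 + np.int64(math.log(np.random.random()) / math.log(1.0 - p_off)) \
                        if p_off > 0 else n_steps
        xs[p] = x; ys[p] = y; zs[p] = z
        bnd[p] = 1 if bound else 0
        sws[p] = sw if sw > 0 else 1
        ks[p] = k
    return n_part, ib


def expected_particle_count(truth: GroundTruth, cfg: SimulationConfig) -> int:
    box = cfg.resolved_box(truth.volume)
    v_box = 8.0 * box[0] * box[1] * box[2]
    return int(round(truth.params.N * v_box / truth.volume.effective_volume_um3()))


def _geometric_steps(rng, p, size):
    """Steps until a switch with per-step probability p (>= 1)."""
    if p <= 0:
        return np.full(size, np.iinfo(np.int64).max // 4, dtype=np.int64)
    u = rng.random(size)
    return 1 + (np.log(u) / np.log1p(-p)).astype(np.int64)


def simulate_binding_trace(cfg: SimulationConfig, truth: GroundTruth,
                           initial_positions: np.ndarray | None = None) -> BinnedTrace:
    """Simulate a binned photon trace for diffusing, binding molecules.

    Returns counts at resolution ``cfg.dt``; rebin downstream if desired.
    Identical (cfg, truth) give bit-identical traces.
    """
    p = truth.params
    if p.kon_star > 0 and p.koff <= 0:
        raise ValueError("koff must be positive when kon_star > 0 "
                         "(a permanently trapping sink is outside the model)")
    if cfg.dt <= 0:
        raise ValueError(f"dt must be positive, got {cfg.dt}")
    if cfg.duration < cfg.dt:
        raise ValueError("duration must be at least one time step")
    if cfg.brightness <= 0:
        raise ValueError(f"brightness must be positive, got {cfg.brightness}")
    dt_max = cfg.dt_limit(truth)
    if cfg.dt > dt_max * (1 + 1e-9):
        raise ValueError(
            f"dt = {cfg.dt} s does not resolve the dynamics: the invariant "
            f"dt <= min(w0^2/(20 D), 1/(20 (kon*+koff))) requires dt <= {dt_max:.3g} s")
    box = cfg.resolved_box(truth.volume)
    n_part = cfg.n_particles if cfg.n_particles is not None \
        else expected_particle_count(truth, cfg)
    n_steps = int(round(cfg.duration / cfg.dt))

    ss = np.random.SeedSequence(cfg.seed)
    rng_init, rng_norm, rng_poisson, rng_drift = \
        [np.random.default_rng(s) for s in ss.spawn(4)]
    _seed_numba(int(ss.generate_state(1, np.uint32)[0]) % 2**31)

    intensity = np.zeros(n_steps)
    if n_part > 0:
        bx, by, bz = box
        if initial_positions is not None:
            pos = np.asarray(initial_positions, float)
            if pos.shape != (n_part, 3):
                raise ValueError("initial_positions must have shape (n_particles, 3)")
            xs, ys, zs = pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy()
        else:
            xs = rng_init.uniform(-bx, bx, n_part)
            ys = rng_init.uniform(-by, by, n_part)
            zs = rng_init.uniform(-bz, bz, n_part)
        fb = p.bound_fraction
        bnd = (rng_init.random(n_part) < fb).astype(np.int8)
        p_on = float(-np.expm1(-p.kon_star * cfg.dt))
        p_off = float(-np.expm1(-p.koff * cfg.dt))
        sws = np.empty(n_part, np.int64)
        free = bnd == 0
        sws[free] = _geometric_steps(rng_init, p_on, int(free.sum()))
        sws[~free] = _geometric_steps(rng_init, p_off, int((~free).sum()))
        ks = np.zeros(n_part, np.int64)
        sc_xy = math.sqrt(2.0) / truth.volume.w0
        sc_z = math.sqrt(2.0) / truth.volume.z0
        chunk = 4_000_000
        p0 = 0
        while p0 < n_part:
            norm = rng_norm.standard_normal(chunk)
            p0_new, used = _trace_kernel(
                n_steps, cfg.dt, p.D, p_on, p_off, bx, by, bz, sc_xy, sc_z,
                xs, ys, zs, bnd, sws, ks, p0, norm, intensity)
            if p0_new == p0 and used == 0 and ks[p0] < n_steps:
                raise RuntimeError("simulation kernel made no progress")
            p0 = p0_new

    lam = intensity * (cfg.brightness * cfg.dt)
    if cfg.background_rate > 0:
        lam = lam + cfg.background_rate * cfg.dt
    counts = rng_poisson.poisson(lam).astype(float)
    trace = BinnedTrace(counts, cfg.dt, 0.0, False, {
        "preset": truth.preset_name, "seed": cfg.seed, "dt_s": cfg.dt,
        "duration_s": cfg.duration, "n_particles": n_part,
        "brightness_hz": cfg.brightness,
        "box_half_widths_um": " ".join(f"{h:g}" for h in box),
        "N": p.N, "D_um2_s": p.D, "kon_star_s": p.kon_star, "koff_s": p.koff,
        "background_rate_hz": cfg.background_rate,
    })
    if cfg.drift_amplitude > 0:
        trace = add_drift(trace, cfg.drift_amplitude, cfg.drift_period, rng=rng_drift)
    return trace


def simulate_diffusion_trace(cfg: SimulationConfig, truth: GroundTruth,
                             initial_positions: np.ndarray | None = None) -> BinnedTrace:
    """Pure-diffusion trace; requires the ground truth to have kon* = 0."""
    if truth.params.kon_star != 0:
        raise ValueError("simulate_diffusion_trace requires kon_star = 0; "
                         "use simulate_binding_trace for binding dynamics")
    return simulate_binding_trace(cfg, truth, initial_positions)


def simulate_photon_trace(cfg: SimulationConfig, truth: GroundTruth) -> PhotonTrace:
    """Time-tag mode: exact photon arrival times.

    Equivalent to thinning an inhomogeneous Poisson process whose rate is
    piecewise constant at the dt resolution of the binned simulation:
    per-bin counts are Poisson with the binned intensity, and times are
    uniform within each bin.
    """
    binned = simulate_binding_trace(cfg, truth)
    ss = np.random.SeedSequence(cfg.seed)
    rng_times = np.random.default_rng(ss.spawn(5)[4])
    return photons_from_binned(binned, rng_times)


def add_drift(trace: BinnedTrace, amplitude: float, period: float,
              mode: str = "scale", rng=None) -> BinnedTrace:
    """Impose a slow multiplicative sinusoidal intensity drift.

    counts are multiplied by 1 + amplitude * sin(2 pi t / period).  With the
    default ``mode="scale"`` the counts are scaled deterministically (the
    choice documented for this package); ``mode="repoisson"`` re-draws
    Poisson counts with the modulated expectation instead.  The mean
    intensity is preserved to within amplitude^2/2 relative.
    """
    if not (0 <= amplitude < 1):
        raise ValueError(f"drift amplitude must be in [0, 1), got {amplitude} "
                         "(amplitude >= 1 would produce negative intensity)")
    if amplitude == 0:
        return trace
    if period < 1.0:
        warnings.warn(
            f"drift period {period} s is shorter than a third of the default "
            "3-s detrending window; such drift is not separable from signal",
            stacklevel=2)
    factor = 1.0 + amplitude * np.sin(2 * np.pi * trace.times / period)
    if mode == "scale":
        counts = trace.counts * factor
        weighted = True
    elif mode == "repoisson":
        rng = np.random.default_rng(rng)
        counts = rng.poisson(np.maximum(trace.counts * factor, 0.0)).astype(float)
        weighted = trace.weighted
    else:
        raise ValueError(f"unknown drift mode {mode!r}")
    meta = dict(trace.meta)
    meta["drift"] = f"amplitude={amplitude} period_s={period} mode={mode}"
    return BinnedTrace(counts, trace.bin_width, trace.t0, weighted, meta)


def attach_tcspc(trace: PhotonTrace, patterns, fractions, seed=None) -> PhotonTrace:
    """Assign TCSPC micro-times to photons from a mixture of decay patterns.

    Each photon is assigned a component with probability ``fractions`` and
    then a micro-time bin drawn from that component's normalised decay
    histogram, so the marginal micro-time histogram converges to the
    fraction-weighted pattern mixture.

    ``patterns`` is a DecayPatternSet (see :mod:`fcsbind.correlate`) or an
    (n_components, n_bins) array of normalised histograms.
    """
    mat = np.asarray(getattr(patterns, "patterns", patterns), dtype=float)
    if mat.ndim != 2:
        raise ValueError("patterns must be a (components, bins) matrix")
    if np.any(mat < 0):
        raise ValueError("decay patterns must be non-negative")
    rowsum = mat.sum(axis=1)
    if np.any(rowsum <= 0):
        raise ValueError("each decay pattern must have positive total weight")
    if not np.allclose(rowsum, 1.0):
        warnings.warn("decay patterns not normalised; normalising rows", stacklevel=2)
        mat = mat / rowsum[:, None]
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (mat.shape[0],):
        raise ValueError("need one fraction per pattern component")
    if np.any(frac < 0) or not np.isclose(frac.sum(), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    if trace.n_photons == 0:
        return PhotonTrace(trace.arrival_times.copy(), trace.duration,
                           np.empty(0, np.int64), dict(trace.meta))
    rng = np.random.default_rng(seed)
    comp = rng.choice(mat.shape[0], size=trace.n_photons, p=frac)
    micro = np.empty(trace.n_photons, dtype=np.int64)
    for c in range(mat.shape[0]):
        sel = comp == c
        if sel.any():
            micro[sel] = rng.choice(mat.shape[1], size=int(sel.sum()), p=mat[c])
    meta = dict(trace.meta)
    meta["tcspc_fractions"] = " ".join(f"{f:g}" for f in frac)
    return PhotonTrace(trace.arrival_times.copy(), trace.duration, micro, meta)


def merge_photon_traces(a: PhotonTrace, b: PhotonTrace) -> PhotonTrace:
    """Interleave two photon records (e.g. signal plus background)."""
    if not np.isclose(a.duration, b.duration):
        raise ValueError("traces must share a duration")
    times = np.concatenate([a.arrival_times, b.arrival_times])
    order = np.argsort(times, kind="stable")
    micro = None
    if a.microtimes is not None or b.microtimes is not None:
        ma = a.microtimes if a.microtimes is not None else np.full(a.n_photons, -1, np.int64)
        mb = b.microtimes if b.microtimes is not None else np.full(b.n_photons, -1, np.int64)
        micro = np.concatenate([ma, mb])[order]
    return PhotonTrace(times[order], a.duration, micro, dict(a.meta))
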