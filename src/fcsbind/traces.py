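"""Photon and binned intensity traces, with plain-text round-trip I/O.

A :class:`PhotonTrace` is the rawest record the pipeline accepts: photon
arrival times in seconds since acquisition start, optionally with a TCSPC
micro-time bin index per photon (for lifetime filtering).  A
:class:`BinnedTrace` holds (possibly photon-weighted) counts on a uniform
time grid.  Both serialise to delimited text with ``#`` metadata headers so
that every intermediate artifact of a run is diffable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _format_meta(meta: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def _parse_meta(lines) -> dict:
    meta = {}
    for ln in lines:
        if not ln.startswith("#"):
            break
        body = ln[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


@dataclass
class PhotonTrace:
    """Photon arrival-time record.

    arrival_times : (n,) float array, seconds, non-decreasing, within
        [0, duration].
    microtimes : optional (n,) int array of TCSPC bin indices (-1 = absent).
    duration : acquisition length in seconds.
    meta : free-form metadata (nucleus id, condition, replicate, seed...).
    """

    arrival_times: np.ndarray
    duration: float
    microtimes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        if self.arrival_times.ndim != 1:
            raise ValueError("arrival_times must be 1-D")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.arrival_times.size:
            if np.any(np.diff(self.arrival_times) < 0):
                raise ValueError("arrival times must be non-decreasing")
            if self.arrival_times[0] < 0 or self.arrival_times[-1] > self.duration:
                raise ValueError("arrival times must lie within [0, duration]")
        if self.microtimes is not None:
            self.microtimes = np.asarray(self.microtimes, dtype=np.int64)
            if self.microtimes.shape != self.arrival_times.shape:
                raise ValueError("microtimes must cover every photon")

    @property
    def n_photons(self) -> int:
        return self.arrival_times.size

    def write(self, path) -> None:
        meta = dict(self.meta)
        meta["format"] = "fcsbind-photon-trace-v1"
        meta["duration_s"] = repr(self.duration)
        meta["columns"] = "arrival_time_s microtime_bin"
        mt = self.microtimes if self.microtimes is not None \
            else np.full(self.n_photons, -1, dtype=np.int64)
        with open(path, "w") as fh:
            fh.write(_format_meta(meta))
            for t, m in zip(self.arrival_times, mt):
                fh.write(f"{t:.9f}\t{m}\n")

    @classmethod
    def read(cls, path) -> "PhotonTrace":
        text = Path(path).read_text().splitlines()
        meta = _parse_meta(text)
        if meta.get("format") != "fcsbind-photon-trace-v1":
            raise ValueError(f"{path}: not a photon-trace file")
        duration = float(meta.pop("duration_s"))
        meta.pop("format"); meta.pop("columns", None)
        body = [ln for ln in text if ln and not ln.startswith("#")]
        if body:
            arr = np.loadtxt(io.StringIO("\n".join(body)), ndmin=2)
            times, micro = arr[:, 0], arr[:, 1].astype(np.int64)
        else:
            times = np.empty(0)
            micro = np.empty(0, dtype=np.int64)
        mt = None if (micro.size == 0 or np.all(micro < 0)) else micro
        return cls(times, duration, mt, meta)


@dataclass
class BinnedTrace:
    """Counts on a uniform time grid of width ``bin_width`` starting at ``t0``.

    Counts are integers for raw photon binning and reals after lifetime
    (FLCS) weighting or detrending; ``weighted`` flags traces that may carry
    negative values.
    """

    counts: np.ndarray
    bin_width: float
    t0: float = 0.0
    weighted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if not self.weighted and self.counts.size and self.counts.min() < 0:
            raise ValueError("negative counts in an unweighted trace")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.bin_width * np.arange(self.counts.size)

    def mean_rate(self) -> float:
        """Mean count rate in photons/s."""
        return float(self.counts.mean() / self.bin_width)

    def rebin(self, factor: int) -> "BinnedTrace":
        """Sum adjacent bins by an integer factor."""
        factor = int(factor)
        if factor < 1:
            raise ValueError("rebin factor must be >= 1")
        n = self.counts.size // factor * factor
        c = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return BinnedTrace(c, self.bin_width * factor, self.t0, self.weighted,
                           dict(self.meta))

    def write(self, path) -> None:
        meta = dict(self.meta)
        meta["format"] = "fcsbind-binned-trace-v1"
        meta["bin_width_s"] = repr(self.bin_width)
        meta["t0_s"] = repr(self.t0)
        meta["weighted"] = str(self.weighted)
        meta["columns"] = "time_s counts"
        t = self.times
        with open(path, "w") as fh:
            fh.write(_format_meta(meta))
            for ti, ci in zip(t, self.counts):
                fh.write(f"{ti:.9f}\t{ci:.9g}\n")

    @classmethod
    def read(cls, path) -> "BinnedTrace":
        text = Path(path).read_text().splitlines()
        meta = _parse_meta(text)
        if meta.get("format") != "fcsbind-binned-trace-v1":
            raise ValueError(f"{path}: not a binned-trace file")
        bin_width = float(meta.pop("bin_width_s"))
        t0 = float(meta.pop("t0_s", "0"))
        weighted = meta.pop("weighted", "False") == "True"
        meta.pop("format"); meta.pop("columns", None)
        body = [ln for ln in text if ln and not ln.startswith("#")]
        counts = np.loadtxt(io.StringIO("\n".join(body)), ndmin=2)[:, 1] if body \
            else np.empty(0)
        return cls(counts, bin_width, t0, weighted, meta)


def bin_photons(trace: PhotonTrace, bin_width: float) -> BinnedTrace:
    """Histogram photon arrivals into bins of ``bin_width`` seconds.

    counts[k] counts photons with k*bin_width <= t < (k+1)*bin_width; the
    total photon number is conserved exactly (a photon at t == duration is
    assigned to the last bin).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    if bin_width > trace.duration:
        raise ValueError(
            f"bin_width {bin_width} s exceeds trace duration {trace.duration} s")
    n_bins = int(np.ceil(trace.duration / bin_width))
    idx = np.minimum((trace.arrival_times / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return BinnedTrace(counts, bin_width, 0.0, False, dict(trace.meta))


def photons_from_binned(trace: BinnedTrace, rng=None) -> PhotonTrace:
    """Draw photon arrival times consistent with a binned trace.

    Counts per bin are kept exactly; arrival times are placed uniformly at
    random within each bin, which realises an inhomogeneous Poisson process
    with piecewise-constant rate at the trace's bin resolution.
    """
    if trace.weighted:
        raise ValueError("cannot draw photons from a weighted (filtered) trace")
    rng = np.random.default_rng(rng)
    counts = trace.counts.astype(np.int64)
    starts = np.repeat(trace.times, counts)
    times = starts + rng.random(starts.size) * trace.bin_width
    times.sort()
    return PhotonTrace(times, trace.duration, None, dict(trace.meta))
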