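"""Synthetic-signal generators with known ground truth.

Every analysis stage in this package has a generator here that produces
inputs with the exact statistical structure the stage assumes, so the whole
pipeline is testable without any clinical recording:

* white noise, fractional Gaussian noise with known Hurst exponent (exact
  circulant-embedding synthesis), and random walks — calibration inputs for
  DFA;
* spectra built from a 1/f^beta background plus five Gaussian band peaks in
  log power, and time series synthesized from them by random-phase inverse
  FFT — ground truth for the band decomposition;
* branching-process event rasters with controllable branching ratio — ground
  truth for avalanche statistics (critical branching gives the mean-field
  size exponent 3/2 and duration exponent 2);
* discrete power-law samples by exact inverse-CDF draws — ground truth for
  the MLE;
* embedding of a raster as negative deflections in smoothed unit-variance
  noise — end-to-end input for the z-score/threshold/bin/extract chain.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special

from .avalanches import BinnedActivity, EventRaster
from .recordings import ChannelInfo, Epoch

__all__ = [
    "gen_white",
    "gen_fgn",
    "gen_random_walk",
    "gen_spectral_mixture",
    "gen_branching_raster",
    "gen_powerlaw_sample",
    "raster_to_signal",
    "BranchingResult",
]


def gen_white(n: int, seed: int) -> np.ndarray:
    """I.i.d. standard Gaussian noise."""
    if n < 8:
        raise ValueError("n must be >= 8")
    return np.random.default_rng(seed).standard_normal(n)


def fgn_autocovariance(H: float, k) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise at lag k:
    gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H) / 2."""
    k = np.abs(np.asarray(k, float))
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                  + np.abs(k - 1) ** (2 * H))


def gen_fgn(H: float, n: int, seed: int) -> np.ndarray:
    """Stationary fractional Gaussian noise by exact circulant embedding
    (Davies-Harte).

    The autocovariance sequence is embedded in a circulant matrix of order
    2(n-1) whose eigenvalues (the FFT of the first row) must be non-negative;
    for fGn they are, up to rounding, for all H in (0, 1). The synthesis is
    exact: the output has the true fGn covariance, unit variance.
    """
    if not 0 < H < 1:
        raise ValueError(f"H must lie in (0, 1), got {H}")
    if n < 2:
        raise ValueError("n must be >= 2")
    m = 2 * (n - 1)
    gamma = fgn_autocovariance(H, np.arange(n))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError(
            f"circulant embedding not non-negative definite for H={H}"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    return w.real[:n] * np.sqrt(2.0)


def gen_random_walk(n: int, seed: int) -> np.ndarray:
    """Cumulative sum of :func:`gen_white`; differencing recovers the
    generating white sequence exactly."""
    return np.cumsum(gen_white(n, seed))


def gen_spectral_mixture(components, beta: float, n: int, fs: float,
                         seed: int) -> np.ndarray:
    """Time series whose PSD follows a 1/f^beta background plus Gaussian
    band peaks in log10 power.

    ``components`` is an iterable of (amplitude, center_hz, sigma_hz)
    triples; centers must lie in 0.7-75 Hz. The target one-sided log10 PSD is

        log10 P(f) = -beta * log10(f) + sum_i A_i exp(-(f-c_i)^2 / (2 s_i^2))

    and the series is synthesized by inverse-transforming the corresponding
    amplitude spectrum with seeded uniform random phases, so its Welch PSD
    matches the target shape within sampling error.
    """
    comps = [tuple(map(float, c)) for c in components]
    for a, c, s in comps:
        if not 0.7 <= c <= 75.0:
            raise ValueError(f"component center {c} Hz outside 0.7-75 Hz")
        if s <= 0:
            raise ValueError("component sigma must be positive")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = fs / n
    if comps and n * min(s for _, _, s in comps) / fs < 2:
        raise ValueError("n too small to resolve the narrowest component")
    log_p = np.zeros_like(freqs)
    with np.errstate(divide="ignore"):
        f_safe = np.maximum(freqs, df)  # background defined away from DC
        log_p -= beta * np.log10(f_safe)
    for a, c, s in comps:
        log_p += a * np.exp(-((freqs - c) ** 2) / (2 * s**2))
    amp = np.sqrt(10.0**log_p)
    amp[0] = 0.0  # zero mean
    rng = np.random.default_rng(seed)
    phases = np.exp(2j * np.pi * rng.uniform(size=freqs.size))
    phases[0] = 1.0
    if n % 2 == 0:
        phases[-1] = 1.0  # Nyquist bin must be real
    return np.fft.irfft(amp * phases, n=n)


# ---------------------------------------------------------------------------
# branching-process rasters
# ---------------------------------------------------------------------------

@dataclass
class BranchingResult:
    """Output of :func:`gen_branching_raster`.

    ``binned`` holds the exact per-bin ground-truth event counts (cascades
    separated by one empty bin). ``raster`` places those events onto
    (channel, sample) slots and may be None when not requested; placement
    saturates (with a warning) if a bin receives more events than
    n_channels x samples_per_bin.
    """

    binned: BinnedActivity
    raster: EventRaster | None
    sizes: np.ndarray       # ground-truth cascade sizes
    durations: np.ndarray   # ground-truth cascade durations (bins)
    n_truncated: int        # cascades stopped by the supercritical guard


def gen_branching_raster(n_channels: int = 16, m_b: float = 1.0,
                         cascades: int = 1000, seed: int = 0,
                         bin_ms: float = 10.0, fs: float = 200.0,
                         size_cap: int = 10_000, spacing_bins: int = 1,
                         build_raster: bool = True) -> BranchingResult:
    """Event raster from a Galton-Watson branching process.

    Each cascade starts with one seed event in an empty bin; every event in
    bin b spawns Poisson(m_b) offspring events in bin b+1, each assigned to a
    uniformly random channel; the cascade runs to extinction (or until the
    ``size_cap`` supercritical guard truncates it, with a warning). Cascades
    are separated by ``spacing_bins`` empty bins (at least one), so
    ground-truth avalanche boundaries are known exactly; larger spacing
    lowers the overall event density, which matters when the raster is to be
    embedded in noise by :func:`raster_to_signal`. At m_b = 1 (critical) the size distribution approaches the
    mean-field power law with exponent 3/2 and the duration exponent 2.
    """
    if m_b <= 0:
        raise ValueError("branching ratio m_b must be positive")
    if n_channels < 1 or cascades < 1:
        raise ValueError("n_channels and cascades must be >= 1")
    if spacing_bins < 1:
        raise ValueError("spacing_bins must be >= 1")
    spb_f = bin_ms * fs / 1000.0
    spb = int(round(spb_f))
    if spb < 1 or abs(spb_f - spb) > 1e-9:
        raise ValueError(f"bin of {bin_ms} ms is not an integer number of "
                         f"samples at fs={fs}")

    rng = np.random.default_rng(seed)
    # vectorized generation-by-generation evolution of all cascades at once
    active = np.ones(cascades, dtype=np.int64)
    sizes = active.copy()
    durations = np.ones(cascades, dtype=np.int64)
    truncated = np.zeros(cascades, dtype=bool)
    gen_counts = [active.copy()]
    while True:
        alive = active > 0
        if not alive.any():
            break
        nxt = np.zeros_like(active)
        nxt[alive] = rng.poisson(m_b * active[alive])
        over = sizes + nxt > size_cap
        if over.any():
            truncated |= over & (nxt > 0)
            nxt[over] = 0
        sizes += nxt
        durations += (nxt > 0).astype(np.int64)
        active = nxt
        if (nxt > 0).any():
            gen_counts.append(nxt.copy())
        else:
            break
    n_trunc = int(truncated.sum())
    if n_trunc:
        warnings.warn(
            f"{n_trunc} cascades truncated at the {size_cap}-event guard",
            stacklevel=2,
        )

    # lay cascades into a count sequence: [gap, cascade, gap, cascade, ...]
    starts = spacing_bins + np.concatenate(
        ([0], np.cumsum(durations + spacing_bins)[:-1]))
    n_bins = int(starts[-1] + durations[-1] + spacing_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for g, gc in enumerate(gen_counts):
        has = gc > 0
        counts[starts[has] + g] = gc[has]
    binned = BinnedActivity(counts=counts, bin_ms=bin_ms, fs=fs)

    raster = None
    if build_raster:
        events = np.zeros((n_channels, n_bins * spb), dtype=np.uint8)
        slots = n_channels * spb
        saturated = 0
        for b in np.nonzero(counts)[0]:
            k = int(counts[b])
            if k > slots:
                saturated += k - slots
                k = slots
            chosen = rng.choice(slots, size=k, replace=False)
            ch, off = np.divmod(chosen, spb)
            events[ch, b * spb + off] = 1
        if saturated:
            warnings.warn(
                f"raster placement saturated: {saturated} events dropped "
                "(counts remain the ground truth)", stacklevel=2,
            )
        raster = EventRaster(events=events, fs=fs)
    return BranchingResult(binned=binned, raster=raster, sizes=sizes,
                           durations=durations, n_truncated=n_trunc)


# ---------------------------------------------------------------------------
# discrete power-law samples
# ---------------------------------------------------------------------------

def gen_powerlaw_sample(tau: float, xmin: int, n: int, seed: int,
                        table_size: int = 100_000) -> np.ndarray:
    """Exact i.i.d. draws from P(x) = x^-tau / zeta(tau, xmin) on
    {xmin, xmin+1, ...} by inverse CDF.

    The CDF is tabulated on {xmin, ..., xmin + table_size}; the rare draws
    beyond the table are resolved by bisection on the Hurwitz-zeta survival
    function, so the sampler is exact over the whole support.
    """
    if tau <= 1:
        raise ValueError("tau must exceed 1")
    if xmin < 1:
        raise ValueError("xmin must be >= 1")
    rng = np.random.default_rng(seed)
    z0 = float(special.zeta(tau, xmin))
    support = np.arange(xmin, xmin + table_size, dtype=float)
    cdf = np.cumsum(support**-tau) / z0
    u = rng.uniform(size=n)
    out = xmin + np.searchsorted(cdf, u, side="left")
    beyond = out >= xmin + table_size
    if beyond.any():
        def cdf_at(x: float) -> float:
            return 1.0 - float(special.zeta(tau, x + 1)) / z0
        for i in np.nonzero(beyond)[0]:
            lo, hi = xmin + table_size - 1, xmin + table_size
            while cdf_at(hi) < u[i]:
                lo, hi = hi, hi * 2
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if cdf_at(mid) >= u[i]:
                    hi = mid
                else:
                    lo = mid
            out[i] = hi
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# raster embedding
# ---------------------------------------------------------------------------

#: Gaussian smoothing width (samples) of the background noise; 0.25 s at
#: 200 Hz, mimicking the slow-wave-dominated background of sleep iEEG so
#: that spontaneous -2 SD crossings are rare relative to planted events.
NOISE_SMOOTH_SAMPLES = 50.0


def raster_to_signal(raster: EventRaster, pulse_amp_sd: float = -3.5,
                     fs: float | None = None, seed: int = 0,
                     noise_smooth: float = NOISE_SMOOTH_SAMPLES,
                     state: str = "W") -> Epoch:
    """Embed an event raster as negative deflections in smooth background
    noise.

    Each channel is unit-variance Gaussian noise, low-pass smoothed with a
    Gaussian kernel of ``noise_smooth`` samples; at every event the sample is
    set to ``pulse_amp_sd`` (a one-sample deflection, in noise-SD units).
    Pushing the result through zscore -> detect_events(-2.0) recovers the
    planted events at high sensitivity with few spurious crossings.
    """
    if pulse_amp_sd >= -2.0:
        raise ValueError(
            f"pulse_amp_sd={pulse_amp_sd} too shallow; must be < -2.0"
        )
    fs = raster.fs if fs is None else fs
    n_ch, n = raster.events.shape
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_ch, n))
    if noise_smooth > 0:
        noise = ndimage.gaussian_filter1d(noise, noise_smooth, axis=1,
                                          mode="wrap")
        noise /= noise.std(axis=1, keepdims=True)
    sig = noise.copy()
    sig[raster.events.astype(bool)] = pulse_amp_sd
    channels = [ChannelInfo(channel_id=f"syn{i}") for i in range(n_ch)]
    return Epoch(samples=sig, fs=fs, state=state, channels=channels)
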