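"""Power spectral density estimation and Gaussian band decomposition.

PSDs are estimated either as a single demeaned periodogram (scaled so the
power bins sum to the signal variance — discrete Parseval) or by Welch's
method (Hann-tapered, 50%-overlapping, segment-wise demeaned segments; the
study defaults are 600-sample windows at fs = 200 Hz, i.e. 0.333 Hz
resolution and 39 averaged segments per 60 s epoch).

Band structure is summarized by modelling the smoothed log10 spectrum in the
0.7–75 Hz range as a sum of five Gaussians, one per canonical EEG band
(delta 0.7–4 Hz, theta 4–8, alpha 8–12, beta 12–30, gamma 30–75 Hz), each
with free amplitude, center and width. Fits are accepted when R^2 >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal

__all__ = [
    "BANDS",
    "PSDEstimate",
    "BandComponent",
    "BandFitResults",
    "BandSpectrumModel",
    "periodogram",
    "welch_psd",
    "normalize_by_mean",
    "smooth_sg",
    "fit_band_gaussians",
]

#: Canonical EEG bands, contiguous over 0.7-75 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.7, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 75.0),
}

#: Analysis frequency range (Hz); spectra are masked to this before fitting.
FREQ_RANGE = (0.7, 75.0)

#: Acceptance threshold on R^2 of the five-Gaussian fit.
R2_ACCEPT = 0.95


@dataclass
class PSDEstimate:
    """A one-sided PSD: frequency grid plus non-negative power values."""

    freqs_hz: np.ndarray
    power: np.ndarray
    method: str = "periodogram"
    window_len: int = 0
    overlap_frac: float = 0.0
    n_segments: int = 1

    def __post_init__(self):
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.power = np.asarray(self.power, float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs_hz and power must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if np.any(self.power < -1e-15):
            raise ValueError("negative power values")

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        return (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)


def periodogram(x, fs: float) -> PSDEstimate:
    """Single-segment, demeaned, unwindowed one-sided periodogram.

    Scaled so that ``sum(power)`` equals the (biased) signal variance, the
    discrete Parseval identity.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError(f"signal too short for a periodogram ({x.size} < 4)")
    n = x.size
    xd = x - x.mean()
    X = np.fft.rfft(xd)
    p = np.abs(X) ** 2 / n**2
    # double interior bins so the one-sided sum preserves total power
    w = np.full(p.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PSDEstimate(freqs, w * p, method="periodogram", window_len=n)


def welch_psd(x, fs: float, window_len: int = 600,
              overlap_frac: float = 0.5) -> PSDEstimate:
    """Welch PSD: Hann-tapered, demeaned, overlapping segments, averaged.

    One-sided density normalization (power per Hz); frequency spacing is
    ``fs / window_len``.
    """
    x = np.asarray(x, float)
    if x.size < window_len:
        raise ValueError(
            f"signal ({x.size} samples) shorter than one window ({window_len})"
        )
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    noverlap = int(round(window_len * overlap_frac))
    freqs, p = signal.welch(
        x, fs=fs, window="hann", nperseg=window_len, noverlap=noverlap,
        detrend="constant", scaling="density",
    )
    hop = window_len - noverlap
    n_seg = (x.size - window_len) // hop + 1
    return PSDEstimate(freqs, p, method="welch", window_len=window_len,
                       overlap_frac=overlap_frac, n_segments=n_seg)


def normalize_by_mean(psds: list[PSDEstimate]) -> list[PSDEstimate]:
    """Rescale each PSD by the pooled across-epoch mean at each frequency.

    The pooled mean of the outputs is exactly 1 at every frequency; relative
    shifts and crossover points between conditions are emphasized while the
    absolute power distribution is discarded.
    """
    if not psds:
        raise ValueError("no PSDs to normalize")
    grid = psds[0].freqs_hz
    for p in psds[1:]:
        if p.freqs_hz.shape != grid.shape or not np.allclose(p.freqs_hz, grid):
            raise ValueError("PSDs do not share one frequency grid")
    pooled = np.mean([p.power for p in psds], axis=0)
    if np.any(pooled <= 0):
        bad = grid[pooled <= 0]
        raise ValueError(f"zero pooled mean power at frequencies {bad[:5]}")
    return [replace(p, power=p.power / pooled) for p in psds]


def smooth_sg(psd: PSDEstimate, window_bins: int = 11,
              polyorder: int = 3) -> PSDEstimate:
    """Savitzky-Golay smoothing of the power values along the frequency axis."""
    if window_bins % 2 == 0 or window_bins <= polyorder:
        raise ValueError(
            f"window_bins must be odd and > polyorder "
            f"(got {window_bins}, {polyorder})"
        )
    sm = signal.savgol_filter(psd.power, window_bins, polyorder)
    return replace(psd, power=np.clip(sm, 0.0, None))


# ---------------------------------------------------------------------------
# five-Gaussian band decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandComponent:
    """One fitted Gaussian: band name, amplitude (log10-power units),
    center (Hz), sigma (Hz)."""

    band: str
    amplitude: float
    center_hz: float
    sigma_hz: float


@dataclass
class BandFitResults:
    """Result of the five-Gaussian decomposition of a log10 spectrum."""

    components: list[BandComponent]
    r_squared: float
    accepted: bool
    converged: bool
    message: str = ""

    def params(self) -> np.ndarray:
        """Flat (A, c, sigma) x 5 parameter vector, band order delta..gamma."""
        return np.array(
            [[c.amplitude, c.center_hz, c.sigma_hz] for c in self.components]
        ).ravel()

    def summary(self) -> str:
        lines = [
            "Five-Gaussian band decomposition (log10 power domain)",
            f"  R^2 = {self.r_squared:.4f}   "
            f"accepted (R^2 >= {R2_ACCEPT}): {self.accepted}",
            f"  {'band':<7}{'amplitude':>11}{'center Hz':>11}{'sigma Hz':>10}",
        ]
        for c in self.components:
            lines.append(
                f"  {c.band:<7}{c.amplitude:>11.4f}{c.center_hz:>11.3f}"
                f"{c.sigma_hz:>10.3f}"
            )
        return "\n".join(lines)


def _gaussian_sum(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of five Gaussians; params is (A, c, sigma) x 5 flattened."""
    p = params.reshape(5, 3)
    out = np.zeros_like(f)
    for a, c, s in p:
        out += a * np.exp(-((f - c) ** 2) / (2.0 * s**2))
    return out


class BandSpectrumModel:
    """Five-Gaussian model of a (smoothed) power spectrum.

    The model is fitted to ``log10(power)`` against linear frequency on the
    0.7–75 Hz grid. Each Gaussian is box-constrained: amplitude >= 0, center
    inside its band, sigma in [0.2 Hz, band width]. Fitting is multi-start
    nonlinear least squares: one start at band midpoints plus ``n_restarts``
    jittered starts from a seeded generator; the best R^2 wins, ties broken
    by the smallest total sigma.
    """

    MIN_SIGMA = 0.2  # Hz

    def __init__(self, psd: PSDEstimate,
                 bands: dict[str, tuple[float, float]] | None = None):
        self.bands = dict(bands) if bands is not None else dict(BANDS)
        mask = psd.band_mask(*FREQ_RANGE)
        self.freqs = psd.freqs_hz[mask]
        power = psd.power[mask]
        for name, (lo, hi) in self.bands.items():
            if np.count_nonzero((self.freqs >= lo) & (self.freqs <= hi)) < 3:
                raise ValueError(
                    f"fewer than 3 frequency points in band {name} ({lo}-{hi} Hz)"
                )
        with np.errstate(divide="ignore"):
            self.log_power = np.log10(np.maximum(power, 1e-300))

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        amp_hi = max(1.0, float(np.ptp(self.log_power)) * 2 + 1.0)
        for name in self.bands:
            b_lo, b_hi = self.bands[name]
            lo += [0.0, b_lo, self.MIN_SIGMA]
            hi += [amp_hi, b_hi, b_hi - b_lo]
        return np.array(lo), np.array(hi)

    def _starts(self, n_restarts: int, seed: int) -> list[np.ndarray]:
        lo, hi = self._bounds()
        base = []
        y = self.log_power
        for name, (b_lo, b_hi) in self.bands.items():
            mid = 0.5 * (b_lo + b_hi)
            amp0 = float(np.interp(mid, self.freqs, y))
            base += [max(amp0, 1e-3), mid, (b_hi - b_lo) / 4.0]
        base = np.clip(np.array(base), lo, hi)
        starts = [base]
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            jit = base * rng.uniform(0.5, 1.5, size=base.shape)
            starts.append(np.clip(jit, lo + 1e-9, hi - 1e-9))
        return starts

    def fit(self, n_restarts: int = 4, seed: int = 0) -> BandFitResults:
        # The sum of non-negative Gaussians is fitted to log10 power with no
        # additive baseline term, so the model presumes spectra expressed
        # relative to a reference level (e.g. after normalize_by_mean); the
        # acceptance flag reports when that presumption fails.
        yz = self.log_power
        lo, hi = self._bounds()

        def resid(p):
            return _gaussian_sum(self.freqs, p) - yz

        ss_tot = float(np.sum((yz - yz.mean()) ** 2))
        best = None
        for x0 in self._starts(n_restarts, seed):
            try:
                sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                             method="trf", max_nfev=20000)
            except Exception:
                continue
            ss_res = float(np.sum(sol.fun**2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
            sig_sum = float(sol.x.reshape(5, 3)[:, 2].sum())
            key = (-(r2 if np.isfinite(r2) else -np.inf), sig_sum)
            if best is None or key < best[0]:
                best = (key, sol, r2)

        if best is None:
            return BandFitResults(
                components=[BandComponent(b, 0.0, sum(self.bands[b]) / 2,
                                          self.MIN_SIGMA)
                            for b in self.bands],
                r_squared=float("nan"), accepted=False, converged=False,
                message="all optimizer starts failed",
            )
        _, sol, r2 = best
        comps = [
            BandComponent(band, float(a), float(c), float(s))
            for band, (a, c, s) in zip(self.bands, sol.x.reshape(5, 3))
        ]
        degenerate = ss_tot == 0.0
        accepted = bool(np.isfinite(r2) and r2 >= R2_ACCEPT and not degenerate)
        msg = "degenerate R^2: flat spectrum" if degenerate else ""
        return BandFitResults(components=comps,
                              r_squared=float(r2) if not degenerate else float("nan"),
                              accepted=accepted, converged=True, message=msg)


def fit_band_gaussians(psd: PSDEstimate, n_restarts: int = 4,
                       seed: int = 0) -> BandFitResults:
    """Fit the five-Gaussian band model to a PSD (functional wrapper)."""
    return BandSpectrumModel(psd).fit(n_restarts=n_restarts, seed=seed)
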