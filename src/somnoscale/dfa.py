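"""Detrended fluctuation analysis (DFA) with fit-range control.

DFA estimates a scaling exponent alpha from the growth of detrended profile
fluctuations with window size:

1. profile: X_i = sum_{j<=i} (x_j - <x>) (cumulative sum of the demeaned
   signal);
2. a log-spaced grid of window sizes from 4 samples to the signal length;
3. at each window size, consecutive windows with 50% overlap are linearly
   detrended by least squares and the fluctuation F is the RMS of the pooled
   detrended residuals;
4. alpha is the OLS slope of log10 F versus log10 window size, restricted to
   a fit range (default 0.04-2.5 s, i.e. 8-500 samples at 200 Hz).

Interpretation of alpha: 0.5 for an uncorrelated process, below 0.5
anti-correlated, between 0.5 and 1 stationary long-range temporal
correlations, above 1 non-stationary integrated dynamics. DFA alpha equals
the Hurst exponent H for stationary fractional Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DFAResults",
    "DetrendedFluctuationAnalysis",
    "profile",
    "window_grid",
    "fluctuation_at",
    "dfa",
]

FIT_LO_S = 0.04
FIT_HI_S = 2.5
N_SCALES = 30
MIN_WINDOW = 4

#: half-width of the band around 0.5 classified as "uncorrelated"
UNCORRELATED_TOL = 0.02


def profile(x) -> np.ndarray:
    """Cumulative sum of the demeaned signal; its last element is ~0."""
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError(f"signal too short for DFA ({x.size} < 4)")
    return np.cumsum(x - x.mean())


def window_grid(n_samples: int, n_scales: int = N_SCALES,
                min_window: int = MIN_WINDOW) -> np.ndarray:
    """Log-spaced integer window sizes in [min_window, n_samples],
    deduplicated and sorted."""
    if n_samples < 2 * min_window:
        raise ValueError(
            f"n_samples={n_samples} too short (need >= {2 * min_window})"
        )
    grid = np.geomspace(min_window, n_samples, num=max(n_scales, 2))
    return np.unique(np.round(grid).astype(int))


def fluctuation_at(prof: np.ndarray, window: int) -> float:
    """RMS of linearly detrended residuals over 50%-overlapping windows.

    The hop is floor(window/2); a trailing partial window is dropped. The
    squared residuals of all windows are pooled before the root is taken.
    """
    prof = np.asarray(prof, float)
    n = prof.size
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    if window < 2:
        raise ValueError("window must be >= 2")
    hop = max(window // 2, 1)
    starts = np.arange(0, n - window + 1, hop)
    segs = prof[starts[:, None] + np.arange(window)]  # (n_win, window)

    # closed-form per-window linear detrend on t = 0..window-1
    t = np.arange(window, dtype=float)
    t_mean = t.mean()
    t_var = np.sum((t - t_mean) ** 2)
    y_mean = segs.mean(axis=1, keepdims=True)
    slope = (segs - y_mean) @ (t - t_mean) / t_var
    resid = segs - y_mean - slope[:, None] * (t - t_mean)
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class DFAResults:
    """Fitted DFA: the F(window) curve, the exponent and its regime."""

    window_sizes: np.ndarray       # samples
    fluctuation: np.ndarray
    alpha: float
    alpha_stderr: float
    fit_lo_s: float
    fit_hi_s: float
    fs: float
    n_fit: int
    regime: str

    @property
    def window_sizes_s(self) -> np.ndarray:
        return self.window_sizes / self.fs

    def alpha_ab(self) -> str:
        from .group_stats import format_ab
        return format_ab(self.alpha, self.alpha_stderr)

    def summary(self) -> str:
        return (
            "Detrended fluctuation analysis\n"
            f"  alpha     = {self.alpha_ab()}  (OLS on log10 F vs log10 dt)\n"
            f"  fit range = {self.fit_lo_s:g}-{self.fit_hi_s:g} s "
            f"({self.n_fit} scales)\n"
            f"  regime    = {self.regime}"
        )

    def plot(self, ax=None):
        """log-log F(dt) curve with the fitted slope over the fit range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        w_s = self.window_sizes_s
        ax.loglog(w_s, self.fluctuation, "o", ms=3, label="F(dt)")
        m = (w_s >= self.fit_lo_s) & (w_s <= self.fit_hi_s)
        if m.any():
            x = w_s[m]
            y0 = self.fluctuation[m][0]
            ax.loglog(x, y0 * (x / x[0]) ** self.alpha, "-",
                      label=f"alpha = {self.alpha:.2f}")
        ax.set_xlabel("window size (s)")
        ax.set_ylabel("F")
        ax.legend()
        return ax


def classify_regime(alpha: float) -> str:
    """Regime label for a DFA exponent.

    alpha within +-0.02 of 0.5 is called uncorrelated; below that band
    anticorrelated; up to 1 correlated (stationary LRTC); above 1
    non-stationary.
    """
    if abs(alpha - 0.5) <= UNCORRELATED_TOL:
        return "uncorrelated"
    if alpha < 0.5:
        return "anticorrelated"
    if alpha <= 1.0:
        return "correlated"
    return "nonstationary"


class DetrendedFluctuationAnalysis:
    """DFA model for one signal; ``fit`` returns :class:`DFAResults`."""

    def __init__(self, signal, fs: float, n_scales: int = N_SCALES,
                 min_window: int = MIN_WINDOW):
        self.signal = np.asarray(signal, float)
        self.fs = float(fs)
        self.prof = profile(self.signal)
        self.window_sizes = window_grid(self.prof.size, n_scales=n_scales,
                                        min_window=min_window)

    def fit(self, fit_lo_s: float = FIT_LO_S,
            fit_hi_s: float = FIT_HI_S) -> DFAResults:
        if self.signal.size < fit_hi_s * self.fs:
            raise ValueError(
                f"signal ({self.signal.size} samples) shorter than the upper "
                f"fit scale ({fit_hi_s} s = {fit_hi_s * self.fs:g} samples)"
            )
        F = np.array([fluctuation_at(self.prof, int(w))
                      for w in self.window_sizes])
        keep = F > 0
        if not keep.all():
            warnings.warn(
                f"dropping {np.count_nonzero(~keep)} scales with zero "
                "fluctuation", stacklevel=2,
            )
        w = self.window_sizes[keep]
        F = F[keep]
        lo, hi = fit_lo_s * self.fs, fit_hi_s * self.fs
        m = (w >= lo) & (w <= hi)  # endpoints inclusive in samples
        if np.count_nonzero(m) < 3:
            raise ValueError(
                f"only {np.count_nonzero(m)} usable scales in the fit range "
                f"[{fit_lo_s}, {fit_hi_s}] s; need >= 3"
            )
        reg = stats.linregress(np.log10(w[m]), np.log10(F[m]))
        alpha = float(reg.slope)
        return DFAResults(
            window_sizes=w, fluctuation=F, alpha=alpha,
            alpha_stderr=float(reg.stderr), fit_lo_s=fit_lo_s,
            fit_hi_s=fit_hi_s, fs=self.fs, n_fit=int(np.count_nonzero(m)),
            regime=classify_regime(alpha),
        )


def dfa(signal, fs: float, fit_lo_s: float = FIT_LO_S,
        fit_hi_s: float = FIT_HI_S, n_scales: int = N_SCALES) -> DFAResults:
    """Run DFA on one signal (functional wrapper)."""
    return DetrendedFluctuationAnalysis(signal, fs, n_scales=n_scales).fit(
        fit_lo_s=fit_lo_s, fit_hi_s=fit_hi_s
    )
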