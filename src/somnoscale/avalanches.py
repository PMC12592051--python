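"""Neuronal avalanche statistics: event detection, binning, cascade
extraction, discrete power-law inference, size-duration scaling, and the
crackling-noise consistency check.

The event-based avalanche definition follows the standard construction for
multichannel field potentials: each channel is z-scored; a discrete event is
registered at every negative-going crossing of a threshold (default -2.0 SD);
events are pooled over channels into consecutive non-overlapping bins
(default 10 ms); an avalanche is a maximal run of contiguous active bins
bounded by empty bins, with size s = total events in the run and duration
T = number of bins.

Size and duration distributions are fitted with a discrete power law
P(x) ∝ x^-tau on {xmin, xmin+1, ...} (Hurwitz-zeta normalization, default
xmin = 3) by maximum likelihood, optionally with an exponential cutoff
P(x) ∝ x^-tau e^(-lambda x). Goodness of fit is the Kolmogorov-Smirnov
distance over the fitted tail; the exponent's standard error comes from the
observed Fisher information.

The crackling-noise relation alpha = 1 + (tau - 1) * gamma ties the size
exponent tau, duration exponent alpha and the size-duration scaling exponent
gamma of scale-free avalanches; :func:`crackling_check` reports the implied
gamma and its discrepancy from the directly fitted one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .recordings import Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "EventRaster",
    "BinnedActivity",
    "Avalanche",
    "PowerLawResults",
    "DiscretePowerLaw",
    "ScalingFit",
    "CracklingReport",
    "detect_events",
    "bin_raster",
    "extract_avalanches",
    "mean_activity_per_active_bin",
    "subsample_channels",
    "fit_power_law",
    "size_duration_scaling",
    "crackling_check",
    "sensitivity_sweep",
]

DEFAULT_THRESHOLD_SD = -2.0
DEFAULT_BIN_MS = 10.0
DEFAULT_XMIN = 3
MIN_TAIL = 50  # default floor on observations >= xmin for a power-law fit

#: Reference band for the size-duration scaling exponent gamma across
#: vigilance states (N3 low end to wakefulness high end).
GAMMA_BAND = (1.10, 1.40)


@dataclass
class EventRaster:
    """Binary per-channel event trains at the signal sampling rate."""

    events: np.ndarray  # (n_channels, N), uint8 in {0, 1}
    fs: float
    threshold_sd: float = DEFAULT_THRESHOLD_SD

    def __post_init__(self):
        self.events = np.asarray(self.events)
        if self.events.ndim != 2:
            raise ValueError("events must be 2-D (n_channels x N)")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        if self.threshold_sd >= 0:
            raise ValueError("threshold_sd must be negative")
        self.events = self.events.astype(np.uint8)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class BinnedActivity:
    """Pooled event counts in consecutive, non-overlapping time bins."""

    counts: np.ndarray  # (n_bins,), non-negative ints
    bin_ms: float = DEFAULT_BIN_MS
    fs: float = 200.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise ValueError("counts must be a 1-D non-negative sequence")
        self.counts = self.counts.astype(np.int64)


@dataclass(frozen=True)
class Avalanche:
    """One cascade: size s (events), duration T (bins), start bin index.

    ``edge`` marks runs touching the start or end of the record, which are
    retained but flagged.
    """

    size: int
    duration: int
    start_bin: int
    edge: bool = False


def detect_events(epoch: Epoch,
                  threshold_sd: float = DEFAULT_THRESHOLD_SD) -> EventRaster:
    """Register one event per negative-going threshold crossing per channel.

    An event occurs at sample i when z[i] < threshold and z[i-1] >= threshold;
    a channel already below threshold at its first sample contributes one
    event at index 0. The input must be z-scored (zero mean, unit SD per
    channel).
    """
    if threshold_sd >= 0:
        raise ValueError("threshold_sd must be negative")
    z = epoch.samples
    sd = z.std(axis=1)
    mu = z.mean(axis=1)
    bad = np.nonzero((np.abs(sd - 1.0) > 1e-3) | (np.abs(mu) > 1e-3))[0]
    if bad.size:
        names = [epoch.channels[i].channel_id for i in bad]
        raise ValueError(
            f"channels not z-scored (apply recordings.zscore first): {names}"
        )
    below = z < threshold_sd
    crossings = np.zeros_like(below)
    crossings[:, 1:] = below[:, 1:] & ~below[:, :-1]
    crossings[:, 0] = below[:, 0]
    return EventRaster(events=crossings.astype(np.uint8), fs=epoch.fs,
                       threshold_sd=threshold_sd)


def bin_raster(raster: EventRaster, bin_ms: float = DEFAULT_BIN_MS) -> BinnedActivity:
    """Pool events over channels into consecutive non-overlapping bins.

    ``bin_ms`` must correspond to an integer number of samples (2 samples at
    10 ms / 200 Hz). A trailing partial bin is dropped and logged.
    """
    spb_f = bin_ms * raster.fs / 1000.0
    spb = int(round(spb_f))
    if spb < 1 or abs(spb_f - spb) > 1e-9:
        raise ValueError(
            f"bin of {bin_ms} ms is {spb_f:g} samples at fs={raster.fs}; "
            "must be a positive integer"
        )
    n = raster.events.shape[1]
    n_bins = n // spb
    if n - n_bins * spb:
        logger.info("dropping %d trailing samples (partial bin)",
                    n - n_bins * spb)
    pooled = raster.events[:, :n_bins * spb].sum(axis=0)
    counts = pooled.reshape(n_bins, spb).sum(axis=1)
    return BinnedActivity(counts=counts, bin_ms=bin_ms, fs=raster.fs)


def extract_avalanches(binned: BinnedActivity) -> list[Avalanche]:
    """Maximal runs of active (count > 0) bins, bounded by empty bins.

    Runs touching the record edges are kept, flagged ``edge=True``. The sum
    of sizes over all avalanches equals the total event count.
    """
    c = binned.counts
    if c.size == 0:
        return []
    active = c > 0
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive
    csum = np.concatenate(([0], np.cumsum(c)))
    out = []
    for s0, e0 in zip(starts, ends):
        out.append(Avalanche(
            size=int(csum[e0] - csum[s0]),
            duration=int(e0 - s0),
            start_bin=int(s0),
            edge=bool(s0 == 0 or e0 == c.size),
        ))
    return out


def mean_activity_per_active_bin(binned: BinnedActivity) -> float:
    """Total events divided by the number of active bins; >= 1 by definition."""
    c = binned.counts
    n_active = int(np.count_nonzero(c))
    if n_active == 0:
        raise ValueError("no active bins")
    return float(c.sum() / n_active)


def subsample_channels(epoch: Epoch, k: int = 16,
                       seed: int | None = 0) -> Epoch:
    """Uniform random subset of exactly k channels, deterministic given seed.

    Recordings with fewer than k channels are rejected (such patients are
    excluded upstream to keep spatial sampling comparable).
    """
    if epoch.n_channels < k:
        raise ValueError(
            f"epoch has {epoch.n_channels} channels; at least {k} required"
        )
    if epoch.n_channels == k:
        return epoch
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(epoch.n_channels, size=k, replace=False))
    return replace(epoch, samples=epoch.samples[idx].copy(),
                   channels=[epoch.channels[i] for i in idx])


# ---------------------------------------------------------------------------
# discrete power-law maximum likelihood
# ---------------------------------------------------------------------------

def _log_zeta(tau: float, xmin: int) -> float:
    return float(np.log(special.zeta(tau, xmin)))


def _truncated_log_norm(tau: float, lam: float, xmin: int) -> float:
    """log of sum_{x=xmin}^inf x^-tau e^(-lam x), by direct summation.

    Terms decay at least geometrically once lam > 0; for lam == 0 the
    Hurwitz zeta is used instead.
    """
    if lam == 0.0:
        return _log_zeta(tau, xmin)
    block, total, x = 4096, 0.0, xmin
    log_scale = -tau * np.log(xmin) - lam * xmin  # overflow guard
    for _ in range(10000):
        xs = np.arange(x, x + block, dtype=float)
        t = np.exp(-tau * np.log(xs) - lam * xs - log_scale)
        total += float(t.sum())
        x += block
        if t[-1] < 1e-17 * max(total, 1e-300):
            break
    return float(np.log(total) + log_scale)


@dataclass
class PowerLawResults:
    """MLE fit of a discrete power law (optionally exponentially truncated).

    ``exponent`` is tau for avalanche sizes or alpha for durations; the
    stderr comes from the observed Fisher information. ``ks_distance`` is the
    max |empirical CDF - fitted CDF| over observed values >= xmin.
    """

    exponent: float
    stderr: float
    xmin: int
    ks_distance: float
    n_tail: int
    lambda_cutoff: float | None = None
    loglik: float = float("nan")
    model: "DiscretePowerLaw | None" = field(default=None, repr=False)

    def exponent_ab(self) -> str:
        """Exponent in compact a(b) uncertainty notation."""
        from .group_stats import format_ab
        return format_ab(self.exponent, self.stderr)

    def summary(self) -> str:
        kind = ("discrete power law with exponential cutoff"
                if self.lambda_cutoff is not None else "discrete power law")
        lines = [
            f"{kind} (maximum likelihood)",
            f"  exponent  = {self.exponent_ab()}   "
            f"(SE {self.stderr:.4g}, Fisher information)",
            f"  xmin      = {self.xmin}",
            f"  n >= xmin = {self.n_tail}",
            f"  KS        = {self.ks_distance:.4f}",
        ]
        if self.lambda_cutoff is not None:
            lines.insert(3, f"  lambda    = {self.lambda_cutoff:.4g}")
        return "\n".join(lines)


class DiscretePowerLaw:
    """Discrete power-law model P(x) = x^-tau / zeta(tau, xmin) on
    {xmin, xmin+1, ...}, fitted by numerical likelihood maximization.

    With ``truncated=True`` the exponentially truncated variant
    P(x) ∝ x^-tau e^(-lambda x) is fitted jointly over (tau, lambda >= 0).
    Observations below xmin are discarded before fitting.
    """

    def __init__(self, data, xmin: int = DEFAULT_XMIN,
                 truncated: bool = False, min_tail: int = MIN_TAIL):
        data = np.asarray(data)
        if data.size == 0:
            raise ValueError("empty sample")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("discrete model requires integer data")
            data = np.round(data).astype(np.int64)
        if (data < 1).any():
            raise ValueError("values must be positive integers")
        self.xmin = int(xmin)
        self.truncated = truncated
        self.tail = np.sort(data[data >= self.xmin]).astype(np.int64)
        if self.tail.size < min_tail:
            raise ValueError(
                f"only {self.tail.size} observations >= xmin={self.xmin}; "
                f"need at least {min_tail}"
            )
        if self.tail[0] == self.tail[-1]:
            raise ValueError(
                f"all tail values equal ({self.tail[0]}); likelihood degenerate"
            )
        self._mean_log = float(np.mean(np.log(self.tail)))
        self._mean_x = float(np.mean(self.tail))

    # -- likelihood -------------------------------------------------------

    def nll(self, tau: float, lam: float = 0.0) -> float:
        """Negative log-likelihood per observation."""
        if tau <= 1.0 and lam == 0.0:
            return np.inf  # pure power law not normalizable
        return tau * self._mean_log + lam * self._mean_x + \
            _truncated_log_norm(tau, lam, self.xmin)

    def fit(self) -> PowerLawResults:
        if self.truncated:
            res = optimize.minimize(
                lambda p: self.nll(p[0], p[1]),
                x0=np.array([1.5, 1e-3]),
                bounds=[(0.01, 20.0), (0.0, 5.0)],
                method="L-BFGS-B",
            )
            tau, lam = float(res.x[0]), float(res.x[1])
            stderr = self._stderr_tau(tau, lam)
            nll = float(res.fun)
        else:
            res = optimize.minimize_scalar(
                lambda t: self.nll(t), bounds=(1.0 + 1e-6, 20.0),
                method="bounded",
                options={"xatol": 1e-8},
            )
            tau, lam = float(res.x), None
            stderr = self._stderr_tau(tau, 0.0)
            nll = float(res.fun)
        ks = self.ks_distance(tau, lam or 0.0)
        return PowerLawResults(
            exponent=tau, stderr=stderr, xmin=self.xmin, ks_distance=ks,
            n_tail=self.tail.size, lambda_cutoff=lam,
            loglik=-nll * self.tail.size, model=self,
        )

    def _stderr_tau(self, tau: float, lam: float) -> float:
        """SE of tau from the observed Fisher information (numerical second
        derivative of the total negative log-likelihood)."""
        h = 1e-4
        d2 = (self.nll(tau + h, lam) - 2 * self.nll(tau, lam)
              + self.nll(tau - h, lam)) / h**2
        d2 *= self.tail.size
        if not np.isfinite(d2) or d2 <= 0:
            return float("nan")
        return float(1.0 / np.sqrt(d2))

    # -- goodness of fit ---------------------------------------------------

    def _cdf_at(self, xs: np.ndarray, tau: float, lam: float) -> np.ndarray:
        """Fitted CDF evaluated at integer points xs (>= xmin - 1).

        For the pure model the survival function is a ratio of Hurwitz zetas,
        so no support array is materialized (the observed tail can span many
        decades). The truncated model has a short tail and is summed directly.
        """
        xs = np.asarray(xs, dtype=np.int64)
        if lam == 0.0:
            z0 = float(special.zeta(tau, self.xmin))
            return 1.0 - special.zeta(tau, xs.astype(float) + 1.0) / z0
        support = np.arange(self.xmin, int(xs.max()) + 1, dtype=float)
        log_pmf = -tau * np.log(support) - lam * support \
            - _truncated_log_norm(tau, lam, self.xmin)
        cdf = np.cumsum(np.exp(log_pmf))
        out = np.zeros(xs.shape, float)
        inside = xs >= self.xmin
        out[inside] = cdf[xs[inside] - self.xmin]
        return out

    def ks_distance(self, tau: float, lam: float = 0.0) -> float:
        """max |empirical CDF - fitted CDF| over the observed tail.

        Both CDFs are step functions on the integers; the supremum is checked
        at each observed value and just below it.
        """
        xs, counts = np.unique(self.tail, return_counts=True)
        ecdf = np.cumsum(counts) / self.tail.size
        fitted_at = self._cdf_at(xs, tau, lam)
        fitted_below = self._cdf_at(xs - 1, tau, lam)
        ecdf_lo = np.concatenate(([0.0], ecdf[:-1]))
        return float(np.max(np.maximum(np.abs(ecdf - fitted_at),
                                       np.abs(ecdf_lo - fitted_below))))


def fit_power_law(values, xmin: int = DEFAULT_XMIN, truncated: bool = False,
                  min_tail: int = MIN_TAIL) -> PowerLawResults:
    """Fit a discrete power law by MLE (functional wrapper)."""
    return DiscretePowerLaw(values, xmin=xmin, truncated=truncated,
                            min_tail=min_tail).fit()


# ---------------------------------------------------------------------------
# size-duration scaling and the crackling relation
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    """OLS fit of log10<s> on log10 T: slope gamma, its SE, and R^2."""

    gamma: float
    stderr: float
    r_squared: float
    n_points: int

    def summary(self) -> str:
        from .group_stats import format_ab
        return (
            "size-duration scaling <s>(T) ~ T^gamma (log-log OLS)\n"
            f"  gamma = {format_ab(self.gamma, self.stderr)}   "
            f"R^2 = {self.r_squared:.4f}   n = {self.n_points} durations"
        )


def size_duration_scaling(avalanches: list[Avalanche],
                          min_per_duration: int = 1) -> ScalingFit:
    """Regress log10 of the mean size per distinct duration on log10 duration.

    Durations represented by fewer than ``min_per_duration`` avalanches are
    excluded; at least 3 usable distinct durations are required.
    """
    sizes = np.array([a.size for a in avalanches], float)
    durs = np.array([a.duration for a in avalanches], float)
    if durs.size == 0:
        raise ValueError("no avalanches")
    uniq, inv, counts = np.unique(durs, return_inverse=True,
                                  return_counts=True)
    mean_s = np.bincount(inv, weights=sizes) / counts
    keep = counts >= min_per_duration
    uniq, mean_s = uniq[keep], mean_s[keep]
    if uniq.size < 3:
        raise ValueError(
            f"only {uniq.size} usable distinct durations; need >= 3"
        )
    reg = stats.linregress(np.log10(uniq), np.log10(mean_s))
    return ScalingFit(gamma=float(reg.slope), stderr=float(reg.stderr),
                      r_squared=float(reg.rvalue**2), n_points=int(uniq.size))


@dataclass(frozen=True)
class CracklingReport:
    """Consistency of (tau, alpha, gamma) with alpha = 1 + (tau - 1) gamma."""

    tau: float
    alpha: float
    gamma: float
    gamma_pred: float
    discrepancy: float
    in_reference_band: bool

    def summary(self) -> str:
        return (
            "crackling-noise relation alpha = 1 + (tau - 1) * gamma\n"
            f"  tau = {self.tau:.3f}  alpha = {self.alpha:.3f}  "
            f"gamma (fitted) = {self.gamma:.3f}\n"
            f"  gamma predicted = {self.gamma_pred:.3f}  "
            f"|gamma - predicted| = {self.discrepancy:.3f}\n"
            f"  predicted gamma within reference band "
            f"[{GAMMA_BAND[0]}, {GAMMA_BAND[1]}]: {self.in_reference_band}"
        )


def crackling_check(tau: float, alpha: float, gamma: float) -> CracklingReport:
    """Compare the fitted gamma with (alpha - 1)/(tau - 1)."""
    if tau <= 1.0:
        raise ValueError("tau must exceed 1 for the crackling relation")
    gamma_pred = (alpha - 1.0) / (tau - 1.0)
    return CracklingReport(
        tau=tau, alpha=alpha, gamma=gamma, gamma_pred=gamma_pred,
        discrepancy=abs(gamma - gamma_pred),
        in_reference_band=bool(GAMMA_BAND[0] <= gamma_pred <= GAMMA_BAND[1]),
    )


# ---------------------------------------------------------------------------
# parameter-sensitivity sweep
# ---------------------------------------------------------------------------

def sensitivity_sweep(epoch: Epoch,
                      bins_ms=(10.0, 15.0, 20.0),
                      thresholds_sd=(-2.2, -2.0, -1.8),
                      xmin: int = DEFAULT_XMIN,
                      min_tail: int = MIN_TAIL) -> pd.DataFrame:
    """Full factorial sweep of bin width x detection threshold.

    For each cell the pipeline detect -> bin -> extract -> fit is rerun and
    tau (sizes), alpha (durations), mean activity per active bin and the
    avalanche count are tabulated. Failing cells are flagged and the sweep
    continues.
    """
    rows = []
    for thr in thresholds_sd:
        raster = None
        try:
            raster = detect_events(epoch, threshold_sd=thr)
        except ValueError as exc:
            err = str(exc)
        for bm in bins_ms:
            row = {"bin_ms": bm, "threshold_sd": thr, "tau": np.nan,
                   "alpha_duration": np.nan, "mean_activity": np.nan,
                   "n_avalanches": 0, "failed": False, "error": ""}
            try:
                if raster is None:
                    raise ValueError(err)
                binned = bin_raster(raster, bin_ms=bm)
                avs = extract_avalanches(binned)
                row["n_avalanches"] = len(avs)
                row["mean_activity"] = mean_activity_per_active_bin(binned)
                sizes = [a.size for a in avs]
                durs = [a.duration for a in avs]
                row["tau"] = fit_power_law(sizes, xmin=xmin,
                                           min_tail=min_tail).exponent
                row["alpha_duration"] = fit_power_law(
                    durs, xmin=xmin, min_tail=min_tail).exponent
            except ValueError as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    df = pd.DataFrame(rows)
    # relative variation of each exponent across each swept parameter
    for col in ("tau", "alpha_duration"):
        ok = df[~df.failed]
        if len(ok) and ok[col].notna().all() and ok[col].abs().min() > 0:
            df.attrs[f"rel_variation_{col}"] = float(
                (ok[col].max() - ok[col].min()) / ok[col].mean()
            )
    return df
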