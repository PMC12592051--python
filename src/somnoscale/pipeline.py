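"""Pipeline orchestration: per-epoch/channel analysis, region and lobe
aggregation, and the between-state statistics layer.

Results flow through one long/tidy table (:class:`pandas.DataFrame`), one
metric per row, keyed by (patient, state, channel, region_id, lobe,
analysis, metric) — so region/lobe/state pivots are one ``groupby`` away.
The avalanche-duration exponent is named ``alpha_duration`` and the DFA
exponent ``alpha_dfa`` to keep the two alphas apart.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import avalanches as av
from . import dfa as dfa_mod
from . import group_stats as gs
from . import spectral as sp
from .recordings import Epoch, load_taxonomy, zscore

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "aggregate_by", "state_contrasts",
           "significance_matrix"]

RESULT_COLUMNS = [
    "patient", "state", "channel", "region_id", "lobe",
    "analysis", "metric", "value", "stderr", "flags",
]

#: Default contrast families: the hardest state pairs.
DEFAULT_CONTRASTS = (("W", "R"), ("N2", "N3"))


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Unknown keys in a config mapping are rejected by :meth:`from_dict`.
    """

    analyses: tuple[str, ...] = ("psd", "bands", "avalanche", "dfa", "stats")
    seed: int = 0
    # spectral
    welch_window_len: int = 600
    welch_overlap: float = 0.5
    sg_window_bins: int = 11
    sg_polyorder: int = 3
    fit_r2_accept: float = sp.R2_ACCEPT
    # avalanches
    avalanche_threshold_sd: float = av.DEFAULT_THRESHOLD_SD
    avalanche_bin_ms: float = av.DEFAULT_BIN_MS
    avalanche_xmin: int = av.DEFAULT_XMIN
    avalanche_k_channels: int = 16
    avalanche_truncated: bool = False
    avalanche_min_tail: int = av.MIN_TAIL
    # dfa
    dfa_fit_lo_s: float = dfa_mod.FIT_LO_S
    dfa_fit_hi_s: float = dfa_mod.FIT_HI_S
    dfa_n_scales: int = dfa_mod.N_SCALES
    # stats
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    alpha_level: float = gs.ALPHA_LEVEL
    # sweep
    sweep_bins_ms: tuple[float, ...] = (10.0, 15.0, 20.0)
    sweep_thresholds_sd: tuple[float, ...] = (-2.2, -2.0, -1.8)

    KNOWN = None  # filled after class creation

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        for key in ("sweep_bins_ms", "sweep_thresholds_sd"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["sweep_bins_ms"] = list(self.sweep_bins_ms)
        d["sweep_thresholds_sd"] = list(self.sweep_thresholds_sd)
        return d


def _row(patient, state, channel, region_id, lobe, analysis, metric, value,
         stderr=np.nan, flags=""):
    return dict(patient=patient, state=state, channel=channel,
                region_id=region_id, lobe=lobe, analysis=analysis,
                metric=metric, value=value, stderr=stderr, flags=flags)


def _channel_rows(epoch: Epoch, cfg: RunConfig, epoch_idx: int) -> list[dict]:
    rows = []
    for ci, ch in enumerate(epoch.channels):
        x = epoch.samples[ci]
        ident = dict(patient=ch.patient_id, state=epoch.state,
                     channel=ch.channel_id, region_id=ch.region_id,
                     lobe=ch.lobe)
        if "psd" in cfg.analyses or "bands" in cfg.analyses:
            try:
                psd = sp.welch_psd(x, epoch.fs,
                                   window_len=cfg.welch_window_len,
                                   overlap_frac=cfg.welch_overlap)
            except ValueError as exc:
                logger.warning("epoch %d ch %s: welch failed: %s",
                               epoch_idx, ch.channel_id, exc)
                continue
            if "psd" in cfg.analyses:
                for band, (lo, hi) in sp.BANDS.items():
                    m = psd.band_mask(lo, hi)
                    rows.append(_row(**ident, analysis="psd",
                                     metric=f"band_power_{band}",
                                     value=float(psd.power[m].mean())))
            if "bands" in cfg.analyses:
                try:
                    smoothed = sp.smooth_sg(psd, cfg.sg_window_bins,
                                            cfg.sg_polyorder)
                    fit = sp.fit_band_gaussians(smoothed, seed=cfg.seed)
                    flag = "" if fit.accepted else "rejected"
                    rows.append(_row(**ident, analysis="bands",
                                     metric="r_squared",
                                     value=fit.r_squared, flags=flag))
                    for comp in fit.components:
                        for attr in ("amplitude", "center_hz", "sigma_hz"):
                            rows.append(_row(
                                **ident, analysis="bands",
                                metric=f"{comp.band}_{attr}",
                                value=getattr(comp, attr), flags=flag,
                            ))
                except ValueError as exc:
                    logger.warning("epoch %d ch %s: band fit failed: %s",
                                   epoch_idx, ch.channel_id, exc)
        if "dfa" in cfg.analyses:
            try:
                res = dfa_mod.dfa(x, epoch.fs, fit_lo_s=cfg.dfa_fit_lo_s,
                                  fit_hi_s=cfg.dfa_fit_hi_s,
                                  n_scales=cfg.dfa_n_scales)
                rows.append(_row(**ident, analysis="dfa", metric="alpha_dfa",
                                 value=res.alpha, stderr=res.alpha_stderr,
                                 flags=res.regime))
            except ValueError as exc:
                logger.warning("epoch %d ch %s: dfa failed: %s",
                               epoch_idx, ch.channel_id, exc)
    return rows


def _avalanche_rows(epochs: list[Epoch], cfg: RunConfig) -> list[dict]:
    """Avalanche statistics pooled per (patient, state) group.

    Groups with fewer than ``avalanche_k_channels`` channels are excluded
    (flagged in the log); larger groups are randomly subset to exactly k
    channels with a per-patient seed derived from the global one.
    """
    groups: dict[tuple[str, str], list[Epoch]] = {}
    for e in epochs:
        pid = e.channels[0].patient_id if e.channels else ""
        groups.setdefault((pid, e.state), []).append(e)

    rows = []
    for (pid, state), eps in sorted(groups.items()):
        ident = dict(patient=pid, state=state, channel="pooled",
                     region_id=None, lobe=None)
        sizes, durs, activities, all_avs = [], [], [], []
        sub_seed = (cfg.seed * 100003 + zlib.crc32(pid.encode())) % (2**31)
        try:
            for e in eps:
                e = av.subsample_channels(zscore(e),
                                          k=cfg.avalanche_k_channels,
                                          seed=sub_seed)
                raster = av.detect_events(
                    e, threshold_sd=cfg.avalanche_threshold_sd)
                binned = av.bin_raster(raster, bin_ms=cfg.avalanche_bin_ms)
                avs = av.extract_avalanches(binned)
                all_avs.extend(avs)
                if np.count_nonzero(binned.counts):
                    activities.append(av.mean_activity_per_active_bin(binned))
            sizes = [a.size for a in all_avs]
            durs = [a.duration for a in all_avs]
            size_fit = av.fit_power_law(sizes, xmin=cfg.avalanche_xmin,
                                        truncated=cfg.avalanche_truncated,
                                        min_tail=cfg.avalanche_min_tail)
            dur_fit = av.fit_power_law(durs, xmin=cfg.avalanche_xmin,
                                       truncated=cfg.avalanche_truncated,
                                       min_tail=cfg.avalanche_min_tail)
            scaling = av.size_duration_scaling(all_avs)
            rows += [
                _row(**ident, analysis="avalanche", metric="tau",
                     value=size_fit.exponent, stderr=size_fit.stderr),
                _row(**ident, analysis="avalanche", metric="ks_size",
                     value=size_fit.ks_distance),
                _row(**ident, analysis="avalanche", metric="alpha_duration",
                     value=dur_fit.exponent, stderr=dur_fit.stderr),
                _row(**ident, analysis="avalanche", metric="gamma",
                     value=scaling.gamma, stderr=scaling.stderr),
                _row(**ident, analysis="avalanche", metric="mean_activity",
                     value=float(np.mean(activities)) if activities
                     else np.nan),
                _row(**ident, analysis="avalanche", metric="n_avalanches",
                     value=float(len(all_avs))),
            ]
        except ValueError as exc:
            logger.warning("avalanche stage skipped for (%s, %s): %s",
                           pid, state, exc)
            rows.append(_row(**ident, analysis="avalanche", metric="tau",
                             value=np.nan, flags=f"failed: {exc}"))
    return rows


def state_contrasts(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Between-state contrasts with BH-FDR within each comparison family.

    Two families mirror the two analysis levels: band amplitudes are compared
    per (band x lobe) cell, DFA exponents per lobe. Each family is corrected
    separately.
    """
    out_rows = []
    for (state_a, state_b) in cfg.contrasts:
        # family 1: Gaussian band amplitudes, band x lobe
        fam = []
        bands_tab = table[(table.analysis == "bands")
                          & table.metric.str.endswith("_amplitude")
                          & table.lobe.notna()]
        for (metric, lobe), g in bands_tab.groupby(["metric", "lobe"]):
            a = g[g.state == state_a].value.to_numpy()
            b = g[g.state == state_b].value.to_numpy()
            if a.size >= 3 and b.size >= 3:
                res = gs.mann_whitney_u(a, b, label=f"{metric}|{lobe}")
                fam.append(res)
        _apply_fdr(fam, cfg.alpha_level)
        out_rows += _contrast_rows(fam, "bands", state_a, state_b)

        # family 2: DFA exponents per lobe
        fam = []
        dfa_tab = table[(table.analysis == "dfa")
                        & (table.metric == "alpha_dfa") & table.lobe.notna()]
        for lobe, g in dfa_tab.groupby("lobe"):
            a = g[g.state == state_a].value.to_numpy()
            b = g[g.state == state_b].value.to_numpy()
            if a.size >= 3 and b.size >= 3:
                res = gs.mann_whitney_u(a, b, label=f"alpha_dfa|{lobe}")
                fam.append(res)
        _apply_fdr(fam, cfg.alpha_level)
        out_rows += _contrast_rows(fam, "dfa", state_a, state_b)

    return pd.DataFrame(out_rows, columns=[
        "family", "contrast", "label", "statistic", "p_value", "p_adjusted",
        "significant", "neg_log10_p",
    ])


def significance_matrix(stats_table: pd.DataFrame,
                        family: str = "dfa") -> pd.DataFrame:
    """Pivot one contrast family into a lobe x contrast matrix of
    -log10(adjusted p), rendering non-significant cells as "n.s."."""
    sub = stats_table[stats_table.family == family].copy()
    if sub.empty:
        raise ValueError(f"no rows for family {family!r}")
    sub["lobe"] = sub.label.str.split("|").str[-1]
    sub["cell"] = [
        f"{r.neg_log10_p:.2f}" if r.significant else "n.s."
        for r in sub.itertuples()
    ]
    return sub.pivot(index="lobe", columns="contrast", values="cell")


def _apply_fdr(family: list[gs.ComparisonResult], alpha_level: float) -> None:
    if not family:
        return
    p_adj, reject = gs.bh_fdr([r.p_value for r in family],
                              alpha_level=alpha_level)
    for r, pa, rej in zip(family, p_adj, reject):
        r.p_adjusted = float(pa)
        r.significant = bool(rej)


def _contrast_rows(family, fam_name, state_a, state_b):
    return [
        dict(family=fam_name, contrast=f"{state_a} vs {state_b}",
             label=r.label, statistic=r.statistic, p_value=r.p_value,
             p_adjusted=r.p_adjusted, significant=r.significant,
             neg_log10_p=r.neg_log10_p)
        for r in family
    ]


def run_pipeline(epochs: list[Epoch], config: RunConfig | None = None
                 ) -> dict[str, pd.DataFrame]:
    """Execute the requested analysis stages on a set of epochs.

    Returns a dict of tidy tables: ``metrics`` (per epoch/channel and pooled
    avalanche rows), plus ``stats`` and/or ``sweep`` when requested. All
    randomness derives from ``config.seed``; identical inputs and config give
    identical outputs.
    """
    if not epochs:
        raise ValueError("empty input set")
    cfg = config or RunConfig()
    rows = []
    for i, e in enumerate(epochs):
        rows.extend(_channel_rows(e, cfg, i))
    if "avalanche" in cfg.analyses:
        rows.extend(_avalanche_rows(epochs, cfg))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    _validate_taxonomy(table)
    out = {"metrics": table}
    if "stats" in cfg.analyses:
        out["stats"] = state_contrasts(table, cfg)
    if "sweep" in cfg.analyses:
        sweeps = []
        for i, e in enumerate(epochs):
            df = av.sensitivity_sweep(zscore(e), bins_ms=cfg.sweep_bins_ms,
                                      thresholds_sd=cfg.sweep_thresholds_sd,
                                      xmin=cfg.avalanche_xmin,
                                      min_tail=cfg.avalanche_min_tail)
            df.insert(0, "epoch", i)
            sweeps.append(df)
        out["sweep"] = pd.concat(sweeps, ignore_index=True)
    return out


def _validate_taxonomy(table: pd.DataFrame) -> None:
    tax = load_taxonomy()
    mapped = table[table.region_id.notna()]
    for rid, lobe in mapped[["region_id", "lobe"]].drop_duplicates().values:
        if tax.loc[int(rid), "lobe"] != lobe:
            raise ValueError(
                f"row with region_id={rid} carries lobe {lobe!r}, taxonomy "
                f"says {tax.loc[int(rid), 'lobe']!r}"
            )


def aggregate_by(table: pd.DataFrame, level: str,
                 order_by_alpha_sd: bool = False) -> pd.DataFrame:
    """Summaries per (region or lobe, state, metric): mean, SD, IQR, n.

    With ``order_by_alpha_sd`` the output is ordered by the mean standard
    deviation of the DFA exponent across the four states per region/lobe
    (ascending), the ordering used to rank regions by state-dependent
    variability.
    """
    if level not in ("region", "lobe"):
        raise ValueError(f"unknown aggregation level {level!r}")
    key = "region_id" if level == "region" else "lobe"
    sub = table[table[key].notna() & table.value.notna()]
    if sub.empty:
        raise ValueError("no aggregatable rows (missing region/lobe metadata)")

    def _iqr(v):
        return float(np.subtract(*np.percentile(v, [75, 25])))

    agg = sub.groupby([key, "state", "metric"])["value"].agg(
        mean="mean",
        sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        iqr=_iqr,
        n="count",
    ).reset_index()
    if order_by_alpha_sd:
        alpha = agg[agg.metric == "alpha_dfa"]
        rank = alpha.groupby(key)["sd"].mean().sort_values()
        order = {k: i for i, k in enumerate(rank.index)}
        agg = agg.assign(_o=agg[key].map(order)).sort_values(
            ["_o", "state", "metric"]).drop(columns="_o").reset_index(drop=True)
    return agg
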