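"""Between-state statistical comparisons and compact uncertainty notation.

The comparison toolkit mirrors standard practice for channel-level iEEG
metrics: two-sided unpaired Mann-Whitney U tests for pairwise state
contrasts, Benjamini-Hochberg FDR control across each comparison family, and
one-way ANOVA with Shapiro-Wilk (normality) and Levene (variance
homogeneity) assumption checks for multi-state exponent comparisons.

``format_ab`` renders the compact a(b) notation in which 0.84(2) means
0.84 +- 0.02 (the uncertainty expressed in the last printed digits).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "bh_fdr",
    "anova_oneway",
    "format_ab",
    "parse_ab",
    "neg_log10_p",
]

ALPHA_LEVEL = 0.05
NEG_LOG10_CAP = 320.0  # avoids -log10(0) overflow in tabular output


@dataclass
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass
class ComparisonResult:
    """One statistical contrast: statistic, p, optional adjusted p, flags."""

    label: str
    statistic: float
    p_value: float
    statistic_name: str = "U"
    p_adjusted: float | None = None
    significant: bool | None = None
    groups: list[GroupSummary] = field(default_factory=list)
    assumptions: dict = field(default_factory=dict)

    @property
    def neg_log10_p(self) -> float:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return neg_log10_p(p)

    def summary(self) -> str:
        parts = [f"{self.label}: {self.statistic_name} = {self.statistic:.4g}, "
                 f"p = {self.p_value:.3g}"]
        if self.p_adjusted is not None:
            parts.append(f"p_adj = {self.p_adjusted:.3g}")
        if self.significant is not None:
            parts.append("significant" if self.significant else "n.s.")
        for i, g in enumerate(self.groups):
            parts.append(f"group{i}: M = {g.mean:.3g}, SD = {g.sd:.3g}, "
                         f"n = {g.n}")
        return "; ".join(parts)


def neg_log10_p(p: float) -> float:
    """-log10(p), capped so p = 0 renders as a large finite value."""
    if p <= 0:
        return NEG_LOG10_CAP
    return float(min(-math.log10(p), NEG_LOG10_CAP))


def _summaries(*groups) -> list[GroupSummary]:
    return [GroupSummary(mean=float(np.mean(g)), sd=float(np.std(g, ddof=1))
                         if len(g) > 1 else 0.0, n=len(g)) for g in groups]


def mann_whitney_u(group_a, group_b, two_sided: bool = True,
                   label: str = "") -> ComparisonResult:
    """Unpaired Mann-Whitney U test.

    Exact enumeration when both groups have n <= 8 and no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"each group needs >= 3 observations (got {a.size}, {b.size})"
        )
    method = "exact" if (a.size <= 8 and b.size <= 8
                         and np.unique(np.concatenate([a, b])).size
                         == a.size + b.size) else "asymptotic"
    alternative = "two-sided" if two_sided else "greater"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        label=label, statistic=float(res.statistic),
        p_value=float(res.pvalue), statistic_name="U",
        groups=_summaries(a, b),
    )


def bh_fdr(p_values, alpha_level: float = ALPHA_LEVEL):
    """Benjamini-Hochberg step-up FDR procedure.

    Returns ``(p_adjusted, reject)``: monotone adjusted p-values and the
    boolean rejection set (largest k with p_(k) <= k * alpha / m, all smaller
    ranks rejected).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha_level,
                                        method="fdr_bh")
    return p_adj, reject


def anova_oneway(groups, label: str = "") -> ComparisonResult:
    """One-way ANOVA with attached assumption checks.

    The result carries per-group Shapiro-Wilk p-values and a Levene
    (center = median) p-value; ``assumptions['violated']`` is True when any
    check has p <= 0.05.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for i, g in enumerate(groups):
        if g.size < 3:
            raise ValueError(f"group {i} has {g.size} < 3 observations")
    f_stat, p = stats.f_oneway(*groups)
    shapiro_p = [float(stats.shapiro(g).pvalue) for g in groups]
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    violated = any(sp <= 0.05 for sp in shapiro_p) or levene_p <= 0.05
    return ComparisonResult(
        label=label, statistic=float(f_stat), p_value=float(p),
        statistic_name="F", groups=_summaries(*groups),
        assumptions={"shapiro_p": shapiro_p, "levene_p": levene_p,
                     "violated": violated},
    )


# ---------------------------------------------------------------------------
# a(b) uncertainty notation
# ---------------------------------------------------------------------------

def format_ab(value: float, stderr: float) -> str:
    """Render value +- stderr as compact a(b) notation.

    The uncertainty is rounded to one significant digit and printed in units
    of the value's last digit: (0.84, 0.02) -> "0.84(2)";
    (2.30, 0.07) -> "2.30(7)"; (12.3, 2.0) -> "12(2)".
    """
    if not (stderr > 0):
        raise ValueError("stderr must be positive")
    if not np.isfinite(value) or not np.isfinite(stderr):
        raise ValueError("value and stderr must be finite")
    exp = math.floor(math.log10(stderr))
    b = round(stderr / 10**exp)
    if b == 10:  # 0.096 rounds up to 0.10: one digit at the next decade
        b, exp = 1, exp + 1
    if exp >= 0:
        a = round(value / 10**exp) * 10**exp
        return f"{a:.0f}({b * 10**exp:.0f})"
    decimals = -exp
    return f"{value:.{decimals}f}({b})"


_AB_RE = re.compile(r"^(-?\d+(?:\.(\d+))?)\((\d+)\)$")


def parse_ab(text: str) -> tuple[float, float]:
    """Invert :func:`format_ab`: "0.84(2)" -> (0.84, 0.02)."""
    m = _AB_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse a(b) notation: {text!r}")
    value = float(m.group(1))
    decimals = len(m.group(2)) if m.group(2) else 0
    stderr = int(m.group(3)) * 10.0 ** (-decimals)
    return value, stderr
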