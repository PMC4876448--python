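"""Model-vs-measurement statistics: correlation, Bland–Altman, paired tests.

The validation loop compares modeled quantities (e.g. the transfer-function
resonance) with measured ones (e.g. LPC formants of recorded or synthesized
snores): correlation for association, Bland–Altman limits of agreement for
bias, and paired tests for before/after-sleep changes.  Normality (Shapiro–
Wilk at alpha = 0.05) drives the parametric/non-parametric choice when a
method is not forced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "PairedResult",
    "correlate",
    "bland_altman",
    "paired_compare",
    "stage_anova",
]

_SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    method: str  # "pearson" | "spearman"
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary: bias and ±1.96 SD limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class PairedResult:
    statistic: float
    p: float
    test: str  # "t" | "wilcoxon"
    n: int


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _normalish(*series: np.ndarray) -> bool:
    """True when every series passes Shapiro–Wilk at alpha 0.05."""
    for s in series:
        if len(s) < 3 or np.ptp(s) == 0:
            return False
        if stats.shapiro(s).pvalue < _SHAPIRO_ALPHA:
            return False
    return True


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Correlation with two-tailed p.

    ``method='auto'`` selects Pearson when both series pass a Shapiro–Wilk
    normality check, Spearman otherwise; 'pearson'/'spearman' force the
    branch.  Constant series have no defined coefficient and raise.
    """
    x, y = _clean_pairs(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs after deletion, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    if method == "auto":
        method = "pearson" if _normalish(x, y) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), method=method, n=n)


def bland_altman(modeled, measured) -> AgreementResult:
    """Limits of agreement for modeled − measured differences.

    SD uses the n−1 denominator; limits are mean ± 1.96·SD.
    """
    modeled, measured = _clean_pairs(modeled, measured)
    n = len(modeled)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = modeled - measured
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=n,
    )


def paired_compare(before, after, test: str = "auto") -> PairedResult:
    """Paired comparison of before/after series.

    ``test='auto'``: paired t when the differences pass Shapiro–Wilk,
    Wilcoxon signed-rank otherwise.  A t-test on zero-variance differences
    is undefined and raises; identical series under 'auto' return the
    trivial t result (statistic 0, p = 1).
    """
    before, after = _clean_pairs(before, after)
    n = len(before)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = after - before
    if test == "auto":
        if np.ptp(d) == 0:
            # all differences equal: degenerate; zero shift is the p=1 case
            if np.allclose(d, 0):
                return PairedResult(statistic=0.0, p=1.0, test="t", n=n)
            test = "wilcoxon"
        else:
            test = "t" if _normalish(d) else "wilcoxon"
    if test == "t":
        if np.ptp(d) == 0 and not np.allclose(d, 0):
            raise ValueError("t-test undefined for zero-variance nonzero differences")
        res = stats.ttest_rel(after, before)
        return PairedResult(statistic=float(res.statistic), p=float(res.pvalue), test="t", n=n)
    if test == "wilcoxon":
        res = stats.wilcoxon(after, before)
        return PairedResult(
            statistic=float(res.statistic), p=float(res.pvalue), test="wilcoxon", n=n
        )
    raise ValueError(f"unknown test {test!r}")


def stage_anova(values_by_stage: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA of a feature across sleep stages (reporting convenience).

    Returns (F, p).  Post-hoc pairwise comparisons, if needed, should use
    Tukey HSD (scipy.stats.tukey_hsd) on the same groups.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_stage.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 stages with >= 2 values each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
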