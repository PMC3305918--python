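"""Paired rest-vs-stress statistics: descriptives and the Wilcoxon test.

The within-subject difference is always stress minus rest, so a negative
difference means the measure decreased under stress.  The signed-rank test
is two-sided, discards zero differences, average-ranks ties, and uses full
sign enumeration when at most ``EXACT_ENUMERATION_LIMIT`` nonzero
differences remain (normal approximation with tie and continuity
corrections otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ValidationError

#: largest n for which the exact sign-enumeration null is used
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    q25: float
    q75: float


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # W+: sum of ranks of positive differences
    p_value: float
    n_effective: int        # pairs with nonzero difference
    exact: bool             # True when p came from full enumeration
    all_zero: bool = False  # degenerate: every difference was zero


def describe(values) -> SummaryStats:
    """Mean, sample SD, median and quartiles (linear interpolation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("describe: empty input")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return SummaryStats(float(np.mean(x)), sd, float(med), float(q25), float(q75))


def paired_differences(dataset, feature: str) -> tuple[np.ndarray, SummaryStats]:
    """Stress-minus-rest differences of one feature, in subject order."""
    diffs = dataset.differences(feature)
    return diffs, describe(diffs)


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ranks of |d|, signs) after discarding zeros; ties average-ranked."""
    nonzero = diffs[diffs != 0]
    ranks = rankdata(np.abs(nonzero))
    return ranks, np.sign(nonzero)


def exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by enumerating all 2^n sign assignments.

    p = 2 * min(P(W+ <= w), P(W+ >= w)) capped at 1, where the null
    distribution of W+ (sum of ranks with positive sign) is uniform over
    the 2^n sign vectors.
    """
    n = len(ranks)
    signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
    w_all = signs @ ranks
    eps = 1e-9
    p_low = np.count_nonzero(w_all <= w_plus + eps) / 2 ** n
    p_high = np.count_nonzero(w_all >= w_plus - eps) / 2 ** n
    return min(1.0, 2.0 * min(p_low, p_high))


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied |d| groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences."""
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise ValidationError("wilcoxon_signed_rank: empty input")
    ranks, signs = _signed_ranks(diffs)
    n_eff = len(ranks)
    if n_eff == 0:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, all_zero=True)
    w_plus = float(np.sum(ranks[signs > 0]))
    if n_eff <= EXACT_ENUMERATION_LIMIT:
        p = exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n_eff, exact=True)
    p = _approx_signed_rank_p(ranks, w_plus)
    return WilcoxonResult(w_plus, p, n_eff, exact=False)


def format_p(p: float, threshold: float = 0.01) -> str:
    """Display convention for report tables: values below 0.01 print as <0.01."""
    return f"<{threshold:g}" if p < threshold else f"{p:.2f}"
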