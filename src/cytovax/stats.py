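"""Self-contained statistical kernel.

Exact binomial (Clopper–Pearson) confidence intervals, one-sample Wilcoxon
signed-rank with an exact sign-enumeration branch, Benjamini–Hochberg
step-up adjustment, one-sample Cohen's D and Pearson chi-squared tests for
proportions.  These are the inferential primitives the cohort analysis is
built on; everything here is pure and in-memory.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError, SmallSampleError

__all__ = [
    "ProportionCI",
    "WilcoxonResult",
    "clopper_pearson",
    "wilcoxon_signed_rank",
    "benjamini_hochberg",
    "cohens_d_one_sample",
    "chi_squared_proportions",
    "round_half_up",
]


@dataclass(frozen=True)
class ProportionCI:
    """Exact binomial confidence interval for k successes in n trials."""

    k: int
    n: int
    alpha: float
    estimate: float
    lower: float
    upper: float

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        """(estimate, lower, upper) on the percent scale, rounded half-up."""
        return (
            round_half_up(100.0 * self.estimate, digits),
            round_half_up(100.0 * self.lower, digits),
            round_half_up(100.0 * self.upper, digits),
        )


@dataclass(frozen=True)
class WilcoxonResult:
    """One-sample Wilcoxon signed-rank result.

    ``w`` is the sum of positive ranks; ``mode`` records whether the exact
    enumeration or the tie-corrected normal approximation produced the
    p-value.
    """

    n_effective: int
    w: float
    p_two_sided: float
    mode: str  # "exact" | "normal_approx"


def round_half_up(x: float, digits: int = 1) -> float:
    """Round with ties away from zero (report-table convention)."""
    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> ProportionCI:
    """Exact (Clopper–Pearson) binomial CI from beta-distribution quantiles.

    lower = Beta^{-1}(alpha/2; k, n-k+1) for k>0, else 0;
    upper = Beta^{-1}(1-alpha/2; k+1, n-k) for k<n, else 1.
    The interval is conservative: coverage is at least 1-alpha.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ParameterError("k and n must be integers")
    if n < 1 or k < 0 or k > n:
        raise ParameterError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1); got {alpha}")
    lower = float(sps.beta.ppf(alpha / 2.0, k, n - k + 1)) if k > 0 else 0.0
    upper = float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k)) if k < n else 1.0
    return ProportionCI(k=int(k), n=int(n), alpha=alpha, estimate=k / n, lower=lower, upper=upper)


def _exact_signed_rank_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) under random signs for the observed ranks.

    The null distribution of the positive-rank sum is built by dynamic
    programming over the 2^n equally likely sign assignments; the counts are
    exact integers so the result is identical to full enumeration.  Midranks
    (multiples of 0.5, from ties in |values|) are handled by doubling, which
    keeps the lattice integral.
    """
    doubled = np.round(2.0 * ranks).astype(int)
    n = len(doubled)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    denom = 2**n
    wi = int(round(2.0 * w))
    cdf = int(np.sum(counts[: wi + 1])) / denom
    sf = int(np.sum(counts[wi:])) / denom
    return cdf, sf


def wilcoxon_signed_rank(
    values,
    exact_max_n: int = 25,
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Zeros are dropped before ranking (``zero_method="wilcox"``, the common
    default) or ranked then discarded from W (``"pratt"``).  Absolute values
    receive midranks on ties.  When the effective n is at most
    ``exact_max_n`` and there are no ties, the exact two-sided p-value
    ``min(1, 2*min(P(W<=w), P(W>=w)))`` is computed by sign enumeration;
    otherwise the tie-corrected normal approximation with a 0.5 continuity
    correction is used.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError("values must be one-dimensional")
    if np.all(x == 0):
        raise DegenerateInputError("all values are zero: signed-rank test undefined")

    if zero_method == "wilcox":
        nz = x[x != 0]
        ranks = sps.rankdata(np.abs(nz))
    elif zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(x))
        nz = x[x != 0]
        ranks = ranks_all[x != 0]
    else:
        raise ParameterError(f"unknown zero_method {zero_method!r}")

    n = len(nz)
    if n < 5:
        raise SmallSampleError(f"need >= 5 nonzero values, got {n}")

    w = float(ranks[nz > 0].sum())

    if n <= exact_max_n and zero_method == "wilcox":
        # exact even under ties: the enumeration conditions on the observed
        # midranks, so the lattice is integral after doubling
        cdf, sf = _exact_signed_rank_sf_cdf(ranks, w)
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(n_effective=n, w=w, p_two_sided=p, mode="exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # midrank tie correction: subtract sum(t^3 - t)/48 over tie groups of |x|
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise DegenerateInputError("zero variance in signed-rank null distribution")
    diff = w - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return WilcoxonResult(n_effective=n, w=w, p_two_sided=p, mode="normal_approx")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p_values must be a nonempty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohens_d_one_sample(values) -> float:
    """Cohen's D = mean / sd with the (n-1)-denominator standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SmallSampleError("Cohen's D needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero standard deviation: Cohen's D undefined")
    return float(np.mean(x)) / sd


def chi_squared_proportions(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2 x C contingency table.

    No continuity correction by default; ``yates=True`` applies the Yates
    correction.  Returns (statistic, p) with df = C - 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ParameterError("table must be 2 x C with C >= 2")
    if np.any(obs < 0):
        raise ParameterError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0:
        raise DegenerateInputError("empty table")
    expected = row @ col / total
    if np.any(expected <= 0):
        raise DegenerateInputError(
            "zero expected count: chi-squared invalid, consider an exact test"
        )
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = obs.shape[1] - 1
    p = float(sps.chi2.sf(stat, df))
    return stat, p
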