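"""Method-agreement and group-comparison statistics.

The battery needed for an echo-vs-CMR validation study:

* one-way ANOVA across dysfunction grades, from raw samples or from
  published n/mean/SD summaries (the two are algebraically identical),
* Fisher's exact test for r×c contingency tables (Freeman–Halton
  extension, probability ordering, with a seeded Monte-Carlo fallback),
* Pearson correlation / least-squares regression with the echo measure as
  predictor,
* Bland–Altman bias and 95% limits of agreement for same-unit pairs,
* ROC AUC via the rank (Mann–Whitney) statistic with tie correction,
  banded poor / good / excellent,
* two-way random single-measure absolute-agreement ICC — ICC(2,1) — with
  the poor / fair-to-good / excellent bands,
* paired t comparison for same-subject, same-unit series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import lgamma, exp, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateLabelsError,
    EnumerationLimitError,
    IncompleteMatrixError,
    ParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "AgreementResult",
    "RocResult",
    "anova_oneway",
    "bonferroni_pairwise",
    "fisher_exact_rxc",
    "pearson_linear",
    "bland_altman",
    "roc_auc_with_band",
    "icc_two_way_random",
    "paired_mean_comparison",
    "format_p",
    "icc_band",
    "auc_band",
]

P_SIGNIFICANT = 0.05  # reported alongside results, never used to drop data


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n / mean / SD triples, e.g. one row of a descriptive table."""

    ns: tuple
    means: tuple
    sds: tuple
    labels: tuple = ()

    def __post_init__(self):
        if not (len(self.ns) == len(self.means) == len(self.sds)):
            raise ParameterError("ns, means and sds must have equal length")
        if len(self.ns) < 2:
            raise ParameterError("need at least two groups")
        if any(n < 2 for n in self.ns):
            raise ParameterError("each group needs n >= 2")
        if any(s < 0 for s in self.sds):
            raise ParameterError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ParameterError("contingency table must be 2-dimensional")
        if np.any(counts < 0):
            raise ParameterError("contingency counts must be non-negative")
        if counts.sum() == 0:
            raise ParameterError("contingency table total must be positive")


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    band: str
    bias: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None


@dataclass(frozen=True)
class RocResult:
    auc: float
    band: str
    p: float
    n_positive: int
    n_negative: int


# ---------------------------------------------------------------- ANOVA


def anova_oneway(groups) -> tuple[float, float]:
    """Omnibus one-way ANOVA F and two-sided p.

    ``groups`` is either a :class:`GroupSummary` or a sequence of raw
    per-group sample arrays.  The summary form uses the moment identities
    SSB = Σ nᵢ(mᵢ − m̄)² and SSW = Σ (nᵢ−1)sᵢ², which coincide exactly
    with the raw-data decomposition.
    """
    if isinstance(groups, GroupSummary):
        ns = np.asarray(groups.ns, float)
        means = np.asarray(groups.means, float)
        sds = np.asarray(groups.sds, float)
    else:
        arrays = [np.asarray(g, float) for g in groups]
        if len(arrays) < 2:
            raise ParameterError("need at least two groups")
        if any(a.size < 2 for a in arrays):
            raise ParameterError("each group needs n >= 2")
        ns = np.array([a.size for a in arrays], float)
        means = np.array([a.mean() for a in arrays])
        sds = np.array([a.std(ddof=1) for a in arrays])
    N = ns.sum()
    k = ns.size
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw == 0:
        if ssb == 0:
            raise UndefinedStatisticError(
                "zero within-group variance with equal means: F undefined"
            )
        return float("inf"), 0.0
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = float(stats.f.sf(F, k - 1, N - k))
    return float(F), p


def bonferroni_pairwise(groups: Sequence[np.ndarray]) -> list[tuple[int, int, float]]:
    """Post hoc pairwise two-sample t tests with Bonferroni correction.

    Secondary output: the omnibus p is the primary result.  Returns
    (i, j, adjusted p) for every unordered pair.
    """
    arrays = [np.asarray(g, float) for g in groups]
    m = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        _, p = stats.ttest_ind(arrays[i], arrays[j], equal_var=True)
        out.append((i, j, float(min(1.0, p * m))))
    return out


# ------------------------------------------------------- Fisher's exact


def _log_table_prob(counts: np.ndarray, log_const: float) -> float:
    return log_const - sum(lgamma(c + 1) for c in counts.ravel())


def _enumerate_tables(row_margins, col_margins, limit):
    """Yield all non-negative integer tables with the given margins.

    Depth-first over cells in row-major order; raises
    :class:`EnumerationLimitError` after ``limit`` completed tables.
    """
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=int)
    count = 0

    def rec(i, j, row_left, col_left):
        nonlocal count
        if i == r - 1:
            # last row is forced by the column margins
            if all(cl >= 0 for cl in col_left):
                for jj in range(c):
                    table[r - 1, jj] = col_left[jj]
                count += 1
                if count > limit:
                    raise EnumerationLimitError(
                        f"more than {limit} margin-consistent tables; "
                        "use monte_carlo=True"
                    )
                yield table
            return
        if j == c - 1:
            v = row_left
            if 0 <= v <= col_left[j]:
                table[i, j] = v
                new_col = list(col_left)
                new_col[j] -= v
                yield from rec(i + 1, 0, row_margins[i + 1], new_col)
            return
        for v in range(min(row_left, col_left[j]) + 1):
            table[i, j] = v
            new_col = list(col_left)
            new_col[j] -= v
            yield from rec(i, j + 1, row_left - v, new_col)

    yield from rec(0, 0, row_margins[0], list(col_margins))


def fisher_exact_rxc(
    table,
    max_tables: int = 2_000_000,
    monte_carlo: bool = False,
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Two-sided Fisher exact p for an r×c contingency table.

    Freeman–Halton extension: under fixed margins, sum the hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed table (probability ordering, the convention used by the
    major statistics packages).  ``monte_carlo=True`` estimates the same
    tail by sampling tables from the margin-fixed null (seeded), for
    tables too large to enumerate.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    row_m = counts.sum(axis=1)
    col_m = counts.sum(axis=0)
    N = int(counts.sum())
    log_const = (
        sum(lgamma(m + 1) for m in row_m)
        + sum(lgamma(m + 1) for m in col_m)
        - lgamma(N + 1)
    )
    lp_obs = _log_table_prob(counts, log_const)
    # relative tolerance groups tables tied with the observed one
    cutoff = lp_obs + 1e-7

    if monte_carlo:
        rng = np.random.default_rng(seed)
        hits = 0
        # sample by random permutation of column labels against fixed rows
        row_of = np.repeat(np.arange(len(row_m)), row_m)
        col_of = np.repeat(np.arange(len(col_m)), col_m)
        for _ in range(n_samples):
            perm = rng.permutation(col_of)
            t = np.zeros_like(counts)
            np.add.at(t, (row_of, perm), 1)
            if _log_table_prob(t, log_const) <= cutoff:
                hits += 1
        return (hits + 1) / (n_samples + 1)

    total = 0.0
    for t in _enumerate_tables(list(row_m), list(col_m), max_tables):
        lp = _log_table_prob(t, log_const)
        if lp <= cutoff:
            total += exp(lp)
    return min(1.0, total)


# ----------------------------------------------- correlation/regression


def pearson_linear(x, y) -> tuple[float, float, float, float]:
    """Pearson r, two-sided p, and the least-squares slope/intercept of
    y on x (x is the predictor — by convention the echo measure)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.pvalue), float(res.slope), float(res.intercept)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland–Altman bias and 95% limits of agreement for same-unit pairs.

    bias = mean(y − x); limits = bias ± 1.96·SD(y − x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("need paired vectors with n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ------------------------------------------------------------------ ROC


def auc_band(auc: float) -> str:
    """Discriminative-ability band: poor [0.5, 0.7), good [0.7, 0.9),
    excellent [0.9, 1.0]; values below 0.5 are worse than chance → poor."""
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.7:
        return "good"
    return "poor"


def roc_auc_with_band(scores, labels, direction: str = "higher") -> RocResult:
    """ROC AUC by the rank statistic, with band and rank-test p.

    ``labels`` are truthy for the positive (diseased) class.
    ``direction="higher"`` means larger scores indicate disease (E/E′, NE,
    DT); ``"lower"`` flips the orientation (E′).  AUC = U/(n₁n₀) with ties
    counted one half; p is the two-sided normal approximation to the
    Mann–Whitney statistic with tie correction.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.size != labels.size:
        raise ParameterError("scores and labels must have equal length")
    if direction not in ("higher", "lower"):
        raise ParameterError("direction must be 'higher' or 'lower'")
    if direction == "lower":
        scores = -scores
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("both outcome classes must be present")
    ranks = stats.rankdata(scores)
    u = float(ranks[labels].sum() - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n0)
    # tie-corrected variance of U under H0
    N = n1 + n0
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    var_u = n1 * n0 / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / sqrt(var_u)
        p = float(2 * stats.norm.sf(abs(z)))
    return RocResult(auc=auc, band=auc_band(auc), p=min(1.0, p),
                     n_positive=n1, n_negative=n0)


# ------------------------------------------------------------------ ICC


def icc_band(icc: float) -> str:
    """Agreement band: poor < 0.40, fair-to-good 0.40–0.75, excellent > 0.75."""
    if icc > 0.75:
        return "excellent"
    if icc >= 0.40:
        return "fair-to-good"
    return "poor"


def icc_two_way_random(ratings) -> AgreementResult:
    """Single-measure absolute-agreement two-way random ICC — ICC(2,1).

    ``ratings`` is a complete subjects × raters matrix.  From the two-way
    mean squares (rows = subjects, columns = raters):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    Bias and limits of agreement are attached via Bland–Altman when there
    are exactly two raters.
    """
    m = np.asarray(ratings, float)
    if m.ndim != 2:
        raise ParameterError("ratings must be a 2-D subjects × raters matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ParameterError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise IncompleteMatrixError("ratings matrix contains missing cells")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedStatisticError("ICC denominator is zero (constant matrix)")
    icc = (msr - mse) / denom
    bias = lo = hi = None
    if k == 2:
        bias, lo, hi = bland_altman(m[:, 0], m[:, 1])
    return AgreementResult(icc=float(icc), band=icc_band(float(icc)),
                           bias=bias, loa_low=lo, loa_high=hi)


# --------------------------------------------------------------- paired


def paired_mean_comparison(x, y) -> tuple[float, float]:
    """Paired t statistic and two-sided p for same-subject series.

    Zero-variance differences with zero mean (identical series) return
    (0, 1) by convention rather than NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ParameterError("need paired vectors with n >= 2")
    d = y - x
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float("inf") * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(y, x)
    return float(t), float(p)


# ------------------------------------------------------------- display


def format_p(p: float) -> str:
    """Report-style p: two decimals above 0.01, four below, '<0.0001' floor."""
    if p < 0.0001:
        return "<0.0001"
    if p < 0.01:
        return f"{p:.4f}"
    return f"{p:.2f}"
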