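"""Comparison statistics for the setup evaluation.

Only the tests the evaluation actually uses are provided, with their
reporting shapes: intraclass correlation for intra-rater reliability,
repeated-measures ANOVA with Mauchly's sphericity test and Bonferroni
pairwise post-hocs, the Friedman test with Wilcoxon signed-rank
post-hocs, the paired t-test, and the exact McNemar test for paired
binary frequencies.

The within-subject F, Mauchly's W, ICC and the Friedman statistic are
computed directly from mean squares / midranks with numpy so the
calibration simulations can run tens of thousands of tests cheaply;
unit tests verify them against pingouin and scipy.  The paired t-test
and Wilcoxon signed-rank test delegate to :mod:`scipy.stats`.

Conventions
-----------
* Friedman p-values are exact (exhaustive enumeration of the per-subject
  rank permutations) whenever ``(k!)**n`` does not exceed
  ``exact_limit``; otherwise the tie-corrected chi-square approximation
  is used.
* Wilcoxon uses the exact null distribution for up to
  ``WILCOXON_EXACT_N`` non-zero differences and the normal approximation
  with continuity correction above; zero differences are dropped before
  ranking.
* McNemar is the exact two-sided binomial test for ``b + c`` up to
  ``MCNEMAR_EXACT_N`` discordant pairs and the continuity-corrected
  chi-square above.
* Paired t with zero-variance differences: p = 1 for zero mean
  difference, p = 0 otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.linalg import helmert
from scipy.stats import rankdata

from .errors import InsufficientDataError, UndefinedStatisticError

#: largest number of rank-permutation products enumerated for an exact Friedman p
FRIEDMAN_EXACT_LIMIT = 50_000
#: exact-vs-approximate switch points
WILCOXON_EXACT_N = 25
MCNEMAR_EXACT_N = 25

_LETTERS = "abcdefgh"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None
    method: str = ""
    adjusted: bool = False

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    result: TestResult
    p_adjusted: float


@dataclass(frozen=True)
class RepeatedBlock:
    """Complete-case subjects x conditions value matrix."""

    subjects: tuple
    conditions: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.subjects), len(self.conditions)):
            raise ValueError("values must be a (subjects x conditions) matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("RepeatedBlock requires complete cases (no missing cells)")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def k(self) -> int:
        return len(self.conditions)


@dataclass(frozen=True)
class OmnibusReport:
    """Omnibus test plus sphericity and pairwise post-hocs."""

    omnibus: TestResult
    pairwise: tuple[PairwiseResult, ...]
    labels: tuple[str, ...]
    sphericity: TestResult | None = None


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


# ---------------------------------------------------------------------------
# paired t-test


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test of ``x`` against ``y``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    n = len(x)
    if n < 2:
        raise InsufficientDataError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, 1.0, df=n - 1, n=n, method="paired-t")
        return TestResult(math.inf * np.sign(d.mean()), 0.0, df=n - 1, n=n,
                          method="paired-t")
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), float(p), df=n - 1, n=n, method="paired-t")


# ---------------------------------------------------------------------------
# ICC


def icc_agreement(ratings, form: str = "icc3") -> TestResult:
    """Intra-rater reliability of repeated measurements.

    ``ratings`` is a (subjects x sessions) matrix.  The default (and only
    implemented) form is the two-way mixed-effects, single-measure,
    consistency ICC -- ICC(3,1) -- computed from the mean squares of the
    subjects x sessions decomposition.
    """
    if form != "icc3":
        raise NotImplementedError(f"ICC form {form!r} not implemented")
    r = np.asarray(ratings, float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratings must be (subjects x sessions) with >= 2 sessions")
    n, k = r.shape
    if n < 3:
        raise InsufficientDataError("ICC needs at least 3 subjects")
    grand = r.mean()
    if np.allclose(r, grand):
        raise UndefinedStatisticError("ICC undefined: zero total variance")
    row_means = r.mean(axis=1, keepdims=True)
    col_means = r.mean(axis=0, keepdims=True)
    ms_rows = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_err = ((r - row_means - col_means + grand) ** 2).sum() / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    return TestResult(float(icc), math.nan, n=n, method="ICC(3,1)")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def mauchly_sphericity(values: np.ndarray) -> TestResult:
    """Mauchly's test of sphericity on a (n x k) within-subject matrix."""
    v = np.asarray(values, float)
    n, k = v.shape
    if k < 3:
        raise ValueError("sphericity is only defined for k >= 3 conditions")
    if n < 3:
        raise InsufficientDataError("Mauchly's test needs at least 3 subjects")
    C = helmert(k, full=False)  # (k-1) orthonormal contrasts
    S = np.cov(v, rowvar=False)
    A = C @ S @ C.T
    tr = np.trace(A)
    if tr <= 1e-12:
        # no within-subject variance at all: sphericity trivially holds
        return TestResult(1.0, 1.0, df=k * (k - 1) / 2 - 1, n=n, method="mauchly")
    det = float(np.linalg.det(A))
    W = det / (tr / (k - 1)) ** (k - 1)
    W = min(max(W, 0.0), 1.0)
    df = k * (k - 1) / 2 - 1
    d = 1 - (2 * (k - 1) ** 2 + (k - 1) + 2) / (6 * (k - 1) * (n - 1))
    if W == 0.0:
        return TestResult(0.0, 0.0, df=df, n=n, method="mauchly")
    chi2 = -(n - 1) * d * math.log(W)
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(float(W), p, df=df, n=n, method="mauchly")


def greenhouse_geisser_epsilon(values: np.ndarray) -> float:
    v = np.asarray(values, float)
    k = v.shape[1]
    C = helmert(k, full=False)
    A = C @ np.cov(v, rowvar=False) @ C.T
    lam = np.linalg.eigvalsh(A)
    denom = (k - 1) * (lam**2).sum()
    if denom <= 1e-24:
        return 1.0
    return float(lam.sum() ** 2 / denom)


def rm_anova(
    block: RepeatedBlock,
    alpha: float = 0.05,
    *,
    gg_correction: bool = False,
) -> OmnibusReport:
    """One-way within-subject ANOVA with Mauchly's test and Bonferroni
    pairwise paired t post-hocs.

    Post-hoc labels of the form ``"a > b"`` (condition letters in column
    order) are emitted only when the omnibus p is below ``alpha``.  By
    default no Greenhouse-Geisser correction is applied; pass
    ``gg_correction=True`` to scale the degrees of freedom by the GG
    epsilon.
    """
    v = block.values
    n, k = block.n, block.k
    if n < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 2 subjects")
    grand = v.mean()
    row_means = v.mean(axis=1, keepdims=True)
    col_means = v.mean(axis=0, keepdims=True)
    ss_cond = n * ((col_means - grand) ** 2).sum()
    ss_err = ((v - row_means - col_means + grand) ** 2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if gg_correction:
        eps = greenhouse_geisser_epsilon(v)
        df1, df2 = df1 * eps, df2 * eps
    if ss_err <= 1e-24:
        if ss_cond <= 1e-24:
            omnibus = TestResult(0.0, 1.0, df=df1, n=n, method="rm-anova")
        else:
            omnibus = TestResult(math.inf, 0.0, df=df1, n=n, method="rm-anova")
    else:
        F = (ss_cond / df1) / (ss_err / df2)
        omnibus = TestResult(float(F), float(sps.f.sf(F, df1, df2)), df=df1, n=n,
                             method="rm-anova")
    sphericity = mauchly_sphericity(v) if k >= 3 and n >= 3 else None
    pairs = list(itertools.combinations(range(k), 2))
    pairwise = []
    for i, j in pairs:
        r = paired_t(v[:, i], v[:, j])
        pairwise.append(
            PairwiseResult(
                (str(block.conditions[i]), str(block.conditions[j])),
                r,
                bonferroni(r.p_value, len(pairs)),
            )
        )
    labels = _posthoc_labels(omnibus.p_value, alpha, v.mean(axis=0), pairwise, pairs)
    return OmnibusReport(omnibus, tuple(pairwise), labels, sphericity)


def _posthoc_labels(p_omnibus, alpha, means, pairwise, pairs) -> tuple[str, ...]:
    if not (p_omnibus < alpha):
        return ()
    labels = []
    for (i, j), pw in zip(pairs, pairwise):
        if pw.p_adjusted < alpha:
            hi, lo = (i, j) if means[i] > means[j] else (j, i)
            labels.append(f"{_LETTERS[hi]} > {_LETTERS[lo]}")
    return tuple(labels)


# ---------------------------------------------------------------------------
# Friedman + Wilcoxon


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from per-subject midranks."""
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (col**2).sum() - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts**3 - counts).sum()
    corr = 1.0 - ties / (n * k * (k**2 - 1))
    if corr <= 0.0:
        return 0.0
    return stat / corr


def friedman_wilcoxon(
    block: RepeatedBlock,
    alpha: float = 0.05,
    *,
    exact_limit: int = FRIEDMAN_EXACT_LIMIT,
    wilcoxon_exact_n: int = WILCOXON_EXACT_N,
) -> OmnibusReport:
    """Friedman test with Bonferroni-adjusted Wilcoxon signed-rank
    post-hoc pairs.

    The Friedman p is exact (enumeration of all per-subject rank
    permutations) when ``(k!)**n <= exact_limit``, otherwise the
    tie-corrected chi-square approximation is used.
    """
    v = block.values
    n, k = block.n, block.k
    if n < 2:
        raise InsufficientDataError("Friedman test needs >= 2 subjects")
    ranks = np.apply_along_axis(rankdata, 1, v)
    stat = _friedman_statistic(ranks)
    if stat == 0.0:
        # includes the all-tied degenerate case: every permutation attains >= 0
        omnibus = TestResult(0.0, 1.0, df=k - 1, n=n, method="friedman")
    elif math.factorial(k) ** n <= exact_limit:
        omnibus = TestResult(stat, _friedman_exact_p(ranks, stat), df=k - 1, n=n,
                             method="friedman-exact")
    else:
        omnibus = TestResult(stat, float(sps.chi2.sf(stat, k - 1)), df=k - 1, n=n,
                             method="friedman")
    pairs = list(itertools.combinations(range(k), 2))
    pairwise = []
    for i, j in pairs:
        r = wilcoxon_signed_rank(v[:, i], v[:, j], exact_n=wilcoxon_exact_n)
        pairwise.append(
            PairwiseResult(
                (str(block.conditions[i]), str(block.conditions[j])),
                r,
                bonferroni(r.p_value, len(pairs)),
            )
        )
    labels = _posthoc_labels(omnibus.p_value, alpha, v.mean(axis=0), pairwise, pairs)
    return OmnibusReport(omnibus, tuple(pairwise), labels, None)


def _friedman_exact_p(ranks: np.ndarray, observed: float) -> float:
    """P(statistic >= observed) over all products of per-subject rank
    permutations (each subject's midranks permuted uniformly)."""
    n, k = ranks.shape
    perms = list(itertools.permutations(range(k)))
    row_variants = [np.array([row[list(p)] for p in perms]) for row in ranks]
    count = 0
    total = len(perms) ** n
    for choice in itertools.product(range(len(perms)), repeat=n):
        perm_ranks = np.array([row_variants[i][c] for i, c in enumerate(choice)])
        if _friedman_statistic(perm_ranks) >= observed - 1e-12:
            count += 1
    return count / total


def wilcoxon_signed_rank(x, y, *, exact_n: int = WILCOXON_EXACT_N) -> TestResult:
    """Two-sided Wilcoxon signed-rank test; zero differences dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = x - y
    nz = int(np.count_nonzero(d))
    if nz == 0:
        return TestResult(0.0, 1.0, n=0, method="wilcoxon")
    mode = "exact" if nz <= exact_n else "approx"
    try:
        res = sps.wilcoxon(
            x, y, zero_method="wilcox", correction=(mode == "approx"), method=mode
        )
    except ValueError:
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True,
                           method="approx")
        mode = "approx"
    return TestResult(
        float(res.statistic), float(res.pvalue), n=nz, method=f"wilcoxon-{mode}"
    )


# ---------------------------------------------------------------------------
# McNemar


def mcnemar(b: int, c: int, *, exact_n: int = MCNEMAR_EXACT_N) -> TestResult:
    """McNemar's test from the two discordant-pair counts.

    Exact two-sided binomial p = min(1, 2 P(X >= max(b, c))) with
    X ~ Binomial(b + c, 1/2) for ``b + c <= exact_n``; the
    continuity-corrected chi-square otherwise.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    b, c = int(b), int(c)
    m = b + c
    if m == 0:
        return TestResult(0.0, 1.0, n=0, method="mcnemar-exact")
    if m <= exact_n:
        p = min(1.0, 2.0 * float(sps.binom.sf(max(b, c) - 1, m, 0.5)))
        return TestResult(float(max(b, c)), p, n=m, method="mcnemar-exact")
    chi2 = (abs(b - c) - 1) ** 2 / m
    return TestResult(float(chi2), float(sps.chi2.sf(chi2, 1)), df=1, n=m,
                      method="mcnemar-cc")
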