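"""Diagnostic-validation statistics for the screening pipeline.

Implements the full evaluation toolkit used to validate a binary screening
classifier against a manual reference standard: confusion tables,
sensitivity/specificity, ROC AUC with bootstrap CI, cut-off sweeps, the
projection of a (sensitivity, specificity) operating point onto a
hypothetical population at a fixed disease prevalence (yielding PPV, NPV and
the predicted prevalence), unweighted Cohen's kappa for repeat-scan
reliability, and the association tests (Pearson chi-squared, Welch t) used
for epidemiological face validity.

Population projection uses half-up integer rounding for the positive stratum
and the true negatives, deriving the complements by subtraction, so the
projected 2x2 table always sums exactly to ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    UndefinedMarginError,
)


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 confusion counts (reference standard in columns)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProjectionResult:
    """Operating point projected onto a hypothetical population."""

    sensitivity: float
    specificity: float
    prevalence: float
    n: int
    table: DiagnosticTable
    ppv: float
    npv: float
    predicted_prevalence: float

    @property
    def ppv_pct(self) -> float:
        return round(100.0 * self.ppv, 1)

    @property
    def npv_pct(self) -> float:
        return round(100.0 * self.npv, 1)

    @property
    def predicted_prevalence_pct(self) -> float:
        return round(100.0 * self.predicted_prevalence, 1)


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CutoffRow:
    """One row of a cut-off sweep."""

    cutoff: float
    table: DiagnosticTable
    sensitivity: float
    specificity: float
    auc: AucResult
    projection: ProjectionResult


@dataclass(frozen=True)
class AgreementResult:
    """Chance-corrected agreement between two categorical ratings."""

    kappa: float
    ci_low: float
    ci_high: float
    percent_agreement: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)

    def band(self) -> str:
        """Conventional qualitative band for the kappa value."""
        if not self.defined:
            return "undefined"
        k = self.kappa
        if k <= 0:
            return "poor"
        for hi, name in [(0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
                         (0.80, "substantial"), (1.00, "almost perfect")]:
            if k <= hi:
                return name
        return "almost perfect"


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, [0, 1, True, False])):
        raise InvalidInputError(f"{name} must be binary (0/1)")
    return arr.astype(int)


def confusion(predicted, truth) -> DiagnosticTable:
    """Confusion table of binary predictions against binary truth."""
    p = _as_binary(predicted, "predicted")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape or p.size == 0:
        raise InvalidInputError("predicted and truth must be equal-length, non-empty")
    return DiagnosticTable(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def sens_spec(table: DiagnosticTable) -> tuple[float, float]:
    """(sensitivity, specificity) of a confusion table, as fractions."""
    if table.tp + table.fn == 0:
        raise UndefinedMarginError("no positives in the reference standard")
    if table.tn + table.fp == 0:
        raise UndefinedMarginError("no negatives in the reference standard")
    return table.tp / (table.tp + table.fn), table.tn / (table.tn + table.fp)


def roc_auc(
    scores, truth, n_boot: int = 2000, seed: int = 0, ci_level: float = 0.95
) -> AucResult:
    """ROC AUC (Mann-Whitney statistic, ties count 1/2) with bootstrap CI.

    The CI is a percentile interval over ``n_boot`` stratified bootstrap
    resamples (positives and negatives resampled separately), seeded for
    reproducibility.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth, "truth")
    if s.shape != t.shape:
        raise InvalidInputError("scores and truth must have equal length")
    pos, neg = s[t == 1], s[t == 0]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("both classes must be present for ROC analysis")
    auc = float(roc_auc_score(t, s))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        bs = np.concatenate([bp, bn])
        bt = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
        boots[i] = roc_auc_score(bt, bs)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return AucResult(auc=auc, ci_low=float(lo), ci_high=float(hi))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def project_population(
    sensitivity: float, specificity: float, prevalence: float, n: int
) -> ProjectionResult:
    """Project an operating point onto a hypothetical population of size n.

    The diseased stratum is ``P = round(n * prevalence)``; true positives
    are ``round(P * sensitivity)`` with false negatives by subtraction, true
    negatives ``round((n - P) * specificity)`` with false positives by
    subtraction, so the table sums exactly to ``n``.  PPV, NPV and the
    predicted prevalence ``(tp + fp) / n`` follow from the projected table.
    """
    for name, v in [("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)]:
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
    if n < 1:
        raise InvalidInputError("population size n must be >= 1")
    p_total = _round_half_up(n * prevalence)
    tp = _round_half_up(p_total * sensitivity)
    fn = p_total - tp
    n_neg = n - p_total
    tn = _round_half_up(n_neg * specificity)
    fp = n_neg - tn
    table = DiagnosticTable(tp=tp, fp=fp, tn=tn, fn=fn)
    if tp + fp == 0:
        raise UndefinedMarginError("no predicted positives: PPV undefined")
    if tn + fn == 0:
        raise UndefinedMarginError("no predicted negatives: NPV undefined")
    return ProjectionResult(
        sensitivity=sensitivity,
        specificity=specificity,
        prevalence=prevalence,
        n=n,
        table=table,
        ppv=tp / (tp + fp),
        npv=tn / (tn + fn),
        predicted_prevalence=(tp + fp) / n,
    )


def sweep_cutoffs(
    scores,
    truth,
    cutoffs,
    prevalence: float = 0.059,
    n_projection: int = 10_000,
    seed: int = 0,
    n_boot: int = 2000,
) -> list[CutoffRow]:
    """Evaluate the binary classifier at each cut-off of the score.

    A call is positive when ``score > cutoff`` (strict).  Sensitivity is
    non-increasing and specificity non-decreasing along the (strictly
    increasing) cut-off list; each row carries the projection of its
    operating point onto the hypothetical population.
    """
    cutoffs = list(cutoffs)
    if cutoffs != sorted(set(cutoffs)) or not all(0 <= c <= 1 for c in cutoffs):
        raise InvalidInputError("cutoffs must be strictly increasing within [0, 1]")
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth, "truth")
    auc = roc_auc(s, t, n_boot=n_boot, seed=seed)
    rows = []
    for c in cutoffs:
        table = confusion(s > c, t)
        se, sp = sens_spec(table)
        rows.append(
            CutoffRow(
                cutoff=c,
                table=table,
                sensitivity=se,
                specificity=sp,
                auc=auc,
                projection=project_population(se, sp, prevalence, n_projection),
            )
        )
    return rows


def cohen_kappa(ratings_a, ratings_b, ci_level: float = 0.95) -> AgreementResult:
    """Unweighted Cohen's kappa with a large-sample normal CI.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with expected agreement from the
    marginal products; the standard error is the classical large-sample form
    ``sqrt(p_o (1 - p_o) / (n (1 - p_e)^2))``.  When both raters are
    constant and identical (p_e = 1) kappa is undefined and returned as NaN
    with the percent agreement still reported.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size < 2:
        raise InvalidInputError("ratings must be equal-length with n >= 2")
    n = a.size
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(np.sum(pa * pb))
    if p_e >= 1.0 - 1e-12:
        return AgreementResult(kappa=float("nan"), ci_low=float("nan"),
                               ci_high=float("nan"), percent_agreement=p_o)
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return AgreementResult(
        kappa=float(kappa),
        ci_low=float(max(-1.0, kappa - z * se)),
        ci_high=float(min(1.0, kappa + z * se)),
        percent_agreement=p_o,
    )


def chi2_association(contingency, correction: bool = False):
    """Pearson chi-squared test of independence on an r x c count table.

    Returns ``(statistic, p_value, dof, expected)``.  Continuity correction
    is off by default (available via ``correction=True``).
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise InvalidInputError("contingency must be a 2-D table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidInputError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=correction)
    if np.any(res.expected_freq <= 0):
        raise InvalidInputError("all expected counts must be positive")
    return float(res.statistic), float(res.pvalue), int(res.dof), res.expected_freq


def row_percentages(contingency) -> np.ndarray:
    """Per-row percentages of an r x c table, rounded to one decimal."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim == 1:
        table = table[None, :]
    totals = table.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise InvalidInputError("every row must have a positive total")
    return np.round(100.0 * table / totals, 1)


def unpaired_t_test(group_a, group_b, welch: bool = True):
    """Two-sample t test (Welch by default; pooled-variance optional).

    Returns ``(statistic, p_value, (mean_a, sd_a), (mean_b, sd_b))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateInputError("both groups have zero variance; t test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return (
        float(res.statistic),
        float(res.pvalue),
        (float(a.mean()), float(a.std(ddof=1))),
        (float(b.mean()), float(b.std(ddof=1))),
    )


def percent_agreement(labels_t1, labels_t2) -> float:
    """Share of positions with equal labels between two ratings."""
    a = np.asarray(labels_t1)
    b = np.asarray(labels_t2)
    if a.shape != b.shape or a.size == 0:
        raise InvalidInputError("label sequences must be equal-length and non-empty")
    return float(np.mean(a == b))
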