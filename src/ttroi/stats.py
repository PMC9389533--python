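"""Diagnostic-accuracy metrics, agreement statistics and hypothesis tests.

Covers the statistics a video-level diagnostic evaluation reports: the 2×2
confusion table and its derived metrics (sensitivity, specificity, accuracy
with Wilson score intervals; positive/negative likelihood ratios with Simel
log-method intervals), per-pathology stratified accuracy, Cohen's kappa for
inter-rater agreement, the paired McNemar test (exact binomial by default),
Pearson's chi-square without continuity correction, Fisher's exact test, and
the Mann–Whitney U test with midrank tie handling.

Display rounding follows the usual reporting style — two decimals for
proportions and likelihood ratios, three for p-values — via half-up rounding
(:func:`round_half_up`), so 10/16 prints as 0.63; full precision is retained
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "Estimate", "ConfusionCounts", "DiagnosticReport", "McNemarResult",
    "confusion_counts", "diagnostic_metrics", "wilson_ci",
    "stratified_accuracy", "cohens_kappa", "mcnemar_test",
    "pearson_chi2_2x2", "fisher_exact_2x2", "mann_whitney", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.625 → 0.63), the convention of printed
    clinical tables; Python's built-in ``round`` is half-even."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class Estimate(NamedTuple):
    """A point estimate with its confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 2) -> "Estimate":
        return Estimate(*(round_half_up(v, ndigits) for v in self))


@dataclass(frozen=True)
class ConfusionCounts:
    """The 2×2 diagnostic table (positive = cancer)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


def confusion_counts(truths, predictions, pos_label="cancer") -> ConfusionCounts:
    """Exact cell counts from aligned truth/prediction vectors."""
    t = np.asarray(truths)
    p = np.asarray(predictions)
    if t.shape != p.shape:
        raise ValueError("truths and predictions differ in length")
    t_pos = t == pos_label if t.dtype.kind not in "bif" else t.astype(bool)
    p_pos = p == pos_label if p.dtype.kind not in "bif" else p.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
    )


def wilson_ci(k: int, n: int, ci_level: float = 0.95) -> Estimate:
    """Binomial proportion with its Wilson score interval."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return Estimate(k / n, float(lo), float(hi))


@dataclass(frozen=True)
class DiagnosticReport:
    """Sensitivity, specificity, accuracy (Wilson CIs) and likelihood ratios
    (log-method CIs) for one confusion table.

    A zero false-positive count makes the PLR infinite (NaN interval, flagged
    via ``plr_defined = False``); a zero specificity does the same for the NLR.
    """

    sensitivity: Estimate
    specificity: Estimate
    accuracy: Estimate
    plr: Estimate
    nlr: Estimate
    n_pos: int
    n_neg: int
    plr_defined: bool = True
    nlr_defined: bool = True

    def to_dict(self, ndigits: int | None = None) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "plr", "nlr"):
            est: Estimate = getattr(self, name)
            if ndigits is not None:
                est = est.rounded(ndigits)
            out[name] = {"value": est.value, "ci_low": est.ci_low,
                         "ci_high": est.ci_high}
        out["n_pos"] = self.n_pos
        out["n_neg"] = self.n_neg
        return out


def _lr_ci(lr: float, se_log: float, z: float) -> Estimate:
    if not np.isfinite(lr) or lr == 0:
        # log interval collapses; report the point with a degenerate CI
        return Estimate(lr, lr, lr)
    log_lr = np.log(lr)
    return Estimate(lr, float(np.exp(log_lr - z * se_log)),
                    float(np.exp(log_lr + z * se_log)))


def diagnostic_metrics(counts: ConfusionCounts, ci_level: float = 0.95) -> DiagnosticReport:
    """Diagnostic metrics for a 2×2 table.

    Sensitivity tp/(tp+fn), specificity tn/(fp+tn), accuracy (tp+tn)/total,
    PLR = sens/(1−spec), NLR = (1−sens)/spec.  Proportions get Wilson score
    intervals; likelihood ratios get the Simel log-method interval
    exp(ln LR ± z·SE) with SE² = 1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn) for the
    PLR and 1/fn − 1/(tp+fn) + 1/tn − 1/(fp+tn) for the NLR.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise ValueError("need at least one positive and one negative case")
    z = float(sps.norm.ppf(0.5 + ci_level / 2))
    sens = wilson_ci(tp, counts.n_pos, ci_level)
    spec = wilson_ci(tn, counts.n_neg, ci_level)
    acc = wilson_ci(tp + tn, counts.total, ci_level)

    plr_defined = fp > 0
    if plr_defined:
        plr_val = sens.value / (fp / counts.n_neg)
        with np.errstate(divide="ignore"):
            se = np.sqrt(
                (1 / tp if tp else np.inf) - 1 / counts.n_pos
                + 1 / fp - 1 / counts.n_neg
            )
        plr = (
            _lr_ci(plr_val, float(se), z)
            if tp > 0
            else Estimate(0.0, np.nan, np.nan)
        )
    else:
        plr = Estimate(np.inf, np.nan, np.nan)

    nlr_defined = tn > 0
    if nlr_defined:
        nlr_val = (fn / counts.n_pos) / spec.value
        se = np.sqrt(
            (1 / fn if fn else np.inf) - 1 / counts.n_pos
            + 1 / tn - 1 / counts.n_neg
        )
        nlr = (
            _lr_ci(nlr_val, float(se), z)
            if fn > 0
            else Estimate(0.0, np.nan, np.nan)
        )
    else:
        nlr = Estimate(np.inf, np.nan, np.nan)

    return DiagnosticReport(
        sensitivity=sens, specificity=spec, accuracy=acc, plr=plr, nlr=nlr,
        n_pos=counts.n_pos, n_neg=counts.n_neg,
        plr_defined=plr_defined, nlr_defined=nlr_defined,
    )


def stratified_accuracy(
    pathology: Sequence[str], correct: Sequence[bool], ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-stratum proportion of correctly classified videos with Wilson CIs.

    Returns a DataFrame with columns pathology, n, n_correct, proportion,
    ci_low, ci_high — one row per stratum present in the input (empty strata
    cannot occur; a stratum name passed with no videos is simply absent, with
    a warning if ``pathology`` is empty overall).
    """
    frame = pd.DataFrame({"pathology": pathology, "correct": np.asarray(correct, bool)})
    if frame.empty:
        warnings.warn("no videos to stratify", stacklevel=2)
        return pd.DataFrame(
            columns=["pathology", "n", "n_correct", "proportion", "ci_low", "ci_high"]
        )
    rows = []
    for name, grp in frame.groupby("pathology", sort=True):
        n = len(grp)
        k = int(grp["correct"].sum())
        est = wilson_ci(k, n, ci_level)
        rows.append((name, n, k, est.value, est.ci_low, est.ci_high))
    return pd.DataFrame(
        rows, columns=["pathology", "n", "n_correct", "proportion", "ci_low", "ci_high"]
    )


def cohens_kappa(ratings_a, ratings_b, ci_level: float = 0.95) -> Estimate:
    """Cohen's kappa between two raters over the same cases.

    κ = (p_o − p_e)/(1 − p_e) with chance agreement p_e from the marginal
    products; the interval uses the large-sample standard error
    SE = sqrt(p_o(1 − p_o)/(n(1 − p_e)²)), clipped to [−1, 1].
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape:
        raise ValueError("ratings differ in length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 cases")
    labels = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        raise ValueError("kappa undefined: both raters are constant")
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    z = float(sps.norm.ppf(0.5 + ci_level / 2))
    return Estimate(
        kappa, max(-1.0, kappa - z * se), min(1.0, kappa + z * se)
    )


class McNemarResult(NamedTuple):
    b: int  #: cases the first classifier got right and the second wrong
    c: int  #: cases the second classifier got right and the first wrong
    pvalue: float


def mcnemar_test(correct_a, correct_b, exact: bool = True) -> McNemarResult:
    """Paired McNemar test on the correctness of two classifiers.

    ``correct_a`` and ``correct_b`` are aligned boolean vectors (or the
    discordant counts may be supplied directly via scalars b, c).  The default
    is the exact two-sided binomial test on the discordant pairs with success
    probability ½; ``exact=False`` uses the asymptotic chi-square statistic
    (b − c)²/(b + c) without continuity correction.  Zero discordance gives
    p = 1 (no evidence either way).
    """
    a = np.asarray(correct_a)
    bb = np.asarray(correct_b)
    if a.ndim == 0 and bb.ndim == 0:
        b, c = int(a), int(bb)
    else:
        if a.shape != bb.shape:
            raise ValueError("correctness vectors differ in length")
        a = a.astype(bool)
        bb = bb.astype(bool)
        b = int(np.sum(a & ~bb))
        c = int(np.sum(~a & bb))
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b, c, 1.0)
    if exact:
        p = float(sps.binomtest(b, n_disc, 0.5).pvalue)
    else:
        stat = (b - c) ** 2 / n_disc
        p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(b, c, min(1.0, p))


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2×2 table, got shape {arr.shape}")
    if np.any(arr < 0) or arr.sum() < 1:
        raise ValueError("table cells must be non-negative with total ≥ 1")
    return arr


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 table, df = 1, no continuity correction.

    Equals N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)); a zero row or column margin
    is a degenerate table and an error.
    """
    arr = _as_2x2(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (hypergeometric summation); a zero margin
    leaves a single possible table, so p = 1."""
    arr = _as_2x2(table)
    return float(sps.fisher_exact(arr.astype(int))[1])


def mann_whitney(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test with midrank tie handling.

    Returns (U, p) where U counts pairs in which ``group_a`` exceeds
    ``group_b`` (ties ½).  ``method="auto"`` uses exact enumeration when
    n₁·n₂ ≤ 400 and there are no ties, otherwise the tie-corrected normal
    approximation with continuity correction; ``"exact"``/``"asymptotic"``
    force a path.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        return a.size * b.size / 2.0, 1.0  # fully tied
    has_ties = np.unique(combined).size < combined.size
    if method == "auto":
        method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)
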