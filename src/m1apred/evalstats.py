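"""Evaluation metrics, split protocols and model-comparison tests.

Metrics follow the usual binary-classification definitions with TP the
correctly called m1A sites and TN the correctly called non-m1A sites:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FP + FN + TN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2 TP / (2 TP + FP + FN)

Degenerate denominators (a zero factor under the MCC root, an empty
positive or negative class for Sn/Sp) return 0 by convention.  AUROC is
the Mann-Whitney probability that a random positive outranks a random
negative, ties counted one half.

Split protocols: a stratified 70/30 independent split and k-fold
cross-validation with shuffling.  Model comparisons: the pooled
two-proportion z test, McNemar's test on discordant pairs (exact binomial
below a configurable discordant-count threshold, continuity-corrected
chi-square above it), and the resampled paired t-test on per-trial
accuracy differences over repeated random 70/30 resplits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, train_test_split


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    Acc: float
    Sp: float
    Sn: float
    MCC: float
    F1: float
    AUROC: float | None = None

    def as_dict(self) -> dict:
        d = {"Acc": self.Acc, "Sp": self.Sp, "Sn": self.Sn, "MCC": self.MCC, "F1-score": self.F1}
        d["AUROC"] = self.AUROC
        return d


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion counts of binary predictions."""
    y_true, y_pred = _check_binary(y_true), _check_binary(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics(c: ConfusionCounts, y_true=None, scores=None) -> EvaluationReport:
    """Derive Acc/Sp/Sn/MCC/F1 (and AUROC when scores are given) from counts."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    TP, TN, FP, FN = c.TP, c.TN, c.FP, c.FN
    mcc_den = float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    report_auroc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required to compute AUROC from scores")
        report_auroc = auroc(y_true, scores)
    return EvaluationReport(
        counts=c,
        Acc=(TP + TN) / c.total,
        Sp=_safe_div(TN, TN + FP),
        Sn=_safe_div(TP, TP + FN),
        MCC=_safe_div(TP * TN - FP * FN, np.sqrt(mcc_den)),
        F1=_safe_div(2 * TP, 2 * TP + FP + FN),
        AUROC=report_auroc,
    )


def auroc(y_true, scores) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y_true = _check_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y_true.sum()), int((1 - y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    test: np.ndarray | None
    folds: tuple[tuple[np.ndarray, np.ndarray], ...] | None
    seed: int
    stratified: bool


def split_70_30(n: int, labels, seed: int = 0, test_size: float = 0.3) -> SplitPlan:
    """Stratified independent split with 70% train / 30% test by default."""
    labels = _check_binary(labels)
    if n != len(labels) or n < 2:
        raise ValueError("need n >= 2 with one label per sample")
    if labels.sum() in (0, n):
        raise ValueError("both classes must be present for a stratified split")
    idx = np.arange(n)
    train, test = train_test_split(idx, test_size=test_size, random_state=seed, stratify=labels)
    return SplitPlan(train=np.sort(train), test=np.sort(test), folds=None, seed=seed, stratified=True)


def kfold(n: int, k: int = 10, seed: int = 0) -> SplitPlan:
    """k disjoint shuffled folds covering all indices; sizes differ by <= 1."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple((tr, te) for tr, te in splitter.split(np.arange(n)))
    return SplitPlan(train=np.arange(n), test=None, folds=folds, seed=seed, stratified=False)


def z_two_proportion(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z test, two-sided.

    Returns (z, p).  With identical proportions z = 0 and p = 1; swapping the
    samples flips z's sign and leaves p unchanged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("trial counts must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mcnemar(b: int, c: int, exact_threshold: int = 25) -> tuple[float, float]:
    """McNemar's test on the discordant counts of a 2x2 paired table.

    ``b`` and ``c`` are the two off-diagonal (discordant) counts.  For
    b + c < ``exact_threshold`` the exact two-sided binomial p is used;
    otherwise the continuity-corrected chi-square statistic.  Returns
    (statistic, p); the statistic is min(b, c) in the exact regime.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        raise UndefinedMetricError("no discordant pairs; McNemar test undefined")
    if n < exact_threshold:
        stat = float(min(b, c))
        p = min(1.0, 2 * stats.binom.cdf(min(b, c), n, 0.5))
        # symmetric case: the two tails overlap at the midpoint
        if b == c:
            p = 1.0
        return stat, float(p)
    stat = max(0, abs(b - c) - 1) ** 2 / n  # correction clamped so b == c gives 0
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return float(stat), p


def resampled_paired_ttest(model_a, model_b, X, y, trials: int = 10, seed: int = 0,
                           test_size: float = 0.3) -> tuple[float, float]:
    """Resampled paired t-test on accuracy over repeated random 70/30 resplits.

    ``model_a`` / ``model_b`` are callables ``(X_tr, y_tr, X_te) -> y_pred``.
    Each trial redraws a stratified split; the paired t statistic is computed
    on the per-trial accuracy differences with trials - 1 degrees of freedom.
    A zero-variance difference returns t = 0, p = 1 when the mean is zero and
    t = +/-inf, p = 0 otherwise.
    """
    if trials < 2:
        raise ValueError("need at least 2 trials")
    X = np.asarray(X)
    y = _check_binary(y)
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(trials):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        plan = split_70_30(len(y), y, seed=sub_seed, test_size=test_size)
        tr, te = plan.train, plan.test
        acc_a = float((model_a(X[tr], y[tr], X[te]) == y[te]).mean())
        acc_b = float((model_b(X[tr], y[tr], X[te]) == y[te]).mean())
        diffs.append(acc_a - acc_b)
    d = np.asarray(diffs)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(trials))
    p = 2 * stats.t.sf(abs(t), df=trials - 1)
    return float(t), float(p)
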