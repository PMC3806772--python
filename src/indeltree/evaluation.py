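"""Classifier evaluation: confusion metrics, ROC/AUC, k-fold
cross-validation, balanced resampling, and greedy forward feature
selection.

Damaging indels are the positive class.  Metric formulas follow the
standard definitions —

    sensitivity = TP / (TP + FN)            specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)            accuracy = (TP + TN) / n
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

— computed in exact rational arithmetic before any display rounding; MCC
is reported missing when a confusion marginal is zero.  AUC is the
tie-averaged area under the sensitivity vs. (1 - specificity) curve,
equivalently the Mann-Whitney pairwise statistic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import DAMAGING, NEUTRAL, TrainParams, train_tree

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy",
                "mcc", "auc")


@dataclass(frozen=True)
class Confusion:
    """TP/TN/FP/FN counts with damaging as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "Confusion") -> "Confusion":
        return Confusion(self.tp + other.tp, self.tn + other.tn,
                         self.fp + other.fp, self.fn + other.fn)


def _ratio(num: int, den: int) -> Fraction | None:
    # exact rational arithmetic; rounding happens only at display time
    return None if den == 0 else Fraction(num, den)


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts plus derived metrics; optionally per-stratum
    sub-reports (insertions/deletions) and mean +/- SD across
    resamplings."""

    confusion: Confusion
    sensitivity: Fraction | None
    specificity: Fraction | None
    precision: Fraction | None
    accuracy: Fraction | None
    mcc: float | None
    auc: float | None = None
    strata: Mapping[str, "EvalReport"] = field(default_factory=dict)
    seed: int | None = None

    def metric(self, name: str) -> float | None:
        return getattr(self, name)

    def display(self) -> dict:
        """Rounded for presentation: percentages to integers, MCC/AUC to
        2 decimals."""
        out = {
            "TP": self.confusion.tp, "TN": self.confusion.tn,
            "FP": self.confusion.fp, "FN": self.confusion.fn,
        }
        for name in ("sensitivity", "specificity", "precision", "accuracy"):
            val = self.metric(name)
            out[name + "_pct"] = None if val is None else round(100 * val)
        out["mcc"] = None if self.mcc is None else round(self.mcc, 2)
        out["auc"] = None if self.auc is None else round(self.auc, 2)
        if self.seed is not None:
            out["seed"] = self.seed
        return out

    def to_json(self) -> str:
        payload = self.display()
        if self.strata:
            payload["strata"] = {k: v.display()
                                 for k, v in self.strata.items()}
        return json.dumps(payload, indent=2, sort_keys=True)


def metrics(c: Confusion, auc: float | None = None,
            seed: int | None = None,
            strata: Mapping[str, EvalReport] | None = None) -> EvalReport:
    """Derive all metrics from confusion counts (exact arithmetic)."""
    if c.n == 0:
        raise ValueError("cannot compute metrics of an empty confusion")
    marg = [(c.tp + c.fn), (c.tp + c.fp), (c.tn + c.fp), (c.tn + c.fn)]
    if 0 in marg:
        mcc = None
    else:
        num = c.tp * c.tn - c.fp * c.fn
        mcc = num / math.sqrt(math.prod(marg))
    return EvalReport(
        confusion=c,
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.n),
        mcc=mcc, auc=auc, seed=seed, strata=strata or {})


def confusion_from_labels(truth: Sequence[str],
                          predicted: Sequence[str]) -> Confusion:
    t = np.asarray(truth)
    p = np.asarray(predicted)
    return Confusion(
        tp=int(((t == DAMAGING) & (p == DAMAGING)).sum()),
        tn=int(((t == NEUTRAL) & (p == NEUTRAL)).sum()),
        fp=int(((t == NEUTRAL) & (p == DAMAGING)).sum()),
        fn=int(((t == DAMAGING) & (p == NEUTRAL)).sum()))


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Area under the ROC curve with ties averaged (the Mann-Whitney
    U-statistic equivalence)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == DAMAGING
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    ranks = rankdata(s)  # average ranks for ties
    r_pos = ranks[pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

Trainer = Callable[[pd.DataFrame, np.ndarray], object]


def _default_trainer(params: TrainParams | None = None) -> Trainer:
    def fit(X: pd.DataFrame, y):
        return train_tree(X, y, params)
    return fit


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample; classes dealt round-robin after a shuffle."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def kfold_cv(features: pd.DataFrame, labels, k: int = 10, *,
             trainer: Trainer | None = None, seed: int = 0,
             strata: Sequence[str] | None = None) -> EvalReport:
    """Stratified k-fold cross-validation with a pooled confusion.

    Each sample is tested exactly once; AUC is computed from the pooled
    held-out ranking scores.  If a training split loses a class, the
    stratified shuffle is retried (up to 10 attempts).
    """
    y = np.asarray([DAMAGING if str(l) in (DAMAGING, "1", "True") else NEUTRAL
                    for l in labels])
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if len({DAMAGING, NEUTRAL} & set(y)) < 2:
        raise ValueError("both classes must be present")
    trainer = trainer or _default_trainer()
    rng = np.random.default_rng(seed)
    ybin = (y == DAMAGING).astype(int)

    for _ in range(10):
        folds = _stratified_folds(ybin, k, rng)
        if all(len(np.unique(ybin[folds != f])) == 2 for f in range(k)):
            break
    else:
        raise ValueError("could not stratify folds with both classes in "
                         "every training split")

    pred = np.empty(n, dtype=object)
    scores = np.empty(n, dtype=float)
    for f in range(k):
        test = folds == f
        model = trainer(features.iloc[~test], y[~test])
        pred[test], scores[test] = model.predict_frame(features.iloc[test])

    pooled = confusion_from_labels(y, pred)
    assert pooled.n == n  # every sample tested exactly once
    try:
        auc = roc_auc(scores, y)
    except ValueError:
        auc = None
    sub: dict[str, EvalReport] = {}
    if strata is not None:
        strata = np.asarray(strata)
        for name in sorted(set(strata)):
            mask = strata == name
            sub[name] = metrics(confusion_from_labels(y[mask], pred[mask]),
                                seed=seed)
    return metrics(pooled, auc=auc, seed=seed, strata=sub)


# --------------------------------------------------------------------------
# Balanced resampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResamplingReport:
    """Mean (and SD when reps > 1) of each metric across resamplings."""

    reps: int
    mean: Mapping[str, float | None]
    sd: Mapping[str, float] | None
    per_rep: tuple[EvalReport, ...]
    seed: int

    def display(self) -> dict:
        out: dict = {"reps": self.reps, "seed": self.seed}
        for name in METRIC_NAMES:
            val = self.mean.get(name)
            if val is None:
                continue
            fractional = name in ("mcc", "auc")
            key = name if fractional else name + "_pct"
            out[key] = round(val, 2) if fractional else round(100 * val)
            if self.sd is not None and self.sd.get(name) is not None:
                sd = self.sd[name]
                out[key + "_sd"] = round(sd if fractional else 100 * sd, 2)
        return out


def balanced_resampling(disease: pd.DataFrame, neutral_pool: pd.DataFrame,
                        reps: int = 1000, *, k: int = 10, seed: int = 0,
                        trainer: Trainer | None = None) -> ResamplingReport:
    """Repeatedly balance the classes and cross-validate.

    Each repetition samples ``len(disease)`` neutral rows from the pool
    without replacement, runs stratified k-fold CV on the balanced set,
    and the per-metric mean and standard deviation (ddof=1) are aggregated
    across repetitions.
    """
    n_d = len(disease)
    if len(neutral_pool) < n_d:
        raise ValueError(
            f"neutral pool ({len(neutral_pool)}) smaller than disease set "
            f"({n_d})")
    rng = np.random.default_rng(seed)
    reports: list[EvalReport] = []
    for _ in range(reps):
        take = rng.choice(len(neutral_pool), size=n_d, replace=False)
        sampled = neutral_pool.iloc[np.sort(take)]
        X = pd.concat([disease, sampled])
        y = np.array([DAMAGING] * n_d + [NEUTRAL] * n_d)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        reports.append(kfold_cv(X, y, k, trainer=trainer, seed=rep_seed))

    mean: dict[str, float | None] = {}
    sd: dict[str, float] | None = {} if reps > 1 else None
    for name in METRIC_NAMES:
        vals = [r.metric(name) for r in reports]
        present = [float(v) for v in vals if v is not None]
        mean[name] = float(np.mean(present)) if present else None
        if sd is not None:
            sd[name] = (float(np.std(present, ddof=1))
                        if len(present) > 1 else None)
    return ResamplingReport(reps=reps, mean=mean, sd=sd,
                            per_rep=tuple(reports), seed=seed)


# --------------------------------------------------------------------------
# Greedy forward feature selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected features with the CV-MCC trace at each step."""

    selected: tuple[str, ...]
    trace: tuple[tuple[str, float], ...]  # (feature added, MCC after adding)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace, columns=["feature", "mcc"],
                            index=pd.RangeIndex(1, len(self.trace) + 1,
                                                name="n_features"))


def _selection_mcc(report: EvalReport) -> float:
    # undefined MCC (a degenerate fold marginal) compares as 0
    return report.mcc if report.mcc is not None else 0.0


def greedy_feature_selection(features: pd.DataFrame, labels,
                             candidates: Sequence[str] | None = None, *,
                             k: int = 10, seed: int = 0,
                             trainer: Trainer | None = None
                             ) -> SelectionResult:
    """Forward selection by cross-validated MCC.

    Each step evaluates every remaining candidate added to the current set
    and keeps the best strict improvement; selection stops when no
    addition strictly increases the MCC.  Ties break to the earliest
    candidate in column order.  The same CV seed is used for every
    evaluation so comparisons share fold assignments.
    """
    candidates = list(candidates if candidates is not None
                      else features.columns)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    best_mcc = -math.inf
    while candidates:
        step_best: tuple[float, str] | None = None
        for feat in candidates:  # column order = tie-break order
            rep = kfold_cv(features[selected + [feat]], labels, k,
                           trainer=trainer, seed=seed)
            score = _selection_mcc(rep)
            if step_best is None or score > step_best[0] + 1e-12:
                step_best = (score, feat)
        assert step_best is not None
        if step_best[0] <= best_mcc + 1e-12:
            break
        best_mcc = step_best[0]
        selected.append(step_best[1])
        candidates.remove(step_best[1])
        trace.append((step_best[1], best_mcc))
    return SelectionResult(selected=tuple(selected), trace=tuple(trace))


# --------------------------------------------------------------------------
# Report serialization
# --------------------------------------------------------------------------

def write_report(report, path: str) -> None:
    """Write an EvalReport or ResamplingReport as JSON."""
    payload = (json.loads(report.to_json())
               if isinstance(report, EvalReport) else report.display())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_roc_points(scores: Sequence[float], labels: Sequence[str],
                     path: str) -> None:
    """Export ROC points (FPR, TPR per threshold) as TSV for plotting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == DAMAGING
    order = np.argsort(-s, kind="stable")
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        fh.write("inf\t0.0\t0.0\n")
        for i in np.nonzero(np.diff(np.append(s[order], -np.inf)))[0]:
            fh.write(f"{s[order][i]:g}\t{fp[i] / n_neg:.6f}\t"
                     f"{tp[i] / n_pos:.6f}\n")
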