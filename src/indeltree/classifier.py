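"""Gene-damaging vs. neutral classification.

Two routes are provided:

* A published-rules engine: an ordered, mutually exclusive set of decision
  rules shipped as a plain-text TSV.  The three high-coverage rules carry
  the training support/correct counts behind their confidence scores
  (0.918 = 291/317, 0.720 = 59/82, 0.894 = 254/284); combinations of the
  four features not covered by a published rule fall to explicit
  ``default-*`` rules at confidence 0.5, which are overridable via the
  rule file.

* A C4.5-style decision-tree trainer to re-derive trees from labeled
  feature matrices: gain-ratio split selection, binary threshold splits on
  numeric features (midpoints between sorted distinct values), boolean
  splits on flags, and pessimistic error-based pruning (confidence 0.25,
  minimum leaf size 2 by default).  Missing numeric values are routed down
  the majority branch — a documented simplification of fractional
  instances.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .feature_extraction import (CORE_FEATURES, ConfigurationError,
                                 FeatureVector)

DAMAGING = "damaging"
NEUTRAL = "neutral"

#: Conservation threshold of the published rules: the 5' flanking base is
#: "not conserved" at scores <= 1.405.
CONSERVATION_THRESHOLD = 1.405


class RuleFileError(ValueError):
    """Malformed or inconsistent rule file."""


# --------------------------------------------------------------------------
# Rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """A single attribute test: ``feature op value``.

    ``op`` is one of ``==``, ``>``, ``<=`` for numeric features and ``is``
    for flags (value true/false).  A missing numeric value satisfies the
    low branch (``<=``) and fails the high branch: the published rules then
    treat a missing conservation score as "not conserved".
    """

    feature: str
    op: str
    value: float

    def matches(self, values: Mapping[str, float]) -> bool:
        if self.feature not in values:
            raise ConfigurationError(
                f"feature {self.feature!r} absent from vector schema")
        x = values[self.feature]
        if isinstance(x, float) and math.isnan(x):
            return self.op == "<="
        if self.op == "==":
            return x == self.value
        if self.op == "is":
            return bool(x) == bool(self.value)
        if self.op == "<=":
            return x <= self.value
        if self.op == ">":
            return x > self.value
        raise RuleFileError(f"unknown operator {self.op!r}")

    def __str__(self) -> str:
        if self.op == "is":
            return f"{self.feature} is {'true' if self.value else 'false'}"
        return f"{self.feature} {self.op} {self.value:g}"


def rule_confidence(correct: int, support: int) -> float:
    """Confidence of a rule: correct/support, rounded to 3 decimals."""
    if support <= 0:
        raise RuleFileError("rule confidence undefined for support 0")
    if not 0 < correct <= support:
        raise RuleFileError(
            f"correct ({correct}) must be in (0, support={support}]")
    return round(correct / support, 3)


@dataclass(frozen=True)
class DecisionRule:
    """An ordered conjunction of attribute tests with a class label."""

    rule_id: str
    conditions: tuple[Condition, ...]
    predicted_class: str
    support: int
    correct: int
    confidence: float

    def matches(self, values: Mapping[str, float]) -> bool:
        return all(c.matches(values) for c in self.conditions)


@dataclass(frozen=True)
class Prediction:
    """A class call with its confidence and ROC ranking score.

    ``score`` ranks toward damaging: the confidence for damaging calls,
    1 - confidence for neutral calls.
    """

    label: str
    confidence: float
    rule_id: str
    score: float


def _prediction(label: str, confidence: float, rule_id: str) -> Prediction:
    score = confidence if label == DAMAGING else 1.0 - confidence
    return Prediction(label=label, confidence=confidence, rule_id=rule_id,
                      score=score)


FALLBACK_RULE_ID = "default-unmatched"


@dataclass(frozen=True)
class RuleSet:
    """An ordered rule list; the first matching rule decides."""

    rules: tuple[DecisionRule, ...]

    def classify(self, fv) -> Prediction:
        values = fv.values if isinstance(fv, FeatureVector) else fv
        for name in CORE_FEATURES:
            if name not in values:
                raise ConfigurationError(
                    f"core feature {name!r} missing from vector")
        for rule in self.rules:
            if rule.matches(values):
                return _prediction(rule.predicted_class, rule.confidence,
                                   rule.rule_id)
        # documented fallback for combinations no shipped rule covers
        return _prediction(DAMAGING, 0.5, FALLBACK_RULE_ID)


def classify_published(fv, rules: RuleSet | None = None) -> Prediction:
    """Classify one feature vector with the shipped published rules."""
    return (rules or published_rules()).classify(fv)


def _parse_condition(text: str) -> Condition:
    parts = text.strip().split()
    if len(parts) != 3:
        raise RuleFileError(f"cannot parse condition {text!r}")
    feature, op, raw = parts
    if op == "is":
        if raw not in ("true", "false"):
            raise RuleFileError(f"flag value must be true/false in {text!r}")
        return Condition(feature, "is", 1.0 if raw == "true" else 0.0)
    if op not in ("==", "<=", ">"):
        raise RuleFileError(f"unknown operator in condition {text!r}")
    return Condition(feature, op, float(raw))


def load_rules(path_or_lines) -> RuleSet:
    """Load a rule TSV (rule_id, conditions, class, support, correct).

    ``default-*`` rules may carry support 0 and get confidence 0.5.  The
    published (non-default) rules are verified to be mutually exclusive;
    an ambiguous pair is a load-time error.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines,
                                                          "__fspath__"):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    rules: list[DecisionRule] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise RuleFileError(f"line {lineno}: expected 5 columns")
        rule_id, cond_text, cls, support_s, correct_s = cols
        if cls not in (DAMAGING, NEUTRAL):
            raise RuleFileError(f"line {lineno}: unknown class {cls!r}")
        conditions = tuple(_parse_condition(c)
                           for c in cond_text.split(";") if c.strip())
        support, correct = int(support_s), int(correct_s)
        if support > 0:
            confidence = rule_confidence(correct, support)
        elif rule_id.startswith("default"):
            confidence = 0.5
        else:
            raise RuleFileError(
                f"line {lineno}: non-default rule with support 0")
        rules.append(DecisionRule(rule_id=rule_id, conditions=conditions,
                                  predicted_class=cls, support=support,
                                  correct=correct, confidence=confidence))
    ruleset = RuleSet(rules=tuple(rules))
    _check_mutual_exclusivity([r for r in rules
                               if not r.rule_id.startswith("default")])
    return ruleset


def _conditions_incompatible(a: Condition, b: Condition) -> bool:
    if a.feature != b.feature:
        return False
    ops = {a.op, b.op}
    if ops == {"is"}:
        return a.value != b.value
    if ops == {"=="}:
        return a.value != b.value
    if ops == {"==", ">"}:
        eq, gt = (a, b) if a.op == "==" else (b, a)
        return eq.value <= gt.value
    if ops == {"==", "<="}:
        eq, le = (a, b) if a.op == "==" else (b, a)
        return eq.value > le.value
    if ops == {"<=", ">"}:
        le, gt = (a, b) if a.op == "<=" else (b, a)
        return le.value <= gt.value
    return False


def _check_mutual_exclusivity(rules: Sequence[DecisionRule]) -> None:
    for i, ra in enumerate(rules):
        for rb in rules[i + 1:]:
            exclusive = any(_conditions_incompatible(ca, cb)
                            for ca in ra.conditions for cb in rb.conditions)
            if not exclusive:
                raise RuleFileError(
                    f"rules {ra.rule_id} and {rb.rule_id} are not mutually "
                    "exclusive")


def published_rules() -> RuleSet:
    """The shipped rule file (three published rules + default branches)."""
    data = importlib.resources.files("indeltree").joinpath(
        "data/published_rules.tsv").read_text()
    return load_rules(data.splitlines())


def save_rules(ruleset: RuleSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# rule_id\tconditions\tclass\tsupport\tcorrect\n")
        for r in ruleset.rules:
            cond = "; ".join(str(c) for c in r.conditions)
            fh.write(f"{r.rule_id}\t{cond}\t{r.predicted_class}\t"
                     f"{r.support}\t{r.correct}\n")


# --------------------------------------------------------------------------
# C4.5-style decision tree induction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainParams:
    pruning_confidence: float = 0.25
    min_leaf: int = 2
    prune: bool = True
    seed: int | None = None  # recorded for provenance; induction is exact


@dataclass
class _Node:
    n: int
    n_damaging: int
    feature: str | None = None
    threshold: float | None = None
    is_bool: bool = False
    left: "_Node | None" = None   # value <= threshold (or flag false)
    right: "_Node | None" = None  # value > threshold (or flag true)
    missing_left: bool = True     # majority branch for missing values

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def label(self) -> str:
        # ties resolve to neutral (the conservative call)
        return DAMAGING if self.n_damaging * 2 > self.n else NEUTRAL

    @property
    def correct(self) -> int:
        return max(self.n_damaging, self.n - self.n_damaging) if \
            self.label == DAMAGING else self.n - self.n_damaging

    @property
    def errors(self) -> int:
        return self.n - self.correct


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def gain_ratio(values: np.ndarray, labels: np.ndarray,
               threshold: float) -> tuple[float, float, float]:
    """Information gain, split information, and gain ratio of the binary
    split ``values <= threshold`` (missing values excluded).

    Exposed for verification against hand-computed textbook values.
    """
    mask = ~np.isnan(values)
    v, y = values[mask], labels[mask]
    n = len(v)
    if n == 0:
        return 0.0, 0.0, 0.0
    parent = _entropy(np.bincount(y, minlength=2))
    left = v <= threshold
    nl = int(left.sum())
    if nl == 0 or nl == n:
        return 0.0, 0.0, 0.0
    e_left = _entropy(np.bincount(y[left], minlength=2))
    e_right = _entropy(np.bincount(y[~left], minlength=2))
    gain = parent - (nl / n) * e_left - ((n - nl) / n) * e_right
    gain *= mask.mean()  # penalise attributes with missing values
    split_info = _entropy(np.array([nl, n - nl]))
    ratio = gain / split_info if split_info > 0 else 0.0
    return gain, split_info, ratio


def _entropy2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise binary entropy of count pairs (0 log 0 := 0)."""
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(total > 0, a / np.maximum(total, 1), 0.0)
        pb = np.where(total > 0, b / np.maximum(total, 1), 0.0)
        out = -(np.where(pa > 0, pa * np.log2(np.maximum(pa, 1e-300)), 0.0)
                + np.where(pb > 0, pb * np.log2(np.maximum(pb, 1e-300)), 0.0))
    return out


def _best_split(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str],
                min_leaf: int) -> tuple[int, float, float] | None:
    """Best (feature index, threshold, gain ratio) or None.

    Candidate thresholds are midpoints between sorted distinct values; the
    whole sweep per feature is vectorised (one sort + cumulative class
    counts).  Ties in gain ratio break to the lowest feature index, then
    the lowest threshold.
    """
    best: tuple[float, int, float] | None = None  # (ratio, j, thr)
    n = len(y)
    for j in range(X.shape[1]):
        col = X[:, j]
        present = ~np.isnan(col)
        v, yv = col[present], y[present]
        n_nm = len(v)
        n_missing = n - n_nm
        if n_nm < 2:
            continue
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], yv[order]
        boundary = np.nonzero(vs[:-1] != vs[1:])[0]  # split after index i
        if len(boundary) == 0:
            continue
        thresholds = (vs[boundary] + vs[boundary + 1]) / 2.0
        cum_d = np.cumsum(ys)
        d_tot = int(cum_d[-1])
        nl = boundary + 1                       # non-missing left counts
        dl = cum_d[boundary].astype(float)      # damaging on the left
        nr = n_nm - nl
        dr = d_tot - dl
        parent = _entropy2(np.array([float(d_tot)]),
                           np.array([float(n_nm - d_tot)]))[0]
        gain = parent - (nl / n_nm) * _entropy2(dl, nl - dl) \
            - (nr / n_nm) * _entropy2(dr, nr - dr)
        gain = gain * (n_nm / n)  # penalise attributes with missing values
        split_info = _entropy2(nl.astype(float), nr.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(split_info > 0, gain / np.maximum(split_info,
                                                               1e-300), 0.0)
        # child sizes after routing missing values to the majority branch
        nl_tot = np.where(nl >= nr, nl + n_missing, nl)
        nr_tot = np.where(nl >= nr, nr, nr + n_missing)
        valid = (gain > 1e-12) & (nl_tot >= min_leaf) & (nr_tot >= min_leaf)
        if not valid.any():
            continue
        ratio = np.where(valid, ratio, -np.inf)
        i = int(np.argmax(ratio))  # first max -> lowest threshold
        if best is None or ratio[i] > best[0] + 1e-12:
            best = (float(ratio[i]), j, float(thresholds[i]))
    if best is None:
        return None
    return best[1], best[2], best[0]


def _partition(col: np.ndarray, thr: float) -> tuple[np.ndarray, np.ndarray, bool]:
    left = col <= thr
    right = col > thr
    missing = ~(left | right)
    missing_left = int(left.sum()) >= int(right.sum())
    if missing_left:
        left = left | missing
    else:
        right = right | missing
    return left, right, missing_left


def _first_admissible_split(X: np.ndarray, min_leaf: int
                            ) -> tuple[int, float] | None:
    """Lowest-index, lowest-threshold split with two viable children."""
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = np.unique(col[~np.isnan(col)])
        for a, b in zip(finite[:-1], finite[1:]):
            thr = (a + b) / 2.0
            nl = int((col <= thr).sum())
            nr = int((col > thr).sum())
            n_missing = n - nl - nr
            if nl >= nr:
                nl += n_missing
            else:
                nr += n_missing
            if nl >= min_leaf and nr >= min_leaf:
                return j, float(thr)
    return None


def _grow(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str],
          bool_cols: Sequence[bool], min_leaf: int,
          exhaustive: bool = False) -> _Node:
    node = _Node(n=len(y), n_damaging=int(y.sum()))
    if node.n_damaging in (0, node.n) or node.n < 2 * min_leaf:
        return node
    choice = _best_split(X, y, feature_names, min_leaf)
    if choice is None:
        if not exhaustive:
            return node
        # pruning-off mode keeps separating even through zero-gain splits
        # (e.g. the XOR of two flags, where every single split is
        # uninformative but the pair is decisive)
        rescue = _first_admissible_split(X, min_leaf)
        if rescue is None:
            return node
        j, thr = rescue
    else:
        j, thr, _ = choice
    left_mask, right_mask, missing_left = _partition(X[:, j], thr)
    if not left_mask.any() or not right_mask.any():  # pragma: no cover
        return node
    node.feature = feature_names[j]
    node.threshold = thr
    node.is_bool = bool_cols[j]
    node.missing_left = missing_left
    node.left = _grow(X[left_mask], y[left_mask], feature_names, bool_cols,
                      min_leaf, exhaustive)
    node.right = _grow(X[right_mask], y[right_mask], feature_names,
                       bool_cols, min_leaf, exhaustive)
    return node


def _added_errors(n: int, errors: int, cf: float) -> float:
    """Extra errors predicted by the pessimistic (upper-confidence-bound)
    estimate, following the classic C4.5 error-based pruning estimate."""
    if n == 0:
        return 0.0
    if errors == 0:
        return n * (1.0 - cf ** (1.0 / n))
    if errors < 1:
        base = n * (1.0 - cf ** (1.0 / n))
        return base + errors * (_added_errors(n, 1.0, cf) - base)
    z = float(norm.ppf(1.0 - cf))
    if errors + 0.5 >= n:
        return max(n - errors, 0.0)
    f = (errors + 0.5) / n
    r = (f + z * z / (2 * n)
         + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) \
        / (1 + z * z / n)
    return r * n - errors


def _estimated_errors(node: _Node, cf: float) -> float:
    if node.is_leaf:
        return node.errors + _added_errors(node.n, node.errors, cf)
    assert node.left is not None and node.right is not None
    return _estimated_errors(node.left, cf) + _estimated_errors(node.right, cf)


def _training_errors(node: _Node) -> int:
    if node.is_leaf:
        return node.errors
    return _training_errors(node.left) + _training_errors(node.right)


def _collapse(node: _Node) -> None:
    """Replace a subtree whose splits do not reduce training error."""
    if node.is_leaf:
        return
    if _training_errors(node) >= node.errors:
        node.feature = None
        node.threshold = None
        node.left = node.right = None
        return
    _collapse(node.left)
    _collapse(node.right)


def _prune(node: _Node, cf: float) -> None:
    if node.is_leaf:
        return
    assert node.left is not None and node.right is not None
    _prune(node.left, cf)
    _prune(node.right, cf)
    leaf_est = node.errors + _added_errors(node.n, node.errors, cf)
    subtree_est = _estimated_errors(node.left, cf) + \
        _estimated_errors(node.right, cf)
    if leaf_est <= subtree_est + 0.1:
        node.feature = None
        node.threshold = None
        node.left = node.right = None


@dataclass
class DecisionTree:
    """A trained binary decision tree over a fixed feature schema."""

    root: _Node
    feature_names: tuple[str, ...]
    bool_features: frozenset[str]
    params: TrainParams
    n_training: int

    # -- prediction --------------------------------------------------------

    def _leaf_for(self, values: Mapping[str, float]) -> tuple[_Node, list[str]]:
        node = self.root
        path = []
        while not node.is_leaf:
            x = values.get(node.feature, math.nan)
            if isinstance(x, float) and math.isnan(x):
                go_left = node.missing_left
            else:
                go_left = x <= node.threshold
            path.append("L" if go_left else "R")
            node = node.left if go_left else node.right
        return node, path

    def predict(self, fv) -> Prediction:
        values = fv.values if isinstance(fv, FeatureVector) else fv
        leaf, path = self._leaf_for(values)
        conf = (leaf.correct / leaf.n) if leaf.n else 0.5
        label = leaf.label
        score = (leaf.n_damaging / leaf.n) if leaf.n else 0.5
        return Prediction(label=label, confidence=round(conf, 3),
                          rule_id="path-" + ("".join(path) or "root"),
                          score=score)

    def predict_frame(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Labels and damaging-fraction scores for a feature matrix."""
        labels = np.empty(len(X), dtype=object)
        scores = np.empty(len(X), dtype=float)
        for i, (_, row) in enumerate(X.iterrows()):
            pred = self.predict(row.to_dict())
            labels[i] = pred.label
            scores[i] = pred.score
        return labels, scores

    def training_accuracy(self) -> float:
        correct = sum(leaf.correct for leaf in self._leaves())
        return correct / self.n_training

    def _leaves(self) -> list[_Node]:
        out = []

        def walk(node: _Node):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)
        walk(self.root)
        return out

    def n_leaves(self) -> int:
        return len(self._leaves())

    def depth(self) -> int:
        def walk(node: _Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(walk(node.left), walk(node.right))
        return walk(self.root)

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        lines = [
            f"# indeltree decision tree n={self.n_training} "
            f"cf={self.params.pruning_confidence} "
            f"min_leaf={self.params.min_leaf}",
            "# features=" + ",".join(self.feature_names),
            "# bool_features=" + ",".join(sorted(self.bool_features)),
        ]

        def walk(node: _Node, depth: int):
            pad = "  " * depth
            if node.is_leaf:
                lines.append(f"{pad}leaf {node.label} n={node.n} "
                             f"d={node.n_damaging}")
            else:
                miss = "left" if node.missing_left else "right"
                lines.append(
                    f"{pad}split {node.feature} <= {node.threshold!r} "
                    f"n={node.n} d={node.n_damaging} missing={miss}")
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)
        walk(self.root, 0)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "DecisionTree":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        meta = {}
        body = []
        for ln in lines:
            if ln.startswith("#"):
                if "features=" in ln and "bool_features=" not in ln:
                    meta["features"] = ln.split("features=", 1)[1]
                elif "bool_features=" in ln:
                    meta["bool"] = ln.split("bool_features=", 1)[1]
                else:
                    meta["header"] = ln
            else:
                body.append(ln)

        def parse(idx: int, depth: int) -> tuple[_Node, int]:
            ln = body[idx]
            indent = (len(ln) - len(ln.lstrip())) // 2
            if indent != depth:
                raise RuleFileError("malformed tree text (bad indentation)")
            tokens = ln.split()
            if tokens[0] == "leaf":
                n = int(tokens[2].split("=")[1])
                d = int(tokens[3].split("=")[1])
                return _Node(n=n, n_damaging=d), idx + 1
            feature = tokens[1]
            thr = float(tokens[3])
            n = int(tokens[4].split("=")[1])
            d = int(tokens[5].split("=")[1])
            miss = tokens[6].split("=")[1] == "left"
            left, nxt = parse(idx + 1, depth + 1)
            right, nxt = parse(nxt, depth + 1)
            node = _Node(n=n, n_damaging=d, feature=feature, threshold=thr,
                         missing_left=miss, left=left, right=right)
            return node, nxt

        root, _ = parse(0, 0)
        features = tuple(meta.get("features", "").split(",")) if \
            meta.get("features") else ()
        bools = frozenset(b for b in meta.get("bool", "").split(",") if b)
        header = meta.get("header", "")
        cf, ml = 0.25, 2
        for tok in header.split():
            if tok.startswith("cf="):
                cf = float(tok[3:])
            elif tok.startswith("min_leaf="):
                ml = int(tok[9:])

        def mark_bools(node: _Node):
            if not node.is_leaf:
                node.is_bool = node.feature in bools
                mark_bools(node.left)
                mark_bools(node.right)
        mark_bools(root)
        return cls(root=root, feature_names=features, bool_features=bools,
                   params=TrainParams(pruning_confidence=cf, min_leaf=ml),
                   n_training=root.n)


def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "biu":
        return arr.astype(int)
    if arr.dtype.kind == "f":
        return arr.astype(int)
    mapped = np.where(arr == DAMAGING, 1, 0)
    bad = ~np.isin(arr, [DAMAGING, NEUTRAL])
    if bad.any():
        raise ValueError(f"unknown labels: {set(arr[bad])}")
    return mapped.astype(int)


def train_tree(features: pd.DataFrame, labels,
               params: TrainParams | None = None) -> DecisionTree:
    """Induce a C4.5-style decision tree from a labeled feature matrix.

    Deterministic given the parameters and input order.  A single-class
    input degenerates to a one-leaf tree with a warning.
    """
    params = params or TrainParams()
    y = _as_binary_labels(labels)
    if len(y) != len(features):
        raise ValueError("features and labels disagree in length")
    if len(y) == 0:
        raise ValueError("empty training set")
    X = features.to_numpy(dtype=float)
    names = tuple(features.columns)
    bool_cols = [set(np.unique(X[~np.isnan(X[:, j]), j])) <= {0.0, 1.0}
                 for j in range(X.shape[1])]
    if y.min() == y.max():
        warnings.warn("single-class training input; returning a degenerate "
                      "single-leaf tree", stacklevel=2)
        root = _Node(n=len(y), n_damaging=int(y.sum()))
    else:
        root = _grow(X, y, names, bool_cols, params.min_leaf,
                     exhaustive=not params.prune)
        if params.prune:
            _collapse(root)
            _prune(root, params.pruning_confidence)
    return DecisionTree(root=root, feature_names=names,
                        bool_features=frozenset(
                            n for n, b in zip(names, bool_cols) if b),
                        params=params, n_training=len(y))


def extract_rules(tree: DecisionTree) -> list[DecisionRule]:
    """One rule per root-to-leaf path (left/false branch first); supports
    sum to the training-set size."""
    rules: list[DecisionRule] = []

    def walk(node: _Node, conditions: tuple[Condition, ...]):
        if node.is_leaf:
            support = node.n
            correct = node.correct
            conf = round(correct / support, 3) if support else 0.5
            rules.append(DecisionRule(
                rule_id=f"rule{len(rules) + 1}", conditions=conditions,
                predicted_class=node.label, support=support, correct=correct,
                confidence=conf))
            return
        if node.is_bool:
            c_left = Condition(node.feature, "is", 0.0)
            c_right = Condition(node.feature, "is", 1.0)
        else:
            c_left = Condition(node.feature, "<=", node.threshold)
            c_right = Condition(node.feature, ">", node.threshold)
        walk(node.left, conditions + (c_left,))
        walk(node.right, conditions + (c_right,))

    walk(tree.root, ())
    return rules


def apply_rules_sequentially(rules: Sequence[DecisionRule],
                             values: Mapping[str, float]) -> str:
    """First-match label over an extracted rule list (used to verify that
    rule application reproduces tree prediction exactly)."""
    for rule in rules:
        if rule.matches(values):
            return rule.predicted_class
    raise ValueError("no rule matched; extracted rules should partition "
                     "the feature space")
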