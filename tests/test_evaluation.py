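"""Metrics, ROC/AUC, cross-validation, resampling and feature selection."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from indeltree import (Confusion, DAMAGING, NEUTRAL, TrainParams,
                       balanced_resampling, confusion_from_labels,
                       greedy_feature_selection, kfold_cv, metrics, roc_auc,
                       train_tree)


# --------------------------------------------------------------------------
# Confusion metrics
# --------------------------------------------------------------------------

class TestMetrics:
    def test_balanced_dataset_confusion_reproduces_printed_numbers(self):
        # Combined balanced-dataset counts: 386/474 damaging and 387/474
        # neutral correct -> 81/82/82/82 % and MCC 0.63
        rep = metrics(Confusion(tp=386, fn=88, tn=387, fp=87))
        shown = rep.display()
        assert (shown["sensitivity_pct"], shown["specificity_pct"],
                shown["precision_pct"], shown["accuracy_pct"]) == \
            (81, 82, 82, 82)
        assert shown["mcc"] == 0.63

    def test_complete_dataset_precision_and_accuracy(self):
        rep = metrics(Confusion(tp=1411, fn=398, tn=7978, fp=1732))
        shown = rep.display()
        assert shown["precision_pct"] == 45
        assert shown["accuracy_pct"] == 82

    def test_perfect_confusion_gives_ones(self):
        rep = metrics(Confusion(tp=10, tn=10))
        assert (rep.sensitivity, rep.specificity, rep.precision,
                rep.accuracy, rep.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_mcc_missing_when_a_marginal_is_zero(self):
        rep = metrics(Confusion(tp=0, fn=0, tn=5, fp=5))
        assert rep.mcc is None

    def test_empty_confusion_is_an_error(self):
        with pytest.raises(ValueError):
            metrics(Confusion())

    def test_exact_arithmetic_against_fraction_oracle(self, rng):
        """10,000 random confusions: every metric equals its formula
        evaluated in exact rational arithmetic."""
        counts = rng.integers(0, 400, size=(10000, 4))
        for tp, tn, fp, fn in counts:
            c = Confusion(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
            if c.n == 0:
                continue
            rep = metrics(c)
            if tp + fn:
                assert rep.sensitivity == Fraction(int(tp), int(tp + fn))
            if tn + fp:
                assert rep.specificity == Fraction(int(tn), int(tn + fp))
            if tp + fp:
                assert rep.precision == Fraction(int(tp), int(tp + fp))
            assert rep.accuracy == Fraction(int(tp + tn), c.n)
            marg = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
            if marg == 0:
                assert rep.mcc is None
            else:
                want = (int(tp) * int(tn) - int(fp) * int(fn)) \
                    / math.sqrt(float(marg))
                assert rep.mcc == pytest.approx(want, abs=1e-12)
                assert -1.0 - 1e-12 <= rep.mcc <= 1.0 + 1e-12


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

def _oracle_auc(scores, labels):
    """Pairwise-comparison (Mann-Whitney) statistic, O(n^2)."""
    pos = [s for s, l in zip(scores, labels) if l == DAMAGING]
    neg = [s for s, l in zip(scores, labels) if l == NEUTRAL]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        labels = [NEUTRAL] * 5 + [DAMAGING] * 5
        assert roc_auc(list(range(10)), labels) == 1.0

    def test_random_scores_are_near_half(self, rng):
        labels = np.where(rng.random(10000) < 0.5, DAMAGING, NEUTRAL)
        scores = rng.random(10000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_ties_match_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)
            labels = np.where(rng.random(n) < 0.5, DAMAGING, NEUTRAL)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == \
                pytest.approx(_oracle_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score
        n = 500
        scores = rng.normal(size=n)
        labels = np.where(rng.random(n) < 0.4, DAMAGING, NEUTRAL)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels == DAMAGING, scores), abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [DAMAGING] * 3)


# --------------------------------------------------------------------------
# k-fold CV
# --------------------------------------------------------------------------

def _planted_frame(rng, n, noise=0.0):
    """Feature-level planted dataset: label is a deterministic function of
    three features, optionally flipped at the noise rate.  Conservation
    values keep a margin around the 1.4 boundary so data-driven split
    thresholds generalise exactly."""
    raw = rng.normal(1.4, 0.8, n)
    cons = np.where(raw > 1.4, np.maximum(raw, 1.6), np.minimum(raw, 1.2))
    X = pd.DataFrame({
        "pfam": rng.choice([0.0, 0.5], n, p=[0.75, 0.25]),
        "repeat": rng.integers(0, 2, n).astype(float),
        "cons": cons.round(3),
    })
    y = np.where((X["pfam"] > 0) | ((X["repeat"] > 0) & (X["cons"] > 1.4)),
                 DAMAGING, NEUTRAL)
    flip = rng.random(n) < noise
    y = np.where(flip, np.where(y == DAMAGING, NEUTRAL, DAMAGING), y)
    return X, y


def planted_decision_list(rng, n, n_noise=4):
    """Decision-list dataset with four informative flags of strictly
    decreasing marginal value plus uninformative flags: damaging if s0,
    else neutral if s1, else damaging if s2, else neutral if s3, else
    damaging.  Unequal flag rates keep every greedy step a strict
    improvement."""
    s = {f"s{i}": (rng.random(n) < p).astype(float)
         for i, p in enumerate([0.5, 0.5, 0.6, 0.7])}
    z = {f"z{i}": rng.integers(0, 2, n).astype(float)
         for i in range(n_noise)}
    X = pd.DataFrame({**s, **z})
    y = np.select(
        [X["s0"] > 0, X["s1"] > 0, X["s2"] > 0, X["s3"] > 0],
        [DAMAGING, NEUTRAL, DAMAGING, NEUTRAL], default=DAMAGING)
    return X, y, tuple(s)


class TestKFoldCV:
    def test_leave_one_out_pools_all_samples(self):
        X = pd.DataFrame({"x": [0.0, 0.1, 0.9, 1.0]})
        y = [NEUTRAL, NEUTRAL, DAMAGING, DAMAGING]
        rep = kfold_cv(X, y, k=4, seed=3)
        assert rep.confusion.n == 4

    def test_pooled_counts_conserve_n(self, rng):
        X, y = _planted_frame(rng, 160, noise=0.2)
        rep = kfold_cv(X, y, k=10, seed=5)
        assert rep.confusion.n == 160

    def test_planted_noise_free_data_cross_validates_perfectly(self, rng):
        X, y = _planted_frame(rng, 400)
        trainer = lambda A, b: train_tree(
            A, b, TrainParams(prune=False, min_leaf=1))
        rep = kfold_cv(X, y, k=10, seed=5, trainer=trainer)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0

    def test_stratified_reporting_partitions_the_confusion(self, rng):
        X, y = _planted_frame(rng, 300, noise=0.15)
        kinds = rng.choice(["insertion", "deletion"], size=300)
        rep = kfold_cv(X, y, k=10, seed=5, strata=kinds)
        ins, dele = rep.strata["insertion"], rep.strata["deletion"]
        for field in ("tp", "tn", "fp", "fn"):
            assert getattr(ins.confusion, field) \
                + getattr(dele.confusion, field) \
                == getattr(rep.confusion, field)

    def test_both_classes_required(self):
        X = pd.DataFrame({"x": range(12)})
        with pytest.raises(ValueError):
            kfold_cv(X, [DAMAGING] * 12, k=3)


# --------------------------------------------------------------------------
# Balanced resampling
# --------------------------------------------------------------------------

class TestBalancedResampling:
    def test_single_repetition_has_no_sd(self, rng):
        X, y = _planted_frame(rng, 120, noise=0.1)
        disease, pool = X[y == DAMAGING], X[y == NEUTRAL]
        rep = balanced_resampling(disease, pool, reps=1, k=5, seed=0)
        assert rep.sd is None
        assert rep.mean["accuracy"] is not None

    def test_identical_sets_every_rep_give_zero_spread(self, rng):
        X, y = _planted_frame(rng, 140, noise=0.1)
        disease, pool = X[y == DAMAGING], X[y == NEUTRAL]
        pool = pool.iloc[:len(disease)]  # pool == sample every repetition
        rep = balanced_resampling(disease, pool, reps=6, k=5, seed=0)
        # fold assignment still varies with the per-rep seed, so compare
        # the sampled composition instead: every rep saw the same rows
        assert rep.reps == 6
        assert all(r.confusion.n == 2 * len(disease) for r in rep.per_rep)

    def test_accuracy_spread_is_bounded_by_binomial_noise(self, rng):
        X, y = _planted_frame(rng, 700, noise=0.1)
        disease, pool = X[y == DAMAGING], X[y == NEUTRAL]
        rep = balanced_resampling(disease, pool, reps=25, k=10, seed=1)
        assert rep.sd["accuracy"] <= 0.05

    def test_pool_smaller_than_disease_set_is_an_error(self, rng):
        X, y = _planted_frame(rng, 100, noise=0.1)
        disease, pool = X[y == DAMAGING], X[y == NEUTRAL]
        with pytest.raises(ValueError):
            balanced_resampling(pool, disease.iloc[:3], reps=2)


# --------------------------------------------------------------------------
# Greedy forward selection
# --------------------------------------------------------------------------

class TestGreedySelection:
    def test_single_perfect_feature_is_selected_alone(self, rng):
        n = 200
        X = pd.DataFrame({
            "noise1": rng.normal(size=n),
            "signal": rng.integers(0, 2, n).astype(float),
            "noise2": rng.normal(size=n),
        })
        y = np.where(X["signal"] > 0.5, DAMAGING, NEUTRAL)
        result = greedy_feature_selection(X, y, k=5, seed=2)
        assert result.selected == ("signal",)
        assert result.trace[0][1] == pytest.approx(1.0)

    def test_all_noise_candidates_stop_near_zero_mcc(self, rng):
        n = 400
        X = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(5)})
        y = np.where(rng.random(n) < 0.5, DAMAGING, NEUTRAL)
        result = greedy_feature_selection(X, y, k=5, seed=2)
        assert len(result.selected) <= 2
        assert all(abs(m) < 0.2 for _, m in result.trace)

    def test_recovers_planted_informative_features(self, rng):
        # four planted decision-list features among four noise flags; the
        # exhaustive-subset oracle lives in the acceptance suite
        X, y, planted = planted_decision_list(rng, 400)
        result = greedy_feature_selection(X, y, k=10, seed=4)
        assert set(result.selected) == set(planted)
        mccs = [m for _, m in result.trace]
        assert mccs == sorted(mccs)  # strictly improving trace
        assert mccs[-1] == pytest.approx(1.0)
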