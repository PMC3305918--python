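"""Two-class LDA, subject-wise cross-validation and exhaustive subset search.

The decision rule convention throughout is

    score = intercept + sum(weight_i * feature_i);  score > 0  =>  stress

with the boundary placed at the midpoint of the class means under equal
priors (the cohort is balanced by construction: one rest and one stress
record per subject).  Cross-validation folds partition *subjects*, never
records, so both sessions of a subject always share a fold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PairingError, ValidationError
from .features import FEATURE_NAMES

STRESS, REST = "stress", "rest"

#: ridge added to a singular pooled covariance diagonal
SINGULAR_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

class PairedDataset:
    """Per-subject (rest, stress) feature vectors backed by a DataFrame.

    The frame must carry ``subject_id`` and ``session`` columns plus one
    column per feature; every subject must contribute exactly one record
    per session.
    """

    def __init__(self, frame: pd.DataFrame,
                 feature_names: list[str] | None = None):
        required = {"subject_id", "session"}
        if not required.issubset(frame.columns):
            raise ValidationError("frame needs subject_id and session columns")
        self.feature_names = feature_names or [
            c for c in FEATURE_NAMES if c in frame.columns]
        if not self.feature_names:
            raise ValidationError("no feature columns found")
        bad_sessions = set(frame["session"]) - {REST, STRESS}
        if bad_sessions:
            raise ValidationError(f"unknown sessions: {sorted(bad_sessions)}")
        counts = frame.groupby(["subject_id", "session"]).size()
        incomplete = []
        for sid in frame["subject_id"].unique():
            for sess in (REST, STRESS):
                if counts.get((sid, sess), 0) != 1:
                    incomplete.append(str(sid))
                    break
        if incomplete:
            raise PairingError(
                "subjects without exactly one record per session: "
                + ", ".join(sorted(incomplete)))
        self.subject_ids = list(dict.fromkeys(frame["subject_id"]))
        if len(self.subject_ids) < 2:
            raise ValidationError("a paired dataset needs >= 2 subjects")
        self.frame = frame.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def matrix(self, subset: list[str] | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, subjects): y is True for stress records."""
        subset = list(subset) if subset is not None else self.feature_names
        missing = [f for f in subset if f not in self.frame.columns]
        if missing:
            raise ValidationError(f"unknown features: {missing}")
        x = self.frame[subset].to_numpy(dtype=float)
        y = (self.frame["session"] == STRESS).to_numpy()
        subjects = self.frame["subject_id"].to_numpy()
        return x, y, subjects

    def differences(self, feature: str) -> np.ndarray:
        """Stress-minus-rest values of one feature, in subject order."""
        if feature not in self.frame.columns:
            raise ValidationError(f"unknown feature {feature!r}")
        pivot = self.frame.pivot(index="subject_id", columns="session",
                                 values=feature)
        pivot = pivot.loc[self.subject_ids]
        return (pivot[STRESS] - pivot[REST]).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearRule:
    """An LDA decision rule; score > 0 classifies the record as stress."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    regularized: bool = False

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"rule expects {len(self.feature_names)} features, "
                f"got {x.shape[1]}")
        return self.intercept + x @ self.weights

    def threshold_form(self) -> tuple[float, str]:
        """Single-feature rule as (threshold, direction).

        direction '<' means "stress if feature < threshold".
        """
        if len(self.feature_names) != 1:
            raise ValidationError("threshold form requires a 1-feature rule")
        w = float(self.weights[0])
        if w == 0:
            raise ValidationError("degenerate rule: zero weight")
        return -self.intercept / w, ("<" if w < 0 else ">")

    def text(self) -> str:
        if len(self.feature_names) == 1:
            t, direction = self.threshold_form()
            return f"{self.feature_names[0]} {direction} {t:.6g}"
        terms = " ".join(
            f"{w:+.6g}*{name}" for name, w in zip(self.feature_names,
                                                  self.weights))
        return f"{self.intercept:.6g} {terms} > 0"


def train_lda(features: np.ndarray, labels: np.ndarray,
              feature_names: list[str] | None = None) -> LinearRule:
    """Fisher LDA with equal priors and the midpoint intercept.

    weights = pooled-within-class-covariance^-1 (mean_stress - mean_rest);
    the boundary passes through the midpoint of the two class means.  A
    singular pooled covariance falls back to a small diagonal ridge with a
    warning.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    if y.dtype != bool:
        y = np.asarray([str(v) == STRESS for v in y])
    if len(x) != len(y):
        raise ValidationError("features and labels length mismatch")
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    n, p = x.shape
    mu_stress = x[y].mean(axis=0)
    mu_rest = x[~y].mean(axis=0)
    centered_s = x[y] - mu_stress
    centered_r = x[~y] - mu_rest
    pooled = (centered_s.T @ centered_s + centered_r.T @ centered_r) / (n - 2)
    delta = mu_stress - mu_rest
    regularized = False
    if np.linalg.matrix_rank(pooled) < p:
        warnings.warn("singular pooled covariance; applying diagonal ridge",
                      stacklevel=2)
        pooled = pooled + SINGULAR_RIDGE * np.eye(p)
        regularized = True
    weights = np.linalg.solve(pooled, delta)
    intercept = -float(weights @ (mu_stress + mu_rest) / 2.0)
    names = tuple(feature_names) if feature_names else tuple(
        f"x{i}" for i in range(p))
    return LinearRule(names, weights, intercept, regularized)


def predict(rule: LinearRule, x: np.ndarray) -> np.ndarray:
    """Boolean stress predictions; a score of exactly 0 classifies as rest."""
    return rule.score(x) > 0


# ---------------------------------------------------------------------------
# Performance measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the five binary performance measures.

    PPV (no predicted positives) or NPV (no predicted negatives) that are
    undefined are reported as NaN with the flag recorded in ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def performance(labels: np.ndarray, predictions: np.ndarray) -> Metrics:
    """ACC/SEN/SPE/PPV/NPV with stress as the positive class."""
    y = np.asarray(labels, dtype=bool)
    yhat = np.asarray(predictions, dtype=bool)
    if len(y) != len(yhat):
        raise ValidationError("labels and predictions length mismatch")
    if len(y) == 0:
        raise ValidationError("performance: empty input")
    tp = int(np.count_nonzero(y & yhat))
    tn = int(np.count_nonzero(~y & ~yhat))
    fp = int(np.count_nonzero(~y & yhat))
    fn = int(np.count_nonzero(y & ~yhat))
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (tp + tn) / len(y)
    sen = _ratio(tp, tp + fn, "SEN")
    spe = _ratio(tn, tn + fp, "SPE")
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, tn + fn, "NPV")
    return Metrics(tp, tn, fp, fn, acc, sen, spe, ppv, npv, tuple(undefined))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_subject_folds(dataset: PairedDataset, k: int = 10,
                       seed: int = 0) -> list[list]:
    """Random subject partition into k folds whose sizes differ by <= 1.

    Both records of a subject always land in the same fold; the assignment
    is deterministic for a fixed seed.
    """
    subjects = list(dataset.subject_ids)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(subjects):
        raise ValidationError(
            f"k = {k} folds exceed the {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    return [list(chunk) for chunk in np.array_split(shuffled, k)]


@dataclass(frozen=True)
class CVReport:
    """Per-fold metrics and their unweighted means for one feature subset."""

    subset: tuple[str, ...]
    folds: tuple[Metrics, ...]
    acc: float
    sen: float
    spe: float
    ppv: float
    npv: float
    #: folds excluded from the PPV / NPV averages because undefined there
    excluded: dict = field(default_factory=dict, compare=False)


def _nan_mean(values: list[float]) -> tuple[float, int]:
    arr = np.asarray(values, dtype=float)
    good = arr[~np.isnan(arr)]
    if good.size == 0:
        return float("nan"), int(arr.size)
    return float(good.mean()), int(np.isnan(arr).sum())


def cross_validate(dataset: PairedDataset, subset: list[str],
                   folds: list[list]) -> CVReport:
    """Leave-one-fold-out evaluation of an LDA on the chosen subset."""
    subset = list(subset)
    if not subset:
        raise ValidationError("feature subset must be non-empty")
    x, y, subjects = dataset.matrix(subset)
    fold_metrics: list[Metrics] = []
    for fold in folds:
        test_mask = np.isin(subjects, list(fold))
        if not test_mask.any():
            raise ValidationError("empty fold")
        rule = train_lda(x[~test_mask], y[~test_mask], subset)
        fold_metrics.append(performance(y[test_mask],
                                        predict(rule, x[test_mask])))
    acc, _ = _nan_mean([m.acc for m in fold_metrics])
    sen, _ = _nan_mean([m.sen for m in fold_metrics])
    spe, _ = _nan_mean([m.spe for m in fold_metrics])
    ppv, ppv_skipped = _nan_mean([m.ppv for m in fold_metrics])
    npv, npv_skipped = _nan_mean([m.npv for m in fold_metrics])
    return CVReport(tuple(subset), tuple(fold_metrics), acc, sen, spe, ppv,
                    npv, excluded={"PPV": ppv_skipped, "NPV": npv_skipped})


# ---------------------------------------------------------------------------
# Exhaustive subset search
# ---------------------------------------------------------------------------

def enumerate_subsets(feature_names: list[str] | None = None):
    """Yield every subset of the feature set, the empty subset included."""
    names = list(feature_names) if feature_names is not None else list(
        FEATURE_NAMES)
    for size in range(len(names) + 1):
        yield from itertools.combinations(names, size)


def exhaustive_search(dataset: PairedDataset, folds: list[list],
                      feature_names: list[str] | None = None
                      ) -> tuple[list[tuple[tuple[str, ...], CVReport]], int]:
    """Cross-validate every non-empty feature subset with shared folds.

    Returns ``(ranking, n_enumerated)``: the ranking covers the
    2^p - 1 non-empty subsets ordered by averaged ACC, ties broken by
    fewer features, then higher SEN, then lexicographic subset order;
    ``n_enumerated`` counts all 2^p subsets including the empty one, which
    is enumerated but not assigned a classifier.
    """
    names = list(feature_names) if feature_names is not None else list(
        dataset.feature_names)
    index = {name: i for i, name in enumerate(names)}
    x, y, subjects = dataset.matrix(names)
    n = len(y)

    # per-fold sufficient statistics over the full feature set; each subset
    # then just slices the pooled scatter and class means
    fold_stats = []
    for fold in folds:
        test_mask = np.isin(subjects, list(fold))
        xt, yt = x[~test_mask], y[~test_mask]
        if yt.all() or not yt.any():
            raise ValidationError("single-class training partition")
        mu_s = xt[yt].mean(axis=0)
        mu_r = xt[~yt].mean(axis=0)
        cs = xt[yt] - mu_s
        cr = xt[~yt] - mu_r
        pooled = (cs.T @ cs + cr.T @ cr) / (len(yt) - 2)
        fold_stats.append((test_mask, mu_s, mu_r, pooled))

    results = []
    n_enumerated = 0
    for subset in enumerate_subsets(names):
        n_enumerated += 1
        if not subset:
            continue
        idx = np.array([index[f] for f in subset])
        fold_metrics = []
        for test_mask, mu_s, mu_r, pooled in fold_stats:
            sub_cov = pooled[np.ix_(idx, idx)]
            delta = (mu_s - mu_r)[idx]
            if np.linalg.matrix_rank(sub_cov) < len(idx):
                sub_cov = sub_cov + SINGULAR_RIDGE * np.eye(len(idx))
            w = np.linalg.solve(sub_cov, delta)
            b = -float(w @ (mu_s[idx] + mu_r[idx]) / 2.0)
            scores = b + x[np.ix_(test_mask, idx)] @ w
            fold_metrics.append(performance(y[test_mask], scores > 0))
        acc, _ = _nan_mean([m.acc for m in fold_metrics])
        sen, _ = _nan_mean([m.sen for m in fold_metrics])
        spe, _ = _nan_mean([m.spe for m in fold_metrics])
        ppv, ppv_sk = _nan_mean([m.ppv for m in fold_metrics])
        npv, npv_sk = _nan_mean([m.npv for m in fold_metrics])
        report = CVReport(subset, tuple(fold_metrics), acc, sen, spe, ppv,
                          npv, excluded={"PPV": ppv_sk, "NPV": npv_sk})
        results.append((subset, report))

    order_index = {name: i for i, name in enumerate(names)}
    results.sort(key=lambda item: (
        -item[1].acc,
        len(item[0]),
        -(item[1].sen if not np.isnan(item[1].sen) else -np.inf),
        tuple(order_index[f] for f in item[0]),
    ))
    return results, n_enumerated


def final_rule(dataset: PairedDataset, subset: list[str]) -> LinearRule:
    """Refit the LDA on every record for the chosen subset."""
    subset = list(subset)
    if not subset:
        raise ValidationError("feature subset must be non-empty")
    x, y, _ = dataset.matrix(subset)
    return train_lda(x, y, subset)
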