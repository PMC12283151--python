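"""Class-balanced bootstrap ensemble of L1 (LASSO) multinomial classifiers.

Predicts a song's behavioral context from its acoustic features.  Because
contexts have unequal base rates in real corpora, a single penalized model
tends to collapse onto the prevalent classes; instead we fit many models on
class-balanced bootstrap resamples and aggregate by modal vote:

  1. split the songs into k disjoint test partitions (default 10);
  2. for each test partition, draw ``n_boot_per_partition`` (default 10)
     balanced bootstraps from the remaining partitions — sampling with
     replacement within each context so every context contributes the same
     number of draws — and fit one L1-penalized multinomial logistic model
     per bootstrap, recording its prediction for every test song;
  3. repeat for ``n_splits`` (default 25) independent random splits, so that
     every song accrues exactly n_splits x n_boot votes (default 250);
  4. the final label is the per-song modal vote.

Chance accuracy is 1/|contexts| (never the empirical base rate), and
significance comes from a permutation test: labels are shuffled, the whole
ensemble re-run, and the p-value is the proportion of permutations with
accuracy higher than observed.  Per-class sensitivity is summarized by the
confusion matrix and signal-detection d-prime.

Feature standardization and penalty selection use only the training
resample, never test rows.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn import config_context
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm._base import _fit_liblinear

from .corpus_io import CONTEXT_VOCABULARY, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "VoteMatrix",
    "ClassifierReport",
    "PermutationResult",
    "FittedClassifier",
    "make_splits",
    "balanced_bootstrap",
    "fit_l1_classifier",
    "run_fold",
    "run_ensemble",
    "modal_prediction",
    "evaluate",
    "permutation_test",
    "subset_to_contexts",
]

#: default penalty grid for cross-validated selection (inverse-penalty C)
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class EnsembleConfig:
    k_partitions: int = 10
    n_boot_per_partition: int = 10
    n_splits: int = 25
    contexts_included: tuple[str, ...] = CONTEXT_VOCABULARY
    balance_target: str = "max-class"       # or "min-class"
    penalty_selection: str = "cv5"          # or "fixed" / "fixed:<C>"
    seed: int = 0

    def __post_init__(self):
        if self.k_partitions < 2:
            raise ValueError("k_partitions must be >= 2")
        if self.balance_target not in ("max-class", "min-class"):
            raise ValueError(f"unknown balance_target {self.balance_target!r}")
        if len(self.contexts_included) < 2:
            raise ValueError("need at least 2 contexts")
        # canonical vocabulary order, regardless of the order given
        order = {c: i for i, c in enumerate(CONTEXT_VOCABULARY)}
        unknown = [c for c in self.contexts_included if c not in order]
        if unknown:
            raise ValueError(f"contexts not in vocabulary: {unknown}")
        self.contexts_included = tuple(
            sorted(set(self.contexts_included), key=order.__getitem__)
        )

    @property
    def votes_per_song(self) -> int:
        return self.n_splits * self.n_boot_per_partition

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.contexts_included)


@dataclass
class VoteMatrix:
    """Per-song ensemble vote counts over contexts (canonical order)."""

    song_ids: list
    contexts: tuple[str, ...]
    counts: np.ndarray  # songs x contexts, int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative vote count")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.contexts))
        df.insert(0, "song", self.song_ids)
        return df


@dataclass
class ClassifierReport:
    accuracy: float
    chance_level: float
    contexts: tuple[str, ...]
    confusion: pd.DataFrame            # row-normalized, true x predicted
    per_context_hit_rate: dict[str, float]
    per_context_false_alarm: dict[str, float]
    per_context_dprime: dict[str, float]
    n_per_context: dict[str, int]
    tie_fraction: float = 0.0


@dataclass
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_overall: float
    p_per_context: dict[str, float]
    n_perm: int
    n_ties: int                        # permutations exactly equal to observed
    rule: str = "strict"               # "strict" (proportion higher) | "add-one"


# ---------------------------------------------------------------------------
# Splitting and resampling
# ---------------------------------------------------------------------------

def make_splits(n_songs: int, k: int, n_splits: int, seed: int) -> list[list[np.ndarray]]:
    """n_splits independent random partitions of range(n_songs) into k
    disjoint folds with sizes differing by at most 1."""
    if k > n_songs:
        raise ValueError(f"k={k} exceeds number of songs {n_songs}")
    rng = np.random.default_rng(seed)
    schemes = []
    for _ in range(n_splits):
        perm = rng.permutation(n_songs)
        schemes.append([np.sort(fold) for fold in np.array_split(perm, k)])
    return schemes


def balanced_bootstrap(
    labels: np.ndarray,
    train_indices: np.ndarray,
    rng: np.random.Generator,
    rule: str = "max-class",
) -> np.ndarray:
    """Bootstrap *train_indices* with replacement, stratified so that every
    class contributes exactly m draws (m = largest or smallest training
    class size, by *rule*)."""
    labels = np.asarray(labels)
    train_indices = np.asarray(train_indices)
    classes, counts = np.unique(labels[train_indices], return_counts=True)
    present = set(np.unique(labels))
    missing = sorted(present - set(classes))
    if missing:
        raise ValueError(f"contexts with no training examples: {missing}")
    m = counts.max() if rule == "max-class" else counts.min()
    out = np.concatenate([
        rng.choice(train_indices[labels[train_indices] == c], size=m, replace=True)
        for c in classes
    ])
    return out


# ---------------------------------------------------------------------------
# Single-model fit
# ---------------------------------------------------------------------------

class FittedClassifier:
    """One L1 multinomial logistic fit, carrying its own training-set
    standardization so prediction never touches test statistics."""

    def __init__(self, model, mu, sd, classes):
        self._model = model
        self._mu = mu
        self._sd = sd
        self.classes_ = classes
        self.coef_ = model.coef_
        self.C_ = model.C

    def predict(self, X):
        X = (np.asarray(X, dtype=float) - self._mu) / self._sd
        # inputs were finiteness-checked at fit time; skip sklearn's re-check
        with config_context(assume_finite=True):
            return self._model.predict(X)


class _BinaryL1Classifier:
    """Binary L1 logistic fit calling sklearn's liblinear routine directly.

    Identical model and solver to ``LogisticRegression(l1_ratio=1,
    solver="liblinear")`` but skips the estimator wrapper's per-fit input
    re-validation, which dominates runtime for the thousands of small fits a
    permutation test performs.  Equivalence to the public estimator is
    asserted in the test suite.
    """

    def __init__(self, X, y, C, seed, tol=1e-3):
        self.classes_ = np.unique(y)
        y01 = (y == self.classes_[1]).astype(np.float64)
        self.coef_, self.intercept_, _ = _fit_liblinear(
            np.ascontiguousarray(X), y01, C=C, fit_intercept=True,
            intercept_scaling=1.0, class_weight=None, penalty="l1",
            dual=False, verbose=0, max_iter=100, tol=tol, random_state=seed,
        )
        self.C = C

    def predict(self, X):
        decision = X @ self.coef_.ravel() + self.intercept_[0]
        return np.where(decision > 0, self.classes_[1], self.classes_[0])


def _make_logreg(C: float, n_classes: int, seed: int) -> LogisticRegression:
    # liblinear solves the equivalent binary problem much faster; saga is the
    # multinomial (softmax) L1 solver
    if n_classes == 2:
        return LogisticRegression(
            l1_ratio=1, C=C, solver="liblinear", random_state=seed, tol=1e-4
        )
    return LogisticRegression(
        l1_ratio=1, C=C, solver="saga", random_state=seed,
        max_iter=500, tol=1e-3,
    )


def fit_l1_classifier(
    X: np.ndarray,
    y: np.ndarray,
    penalty_selection: str = "cv5",
    seed: int = 0,
) -> FittedClassifier:
    """Fit one L1-penalized multinomial logistic model.

    ``penalty_selection``: ``"cv5"`` picks the inverse-penalty C from
    DEFAULT_C_GRID by 5-fold cross-validated deviance on the training data;
    ``"fixed"`` / ``"fixed:<C>"`` uses a fixed C (default 1.0).
    Standardization statistics are computed here, from *X* only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    with warnings.catch_warnings(), config_context(assume_finite=True):
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalty_selection.startswith("fixed"):
            C = float(penalty_selection.split(":", 1)[1]) \
                if ":" in penalty_selection else 1.0
        elif penalty_selection == "cv5":
            C = _select_penalty_cv(Xs, y, seed)
        else:
            raise ValueError(f"unknown penalty_selection {penalty_selection!r}")
        if len(classes) == 2:
            model = _BinaryL1Classifier(Xs, y, C, seed)
        else:
            model = _make_logreg(C, len(classes), seed)
            model.fit(Xs, y)
    return FittedClassifier(model, mu, sd, classes)


def _select_penalty_cv(Xs, y, seed, grid=DEFAULT_C_GRID, n_folds=5):
    """5-fold CV deviance minimization over the penalty grid."""
    _, counts = np.unique(y, return_counts=True)
    n_folds = min(n_folds, counts.min())
    if n_folds < 2:
        return grid[len(grid) // 2]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    classes = np.unique(y)
    best_C, best_dev = grid[0], np.inf
    folds = list(skf.split(Xs, y))
    for C in grid:
        dev = 0.0
        try:
            for tr, va in folds:
                if len(np.unique(y[tr])) < 2:
                    raise ValueError
                m = _make_logreg(C, len(classes), seed)
                m.fit(Xs[tr], y[tr])
                prob = m.predict_proba(Xs[va])
                # align columns to the full class set
                full = np.full((len(va), len(classes)), 1e-12)
                for j, c in enumerate(m.classes_):
                    full[:, np.searchsorted(classes, c)] = prob[:, j]
                dev += log_loss(y[va], full, labels=classes, normalize=False)
        except ValueError:
            continue
        if dev < best_dev:
            best_C, best_dev = C, dev
    return best_C


def run_fold(
    X: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: EnsembleConfig,
    rng: np.random.Generator,
) -> tuple[FittedClassifier, np.ndarray]:
    """One balanced-bootstrap fit for one test partition: resample the
    training indices, fit, predict the test rows.  Everything learned
    (standardization, penalty, coefficients) depends only on training rows."""
    boot = balanced_bootstrap(labels, train_idx, rng, cfg.balance_target)
    fit_seed = int(rng.integers(2**31))
    t0 = time.perf_counter()
    clf = fit_l1_classifier(X[boot], labels[boot], cfg.penalty_selection,
                            seed=fit_seed)
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug("fit n=%d seed=%d C=%s time=%.4fs",
                     len(boot), fit_seed, clf.C_, time.perf_counter() - t0)
    return clf, clf.predict(X[test_idx])


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

def subset_to_contexts(features, labels, contexts):
    """Restrict a feature matrix/table + labels to songs of the given contexts."""
    labels = np.asarray(labels)
    keep = np.isin(labels, list(contexts))
    if isinstance(features, FeatureTable):
        X = features.values[keep]
        ids = [s for s, k in zip(features.song_ids, keep) if k]
    else:
        X = np.asarray(features, dtype=float)[keep]
        ids = list(np.flatnonzero(keep))
    return X, labels[keep], ids


def run_ensemble(features, labels, cfg: EnsembleConfig) -> VoteMatrix:
    """Run the full split/bootstrap/fit/vote procedure.

    Every song is in exactly one test partition per split, and receives one
    vote from each of the ``n_boot_per_partition`` classifiers fitted for
    that partition — so vote totals are exactly n_splits x n_boot for every
    song, whatever the class imbalance.
    """
    if isinstance(features, FeatureTable):
        X = features.values
        song_ids = features.song_ids
    else:
        X = np.asarray(features, dtype=float)
        song_ids = list(range(len(X)))
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels not aligned to features")
    extra = sorted(set(labels) - set(cfg.contexts_included))
    if extra:
        raise ValueError(
            f"labels outside contexts_included: {extra}; "
            "use subset_to_contexts first"
        )

    contexts = cfg.contexts_included
    ctx_col = {c: j for j, c in enumerate(contexts)}
    counts = np.zeros((len(X), len(contexts)), dtype=np.int32)

    rng = np.random.default_rng(cfg.seed)
    schemes = make_splits(len(X), cfg.k_partitions, cfg.n_splits,
                          seed=int(rng.integers(2**31)))
    t0 = time.perf_counter()
    n_fits = 0
    for folds in schemes:
        for p, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for q, f in enumerate(folds) if q != p])
            for _ in range(cfg.n_boot_per_partition):
                _, pred = run_fold(X, labels, train_idx, test_idx, cfg, rng)
                for i, c in zip(test_idx, pred):
                    counts[i, ctx_col[c]] += 1
                n_fits += 1
    logger.info(
        "run_ensemble n=%d fits=%d seed=%d time=%.2fs",
        len(X), n_fits, cfg.seed, time.perf_counter() - t0,
    )
    return VoteMatrix(song_ids, contexts, counts)


def modal_prediction(votes: VoteMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-song modal vote; ties go to the earlier context in canonical
    vocabulary order and are flagged.  Returns (labels, tie_mask)."""
    if np.any(votes.totals == 0):
        raise ValueError("every song needs at least one vote")
    # canonical order = vocabulary order, independent of column order
    order = np.argsort([CONTEXT_VOCABULARY.index(c) for c in votes.contexts])
    counts = votes.counts[:, order]
    contexts = np.array(votes.contexts)[order]
    best = counts.argmax(axis=1)
    ties = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return contexts[best], ties


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _corrected_rate(hits: int, n: int) -> float:
    """Rate with 0 and 1 replaced by 1/(2N) and 1 - 1/(2N) (so z is finite)."""
    if n == 0:
        return np.nan
    return min(max(hits / n, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))


def evaluate(predicted, true_labels, contexts) -> ClassifierReport:
    """Accuracy, row-normalized confusion, hit/false-alarm rates, d-prime.

    d'_c = z(H_c) - z(FA_c) against all other classes pooled, with the
    1/(2N) correction applied to extreme rates.  Chance is 1/|contexts|.
    """
    predicted = np.asarray(predicted)
    true_labels = np.asarray(true_labels)
    if len(predicted) != len(true_labels):
        raise ValueError("prediction/label length mismatch")
    contexts = tuple(contexts)

    accuracy = float(np.mean(predicted == true_labels))
    conf = np.full((len(contexts), len(contexts)), np.nan)
    hit, fa, dprime, n_per = {}, {}, {}, {}
    for i, c in enumerate(contexts):
        is_c = true_labels == c
        n_c = int(is_c.sum())
        n_per[c] = n_c
        if n_c:
            row = np.array([np.mean(predicted[is_c] == p) for p in contexts])
            conf[i] = row
        n_not = len(true_labels) - n_c
        h = _corrected_rate(int(np.sum(predicted[is_c] == c)), n_c)
        f = _corrected_rate(int(np.sum(predicted[~is_c] == c)), n_not)
        hit[c] = h
        fa[c] = f
        dprime[c] = float(norm.ppf(h) - norm.ppf(f)) \
            if not (np.isnan(h) or np.isnan(f)) else np.nan

    return ClassifierReport(
        accuracy=accuracy,
        chance_level=1.0 / len(contexts),
        contexts=contexts,
        confusion=pd.DataFrame(conf, index=list(contexts), columns=list(contexts)),
        per_context_hit_rate=hit,
        per_context_false_alarm=fa,
        per_context_dprime=dprime,
        n_per_context=n_per,
    )


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    features,
    labels,
    cfg: EnsembleConfig,
    n_perm: int = 200,
    seed: int = 0,
    rule: str = "strict",
) -> PermutationResult:
    """Ensemble accuracy against a label-permutation null.

    For each permutation the labels are shuffled uniformly and the *entire*
    ensemble re-run.  p_overall is the proportion of permutations with
    accuracy strictly higher than observed (``rule="strict"``, the literal
    definition); ``rule="add-one"`` uses (1 + #higher) / (1 + n_perm).
    Per-context p-values apply the same rule to per-context hit rates from
    the same permutations.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 to resolve alpha = 0.05")
    labels = np.asarray(labels)
    contexts = cfg.contexts_included

    votes = run_ensemble(features, labels, cfg)
    pred, _ = modal_prediction(votes)
    report = evaluate(pred, labels, contexts)
    obs_acc = report.accuracy
    obs_hit = {c: np.sum((pred == c) & (labels == c)) for c in contexts}

    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    perm_hit = {c: np.empty(n_perm) for c in contexts}
    for b in range(n_perm):
        shuffled = rng.permutation(labels)
        pcfg = EnsembleConfig(
            k_partitions=cfg.k_partitions,
            n_boot_per_partition=cfg.n_boot_per_partition,
            n_splits=cfg.n_splits,
            contexts_included=cfg.contexts_included,
            balance_target=cfg.balance_target,
            penalty_selection=cfg.penalty_selection,
            seed=int(rng.integers(2**31)),
        )
        v = run_ensemble(features, shuffled, pcfg)
        p, _ = modal_prediction(v)
        perm_acc[b] = np.mean(p == shuffled)
        for c in contexts:
            perm_hit[c][b] = np.sum((p == c) & (shuffled == c))

    def pval(null, obs):
        higher = int(np.sum(null > obs))
        if rule == "add-one":
            return (1 + higher) / (1 + n_perm)
        return higher / n_perm

    return PermutationResult(
        observed_accuracy=obs_acc,
        permuted_accuracies=perm_acc,
        p_overall=pval(perm_acc, obs_acc),
        p_per_context={c: pval(perm_hit[c], obs_hit[c]) for c in contexts},
        n_perm=n_perm,
        n_ties=int(np.sum(perm_acc == obs_acc)),
        rule=rule,
    )
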