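"""Flowering-status classification from specimen label text.

Field notes are normalized (accent folding, punctuation and digit
removal, multilingual stopwords), turned into a bag-of-words count
matrix, and fed to three standard text classifiers — multinomial naive
Bayes, regularized logistic regression and a 500-tree random forest —
compared by stratified fivefold cross-validation on five metrics
(accuracy, precision, recall, F1, AUROC).  The best model by mean F1
(ties by AUROC) is retrained on all labelled data and used to score every
record; downstream stages keep only records predicted to be flowering.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB

from ._lexicon import STOPWORDS

__all__ = [
    "TermMatrix",
    "ClassifierReport",
    "CLASSIFIER_IDS",
    "METRIC_NAMES",
    "normalize_text",
    "build_term_matrix",
    "crossvalidate",
    "train_and_predict",
]

CLASSIFIER_IDS = ("naive_bayes", "logistic_regression", "random_forest")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auroc")

_TOKEN_RE = re.compile(r"[^a-z\s]+")


def normalize_text(text: str | None, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Clean one label into tokens.

    Lowercase, fold accents, strip digits and punctuation, split on
    whitespace, drop stopwords and single characters.

    >>> normalize_text("Árbol 12 m; estéril")
    ['arbol', 'esteril']
    """
    if not text:
        return []
    s = unicodedata.normalize("NFKD", str(text).lower())
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = _TOKEN_RE.sub(" ", s)
    return [t for t in s.split() if len(t) >= 2 and t not in stopwords]


@dataclass
class TermMatrix:
    """Bag-of-words counts: records × sorted vocabulary."""

    vocabulary: list[str]
    counts: sparse.csr_matrix
    record_ids: list[str]


def build_term_matrix(
    corpus: Sequence[str],
    min_df: int = 1,
    record_ids: Sequence[str] | None = None,
    vocabulary: Sequence[str] | None = None,
    stopwords: frozenset[str] = STOPWORDS,
) -> TermMatrix:
    """Count token occurrences per document.

    With ``vocabulary`` given (e.g. the training vocabulary when scoring
    the full dataset), out-of-vocabulary tokens are ignored and ``min_df``
    does not apply.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    docs = [normalize_text(t, stopwords) for t in corpus]
    if vocabulary is None:
        df_count: dict[str, int] = {}
        for toks in docs:
            for t in set(toks):
                df_count[t] = df_count.get(t, 0) + 1
        vocab = sorted(t for t, c in df_count.items() if c >= min_df)
        if not vocab:
            raise ValueError("corpus is empty after cleaning")
    else:
        vocab = list(vocabulary)
    index = {t: j for j, t in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for i, toks in enumerate(docs):
        seen: dict[int, int] = {}
        for t in toks:
            j = index.get(t)
            if j is not None:
                seen[j] = seen.get(j, 0) + 1
        for j, c in seen.items():
            rows.append(i), cols.append(j), vals.append(c)
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.int64)
    ids = list(record_ids) if record_ids is not None else [str(i) for i in range(len(docs))]
    return TermMatrix(vocabulary=vocab, counts=counts, record_ids=ids)


def _make_classifier(cid: str, seed: int):
    if cid == "naive_bayes":
        return MultinomialNB()
    if cid == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if cid == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown classifier {cid!r}")


@dataclass
class ClassifierReport:
    """Fivefold × five-metric comparison of the three classifiers."""

    fold_metrics: dict[str, dict[str, list[float]]]  # classifier -> metric -> 5 values
    means: dict[str, dict[str, float]] = field(default_factory=dict)
    sds: dict[str, dict[str, float]] = field(default_factory=dict)
    selected_best: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"fold_metrics": self.fold_metrics, "means": self.means,
                        "sds": self.sds, "selected_best": self.selected_best}, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _score_fold(clf, x_te, y_te) -> dict[str, float]:
    pred = clf.predict(x_te)
    proba = clf.predict_proba(x_te)[:, list(clf.classes_).index(True)]
    return {
        "accuracy": float(accuracy_score(y_te, pred)),
        "precision": float(precision_score(y_te, pred, zero_division=0)),
        "recall": float(recall_score(y_te, pred, zero_division=0)),
        "f1": float(f1_score(y_te, pred, zero_division=0)),
        "auroc": float(roc_auc_score(y_te, proba)) if len(set(y_te)) > 1 else 0.5,
    }


def crossvalidate(
    matrix: TermMatrix, labels: Sequence[bool], seed: int = 0, n_folds: int = 5
) -> ClassifierReport:
    """Stratified k-fold comparison of the three classifiers.

    Best classifier = highest mean F1; ties break by mean AUROC.
    """
    y = np.asarray(labels, dtype=bool)
    if y.size != matrix.counts.shape[0]:
        raise ValueError("labels do not match matrix rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both flowering and non-flowering examples")
    if counts.min() < 10:
        raise ValueError("need at least 10 records per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_metrics = {cid: {m: [] for m in METRIC_NAMES} for cid in CLASSIFIER_IDS}
    x = matrix.counts
    for tr, te in skf.split(np.zeros(y.size), y):
        for cid in CLASSIFIER_IDS:
            clf = _make_classifier(cid, seed)
            clf.fit(x[tr], y[tr])
            for m, v in _score_fold(clf, x[te], y[te]).items():
                fold_metrics[cid][m].append(v)
    means = {cid: {m: float(np.mean(v)) for m, v in d.items()}
             for cid, d in fold_metrics.items()}
    sds = {cid: {m: float(np.std(v, ddof=1)) for m, v in d.items()}
           for cid, d in fold_metrics.items()}
    best = max(CLASSIFIER_IDS,
               key=lambda c: (means[c]["f1"], means[c]["auroc"], c))
    return ClassifierReport(fold_metrics=fold_metrics, means=means, sds=sds,
                            selected_best=best)


def train_and_predict(
    matrix_train: TermMatrix,
    labels_train: Sequence[bool],
    matrix_all: TermMatrix,
    classifier: str = "random_forest",
    seed: int = 0,
) -> pd.DataFrame:
    """Retrain the chosen classifier on all labelled data and score every
    record: one (record_id, flowering, score) row each.

    ``matrix_all`` must be built with the training vocabulary, so tokens
    unseen in training are ignored; an all-out-of-vocabulary record falls
    back to the classifier's empty-feature behaviour (≈ the class prior).
    """
    if matrix_all.counts.shape[1] != matrix_train.counts.shape[1] or (
            matrix_all.vocabulary != matrix_train.vocabulary):
        raise ValueError("matrix_all must use the training vocabulary")
    clf = _make_classifier(classifier, seed)
    clf.fit(matrix_train.counts, np.asarray(labels_train, dtype=bool))
    proba = clf.predict_proba(matrix_all.counts)[:, list(clf.classes_).index(True)]
    return pd.DataFrame({
        "record_id": matrix_all.record_ids,
        "flowering": proba >= 0.5,
        "score": proba,
    })
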