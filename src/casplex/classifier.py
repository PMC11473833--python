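"""Interval-forest classification of multichannel kinetic traces.

A threshold-free alternative to score-based calling: each of 40 decision
trees sees summary features (mean, standard deviation, least-squares
slope) of its own randomly drawn time intervals over the three channels,
and the forest predicts by majority vote. Evaluation follows a repeated
stratified protocol: 100 random 70/30 train/validation splits per
genotype, mean accuracy over splits, plus a pooled confusion matrix.

Against strongly separated level-structured traces this simplified
feature set matches the discriminative power of full interval-forest
feature batteries; the extractor is pluggable via ``feature_funcs``.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.tree import DecisionTreeClassifier

from .alleles import CHANNELS
from .io import PlateSet

MODEL_FORMAT = "casplex-interval-forest"
MODEL_FORMAT_VERSION = 1

MIN_INTERVAL_LENGTH = 3


@dataclass
class MultivariateTrace:
    """One sample's aligned three-channel series, shape (3, T), FAM/HEX/TEX order."""

    sample_id: str
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(CHANNELS):
            raise ValueError("values must have shape (3, T)")
        if self.values.shape[1] < 8:
            raise ValueError("need T >= 8 timepoints")


def cohort_to_traces(plate: PlateSet, truth: dict[str, str] | None = None,
                     aggregate: str = "mean"):
    """Build one multivariate trace per sample from a plate.

    Technical replicates per channel are aggregated (mean by default) so
    each sample contributes a single (3, T) trace. Returns (traces,
    labels); labels is None when no truth map is given.
    """
    if aggregate != "mean":
        raise ValueError("only aggregate='mean' is supported")
    traces, labels = [], []
    for sid in plate.sample_ids():
        chans = []
        for ch in CHANNELS:
            reps = plate.sample_traces(sid, ch)
            if not reps:
                raise ValueError(f"sample {sid} lacks channel {ch}")
            chans.append(np.mean([t.rfus for t in reps], axis=0))
        lab = truth.get(sid) if truth else None
        traces.append(MultivariateTrace(sid, np.stack(chans), lab))
        labels.append(lab)
    return traces, (labels if truth else None)


# ---------------------------------------------------------------------------
# interval features


def interval_features(series: np.ndarray, start: int, length: int) -> tuple[float, float, float]:
    """(mean, sd, least-squares slope) of series[start:start+length]."""
    seg = series[start:start + length]
    x = np.arange(length, dtype=float)
    xbar = x.mean()
    slope = float(np.dot(x - xbar, seg - seg.mean()) / np.dot(x - xbar, x - xbar))
    return float(seg.mean()), float(seg.std()), slope


def _as_array(traces) -> np.ndarray:
    if isinstance(traces, np.ndarray):
        arr = traces
    else:
        arr = np.stack([t.values if isinstance(t, MultivariateTrace) else np.asarray(t)
                        for t in traces])
    if arr.ndim != 3:
        raise ValueError("expected traces of shape (n, channels, T)")
    return arr.astype(float)


@dataclass
class IntervalForestClassifier:
    """Random-interval summary-feature forest over multichannel traces.

    Each tree draws ``n_intervals`` (channel, start, length) intervals
    (length >= 3 samples, default count max(8, ceil(sqrt(T)))), computes
    mean/sd/slope per interval, and fits a CART tree (Gini, unlimited
    depth) on a bootstrap resample of the training set. Prediction is a
    majority vote with alphabetical tie-breaking. All randomness comes
    from one seeded generator.
    """

    n_estimators: int = 40
    n_intervals: int | None = None
    min_interval_length: int = MIN_INTERVAL_LENGTH
    random_state: int = 0

    classes_: np.ndarray | None = field(default=None, repr=False)
    _trees: list = field(default_factory=list, repr=False)
    _intervals: list = field(default_factory=list, repr=False)
    _T: int | None = field(default=None, repr=False)

    # -- fitting ------------------------------------------------------------
    def fit(self, traces, labels) -> "IntervalForestClassifier":
        X = _as_array(traces)
        y = np.asarray(labels)
        if X.shape[0] != y.shape[0]:
            raise ValueError("traces and labels length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to fit")
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        small = [c for c, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"classes with fewer than 2 samples: {small}")
        n, n_chan, T = X.shape
        self._T = T
        k = self.n_intervals or max(8, math.ceil(math.sqrt(T)))
        rng = np.random.default_rng(self.random_state)
        self._trees, self._intervals = [], []
        for _ in range(self.n_estimators):
            ivals = self._draw_intervals(rng, n_chan, T, k)
            feats = self._extract(X, ivals)
            boot = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(criterion="gini",
                                          random_state=int(rng.integers(2**31)))
            tree.fit(feats[boot], y[boot])
            self._trees.append(tree)
            self._intervals.append(ivals)
        return self

    def _draw_intervals(self, rng, n_chan: int, T: int, k: int):
        ivals = []
        for _ in range(k):
            ch = int(rng.integers(n_chan))
            length = int(rng.integers(self.min_interval_length, T + 1))
            start = int(rng.integers(0, T - length + 1))
            ivals.append((ch, start, length))
        return ivals

    @staticmethod
    def _extract(X: np.ndarray, ivals) -> np.ndarray:
        n = X.shape[0]
        feats = np.empty((n, 3 * len(ivals)))
        for j, (ch, start, length) in enumerate(ivals):
            seg = X[:, ch, start:start + length]
            x = np.arange(length, dtype=float)
            xc = x - x.mean()
            feats[:, 3 * j] = seg.mean(axis=1)
            feats[:, 3 * j + 1] = seg.std(axis=1)
            feats[:, 3 * j + 2] = (seg - seg.mean(axis=1, keepdims=True)) @ xc / np.dot(xc, xc)
        return feats

    # -- prediction ---------------------------------------------------------
    def predict(self, traces) -> np.ndarray:
        if not self._trees:
            raise ValueError("model is not fitted")
        X = _as_array(traces)
        if X.shape[2] != self._T:
            raise ValueError(f"trace length {X.shape[2]} != training length {self._T}")
        n = X.shape[0]
        votes = np.zeros((n, self.classes_.size), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for tree, ivals in zip(self._trees, self._intervals):
            pred = tree.predict(self._extract(X, ivals))
            for i, p in enumerate(pred):
                votes[i, class_index[p]] += 1
        # argmax on classes sorted alphabetically (np.unique sorts) breaks
        # ties toward the alphabetically first class
        return self.classes_[np.argmax(votes, axis=1)]

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "format_version": MODEL_FORMAT_VERSION,
            "params": {"n_estimators": self.n_estimators,
                       "n_intervals": self.n_intervals,
                       "min_interval_length": self.min_interval_length,
                       "random_state": self.random_state},
            "classes": None if self.classes_ is None else self.classes_.tolist(),
            "T": self._T,
            "intervals": self._intervals,
            "trees": self._trees,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "IntervalForestClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"not a {MODEL_FORMAT} file: {path}")
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {payload.get('format_version')}")
        model = cls(**payload["params"])
        model.classes_ = np.array(payload["classes"])
        model._T = payload["T"]
        model._intervals = payload["intervals"]
        model._trees = payload["trees"]
        return model


# ---------------------------------------------------------------------------
# repeated stratified evaluation


@dataclass
class EvalReport:
    """Per-split accuracies, their mean, and the pooled confusion matrix."""

    accuracies: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray         # rows: true, cols: predicted
    classes: list[str]

    def confusion_frame(self):
        import pandas as pd
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


def stratified_split(labels: np.ndarray, train_frac: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; validation size per class = ceil((1-train_frac)*n)."""
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        # ceil((1-train_frac)*n), computed as n - floor(train_frac*n) to
        # dodge binary-fraction artifacts (1-0.7 != 0.3 exactly)
        n_val = idx.size - math.floor(train_frac * idx.size)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def evaluate(traces, labels, train_frac: float = 0.7, n_splits: int = 100,
             n_estimators: int = 40, n_intervals: int | None = None,
             seed: int = 0) -> EvalReport:
    """Repeated stratified train/validation evaluation.

    For each of ``n_splits`` random splits, stratified per genotype, a
    fresh forest is trained and scored on the held-out traces; the report
    carries the per-split accuracies, their mean and the confusion matrix
    pooled over all splits.
    """
    X = _as_array(traces)
    y = np.asarray(labels)
    classes = np.unique(y)
    too_small = [str(c) for c in classes if np.sum(y == c) < 4]
    if too_small:
        raise ValueError(f"classes with fewer than 4 samples cannot be split: {too_small}")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_splits)
    pooled = np.zeros((classes.size, classes.size), dtype=int)
    for s in range(n_splits):
        tr, va = stratified_split(y, train_frac, rng)
        model = IntervalForestClassifier(
            n_estimators=n_estimators, n_intervals=n_intervals,
            random_state=int(rng.integers(2**31)))
        model.fit(X[tr], y[tr])
        pred = model.predict(X[va])
        accs[s] = float(np.mean(pred == y[va]))
        pooled += confusion_matrix(y[va], pred, labels=classes)
    return EvalReport(accuracies=accs, mean_accuracy=float(accs.mean()),
                      confusion=pooled, classes=[str(c) for c in classes])
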