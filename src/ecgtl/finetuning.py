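"""Downstream transfer: preprocessing, finetuning and repeated evaluation.

Records are standardized with statistics pooled over the whole
downstream set (the protocol's own choice; it leaks test statistics into
training and is kept for fidelity), resampled to the upstream rate and
zero-padded to a fixed duration. A pretrained encoder gets a freshly
initialised head and is trained end-to-end; training stops early when
training accuracy has not improved for a set number of epochs, and the
weights revert to the best-validation checkpoint (macro F1 for
single-label, loss for multi-label). Evaluation repeats the whole
procedure with resampled train/validation sets against one fixed test
set and reports mean and standard deviation per metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .metrics import (f_beta_g_beta, f_max, macro_f1, mean_classwise_auc,
                      threshold_search)
from .models import (ClassifierModel, ModelSpec, adapt_encoder_channels,
                     build_encoder, transfer_encoder_weights)
from .synth import child_seed
from .types import DownstreamRecord


@dataclass
class FinetuneConfig:
    max_epochs: int = 200
    early_stop_patience: int = 50
    checkpoint_criterion: str = "val_macro_f1"   # or "val_loss"
    target_fs: float = 250.0
    target_len_s: float = 60.0
    n_runs: int = 10
    train_fraction: float = 0.75
    val_fraction: float = 0.05
    test_fraction: float = 0.20
    batch_size: int = 16
    seed: int = 0

    def validate(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")
        if self.checkpoint_criterion not in ("val_macro_f1", "val_loss"):
            raise ValueError(f"unknown criterion {self.checkpoint_criterion!r}")


@dataclass
class EvalReport:
    """Per-run test metrics with mean and standard deviation."""

    runs: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def metric_names(self) -> list[str]:
        return sorted(self.runs[0]) if self.runs else []

    def mean(self) -> dict:
        return {m: float(np.mean([r[m] for r in self.runs]))
                for m in self.metric_names}

    def std(self) -> dict:
        return {m: float(np.std([r[m] for r in self.runs]))
                for m in self.metric_names}

    def to_dict(self) -> dict:
        return {"runs": self.runs, "mean": self.mean(), "std": self.std(),
                "config": self.config}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ------------------------------------------------------------ preprocessing

def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase rational resampling along the last axis."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return np.asarray(signal, dtype=np.float64)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = sps.resample_poly(np.asarray(signal, dtype=np.float64),
                            frac.numerator, frac.denominator, axis=-1)
    target = int(round(signal.shape[-1] * fs_out / fs_in))
    if out.shape[-1] > target:
        out = out[..., :target]
    elif out.shape[-1] < target:
        pad = [(0, 0)] * (out.ndim - 1) + [(0, target - out.shape[-1])]
        out = np.pad(out, pad)
    return out


def downstream_stats(records: list[DownstreamRecord]) -> tuple[float, float]:
    """Mean and std pooled over every sample of the downstream set."""
    n = sum(r.signal.size for r in records)
    mean = sum(float(r.signal.sum()) for r in records) / n
    sq = sum(float(((r.signal - mean) ** 2).sum()) for r in records)
    return mean, float(np.sqrt(sq / n))


def preprocess_downstream(record: DownstreamRecord, config: FinetuneConfig,
                          stats: tuple[float, float]) -> np.ndarray:
    """Standardize, resample to the target rate, zero-pad (right) to the
    target duration; over-long records are tail-truncated."""
    mean, std = stats
    if std <= 0:
        raise ValueError("dataset standard deviation must be positive")
    x = (record.signal - mean) / std
    x = resample(x, record.fs, config.target_fs)
    target = int(round(config.target_len_s * config.target_fs))
    if x.shape[-1] >= target:
        return x[..., :target]
    pad = [(0, 0)] * (x.ndim - 1) + [(0, target - x.shape[-1])]
    return np.pad(x, pad)


def prepare_downstream(records: list[DownstreamRecord],
                       config: FinetuneConfig) -> np.ndarray:
    """Preprocess a whole record set into a (n, leads, samples) array."""
    stats = downstream_stats(records)
    return np.stack([preprocess_downstream(r, config, stats)
                     for r in records]).astype(np.float32)


# ------------------------------------------------------------ splitting

def stratified_split(labels, fractions: tuple[float, float, float] = (0.75, 0.05, 0.20),
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test split keeping class ratios.

    Per-class allocation uses largest-remainder rounding; a class too
    small to populate every non-empty split is rejected.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        raw = [len(idx) * f for f in fractions]
        counts = [int(np.floor(v)) for v in raw]
        rem = len(idx) - sum(counts)
        order = sorted(range(3), key=lambda i: -(raw[i] - counts[i]))
        for i in order[:rem]:
            counts[i] += 1
        for i, f in enumerate(fractions):
            if f > 0 and counts[i] == 0:
                # borrow one from the largest split if possible
                donor = int(np.argmax(counts))
                if counts[donor] >= 2:
                    counts[donor] -= 1
                    counts[i] += 1
                else:
                    raise ValueError(
                        f"class {cls!r} has too few members ({len(idx)}) to "
                        f"fill every non-empty split")
        a, b = counts[0], counts[0] + counts[1]
        parts[0].extend(idx[:a])
        parts[1].extend(idx[a:b])
        parts[2].extend(idx[b:])
    return tuple(np.sort(np.asarray(p, dtype=int)) for p in parts)


def fold_split(n_records: int, seed: int = 0, n_folds: int = 10,
               train_folds=tuple(range(1, 9)), val_fold: int = 9,
               test_fold: int = 10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold-based split (folds 1-8 train / 9 val / 10 test by default)."""
    rng = np.random.default_rng(seed)
    folds = rng.permutation(np.arange(n_records) % n_folds + 1)
    train = np.flatnonzero(np.isin(folds, train_folds))
    val = np.flatnonzero(folds == val_fold)
    test = np.flatnonzero(folds == test_fold)
    return train, val, test


# ------------------------------------------------------------ estimator

class ECGClassifier(ClassifierMixin, BaseEstimator):
    """Finetunable ECG classifier over a 1D residual encoder.

    ``init_encoder`` carries pretrained weights (a fitted encoder or its
    state dict together with its ``ModelSpec``); ``None`` trains from
    random initialisation. Multi-label mode uses a sigmoid head with
    binary cross-entropy; single-label a softmax head with categorical
    cross-entropy. Training is end-to-end: no weights are frozen.

    Fitted attributes: ``model_``, ``classes_``, ``history_`` (per-epoch
    train accuracy / val metric), ``best_epoch_``, ``n_epochs_``.
    """

    def __init__(self, init_encoder=None, depth: int = 18,
                 width_multiplier: float = 1.0, multi_label: bool = False,
                 max_epochs: int = 200, early_stop_patience: int = 50,
                 checkpoint_criterion: str | None = None, batch_size: int = 16,
                 learning_rate: float = 1e-3, random_state: int = 0) -> None:
        self.init_encoder = init_encoder
        self.depth = depth
        self.width_multiplier = width_multiplier
        self.multi_label = multi_label
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.checkpoint_criterion = checkpoint_criterion
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build_model(self, n_channels: int, n_classes: int,
                     rng: np.random.Generator) -> ClassifierModel:
        spec = ModelSpec(depth=self.depth, in_channels=1,
                         width_multiplier=self.width_multiplier)
        encoder = build_encoder(spec, rng=rng)
        if self.init_encoder is not None:
            src = self.init_encoder
            if isinstance(src, nn.ResNet1D):
                # handles encoders pretrained with fewer stages: the
                # missing stages keep their fresh initialisation
                transfer_encoder_weights(src, encoder)
            else:
                encoder.load_state_dict({k: np.array(v) for k, v in dict(src).items()})
        if n_channels != 1:
            adapt_encoder_channels(encoder, n_channels)
        activation = "sigmoid" if self.multi_label else "softmax"
        return ClassifierModel(encoder, n_classes, activation=activation, rng=rng)

    def _encode_targets(self, y) -> np.ndarray:
        if self.multi_label:
            return np.asarray(y, dtype=np.float64)
        return np.asarray([list(self.classes_).index(v) for v in y])

    def fit(self, X, y, X_val=None, y_val=None) -> "ECGClassifier":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_records, n_leads, n_samples)")
        if len(X) == 0:
            raise ValueError("empty training set")
        criterion = self.checkpoint_criterion or (
            "val_loss" if self.multi_label else "val_macro_f1")
        if criterion not in ("val_macro_f1", "val_loss"):
            raise ValueError(f"unknown criterion {criterion!r}")
        if self.multi_label:
            y = np.atleast_2d(np.asarray(y))
            self.classes_ = np.arange(y.shape[1])
        else:
            seen = list(np.asarray(y))
            if y_val is not None:
                seen.extend(np.asarray(y_val))
            self.classes_ = np.unique(seen)
            if len(self.classes_) < 2:
                raise ValueError("need at least two classes")
        rng = np.random.default_rng(child_seed(self.random_state, 11))
        n_out = y.shape[1] if self.multi_label else len(self.classes_)
        model = self._build_model(X.shape[1], n_out, rng)
        yt = self._encode_targets(y)
        has_val = X_val is not None and len(X_val) > 0
        if has_val:
            X_val = np.asarray(X_val, dtype=np.float32)
            yv = self._encode_targets(y_val)

        opt = nn.Adam(model.params(), lr=self.learning_rate)
        n = len(X)
        history = {"train_accuracy": [], "val_metric": []}
        best_metric = -np.inf
        best_weights = nn.copy_weights(model)
        best_epoch = 0
        best_train_acc = -np.inf
        since_improve = 0
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            correct = 0
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                logits = model.forward(X[idx], train=True)
                if self.multi_label:
                    _, dlogits = nn.sigmoid_binary_cross_entropy(logits, yt[idx])
                    correct += int(((logits > 0) == (yt[idx] > 0.5)).all(axis=1).sum())
                else:
                    _, dlogits = nn.softmax_cross_entropy(logits, yt[idx])
                    correct += int((logits.argmax(axis=1) == yt[idx]).sum())
                opt.zero_grad()
                model.backward(dlogits)
                opt.step()
            train_acc = correct / n
            history["train_accuracy"].append(train_acc)

            if has_val:
                vlogits = model.forward(X_val, train=False)
                if criterion == "val_macro_f1":
                    pred = self.classes_[vlogits.argmax(axis=1)]
                    truth = self.classes_[yv.astype(int)]
                    metric, _ = macro_f1(truth, pred, classes=list(self.classes_))
                else:
                    if self.multi_label:
                        loss, _ = nn.sigmoid_binary_cross_entropy(vlogits, yv)
                    else:
                        loss, _ = nn.softmax_cross_entropy(vlogits, yv)
                    metric = -loss
                history["val_metric"].append(metric)
                if metric > best_metric:
                    best_metric = metric
                    best_weights = nn.copy_weights(model)
                    best_epoch = epoch
            else:
                best_weights = nn.copy_weights(model)
                best_epoch = epoch

            # early stop on train-accuracy plateau (strict improvement)
            if train_acc > best_train_acc:
                best_train_acc = train_acc
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= self.early_stop_patience:
                    break

        model.load_state_dict(best_weights)
        self.model_ = model
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = epoch
        self.best_val_metric_ = best_metric if has_val else None
        self.criterion_ = criterion
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        out = []
        for lo in range(0, len(X), self.batch_size):
            out.append(self.model_.predict_proba(X[lo:lo + self.batch_size]))
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.multi_label:
            return (proba >= 0.5).astype(int)
        return self.classes_[proba.argmax(axis=1)]


def run_finetune(init_encoder, X, y, splits, config: FinetuneConfig,
                 model_spec: ModelSpec | None = None,
                 multi_label: bool = False, seed: int | None = None
                 ) -> ECGClassifier:
    """Finetune on explicit (train, val, test) index splits."""
    config.validate()
    train, val, _ = splits
    if len(set(train) & set(val)):
        raise ValueError("train and validation splits overlap")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty split")
    spec = model_spec or ModelSpec()
    clf = ECGClassifier(
        init_encoder=init_encoder, depth=spec.depth,
        width_multiplier=spec.width_multiplier, multi_label=multi_label,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        checkpoint_criterion=config.checkpoint_criterion if multi_label is False
        else "val_loss",
        batch_size=config.batch_size,
        random_state=config.seed if seed is None else seed)
    y = np.asarray(y)
    return clf.fit(X[train], y[train], X_val=X[val], y_val=y[val])


def _single_label_metrics(clf: ECGClassifier, X_test, y_test) -> dict:
    pred = clf.predict(X_test)
    classes = list(clf.classes_)
    macro, per_class = macro_f1(y_test, pred, classes=classes)
    out = {"macro_f1": macro}
    for c in classes:
        out[f"f1_{str(c).lower()}"] = per_class[c]
    return out


def _multi_label_metrics(clf: ECGClassifier, X_train, y_train, X_test, y_test
                         ) -> dict:
    s_test = clf.predict_proba(X_test)
    s_train = clf.predict_proba(X_train)
    t_f = threshold_search(y_train, s_train,
                           lambda yt, yp: f_beta_g_beta(yt, yp)[0])
    t_g = threshold_search(y_train, s_train,
                           lambda yt, yp: f_beta_g_beta(yt, yp)[1])
    fbeta, _ = f_beta_g_beta(y_test, s_test >= t_f)
    _, gbeta = f_beta_g_beta(y_test, s_test >= t_g)
    return {"auc": mean_classwise_auc(y_test, s_test),
            "f_max": f_max(y_test, s_test),
            "f_beta2": fbeta, "g_beta2": gbeta}


def repeated_evaluation(init_encoder, X: np.ndarray, y,
                        config: FinetuneConfig,
                        model_spec: ModelSpec | None = None,
                        multi_label: bool = False,
                        strata=None) -> EvalReport:
    """The repeated finetuning protocol.

    A stratified test set (``test_fraction``) is fixed once; each of the
    ``n_runs`` runs draws fresh train/validation sets from the remaining
    pool, finetunes from the same initial weights and records the test
    metrics.
    """
    config.validate()
    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    y = np.asarray(y)
    strata = y if strata is None else np.asarray(strata)
    pool_frac = 1.0 - config.test_fraction
    _, _, test = stratified_split(
        strata, (pool_frac, 0.0, config.test_fraction),
        seed=child_seed(config.seed, 100))
    pool = np.setdiff1d(np.arange(len(y)), test)
    report = EvalReport(config={
        "n_runs": config.n_runs, "test_size": int(len(test)),
        "pool_size": int(len(pool)),
        "criterion": config.checkpoint_criterion,
        "multi_label": bool(multi_label), "seed": config.seed})
    rel_train = config.train_fraction / pool_frac
    rel_val = 1.0 - rel_train
    for run in range(config.n_runs):
        run_seed = child_seed(config.seed, 101 + run)
        tr_rel, va_rel, _ = stratified_split(
            strata[pool], (rel_train, rel_val, 0.0), seed=run_seed)
        train, val = pool[tr_rel], pool[va_rel]
        assert not (set(train) | set(val)) & set(test)
        clf = run_finetune(init_encoder, X, y, (train, val, test), config,
                           model_spec=model_spec, multi_label=multi_label,
                           seed=run_seed)
        if multi_label:
            metrics = _multi_label_metrics(clf, X[train], y[train], X[test], y[test])
        else:
            metrics = _single_label_metrics(clf, X[test], y[test])
        metrics["best_epoch"] = clf.best_epoch_
        metrics["n_epochs"] = clf.n_epochs_
        report.runs.append(metrics)
    report.config["test_indices"] = [int(i) for i in test]
    return report
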