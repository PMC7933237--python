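"""Pretraining tasks over a continuous annotated corpus.

Four tasks share one loop: supervised beat / rhythm / heart-rate
classification of sampled frames, and contrastive future prediction.
Frames are standardized with corpus-level statistics, patients are split
into train and validation groups (5% of patients by default), the
categorical cross-entropy is minimised with Adam at default
hyperparameters, and the weights with the best validation accuracy
among the periodic checkpoints are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .framing import (Frame, UnlabelableFrame, label_beat, label_heart_rate,
                      label_rhythm, make_cpc_example, sample_frame, standardize)
from .models import (AttentionPoolSpec, ClassifierModel, CpcModel, ModelSpec,
                     build_encoder)
from .synth import child_seed
from .types import BeatClass, Corpus, HeartRateClass, RhythmClass

PRETRAIN_TASKS = ("beat", "rhythm", "heart_rate", "future_prediction")

TASK_CLASSES = {
    "beat": [c.value for c in BeatClass],
    "rhythm": [c.value for c in RhythmClass],
    "heart_rate": [c.value for c in HeartRateClass],
}


@dataclass
class PretrainConfig:
    task: str = "heart_rate"
    frame_length: int = 2048
    context_size: int = 8       # CPC only
    ns: int = 4                 # CPC negative samples
    offset: int = 2             # CPC offset in frames
    frames_per_patient: int = 4096
    val_patient_fraction: float = 0.05
    checkpoint_interval_steps: int = 2000
    batch_size: int = 32
    max_steps: int = 3000
    val_frames: int = 256
    beat_source: str = "ground_truth"
    seed: int = 0

    def validate(self) -> None:
        if self.task not in PRETRAIN_TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not 0 < self.val_patient_fraction < 1:
            raise ValueError("val_patient_fraction must be in (0, 1)")
        if self.checkpoint_interval_steps < 1:
            raise ValueError("checkpoint_interval_steps must be >= 1")


@dataclass
class CheckpointHistory:
    """Validation accuracy per saved checkpoint, plus stored weights."""

    steps: list[int] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    weights: dict[int, dict] = field(default_factory=dict)

    def record(self, step: int, acc: float, weights: dict) -> None:
        if self.steps and step <= self.steps[-1]:
            raise ValueError("checkpoint steps must be strictly increasing")
        self.steps.append(step)
        self.val_accuracy.append(acc)
        self.weights[step] = weights

    def best_step(self) -> int:
        """Step with the highest validation accuracy (ties: earliest)."""
        if not self.steps:
            raise ValueError("no checkpoints recorded")
        best = int(np.argmax(self.val_accuracy))
        return self.steps[best]


def split_patients(patient_ids: list[str], val_fraction: float = 0.05,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Patient-level train/validation split; at least one patient in
    validation, none in both."""
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_val = max(int(round(val_fraction * len(ids))), 1)
    val = sorted(ids[i] for i in perm[:n_val])
    train = sorted(ids[i] for i in perm[n_val:])
    return train, val


def sampling_budget(n_patients_train: int, frames_per_patient: int = 4096) -> int:
    """Total pretraining samples: frames per patient times patients."""
    if n_patients_train <= 0 or frames_per_patient <= 0:
        raise ValueError("inputs must be positive")
    return n_patients_train * frames_per_patient


def format_budget_millions(total_frames: int) -> str:
    """Reporting helper: round to 0.1 million (e.g. '42.8 million')."""
    return f"{total_frames / 1e6:.1f} million"


class FramePretrainer(BaseEstimator):
    """Pretrain a residual encoder on one task over a corpus.

    Parameters mirror the pretraining protocol: ``task`` is one of
    ``beat``, ``rhythm``, ``heart_rate`` or ``future_prediction``;
    ``frame_length`` is in samples at the corpus sampling frequency;
    ``context_size``/``ns``/``offset`` shape the contrastive task.

    Fitted attributes: ``encoder_`` (the selected-checkpoint encoder),
    ``model_`` (task model), ``history_`` (checkpoints), ``best_step_``,
    ``best_val_accuracy_``, ``corpus_mean_`` / ``corpus_std_``,
    ``train_patients_`` / ``val_patients_``.
    """

    def __init__(self, task: str = "heart_rate", frame_length: int = 2048,
                 depth: int = 18, width_multiplier: float = 1.0,
                 stages_used: int = 4, context_size: int = 8, ns: int = 4,
                 offset: int = 2, batch_size: int = 32, max_steps: int = 3000,
                 checkpoint_interval_steps: int = 2000,
                 val_patient_fraction: float = 0.05, val_frames: int = 256,
                 beat_source: str = "ground_truth", learning_rate: float = 1e-3,
                 attention_heads: int = 8, attention_layers: int = 3,
                 use_positional: bool = True, random_state: int = 0) -> None:
        self.task = task
        self.frame_length = frame_length
        self.depth = depth
        self.width_multiplier = width_multiplier
        self.stages_used = stages_used
        self.context_size = context_size
        self.ns = ns
        self.offset = offset
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.checkpoint_interval_steps = checkpoint_interval_steps
        self.val_patient_fraction = val_patient_fraction
        self.val_frames = val_frames
        self.beat_source = beat_source
        self.learning_rate = learning_rate
        self.attention_heads = attention_heads
        self.attention_layers = attention_layers
        self.use_positional = use_positional
        self.random_state = random_state

    # ------------------------------------------------------ internals

    def _labeler(self):
        if self.task == "beat":
            return lambda f: label_beat(f).value
        if self.task == "rhythm":
            return lambda f: label_rhythm(f).value
        return lambda f: label_heart_rate(f, beat_source=self.beat_source).value

    def _sample_labeled_batch(self, corpus: Corpus, n: int,
                              rng: np.random.Generator, track: bool = False
                              ) -> tuple[np.ndarray, np.ndarray, list[Frame]]:
        labeler = self._labeler()
        classes = TASK_CLASSES[self.task]
        xs, ys, frames = [], [], []
        attempts = 0
        while len(xs) < n:
            attempts += 1
            if attempts > 50 * n:
                raise RuntimeError("too many unlabelable frames in corpus")
            frame = sample_frame(corpus, self.frame_length, rng)
            try:
                lab = labeler(frame)
            except UnlabelableFrame:
                continue
            xs.append(standardize(frame.signal, self._mean, self._std))
            ys.append(classes.index(lab))
            frames.append(frame)
            if track:
                self.trained_patient_ids_.add(frame.recording.patient_id)
        x = np.stack(xs)[:, None, :].astype(np.float32)
        return x, np.asarray(ys), frames

    def _sample_cpc_batch(self, corpus: Corpus, n: int, rng: np.random.Generator,
                          negative_corpus: Corpus | None = None,
                          track: bool = False) -> np.ndarray:
        batches = []
        for _ in range(n):
            ex = make_cpc_example(corpus, self.context_size, self.frame_length,
                                  self.offset, self.ns, rng,
                                  negative_corpus=negative_corpus)
            frames = ex.context + [ex.positive] + ex.negatives
            if track:
                self.trained_patient_ids_.update(
                    f.recording.patient_id for f in frames)
            arr = np.stack([standardize(f.signal, self._mean, self._std)
                            for f in frames])
            batches.append(arr)
        return np.stack(batches)[:, :, None, :].astype(np.float32)

    def _validation_accuracy(self, model) -> float:
        if self.task == "future_prediction":
            correct = 0
            for xb in self._val_batches:
                logits = model.forward(xb, train=False)
                correct += int((logits.argmax(axis=1) == 0).sum())
            return correct / sum(len(b) for b in self._val_batches)
        correct = total = 0
        for xb, yb in self._val_batches:
            logits = model.forward(xb, train=False)
            correct += int((logits.argmax(axis=1) == yb).sum())
            total += len(yb)
        return correct / total

    # ------------------------------------------------------ fit

    def fit(self, corpus: Corpus, y=None) -> "FramePretrainer":
        if self.task not in PRETRAIN_TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {PRETRAIN_TASKS}")
        if len(corpus) == 0:
            raise ValueError("corpus is empty")
        max_len = max(r.n_samples for r in corpus)
        if self.task == "future_prediction":
            needed = (self.context_size + self.offset + 1) * self.frame_length
            if max_len < needed:
                raise ValueError(
                    f"contrastive geometry needs segments of {needed} samples, "
                    f"longest is {max_len}")
        elif max_len < self.frame_length:
            raise ValueError("no segment is long enough for the frame length")

        self._mean, self._std = corpus.stats()
        self.corpus_mean_, self.corpus_std_ = self._mean, self._std
        train_ids, val_ids = split_patients(corpus.patient_ids,
                                            self.val_patient_fraction,
                                            seed=child_seed(self.random_state, 1))
        self.train_patients_, self.val_patients_ = train_ids, val_ids
        train_corpus = corpus.subset(train_ids)
        val_corpus = corpus.subset(val_ids)

        init_rng = np.random.default_rng(child_seed(self.random_state, 2))
        spec = ModelSpec(depth=self.depth, in_channels=1,
                         width_multiplier=self.width_multiplier,
                         stages_used=self.stages_used)
        encoder = build_encoder(spec, rng=init_rng)
        if self.task == "future_prediction":
            pool_spec = AttentionPoolSpec(
                d_model=encoder.out_features, n_heads=self.attention_heads,
                n_layers=self.attention_layers,
                max_len=max(self.context_size + 1, 8),
                use_positional=self.use_positional)
            model: nn.Layer = CpcModel(encoder, self.context_size, pool_spec,
                                       rng=init_rng)
        else:
            model = ClassifierModel(encoder, len(TASK_CLASSES[self.task]),
                                    rng=init_rng)
        self.model_spec_ = spec

        # fixed validation batches drawn once from held-out patients
        val_rng = np.random.default_rng(child_seed(self.random_state, 3))
        self._val_batches = []
        n_done = 0
        while n_done < self.val_frames:
            k = min(self.batch_size, self.val_frames - n_done)
            if self.task == "future_prediction":
                # context and positive from held-out patients; negatives
                # come from the whole data set, as in training
                self._val_batches.append(
                    self._sample_cpc_batch(val_corpus, k, val_rng,
                                           negative_corpus=corpus))
            else:
                xb, yb, _ = self._sample_labeled_batch(val_corpus, k, val_rng)
                self._val_batches.append((xb, yb))
            n_done += k

        opt = nn.Adam(model.params(), lr=self.learning_rate)
        train_rng = np.random.default_rng(child_seed(self.random_state, 4))
        history = CheckpointHistory()
        self.loss_curve_ = []
        self.trained_patient_ids_: set[str] = set()
        for step in range(1, self.max_steps + 1):
            if self.task == "future_prediction":
                xb = self._sample_cpc_batch(train_corpus, self.batch_size,
                                            train_rng, track=True)
                yb = np.zeros(len(xb), dtype=int)  # positive is candidate 0
            else:
                xb, yb, _ = self._sample_labeled_batch(train_corpus,
                                                       self.batch_size, train_rng,
                                                       track=True)
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            self.loss_curve_.append(loss)
            if step % self.checkpoint_interval_steps == 0 or step == self.max_steps:
                acc = self._validation_accuracy(model)
                history.record(step, acc, nn.copy_weights(model))
                history.losses.append(loss)

        best = history.best_step()
        model.load_state_dict(history.weights[best])
        self.model_ = model
        self.encoder_ = encoder
        self.history_ = history
        self.best_step_ = best
        self.best_val_accuracy_ = history.val_accuracy[history.steps.index(best)]
        del self._val_batches
        return self

    def score(self, corpus: Corpus, y=None) -> float:
        """Task accuracy on frames sampled from the given corpus."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        self._mean, self._std = self.corpus_mean_, self.corpus_std_
        rng = np.random.default_rng(child_seed(self.random_state, 5))
        if self.task == "future_prediction":
            xb = self._sample_cpc_batch(corpus, self.val_frames, rng)
            logits = self.model_.forward(xb, train=False)
            return float((logits.argmax(axis=1) == 0).mean())
        xb, yb, _ = self._sample_labeled_batch(corpus, self.val_frames, rng)
        logits = self.model_.forward(xb, train=False)
        return float((logits.argmax(axis=1) == yb).mean())


def run_pretraining(corpus: Corpus, model_spec: ModelSpec,
                    config: PretrainConfig) -> FramePretrainer:
    """Functional wrapper: pretrain per the config and return the fitted
    estimator (history in ``.history_``, weights in ``.model_``)."""
    config.validate()
    est = FramePretrainer(
        task=config.task, frame_length=config.frame_length,
        depth=model_spec.depth, width_multiplier=model_spec.width_multiplier,
        stages_used=model_spec.stages_used, context_size=config.context_size,
        ns=config.ns, offset=config.offset, batch_size=config.batch_size,
        max_steps=config.max_steps,
        checkpoint_interval_steps=config.checkpoint_interval_steps,
        val_patient_fraction=config.val_patient_fraction,
        val_frames=config.val_frames, beat_source=config.beat_source,
        random_state=config.seed)
    return est.fit(corpus)
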