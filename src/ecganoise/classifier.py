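"""1D ResNet beat classifier over 512-sample segments, with transfer learning.

The network is a stack of residual stages (each block: two same-padded
convolutions with batch normalization and ReLU plus an identity shortcut,
reconciled by a 1x1 convolution when the channel count changes), global
average pooling, and a softmax output over the beat-class alphabet.
Training minimizes cross-entropy.  ``transfer_fit`` warm-starts from a
fitted model, optionally freezing early stages and remapping the output
layer when the new data uses a subset of the original classes (e.g. fusion
beats absent from a wearable recording).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ArgumentError, TrainingDivergedError
from .metrics import ClassificationReport, classification_report
from .nn import Adam, BatchNorm1d, Conv1d, Linear, Module, ResidualBlock1d
from .nn import tensor as T
from .nn.tensor import Tensor


@dataclass
class ResNetSpec:
    """Residual classifier architecture: (blocks, filters, pool) per stage."""

    input_len: int = 512
    n_classes: int = 5
    stages: Tuple[Tuple[int, int, int], ...] = ((2, 32, 2), (2, 64, 2), (2, 128, 2))
    kernel_size: int = 9
    stem_filters: int = 32

    def __post_init__(self):
        total_pool = int(np.prod([p for _, _, p in self.stages]))
        if self.input_len % total_pool:
            raise ArgumentError("input_len must be divisible by the product of stage pools")


@dataclass
class ClassifierTrainingConfig:
    epochs: int = 10
    batch_size: int = 64
    lr: float = 1e-3
    betas: Tuple[float, float] = (0.9, 0.999)


class ResNet1d(Module):
    def __init__(self, spec: ResNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k = spec.kernel_size
        self.stem = Conv1d(1, spec.stem_filters, k, rng)
        self.stem_bn = BatchNorm1d(spec.stem_filters)
        cin = spec.stem_filters
        for s, (blocks, filters, _pool) in enumerate(spec.stages):
            for b in range(blocks):
                setattr(self, f"stage{s}_block{b}",
                        ResidualBlock1d(cin, filters, k, rng, activation="relu"))
                cin = filters
        self.fc = Linear(cin, spec.n_classes, rng)

    def stage_modules(self, s: int) -> List[Module]:
        blocks, _, _ = self.spec.stages[s]
        return [getattr(self, f"stage{s}_block{b}") for b in range(blocks)]

    def forward(self, x: Tensor) -> Tensor:
        """Logits of shape (B, n_classes) for input (B, 1, L)."""
        h = T.relu(self.stem_bn(self.stem(x)))
        for s, (_blocks, _f, pool) in enumerate(self.spec.stages):
            for block in self.stage_modules(s):
                h = block(h)
            if pool > 1:
                h = T.avg_pool1d(h, pool)
        h = T.global_avg_pool1d(h)
        return self.fc(h)


def build_resnet(spec: Optional[ResNetSpec] = None, seed: int = 0) -> ResNet1d:
    """Construct the residual classifier with seeded initialization."""
    return ResNet1d(spec or ResNetSpec(), np.random.default_rng(seed))


def cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (numerically stable)."""
    lse = T.logsumexp(logits, axis=1)  # (B,)
    true_logit = T.sum_(logits * Tensor(onehot), axis=1)
    return T.mean(lse - true_logit)


def _segments_to_arrays(segments, classes=None):
    X, y = [], []
    for s in segments:
        if hasattr(s, "window"):
            X.append(np.asarray(s.window, dtype=float))
            y.append(s.label)
        else:
            w, lab = s
            X.append(np.asarray(w, dtype=float))
            y.append(lab)
    X = np.stack(X).astype(np.float32)
    if classes is None:
        classes = tuple(sorted(set(y)))
    return X, np.asarray(y, dtype=object), classes


class BeatClassifier:
    """Beat-class model over labeled 512-sample segments.

    Parameters
    ----------
    segments : sequence of LabeledSegment or (window, label) tuples
    classes : optional explicit class alphabet (defaults to observed labels)
    """

    def __init__(self, segments, classes: Optional[Sequence[str]] = None,
                 spec: Optional[ResNetSpec] = None,
                 train_cfg: Optional[ClassifierTrainingConfig] = None):
        self.X, self.y, self.classes = _segments_to_arrays(segments, classes)
        if len(set(self.y)) < 2:
            raise ArgumentError("training data must contain at least two classes")
        unknown = set(self.y) - set(self.classes)
        if unknown:
            raise ArgumentError(f"labels outside declared class alphabet: {unknown}")
        self.spec = spec or ResNetSpec(input_len=self.X.shape[1], n_classes=len(self.classes))
        if self.spec.n_classes != len(self.classes):
            raise ArgumentError("spec.n_classes must match the class alphabet size")
        self.train_cfg = train_cfg or ClassifierTrainingConfig()

    def class_counts(self) -> Dict[str, int]:
        """Per-class segment counts (imbalance is reported, not resampled)."""
        return {c: int(np.sum(self.y == c)) for c in self.classes}

    def fit(self, epochs: Optional[int] = None, seed: int = 0,
            net: Optional[ResNet1d] = None, lr: Optional[float] = None,
            callback=None) -> "ClassifierResults":
        """Cross-entropy training; deterministic under ``seed``."""
        cfg = self.train_cfg
        epochs = epochs if epochs is not None else cfg.epochs
        rng = np.random.default_rng(seed)
        if net is None:
            net = ResNet1d(self.spec, rng)
        opt = Adam([p for p in net.parameters() if p.requires_grad],
                   lr=lr if lr is not None else cfg.lr, betas=cfg.betas)
        cls_index = {c: i for i, c in enumerate(self.classes)}
        y_idx = np.array([cls_index[c] for c in self.y])
        onehot_all = np.eye(len(self.classes))[y_idx]

        n = len(self.X)
        history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
        for epoch in range(epochs):
            order = rng.permutation(n)
            loss_sum, correct = 0.0, 0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo:lo + cfg.batch_size]
                x = Tensor(self.X[idx][:, None, :])
                logits = net(x)
                loss = cross_entropy(logits, onehot_all[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                loss_sum += loss.item() * len(idx)
                correct += int(np.sum(logits.data.argmax(axis=1) == y_idx[idx]))
            history["loss"].append(loss_sum / n)
            history["accuracy"].append(correct / n)
            if not np.isfinite(history["loss"][-1]):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            if callback is not None:
                callback(epoch, {k: v[-1] for k, v in history.items()})
        return ClassifierResults(net=net, classes=self.classes, history=history,
                                 seed=seed, spec=self.spec)


class ClassifierResults:
    """Fitted beat classifier: network, class alphabet, history, inference."""

    def __init__(self, net: ResNet1d, classes: Tuple[str, ...],
                 history: Dict[str, List[float]], seed: int, spec: ResNetSpec):
        self.net = net
        self.classes = tuple(classes)
        self.history = history
        self.seed = seed
        self.spec = spec

    def predict_proba(self, segments, batch_size: int = 128) -> np.ndarray:
        """Class probabilities (rows sum to one); batch-order invariant."""
        X = self._to_array(segments)
        self.net.eval()
        out = np.empty((len(X), len(self.classes)))
        for lo in range(0, len(X), batch_size):
            logits = self.net(Tensor(X[lo:lo + batch_size][:, None, :]))
            out[lo:lo + batch_size] = T.softmax(logits.data, axis=1)
        self.net.train()
        return out

    def predict(self, segments) -> np.ndarray:
        """Argmax labels over the class alphabet."""
        proba = self.predict_proba(segments)
        return np.asarray([self.classes[i] for i in proba.argmax(axis=1)], dtype=object)

    def report(self, segments, y_true: Optional[Sequence[str]] = None) -> ClassificationReport:
        """Precision/recall/F1 against true labels (taken from segments if labeled)."""
        if y_true is None:
            y_true = [s.label for s in segments]
        return classification_report(list(y_true), list(self.predict(segments)),
                                     classes=self.classes)

    def summary(self) -> str:
        lines = ["Beat classifier training summary",
                 f"  classes: {self.classes}, seed: {self.seed}",
                 f"  stages: {self.spec.stages}, kernel {self.spec.kernel_size}",
                 f"  {'epoch':>5}{'loss':>12}{'accuracy':>10}"]
        for e, (l, a) in enumerate(zip(self.history["loss"], self.history["accuracy"])):
            lines.append(f"  {e:>5}{l:>12.4f}{a:>10.3f}")
        return "\n".join(lines)

    @staticmethod
    def _to_array(segments) -> np.ndarray:
        if isinstance(segments, np.ndarray):
            return segments
        return np.stack([np.asarray(s.window if hasattr(s, "window") else s, dtype=float)
                         for s in segments])

    def save(self, path) -> Path:
        path = Path(path)
        meta = {"format": "ecganoise-classifier", "version": 1,
                "classes": list(self.classes), "seed": self.seed,
                "history": self.history,
                "spec": {"input_len": self.spec.input_len,
                         "n_classes": self.spec.n_classes,
                         "stages": [list(s) for s in self.spec.stages],
                         "kernel_size": self.spec.kernel_size,
                         "stem_filters": self.spec.stem_filters}}
        arrays = {f"net/{k}": v for k, v in self.net.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path) -> "ClassifierResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]))
            if meta.get("format") != "ecganoise-classifier":
                raise ArgumentError(f"not a classifier checkpoint: {path}")
            state = {k[4:]: data[k] for k in data.files if k.startswith("net/")}
        spec = ResNetSpec(input_len=meta["spec"]["input_len"],
                          n_classes=meta["spec"]["n_classes"],
                          stages=tuple(tuple(s) for s in meta["spec"]["stages"]),
                          kernel_size=meta["spec"]["kernel_size"],
                          stem_filters=meta["spec"]["stem_filters"])
        net = ResNet1d(spec, np.random.default_rng(0))
        net.load_state_dict(state)
        return cls(net=net, classes=tuple(meta["classes"]), history=meta["history"],
                   seed=meta["seed"], spec=spec)


def train_classifier(segments, classes=None, spec=None, train_cfg=None,
                     epochs=None, seed: int = 0) -> ClassifierResults:
    """Functional wrapper around :class:`BeatClassifier` + :meth:`fit`."""
    return BeatClassifier(segments, classes, spec, train_cfg).fit(epochs=epochs, seed=seed)


def transfer_fit(pretrained: ClassifierResults, new_segments,
                 freeze_stages: int = 1, lr_scale: float = 0.1,
                 epochs: int = 5, seed: int = 0,
                 train_cfg: Optional[ClassifierTrainingConfig] = None) -> ClassifierResults:
    """Fine-tune a pretrained classifier on new data.

    The new data's class alphabet must be a subset of the pretrained one;
    when it shrinks, the output layer is re-mapped to the surviving classes.
    The stem plus the first ``freeze_stages`` stages are frozen and the rest
    fine-tuned at ``lr_scale`` times the base learning rate.
    """
    X, y, _ = _segments_to_arrays(new_segments)
    new_classes = tuple(c for c in pretrained.classes if c in set(y))
    unknown = set(y) - set(pretrained.classes)
    if unknown:
        raise ArgumentError(f"new data contains unknown classes: {unknown}")

    spec = ResNetSpec(input_len=pretrained.spec.input_len, n_classes=len(new_classes),
                      stages=pretrained.spec.stages,
                      kernel_size=pretrained.spec.kernel_size,
                      stem_filters=pretrained.spec.stem_filters)
    net = ResNet1d(spec, np.random.default_rng(seed))
    # warm start: copy backbone weights, remap the head to surviving classes
    state = pretrained.net.state_dict()
    keep = [pretrained.classes.index(c) for c in new_classes]
    state["fc.weight"] = state["fc.weight"][:, keep]
    state["fc.bias"] = state["fc.bias"][keep]
    net.load_state_dict(state)

    net.stem.freeze()
    net.stem_bn.freeze()
    for s in range(min(freeze_stages, len(spec.stages))):
        for block in net.stage_modules(s):
            block.freeze()

    cfg = train_cfg or ClassifierTrainingConfig()
    model = BeatClassifier(list(zip(X, y)), classes=new_classes, spec=spec, train_cfg=cfg)
    return model.fit(epochs=epochs, seed=seed, net=net, lr=cfg.lr * lr_scale)


def predict(results: ClassifierResults, segments):
    """Functional wrapper: (labels, probabilities)."""
    return results.predict(segments), results.predict_proba(segments)
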