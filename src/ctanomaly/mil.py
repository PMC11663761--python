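"""Multiple-instance slice-bag classifier for single-organ anomaly detection.

Each organ volume is presented as an ordered sequence of five-slice bags.
A 2D convolutional encoder embeds every bag independently; a single-layer
LSTM shares information along the cranio-caudal bag sequence; a fully
connected layer maps each step's hidden state to per-category logits,
which are averaged over the bag axis (global average pooling along
slices) into the final multi-label output. Category probabilities are
independent sigmoids trained with mean binary cross-entropy, and the
scalar organ anomaly score is the maximum category probability.

The encoder is pluggable: anything exposing ``forward(batch) -> features``
and ``backward(dfeatures)`` with a ``layers`` attribute can replace the
default small CNN — e.g. a large pretrained backbone such as ConvNeXt v2;
weights for such encoders are intentionally not bundled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .preprocess import OrganVolume, SliceBagSequence, build_slice_bags

__all__ = [
    "ModelConfig",
    "PredictionRecord",
    "SmallConvEncoder",
    "MILNet",
    "MILBagClassifier",
    "encode_bags",
    "aggregate",
    "predict_record",
    "loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    encoder_widths: tuple[int, ...] = (8, 16, 32, 64)
    feature_dim: int = 64
    lstm_hidden: int = 128
    n_categories: int = 4
    dropout: float = 0.0
    in_channels: int = 5
    any_abnormal_head: bool = False
    encoder_pool: str = "max"  # "max" keeps focal activations; "avg" available

    def __post_init__(self) -> None:
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.feature_dim <= 0 or self.lstm_hidden <= 0:
            raise ValueError("feature_dim and lstm_hidden must be positive")


@dataclass
class PredictionRecord:
    """Per-(exam, organ) category probabilities and scalar anomaly score."""

    exam_id: str
    organ: str
    category_probs: dict[str, float]
    anomaly_score: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = max(self.category_probs.values())
        if self.anomaly_score is None:
            self.anomaly_score = float(expected)
        elif abs(self.anomaly_score - expected) > 1e-9:
            raise ValueError("anomaly_score must equal max(category_probs)")


class SmallConvEncoder:
    """Stride-2 3x3 conv blocks with per-exam channel normalisation and
    ReLU, a spatial max pool, and a linear projection to the bag feature."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.layers: list[nn.Layer] = []
        cin = config.in_channels
        for width in config.encoder_widths:
            self.layers.append(nn.Conv2d(cin, width, rng))
            self.layers.append(nn.BatchNorm2d(width))
            self.layers.append(nn.ReLU())
            cin = width
        pool = nn.GlobalMaxPool2d() if config.encoder_pool == "max" else nn.GlobalAvgPool2d()
        self.layers.append(pool)
        self.layers.append(nn.Linear(cin, config.feature_dim, rng))

    def forward(self, batch: np.ndarray) -> np.ndarray:
        out = batch
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def backward(self, dfeatures: np.ndarray) -> np.ndarray:
        d = dfeatures
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class MILNet:
    """Encoder -> LSTM -> per-step FC -> mean over bags -> category logits."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.encoder = SmallConvEncoder(config, rng)
        self.lstm = nn.LSTM(config.feature_dim, config.lstm_hidden, rng)
        n_out = config.n_categories + (1 if config.any_abnormal_head else 0)
        self.head = nn.Linear(config.lstm_hidden, n_out, rng)

    @property
    def layers(self) -> list[nn.Layer]:
        return [*self.encoder.layers, self.lstm, self.head]

    def forward(
        self,
        bags: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """bags: (T, C, W, H) -> logits (n_categories,)."""
        if bags.shape[0] < 1:
            raise ValueError("bag sequence must be non-empty")
        feats = self.encoder.forward(bags.astype(nn.DTYPE))
        if train and self.config.dropout > 0:
            if rng is None:
                raise ValueError("dropout requires an rng in training mode")
            keep = 1.0 - self.config.dropout
            self._drop_mask = (
                rng.random(feats.shape) < keep
            ).astype(nn.DTYPE) / keep
            feats = feats * self._drop_mask
        else:
            self._drop_mask = None
        hs = self.lstm.forward(feats)
        step_logits = self.head.forward(hs)  # (T, K)
        self._T = bags.shape[0]
        return step_logits.mean(axis=0)

    def backward(self, dlogits: np.ndarray) -> None:
        dstep = np.tile(dlogits.astype(nn.DTYPE) / self._T, (self._T, 1))
        dh = self.head.backward(dstep)
        dfeats = self.lstm.backward(dh)
        if self._drop_mask is not None:
            dfeats = dfeats * self._drop_mask
        self.encoder.backward(dfeats)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"layer{i}/{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}/{k}"]


def _as_bags(x) -> np.ndarray:
    """Accept OrganVolume / 3D array / SliceBagSequence -> (T, C, W, H)."""
    if isinstance(x, SliceBagSequence):
        bags = x.bags
    elif isinstance(x, (OrganVolume, np.ndarray)):
        bags = build_slice_bags(x).bags
    else:
        raise TypeError(f"cannot interpret {type(x)} as a bag sequence")
    return np.ascontiguousarray(bags.transpose(0, 3, 1, 2), dtype=nn.DTYPE)


class MILBagClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style multi-label slice-bag classifier for one organ.

    Parameters
    ----------
    encoder_widths : tuple of int
        Channel widths of the conv encoder blocks (one stride-2 block each).
    feature_dim, lstm_hidden : int
        Bag embedding size and LSTM hidden size.
    dropout : float
        Dropout rate on bag features during training.
    lr : float
        Base AdamW learning rate, annealed to 0 by a cosine schedule.
    epochs, batch_size : int
        Passes over the training exams and exams per optimiser step.
    threshold : float
        Decision threshold on the anomaly score for ``predict``.
    seed : int
        Seeds weight initialisation and data shuffling.

    Attributes
    ----------
    net_ : MILNet
        Trained network (best validation epoch when a validation set is
        given to ``fit``, otherwise the final epoch).
    loss_curve_ : list of float
        Mean training loss per epoch.
    val_auc_trace_ : list of float
        Per-epoch validation AUC of the organ-abnormal score (when a
        validation set is given); always ``epochs`` entries.
    best_epoch_ : int
        Epoch whose checkpoint was kept (earliest in case of AUC ties).
    """

    def __init__(
        self,
        encoder_widths: tuple[int, ...] = (8, 16, 32, 64),
        feature_dim: int = 64,
        lstm_hidden: int = 128,
        dropout: float = 0.0,
        any_abnormal_head: bool = False,
        encoder_pool: str = "max",
        lr: float = 2.3e-4,
        weight_decay: float = 1e-2,
        epochs: int = 12,
        batch_size: int = 8,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.encoder_widths = encoder_widths
        self.feature_dim = feature_dim
        self.lstm_hidden = lstm_hidden
        self.dropout = dropout
        self.any_abnormal_head = any_abnormal_head
        self.encoder_pool = encoder_pool
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed

    def _model_config(self, n_categories: int) -> ModelConfig:
        return ModelConfig(
            encoder_widths=tuple(self.encoder_widths),
            feature_dim=self.feature_dim,
            lstm_hidden=self.lstm_hidden,
            n_categories=n_categories,
            dropout=self.dropout,
            any_abnormal_head=self.any_abnormal_head,
            encoder_pool=self.encoder_pool,
        )

    def fit(self, X: Sequence, y, X_val: Sequence | None = None, y_val=None):
        """Train on bag sequences X with multi-label targets y (n, K).

        When a validation set is supplied, the per-epoch organ-abnormal
        validation AUC is traced and the best epoch's weights are restored
        at the end (argmax with earliest-epoch tie-break).
        """
        from .metrics import roc_auc

        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        bags = [_as_bags(x) for x in X]
        if len(bags) != len(y):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.seed)
        self.n_categories_ = y.shape[1]
        self.net_ = MILNet(self._model_config(self.n_categories_), rng)
        opt = nn.AdamW(
            self.net_.layers, lr=self.lr, weight_decay=self.weight_decay
        )
        val_bags = None
        if X_val is not None:
            val_bags = [_as_bags(x) for x in X_val]
            y_val = np.asarray(y_val, dtype=np.float64)
            if y_val.ndim == 1:
                y_val = y_val[:, None]
            val_abn = (y_val.max(axis=1) > 0).astype(int)
            if val_abn.min() == val_abn.max():
                raise ValueError(
                    "validation AUC undefined: single-class validation set"
                )
        self.loss_curve_ = []
        self.val_auc_trace_ = []
        best_auc, best_state, best_epoch = -np.inf, None, 0
        n = len(bags)
        for epoch in range(self.epochs):
            lr_t = nn.cosine_lr(self.lr, epoch, self.epochs)
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                opt.zero_grad()
                for i in batch:
                    logits = self.net_.forward(bags[i], train=True, rng=rng)
                    li, dz = nn.bce_with_logits(
                        logits[: self.n_categories_], y[i]
                    )
                    if self.any_abnormal_head:
                        la, dza = nn.bce_with_logits(
                            logits[self.n_categories_ :], [float(y[i].max())]
                        )
                        li, dz = li + la, np.concatenate([dz, dza])
                    total += li
                    self.net_.backward(dz / len(batch))
                opt.step(lr_t)
            self.loss_curve_.append(total / n)
            if val_bags is not None:
                scores = np.array(
                    [self._score_bags(b) for b in val_bags]
                )
                auc = roc_auc(scores, val_abn)
                self.val_auc_trace_.append(auc)
                if auc > best_auc:
                    best_auc, best_epoch = auc, epoch
                    best_state = self.net_.state_dict()
        if best_state is not None:
            self.net_.load_state_dict(best_state)
        self.best_epoch_ = best_epoch
        return self

    def _predict_one(self, bags: np.ndarray) -> np.ndarray:
        logits = self.net_.forward(bags, train=False)
        return nn.sigmoid(logits[: self.n_categories_])

    def _score_bags(self, bags: np.ndarray) -> float:
        return float(self._predict_one(bags).max())

    def predict_proba(self, X: Sequence) -> np.ndarray:
        """Per-category sigmoid probabilities, shape (n, n_categories)."""
        return np.array([self._predict_one(_as_bags(x)) for x in X])

    def anomaly_score(self, X: Sequence) -> np.ndarray:
        """Scalar organ anomaly score: max over category probabilities."""
        return self.predict_proba(X).max(axis=1)

    def predict(self, X: Sequence) -> np.ndarray:
        """Binary organ-abnormal decision at the configured threshold."""
        return (self.anomaly_score(X) >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# Functional wrappers around the estimator


def encode_bags(bags: SliceBagSequence | np.ndarray, encoder) -> np.ndarray:
    """One feature vector per bag, order preserved."""
    arr = _as_bags(bags) if not isinstance(bags, np.ndarray) or bags.ndim != 4 else bags
    if arr.shape[0] < 1:
        raise ValueError("bag sequence must be non-empty")
    return encoder.forward(arr.astype(np.float32))


def aggregate(features: np.ndarray, lstm: nn.LSTM, head: nn.Linear) -> np.ndarray:
    """LSTM over the bag sequence, per-step FC, mean over steps -> logits."""
    features = np.asarray(features, dtype=np.float32)
    if features.ndim != 2 or features.shape[0] < 1:
        raise ValueError("need a non-empty (T, feature_dim) sequence")
    return head.forward(lstm.forward(features)).mean(axis=0)


def predict_record(
    organ_volume: OrganVolume,
    model: MILBagClassifier,
    categories: Sequence[str],
) -> PredictionRecord:
    probs = model.predict_proba([organ_volume])[0]
    return PredictionRecord(
        exam_id=organ_volume.exam_id,
        organ=organ_volume.organ,
        category_probs={c: float(p) for c, p in zip(categories, probs)},
    )


def loss(logits, label_vector) -> float:
    """Mean per-category binary cross-entropy (labels must be 0/1)."""
    return nn.bce_with_logits(np.asarray(logits), np.asarray(label_vector))[0]


def save_checkpoint(model: MILBagClassifier, path: str | Path, **provenance) -> None:
    """Serialise weights (.npz) plus a JSON sidecar with config and provenance."""
    path = Path(path)
    np.savez(path, **model.net_.state_dict())
    sidecar = {
        "params": model.get_params(),
        "n_categories": model.n_categories_,
        "provenance": provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(path: str | Path) -> MILBagClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    params = sidecar["params"]
    params["encoder_widths"] = tuple(params["encoder_widths"])
    model = MILBagClassifier(**params)
    model.n_categories_ = int(sidecar["n_categories"])
    rng = np.random.default_rng(model.seed)
    model.net_ = MILNet(model._model_config(model.n_categories_), rng)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.net_.load_state_dict({k: data[k] for k in data.files})
    return model
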