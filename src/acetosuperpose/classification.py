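"""Binary A1-vs-P1B classification under an 8:2 split and 5-fold CV.

The default backbone is deliberately desk-scale: the contribution being
evaluated is the image recombination upstream, not the network. Images are
reduced to a grid of per-channel block means (average pooling), the
features are standardised, and a logistic-regression head is fit — a fully
deterministic pipeline that trains in seconds on a CPU. A ResNet50
transfer-learning backbone with the conventional hyperparameters (Adam,
batch 40, 200 epochs, learning rate 1e-4) is available behind
``backbone="resnet50_transfer"`` when torch/torchvision are installed.

Class semantics: P1B (dysplasia) is the positive/abnormal class; predicted
label = positive when the score reaches 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from . import evaluation
from .evaluation import METRIC_COLUMNS, PredictionSet
from .preprocessing import ProcessedPair, preprocess_pair
from .superposition import ChannelCombo, enumerate_superposition_cases, superpose
from .types import AnnotatedImage, POSITIVE_LABEL, ValidationError

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "split_train_test",
    "make_cv_folds",
    "train_classifier",
    "predict_scores",
    "run_comparison",
    "variant_images",
    "ALL_VARIANTS",
]

#: The eleven comparable variants: unprocessed, ROI-masked, and the nine
#: superposition cases.
ALL_VARIANTS = ["original", "mask"] + [c.name for c in enumerate_superposition_cases()]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test and cross-validation protocol parameters."""

    train_fraction: float = 0.8
    k_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError(f"train_fraction must lie in (0,1), got {self.train_fraction}")
        if self.k_folds < 2:
            raise ValidationError(f"k_folds must be >= 2, got {self.k_folds}")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "pooled_logreg"
    optimizer: str = "adam"
    batch_size: int = 40
    epochs: int = 200
    learning_rate: float = 1e-4
    pool_grid: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.backbone not in ("pooled_logreg", "resnet50_transfer"):
            raise ValidationError(f"unknown backbone {self.backbone!r}")
        for name in ("batch_size", "epochs", "pool_grid"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


def _labels_of(dataset) -> np.ndarray:
    return np.asarray([item.label for item in dataset])


def split_train_test(dataset, spec: SplitSpec):
    """Deterministic 8:2 (by default) split; stratified per class.

    Returns (train, test) lists. Per-class proportions are within one
    image of the requested fraction when stratified.
    """
    spec.validate()
    dataset = list(dataset)
    labels = _labels_of(dataset)
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")
    if spec.stratified and len(np.unique(labels)) < 2:
        raise ValidationError("stratified split requires both classes present")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]


def _cv_fold_indices(labels: np.ndarray, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    spec.validate()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < spec.k_folds:
        raise ValidationError(
            f"cross-validation needs >= {spec.k_folds} images of each class, got {dict(counts)}"
        )
    skf = StratifiedKFold(n_splits=spec.k_folds, shuffle=True, random_state=spec.seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def make_cv_folds(dataset, spec: SplitSpec):
    """Stratified k-fold partition; each image is tested exactly once."""
    dataset = list(dataset)
    folds = []
    for train_idx, test_idx in _cv_fold_indices(_labels_of(dataset), spec):
        folds.append(
            ([dataset[i] for i in train_idx], [dataset[i] for i in test_idx])
        )
    return folds


# ---------------------------------------------------------------------------
# backbone: block-pooled features + logistic head


def _pool_features(images: np.ndarray, grid: int) -> np.ndarray:
    """Per-channel block means on a grid x grid partition, scaled to [0,1]."""
    n, h, w, c = images.shape
    if h % grid or w % grid:
        raise ValidationError(f"image size {h}x{w} not divisible by pool grid {grid}")
    bh, bw = h // grid, w // grid
    pooled = images.reshape(n, grid, bh, grid, bw, c).mean(axis=(2, 4))
    return pooled.reshape(n, grid * grid * c) / 255.0


@dataclass
class PooledLogisticModel:
    """Trained block-pooling + logistic-regression classifier."""

    scaler: StandardScaler
    head: LogisticRegression
    grid: int
    input_shape: tuple[int, int, int]
    classes_: tuple[str, str] = ("A1", POSITIVE_LABEL)

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.shape[1:] != self.input_shape:
            raise ValidationError(
                f"test images have shape {images.shape[1:]}, model expects {self.input_shape}"
            )
        x = self.scaler.transform(_pool_features(images, self.grid))
        pos = list(self.head.classes_).index(POSITIVE_LABEL)
        return self.head.predict_proba(x)[:, pos]


def train_classifier(images, labels, config: TrainConfig = TrainConfig()):
    """Fit a classifier on stacked images; returns a model with predict_scores.

    ``images``: array-like of shape (N, H, W, 3); ``labels``: N class labels.
    """
    config.validate()
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.ndim != 4 or len(images) == 0:
        raise ValidationError("training set must be a nonempty (N, H, W, 3) stack")
    if len(np.unique(labels)) < 2:
        raise ValidationError("training set must contain both classes")
    if config.backbone == "resnet50_transfer":
        return _train_resnet50(images, labels, config)
    x = _pool_features(images, config.pool_grid)
    scaler = StandardScaler().fit(x)
    head = LogisticRegression(C=1.0, max_iter=5000)
    head.fit(scaler.transform(x), labels)
    return PooledLogisticModel(
        scaler=scaler, head=head, grid=config.pool_grid, input_shape=images.shape[1:]
    )


def _train_resnet50(images, labels, config: TrainConfig):
    """ImageNet-pretrained ResNet50 fine-tuned with Adam (needs torch)."""
    try:
        import torch
        from torch import nn
        from torchvision import models
    except ImportError as exc:  # pragma: no cover - torch not installed here
        raise RuntimeError(
            "backbone='resnet50_transfer' requires torch and torchvision; "
            "install the 'torch' extra or use the default pooled_logreg backbone"
        ) from exc

    torch.manual_seed(config.seed)  # pragma: no cover
    net = models.resnet50(weights=models.ResNet50_Weights.IMAGENET1K_V1)
    net.fc = nn.Linear(net.fc.in_features, 1)
    opt = torch.optim.Adam(net.parameters(), lr=config.learning_rate)
    loss_fn = nn.BCEWithLogitsLoss()
    x = torch.from_numpy(np.asarray(images)).permute(0, 3, 1, 2).float() / 255.0
    y = torch.from_numpy((np.asarray(labels) == POSITIVE_LABEL).astype(np.float32))
    net.train()
    for _ in range(config.epochs):
        perm = torch.randperm(len(x))
        for start in range(0, len(x), config.batch_size):
            sel = perm[start : start + config.batch_size]
            opt.zero_grad()
            loss = loss_fn(net(x[sel]).squeeze(1), y[sel])
            loss.backward()
            opt.step()

    class _TorchModel:
        input_shape = np.asarray(images).shape[1:]

        def predict_scores(self, imgs):
            t = torch.from_numpy(np.asarray(imgs)).permute(0, 3, 1, 2).float() / 255.0
            net.eval()
            with torch.no_grad():
                return torch.sigmoid(net(t).squeeze(1)).numpy()

    return _TorchModel()


def predict_scores(model, images, labels) -> PredictionSet:
    """Score a test set; one positive-class probability per image."""
    images = np.asarray(images)
    scores = np.clip(model.predict_scores(images), 0.0, 1.0)
    return PredictionSet(y_true=np.asarray(labels), scores=scores)


# ---------------------------------------------------------------------------
# full comparison harness


def variant_images(pairs: list[ProcessedPair], variant: str) -> np.ndarray:
    """Stack one image variant for every processed pair.

    ``variant`` is "original", "mask", or a canonical combo name such as
    "MR + OB + OR".
    """
    if variant == "original":
        return np.stack([p.original for p in pairs])
    if variant == "mask":
        return np.stack([p.mask for p in pairs])
    combo = ChannelCombo.from_name(variant)
    return np.stack([superpose(p.original, p.mask, combo) for p in pairs])


def run_comparison(
    dataset,
    variants="all",
    spec: SplitSpec = SplitSpec(),
    config: TrainConfig = TrainConfig(),
    collect_predictions: dict | None = None,
) -> pd.DataFrame:
    """k-fold CV of every requested variant; metrics averaged across folds.

    ``dataset`` is a list of :class:`AnnotatedImage` (preprocessed here) or
    ready :class:`ProcessedPair` objects. Folds are shared across variants
    (same seed), so the comparison is paired. Returns a DataFrame indexed
    by variant with columns precision, recall, f1, accuracy (percent) and
    auc (fraction). When ``collect_predictions`` is a dict, the pooled
    out-of-fold :class:`PredictionSet` of each variant is stored in it.
    """
    spec.validate()
    config.validate()
    if variants == "all":
        variants = list(ALL_VARIANTS)
    dataset = list(dataset)
    if dataset and isinstance(dataset[0], AnnotatedImage):
        pairs = [preprocess_pair(img) for img in dataset]
    else:
        pairs = dataset
    labels = _labels_of(pairs)
    folds = _cv_fold_indices(labels, spec)

    rows = {}
    for variant in variants:
        images = variant_images(pairs, variant)
        fold_metrics = []
        all_true, all_scores = [], []
        for train_idx, test_idx in folds:
            model = train_classifier(images[train_idx], labels[train_idx], config)
            preds = predict_scores(model, images[test_idx], labels[test_idx])
            cm = evaluation.confusion_counts(preds)
            m = evaluation.metrics_from_cm(cm)
            m["auc"] = evaluation.auc_from_predictions(preds)
            fold_metrics.append(m)
            all_true.append(preds.y_true)
            all_scores.append(preds.scores)
        rows[variant] = pd.DataFrame(fold_metrics).mean()
        if collect_predictions is not None:
            collect_predictions[variant] = PredictionSet(
                y_true=np.concatenate(all_true), scores=np.concatenate(all_scores)
            )
    table = pd.DataFrame(rows).T.loc[:, list(METRIC_COLUMNS)]
    table.index.name = "model"
    return table
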