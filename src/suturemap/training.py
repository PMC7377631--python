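"""Dataset assembly, transfer-learning classification, and evaluation.

The classification stage follows the transfer-learning recipe: a *fixed*
feature-extracting backbone (stand-in for a network pretrained on a large
image corpus) feeds a small dense head, and only the last layers are trained
— plain gradient descent on the softmax cross-entropy, a constant learning
rate, training accuracy logged every step and validation accuracy every few
steps.  The shipped :class:`TinyConvBackbone` is a seeded random-convolution
extractor so the whole pipeline runs on a desk CPU without downloaded
weights; any object with the same ``transform``/``checksum`` surface (e.g. a
wrapper around a real pretrained CNN) can be plugged in instead.

Dataset assembly mirrors the clinical protocol: a blind hold-out of
``holdout_per_class`` cases per subtype is removed *before* augmentation and
kept un-augmented; the remaining cases are expanded with the augmentation
recipe and the augmented images are split 3:1:1 into train/validation/test.
The default split is image-level (augments of one case may land in train and
test, as in the original protocol); ``grouped=True`` splits at case level,
which is the leakage-free alternative.

The model object follows the fit/results idiom: build a
:class:`SutureClassifier` from a :class:`DatasetSplit` and a
:class:`TrainingConfig`, call ``fit()``, and read curves, accuracies and
confusion matrices off the returned :class:`TrainingReport` (or print
``report.summary()``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.measure import block_reduce
from skimage.transform import resize
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix

from .augmentation import AugmentationRecipe, augment_case, default_recipe
from .datatypes import ProjectedImage
from .errors import DegenerateDataError, InsufficientDataError, ValidationError

__all__ = [
    "TinyConvBackbone",
    "TrainingConfig",
    "DatasetSplit",
    "TrainingReport",
    "assemble_dataset",
    "SutureClassifier",
    "train_classifier",
    "repeated_train",
    "evaluate",
    "extract_features",
    "embed_2d",
    "shuffle_split_labels",
]


class TinyConvBackbone:
    """Fixed random-convolution feature extractor (the frozen "backbone").

    Images are resized to ``input_side``², convolved with ``n_filters``
    seeded zero-mean random kernels, rectified, and mean-pooled.  The
    filters never train; :meth:`checksum` fingerprints them so tests can
    assert the backbone is untouched by fine-tuning.
    """

    def __init__(self, input_side: int = 32, n_filters: int = 8,
                 kernel: int = 3, pool: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        filters = rng.normal(0.0, 1.0, size=(n_filters, kernel, kernel))
        filters -= filters.mean(axis=(1, 2), keepdims=True)
        self.filters = filters
        self.input_side = input_side
        self.pool = pool

    @property
    def n_features(self) -> int:
        side = self.input_side // self.pool
        return self.filters.shape[0] * side * side

    def checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.filters).tobytes()).hexdigest()

    def transform(self, images: np.ndarray) -> np.ndarray:
        """(B, N, N) binary images -> (B, n_features) float features."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        b, n, _ = images.shape
        s = self.input_side
        if n != s:
            if n % s == 0:  # exact block mean keeps determinism simple
                x = block_reduce(images, (1, n // s, n // s), np.mean)
            else:
                x = resize(images, (b, s, s), order=1, mode="constant",
                           anti_aliasing=False, preserve_range=True)
        else:
            x = images
        maps = fftconvolve(x[:, None, :, :], self.filters[None, :, :, :],
                           mode="same", axes=(2, 3))
        maps = np.maximum(maps, 0.0)
        pooled = block_reduce(maps, (1, 1, self.pool, self.pool), np.mean)
        return pooled.reshape(b, -1)


@dataclass(frozen=True)
class TrainingConfig:
    """Fine-tuning hyperparameters.

    Defaults follow the reference protocol: learning rate 0.001, 7000 steps
    of plain gradient descent, head-only fine-tuning, validation every 10
    steps.  ``trainable_scope`` is ``"head"`` (last layer only) or ``"all"``
    (the two dense layers after the frozen backbone).
    """

    learning_rate: float = 0.001
    steps: int = 7000
    batch_size: int = 32
    trainable_scope: str = "head"
    hidden_units: int = 64
    validation_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.steps < 1 or self.batch_size < 1 or self.validation_every < 1:
            raise ValidationError("steps, batch_size and validation_every must be >= 1")
        if self.trainable_scope not in ("head", "all"):
            raise ValidationError("trainable_scope must be 'head' or 'all'")


@dataclass
class DatasetSplit:
    """Train/validation/test partitions of augmented images plus blind cases."""

    train_images: np.ndarray
    train_labels: np.ndarray
    val_images: np.ndarray
    val_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    blind_images: np.ndarray
    blind_labels: np.ndarray
    blind_case_ids: tuple = ()
    train_case_ids: tuple = ()
    val_case_ids: tuple = ()
    test_case_ids: tuple = ()
    ratio: tuple[int, int, int] = (3, 1, 1)
    grouped: bool = False
    seed: int = 0

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_labels), len(self.val_labels), len(self.test_labels))


def _stack(images: Sequence[ProjectedImage | np.ndarray]) -> np.ndarray:
    arrs = [im.pixels if isinstance(im, ProjectedImage) else np.asarray(im) for im in images]
    if not arrs:
        return np.zeros((0, 0, 0), dtype=np.uint8)
    return np.stack(arrs).astype(np.uint8)


def _proportional_cuts(n: int, ratio: tuple[int, int, int]) -> tuple[int, int]:
    """Cumulative-rounding allocation: every part within ±1 of exact."""
    total = sum(ratio)
    c1 = int(round(n * ratio[0] / total))
    c2 = int(round(n * (ratio[0] + ratio[1]) / total))
    return c1, c2


def assemble_dataset(
    images: Mapping,
    labels: Mapping,
    holdout_per_class: int = 2,
    recipe: AugmentationRecipe | None = None,
    ratio: tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
    grouped: bool = False,
) -> DatasetSplit:
    """Build the training protocol's dataset from per-case suture maps.

    Parameters
    ----------
    images, labels
        Maps case id -> :class:`ProjectedImage` and case id -> subtype.
        Cases labeled ``"unlabeled"`` (or absent from ``labels``) are removed.
    holdout_per_class
        Blind cases per class, excluded before augmentation (default 2).
    recipe
        Augmentation recipe for the non-blind cases (default: the fixed
        61-transform recipe).
    ratio, seed, grouped
        Split proportions over the augmented images, the RNG seed driving
        hold-out choice and shuffling, and whether to split at case level
        instead of image level.
    """
    recipe = default_recipe() if recipe is None else recipe
    labeled = {c: labels[c] for c in images if labels.get(c, "unlabeled") != "unlabeled"}
    classes = sorted(set(labeled.values()))
    rng = np.random.default_rng(seed)

    blind_ids: list = []
    train_pool: list = []
    for cls in classes:
        ids = sorted(c for c, lab in labeled.items() if lab == cls)
        if len(ids) < holdout_per_class + 1:
            raise InsufficientDataError(
                f"class {cls!r} has {len(ids)} cases; needs > {holdout_per_class}"
            )
        picked = rng.permutation(len(ids))
        blind_ids += [ids[i] for i in picked[:holdout_per_class]]
        train_pool += [ids[i] for i in picked[holdout_per_class:]]

    aug_images: list = []
    aug_labels: list = []
    aug_cases: list = []
    for cid in sorted(train_pool):
        for out in augment_case(images[cid], recipe):
            aug_images.append(out)
            aug_labels.append(labeled[cid])
            aug_cases.append(cid)
    n = len(aug_images)
    lab_arr = np.array(aug_labels)
    case_arr = np.array(aug_cases, dtype=object)

    if not grouped:
        order = rng.permutation(n)
        c1, c2 = _proportional_cuts(n, ratio)
        parts = (order[:c1], order[c1:c2], order[c2:])
    else:
        case_list = sorted(set(train_pool))
        case_order = rng.permutation(len(case_list))
        k = len(recipe)
        c1, c2 = _proportional_cuts(len(case_list) * k, ratio)
        part_cases: list[list] = [[], [], []]
        count = 0
        for ci in case_order:
            part = 0 if count < c1 else (1 if count < c2 else 2)
            part_cases[part].append(case_list[ci])
            count += k
        parts = tuple(
            np.flatnonzero(np.isin(case_arr, pc)) for pc in part_cases
        )

    stacked = _stack(aug_images)
    def take(idx):
        return stacked[idx], lab_arr[idx], tuple(case_arr[idx])

    (tr_x, tr_y, tr_c), (va_x, va_y, va_c), (te_x, te_y, te_c) = (take(p) for p in parts)
    return DatasetSplit(
        train_images=tr_x, train_labels=tr_y,
        val_images=va_x, val_labels=va_y,
        test_images=te_x, test_labels=te_y,
        blind_images=_stack([images[c] for c in blind_ids]),
        blind_labels=np.array([labeled[c] for c in blind_ids]),
        blind_case_ids=tuple(blind_ids),
        train_case_ids=tr_c, val_case_ids=va_c, test_case_ids=te_c,
        ratio=ratio, grouped=grouped, seed=seed,
    )


@dataclass
class TrainingReport:
    """Curves and final metrics of one fine-tuning run (Results object)."""

    train_accuracy: np.ndarray            # per-step, on the step's batch, in %
    validation_accuracy: list[tuple[int, float]]  # (step, %) every validation_every
    cross_entropy: np.ndarray             # per-step batch loss, natural log
    final_train_accuracy: float
    final_validation_accuracy: float
    final_test_accuracy: float
    confusion: pd.DataFrame               # rows true, columns predicted
    blind_accuracy: float | None
    blind_confusion: pd.DataFrame | None
    classes: tuple
    config: TrainingConfig

    def summary(self) -> str:
        rows = [
            ("Training (generated)", self.final_train_accuracy),
            ("Validation (generated)", self.final_validation_accuracy),
            ("Test (generated)", self.final_test_accuracy),
        ]
        if self.blind_accuracy is not None:
            rows.append(("Test (blind hold-out)", self.blind_accuracy))
        width = max(len(r[0]) for r in rows)
        lines = ["Suture-map classifier fine-tuning", "-" * (width + 10)]
        lines += [f"{name:<{width}}  {acc:6.2f}%" for name, acc in rows]
        lines += ["", "Confusion (test, rows=true):", self.confusion.to_string()]
        return "\n".join(lines)


class SutureClassifier:
    """Frozen backbone + dense head over the four subtypes.

    ``fit()`` runs plain mini-batch gradient descent on the softmax
    cross-entropy of the head (and, with ``trainable_scope="all"``, the
    hidden layer too) and returns a :class:`TrainingReport`.  Everything is
    deterministic given ``cfg.seed``.
    """

    def __init__(self, split: DatasetSplit, cfg: TrainingConfig | None = None,
                 backbone: TinyConvBackbone | None = None):
        self.split = split
        self.cfg = cfg or TrainingConfig()
        self.backbone = backbone or TinyConvBackbone(seed=0)
        self.classes = tuple(np.unique(split.train_labels))
        if len(self.classes) < 2:
            raise DegenerateDataError(
                f"training set holds {len(self.classes)} class(es); need >= 2"
            )
        self._fitted = False

    # -- internals ---------------------------------------------------------

    def _encode(self, labels: np.ndarray) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([lut[l] for l in labels])
        except KeyError as exc:
            raise ValidationError(f"label {exc} not seen in training") from exc

    def _features(self, images: np.ndarray) -> np.ndarray:
        phi = self.backbone.transform(images)
        return (phi - self._mu) / self._sd

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.maximum(x @ self._w1 + self._b1, 0.0)
        logits = h @ self._w2 + self._b2
        return h, logits

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        _, logits = self._forward(x)
        return float(100.0 * np.mean(logits.argmax(axis=1) == y))

    # -- fitting -----------------------------------------------------------

    def fit(self) -> TrainingReport:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)

        phi = self.backbone.transform(self.split.train_images)
        self._mu = phi.mean(axis=0)
        self._sd = np.maximum(phi.std(axis=0), 1e-8)
        x_tr = (phi - self._mu) / self._sd
        y_tr = self._encode(self.split.train_labels)
        x_va = self._features(self.split.val_images) if len(self.split.val_labels) else None
        y_va = self._encode(self.split.val_labels) if x_va is not None else None

        d, h, k = x_tr.shape[1], cfg.hidden_units, len(self.classes)
        self._w1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h))
        self._b1 = np.zeros(h)
        self._w2 = np.zeros((h, k))
        self._b2 = np.zeros(k)

        n = len(y_tr)
        onehot = np.eye(k)
        train_curve = np.empty(cfg.steps)
        ce_curve = np.empty(cfg.steps)
        val_curve: list[tuple[int, float]] = []
        for step in range(cfg.steps):
            batch = rng.integers(0, n, size=min(cfg.batch_size, n))
            xb, yb = x_tr[batch], y_tr[batch]
            hb, logits = self._forward(xb)
            p = self._softmax(logits)
            ce_curve[step] = float(-np.mean(np.log(p[np.arange(len(yb)), yb] + 1e-300)))
            train_curve[step] = float(100.0 * np.mean(logits.argmax(axis=1) == yb))

            dz2 = (p - onehot[yb]) / len(yb)
            gw2 = hb.T @ dz2
            gb2 = dz2.sum(axis=0)
            self._w2 -= cfg.learning_rate * gw2
            self._b2 -= cfg.learning_rate * gb2
            if cfg.trainable_scope == "all":
                dh = (dz2 @ (self._w2 + cfg.learning_rate * gw2).T) * (hb > 0)
                self._w1 -= cfg.learning_rate * (xb.T @ dh)
                self._b1 -= cfg.learning_rate * dh.sum(axis=0)

            if x_va is not None and (step + 1) % cfg.validation_every == 0:
                val_curve.append((step + 1, self._accuracy(x_va, y_va)))

        self._fitted = True
        final_train = self._accuracy(x_tr, y_tr)
        final_val = self._accuracy(x_va, y_va) if x_va is not None else float("nan")
        test_acc, conf = evaluate(self, self.split.test_images, self.split.test_labels)
        blind_acc, blind_conf = (None, None)
        if len(self.split.blind_labels):
            blind_acc, blind_conf = evaluate(
                self, self.split.blind_images, self.split.blind_labels
            )
        return TrainingReport(
            train_accuracy=train_curve,
            validation_accuracy=val_curve,
            cross_entropy=ce_curve,
            final_train_accuracy=final_train,
            final_validation_accuracy=final_val,
            final_test_accuracy=test_acc,
            confusion=conf,
            blind_accuracy=blind_acc,
            blind_confusion=blind_conf,
            classes=self.classes,
            config=cfg,
        )

    # -- inference ---------------------------------------------------------

    def _require_fit(self) -> None:
        if not self._fitted:
            raise ValidationError("call fit() before prediction")

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self._require_fit()
        _, logits = self._forward(self._features(images))
        return self._softmax(logits)

    def predict(self, images: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(images)
        return np.array(self.classes)[proba.argmax(axis=1)]

    def penultimate(self, images: np.ndarray) -> np.ndarray:
        """Activations of the last hidden (fully connected) layer."""
        self._require_fit()
        h, _ = self._forward(self._features(images))
        return h


def train_classifier(
    split: DatasetSplit,
    cfg: TrainingConfig | None = None,
    backbone: TinyConvBackbone | None = None,
) -> tuple[SutureClassifier, TrainingReport]:
    """Functional wrapper: build a classifier, fit it, return both pieces."""
    model = SutureClassifier(split, cfg, backbone)
    return model, model.fit()


def repeated_train(
    split_factory: Callable[[int], DatasetSplit],
    cfg: TrainingConfig | None = None,
    n_runs: int = 30,
    backbone: TinyConvBackbone | None = None,
) -> dict:
    """Re-split and re-fit ``n_runs`` times; average the test accuracy.

    Each run draws a fresh split (and initialisation) from a seed derived
    from ``cfg.seed``, mirroring repeated fine-tuning on small cohorts where
    a single unlucky split biases the estimate.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    cfg = cfg or TrainingConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_runs) % (2**31)
    accs = []
    for s in seeds:
        split = split_factory(int(s))
        _, report = train_classifier(split, replace(cfg, seed=int(s)), backbone)
        accs.append(report.final_test_accuracy)
    accs = np.array(accs)
    sd = float(accs.std(ddof=1)) if n_runs > 1 else 0.0
    return {"mean": float(accs.mean()), "sd": sd, "accuracies": accs.tolist()}


def evaluate(model: SutureClassifier, images: np.ndarray, labels: np.ndarray
             ) -> tuple[float, pd.DataFrame]:
    """Accuracy (percent, two decimals) and confusion matrix on labeled images.

    Accuracy is the share of images whose predicted subtype matches the
    ground truth; the confusion matrix has true classes as rows and
    predicted classes as columns, in the model's class order.
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValidationError("evaluation needs at least one image")
    preds = model.predict(images)
    acc = round(float(100.0 * np.mean(preds == labels)), 2)
    conf = confusion_matrix(labels, preds, labels=list(model.classes))
    frame = pd.DataFrame(conf, index=list(model.classes), columns=list(model.classes))
    return acc, frame


def extract_features(model: SutureClassifier, images: np.ndarray) -> np.ndarray:
    """Feature vectors from the last fully connected layer."""
    return model.penultimate(images)


def embed_2d(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """t-SNE embedding of feature vectors into 2D, deterministic given seed."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValidationError("embedding needs at least two feature vectors")
    n = features.shape[0]
    if np.allclose(features, features[0]):
        return np.zeros((n, 2))  # coincident inputs -> coincident embedding
    perplexity = float(min(30.0, max(1.0, (n - 1) / 3.0)))
    tsne = TSNE(n_components=2, random_state=int(seed), perplexity=perplexity,
                init="pca", max_iter=500)
    return tsne.fit_transform(features)


def shuffle_split_labels(split: DatasetSplit, seed: int = 0) -> DatasetSplit:
    """Label-permutation null: shuffle train/validation labels, keep the rest."""
    rng = np.random.default_rng(seed)
    out = replace(split)
    out.train_labels = split.train_labels[rng.permutation(len(split.train_labels))]
    out.val_labels = split.val_labels[rng.permutation(len(split.val_labels))]
    return out
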