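"""Training, resumption, prediction, and evaluation for the human-in-the-loop
classifier.

The workflow the module supports: label a few items, ``fit`` a model, ``predict``
the unlabeled pool, stage the predictions on the project for review, correct
mislabels with :meth:`pixikit.project.Project.assign`, then call ``fit`` again —
training resumes from the stored weights *and* optimizer state rather than
restarting, now on the expanded label set.  :func:`hitl_round` packages one such
iteration.

One seed drives everything: the train/validation split, weight initialization,
and per-epoch batch shuffling (each epoch reseeds from (seed, epoch index), so
fit(a) followed by fit(b) shuffles identically to fit(a+b)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import train_test_split

from ..errors import ValidationError
from ..project import (
    IMAGE_KIND,
    ImageItem,
    Partition,
    Project,
    Split,
    UNKNOWN_CATEGORY_NAME,
)
from .layers import (
    Conv2D,
    Dense,
    GlobalAvgPool,
    MaxPool2,
    Network,
    ReLU,
    cross_entropy,
    softmax,
)

REGISTERED_LOSSES = ("categorical_crossentropy",)


@dataclass(frozen=True)
class ClassifierConfig:
    architecture: str = "simple_cnn"  # or "transfer_head"
    input_extent: tuple[int, int, int] = (32, 32, 1)  # (height, width, channels)
    loss_name: str = "categorical_crossentropy"
    learning_rate: float = 0.05
    epochs: int = 10
    batch_size: int = 16
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be strictly between 0 and 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.loss_name not in REGISTERED_LOSSES:
            raise ValidationError(f"unknown loss {self.loss_name!r}")
        if self.architecture not in ("simple_cnn", "transfer_head"):
            raise ValidationError(f"unknown architecture {self.architecture!r}")


@dataclass
class TrainingState:
    """Weights + optimizer state + history; everything needed to resume."""

    network: Network
    config: ClassifierConfig
    class_names: Optional[tuple[str, ...]] = None
    epochs_completed: int = 0
    optimizer_state: dict[str, np.ndarray] = field(default_factory=dict)
    history: list[dict[str, float]] = field(default_factory=list)


@dataclass
class EvaluationReport:
    class_names: tuple[str, ...]
    confusion_matrix: np.ndarray  # rows = true class, cols = predicted
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float


def build_model(
    config: ClassifierConfig,
    n_classes: int,
    class_names: Optional[Sequence[str]] = None,
) -> TrainingState:
    """Untrained model: conv stack -> global average pool -> dense softmax.

    ``simple_cnn`` trains every layer; ``transfer_head`` freezes the
    convolutional feature extractor (a stand-in for a pretrained backbone;
    any layer stack can be substituted) and trains only the final dense layer.
    """
    if n_classes < 2:
        raise ValidationError("a classifier needs at least 2 classes")
    if class_names is not None and len(class_names) != n_classes:
        raise ValidationError("class_names length must equal n_classes")
    h, w, c = config.input_extent
    rng = np.random.default_rng(config.seed)
    conv1 = Conv2D("conv1", c, 8, 3, rng)
    conv2 = Conv2D("conv2", 8, 16, 3, rng)
    head = Dense("head", 16, n_classes, rng)
    layers = [conv1, ReLU("relu1"), MaxPool2("pool1"),
              conv2, ReLU("relu2"), MaxPool2("pool2"),
              GlobalAvgPool("gap"), head]
    if config.architecture == "transfer_head":
        for layer in (conv1, conv2):
            layer.trainable = False
    return TrainingState(
        network=Network(layers),
        config=config,
        class_names=tuple(class_names) if class_names is not None else None,
    )


# --------------------------------------------------------------------------
# input preparation


def prepare_inputs(
    items: Sequence, input_extent: tuple[int, int, int]
) -> np.ndarray:
    """Standardize items to an (n, channels, height, width) batch.

    Accepts ImageItem objects (first z-plane), (c, y, x)/(y, x) arrays, or
    pre-batched arrays.  Each image is bilinearly resized to the configured
    extent and min-max scaled to [0, 1]; if the model expects one channel and
    the image has several, channels are averaged.
    """
    h, w, c = input_extent
    out = np.empty((len(items), c, h, w))
    for i, item in enumerate(items):
        if isinstance(item, ImageItem):
            arr = item.pixels[0]  # (c, y, x)
        else:
            arr = np.asarray(item, dtype=float)
            if arr.ndim == 2:
                arr = arr[None]
        if arr.shape[0] != c:
            if c == 1:
                arr = arr.mean(axis=0, keepdims=True)
            else:
                raise ValidationError(
                    f"item has {arr.shape[0]} channels, model expects {c}"
                )
        arr = resize(arr, (c, h, w), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        lo, hi = arr.min(), arr.max()
        out[i] = (arr - lo) / (hi - lo) if hi > lo else 0.0
    return out


def split_train_val(
    item_ids: Sequence[str],
    labels: Sequence[str],
    train_fraction: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Deterministic, stratified-where-possible train/validation split."""
    if len(item_ids) < 2:
        raise ValidationError("need at least 2 labeled items to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must leave both sides nonempty")
    labels = list(labels)
    _, counts = np.unique(labels, return_counts=True)
    stratify = labels if counts.min() >= 2 else None
    if stratify is None:
        warnings.warn(
            "a class has a single item; falling back to unstratified split",
            stacklevel=2,
        )
    train_ids, val_ids = train_test_split(
        list(item_ids),
        train_size=train_fraction,
        random_state=seed,
        stratify=stratify,
        shuffle=True,
    )
    return list(train_ids), list(val_ids)


# --------------------------------------------------------------------------
# optimization (SGD with momentum; velocity is the serialized optimizer state)

_MOMENTUM = 0.9


def _sgd_step(state: TrainingState) -> None:
    lr = state.config.learning_rate
    for name, layer, pname, arr in state.network.named_params():
        if not layer.trainable:
            continue
        g = layer.grads[pname]
        v = state.optimizer_state.get(name)
        if v is None:
            v = np.zeros_like(arr)
        v = _MOMENTUM * v - lr * g
        state.optimizer_state[name] = v
        layer.params[pname] = arr + v


def _encode_labels(labels: Sequence[str], class_names: Sequence[str]) -> np.ndarray:
    index = {name: i for i, name in enumerate(class_names)}
    try:
        return np.asarray([index[lab] for lab in labels])
    except KeyError as err:
        raise ValidationError(f"label {err.args[0]!r} not in class_names") from None


def fit(
    state: TrainingState,
    items: Sequence,
    labels: Sequence[str],
    additional_epochs: Optional[int] = None,
) -> TrainingState:
    """Train for ``additional_epochs`` more epochs, resuming where left off.

    Weights, optimizer velocity, and the epoch counter all carry across calls;
    the train/validation split is re-derived from the config seed so resumed
    runs train on a superset of the previous training set when labels grew.
    """
    cfg = state.config
    n_epochs = cfg.epochs if additional_epochs is None else int(additional_epochs)
    labels = list(labels)
    if len(items) != len(labels):
        raise ValidationError("items and labels must align")
    if any(lab == UNKNOWN_CATEGORY_NAME for lab in labels):
        raise ValidationError('items labeled "Unknown" cannot enter training')
    present = sorted(set(labels))
    if len(present) < 2:
        raise ValidationError("training needs at least 2 distinct labels")
    if state.class_names is None:
        state.class_names = tuple(present)
    if not set(present) <= set(state.class_names):
        raise ValidationError(
            f"labels {sorted(set(present) - set(state.class_names))} "
            "outside the model's class set"
        )

    x = prepare_inputs(items, cfg.input_extent)
    y = _encode_labels(labels, state.class_names)
    idx = np.arange(len(labels))
    tr, va = split_train_val(idx, labels, cfg.train_fraction, cfg.seed)
    tr = np.asarray(tr)
    va = np.asarray(va)

    for _ in range(n_epochs):
        rng = np.random.default_rng([cfg.seed, state.epochs_completed])
        order = rng.permutation(len(tr))
        losses, accs = [], []
        for start in range(0, len(tr), cfg.batch_size):
            batch = tr[order[start : start + cfg.batch_size]]
            probs = state.network.predict_proba(x[batch])
            losses.append(cross_entropy(probs, y[batch]) * len(batch))
            accs.append((probs.argmax(axis=1) == y[batch]).sum())
            state.network.backward_from_probs(probs, y[batch])
            _sgd_step(state)
        val_probs = state.network.predict_proba(x[va])
        state.history.append(
            {
                "train_loss": float(np.sum(losses) / len(tr)),
                "train_accuracy": float(np.sum(accs) / len(tr)),
                "val_loss": cross_entropy(val_probs, y[va]),
                "val_accuracy": float((val_probs.argmax(axis=1) == y[va]).mean()),
            }
        )
        state.epochs_completed += 1
    return state


def predict(
    state: TrainingState, items: Sequence, batch_size: int = 64
) -> tuple[list[str], np.ndarray]:
    """Predicted category per item plus the full probability matrix."""
    if state.epochs_completed < 1:
        raise ValidationError("model has not been trained")
    x = prepare_inputs(items, state.config.input_extent)
    probs = np.vstack(
        [
            state.network.predict_proba(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
    )
    names = [state.class_names[k] for k in probs.argmax(axis=1)]
    return names, probs


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_names: Sequence[str],
) -> EvaluationReport:
    """Confusion matrix and per-class precision/recall/F1 plus macro-F1."""
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValidationError("cannot evaluate an empty prediction set")
    if len(y_true) != len(y_pred):
        raise ValidationError("prediction/label lengths differ")
    cm = confusion_matrix(y_true, y_pred, labels=list(class_names))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_names), zero_division=0
    )
    return EvaluationReport(
        class_names=tuple(class_names),
        confusion_matrix=cm,
        precision=prec,
        recall=rec,
        f1=f1,
        accuracy=float(np.trace(cm) / cm.sum()),
        macro_f1=float(f1.mean()),
    )


# --------------------------------------------------------------------------
# human-in-the-loop round


def class_names_for_kind(project: Project, kind_id: str) -> tuple[str, ...]:
    """Category names of a kind in registration order, Unknown excluded."""
    kind = project.kinds()[kind_id]
    cats = project.categories()
    return tuple(
        cats[cid].name
        for cid in kind.category_ids
        if cats[cid].name != UNKNOWN_CATEGORY_NAME
    )


def hitl_round(
    project: Project,
    state: TrainingState,
    additional_epochs: Optional[int] = None,
    kind_id: str = IMAGE_KIND,
) -> tuple[TrainingState, EvaluationReport]:
    """One labeling-loop iteration: fit on labeled items, evaluate, then
    predict the unlabeled pool and stage the predictions for review.

    Corrections are ordinary :meth:`Project.assign` calls; the next round
    resumes training on the expanded labels.
    """
    if state.class_names is None:
        state.class_names = class_names_for_kind(project, kind_id)
    cats = project.categories()
    unknown_id = project.unknown_category(kind_id)
    pool = project.select_split(Split(kind_id=kind_id))
    labeled = [i for i in pool if project.get(i).category_id != unknown_id]
    unlabeled = [i for i in pool if project.get(i).category_id == unknown_id]
    if not labeled:
        raise ValidationError("no labeled items to train on")
    items = [project.get(i) for i in labeled]
    labels = [cats[project.get(i).category_id].name for i in labeled]
    fit(state, items, labels, additional_epochs)

    # evaluate on the held-out side of the configured split
    idx = np.arange(len(labeled))
    _, va = split_train_val(idx, labels, state.config.train_fraction,
                            state.config.seed)
    va_items = [items[i] for i in va]
    va_true = [labels[i] for i in va]
    va_pred, _ = predict(state, va_items)
    report = evaluate(va_true, va_pred, state.class_names)

    if unlabeled:
        pred_names, _ = predict(state, [project.get(i) for i in unlabeled])
        name_to_id = {
            cats[cid].name: cid
            for cid in project.kinds()[kind_id].category_ids
        }
        for item_id, pred in zip(unlabeled, pred_names):
            project.assign([item_id], category_id=name_to_id[pred])
    return state, report
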