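"""Training of 21-class patch coverage classifiers.

One classifier is trained per category per dataset: the input is a square RGB
patch, the output one of the 21 coverage class values {0, 5, ..., 100}.
Training follows the study protocol — mini-batch momentum SGD (learning rate
0.01, batch 32, momentum 0.9), softmax cross-entropy over the 21 classes,
validation accuracy checked every ``validation_interval`` iterations and the
weights with the highest validation accuracy kept as the model.

The backbone is pluggable.  The study-scale configuration is an
inception-style deep network with a 21-class head, fine-tuned from
natural-image pretraining on 256x256 upscaled patches; desk-scale work and
the test-suite use the shipped ``tiny`` backbone, a small MLP over pooled
colour features that trains in seconds on a CPU.  Backbones register
themselves in :data:`BACKBONES`; training, checkpoint selection and
prediction are backbone-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .patches import CLASS_VALUES, N_CLASSES, PatchDataset


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run (study defaults)."""

    learning_rate: float = 0.01
    batch_size: int = 32
    momentum: float = 0.9
    epochs: int = 500
    validation_interval: int = 1000
    seed: int = 0
    backbone: str = "tiny"
    class_values: tuple[int, ...] = CLASS_VALUES
    #: Optional hard cap on iterations (desk-scale runs); None = epochs * batches.
    max_iterations: int | None = None

    def total_iterations(self, n_samples: int) -> int:
        per_epoch = max(1, n_samples // self.batch_size)
        total = self.epochs * per_epoch
        if self.max_iterations is not None:
            total = min(total, self.max_iterations)
        return total


@dataclass
class ModelSpec:
    """Metadata of a trained model (Table-2 style naming)."""

    category: str
    training_plots: tuple[str, ...]
    name: str
    backbone: str
    best_val_accuracy: float
    best_iteration: int
    checkpoint: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    config: TrainConfig | None = None


def model_name(category: str, source: str) -> str:
    """Study naming convention: ``WC-plot 1-1`` or ``TY-group 2``."""
    return f"{category}-{source}"


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class TinyBackbone:
    """Small deterministic classifier for desk-scale runs.

    Features: the patch is mean-pooled onto a ``pool x pool`` grid of RGB
    cells (spatial colour layout) plus overall channel means; a single hidden
    ReLU layer feeds the 21-way softmax head.  Coverage class is largely a
    function of how much of the patch shows the category's colour/texture, so
    pooled colour statistics carry the signal at a fraction of the cost of a
    deep network.
    """

    input_side = 64

    def __init__(self, pool: int = 8, hidden: int = 48, seed: int = 0):
        self.pool = pool
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        n_feat = pool * pool * 3 + 3
        # He-style init for the ReLU layer, small head init
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / n_feat), (n_feat, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, 0.01, (hidden, N_CLASSES)),
            "b2": np.zeros(N_CLASSES),
        }

    # -- feature extraction -------------------------------------------------
    def features(self, patches: np.ndarray) -> np.ndarray:
        """(n, side, side, 3) uint8 -> (n, n_feat) float64 in [0, 1]."""
        if patches.ndim == 3:
            patches = patches[None]
        n, h, w, c = patches.shape
        if h != w or c != 3:
            raise ValueError(f"expected square RGB patches, got {patches.shape}")
        if h % self.pool:
            raise ValueError(f"patch side {h} not divisible by pool grid {self.pool}")
        k = h // self.pool
        x = patches.astype(np.float64) / 255.0
        pooled = x.reshape(n, self.pool, k, self.pool, k, 3).mean(axis=(2, 4))
        overall = x.mean(axis=(1, 2))
        return np.concatenate([pooled.reshape(n, -1), overall], axis=1)

    # -- forward / backward -------------------------------------------------
    def logits(self, feats: np.ndarray) -> np.ndarray:
        h = np.maximum(feats @ self.params["W1"] + self.params["b1"], 0.0)
        return h @ self.params["W2"] + self.params["b2"]

    def loss_and_grads(
        self, feats: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean softmax cross-entropy and parameter gradients for one batch."""
        W1, b1, W2, b2 = (self.params[k] for k in ("W1", "b1", "W2", "b2"))
        pre = feats @ W1 + b1
        h = np.maximum(pre, 0.0)
        logits = h @ W2 + b2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        n = len(y)
        loss = -float(np.log(p[np.arange(n), y] + 1e-300).mean())
        dlogits = p
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "W2": h.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ W2.T
        dh[pre <= 0.0] = 0.0
        grads["W1"] = feats.T @ dh
        grads["b1"] = dh.sum(axis=0)
        return loss, grads

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v).copy() for k, v in state.items()}


#: Registry of available backbones (name -> constructor taking a seed).
BACKBONES: dict[str, Callable[[int], TinyBackbone]] = {
    "tiny": lambda seed: TinyBackbone(seed=seed),
}


def make_backbone(name: str, seed: int = 0) -> TinyBackbone:
    if name not in BACKBONES:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}. "
            "Deep study-scale backbones can be added via swardcover.train.BACKBONES."
        )
    return BACKBONES[name](seed)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainLogEntry:
    iteration: int
    loss: float
    val_accuracy: float | None = None


def _accuracy(model: TinyBackbone, feats: np.ndarray, y: np.ndarray) -> float:
    pred = model.logits(feats).argmax(axis=1)
    return float((pred == y).mean())


def train(
    dataset: PatchDataset,
    val_dataset: PatchDataset,
    category: str,
    config: TrainConfig | None = None,
    name: str | None = None,
    log: list[TrainLogEntry] | None = None,
) -> ModelSpec:
    """Train one category's classifier and return the best checkpoint.

    The checkpoint with the highest validation accuracy across all validation
    events wins; ties keep the earliest iteration.  Deterministic for a fixed
    ``config.seed`` (single-threaded numpy).
    """
    config = config or TrainConfig()
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    y = dataset.class_indices(category)
    y_val = val_dataset.class_indices(category)
    for arr, which in ((y, "training"), (y_val, "validation")):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{which} labels outside class indices 0..{N_CLASSES - 1}")

    model = make_backbone(config.backbone, seed=config.seed)
    feats = model.features(dataset.images)
    feats_val = model.features(val_dataset.images)

    rng = np.random.default_rng(config.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    total = config.total_iterations(len(dataset))

    best_acc, best_iter = -1.0, -1
    best_state = model.state_dict()

    def validate(iteration: int, last_loss: float) -> None:
        nonlocal best_acc, best_iter, best_state
        acc = _accuracy(model, feats_val, y_val)
        if log is not None:
            log.append(TrainLogEntry(iteration, last_loss, acc))
        if acc > best_acc:
            best_acc, best_iter, best_state = acc, iteration, model.state_dict()

    last_loss = float("nan")
    for it in range(1, total + 1):
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        loss, grads = model.loss_and_grads(feats[idx], y[idx])
        last_loss = loss
        for k in model.params:
            velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
            model.params[k] += velocity[k]
        if it % config.validation_interval == 0:
            validate(it, loss)
        elif log is not None:
            log.append(TrainLogEntry(it, loss))
    if total % config.validation_interval != 0:
        validate(total, last_loss)  # final weights also compete

    return ModelSpec(
        category=category,
        training_plots=dataset.source_plots,
        name=name or model_name(category, "+".join(dataset.source_plots)),
        backbone=config.backbone,
        best_val_accuracy=best_acc,
        best_iteration=best_iter,
        checkpoint=best_state,
        config=config,
    )


def load_model(spec: ModelSpec) -> TinyBackbone:
    """Materialize the backbone carrying a spec's checkpoint weights."""
    seed = spec.config.seed if spec.config else 0
    model = make_backbone(spec.backbone, seed=seed)
    model.load_state_dict(spec.checkpoint)
    return model


def predict_class_value(spec: ModelSpec, patches: np.ndarray) -> np.ndarray:
    """Predicted class value(s) in {0, 5, ..., 100} for patch(es).

    Accepts one ``(side, side, 3)`` patch or a batch ``(n, side, side, 3)``;
    returns a scalar array or a length-n vector.  Argmax ties resolve to the
    lowest class index (numpy argmax takes the first maximum).
    """
    model = load_model(spec)
    single = patches.ndim == 3
    feats = model.features(patches)
    idx = model.logits(feats).argmax(axis=1)
    values = np.asarray(CLASS_VALUES)[idx]
    return values[0] if single else values


# ---------------------------------------------------------------------------
# Checkpoint persistence
# ---------------------------------------------------------------------------

def save_model(spec: ModelSpec, out_dir: str | Path) -> Path:
    """Write checkpoint (.npz) plus a JSON sidecar with the spec metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = spec.name.replace(" ", "_")
    np.savez(out / f"{stem}.npz", **spec.checkpoint)
    meta = {
        "category": spec.category,
        "training_plots": list(spec.training_plots),
        "name": spec.name,
        "backbone": spec.backbone,
        "best_val_accuracy": spec.best_val_accuracy,
        "best_iteration": spec.best_iteration,
        "config": asdict(spec.config) if spec.config else None,
    }
    path = out / f"{stem}.json"
    path.write_text(json.dumps(meta, indent=2))
    return path


def load_model_spec(meta_path: str | Path) -> ModelSpec:
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    ckpt_path = meta_path.with_suffix(".npz")
    with np.load(ckpt_path) as z:
        checkpoint = {k: z[k].copy() for k in z.files}
    cfg = meta.get("config")
    if cfg:
        cfg["class_values"] = tuple(cfg.get("class_values", CLASS_VALUES))
        config = TrainConfig(**cfg)
    else:
        config = None
    return ModelSpec(
        category=meta["category"],
        training_plots=tuple(meta["training_plots"]),
        name=meta["name"],
        backbone=meta["backbone"],
        best_val_accuracy=meta["best_val_accuracy"],
        best_iteration=meta["best_iteration"],
        checkpoint=checkpoint,
        config=config,
    )


def select_best_checkpoint(accuracies: Sequence[float]) -> int:
    """Index of the best validation event (highest accuracy, earliest wins)."""
    if not accuracies:
        raise ValueError("no validation events")
    arr = np.asarray(accuracies, dtype=float)
    return int(arr.argmax())
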