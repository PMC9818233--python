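"""Imbalance-aware training loop.

The loss is the class-weighted binary cross-entropy: for a batch X with
per-class weights eta_c = 1 - |X_c|/|X|, the minimized quantity is

    l = -(1/|X|) sum_x eta_{i(x)} [ y ln p + (1 - y) ln(1 - p) ]

with p the predicted PVC probability clamped to [1e-7, 1 - 1e-7].  The
rarer class gets the larger weight, so PVC beats contribute to the loss on
a par with normal beats despite the imbalance.  Batches are drawn by a
weighted random sampler (item weight inversely proportional to class
frequency, draws with replacement) so each class is equally represented
in expectation; on-the-fly affine augmentation jitters each drawn image
without ever persisting it.  Optimization is Adam at an initial learning
rate of 0.001 with batch size 32; the learning rate is cut by 10x when the
validation loss fails to improve for 5 successive epochs, and training
halts when it fails to improve for 8 successive epochs (best-validation
weights restored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .beats import BeatImage
from .nn import Adam, ResNetModel, softmax

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-7


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------


@dataclass
class BeatDataset:
    """Beat images ready for the classifier.

    images: (N, 3, H, W) float32 in [0, 1]; labels: (N,) int, 0 = NORMAL,
    1 = PVC; subjects: (N,) array of subject ids.
    """

    images: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.images) == len(self.labels) == len(self.subjects)):
            raise ValueError("images, labels and subjects must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def subject_ids(self) -> set[str]:
        return set(map(str, np.unique(self.subjects)))

    def subset(self, idx: np.ndarray) -> "BeatDataset":
        return BeatDataset(self.images[idx], self.labels[idx], self.subjects[idx])

    @staticmethod
    def concatenate(parts: list["BeatDataset"]) -> "BeatDataset":
        return BeatDataset(
            np.concatenate([p.images for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subjects for p in parts]),
        )


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------


def class_weights(batch_labels: np.ndarray) -> np.ndarray:
    """Per-class weights eta_c = 1 - |X_c| / |X| for classes (0, 1)."""
    y = np.asarray(batch_labels)
    if y.size == 0:
        raise ValueError("batch must be non-empty")
    n = y.size
    return np.array([1.0 - np.sum(y == 0) / n, 1.0 - np.sum(y == 1) / n])


def weighted_bce(
    y_out: np.ndarray,
    y_true: np.ndarray,
    eta: np.ndarray,
    return_grad: bool = False,
):
    """Weighted binary cross-entropy, batch-mean reduction.

    y_out are predicted PVC probabilities, y_true 0/1 labels, eta the
    per-class weight pair indexed by label.  Returns the scalar loss, and
    optionally d loss / d y_out (computed at the clamped probabilities).
    """
    p = np.asarray(y_out, dtype=np.float64)
    y = np.asarray(y_true, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    pc = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    w = np.asarray(eta, dtype=np.float64)[y.astype(int)]
    n = p.size
    loss = -np.sum(w * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))) / n
    if not return_grad:
        return float(loss)
    grad = -w * (y / pc - (1.0 - y) / (1.0 - pc)) / n
    return float(loss), grad


# --------------------------------------------------------------------------
# sampler
# --------------------------------------------------------------------------


def make_weighted_sampler(labels: np.ndarray, seed: int):
    """Inverse-class-frequency sampling weights plus a draw procedure.

    Returns (weights, draw) where draw(n) yields n indices sampled with
    replacement; the expected per-class frequency is 1/2 each.
    """
    y = np.asarray(labels)
    counts = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=np.float64)
    for c, name in ((0, "NORMAL"), (1, "PVC")):
        if counts[c] == 0:
            raise ValueError(f"cannot build a weighted sampler: no {name} items")
    weights = 1.0 / counts[y.astype(int)]
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)

    def draw(n: int) -> np.ndarray:
        return rng.choice(y.size, size=n, replace=True, p=probs)

    return weights, draw


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentConfig:
    enabled: bool = True
    max_translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.95, 1.05)
    max_rotate_deg: float = 5.0


def _augment_chw(
    chw: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random small affine jitter of one (C, H, W) image (no flips: time
    reversal would alter beat semantics)."""
    if not cfg.enabled:
        return chw
    h, w = chw.shape[1:]
    theta = np.deg2rad(rng.uniform(-cfg.max_rotate_deg, cfg.max_rotate_deg))
    scale = rng.uniform(*cfg.scale_range)
    tr = rng.uniform(-cfg.max_translate_frac, cfg.max_translate_frac, 2) * (h, w)
    c, s = np.cos(theta), np.sin(theta)
    mat = np.array([[c, -s], [s, c]]) / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ (center + tr)
    out = np.empty_like(chw)
    for ch in range(chw.shape[0]):
        out[ch] = ndimage.affine_transform(
            chw[ch], mat, offset=offset, order=1, mode="nearest"
        )
    return out


def augment(
    image: BeatImage, cfg: AugmentConfig, rng: np.random.Generator
) -> BeatImage:
    """Augmented copy of a beat image; identity when augmentation is disabled."""
    if not cfg.enabled:
        return BeatImage(image.pixels.copy(), image.height, image.width, image.source)
    chw = np.transpose(image.pixels, (2, 0, 1)).astype(np.float64)
    aug = _augment_chw(chw, cfg, rng)
    pixels = np.clip(np.round(np.transpose(aug, (1, 2, 0))), 0, 255).astype(np.uint8)
    return BeatImage(pixels, image.height, image.width, image.source)


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    early_stop_patience: int = 8
    validation_fraction: float = 0.10
    seed: int = 0
    augmentation: AugmentConfig = field(default_factory=lambda: AugmentConfig(enabled=False))
    sampler: str = "weighted"  # weighted | uniform
    min_delta: float = 1e-6    # "remains the same" tolerance
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.sampler not in {"weighted", "uniform"}:
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""


class PlateauEarlyStop:
    """Reduce-on-plateau plus early stopping, driven by the validation loss.

    An epoch "improves" when the loss drops below the best seen by more
    than ``min_delta``.  After ``plateau_patience`` successive
    non-improving epochs the learning rate is multiplied by ``factor``
    (and the plateau counter resets); after ``early_stop_patience``
    successive non-improving epochs training stops.
    """

    def __init__(
        self,
        plateau_patience: int = 5,
        early_stop_patience: int = 8,
        factor: float = 0.1,
        min_delta: float = 1e-6,
    ) -> None:
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.since_improve = 0
        self.since_plateau = 0

    def update(self, val_loss: float) -> tuple[bool, bool]:
        """Returns (reduce_lr_now, stop_now) for this epoch's validation loss."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.since_improve = 0
            self.since_plateau = 0
            return False, False
        self.since_improve += 1
        self.since_plateau += 1
        reduce_lr = self.since_plateau >= self.plateau_patience
        if reduce_lr:
            self.since_plateau = 0
        return reduce_lr, self.since_improve >= self.early_stop_patience


def replay_validation_trace(
    val_losses: list[float], cfg: TrainConfig | None = None
) -> TrainHistory:
    """Run the scheduler/early-stop state machine over a given loss trace.

    Epochs are 1-based; the history records the epoch at which training
    would halt and the learning-rate trajectory.
    """
    cfg = cfg or TrainConfig()
    ctl = PlateauEarlyStop(
        cfg.plateau_patience, cfg.early_stop_patience, cfg.plateau_factor, cfg.min_delta
    )
    hist = TrainHistory()
    lr = cfg.learning_rate
    for epoch, v in enumerate(val_losses, start=1):
        reduce_lr, stop = ctl.update(float(v))
        if reduce_lr:
            lr *= cfg.plateau_factor
        hist.val_loss.append(float(v))
        hist.learning_rate.append(lr)
        hist.stop_epoch = epoch
        if stop:
            hist.stop_reason = "early_stop"
            return hist
        if epoch >= cfg.max_epochs:
            break
    hist.stop_reason = "max_epochs"
    return hist


# --------------------------------------------------------------------------
# fit
# --------------------------------------------------------------------------


def _batch_loss_and_grad(model: ResNetModel, images: np.ndarray, labels: np.ndarray):
    logits = model.forward(images)
    probs = softmax(logits)
    p1 = probs[:, 1]
    eta = class_weights(labels)
    if np.any(eta == 0.0):  # single-class batch: eta would zero the gradient
        logger.warning("single-class batch encountered; using unweighted BCE")
        eta = np.ones(2)
    loss, dldp = weighted_bce(p1, labels, eta, return_grad=True)
    gz = np.zeros_like(logits)
    dp1 = p1 * (1.0 - p1)  # softmax pair Jacobian
    gz[:, 1] = dldp * dp1
    gz[:, 0] = -gz[:, 1]
    return loss, gz


def _dataset_loss(model: ResNetModel, ds: BeatDataset, batch_size: int = 64) -> float:
    probs = model.predict_proba(ds.images, batch_size=batch_size)[:, 1]
    eta = class_weights(ds.labels)
    if np.any(eta == 0.0):
        eta = np.ones(2)
    return weighted_bce(probs, ds.labels, eta)


def fit(
    model: ResNetModel,
    dataset: BeatDataset,
    cfg: TrainConfig,
    eval_subjects: set[str] | None = None,
) -> tuple[ResNetModel, TrainHistory]:
    """Fine-tune ``model`` on ``dataset`` under the training protocol.

    ``eval_subjects`` is the id set of any evaluation data; training
    refuses to proceed on overlap (patient-specific leakage guard).  A
    random 10 % of the items is held out for validation.  Returns the
    model with its best-validation-loss weights restored, plus the
    per-epoch history.
    """
    if len(dataset) == 0:
        raise ValueError("empty training set")
    if eval_subjects:
        overlap = dataset.subject_ids & set(eval_subjects)
        if overlap:
            raise ValueError(
                f"training subjects overlap evaluation subjects: {sorted(overlap)}"
            )

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(dataset))
    n_val = max(1, int(round(cfg.validation_fraction * len(dataset))))
    val_ds = dataset.subset(perm[:n_val])
    train_ds = dataset.subset(perm[n_val:])
    if len(train_ds) == 0:
        raise ValueError("validation split left no training items")

    if cfg.sampler == "weighted":
        _, draw = make_weighted_sampler(train_ds.labels, seed=int(rng.integers(2**31)))
    else:
        draw_rng = np.random.default_rng(int(rng.integers(2**31)))

        def draw(n: int) -> np.ndarray:
            return draw_rng.permutation(len(train_ds))[:n]

    params = (
        model.head.params() if cfg.freeze_backbone else model.params()
    )
    opt = Adam(params, lr=cfg.learning_rate)
    ctl = PlateauEarlyStop(
        cfg.plateau_patience, cfg.early_stop_patience, cfg.plateau_factor, cfg.min_delta
    )
    hist = TrainHistory()
    aug_rng = np.random.default_rng(int(rng.integers(2**31)))
    best_state = model.capture_state()

    for epoch in range(1, cfg.max_epochs + 1):
        model.set_training(True)
        order = draw(len(train_ds))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            images = train_ds.images[idx].astype(np.float64)
            if cfg.augmentation.enabled:
                images = np.stack(
                    [_augment_chw(im, cfg.augmentation, aug_rng) for im in images]
                )
            loss, gz = _batch_loss_and_grad(model, images, train_ds.labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            opt.zero_grad()
            model.backward(gz)
            opt.step()
            epoch_losses.append(loss)

        # recalibrate batch-norm running statistics at the current weights
        # before eval-mode validation (precise-BN)
        model.recalibrate_batchnorm(train_ds.images, batch_size=cfg.batch_size)
        val_loss = _dataset_loss(model, val_ds)
        improved = val_loss < ctl.best - ctl.min_delta
        reduce_lr, stop = ctl.update(val_loss)
        if improved:
            best_state = model.capture_state()
        if reduce_lr:
            opt.lr *= cfg.plateau_factor
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.val_loss.append(float(val_loss))
        hist.learning_rate.append(opt.lr)
        hist.stop_epoch = epoch
        if stop:
            hist.stop_reason = "early_stop"
            break
    else:
        hist.stop_reason = "max_epochs"

    model.restore_state(best_state)
    model.set_training(False)
    return model, hist
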