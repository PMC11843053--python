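"""Local training, inference and metrics for the segmentation network.

This is the "train" payload that every data station executes: take the
incoming global :class:`~fedseg.weights.WeightSet`, run a fixed number of
minibatch gradient updates (Adam on soft-Dice or BCE+Dice loss) on the
local phantom cases, and return the updated weights tagged with the local
sample count for sample-weighted federated averaging.

Steps are *minibatch updates* throughout.  In deterministic mode (plain
NumPy, single thread, seeded batch sampling) the mapping
``(weights, data, config, steps, seed) -> weights`` is a pure function
and bit-reproducible, which the federation-level equivalence tests rely
on.

Images are standardised per image (zero mean, unit variance) before they
enter the network, so that per-site additive intensity offsets — the
phantom generator's stand-in for scanner heterogeneity — do not move the
input distribution between stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, WeightCompatibilityError
from .unet import ModelConfig, UNet2D
from .weights import WeightMeta, WeightSet

_SMOOTH = 1.0  # soft-Dice smoothing; also defines the all-empty limit = 1


@dataclass
class TrainMetrics:
    """Per-station, per-iteration record mirrored into the federation history.

    ``val_dice_global`` scores the *incoming averaged* model on the local
    validation sample (computed before local training starts);
    ``val_dice_local`` scores the freshly trained local model.  Either is
    ``None`` when not yet computed.
    """

    station_id: str
    iteration: int
    steps_run: int
    mean_train_loss: float | None
    val_dice_global: float | None = None
    val_dice_local: float | None = None

    def as_dict(self) -> dict:
        return {
            "station_id": self.station_id,
            "iteration": int(self.iteration),
            "steps_run": int(self.steps_run),
            "mean_train_loss": self.mean_train_loss,
            "val_dice_global": self.val_dice_global,
            "val_dice_local": self.val_dice_local,
        }


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance normalisation (float32)."""
    x = np.asarray(image, dtype=np.float32)
    sd = float(x.std())
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _loss_and_dlogits(logits: np.ndarray, targets: np.ndarray, loss_name: str):
    """Soft-Dice (optionally + BCE) over the whole batch; returns
    (scalar loss, d loss / d logits)."""
    dtype = logits.dtype
    p = sigmoid(logits)
    t = targets.astype(dtype)
    inter = float((p * t).sum())
    psum = float(p.sum())
    tsum = float(t.sum())
    num = 2.0 * inter + _SMOOTH
    den = psum + tsum + _SMOOTH
    dice_loss = 1.0 - num / den
    # d dice_loss / d p_i = -(2 t_i den - num) / den^2
    dp = -(2.0 * t * den - num) / (den * den)
    if loss_name == "bce_dice":
        eps = 1e-7
        pc = np.clip(p, eps, 1.0 - eps)
        bce = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
        loss = dice_loss + bce
        dlogits = dp * p * (1.0 - p) + (p - t) / p.size
    else:
        loss = dice_loss
        dlogits = dp * p * (1.0 - p)
    return loss, dlogits.astype(dtype)


class AdamState:
    """Plain Adam; state is created fresh for every ``train_local`` call."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * np.square(g)
            params[k] -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# model_core operations
# ---------------------------------------------------------------------------

def init_weights(config: ModelConfig, seed: int, task_id: str = "") -> WeightSet:
    """Deterministic He-normal initialisation of the U-Net as a WeightSet.

    The result carries ``iteration=0`` and ``origin="SAS"``: in the
    federation it is the aggregation server that creates and broadcasts
    the common starting model.
    """
    net = UNet2D(config)
    params = net.init_params(seed)
    entries = [(name, params[name]) for name, _ in net.param_shapes()]
    return WeightSet(entries, WeightMeta(task_id=task_id, iteration=0, origin="SAS"))


def _check_manifest(net: UNet2D, w: WeightSet) -> None:
    expected = tuple((n, tuple(s)) for n, s in net.param_shapes())
    if w.manifest() != expected:
        raise WeightCompatibilityError(
            "weight manifest does not match the configured architecture"
        )


def _case_arrays(cases) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([standardize_image(c.image) for c in cases])[:, None]
    masks = np.stack([np.asarray(c.mask, dtype=np.float32) for c in cases])[:, None]
    return imgs, masks


def train_local_with_history(
    start: WeightSet,
    train_cases,
    config: ModelConfig,
    steps: int,
    seed: int,
) -> tuple[WeightSet, list[float]]:
    """Like :func:`train_local`, but returns the full per-step loss curve."""
    if steps < 0:
        raise ConfigurationError("steps must be >= 0")
    net = UNet2D(config)
    _check_manifest(net, start)
    if steps == 0:
        out = start.copy(n_train_samples=len(train_cases))
        return out, []
    if not train_cases:
        raise DataError("cannot train: empty training set with steps > 0")

    imgs, masks = _case_arrays(train_cases)
    params = {name: v.copy() for name, v in start.entries}
    opt = AdamState(params, lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    n = len(train_cases)
    bs = min(config.batch_size, n)
    losses = []
    for _ in range(steps):
        idx = rng.choice(n, size=bs, replace=n < bs)
        logits, cache = net.forward(params, imgs[idx])
        loss, dlogits = _loss_and_dlogits(logits, masks[idx], config.loss_name)
        grads = net.backward(params, cache, dlogits)
        opt.step(params, grads)
        losses.append(loss)
    entries = [(name, params[name]) for name, _ in net.param_shapes()]
    meta = WeightMeta(
        task_id=start.meta.task_id,
        iteration=start.meta.iteration,
        origin=start.meta.origin,
        n_train_samples=n,
    )
    return WeightSet(entries, meta), losses


def train_local(
    start: WeightSet,
    train_cases,
    config: ModelConfig,
    steps: int,
    seed: int,
) -> tuple[WeightSet, float | None]:
    """Run ``steps`` minibatch Adam updates from ``start``; return the new
    weights (``meta.n_train_samples = len(train_cases)``) and the mean
    training loss over the run (``None`` when ``steps == 0``)."""
    weights, losses = train_local_with_history(start, train_cases, config, steps, seed)
    return weights, (float(np.mean(losses)) if losses else None)


def predict_proba(weights: WeightSet, image: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Per-pixel tumour probability map for a single image."""
    net = UNet2D(config)
    _check_manifest(net, weights)
    img = np.asarray(image)
    if img.shape != tuple(config.input_shape):
        raise DataError(
            f"image shape {img.shape} != configured input shape {config.input_shape}"
        )
    x = standardize_image(img)[None, None]
    logits, _ = net.forward(weights.as_dict(), x)
    return sigmoid(logits)[0, 0]


def predict_mask(
    weights: WeightSet,
    image: np.ndarray,
    config: ModelConfig,
    threshold: float = 0.5,
) -> np.ndarray:
    """Thresholded binary tumour mask (uint8 {0,1}), same shape as input."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError("threshold must lie strictly between 0 and 1")
    proba = predict_proba(weights, image, config)
    return (proba > threshold).astype(np.uint8)


def dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both-empty masks score 1.0."""
    a = np.asarray(pred)
    b = np.asarray(truth)
    if a.shape != b.shape:
        raise DataError(f"mask shapes differ: {a.shape} vs {b.shape}")
    for m in (a, b):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise DataError("masks must be binary (values in {0,1})")
    a = a.astype(bool)
    b = b.astype(bool)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / total


def mean_validation_dice(
    weights: WeightSet,
    cases,
    config: ModelConfig,
    threshold: float = 0.5,
) -> float:
    """Mean Dice of thresholded predictions over a list of phantom cases."""
    if not cases:
        raise DataError("validation set is empty")
    scores = [
        dice_score(predict_mask(weights, c.image, config, threshold), c.mask)
        for c in cases
    ]
    return float(np.mean(scores))


def derive_seed(*parts: int) -> int:
    """Fold integer parts into one 31-bit seed, stably across runs."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
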