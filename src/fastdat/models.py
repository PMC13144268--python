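"""U-Net depth family (L1-L5), training loop, and classical filter baselines.

The restoration task maps a 5-slice short-time (single-cycle) input window to
the matching long-time (5-cycle) slice.  Training minimises pixel-wise MSE
with Adam for 200 epochs at batch size 8; the learning rate steps from 1e-3
to 1e-5 strictly after epoch 150.  Gaussian and bilateral filters of the
centre input slice serve as non-learned baselines, and a string-keyed
registry makes further architectures pluggable.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .nn import Adam, UNet, mse_loss

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "TrainedModel",
    "build_unet",
    "lr_schedule",
    "train",
    "predict",
    "gaussian_baseline",
    "bilateral_baseline",
    "MODEL_REGISTRY",
    "save_checkpoint",
    "load_checkpoint",
]

FILTER_SCHEDULES = {d: tuple(16 * 2**i for i in range(d)) for d in range(1, 6)}


@dataclass(frozen=True)
class UNetConfig:
    depth: int
    filters_per_level: tuple[int, ...]
    in_channels: int = 5
    out_channels: int = 1
    conv_kernel: int = 3
    pool_factor: int = 2

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 5:
            raise ValueError(f"depth must be in 1..5, got {self.depth}")
        if tuple(self.filters_per_level) != FILTER_SCHEDULES[self.depth]:
            raise ValueError(
                f"filter schedule for depth {self.depth} must be {FILTER_SCHEDULES[self.depth]}"
            )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr_initial: float = 1.0e-3
    lr_late: float = 1.0e-5
    lr_switch_epoch: int = 150
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.lr_initial <= 0 or self.lr_late <= 0:
            raise ValueError("learning rates must be > 0")
        if self.epochs and self.lr_switch_epoch >= self.epochs:
            raise ValueError("lr_switch_epoch must be < epochs")


@dataclass
class TrainedModel:
    config: UNetConfig
    network: UNet = field(repr=False)
    history: list[dict] = field(default_factory=list)
    seed: int = 0


def build_unet(depth: int, seed: int = 0) -> TrainedModel:
    """Instantiate a U-Net of the given depth with its canonical filter widths."""
    config = UNetConfig(depth=depth, filters_per_level=FILTER_SCHEDULES.get(depth, ()))
    return TrainedModel(config=config, network=UNet(depth=depth, seed=seed), seed=seed)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step schedule: lr_initial through epoch ``lr_switch_epoch``, lr_late after."""
    if not 1 <= epoch <= max(cfg.epochs, 1):
        raise ValueError(f"epoch {epoch} outside 1..{cfg.epochs}")
    return cfg.lr_initial if epoch <= cfg.lr_switch_epoch else cfg.lr_late


def _stack_samples(samples):
    """(N, 64, 64, 5) inputs and (N, 64, 64, 1) targets, channels-last float32."""
    x = np.stack([np.moveaxis(s.input_window, 0, -1) for s in samples]).astype(np.float32)
    y = np.stack([np.moveaxis(s.target, 0, -1) for s in samples]).astype(np.float32)
    return x, y


def train(model: TrainedModel, train_samples, val_samples=(), cfg: TrainConfig | None = None,
          log=None) -> TrainedModel:
    """Train in place with MSE + Adam; deterministic given ``cfg.seed``.

    Shuffling, batching and (via ``build_unet``) initialisation all derive
    from fixed seeds.  No early stopping: the final-epoch weights are kept.
    Per-epoch mean train loss and validation loss are recorded in
    ``model.history``.
    """
    cfg = cfg or TrainConfig()
    if len(train_samples) == 0:
        raise ValueError("training set is empty")
    train_cases = {s.case_id for s in train_samples}
    if train_cases & {s.case_id for s in val_samples}:
        raise ValueError("train and validation sets must be case-disjoint")

    x_train, y_train = _stack_samples(train_samples)
    x_val, y_val = _stack_samples(val_samples) if len(val_samples) else (None, None)
    rng = np.random.default_rng(int(cfg.seed) & 0x7FFFFFFF)
    opt = Adam(model.network.params)
    model.history = []
    n = len(train_samples)
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            out, cache = model.network.forward(x_train[batch], want_cache=True)
            loss, dout = mse_loss(out, y_train[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr={lr}); "
                    "check input normalisation and learning rate"
                )
            grads = model.network.backward(dout, cache)
            opt.step(model.network.params, grads, lr)
            losses.append(loss)
        record = {"epoch": epoch, "lr": lr, "train_mse": float(np.mean(losses))}
        if x_val is not None:
            record["val_mse"] = float(
                np.mean((model.network.forward(x_val) - y_val).astype(np.float64) ** 2)
            )
        model.history.append(record)
        if log is not None:
            log(record)
    return model


def predict(model: TrainedModel, samples, batch_size: int = 32) -> np.ndarray:
    """Run inference; returns (N, 64, 64) slices clipped to [0, 1]."""
    x, _ = _stack_samples(samples)
    outs = []
    for start in range(0, len(x), batch_size):
        outs.append(model.network.forward(x[start : start + batch_size])[..., 0])
    return np.clip(np.concatenate(outs, axis=0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------


def gaussian_baseline(image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Isotropic Gaussian smoothing with reflect boundaries; sigma in pixels."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma == 0:
        return image.copy()
    return gaussian_filter(image, sigma, mode="reflect")


def bilateral_baseline(
    image: np.ndarray, sigma_spatial: float = 2.0, sigma_range: float = 0.1
) -> np.ndarray:
    """Bilateral filter: spatial-Gaussian x range-Gaussian weights, normalised.

    The spatial kernel is truncated at the same radius scipy uses for its
    Gaussian filter (4 sigma), with reflect boundaries, so the
    sigma_range -> infinity limit reproduces ``gaussian_baseline`` exactly.
    """
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigma_spatial and sigma_range must be > 0")
    image = np.asarray(image, dtype=np.float64)
    radius = int(4.0 * sigma_spatial + 0.5)
    padded = np.pad(image, radius, mode="symmetric")
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    H, W = image.shape
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            g = np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_spatial**2))
            shifted = padded[radius + dy : radius + dy + H, radius + dx : radius + dx + W]
            w = g * np.exp(-((shifted - image) ** 2) / (2.0 * sigma_range**2))
            num += w * shifted
            den += w
    return num / den


# ---------------------------------------------------------------------------
# Registry and checkpoints
# ---------------------------------------------------------------------------

#: Method ids -> factory (None for non-learned methods handled by the pipeline).
MODEL_REGISTRY: dict[str, object] = {
    "short": None,
    "gaussian": None,
    "bilateral": None,
    **{f"unet_l{d}": (lambda d=d: (lambda seed=0: build_unet(d, seed=seed)))() for d in range(1, 6)},
}


def save_checkpoint(model: TrainedModel, path) -> Path:
    """Persist weights + config + seed + history in one .npz-in-zip archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = BytesIO()
    np.savez(buf, **model.network.state_dict())
    import json

    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr(
            "meta.json",
            json.dumps(
                {"config": asdict(model.config), "seed": model.seed, "history": model.history}
            ),
        )
    return path


def load_checkpoint(path) -> TrainedModel:
    import json

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as fh:
            weights = dict(np.load(BytesIO(fh.read())))
    model = build_unet(meta["config"]["depth"], seed=meta["seed"])
    model.network.load_state_dict(weights)
    model.history = meta["history"]
    return model
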