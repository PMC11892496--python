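"""Self-supervised 3D denoiser: network, averaged L1+L2 objective, training, inference.

Training is Noise2Noise over adjacent-z-slice stack pairs: every sample is
one time-point volume's :class:`~tagspark.pairing.StackPair`, so pairs never
cross time points and inference on frame t reads frame t alone.  The loss is
the average of the L1 and L2 norms of the output/target difference.  A
temporal-pairing mode (input/target = adjacent time points) is provided only
as the comparison baseline whose frame-mixing artifacts the spatial pairing
avoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from tagspark.nn import Adam, UNet3D
from tagspark.pairing import make_stack_pair, make_temporal_pairs
from tagspark.volume_io import ShapeError, Volume3D, Volume4D


class TrainingError(RuntimeError):
    """Raised when the optimisation produces a non-finite loss."""


class StateError(RuntimeError):
    """Raised when inference is requested from an untrained model."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture family: 3D U-Net with 3x3x3 kernels, one input/output channel.

    ``levels`` resolution levels (>= 2) and ``base_channels`` (>= 8) channels
    at the finest level, doubling per level.  Input spatial dims must each be
    divisible by ``2**(levels - 1)``; inference pads reflectively to satisfy
    this.  The reference configuration is levels=3, base_channels=16.
    """

    levels: int = 3
    base_channels: int = 16
    kernel: int = 3
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        if self.kernel != 3:
            raise ValueError("only 3x3x3 spatial kernels are supported")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings.

    ``loss_weights`` are the (L1, L2) mixture weights, non-negative and
    summing to 1.  ``patch`` optionally trains on random (z, y, x) crops of
    each stack pair (each dim divisible by ``2**(levels-1)``), which bounds
    the per-step cost on large volumes.  ``pairing`` selects the
    self-supervision source: ``"spatial"`` (adjacent z-slices, the method) or
    ``"temporal"`` (adjacent time points, the artifact-prone baseline).
    """

    epochs: int = 100
    learning_rate: float = 1e-3
    batch: int = 1
    swap_prob: float = 0.5
    loss_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    patch: tuple[int, int, int] | None = None
    swap_per_epoch: bool = True
    pairing: str = "spatial"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        w1, w2 = self.loss_weights
        if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-9:
            raise ValueError("loss weights must be non-negative and sum to 1")
        if self.pairing not in ("spatial", "temporal"):
            raise ValueError("pairing must be 'spatial' or 'temporal'")


@dataclass
class DenoiserModel:
    """Trainable parameters plus architecture config and normalisation state."""

    net: UNet3D
    config: NetworkConfig
    training_log: list[float] = field(default_factory=list)
    norm_stats: tuple[float, float] | None = None  # (offset, scale)

    @property
    def trained(self) -> bool:
        return len(self.training_log) > 0


def build_network(config: NetworkConfig, seed: int = 0) -> DenoiserModel:
    """Instantiate the network with deterministically seeded parameters."""
    return DenoiserModel(net=UNet3D(config.levels, config.base_channels, seed=seed),
                         config=config)


def loss(
    output: np.ndarray,
    target: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Averaged L1+L2 objective: w1 * mean|d| + w2 * mean(d^2), d = output - target."""
    output = np.asarray(output)
    target = np.asarray(target)
    if output.shape != target.shape:
        raise ShapeError(f"shape mismatch: {output.shape} vs {target.shape}")
    d = output - target
    w1, w2 = weights
    return float(w1 * np.mean(np.abs(d)) + w2 * np.mean(d * d))


def _loss_and_grad(
    output: np.ndarray, target: np.ndarray, weights: tuple[float, float]
) -> tuple[float, np.ndarray]:
    d = output - target
    w1, w2 = weights
    val = float(w1 * np.mean(np.abs(d)) + w2 * np.mean(d * d))
    grad = (w1 * np.sign(d) + 2.0 * w2 * d) / d.size
    return val, grad.astype(np.float32)


def _pad_to_divisible(stack: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    pads = tuple((-s) % div for s in stack.shape)
    if any(pads):
        stack = np.pad(stack, [(0, p) for p in pads], mode="reflect")
    return stack, pads


def train(model: DenoiserModel, volumes: Volume4D, tc: TrainingConfig) -> DenoiserModel:
    """Train the model on one recording (all time-point volumes as i.i.d. samples).

    Intensities are normalised to zero mean / unit variance using statistics
    of the whole recording, captured once in ``model.norm_stats``.  Per epoch
    the sample order is reshuffled and (for spatial pairing) the per-pair
    swap decisions are redrawn, so each epoch sees a different input/target
    assignment of the same slices.  Raises :class:`TrainingError` with the
    epoch index if the loss becomes non-finite.
    """
    data = volumes.data.astype(np.float32)
    offset = float(data.mean())
    scale = float(data.std())
    if scale <= 0:
        scale = 1.0
    model.norm_stats = (offset, scale)
    normed = (data - offset) / scale

    if tc.pairing == "temporal":
        base_pairs = make_temporal_pairs(normed)
        samples = list(range(len(base_pairs)))
    else:
        samples = list(range(volumes.n_frames))

    div = 2 ** (model.config.levels - 1)
    if tc.patch is not None and any(p % div for p in tc.patch):
        raise ValueError(f"patch dims must be divisible by {div}")

    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.net.parameters(), lr=tc.learning_rate)
    accum = max(1, int(tc.batch))

    for epoch in range(tc.epochs):
        order = rng.permutation(samples)
        epoch_losses = []
        pending = 0
        model.net.zero_grad()
        for idx in order:
            if tc.pairing == "temporal":
                inp, tgt = base_pairs[idx]
            else:
                swap_seed = (
                    tc.seed * 1_000_003 + epoch * 8191 + int(idx)
                    if tc.swap_per_epoch
                    else tc.seed * 1_000_003 + int(idx)
                )
                pair = make_stack_pair(normed[idx], tc.swap_prob, seed=swap_seed)
                inp, tgt = pair.input_stack, pair.target_stack
            if tc.patch is not None:
                origins = [
                    int(rng.integers(0, max(s - p, 0) + 1))
                    for s, p in zip(inp.shape, tc.patch)
                ]
                sl = tuple(slice(o, o + p) for o, p in zip(origins, tc.patch))
                inp, tgt = inp[sl], tgt[sl]
            inp, _ = _pad_to_divisible(inp, div)
            tgt, _ = _pad_to_divisible(tgt, div)
            out = model.net.forward(inp)
            val, grad = _loss_and_grad(out, tgt.astype(np.float32), tc.loss_weights)
            if not np.isfinite(val):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_losses.append(val)
            model.net.backward(grad)
            pending += 1
            if pending == accum:
                opt.step(model.net.gradients())
                model.net.zero_grad()
                pending = 0
        if pending:
            opt.step(model.net.gradients())
            model.net.zero_grad()
        model.training_log.append(float(np.mean(epoch_losses)))
    return model


def _denoise_stack(model: DenoiserModel, stack: np.ndarray) -> np.ndarray:
    offset, scale = model.norm_stats  # type: ignore[misc]
    div = 2 ** (model.config.levels - 1)
    xn = (stack.astype(np.float32) - offset) / scale
    xp, pads = _pad_to_divisible(xn, div)
    out = model.net.forward(xp)
    sl = tuple(slice(0, s) for s in stack.shape)
    out = out[sl]
    return np.clip(out * scale + offset, 0.0, None).astype(np.float64)


def denoise(
    model: DenoiserModel,
    volume: Volume4D | Volume3D,
    mode: str = "full",
) -> Volume4D | Volume3D:
    """Denoise a recording frame by frame.

    ``mode="full"`` (default) passes each time-point volume through the
    network as a single full-depth stack (the network is fully convolutional
    in z, padded reflectively to the divisibility constraint).  ``mode=
    "paired"`` denoises the even/odd slice stacks separately and interleaves
    them back.  Frame t of the output depends on frame t of the input alone.
    """
    if not model.trained or model.norm_stats is None:
        raise StateError("model has not been trained")
    if mode not in ("full", "paired"):
        raise ValueError("mode must be 'full' or 'paired'")
    single = isinstance(volume, Volume3D)
    frames = volume.data[None] if single else volume.data
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        if mode == "full":
            out[t] = _denoise_stack(model, frames[t])
        else:
            from tagspark.pairing import interleave

            pair = make_stack_pair(frames[t], swap_prob=0.0, seed=0)
            den_in = _denoise_stack(model, pair.input_stack)
            den_tg = _denoise_stack(model, pair.target_stack)
            out[t] = interleave(den_in, den_tg, pair.index_map, z_depth=frames.shape[1])
    if single:
        return Volume3D(out[0], volume.meta)
    return Volume4D(out, volume.meta, t0=volume.t0)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: DenoiserModel, path: str | Path) -> None:
    """Serialize parameters + config + norm_stats for exact reproducibility."""
    meta = dict(
        levels=model.config.levels,
        base_channels=model.config.base_channels,
        norm_offset=model.norm_stats[0] if model.norm_stats else np.nan,
        norm_scale=model.norm_stats[1] if model.norm_stats else np.nan,
    )
    np.savez(
        str(path),
        training_log=np.asarray(model.training_log),
        **{k: np.asarray(v) for k, v in meta.items()},
        **model.net.state_dict(),
    )


def load_model(path: str | Path) -> DenoiserModel:
    with np.load(str(path)) as npz:
        config = NetworkConfig(levels=int(npz["levels"]), base_channels=int(npz["base_channels"]))
        model = build_network(config, seed=0)
        model.net.load_state_dict({k: npz[k] for k in npz.files if k.startswith("p")})
        model.training_log = [float(v) for v in npz["training_log"]]
        off, sc = float(npz["norm_offset"]), float(npz["norm_scale"])
        if np.isfinite(off):
            model.norm_stats = (off, sc)
    return model
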