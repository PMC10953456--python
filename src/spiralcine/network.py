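"""Sliding-window video artifact-suppression network (modified FastDVDnet).

Five consecutive gridded magnitude frames map to the restored latest frame.
Stage 1 applies one shared-weight 3-in/1-out denoising block to the frame
triplets (1,2,3), (2,3,4), (3,4,5); stage 2 applies a second block to the
three stage-1 outputs.  Each block is a small U-shaped encoder-decoder with
strided-conv downsampling, sub-pixel upsampling, channel-wise concatenation
skips, no batch normalization and no global residual connection.  Training
minimizes ``1 - mean SSIM``.

Applied in a sliding window, the output at time t depends only on frames
t-4..t (strict causality, which is what enables low-latency streaming); the
first four frames of a series produce no output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .mri_sim import TrainingExample, normalize
from .ssim import ssim, ssim_and_grad

__all__ = [
    "DenoiserConfig",
    "DenoiserState",
    "build_model",
    "model_forward",
    "ssim_loss",
    "train_model",
    "infer_stream",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class DenoiserConfig:
    """Network and training hyperparameters.

    ``base_channels`` is the channel count of the first encoder level; each of
    the ``depth`` downsampling levels doubles it.  ``ssim_window`` is the loss
    window in pixels (odd).
    """

    base_channels: int = 32
    depth: int = 2
    ssim_window: int = 11
    learning_rate: float = 1e-4
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("ssim_window must be odd and >= 3")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class DenoiserState:
    """Weights, optimizer state and training history of a denoiser."""

    config: DenoiserConfig
    params: dict = field(default_factory=dict)
    opt_state: dict | None = None
    history: list = field(default_factory=list)
    epochs_completed: int = 0
    best_params: dict | None = None
    best_val_ssim: float = -np.inf
    best_epoch: int = -1

    def n_weight_sets(self) -> int:
        """Distinct trainable blocks (2: the shared stage-1 block, stage 2)."""
        return len({k.split("/")[0] for k in self.params})


# ---------------------------------------------------------------------------
# Denoising block: e0 -> [down_l, bottleneck_l]*depth -> [up_l, merge_l] -> out


def _channels(cfg: DenoiserConfig) -> list[int]:
    return [cfg.base_channels * 2**l for l in range(cfg.depth + 1)]


def _block_param_specs(cfg: DenoiserConfig, in_ch: int = 3):
    ch = _channels(cfg)
    specs = [("e0", in_ch, ch[0])]
    for l in range(1, cfg.depth + 1):
        specs.append((f"d{l}", ch[l - 1], ch[l]))
        specs.append((f"b{l}", ch[l], ch[l]))
    for l in range(cfg.depth, 0, -1):
        specs.append((f"u{l}", ch[l], 4 * ch[l - 1]))
        specs.append((f"m{l}", 2 * ch[l - 1], ch[l - 1]))
    specs.append(("out", ch[0], 1))
    return specs


def _init_block(cfg: DenoiserConfig, rng: np.random.Generator, prefix: str,
                in_ch: int = 3) -> dict:
    params = {}
    for name, ci, co in _block_param_specs(cfg, in_ch):
        params[f"{prefix}/{name}/w"] = _nn.he_init(rng, co, ci)
        bias = np.zeros(co, dtype=np.float32)
        if name == "out":
            bias += 0.05  # start the clamped output in its active region
        params[f"{prefix}/{name}/b"] = bias
    return params


def _block_forward(params: dict, prefix: str, x: np.ndarray, cfg: DenoiserConfig):
    caches = {}

    def cv(name, inp, stride=1):
        out, cache = _nn.conv2d(
            inp, params[f"{prefix}/{name}/w"], params[f"{prefix}/{name}/b"],
            stride=stride,
        )
        caches[name] = cache
        return out

    def act(name, inp):
        out, mask = _nn.relu(inp)
        caches[f"{name}:relu"] = mask
        return out

    skips = []
    h = act("e0", cv("e0", x))
    skips.append(h)
    for l in range(1, cfg.depth + 1):
        h = act(f"d{l}", cv(f"d{l}", h, stride=2))
        h = act(f"b{l}", cv(f"b{l}", h))
        if l < cfg.depth:
            skips.append(h)
    for l in range(cfg.depth, 0, -1):
        h = _nn.pixel_shuffle(cv(f"u{l}", h))
        h = np.concatenate([h, skips[l - 1]], axis=1)
        h = act(f"m{l}", cv(f"m{l}", h))
    # Outputs are magnitude frames: clamp non-negative.  (SSIM's luminance x
    # structure product has a spurious optimum at sign-flipped images, which
    # an unconstrained output can fall into.)
    out = act("out", cv("out", h))
    return out, caches


def _block_backward(params: dict, prefix: str, dy: np.ndarray, caches: dict,
                    cfg: DenoiserConfig):
    """Backward through one block; returns (param grads, input grad)."""
    grads = {}

    def cvb(name, g):
        dx, dw, db = _nn.conv2d_backward(g, caches[name])
        grads[f"{prefix}/{name}/w"] = dw
        grads[f"{prefix}/{name}/b"] = db
        return dx

    def actb(name, g):
        return _nn.relu_backward(g, caches[f"{name}:relu"])

    ch = _channels(cfg)
    g = cvb("out", actb("out", dy))
    d_skip = [None] * cfg.depth
    # Decoder ran l = depth..1, so its backward visits l = 1..depth; the
    # gradient flowing out of up-conv l is the gradient at decoder stage
    # (l+1)'s output (or at the bottleneck for l = depth).
    for l in range(1, cfg.depth + 1):
        g = actb(f"m{l}", g)
        g = cvb(f"m{l}", g)
        g, d_skip[l - 1] = g[:, : ch[l - 1]], g[:, ch[l - 1]:]
        g = cvb(f"u{l}", _nn.pixel_unshuffle(g))
    # Encoder backward, deepest level first; skip gradients rejoin where the
    # activation was forked.
    for l in range(cfg.depth, 0, -1):
        if l < cfg.depth:
            g = g + d_skip[l]
        g = actb(f"b{l}", g)
        g = cvb(f"b{l}", g)
        g = actb(f"d{l}", g)
        g = cvb(f"d{l}", g)
    g = g + d_skip[0]
    g = actb("e0", g)
    g = cvb("e0", g)
    return grads, g


# ---------------------------------------------------------------------------
# Two-stage cascade


def build_model(config: DenoiserConfig) -> DenoiserState:
    """Initialize an untrained two-stage denoiser (seeded)."""
    rng = np.random.default_rng(config.seed)
    params = {}
    params.update(_init_block(config, rng, "stage1", in_ch=3))
    params.update(_init_block(config, rng, "stage2", in_ch=3))
    return DenoiserState(config=config, params=params)


def model_forward(state: DenoiserState, x: np.ndarray, want_caches: bool = False):
    """Map [N, 5, H, W] input windows to [N, 1, H, W] restored frames.

    H and W must be divisible by ``2**depth``.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[1] != 5:
        raise ValueError(f"expected [N, 5, H, W] input, got {x.shape}")
    cfg = state.config
    if x.shape[2] % 2**cfg.depth or x.shape[3] % 2**cfg.depth:
        raise ValueError(f"spatial size must be divisible by {2**cfg.depth}")
    t_out, t_caches = [], []
    for i in range(3):
        out, caches = _block_forward(state.params, "stage1", x[:, i: i + 3], cfg)
        t_out.append(out)
        t_caches.append(caches)
    stage2_in = np.concatenate(t_out, axis=1)
    y, caches2 = _block_forward(state.params, "stage2", stage2_in, cfg)
    if want_caches:
        return y, (t_caches, caches2)
    return y


def _model_backward(state: DenoiserState, dy: np.ndarray, caches) -> dict:
    cfg = state.config
    t_caches, caches2 = caches
    grads2, d_stage2_in = _block_backward(state.params, "stage2", dy, caches2, cfg)
    grads = dict(grads2)
    for i in range(3):
        gi, _ = _block_backward(
            state.params, "stage1", d_stage2_in[:, i: i + 1], t_caches[i], cfg
        )
        for k, v in gi.items():
            grads[k] = grads.get(k, 0.0) + v  # shared weights: sum over the 3 uses
    return grads


def ssim_loss(prediction: np.ndarray, target: np.ndarray,
              config: DenoiserConfig | None = None, want_grad: bool = False):
    """``1 - mean SSIM`` over a batch of frames (values expected in [0, 1]).

    With ``want_grad`` also returns d(loss)/d(prediction).
    """
    window = config.ssim_window if config is not None else 11
    pred = np.asarray(prediction, dtype=float)
    targ = np.asarray(target, dtype=float)
    if pred.shape != targ.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {targ.shape}")
    p2 = pred.reshape(-1, *pred.shape[-2:])
    t2 = targ.reshape(-1, *targ.shape[-2:])
    if not want_grad:
        vals = [ssim(a, b, window_size=window) for a, b in zip(p2, t2)]
        return 1.0 - float(np.mean(vals))
    grad = np.empty_like(p2)
    total = 0.0
    for i in range(p2.shape[0]):
        v, g = ssim_and_grad(p2[i], t2[i], window_size=window)
        total += v
        grad[i] = -g / p2.shape[0]
    return 1.0 - total / p2.shape[0], grad.reshape(pred.shape)


def _examples_to_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for ex in dataset:
        if isinstance(ex, TrainingExample):
            xs.append(ex.inputs)
            ys.append(ex.target)
        else:
            xs.append(ex[0])
            ys.append(ex[1])
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.float32)


def validation_ssim(state: DenoiserState, val_set, params: dict | None = None) -> float:
    """Mean SSIM of model outputs against targets over a validation set."""
    xs, ys = _examples_to_arrays(val_set)
    use = state if params is None else DenoiserState(config=state.config, params=params)
    preds = model_forward(use, xs)[:, 0]
    return float(np.mean([ssim(p, t, window_size=state.config.ssim_window)
                          for p, t in zip(preds, ys)]))


def train_model(
    state: DenoiserState,
    dataset,
    epochs: int,
    seed: int | None = None,
    val_set=None,
) -> DenoiserState:
    """Train (or resume training) for ``epochs`` additional epochs.

    Deterministic given the seed: shuffling is drawn from a generator keyed
    on (seed, epoch index), so resuming after a checkpoint reproduces the
    single uninterrupted run.  Tracks the best-validation-SSIM checkpoint.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    cfg = state.config
    seed = cfg.seed if seed is None else seed
    xs, ys = _examples_to_arrays(dataset)
    opt = (
        _nn.Adam.from_state(state.opt_state, lr=cfg.learning_rate)
        if state.opt_state is not None
        else _nn.Adam(lr=cfg.learning_rate)
    )
    n = xs.shape[0]
    bs = min(cfg.batch_size, n)
    for _ in range(epochs):
        epoch = state.epochs_completed
        rng = np.random.default_rng([seed, epoch])
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            xb, yb = xs[idx], ys[idx]
            pred, caches = model_forward(state, xb, want_caches=True)
            loss, dpred = ssim_loss(pred[:, 0], yb, cfg, want_grad=True)
            grads = _model_backward(state, dpred[:, None].astype(np.float32), caches)
            opt.step(state.params, grads)
            losses.append(loss)
        record = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val_set:
            v = validation_ssim(state, val_set)
            record["val_ssim"] = v
            if v > state.best_val_ssim:
                state.best_val_ssim = v
                state.best_params = copy.deepcopy(state.params)
                state.best_epoch = epoch + 1
        state.history.append(record)
        state.epochs_completed += 1
    state.opt_state = opt.state_dict()
    return state


def infer_stream(
    state: DenoiserState, frames: np.ndarray, per_frame_normalize: bool = True
) -> np.ndarray:
    """Sliding-window restoration of a gridded magnitude frame stream.

    Returns ``len(frames) - 4`` restored frames; output t uses only input
    frames t-4..t.  Each input frame is rescaled to [0, 1] on its own
    (the inference-time convention) unless disabled.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError("frames must be [T, H, W]")
    if frames.shape[0] < 5:
        raise ValueError("need at least 5 frames")
    if per_frame_normalize:
        frames = normalize(frames, mode="per_frame").astype(np.float32)
    windows = np.stack([frames[t: t + 5] for t in range(frames.shape[0] - 4)])
    params = state.best_params if state.best_params is not None else state.params
    use = DenoiserState(config=state.config, params=params)
    out = []
    bs = max(1, state.config.batch_size)
    for start in range(0, windows.shape[0], bs):
        out.append(model_forward(use, windows[start: start + bs])[:, 0])
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Checkpoint I/O (HDF5 tensor export)


def save_state(state: DenoiserState, path: str) -> None:
    import json

    import h5py

    with h5py.File(path, "w") as f:
        for k, v in state.params.items():
            f.create_dataset(f"params/{k}", data=v)
        if state.best_params is not None:
            for k, v in state.best_params.items():
                f.create_dataset(f"best_params/{k}", data=v)
        f.attrs["config"] = json.dumps(vars(state.config) | {})
        f.attrs["history"] = json.dumps(state.history)
        f.attrs["epochs_completed"] = state.epochs_completed
        f.attrs["best_val_ssim"] = state.best_val_ssim
        f.attrs["best_epoch"] = state.best_epoch


def load_state(path: str) -> DenoiserState:
    import json

    import h5py

    with h5py.File(path, "r") as f:
        cfg = DenoiserConfig(**json.loads(f.attrs["config"]))
        params = {k: f[f"params/{k}"][...] for k in _flat_keys(f["params"])}
        best = None
        if "best_params" in f:
            best = {k: f[f"best_params/{k}"][...] for k in _flat_keys(f["best_params"])}
        state = DenoiserState(
            config=cfg,
            params=params,
            history=json.loads(f.attrs["history"]),
            epochs_completed=int(f.attrs["epochs_completed"]),
            best_params=best,
            best_val_ssim=float(f.attrs["best_val_ssim"]),
            best_epoch=int(f.attrs["best_epoch"]),
        )
    return state


def _flat_keys(group, prefix: str = "") -> list[str]:
    import h5py

    keys = []
    for name, item in group.items():
        full = f"{prefix}{name}"
        if isinstance(item, h5py.Group):
            keys.extend(_flat_keys(item, full + "/"))
        else:
            keys.append(full)
    return keys
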