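"""Retrospective undersampling simulation and gridded reconstruction.

A fully sampled dynamic multicoil series is resampled along a candidate
trajectory (forward NUFFT per coil), then reconstructed by the adjoint NUFFT
of the density-compensated samples and root-sum-of-squares (RSS) coil
combination.  Pairing a gridded frame stack with the matching ground truth
yields the training examples for the artifact-suppression network: five
consecutive gridded magnitude frames mapped to the latest frame's truth.

Scaling conventions: ground truth is scaled to [0, 1] once per series, and
the same factor is applied to the multicoil images before undersampling;
at inference each individual gridded frame is rescaled to [0, 1] instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import NufftPlan
from .trajectory import ImagingGrid, Trajectory, density_compensation

__all__ = [
    "CineSeries",
    "TrainingExample",
    "forward_sample",
    "grid_reconstruct",
    "normalize",
    "make_training_example",
    "gridded_series",
    "save_cines",
    "load_cines",
    "save_examples",
    "load_examples",
]


@dataclass
class CineSeries:
    """Dynamic multicoil image series.

    ``coil_images``: complex [frame, coil, y, x]; ``truth``: magnitude
    [frame, y, x] in [0, 1], equal to the rescaled RSS of the coil images.
    """

    coil_images: np.ndarray
    truth: np.ndarray
    grid: ImagingGrid
    frame_ms: float = 55.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coil_images.ndim != 4:
            raise ValueError("coil_images must be [frame, coil, y, x]")
        if self.truth.shape != (
            self.coil_images.shape[0],
            *self.coil_images.shape[2:],
        ):
            raise ValueError("truth shape inconsistent with coil_images")

    @property
    def n_frames(self) -> int:
        return self.coil_images.shape[0]

    @property
    def n_coils(self) -> int:
        return self.coil_images.shape[1]

    @classmethod
    def from_coil_images(
        cls, coil_images: np.ndarray, grid: ImagingGrid, frame_ms: float = 55.0, **meta
    ) -> "CineSeries":
        """Build a series from raw coil images, applying the series-wide
        [0, 1] scaling to both the RSS truth and the coil images."""
        rss = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=1))
        lo, hi = rss.min(), rss.max()
        if hi <= lo:
            raise ValueError("degenerate series: constant RSS")
        scale = 1.0 / (hi - lo)
        truth = (rss - lo) * scale
        return cls(
            coil_images=coil_images * scale,
            truth=truth,
            grid=grid,
            frame_ms=frame_ms,
            meta=dict(meta),
        )


@dataclass
class TrainingExample:
    """Five consecutive gridded magnitude frames and the truth of the fifth."""

    inputs: np.ndarray  # [5, y, x]
    target: np.ndarray  # [y, x]
    frame_index: int  # 1-based index of the target frame in the series

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != 5:
            raise ValueError("exactly 5 input frames required")
        if self.inputs.shape[1:] != self.target.shape:
            raise ValueError("input/target spatial shapes differ")


def _plan_for_frame(traj: Trajectory, t: int, **nufft_kw) -> NufftPlan:
    pts = traj.frame(t).reshape(-1, 2)
    return NufftPlan(pts, traj.grid.matrix, **nufft_kw)


def forward_sample(
    coil_images: np.ndarray,
    traj: Trajectory,
    t: int = 0,
    plan: NufftPlan | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample one frame's coil images along frame ``t`` of the trajectory.

    ``coil_images``: complex [coil, y, x] matching the trajectory's grid.
    Returns complex samples [coil, interleave, sample].  ``noise_sigma`` adds
    complex Gaussian acquisition noise (per real/imaginary component, in
    k-space units); the default simulation is noise-free.
    """
    coil_images = np.asarray(coil_images)
    M = traj.grid.matrix
    if coil_images.shape[-2:] != (M, M):
        raise ValueError(
            f"image shape {coil_images.shape[-2:]} does not match grid matrix {M}"
        )
    if plan is None:
        plan = _plan_for_frame(traj, t)
    n_il, n_s, _ = traj.frame(t).shape
    samples = plan.forward(coil_images)
    if noise_sigma > 0.0:
        rng = np.random.default_rng() if rng is None else rng
        samples = samples + noise_sigma * (
            rng.standard_normal(samples.shape)
            + 1j * rng.standard_normal(samples.shape)
        )
    return samples.reshape(coil_images.shape[:-2] + (n_il, n_s))


def grid_reconstruct(
    samples: np.ndarray,
    traj: Trajectory,
    t: int = 0,
    dcw: np.ndarray | None = None,
    plan: NufftPlan | None = None,
) -> np.ndarray:
    """Adjoint-NUFFT ("gridded") reconstruction of one frame.

    Density-compensation weights are applied to the samples before the
    adjoint; coils are combined by RSS.  Returns a magnitude image [y, x].
    """
    import warnings

    samples = np.asarray(samples)
    if dcw is None:
        if traj.dcw.size:
            dcw = traj.frame_dcw(t)
        else:
            warnings.warn("no density-compensation weights; computing Voronoi weights")
            dcw = density_compensation(traj, frame=t, method="voronoi")
    n_il, n_s, _ = traj.frame(t).shape
    if samples.shape[-2:] != (n_il, n_s):
        raise ValueError("samples do not match the trajectory frame")
    if plan is None:
        plan = _plan_for_frame(traj, t)
    weighted = (samples * dcw).reshape(samples.shape[:-2] + (n_il * n_s,))
    coil_imgs = plan.adjoint(weighted)
    if coil_imgs.ndim == 2:
        return np.abs(coil_imgs)
    return np.sqrt(np.sum(np.abs(coil_imgs) ** 2, axis=-3))


def normalize(data: np.ndarray, mode: str = "per_series") -> np.ndarray:
    """Rescale magnitude data to [0, 1].

    ``per_series`` uses one min/max over the whole array; ``per_frame``
    rescales each leading-axis frame independently.  A constant scope maps to
    all-zeros (degenerate rule).
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("empty input")
    if mode == "per_series":
        lo, hi = data.min(), data.max()
        if hi <= lo:
            return np.zeros_like(data)
        return (data - lo) / (hi - lo)
    if mode == "per_frame":
        frames = data.reshape(data.shape[0], -1)
        lo = frames.min(axis=1, keepdims=True)
        hi = frames.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (frames - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out.reshape(data.shape)
    raise ValueError(f"unknown mode {mode!r}")


def gridded_series(
    cine: CineSeries,
    traj: Trajectory,
    frames: range | None = None,
    frame_offset: int = 0,
) -> np.ndarray:
    """Gridded magnitude reconstruction of each requested frame.

    ``frame_offset`` shifts the trajectory's rotation state, so a spliced or
    windowed series keeps the acquisition continuing where it left off.
    Returns [n_frames, y, x]; no normalization is applied.
    """
    if frames is None:
        frames = range(cine.n_frames)
    stationary = traj.n_frames == 1 or (
        traj.params is not None and traj.params.ordering == "linear"
    )
    plan = _plan_for_frame(traj, 0) if stationary else None
    out = np.empty((len(frames), cine.grid.matrix, cine.grid.matrix))
    for i, t in enumerate(frames):
        tt = 0 if stationary else t + frame_offset
        p = plan if stationary else _plan_for_frame(traj, tt)
        samples = forward_sample(cine.coil_images[t], traj, tt, plan=p)
        out[i] = grid_reconstruct(samples, traj, tt, plan=p)
    return out


def make_training_example(
    cine: CineSeries, traj: Trajectory, t: int, gridded: np.ndarray | None = None
) -> TrainingExample:
    """Training pair for target frame ``t`` (1-based, so ``t >= 5``).

    Inputs are the gridded reconstructions of frames t-4..t, each simulated
    with that frame's trajectory rotation state; the target is the ground
    truth of frame t.  Precomputed ``gridded`` (full series) is reused when
    given.
    """
    if t < 5:
        raise IndexError(f"target frame must be >= 5 (1-based), got {t}")
    if t > cine.n_frames:
        raise IndexError(f"target frame {t} beyond series length {cine.n_frames}")
    if gridded is None:
        gridded = gridded_series(cine, traj, range(t - 5, t))
        inputs = gridded
    else:
        inputs = gridded[t - 5: t]
    return TrainingExample(
        inputs=np.asarray(inputs, dtype=float),
        target=np.asarray(cine.truth[t - 1], dtype=float),
        frame_index=t,
    )


# ---------------------------------------------------------------------------
# HDF5 I/O


def save_cines(cines: list[CineSeries], path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for i, c in enumerate(cines):
            g = f.create_group(f"cine_{i:04d}")
            g.create_dataset("coil_images", data=c.coil_images.astype(np.complex64))
            g.create_dataset("truth", data=c.truth.astype(np.float32))
            g.attrs["matrix"] = c.grid.matrix
            g.attrs["fov_mm"] = c.grid.fov_mm
            g.attrs["frame_ms"] = c.frame_ms


def save_examples(examples: list[TrainingExample], path: str) -> None:
    """Write training pairs (5 gridded inputs + target each) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, ex in enumerate(examples):
            g = f.create_group(f"example_{i:05d}")
            g.create_dataset("inputs", data=ex.inputs.astype(np.float32))
            g.create_dataset("target", data=ex.target.astype(np.float32))
            g.attrs["frame_index"] = ex.frame_index


def load_examples(path: str) -> list[TrainingExample]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                TrainingExample(
                    inputs=g["inputs"][...].astype(float),
                    target=g["target"][...].astype(float),
                    frame_index=int(g.attrs["frame_index"]),
                )
            )
    return out


def load_cines(path: str) -> list[CineSeries]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                CineSeries(
                    coil_images=g["coil_images"][...].astype(complex),
                    truth=g["truth"][...].astype(float),
                    grid=ImagingGrid(int(g.attrs["matrix"]), float(g.attrs["fov_mm"])),
                    frame_ms=float(g.attrs["frame_ms"]),
                )
            )
    return out
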