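"""Synthetic dynamic multicoil cardiac-like phantoms.

Stands in for a clinical cine archive: each phantom is a bright "blood pool"
surrounded by a darker "myocardial" ring whose radius contracts periodically
(one cardiac cycle every ``heart_rate_frames`` frames), over a bed of static
elliptical background structures.  Smooth complex coil-sensitivity maps
(Gaussian magnitude lobes around the FOV border, low-order polynomial phase)
turn the scene into multicoil complex images; truth is the [0, 1]-rescaled
RSS.  Everything is deterministic given the seed.

What this emulates: 2D+time magnitude structure, periodic motion, coil
shading, and abrupt scan-plane changes (two independent phantoms spliced
together).  What it does not: bSSFP contrast, breathing motion, flow, or
realistic noise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mri_sim import CineSeries
from .trajectory import ImagingGrid

__all__ = [
    "PhantomSpec",
    "make_phantom_cine",
    "make_transition_pair",
    "load_video_frames",
    "save_preview",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cine phantom."""

    grid: ImagingGrid = ImagingGrid(64, 400.0)
    n_frames: int = 16
    heart_rate_frames: int = 8
    motion_amplitude: float = 0.15
    n_coils: int = 8
    background_objects: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 9:
            raise ValueError("n_frames must be >= 9 (5 inputs + transition room)")
        if not 0.0 <= self.motion_amplitude <= 0.5:
            raise ValueError("motion_amplitude must be in [0, 0.5]")
        if self.n_coils < 1 or self.heart_rate_frames < 2:
            raise ValueError("invalid n_coils or heart_rate_frames")


def _soft_disk(xx, yy, cx, cy, rx, ry, softness):
    """Anti-aliased ellipse indicator via a logistic edge profile."""
    d = np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)
    return 1.0 / (1.0 + np.exp((d - 1.0) * (rx + ry) / (2.0 * softness)))


def make_coil_maps(grid: ImagingGrid, n_coils: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth complex coil sensitivities [coil, y, x] with strictly positive RSS."""
    M = grid.matrix
    c = np.linspace(-1.0, 1.0, M)
    xx, yy = np.meshgrid(c, c)
    maps = np.empty((n_coils, M, M), dtype=complex)
    for i in range(n_coils):
        ang = 2.0 * np.pi * i / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = 1.1 * np.cos(ang), 1.1 * np.sin(ang)
        width = rng.uniform(0.9, 1.3)
        mag = 0.2 + np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)) / (2 * width**2))
        a = rng.uniform(-0.5, 0.5, size=4)
        phase = a[0] + a[1] * xx + a[2] * yy + a[3] * xx * yy
        maps[i] = mag * np.exp(1j * phase)
    return maps


def make_phantom_cine(spec: PhantomSpec) -> CineSeries:
    """Generate one dynamic multicoil phantom series."""
    rng = np.random.default_rng(spec.seed)
    M = spec.grid.matrix
    c = np.arange(M) - M / 2.0
    xx, yy = np.meshgrid(c, c)

    # Heart-like structure: jittered center, pool + ring radii.
    cx = rng.uniform(-0.12, 0.12) * M
    cy = rng.uniform(-0.12, 0.12) * M
    r_pool = rng.uniform(0.10, 0.16) * M
    r_ring = r_pool * rng.uniform(1.5, 1.9)
    ecc = rng.uniform(0.85, 1.15)

    # Static background ellipses.
    bg = np.zeros((M, M))
    for _ in range(spec.background_objects):
        bx, by = rng.uniform(-0.38, 0.38, size=2) * M
        brx = rng.uniform(0.05, 0.18) * M
        bry = rng.uniform(0.05, 0.18) * M
        amp = rng.uniform(0.1, 0.45)
        bg += amp * _soft_disk(xx, yy, bx, by, brx, bry, softness=1.5)
    bg = np.clip(bg, 0.0, 0.6)

    frames = np.empty((spec.n_frames, M, M))
    for t in range(spec.n_frames):
        contraction = 1.0 + spec.motion_amplitude * np.sin(
            2.0 * np.pi * t / spec.heart_rate_frames
        )
        rp = r_pool * contraction
        rr = r_ring * (1.0 + 0.5 * (contraction - 1.0))  # ring moves less
        ring = 0.45 * _soft_disk(xx, yy, cx, cy, rr, rr * ecc, 1.2)
        pool = _soft_disk(xx, yy, cx, cy, rp, rp * ecc, 1.2)
        frames[t] = np.clip(bg * (1 - _soft_disk(xx, yy, cx, cy, rr, rr * ecc, 1.2))
                            + ring + 0.5 * pool, 0.0, 1.1)

    maps = make_coil_maps(spec.grid, spec.n_coils, rng)
    coil_images = frames[:, None, :, :] * maps[None, :, :, :]
    return CineSeries.from_coil_images(
        coil_images, spec.grid, frame_ms=55.0, seed=spec.seed
    )


def make_transition_pair(spec: PhantomSpec, seed: int | None = None) -> tuple[CineSeries, CineSeries]:
    """Two independent phantoms on the same grid (distinct geometry draws),
    for scan-plane-change experiments."""
    root = spec.seed if seed is None else seed
    s1, s2 = np.random.SeedSequence(root).spawn(2)
    a = make_phantom_cine(_with_seed(spec, int(s1.generate_state(1)[0] % 2**31)))
    b = make_phantom_cine(_with_seed(spec, int(s2.generate_state(1)[0] % 2**31)))
    return a, b


def _with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)


def save_preview(cine: CineSeries, path: str) -> None:
    """Export the ground-truth frames as an animated GIF (or a PNG of the
    first frame if the extension is .png)."""
    import imageio.v3 as iio

    frames = (np.clip(cine.truth, 0.0, 1.0) * 255).astype(np.uint8)
    if str(path).lower().endswith(".png"):
        iio.imwrite(path, frames[0])
    else:
        iio.imwrite(path, frames, extension=".gif", duration=int(cine.frame_ms))


def load_video_frames(path: str, grid: ImagingGrid, n_coils: int = 8, seed: int = 0) -> CineSeries:
    """Load a natural-video frame stack as a stand-in cine.

    Frames are converted to grayscale, center-cropped to square, resized to
    the grid, given synthetic coil maps, and scaled to [0, 1].  Any
    multi-frame format imageio reads natively works (GIF, TIFF stack, ...).
    """
    import imageio.v3 as iio
    from skimage.transform import resize

    try:
        frames = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read video frames from {path!r}: {exc}") from exc
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # RGB(A) -> grayscale
        frames = frames[..., :3].mean(axis=-1)
    if frames.ndim != 3:
        raise OSError(f"unsupported frame stack shape {frames.shape} in {path!r}")
    h, wid = frames.shape[1:]
    side = min(h, wid)
    y0, x0 = (h - side) // 2, (wid - side) // 2
    frames = frames[:, y0: y0 + side, x0: x0 + side]
    M = grid.matrix
    out = np.stack([resize(f, (M, M), anti_aliasing=True) for f in frames])
    rng = np.random.default_rng(seed)
    maps = make_coil_maps(grid, n_coils, rng)
    coil_images = out[:, None] * maps[None]
    return CineSeries.from_coil_images(coil_images, grid, source=str(path))
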