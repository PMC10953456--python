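"""Variable-density spiral, uniform spiral, and tiny-golden radial k-space trajectories.

A frame of real-time data is acquired as several rotated copies of a single
spiral interleave (or several radial spokes).  The interleave shape is
controlled by six parameters: an inner k-space radius inside which sampling is
dense, the per-interleave acceleration there, an outer radius beyond which a
sparser density applies, the outer/inner density ratio, the shape of the
density transition between the two radii, and the interleave ordering
(identical per frame, or a continuing tiny-golden-angle rotation).

Units: k-space coordinates are normalized cycles/pixel with |k| <= 0.5 and the
image DC at pixel ``matrix / 2``.  An acceleration ``a(k)`` means the radial
gap between successive turns of one interleave is ``a(k) / matrix``, so that
``a(k) = N`` interleaves rotated uniformly tile k-space exactly at the Nyquist
pitch ``1 / matrix``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PHI",
    "ImagingGrid",
    "SpiralParams",
    "Trajectory",
    "tiny_golden_angle",
    "interleaf_count",
    "acceleration_profile",
    "density_profile",
    "design_interleave",
    "build_trajectory",
    "build_radial",
    "density_compensation",
    "turn_crossings",
    "frame_acceleration_range",
    "save_trajectory",
    "save_trajectory_csv",
    "load_trajectory",
    "plot_trajectory",
]

PHI = (1.0 + np.sqrt(5.0)) / 2.0
"""Golden ratio."""

TRANSITIONS = ("linear", "hanning", "quadratic")
ORDERINGS = ("linear", "tiny_golden")

#: Search ranges for the six trajectory parameters.
PARAM_RANGES = {
    "r_inner": (0.1, 0.3),
    "a_inner": (12.0, 24.0),
    "density_ratio": (0.01, 0.35),
    "tr_ms": (2.88, 3.7),
}


@dataclass(frozen=True)
class ImagingGrid:
    """Reconstruction grid: base matrix and field of view."""

    matrix: int = 240
    fov_mm: float = 400.0

    def __post_init__(self) -> None:
        if self.matrix < 16 or self.matrix % 2:
            raise ValueError(f"matrix must be even and >= 16, got {self.matrix}")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix


@dataclass(frozen=True)
class SpiralParams:
    """The six searched spiral parameters plus timing.

    ``r_inner``/``r_outer`` are fractions of the maximum k-space radius;
    ``a_inner`` is the per-interleave acceleration at/inside ``r_inner``
    (relative to the single-interleave Nyquist pitch); ``density_ratio`` is the
    outer/inner sampling-density ratio (< 1 means sparser outside);
    ``transition`` shapes the density ramp between the radii; ``ordering``
    selects per-frame interleave rotation; ``tr_ms`` is the repetition time of
    one interleave and ``t_acq_ms`` the maximum time per frame.
    """

    r_inner: float = 0.15
    a_inner: float = 16.0
    r_outer: float = 0.56
    density_ratio: float = 0.07
    transition: str = "hanning"
    ordering: str = "linear"
    tr_ms: float = 3.67
    t_acq_ms: float = 55.0
    n_interleaves: int | None = None  # explicit override of floor(t_acq/tr)

    def __post_init__(self) -> None:
        if self.transition not in TRANSITIONS:
            raise ValueError(f"transition must be one of {TRANSITIONS}")
        if self.ordering not in ORDERINGS:
            raise ValueError(f"ordering must be one of {ORDERINGS}")
        if self.tr_ms <= 0 or self.t_acq_ms <= 0:
            raise ValueError("tr_ms and t_acq_ms must be positive")
        if not self.r_inner <= self.r_outer:
            raise ValueError("r_outer must be >= r_inner")
        if self.density_ratio <= 0:
            raise ValueError("density_ratio must be positive")
        lo, hi = PARAM_RANGES["r_inner"]
        checks = [
            ("r_inner", self.r_inner, lo, hi),
            ("a_inner", self.a_inner, *PARAM_RANGES["a_inner"]),
            ("r_outer", self.r_outer, self.r_inner, 1.0 - self.r_inner),
            ("density_ratio", self.density_ratio, *PARAM_RANGES["density_ratio"]),
            ("tr_ms", self.tr_ms, *PARAM_RANGES["tr_ms"]),
        ]
        for name, value, vlo, vhi in checks:
            if not vlo <= value <= vhi:
                warnings.warn(
                    f"{name}={value} outside the searched range [{vlo}, {vhi}]",
                    stacklevel=3,
                )

    def interleaves_per_frame(self) -> int:
        if self.n_interleaves is not None:
            return int(self.n_interleaves)
        return interleaf_count(self.tr_ms, self.t_acq_ms)



@dataclass
class Trajectory:
    """Sampling pattern: per-frame, per-interleave k-space sample coordinates.

    ``coords`` has shape [frame, interleave, sample, 2] in normalized
    cycles/pixel; ``dcw`` holds matching density-compensation weights.
    """

    coords: np.ndarray
    dcw: np.ndarray
    grid: ImagingGrid
    params: SpiralParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_interleaves_per_frame(self) -> int:
        return self.coords.shape[1]

    @property
    def samples_per_interleave(self) -> int:
        return self.coords.shape[2]

    def frame(self, t: int) -> np.ndarray:
        """Coordinates of frame ``t`` (0-based), shape [interleave, sample, 2]."""
        return self.coords[t % self.n_frames]

    def frame_dcw(self, t: int) -> np.ndarray:
        return self.dcw[t % self.n_frames]


def tiny_golden_angle(order: int, arc_degrees: float = 360.0) -> float:
    """Tiny golden angle of the given order: ``arc / (phi + order - 1)``.

    Order 7 on the full circle gives the 47.25° increment used for spiral
    interleave ordering; order 1 is the classical golden angle.
    """
    if order < 1 or int(order) != order:
        raise ValueError(f"order must be a positive integer, got {order}")
    if arc_degrees not in (180.0, 360.0, 180, 360):
        raise ValueError("arc_degrees must be 180 or 360")
    return float(arc_degrees) / (PHI + order - 1)


def interleaf_count(tr_ms: float, t_acq_ms: float = 55.0) -> int:
    """Number of interleaves fitting in one frame: ``floor(t_acq / tr)``."""
    if tr_ms <= 0 or t_acq_ms <= 0:
        raise ValueError("tr_ms and t_acq_ms must be positive")
    return int(np.floor(t_acq_ms / tr_ms))


def density_profile(params: SpiralParams, k: np.ndarray | float) -> np.ndarray | float:
    """Sampling density ``d(k) = 1/a(k)`` as a function of normalized radius.

    Constant ``1/a_inner`` inside ``r_inner``, constant
    ``density_ratio/a_inner`` outside ``r_outer``, and ramped in between by the
    transition shape (acting on density, not acceleration).
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0) or np.any(k_arr > 1):
        raise ValueError("k must lie in [0, 1]")
    d_in = 1.0 / params.a_inner
    d_out = params.density_ratio / params.a_inner
    span = params.r_outer - params.r_inner
    if span <= 0:
        d = np.where(k_arr < params.r_outer, d_in, d_out)
    else:
        u = np.clip((k_arr - params.r_inner) / span, 0.0, 1.0)
        if params.transition == "linear":
            w = 1.0 - u
        elif params.transition == "hanning":
            w = 0.5 * (1.0 + np.cos(np.pi * u))
        else:  # quadratic
            w = (1.0 - u) ** 2
        d = d_out + (d_in - d_out) * w
    return d if np.ndim(k) else float(d)


def acceleration_profile(params: SpiralParams, k: np.ndarray | float) -> np.ndarray | float:
    """Per-interleave acceleration ``a(k) = 1/d(k)`` at normalized radius k."""
    d = density_profile(params, k)
    return 1.0 / d


def design_interleave(
    params: SpiralParams,
    grid: ImagingGrid,
    samples_per_interleave: int = 1024,
) -> np.ndarray:
    """Design a single spiral interleave as [samples, 2] k-space coordinates.

    The path is an Archimedean-type spiral whose local radial pitch between
    successive turns equals ``a(k)/matrix`` in normalized units, obtained by
    integrating ``dk/dtheta = a(k) / (2 pi matrix)`` from the k-space center to
    ``|k| = 0.5`` and resampling the path to uniform arc length.
    """
    if samples_per_interleave < 16:
        raise ValueError("samples_per_interleave must be >= 16")
    M = grid.matrix
    k_max = 0.5

    def dk_dtheta(_theta: float, kk: np.ndarray) -> np.ndarray:
        knorm = min(max(kk[0], 0.0) / k_max, 1.0)
        return np.array([acceleration_profile(params, knorm) / (2.0 * np.pi * M)])

    # Upper bound on total turn angle: slowest pitch is a_inner/M per turn.
    theta_max = 2.0 * np.pi * (k_max * M / params.a_inner + 2.0)

    def reached_edge(_theta: float, kk: np.ndarray) -> float:
        return kk[0] - k_max

    reached_edge.terminal = True
    reached_edge.direction = 1.0

    sol = solve_ivp(
        dk_dtheta,
        (0.0, theta_max),
        np.array([0.0]),
        events=reached_edge,
        dense_output=True,
        max_step=np.pi / 64,
        rtol=1e-9,
        atol=1e-12,
    )
    if sol.t_events[0].size == 0:
        raise RuntimeError(
            f"spiral never reached k_max; check a_inner={params.a_inner}"
        )
    theta_end = float(sol.t_events[0][0])

    # Dense polyline for arc-length resampling.
    n_dense = max(4096, 16 * samples_per_interleave)
    theta = np.linspace(0.0, theta_end, n_dense)
    k = np.clip(sol.sol(theta)[0], 0.0, k_max)
    x = k * np.cos(theta)
    y = k * np.sin(theta)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate(([0.0], np.cumsum(seg)))
    s_uniform = np.linspace(0.0, s[-1], samples_per_interleave)
    xs = np.interp(s_uniform, s, x)
    ys = np.interp(s_uniform, s, y)
    path = np.stack([xs, ys], axis=-1)
    path[0] = 0.0
    return path


def _rotate(path: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, -s], [s, c]])
    return path @ rot.T


def build_trajectory(
    params: SpiralParams,
    grid: ImagingGrid,
    n_frames: int,
    samples_per_interleave: int = 1024,
    dcw_method: str = "voronoi",
) -> Trajectory:
    """Build a multi-frame spiral trajectory.

    Linear ordering places interleaf j at ``360 j / N`` degrees, identically in
    every frame.  Tiny-golden ordering rotates the global interleave counter by
    ``360 / (phi + 6)`` ≈ 47.25° per interleave, continuing across frames.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n_il = params.interleaves_per_frame()
    if n_il < 1:
        raise ValueError("interleaf count must be >= 1")
    base = design_interleave(params, grid, samples_per_interleave)
    coords = np.empty((n_frames, n_il, samples_per_interleave, 2))
    if params.ordering == "linear":
        frame = np.stack([_rotate(base, 360.0 * j / n_il) for j in range(n_il)])
        coords[:] = frame[None]
    else:
        inc = tiny_golden_angle(7, 360.0)
        for t in range(n_frames):
            for j in range(n_il):
                m = t * n_il + j
                coords[t, j] = _rotate(base, (m * inc) % 360.0)
    traj = Trajectory(coords=coords, dcw=np.empty(0), grid=grid, params=params,
                      meta={"kind": "spiral"})
    traj.dcw = _populate_dcw(traj, dcw_method)
    return traj


def build_radial(
    grid: ImagingGrid,
    spokes_per_frame: int = 17,
    n_frames: int = 1,
    samples_per_spoke: int = 1024,
    dcw_method: str = "voronoi",
) -> Trajectory:
    """Tiny-golden-angle radial trajectory: full-diameter spokes through k=0.

    The spoke angle advances by the half-circle tiny golden angle
    ``180 / (phi + 6)`` ≈ 23.63° per spoke, continuing across frames.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    inc = tiny_golden_angle(7, 180.0)
    radius = np.linspace(-0.5, 0.5, samples_per_spoke)
    coords = np.empty((n_frames, spokes_per_frame, samples_per_spoke, 2))
    for t in range(n_frames):
        for j in range(spokes_per_frame):
            ang = np.deg2rad(((t * spokes_per_frame + j) * inc) % 360.0)
            coords[t, j, :, 0] = radius * np.cos(ang)
            coords[t, j, :, 1] = radius * np.sin(ang)
    traj = Trajectory(coords=coords, dcw=np.empty(0), grid=grid, params=None,
                      meta={"kind": "radial", "spokes_per_frame": spokes_per_frame})
    traj.dcw = _populate_dcw(traj, dcw_method)
    return traj


def _populate_dcw(traj: Trajectory, method: str) -> np.ndarray:
    # Every generated ordering (linear, tiny-golden spiral, golden radial)
    # advances by a constant rotation, so each frame's sample set is a rigid
    # rotation of frame 0 and the cell areas are identical across frames.
    dcw = np.empty(traj.coords.shape[:-1])
    dcw[:] = density_compensation(traj, frame=0, method=method)[None]
    return dcw


def _pitch_dcw(traj: Trajectory, frame: int) -> np.ndarray:
    """Analytic cell-area weights: along-track spacing x cross-track pitch."""
    pts = traj.frame(frame)
    n_il, n_s, _ = pts.shape
    M = traj.grid.matrix
    radii = np.hypot(pts[..., 0], pts[..., 1])
    # Along-track sample spacing (uniform arc length -> nearly constant).
    seg = np.hypot(np.diff(pts[..., 0], axis=1), np.diff(pts[..., 1], axis=1))
    ds = np.empty_like(radii)
    ds[:, 1:-1] = 0.5 * (seg[:, :-1] + seg[:, 1:])
    ds[:, 0] = seg[:, 0]
    ds[:, -1] = seg[:, -1]
    if traj.meta.get("kind") == "radial":
        # Cross-track spacing between spokes at radius k is k * dtheta.
        dtheta = np.pi / n_il
        w = radii * dtheta * ds
        # Center sample covers a small disk rather than a zero-area wedge.
        w = np.maximum(w, ds**2 * dtheta / (2 * np.pi))
        return w
    params = traj.params
    knorm = np.clip(radii / 0.5, 0.0, 1.0)
    pitch = acceleration_profile(params, knorm) / (M * n_il)
    # Near the center the rotated arms overlap: the cross-track spacing is
    # the azimuthal arm distance 2 pi k / N where that is smaller than the
    # radial pitch.
    cross = np.minimum(pitch, 2.0 * np.pi * radii / n_il)
    w = ds * cross
    # All interleaves share the k = 0 starting point; split its small cell.
    center = radii < 0.5 * ds
    w[center] = np.pi * (0.5 * ds[center]) ** 2 / n_il
    return np.maximum(w, 1e-15)


def _voronoi_dcw(traj: Trajectory, frame: int) -> np.ndarray:
    """Voronoi-cell-area weights, cells clipped to the sampled disk |k|<=0.5."""
    from scipy.spatial import Voronoi
    from shapely.geometry import Point, Polygon

    pts = traj.frame(frame)
    shape = pts.shape[:-1]
    flat = pts.reshape(-1, 2)
    # Merge coincident samples; their shared cell is split evenly afterwards.
    key = np.round(flat / 1e-9).astype(np.int64)
    _, uniq_idx, inverse, counts = np.unique(
        key, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    uniq = flat[uniq_idx]
    # Guard ring keeps interior cells bounded.
    n_guard = 256
    ang = np.linspace(0, 2 * np.pi, n_guard, endpoint=False)
    guard_r = 0.5 + 2.0 / traj.grid.matrix
    guard = guard_r * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    vor = Voronoi(np.vstack([uniq, guard]))
    disk = Point(0.0, 0.0).buffer(0.5, quad_segs=128)
    areas = np.zeros(len(uniq))
    for i in range(len(uniq)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        areas[i] = poly.intersection(disk).area
    w = areas[inverse] / counts[inverse]
    return w.reshape(shape)


def density_compensation(
    traj: Trajectory, frame: int = 0, method: str = "voronoi"
) -> np.ndarray:
    """Per-sample density-compensation weights for one frame.

    ``method='pitch'`` uses the analytic cell-area model (fast, exact for the
    generated spiral/radial geometries); ``method='voronoi'`` computes clipped
    Voronoi cell areas (general, slower).  Weights integrate the sampled
    k-space disk: they sum to approximately pi/4.
    """
    pts = traj.frame(frame)
    if pts.size == 0:
        raise ValueError("empty trajectory frame")
    if method == "voronoi":
        return _voronoi_dcw(traj, frame)
    if method == "pitch":
        if traj.meta.get("kind") in ("spiral", "radial"):
            return _pitch_dcw(traj, frame)
        return _voronoi_dcw(traj, frame)
    raise ValueError(f"unknown dcw method {method!r}")


def turn_crossings(traj: Trajectory, frame: int = 0, azimuth_deg: float = 0.0) -> np.ndarray:
    """Sorted radii at which the frame's interleaves cross a fixed azimuth.

    Diagnostic for Nyquist self-consistency: one radius per spiral turn per
    interleave, found by interpolating each interleave's unwrapped angle.
    Successive differences give the composite turn spacing; for a uniform
    spiral at the frame Nyquist rate they equal 1/matrix.
    """
    pts = traj.frame(frame)
    phi0 = np.deg2rad(azimuth_deg)
    crossings = []
    for il in range(pts.shape[0]):
        x, y = pts[il, :, 0], pts[il, :, 1]
        r = np.hypot(x, y)
        # Skip the near-center samples where the angle is ill-defined.
        good = r > 2.0 / traj.grid.matrix
        if good.sum() < 8:
            continue
        theta = np.unwrap(np.arctan2(y[good], x[good]))
        rr = r[good]
        m_lo = int(np.ceil((theta.min() - phi0) / (2 * np.pi)))
        m_hi = int(np.floor((theta.max() - phi0) / (2 * np.pi)))
        for m in range(m_lo, m_hi + 1):
            crossings.append(np.interp(phi0 + 2 * np.pi * m, theta, rr))
    return np.sort(np.asarray(crossings))


def frame_acceleration_range(params: SpiralParams, grid: ImagingGrid | None = None) -> tuple[float, float]:
    """Net per-frame acceleration range ``(a_inner/N, a_inner/(ratio N))``."""
    n = params.interleaves_per_frame()
    if n < 1:
        raise ValueError("interleaf count is zero")
    low = params.a_inner / n
    high = params.a_inner / (params.density_ratio * n)
    return (low, high)


# ---------------------------------------------------------------------------
# I/O and plotting


def save_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory (coords, dcw, grid and parameters) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=traj.coords.astype(np.float64))
        f.create_dataset("dcw", data=traj.dcw.astype(np.float64))
        f.attrs["matrix"] = traj.grid.matrix
        f.attrs["fov_mm"] = traj.grid.fov_mm
        f.attrs["kind"] = traj.meta.get("kind", "custom")
        if traj.meta.get("spokes_per_frame"):
            f.attrs["spokes_per_frame"] = traj.meta["spokes_per_frame"]
        if traj.params is not None:
            p = traj.params
            for name in ("r_inner", "a_inner", "r_outer", "density_ratio", "tr_ms", "t_acq_ms"):
                f.attrs[name] = getattr(p, name)
            f.attrs["transition"] = p.transition
            f.attrs["ordering"] = p.ordering
            if p.n_interleaves is not None:
                f.attrs["n_interleaves"] = p.n_interleaves


def load_trajectory(path: str) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        coords = f["coords"][...]
        dcw = f["dcw"][...]
        grid = ImagingGrid(matrix=int(f.attrs["matrix"]), fov_mm=float(f.attrs["fov_mm"]))
        params = None
        if "r_inner" in f.attrs:
            params = SpiralParams(
                r_inner=float(f.attrs["r_inner"]),
                a_inner=float(f.attrs["a_inner"]),
                r_outer=float(f.attrs["r_outer"]),
                density_ratio=float(f.attrs["density_ratio"]),
                transition=str(f.attrs["transition"]),
                ordering=str(f.attrs["ordering"]),
                tr_ms=float(f.attrs["tr_ms"]),
                t_acq_ms=float(f.attrs["t_acq_ms"]),
                n_interleaves=int(f.attrs["n_interleaves"]) if "n_interleaves" in f.attrs else None,
            )
        meta = {"kind": str(f.attrs.get("kind", "custom"))}
        if "spokes_per_frame" in f.attrs:
            meta["spokes_per_frame"] = int(f.attrs["spokes_per_frame"])
    return Trajectory(coords=coords, dcw=dcw, grid=grid, params=params, meta=meta)


def save_trajectory_csv(traj: Trajectory, path: str, frame: int = 0) -> None:
    """Write one frame's samples as CSV (interleave, sample, kx, ky, dcw);
    intended for small cases and external inspection."""
    pts = traj.frame(frame)
    dcw = traj.frame_dcw(frame)
    with open(path, "w") as f:
        f.write("interleave,sample,kx,ky,dcw\n")
        for il in range(pts.shape[0]):
            for s in range(pts.shape[1]):
                f.write(
                    f"{il},{s},{pts[il, s, 0]:.8f},{pts[il, s, 1]:.8f},"
                    f"{dcw[il, s]:.8e}\n"
                )


def plot_trajectory(traj: Trajectory, path: str, frame: int = 0) -> None:
    """Save a PNG of one frame's sampling pattern."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = traj.frame(frame)
    fig, ax = plt.subplots(figsize=(5, 5))
    for il in range(pts.shape[0]):
        ax.plot(pts[il, :, 0], pts[il, :, 1], lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlim(-0.55, 0.55)
    ax.set_ylim(-0.55, 0.55)
    ax.set_xlabel("$k_x$ (cycles/pixel)")
    ax.set_ylabel("$k_y$ (cycles/pixel)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
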