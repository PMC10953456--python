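"""Named acquisition presets: the optimized variable-density spiral, the
matched uniform spiral, and tiny-golden radial sampling.

Acceleration parameters are relative to the interleave count (net
acceleration ``a / N`` is matrix-independent), so the presets apply unchanged
at any grid size; the reference protocol grid is 240 px / 400 mm.
"""

from __future__ import annotations

import warnings

from .trajectory import ImagingGrid, SpiralParams

__all__ = ["PRESETS", "RADIAL_SPOKES_PER_FRAME", "resolve_preset", "REFERENCE_GRID"]

REFERENCE_GRID = ImagingGrid(240, 400.0)
RADIAL_SPOKES_PER_FRAME = 17


def _make_presets() -> dict[str, SpiralParams]:
    with warnings.catch_warnings():
        # The uniform preset intentionally sits outside the searched ranges.
        warnings.simplefilter("ignore")
        return {
            "optimized": SpiralParams(
                r_inner=0.15,
                a_inner=16.0,
                r_outer=0.56,
                density_ratio=0.07,
                transition="hanning",
                ordering="linear",
                tr_ms=3.67,
                t_acq_ms=55.0,
                n_interleaves=15,
            ),
            "uniform": SpiralParams(
                r_inner=1.0,
                a_inner=92.0,
                r_outer=1.0,
                density_ratio=1.0,
                transition="linear",
                ordering="linear",
                tr_ms=3.67,
                t_acq_ms=55.0,
                n_interleaves=15,
            ),
        }


PRESETS = _make_presets()


def resolve_preset(name: str, grid: ImagingGrid | None = None) -> SpiralParams:
    """Look up a spiral preset (grid-independent; ``grid`` kept for API
    symmetry with the radial preset, which needs the matrix)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]
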