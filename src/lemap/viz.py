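"""Slice rendering: entropy-map color encoding and CT-fusion overlays.

Rasters are returned as float RGB arrays in [0, 1] so every pixel is an
exact, testable function of the inputs; ``save_png`` quantizes to 8-bit on
write. The entropy range is encoded with a perceptually uniform sequential
palette (viridis by default); a fixed ``value_range`` shared across slices
keeps renders comparable. Fusion mode alpha-blends the colored map over a
windowed grayscale CT, as PET-CT viewers do.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .entropy_core import EntropyMap
from .volume_io import Volume

__all__ = ["render_slice", "render_fusion", "render_ct_slice", "save_png"]

AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
DEFAULT_PALETTE = "viridis"
DEFAULT_CT_WINDOW = (-150.0, 250.0)


def _plane(data: np.ndarray, axis: str, index: int) -> np.ndarray:
    try:
        ax = AXES[axis]
    except KeyError:
        raise ValueError(f"axis must be one of {sorted(AXES)}, got {axis!r}") from None
    if not 0 <= index < data.shape[ax]:
        raise IndexError(f"slice index {index} out of range [0, {data.shape[ax]}) on {axis} axis")
    # rows = the later remaining axis, so axial slices show x across, y down
    return np.take(data, index, axis=ax).T


def _normalize(plane: np.ndarray, value_range: tuple[float, float] | None) -> np.ndarray:
    finite = np.isfinite(plane)
    if value_range is None:
        if not finite.any():
            return np.zeros_like(plane)
        lo, hi = float(plane[finite].min()), float(plane[finite].max())
    else:
        lo, hi = map(float, value_range)
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((np.where(finite, plane, lo) - lo) / span, 0.0, 1.0)
    return norm


def _colorize(norm: np.ndarray, palette: str) -> np.ndarray:
    cmap = colormaps[palette]
    return np.asarray(cmap(norm), dtype=np.float64)[..., :3]


def _colorbar(height: int, palette: str, width: int) -> np.ndarray:
    ramp = np.linspace(1.0, 0.0, height)[:, None].repeat(width, axis=1)
    return _colorize(ramp, palette)


def render_slice(
    m: EntropyMap | Volume,
    axis: str = "axial",
    index: int = 0,
    palette: str = DEFAULT_PALETTE,
    value_range: tuple[float, float] | None = None,
    colorbar: bool = True,
) -> np.ndarray:
    """Render one map slice as a float RGB raster (rows, cols, 3) in [0, 1].

    With ``value_range=None`` the slice's finite min/max map to the palette
    endpoints; pass an explicit range to keep multiple slices comparable.
    ``colorbar=True`` appends a vertical palette ramp (max at top) separated
    by a two-pixel white gutter.
    """
    plane = _plane(m.data, axis, index)
    img = _colorize(_normalize(plane, value_range), palette)
    if colorbar:
        h = img.shape[0]
        gutter = np.ones((h, 2, 3))
        bar = _colorbar(h, palette, max(4, img.shape[1] // 16))
        img = np.concatenate([img, gutter, bar], axis=1)
    return img


def render_ct_slice(
    ct: Volume,
    axis: str = "axial",
    index: int = 0,
    window: tuple[float, float] = DEFAULT_CT_WINDOW,
) -> np.ndarray:
    """Windowed grayscale CT slice as float RGB in [0, 1]."""
    plane = _plane(ct.data, axis, index)
    gray = _normalize(plane, window)
    return np.repeat(gray[..., None], 3, axis=2)


def render_fusion(
    ct: Volume,
    m: EntropyMap,
    axis: str = "axial",
    index: int = 0,
    alpha: float = 0.5,
    palette: str = DEFAULT_PALETTE,
    value_range: tuple[float, float] | None = None,
    window: tuple[float, float] = DEFAULT_CT_WINDOW,
) -> np.ndarray:
    """Alpha-blend the colored entropy map over the grayscale CT slice.

    ``alpha=0`` reproduces the CT render exactly; ``alpha=1`` the map render
    (without color bar); in between, the per-pixel convex combination.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    ct.require_same_grid(m, what="entropy map")
    base = render_ct_slice(ct, axis, index, window)
    over = render_slice(m, axis, index, palette, value_range, colorbar=False)
    return (1.0 - alpha) * base + alpha * over


def save_png(img: np.ndarray, path: str) -> None:
    """Write a float RGB raster to PNG (8-bit)."""
    import matplotlib.image

    matplotlib.image.imsave(path, np.clip(img, 0.0, 1.0))
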