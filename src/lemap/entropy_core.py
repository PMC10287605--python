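"""Voxel-wise local Shannon entropy maps of CT-like volumes.

The map is built by sliding a cubic k×k×k kernel across the volume with a
one-voxel stride. Within each kernel the intensities are treated as discrete
symbols (integer HU by default, optionally coarsened by a bin width) and the
first-order Shannon entropy

    H = -sum_i P(i) * ln P(i)

is computed in nats, where P(i) is the occurrence probability of symbol i
among the k^3 kernel voxels. The entropy is stored at the kernel's central
voxel. The map can then be Gaussian-smoothed (sigma = 1 voxel by default)
and normalized over the mean entropy of a liver-parenchyma reference VOI.

The fast path accumulates, for every intensity symbol present in the volume,
a box-filtered occurrence count, and sums the -p*ln(p) contributions symbol
by symbol in ascending order. Per voxel this performs bit-identical
floating-point operations to the per-kernel formula, so the map matches a
brute-force per-voxel evaluation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .volume_io import Mask, Volume

__all__ = [
    "KernelConfig",
    "EntropyMap",
    "kernel_entropy",
    "local_entropy_map",
    "smooth_map",
    "normalize_map",
]

PaddingMode = Literal["reflect", "exclude-border"]


@dataclass(frozen=True)
class KernelConfig:
    """Sliding-kernel configuration.

    k
        Odd kernel side length in voxels. 5 (a 5×5×5 neighborhood, 125
        voxels) is the default trade-off between spatial resolution and
        noise smoothing.
    quantization_bin_width
        Intensity units per symbol bin. The default of 1 keeps integer HU
        values as distinct symbols; larger widths merge adjacent intensities
        (floor(value / bin_width)).
    padding_mode
        'reflect' mirrors the volume at its faces (no edge duplication) so
        the map has the full input shape; 'exclude-border' marks the
        (k-1)/2-voxel border shell as missing (NaN) instead.
    """

    k: int = 5
    quantization_bin_width: float = 1.0
    padding_mode: PaddingMode = "reflect"

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"kernel side k must be odd and >= 3, got {self.k}")
        if not self.quantization_bin_width > 0:
            raise ValueError(f"quantization bin width must be > 0, got {self.quantization_bin_width}")
        if self.padding_mode not in ("reflect", "exclude-border"):
            raise ValueError(f"unknown padding mode {self.padding_mode!r}")

    @property
    def n_kernel_voxels(self) -> int:
        return self.k ** 3

    @property
    def max_entropy(self) -> float:
        """Upper bound ln(k^3) on any kernel's entropy, in nats."""
        return math.log(self.n_kernel_voxels)


@dataclass
class EntropyMap(Volume):
    """A local-entropy map: per-voxel entropy in nats, with provenance flags."""

    kernel: KernelConfig = field(default_factory=KernelConfig)
    smoothed: bool = False
    smooth_sigma: float | None = None
    normalized: bool = False
    norm_reference: float | None = None

    @property
    def stage(self) -> str:
        """Pipeline stage of this map: raw, smoothed, or normalized."""
        if self.normalized:
            return "normalized"
        return "smoothed" if self.smoothed else "raw"

    def provenance_description(self) -> str:
        """One-line provenance string (recorded in the NIfTI description)."""
        parts = [f"local entropy k={self.kernel.k}",
                 f"bin={self.kernel.quantization_bin_width:g}",
                 f"pad={self.kernel.padding_mode}"]
        if self.smoothed:
            parts.append(f"sigma={self.smooth_sigma:g}")
        if self.normalized:
            parts.append(f"norm_ref={self.norm_reference:.6g}")
        return "; ".join(parts)


def _symbols(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Map intensities to integer symbol labels by flooring value/bin_width."""
    if bin_width == 1.0:
        return np.floor(values).astype(np.int64)
    return np.floor(values / bin_width).astype(np.int64)


def kernel_entropy(values, bin_width: float = 1.0) -> float:
    """Shannon entropy in nats of one kernel's intensity multiset.

    Symbols are formed by flooring value/bin_width; P(i) is the count of
    symbol i over the total count. Contributions -P(i) ln P(i) are summed
    in ascending symbol order (the same order and arithmetic as the map
    fast path, so the two agree exactly).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("kernel_entropy: empty input")
    if not np.isfinite(values).all():
        raise ValueError("kernel_entropy: non-finite values")
    _, counts = np.unique(_symbols(values, bin_width), return_counts=True)
    n = float(values.size)
    ent = np.float64(0.0)
    for c in counts:  # ascending symbol order
        p = np.float64(c) / n
        ent = ent - p * np.log(p)
    return float(ent)


def local_entropy_map(v: Volume, cfg: KernelConfig | None = None) -> EntropyMap:
    """Compute the local-entropy map of a volume.

    Each output voxel holds the entropy of the k×k×k neighborhood centered
    on it (one-voxel stride, full input shape). With ``reflect`` padding the
    volume is mirrored at its faces; with ``exclude-border`` the border
    shell of width (k-1)/2 is NaN.
    """
    cfg = cfg or KernelConfig()
    k = cfg.k
    half = k // 2
    if cfg.padding_mode == "exclude-border" and min(v.data.shape) < k:
        raise ValueError(
            f"volume shape {v.data.shape} smaller than kernel k={k} with exclude-border padding"
        )
    if not np.isfinite(v.data).all():
        raise ValueError("local_entropy_map: volume contains non-finite voxels")

    sym = _symbols(np.asarray(v.data, dtype=np.float64), cfg.quantization_bin_width)
    uniq = np.unique(sym)
    n = float(cfg.n_kernel_voxels)
    ent = np.zeros(v.data.shape, dtype=np.float64)
    # Per-symbol occurrence counts over each kernel via a separable box filter.
    # uniform_filter returns the neighborhood mean of the 0/1 indicator; times
    # k^3 and rounded it is the exact integer count (the float error is far
    # below 0.5 for counts <= k^3).
    for s in uniq:
        counts = ndimage.uniform_filter((sym == s).astype(np.float64), size=k, mode="mirror")
        counts = np.rint(counts * n)
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts > 0, p * np.log(p), 0.0)
        ent = ent - term

    if cfg.padding_mode == "exclude-border":
        valid = np.zeros(v.data.shape, dtype=bool)
        valid[half:-half or None, half:-half or None, half:-half or None] = True
        ent[~valid] = np.nan

    meta = dict(v.meta)
    m = EntropyMap(data=ent, spacing=v.spacing, origin=v.origin, meta=meta, kernel=cfg)
    m.meta["description"] = m.provenance_description()
    return m


def smooth_map(m: EntropyMap, sigma: float = 1.0) -> EntropyMap:
    """Gaussian-smooth an entropy map (sigma in voxels, default 1).

    With exclude-border maps the missing shell is excluded from the filter
    support (normalized convolution over valid voxels only).
    """
    if m.smoothed:
        raise ValueError("map is already smoothed")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    data = m.data
    missing = ~np.isfinite(data)
    if missing.any():
        filled = np.where(missing, 0.0, data)
        num = ndimage.gaussian_filter(filled, sigma=sigma, mode="mirror")
        den = ndimage.gaussian_filter((~missing).astype(np.float64), sigma=sigma, mode="mirror")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[missing] = np.nan
    else:
        sm = ndimage.gaussian_filter(data, sigma=sigma, mode="mirror")
    out = replace(m, data=sm, smoothed=True, smooth_sigma=float(sigma), meta=dict(m.meta))
    out.meta["description"] = out.provenance_description()
    return out


def normalize_map(m: EntropyMap, liver: Mask, method: str = "divide") -> EntropyMap:
    """Normalize a map over the mean entropy of the liver-parenchyma VOI.

    Every voxel is divided by the mean map value inside ``liver`` (so the
    in-mask mean of the result is exactly 1). ``method='subtract'`` is
    available as an alternative reading of "normalized over the mean".
    """
    if m.normalized:
        raise ValueError("map is already normalized")
    if method not in ("divide", "subtract"):
        raise ValueError(f"unknown normalization method {method!r}")
    m.require_same_grid(liver, what="liver mask")
    vals = m.data[liver.data]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("liver mask contains no valid map voxels")
    ref = float(vals.mean())
    if method == "divide" and abs(ref) < 1e-12:
        raise ValueError(
            "liver reference mean entropy is zero (constant liver); "
            "division normalization is undefined"
        )
    data = m.data / ref if method == "divide" else m.data - ref
    out = replace(m, data=data, normalized=True, norm_reference=ref, meta=dict(m.meta))
    out.meta["description"] = out.provenance_description()
    return out
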