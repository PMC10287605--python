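"""Seeded digital phantoms: liver background, patterned lesions, vessels.

A phantom is a CT-like integer-HU volume: Gaussian liver parenchyma, one
spherical lesion whose *texture* (local intensity SD) is arranged to carry a
prescribed entropy pattern, and optional bright tubular vessels. Because
integer-quantized HU with a larger local SD spread over more distinct
symbols per kernel, high-SD regions are provably hyper-entropic on the
local-entropy map — the simplest mechanism that moves the statistic the
map measures.

Default condition set: 64^3 grid at 1 mm isotropic, liver 100 +/- 10 HU,
hypodense lesion (60 HU) of radius 14 voxels, hyper texture SD 35 HU,
iso/hypo texture SD 5 HU, rim thickness 3 voxels, scattered-component
fraction 0.4, incomplete-rim angular gap 0.2 of the azimuth, two vessels of
radius 2 at +150 HU, liver-reference VOI a radius-8 "virtual biopsy" ball
remote from the lesion. All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import Mask, Volume

__all__ = [
    "PHANTOM_PATTERNS",
    "PhantomSpec",
    "Phantom",
    "CohortMember",
    "generate_phantom",
    "generate_cohort",
]

#: generator target patterns (rim split into its complete/incomplete variants)
PHANTOM_PATTERNS: tuple[str, ...] = (
    "homogeneous",
    "inhomogeneous",
    "peripheral_rim_complete",
    "peripheral_rim_incomplete",
    "mixed",
)

#: generator pattern -> (classifier label, rim subtype) ground truth
TRUTH_LABELS: dict[str, tuple[str, str]] = {
    "homogeneous": ("homogeneous", "none"),
    "inhomogeneous": ("inhomogeneous", "none"),
    "peripheral_rim_complete": ("peripheral_rim", "complete"),
    "peripheral_rim_incomplete": ("peripheral_rim", "incomplete"),
    "mixed": ("mixed", "complete"),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver_mean: float = 100.0
    liver_sd: float = 10.0
    lesion_center: tuple[int, int, int] | None = None  # default: grid center
    lesion_radius: int = 14
    lesion_mean: float = 60.0
    pattern: str = "homogeneous"
    hyper_sd: float = 35.0  # high-heterogeneity texture SD (hyper regions)
    low_sd: float = 5.0  # low texture SD (iso/hypo regions)
    rim_thickness: int = 3
    scatter_fraction: float = 0.4  # hyper share of a scattered lesion/core
    scatter_scale: float = 3.0  # blob length scale (voxels) of the scatter field
    gap_fraction: float = 0.2  # azimuthal gap of an incomplete rim
    vessel_count: int = 2
    vessel_radius: float = 2.0
    vessel_contrast: float = 150.0
    biopsy_radius: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PHANTOM_PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PHANTOM_PATTERNS}")
        if self.lesion_radius < 5:
            raise ValueError(
                f"lesion radius must be >= 5 voxels (smaller lesions carry too few "
                f"voxels for stable statistics), got {self.lesion_radius}"
            )
        center = self.center
        for c, r, n in zip(center, (self.lesion_radius,) * 3, self.shape):
            if c - r < 0 or c + r >= n:
                raise ValueError(f"lesion (center {center}, radius {self.lesion_radius}) "
                                 f"does not fit inside grid {self.shape}")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        if not 0.0 < self.scatter_fraction < 1.0:
            raise ValueError("scatter_fraction must be in (0, 1)")

    @property
    def center(self) -> tuple[int, int, int]:
        if self.lesion_center is not None:
            return self.lesion_center
        return tuple(n // 2 for n in self.shape)

    @property
    def truth(self) -> tuple[str, str]:
        """Ground-truth (pattern label, rim subtype) of this spec."""
        return TRUTH_LABELS[self.pattern]


@dataclass
class Phantom:
    """One generated phantom: CT, masks, and the ground-truth pattern."""

    ct: Volume
    tumor: Mask
    liver: Mask
    truth_label: str
    truth_subtype: str
    spec: PhantomSpec


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _lesion_sd_field(spec: PhantomSpec, lesion: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Texture-SD assignment inside the lesion for the target pattern."""
    shape = spec.shape
    center = spec.center
    sd = np.where(lesion, spec.low_sd, 0.0)
    inner = _sphere(shape, center, spec.lesion_radius - spec.rim_thickness)
    shell = lesion & ~inner

    pattern = spec.pattern
    if pattern == "homogeneous":
        sd[lesion] = spec.hyper_sd
        return sd

    if pattern in ("peripheral_rim_complete", "peripheral_rim_incomplete", "mixed"):
        sd[shell] = spec.hyper_sd
        if pattern == "peripheral_rim_incomplete" and spec.gap_fraction > 0:
            # carve an azimuthal wedge out of the rim; for a spherical shell
            # the wedge's area fraction equals its azimuth fraction
            x, y = np.ogrid[0:shape[0], 0:shape[1]]
            phi0 = float(rng.uniform(0, 2 * np.pi))
            phi = (np.arctan2(y - center[1], x - center[0]) - phi0) % (2 * np.pi)
            gap2d = phi < 2 * np.pi * spec.gap_fraction
            sd[shell & gap2d[:, :, None]] = spec.low_sd
    if pattern in ("inhomogeneous", "mixed"):
        # blob-scale scattered hyper patches: threshold a smoothed random
        # field at the quantile giving the requested hyper share. Patches are
        # wider than the entropy kernel so the mixture stays resolvable.
        g = ndimage.gaussian_filter(rng.standard_normal(shape), spec.scatter_scale)
        region = lesion if pattern == "inhomogeneous" else inner
        if region.any():
            thr = np.quantile(g[region], 1.0 - spec.scatter_fraction)
            sd[region & (g >= thr)] = spec.hyper_sd
    return sd


def _vessel_mask(spec: PhantomSpec) -> np.ndarray:
    """Straight y-axis cylinders at fixed fractional (x, z) stations."""
    nx, ny, nz = spec.shape
    mask = np.zeros(spec.shape, dtype=bool)
    stations = [(0.80, 0.30), (0.30, 0.80), (0.80, 0.80), (0.15, 0.45)]
    x, z = np.ogrid[0:nx, 0:nz]
    for fx, fz in stations[: spec.vessel_count]:
        cx, cz = fx * (nx - 1), fz * (nz - 1)
        tube2d = (x - cx) ** 2 + (z - cz) ** 2 <= spec.vessel_radius**2
        mask |= np.broadcast_to(tube2d[:, None, :], spec.shape)
    return mask


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> Phantom:
    """Generate one phantom, fully reproducible from ``spec.seed``."""
    spec = replace(spec, **overrides) if spec is not None else PhantomSpec(**overrides)
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    lesion = _sphere(shape, spec.center, spec.lesion_radius)
    # draw order is fixed so every field is reproducible from the seed
    liver_noise = rng.normal(0.0, spec.liver_sd, shape)
    lesion_noise = rng.standard_normal(shape)
    sd_field = _lesion_sd_field(spec, lesion, rng)

    ct = spec.liver_mean + liver_noise
    ct[lesion] = spec.lesion_mean + sd_field[lesion] * lesion_noise[lesion]

    vessels = _vessel_mask(spec)
    vessels &= ~lesion
    ct[vessels] = spec.liver_mean + spec.vessel_contrast + 5.0 * lesion_noise[vessels]
    ct = np.rint(ct)  # integer HU, CT convention

    # liver-reference VOI: a "virtual biopsy" ball remote from the lesion,
    # in the low-(x,y,z) octant, excluding (dilated) vessels
    b = spec.biopsy_radius
    bc = tuple(max(b + 2, int(0.22 * n)) for n in shape)
    biopsy = _sphere(shape, bc, b)
    vessels_wide = ndimage.binary_dilation(vessels, iterations=2)
    liver_voi = biopsy & ~vessels_wide & ~lesion
    if not liver_voi.any():
        raise ValueError("liver reference VOI is empty; adjust biopsy/vessel geometry")

    meta = {"phantom_pattern": spec.pattern, "seed": spec.seed}
    vol = Volume(data=ct, spacing=spec.spacing, meta=meta)
    label, subtype = spec.truth
    return Phantom(
        ct=vol,
        tumor=Mask(data=lesion, spacing=spec.spacing),
        liver=Mask(data=liver_voi, spacing=spec.spacing),
        truth_label=label,
        truth_subtype=subtype,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortMember:
    """One subject of a synthetic two-group cohort (lazily generated)."""

    spec: PhantomSpec
    group: str

    def generate(self) -> Phantom:
        return generate_phantom(self.spec)


def generate_cohort(
    n_per_pattern: int,
    base_spec: PhantomSpec | None = None,
    effect: float = 20.0,
    seed: int = 0,
    patterns: Sequence[str] = PHANTOM_PATTERNS,
) -> list[CohortMember]:
    """Build a two-group phantom cohort differing in lesion texture SD.

    Group "responder" lesions use ``base_spec.hyper_sd``; group
    "non_responder" lesions use ``hyper_sd - effect`` (HU). With
    ``effect=0`` the groups are exchangeable (null condition). Returns
    ``2 * n_per_pattern * len(patterns)`` members with per-member seeds
    derived deterministically from ``seed``.
    """
    if n_per_pattern < 1:
        raise ValueError("n_per_pattern must be >= 1")
    base = base_spec or PhantomSpec()
    if base.hyper_sd - effect <= 0:
        raise ValueError("effect too large: non-responder texture SD would be <= 0")
    members = []
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(2 * n_per_pattern * len(patterns) * 2) % (2**31))
    for group, hyper_sd in (("responder", base.hyper_sd), ("non_responder", base.hyper_sd - effect)):
        for pattern in patterns:
            for _ in range(n_per_pattern):
                s = replace(base, pattern=pattern, hyper_sd=float(hyper_sd), seed=int(next(child)))
                members.append(CohortMember(spec=s, group=group))
    return members
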