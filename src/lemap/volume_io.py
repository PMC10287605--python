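"""NIfTI volume and mask I/O and the in-memory grid data model.

Volumes are held as plain float arrays indexed ``(x, y, z)`` in the RAS+
anatomical convention (nibabel's closest-canonical orientation). All kernel
and rim geometry downstream is defined in voxel space of that orientation.
Voxel coordinates are 0-based; masks are pure voxel-membership sets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "GridMismatchError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "crop_to_mask",
]

#: absolute tolerance (mm) for spacing/origin compatibility between grids
GRID_TOL = 1e-4


class GridMismatchError(ValueError):
    """Two images do not live on the same voxel lattice."""


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities: Hounsfield units for CT-like input,
        nats for entropy maps.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Per-axis physical offset of voxel (0,0,0) in mm.
    meta
        Free-form provenance record.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume must be 3D with all dimensions >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must have 3 components, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume | Mask", tol: float = GRID_TOL) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_grid(self, other: "Volume | Mask", what: str = "image") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} grid (shape={other.data.shape}, spacing={tuple(other.spacing)}, "
                f"origin={tuple(other.origin)}) does not match reference grid "
                f"(shape={self.data.shape}, spacing={self.spacing}, origin={self.origin})"
            )


@dataclass
class Mask(Volume):
    """A boolean VOI on the same lattice as its companion Volume."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            self.data = self.data != 0
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1/2 volume, reorienting to closest-canonical (RAS+).

    The file's scaling slope/intercept is applied; a trailing singleton
    fourth axis is squeezed. Non-finite voxels are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(path)
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D payload (or 4D with singleton fourth axis), "
            f"got shape {data.shape}"
        )
    if not np.isfinite(data).all():
        n_bad = int((~np.isfinite(data)).sum())
        raise ValueError(f"{path}: {n_bad} NaN/Inf voxel(s); refusing to load")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    meta: dict = {"source": path}
    descrip = img.header.get("descrip")
    if descrip is not None:
        text = bytes(descrip.tobytes()).split(b"\x00")[0].decode("utf-8", "replace")
        if text:
            meta["description"] = text
    return Volume(data=data, spacing=tuple(float(z) for z in zooms),
                  origin=tuple(float(o) for o in origin), meta=meta)


def read_mask(path: str | os.PathLike, reference: Volume) -> Mask:
    """Read a VOI mask and enforce grid compatibility with ``reference``.

    Any nonzero voxel is treated as inside the VOI. An all-zero mask is
    rejected: an empty VOI cannot serve as tumor or liver reference.
    """
    vol = read_volume(path)
    reference.require_same_grid(vol, what=f"mask {path}")
    mask = Mask(data=vol.data != 0, spacing=vol.spacing, origin=vol.origin, meta=vol.meta)
    if mask.n_voxels == 0:
        raise ValueError(f"{path}: empty VOI (no nonzero voxels)")
    return mask


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a Volume (or Mask) as NIfTI.

    Float maps are stored as float64 so the write→read round trip is exact;
    masks are stored as uint8. ``v.meta['description']`` (if present) is
    recorded in the header description field, truncated to its 80-byte limit.
    """
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"cannot write {path}: directory {parent} does not exist")
    data = v.data
    dtype = np.uint8 if data.dtype == bool else np.float64
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    descrip = v.meta.get("description")
    if descrip:
        img.header["descrip"] = str(descrip).encode("utf-8")[:79]
    nib.save(img, path)


def write_mask(m: Mask, path: str | os.PathLike) -> None:
    write_volume(m, path)


def crop_to_mask(v: Volume, mask: Mask, margin: int = 0) -> tuple[Volume, Mask]:
    """Crop a volume and mask to the mask's bounding box plus ``margin`` voxels.

    Used to restrict expensive per-voxel work to a neighborhood of a VOI:
    local operations whose support radius is at most ``margin`` produce the
    same values inside the VOI on the crop as on the full grid.
    """
    v.require_same_grid(mask, what="mask")
    if mask.n_voxels == 0:
        raise ValueError("cannot crop to an empty mask")
    idx = np.argwhere(mask.data)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.data.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    origin = tuple(o + s * int(a) for o, s, a in zip(v.origin, v.spacing, lo))
    cv = replace(v, data=v.data[sl], origin=origin, meta=dict(v.meta))
    cm = Mask(data=mask.data[sl], spacing=mask.spacing, origin=origin, meta=dict(mask.meta))
    return cv, cm
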