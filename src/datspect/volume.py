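"""3D uptake-volume container with NIfTI-1 round-tripping.

All stages of the pipeline operate on :class:`UptakeVolume`, a thin wrapper
around a 3D float array that carries the voxel size, a tag naming the common
space the cohort is registered in, and whether the values are raw tracer
counts or standardized (reference-region sd) units.  The grid convention is
RAS-like: the first axis runs left -> right, the second posterior ->
anterior, the third inferior -> superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

RAW = "raw"
STANDARDIZED = "standardized"

#: default label for the common space synthetic cohorts are generated in
DEFAULT_SPACE = "synthetic-RAS"


@dataclass
class UptakeVolume:
    """A co-registered 3D uptake map.

    Parameters
    ----------
    data:
        3D array of voxel values; must be finite everywhere.
    voxel_size:
        Physical voxel edge lengths in mm, one per axis.
    space_tag:
        Label of the common anatomical space; volumes from different spaces
        must never be combined.
    units:
        ``"raw"`` or ``"standardized"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = DEFAULT_SPACE
    units: str = RAW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        self.voxel_size = vs
        if self.units not in (RAW, STANDARDIZED):
            raise ValueError(f"units must be {RAW!r} or {STANDARDIZED!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cc (cm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def with_data(self, data: np.ndarray, units: str | None = None) -> "UptakeVolume":
        """Copy of this volume with new voxel data (same grid metadata)."""
        out = replace(self, data=np.asarray(data, dtype=np.float64))
        if units is not None:
            out.units = units
        return out

    # ------------------------------------------------------------------ I/O
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size) + [1.0])

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header["descrip"] = f"units={self.units};space={self.space_tag}".encode()[:79]
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, units: str | None = None, space_tag: str | None = None) -> "UptakeVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
        meta = dict(item.split("=", 1) for item in descrip.split(";") if "=" in item)
        if units is None:
            units = meta.get("units", RAW)
        if space_tag is None:
            space_tag = meta.get("space", DEFAULT_SPACE)
        return cls(data=data, voxel_size=voxel_size, space_tag=space_tag, units=units)


def load_mask(path, reference: UptakeVolume | None = None) -> np.ndarray:
    """Load a binary NIfTI mask, optionally checking it matches a reference grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must contain only 0/1 values, found {uniq[:10]}")
    mask = data.astype(bool)
    if reference is not None and mask.shape != reference.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {reference.shape}")
    return mask


def save_mask(mask: np.ndarray, voxel_size, path) -> None:
    vol = UptakeVolume(np.asarray(mask, dtype=np.float64), voxel_size=tuple(voxel_size))
    img = nib.Nifti1Image(mask.astype(np.uint8), vol.affine())
    nib.save(img, str(path))


def check_same_grid(volumes: "list[UptakeVolume]") -> None:
    """Raise if volumes differ in shape, voxel size or declared space."""
    if not volumes:
        raise ValueError("no volumes given")
    first = volumes[0]
    for v in volumes[1:]:
        if v.shape != first.shape:
            raise ValueError(f"mixed grid shapes: {first.shape} vs {v.shape}")
        if not np.allclose(v.voxel_size, first.voxel_size):
            raise ValueError(f"mixed voxel sizes: {first.voxel_size} vs {v.voxel_size}")
        if v.space_tag != first.space_tag:
            raise ValueError(
                f"volumes declare different spaces ({first.space_tag!r} vs {v.space_tag!r}); "
                "co-registration to a single common space is required"
            )
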