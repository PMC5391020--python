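"""Reference-region intensity standardization.

DaT-SPECT voxel values have arbitrary units that vary between subjects and
scans, so each volume is re-expressed relative to a low-binding reference
region (the occipital cortex): every voxel becomes the number of
reference-region standard deviations it sits above the reference mean,

    x_sd = (x - ref_mean) / ref_sd.

After this transform a voxel value of 3 reads directly as "3 sd above
background", which is what the template-mask threshold later exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import RAW, STANDARDIZED, UptakeVolume


@dataclass(frozen=True)
class ReferenceStats:
    """Summary of the reference (occipital) region of one volume."""

    mean: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise ValueError(f"reference region needs >= 2 voxels, got {self.n_voxels}")
        if self.sd < 0:
            raise ValueError("reference sd must be non-negative")


def compute_reference_stats(volume: UptakeVolume, reference_mask: np.ndarray) -> ReferenceStats:
    """Mean and sample standard deviation of the voxels under the mask.

    The standard deviation uses the n-1 (sample) denominator; the reference
    region is typically thousands of voxels so the estimator choice is
    numerically negligible, but it is fixed for reproducibility.
    """
    mask = np.asarray(reference_mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    values = volume.data[mask]
    if values.size == 0:
        raise ValueError("reference mask is empty")
    if values.size < 2:
        raise ValueError("reference mask must cover at least 2 voxels")
    return ReferenceStats(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_voxels=int(values.size),
    )


def standardize(volume: UptakeVolume, stats: ReferenceStats) -> UptakeVolume:
    """Transform every voxel to reference-sd units: (x - mean) / sd.

    Raises if the reference sd is zero (a constant reference region carries
    no scale information and would make the transform degenerate).
    """
    if stats.sd <= 0:
        raise ValueError(
            "reference region standard deviation is zero; the region is degenerate "
            "and cannot define a standardization scale"
        )
    return volume.with_data((volume.data - stats.mean) / stats.sd, units=STANDARDIZED)


def standardize_to_reference(volume: UptakeVolume, reference_mask: np.ndarray) -> UptakeVolume:
    """Convenience: compute reference stats and standardize in one call."""
    return standardize(volume, compute_reference_stats(volume, reference_mask))
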