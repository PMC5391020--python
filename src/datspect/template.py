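"""Population template and striatum-mask extraction.

The control-group template is the voxel-wise mean of the standardized maps
of the control (NMNC) cohort.  Because standardized units already express
uptake as "standard deviations above the reference background", the
striatum analysis mask is simply the set of template voxels strictly above
a threshold (default 3 sd), cleaned of small speckle components.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume import STANDARDIZED, UptakeVolume, check_same_grid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class CohortTemplate:
    """Mean standardized map of a control cohort, optionally with its mask."""

    mean_map: UptakeVolume
    n_subjects: int
    striatum_mask: np.ndarray | None = None
    threshold_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a template requires at least 2 subjects")


def build_template(scans: list[UptakeVolume]) -> CohortTemplate:
    """Voxel-wise arithmetic mean of standardized volumes on one grid."""
    if len(scans) < 2:
        raise ValueError(f"need >= 2 volumes to build a template, got {len(scans)}")
    check_same_grid(scans)
    for s in scans:
        if s.units != STANDARDIZED:
            raise ValueError("all template inputs must be standardized volumes")
    mean = np.mean([s.data for s in scans], axis=0)
    return CohortTemplate(mean_map=scans[0].with_data(mean), n_subjects=len(scans))


def extract_striatum_mask(
    template: CohortTemplate,
    threshold_sd: float = 3.0,
    min_component_voxels: int = 20,
    connectivity: int = 26,
) -> CohortTemplate:
    """Threshold the template and keep sufficiently large components.

    Voxels strictly above ``threshold_sd`` are kept; connected components
    (26-neighbourhood by default) smaller than ``min_component_voxels`` are
    discarded as speckle.  Returns a new template with the mask set.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    raw = template.mean_map.data > threshold_sd
    if not raw.any():
        raise ValueError(
            f"no voxels exceed {threshold_sd} sd above background; "
            "review the threshold or the input standardization"
        )
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labeled, n_comp = ndimage.label(raw, structure=structure)
    sizes = np.bincount(labeled.ravel())
    keep = np.flatnonzero(sizes >= min_component_voxels)
    keep = keep[keep != 0]
    mask = np.isin(labeled, keep)
    if not mask.any():
        raise ValueError(
            f"thresholding at {threshold_sd} sd left only components smaller than "
            f"{min_component_voxels} voxels; review the threshold"
        )
    return replace(template, striatum_mask=mask, threshold_sd=float(threshold_sd))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
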