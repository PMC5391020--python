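"""Seeded synthetic DaT-SPECT cohort generator.

Real DaT-SPECT studies of this kind compare a Parkinson's disease group
(PD), non-manifesting LRRK2 G2019S carriers (NMC) and non-manifesting
non-carriers (NMNC) on spatially normalized, occipital-standardized uptake
volumes.  This module emulates those *post-registration* volumes directly:

* a low-uptake background filling the grid,
* a large posterior-inferior ellipsoid acting as the occipital reference
  region (pure background signal),
* four striatal ellipsoids — dorsal and ventral bodies in each hemisphere,
  mirrored across the midsagittal plane, the dorsal body superior and
  posterior to the ventral one — with group-specific mean amplitudes,
* voxel-wise Gaussian measurement noise, optional Gaussian smoothing, and
  a per-subject, per-region amplitude offset that produces realistic
  between-subject spread of VOI means.

Amplitudes are expressed in "standardized-equivalent" units: the background
texture is calibrated so the occipital region has unit standard deviation,
hence after reference-region standardization a region generated with
amplitude A averages approximately A.  Group defaults follow the published
pattern for this design: PD strongly reduced everywhere (most of all
dorsally), NMC mildly reduced in the right dorsal striatum, NMNC at
baseline.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configurations yield
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import DEFAULT_SPACE, RAW, UptakeVolume, save_mask

GROUPS = ("PD", "NMC", "NMNC")
SUBREGIONS = ("R_dorsal", "R_ventral", "L_dorsal", "L_ventral")

#: clinical scales: (column, valid minimum, valid maximum)
CLINICAL_SCALES = {
    "UPDRS3": (0.0, 132.0),
    "MoCA": (0.0, 30.0),
    "UPSIT": (0.0, 40.0),
    "BDI": (0.0, 63.0),
    "SCOPA_AUT": (0.0, 69.0),
    "ESS": (0.0, 24.0),
    "RBDQ": (0.0, 13.0),
    "NMS": (0.0, 30.0),
}

MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex"] + list(CLINICAL_SCALES)


@dataclass(frozen=True)
class RegionSpec:
    """An ellipsoidal region on the voxel grid.

    ``center`` and ``semi_axes`` are in voxel coordinates; ``amplitude`` is
    the mean uptake added inside the ellipsoid, in standardized-equivalent
    units.
    """

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    amplitude: float

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"region {self.name!r}: semi_axes must be positive")

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean voxel mask of the ellipsoid."""
        self.check_inside(grid_shape)
        grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
        q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, self.center, self.semi_axes))
        return q <= 1.0

    def check_inside(self, grid_shape: tuple[int, int, int]) -> None:
        for axis, (c, s, n) in enumerate(zip(self.center, self.semi_axes, grid_shape)):
            if c - s < 0 or c + s > n - 1:
                raise ValueError(
                    f"region {self.name!r} extends outside the grid on axis {axis} "
                    f"(center {c}, semi-axis {s}, grid size {n})"
                )


@dataclass(frozen=True)
class GroupProfile:
    """Group-level generative parameters.

    ``amplitudes`` maps each striatal sub-region (hemisphere x dorsal/
    ventral) to its mean uptake; ``age_mean``/``age_sd`` are in years;
    ``clinical`` maps each scale to its (mean, sd); ``female_fraction`` is
    the probability of drawing a female subject.
    """

    name: str
    amplitudes: dict[str, float]
    age_mean: float
    age_sd: float
    clinical: dict[str, tuple[float, float]] = field(default_factory=dict)
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        missing = set(SUBREGIONS) - set(self.amplitudes)
        if missing:
            raise ValueError(f"profile {self.name!r} missing amplitudes for {sorted(missing)}")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError(f"profile {self.name!r}: amplitudes must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation settings.

    ``background_sd`` is the voxel texture of non-striatal tissue (the
    occipital reference inherits it); ``noise_sd`` is measurement noise
    added to every voxel; together the defaults give the reference region
    unit variance, which keeps standardized uptake on the amplitude scale.
    ``amplitude_between_subject_sd`` is the sd of the per-subject,
    per-region amplitude offset, the dominant source of between-subject
    spread of VOI means.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"PD": 18, "NMC": 30, "NMNC": 30}
    )
    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: float = 2.0
    background_mean: float = 0.0
    background_sd: float = float(np.sqrt(1.0 - 0.5**2))
    noise_sd: float = 0.5
    amplitude_between_subject_sd: float = 0.5
    smoothing_fwhm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("subject counts must be >= 0")
        if sum(self.n_per_group.values()) < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.noise_sd < 0 or self.background_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.smoothing_fwhm < 0:
            raise ValueError("smoothing_fwhm must be >= 0")

    @property
    def voxel_size_tuple(self) -> tuple[float, float, float]:
        return (self.voxel_size,) * 3


@dataclass
class SubjectRecord:
    """One synthetic subject: volume plus manifest metadata."""

    subject_id: str
    group: str
    age: float
    sex: str
    scores: dict[str, float]
    volume: UptakeVolume

    def manifest_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "age": self.age,
            "sex": self.sex,
        }
        row.update({k: self.scores.get(k, np.nan) for k in CLINICAL_SCALES})
        return row


@dataclass
class Cohort:
    """A generated cohort with its ground truth."""

    subjects: list[SubjectRecord]
    manifest: pd.DataFrame
    truth_labels: np.ndarray  # 0 outside; 1..4 per SUBREGIONS order
    truth_names: dict[int, str]
    reference_mask: np.ndarray
    config: CohortConfig

    @property
    def striatum_mask(self) -> np.ndarray:
        return self.truth_labels > 0

    def truth_mask(self, name: str) -> np.ndarray:
        ids = [i for i, n in self.truth_names.items() if n == name]
        if not ids:
            raise KeyError(name)
        return self.truth_labels == ids[0]


# --------------------------------------------------------------------------
# default geometry and profiles
# --------------------------------------------------------------------------

def default_regions(
    grid_shape: tuple[int, int, int] = (64, 64, 48),
    amplitudes: dict[str, float] | None = None,
) -> list[RegionSpec]:
    """Bilateral dorsal/ventral striatal ellipsoids, mirrored at the midline.

    On the default 64x64x48 grid at 2 mm the dorsal body holds ~2.4 cc and
    the ventral ~1.1 cc, matching the order of magnitude of data-driven
    striatal VOIs.  Coordinates scale linearly with the grid.
    """
    amplitudes = amplitudes or {r: 0.0 for r in SUBREGIONS}
    nx, ny, nz = grid_shape
    sx, sy, sz = nx / 64.0, ny / 64.0, nz / 48.0
    mid = (nx - 1) / 2.0
    lateral = 10.5 * sx  # voxels from midline to each striatum's center

    def spec(name, y, z, semi):
        x = mid + lateral if name.startswith("R") else mid - lateral
        return RegionSpec(
            name=name,
            center=(x, y * sy, z * sz),
            semi_axes=(semi[0] * sx, semi[1] * sy, semi[2] * sz),
            amplitude=amplitudes[name],
        )

    dorsal_semi, ventral_semi = (3.0, 6.0, 4.0), (2.5, 4.0, 3.2)
    return [
        spec("R_dorsal", 30.0, 28.0, dorsal_semi),
        spec("R_ventral", 39.0, 20.0, ventral_semi),
        spec("L_dorsal", 30.0, 28.0, dorsal_semi),
        spec("L_ventral", 39.0, 20.0, ventral_semi),
    ]


def default_reference_region(grid_shape: tuple[int, int, int] = (64, 64, 48)) -> RegionSpec:
    """Occipital-like reference: a large posterior-inferior ellipsoid."""
    nx, ny, nz = grid_shape
    sx, sy, sz = nx / 64.0, ny / 64.0, nz / 48.0
    return RegionSpec(
        name="occipital_reference",
        center=((nx - 1) / 2.0, 10.0 * sy, 18.0 * sz),
        semi_axes=(12.0 * sx, 5.5 * sy, 8.0 * sz),
        amplitude=0.0,
    )


def default_profiles() -> list[GroupProfile]:
    """Default generative profiles for the PD / NMC / NMNC design.

    Dorsal amplitudes follow the published group means for this design
    (PD right/left 2.2/2.3, NMC 4.2/4.3, NMNC 4.5/4.6); ventral amplitudes
    preserve the same ordering at a smaller dorsoventral gradient.  Ages and
    clinical scales use the cohort table of that design, truncated to each
    scale's valid range when drawn.
    """
    clin = {
        "PD": {
            "UPDRS3": (16.4, 6.9), "MoCA": (26.5, 2.0), "UPSIT": (23.4, 3.3),
            "BDI": (5.2, 4.6), "SCOPA_AUT": (16.7, 14.0), "ESS": (7.9, 5.0),
            "RBDQ": (3.5, 3.3), "NMS": (8.8, 5.4),
        },
        "NMC": {
            "UPDRS3": (2.0, 2.3), "MoCA": (27.5, 2.5), "UPSIT": (30.6, 3.1),
            "BDI": (3.7, 5.2), "SCOPA_AUT": (6.2, 6.0), "ESS": (6.1, 2.9),
            "RBDQ": (1.8, 1.5), "NMS": (3.7, 4.2),
        },
        "NMNC": {
            "UPDRS3": (2.2, 4.4), "MoCA": (27.1, 2.2), "UPSIT": (32.2, 3.1),
            "BDI": (6.1, 9.0), "SCOPA_AUT": (7.9, 7.8), "ESS": (8.0, 3.5),
            "RBDQ": (2.4, 2.0), "NMS": (4.5, 4.3),
        },
    }
    return [
        GroupProfile(
            name="PD",
            amplitudes={"R_dorsal": 2.2, "L_dorsal": 2.3, "R_ventral": 2.0, "L_ventral": 2.0},
            age_mean=63.0, age_sd=9.0, clinical=clin["PD"], female_fraction=9 / 18,
        ),
        GroupProfile(
            name="NMC",
            amplitudes={"R_dorsal": 4.2, "L_dorsal": 4.3, "R_ventral": 3.4, "L_ventral": 3.4},
            age_mean=48.0, age_sd=11.0, clinical=clin["NMC"], female_fraction=17 / 31,
        ),
        GroupProfile(
            name="NMNC",
            amplitudes={"R_dorsal": 4.5, "L_dorsal": 4.6, "R_ventral": 3.5, "L_ventral": 3.5},
            age_mean=47.0, age_sd=12.0, clinical=clin["NMNC"], female_fraction=20 / 31,
        ),
    ]


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _check_disjoint(regions: list[RegionSpec], grid_shape) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    for r in regions:
        masks[r.name] = r.mask(grid_shape)
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"regions {a!r} and {b!r} overlap")
    return masks


def _fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size


def generate_subject(
    profile: GroupProfile,
    regions: list[RegionSpec],
    reference_region: RegionSpec,
    config: CohortConfig,
    seed,
    amplitude_overrides: dict[str, float] | None = None,
) -> tuple[SubjectRecord, np.ndarray]:
    """Generate one subject's volume plus its ground-truth label map.

    The volume is ``background_mean`` everywhere, region amplitudes added
    inside the ellipsoids (``amplitude_overrides`` replaces the profile
    values per region when given), background texture of sd
    ``background_sd`` on non-striatal voxels, measurement noise of sd
    ``noise_sd`` everywhere, then optional Gaussian smoothing.  Age, sex and
    clinical scores are drawn from the profile.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(seed)
    shape = config.grid_shape

    overrides = amplitude_overrides or {}
    placed = [
        replace(r, amplitude=overrides.get(r.name, profile.amplitudes.get(r.name, r.amplitude)))
        for r in regions
    ]
    masks = _check_disjoint(placed + [reference_region], shape)

    data = np.full(shape, config.background_mean, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    striatal = np.zeros(shape, dtype=bool)
    for idx, r in enumerate(placed, start=1):
        m = masks[r.name]
        data[m] += r.amplitude
        labels[m] = idx
        striatal |= m

    if config.background_sd > 0:
        texture = rng.normal(0.0, config.background_sd, size=shape)
        data[~striatal] += texture[~striatal]
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=shape)
    if config.smoothing_fwhm > 0:
        data = gaussian_filter(
            data, _fwhm_to_sigma_voxels(config.smoothing_fwhm, config.voxel_size)
        )

    age = float(rng.normal(profile.age_mean, profile.age_sd))
    sex = "F" if rng.random() < profile.female_fraction else "M"
    scores = {}
    for scale, (lo, hi) in CLINICAL_SCALES.items():
        if scale in profile.clinical:
            mu, sd = profile.clinical[scale]
            scores[scale] = float(np.clip(rng.normal(mu, sd), lo, hi))

    volume = UptakeVolume(
        data, voxel_size=config.voxel_size_tuple, space_tag=DEFAULT_SPACE, units=RAW
    )
    record = SubjectRecord(
        subject_id="", group=profile.name, age=age, sex=sex, scores=scores, volume=volume
    )
    return record, labels


def generate_cohort(
    config: CohortConfig,
    profiles: list[GroupProfile] | None = None,
    regions: list[RegionSpec] | None = None,
    reference_region: RegionSpec | None = None,
) -> Cohort:
    """Generate a full seeded cohort with ground truth.

    Per-subject amplitudes are the profile means plus a subject- and
    region-specific Gaussian offset of sd ``amplitude_between_subject_sd``
    (clipped at zero), which yields VOI-mean spread of that order between
    subjects of a group.
    """
    if profiles is None:
        profiles = default_profiles()
    if not profiles:
        raise ValueError("at least one group profile is required")
    if regions is None:
        regions = default_regions(config.grid_shape)
    if reference_region is None:
        reference_region = default_reference_region(config.grid_shape)

    by_name = {p.name: p for p in profiles}
    root = np.random.SeedSequence(config.seed)
    subjects: list[SubjectRecord] = []
    labels_ref: np.ndarray | None = None
    counter = 0
    for group, n in config.n_per_group.items():
        if n == 0:
            continue
        if group not in by_name:
            raise ValueError(f"no profile for group {group!r}")
        profile = by_name[group]
        for _ in range(n):
            counter += 1
            # one spawned stream per subject; amplitude jitter drawn first
            rng = np.random.default_rng(root.spawn(1)[0])
            overrides = {
                r.name: max(
                    0.0,
                    profile.amplitudes[r.name]
                    + rng.normal(0.0, config.amplitude_between_subject_sd),
                )
                for r in regions
            }
            record, labels = generate_subject(
                profile, regions, reference_region, config, rng, amplitude_overrides=overrides
            )
            record.subject_id = f"sub-{counter:03d}"
            subjects.append(record)
            if labels_ref is None:
                labels_ref = labels

    assert labels_ref is not None
    manifest = pd.DataFrame([s.manifest_row() for s in subjects], columns=MANIFEST_COLUMNS)
    truth_names = {i: r.name for i, r in enumerate(regions, start=1)}
    return Cohort(
        subjects=subjects,
        manifest=manifest,
        truth_labels=labels_ref,
        truth_names=truth_names,
        reference_mask=reference_region.mask(config.grid_shape),
        config=config,
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write per-subject NIfTI volumes, ground-truth maps and the manifest."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        s.volume.save(out / "scans" / f"{s.subject_id}.nii.gz")
    vs = cohort.config.voxel_size_tuple
    save_mask(cohort.reference_mask, vs, out / "reference_mask.nii.gz")
    truth = UptakeVolume(cohort.truth_labels.astype(np.float64), voxel_size=vs)
    import nibabel as nib

    nib.save(nib.Nifti1Image(cohort.truth_labels.astype(np.int16), truth.affine()),
             str(out / "truth_labels.nii.gz"))
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out
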