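"""End-to-end orchestration: simulate/load -> standardize -> template ->
VOIs -> statistics, with a machine-readable summary.

The template is always built from the designated control group only
(``template_group``, NMNC by default) while VOI definition uses the scans
of *all* groups — the former captures the normal anatomy, the latter the
pathology-driven covariance structure the clustering exploits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import standardize_to_reference
from .stats import (
    TFCEParams,
    correlate_voi_clinical,
    flag_individual,
    voi_group_comparison,
    voxelwise_permutation_test,
)
from .synthetic import CLINICAL_SCALES, CohortConfig, generate_cohort, write_cohort
from .template import build_template, extract_striatum_mask
from .voi import define_vois, voi_means_table
from .volume import UptakeVolume, load_mask

log = logging.getLogger("datspect")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run."""

    out_dir: str = "datspect-run"
    # either synthetic generation ...
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # ... or pre-existing inputs
    scan_paths: list[str] = field(default_factory=list)
    manifest_path: str | None = None
    reference_mask_path: str | None = None
    # analysis settings
    template_group: str = "NMNC"
    threshold_sd: float = 3.0
    min_component_voxels: int = 20
    k_min: int = 2
    k_max: int = 7
    n_perm: int = 1000
    tfce: TFCEParams = field(default_factory=TFCEParams)
    alpha: float = 0.05
    correction: str = "fwe"  # or "fdr"
    expected_order: tuple[str, ...] = ("PD", "NMC", "NMNC")
    run_voxelwise: bool = True
    run_correlations: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        def default(o):
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage: %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


@_stage("inputs")
def _load_inputs(config: PipelineConfig, out: Path):
    if config.synthetic:
        cohort = generate_cohort(config.cohort)
        scans = [s.volume for s in cohort.subjects]
        manifest = cohort.manifest
        ref_mask = cohort.reference_mask
        truth = cohort
    else:
        if not config.scan_paths or not config.manifest_path or not config.reference_mask_path:
            raise ValueError("non-synthetic runs need scan_paths, manifest_path and reference_mask_path")
        scans = [UptakeVolume.load(p) for p in config.scan_paths]
        manifest = pd.read_csv(config.manifest_path, sep="\t")
        ref_mask = load_mask(config.reference_mask_path, reference=scans[0])
        truth = None
    if config.template_group not in set(manifest["group"]):
        raise ValueError(
            f"template group {config.template_group!r} not present in the manifest "
            f"(groups: {sorted(set(manifest['group']))})"
        )
    return scans, manifest, ref_mask, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("run in progress\n")

    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    try:
        scans, manifest, ref_mask, truth = _load_inputs(config, out)
        subject_ids = list(manifest["subject_id"])
        groups = manifest["group"]
        ages = manifest["age"].astype(float)

        std = _standardize_all(scans, ref_mask)
        tpl = _build_template_stage(std, groups, config)
        vois = _define_vois_stage(std, tpl.striatum_mask, config)
        means = voi_means_table(std, vois, subject_ids)
        voi_stats = _voi_stats_stage(means, groups, ages, config)

        summary.update(
            {
                "n_subjects": len(std),
                "groups": groups.value_counts().to_dict(),
                "template": {
                    "group": config.template_group,
                    "n_subjects": tpl.n_subjects,
                    "threshold_sd": tpl.threshold_sd,
                    "mask_voxels": int(tpl.striatum_mask.sum()),
                },
                "k_selected": vois.k_selected,
                "silhouette_by_k": {
                    h: {str(k): v for k, v in d.items()} for h, d in vois.silhouette_by_k.items()
                },
                "stable_clustering": vois.stable,
                "n_vois": len(vois.vois),
                "vois": vois.summary().to_dict(orient="records"),
                "adjusted_means": voi_stats.adjusted_means.round(6).to_dict(),
                "contrasts": voi_stats.contrasts.round(6).to_dict(orient="records"),
            }
        )

        if config.run_voxelwise:
            summary["voxelwise"] = _voxelwise_stage(std, manifest, tpl.striatum_mask, config)
        if config.run_correlations:
            summary["correlations"] = _correlations_stage(means, manifest, config)

        _write_outputs(out, std, tpl, vois, means, voi_stats, summary, config)
        incomplete.unlink(missing_ok=True)
    except PipelineError as err:
        incomplete.write_text(f"failed at stage {err.stage!r}: {err.cause}\n")
        raise
    return summary


@_stage("standardize")
def _standardize_all(scans, ref_mask):
    return [standardize_to_reference(s, ref_mask) for s in scans]


@_stage("template")
def _build_template_stage(std, groups, config: PipelineConfig):
    control = [s for s, g in zip(std, groups) if g == config.template_group]
    tpl = build_template(control)
    return extract_striatum_mask(
        tpl, threshold_sd=config.threshold_sd, min_component_voxels=config.min_component_voxels
    )


@_stage("define-vois")
def _define_vois_stage(std, mask, config: PipelineConfig):
    return define_vois(
        std, mask, k_range=range(config.k_min, config.k_max + 1), seed=config.seed
    )


@_stage("voi-stats")
def _voi_stats_stage(means, groups, ages, config: PipelineConfig):
    order = config.expected_order if set(groups) <= set(config.expected_order) else None
    return voi_group_comparison(
        means, groups, ages, alpha=config.alpha, expected_order=order
    )


@_stage("voxelwise")
def _voxelwise_stage(std, manifest, mask, config: PipelineConfig):
    data = np.stack([s.data for s in std])
    groups = manifest["group"]
    ages = manifest["age"].to_numpy(dtype=float)
    present = [g for g in config.expected_order if g in set(groups)]
    out = {}
    # directional contrasts between adjacent-and-extreme ranks: higher > lower
    pairs = [(hi, lo) for i, lo in enumerate(present) for hi in present[i + 1:]]
    for hi, lo in pairs:
        res = voxelwise_permutation_test(
            data,
            groups,
            mask,
            covariates=ages,
            contrast=(hi, lo),
            n_perm=config.n_perm,
            params=config.tfce,
            seed=config.seed,
        )
        table = res.cluster_table(
            alpha=config.alpha, voxel_size=std[0].voxel_size,
            use=config.correction,
        )
        pmap = res.p_fwe_map if config.correction == "fwe" else res.p_fdr_map
        out[f"{hi}-gt-{lo}"] = {
            "n_perm": res.n_perm,
            "min_p_corr": float(pmap[mask].min()),
            "n_sig_voxels": int(((pmap < config.alpha) & mask).sum()),
            "clusters": table.to_dict(orient="records"),
        }
    return out


@_stage("correlations")
def _correlations_stage(means, manifest, config: PipelineConfig):
    nm = manifest[manifest["group"] != "PD"]
    clinical = nm.set_index("subject_id")[[c for c in CLINICAL_SCALES if c in nm.columns]]
    sub_means = means.loc[clinical.index]
    table = correlate_voi_clinical(sub_means, clinical)
    return {
        "n_pairs": len(table),
        "n_significant": int(table["significant"].sum()),
        "table": table.round(6).to_dict(orient="records"),
    }


def _write_outputs(out, std, tpl, vois, means, voi_stats, summary, config: PipelineConfig):
    from .volume import save_mask

    tpl.mean_map.save(out / "template_mean.nii.gz")
    save_mask(tpl.striatum_mask, tpl.mean_map.voxel_size, out / "striatum_mask.nii.gz")
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(vois.label_map.astype(np.int16), tpl.mean_map.affine()),
        str(out / "voi_labels.nii.gz"),
    )
    vois.summary().to_csv(out / "voi_summary.tsv", sep="\t", index=False)
    means.to_csv(out / "voi_means.tsv", sep="\t")
    voi_stats.contrasts.to_csv(out / "voi_contrasts.tsv", sep="\t", index=False)
    voi_stats.adjusted_means.to_csv(out / "voi_adjusted_means.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
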