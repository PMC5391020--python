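# datspect

Quantitative analysis of dopamine-transporter SPECT (DaT-SPECT) brain
volumes, built around the study design that compares Parkinson's disease
patients (PD) with non-manifesting carriers (NMC) and non-carriers (NMNC)
of the LRRK2 G2019S mutation. Visual reading of DaT scans is subjective and
insensitive to the subtle dorsal-striatal uptake loss expected in the
prodromal phase; this package implements an objective, fully data-driven
alternative and a seeded synthetic-cohort generator to validate it.

## What it computes

Given co-registered, spatially normalized uptake volumes and an occipital
reference mask:

1. **Standardization** — every voxel is expressed in reference-region
   standard-deviation units, `x_sd = (x − x̄_ref) / σ_ref`, so values are
   comparable across subjects.
2. **Population template** — the voxel-wise mean standardized map of the
   control (NMNC) cohort; voxels more than 3 sd above background form the
   striatum analysis mask.
3. **Data-driven VOIs** — striatum voxels are clustered by k-means on
   their across-subject uptake profiles (all groups pooled, no anatomical
   priors), with the cluster count chosen per hemisphere by the mean
   silhouette over k = 2..7. With the canonical dorsoventral uptake
   gradient this yields four VOIs: right/left dorsal and ventral striatum.
4. **Inference** — per-VOI linear models `uptake ~ group + age` with
   Bonferroni-corrected pairwise contrasts; voxel-wise two-group
   permutation tests with Freedman–Lane covariate handling and
   family-wise error control via the maximum TFCE (threshold-free cluster
   enhancement) statistic; Pearson/Spearman clinical correlation screens;
   and single-subject flagging against an age-adjusted normative range
   (regression prediction minus 2 residual sd).

Because no raw scans ship with studies of this kind, the package includes a
first-class synthetic cohort generator (`datspect.synthetic`) that emulates
the post-normalization volumes: bilateral dorsal/ventral striatal
ellipsoids with group-specific amplitudes, an occipital reference region,
voxel noise, and between-subject amplitude variability.

## Worked example

Run the full pipeline on the default synthetic cohort (30 NMNC, 30 NMC,
18 PD; 64×64×48 grid at 2 mm; seed 42):

```python
from datspect import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="run", cohort=CohortConfig(seed=42),
                        seed=42, n_perm=500)
summary = run_pipeline(config)
```

Inspecting the summary prints:

```
k per hemisphere: {'R': 2, 'L': 2}
  R_dorsal    287 voxels  2.30 cc
  R_ventral   135 voxels  1.08 cc
  L_dorsal    287 voxels  2.30 cc
  L_ventral   135 voxels  1.08 cc
adjusted group means (R_dorsal): {'NMC': 4.29, 'NMNC': 4.33, 'PD': 2.11}
   NMC-NMNC  t =  -0.39  p_bonf = 1.0
     NMC-PD  t =  15.39  p_bonf < 1e-6
    NMNC-PD  t =  14.73  p_bonf < 1e-6
voxel-wise NMNC>PD: 843 significant voxels, min p = 0.0020
significant clinical correlations: 0 / 32
```

Silhouette selection finds two clusters per striatum, splitting each
hemisphere into a dorsal (~2.3 cc) and a ventral (~1.1 cc) VOI. The PD
group shows the expected severe dorsal deficit (adjusted mean ≈ 2.1 vs
≈ 4.3 in non-manifesting groups, corrected p ≪ 0.001 after age
adjustment), the voxel-wise permutation test converges on the same answer,
and — because the generator draws clinical scores independently of uptake
within group — the correlation screen correctly finds nothing.

The same stages are available as a CLI
(`datspect simulate | standardize | template | define-vois | compare |
run-all`), e.g.:

```sh
datspect run-all --out run --seed 42
```

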