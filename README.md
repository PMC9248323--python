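# hdwm — white-matter microstructure analysis for premanifest Huntington disease

`hdwm` is a tested, reusable re-implementation of a multimodal white-matter
analysis pipeline for premanifest Huntington disease (HD) studies. It is
aimed at neuroimaging researchers who want the full chain — quantitative
map computation, callosal tractometry, whole-brain tract-based cluster
analysis (TBCA), and the group-level statistics — as composable library
functions, exercised end to end on a synthetic cohort generator so every
stage is testable without any MRI download.

## What it computes

**Quantitative maps** (`hdwm.micro_maps`)

- Magnetization transfer ratio: `MTR = (S0 − S_MT) / S0 × 100`, a proxy for
  macromolecular (myelin/iron-associated) content.
- Diffusion tensor scalars FA, AD = λ₁, RD = (λ₂+λ₃)/2, MD, fitted by
  linearly weighted least squares restricted to the b = 500–1200 s/mm²
  shells (plus b = 0) to limit CSF partial-volume effects.
- Restricted signal fraction FR from a composite hindered-and-restricted
  two-compartment model,
  `S = S0 [(1 − FR) · E_h + FR · E_r]`, where `E_h = exp(−b gᵀ D_h g)` is a
  Gaussian hindered tensor and `E_r` combines free axial diffusion inside a
  cylinder with the Gaussian-phase small-radius perpendicular attenuation.
  FR is a proxy for axon density.
- Free-water signal fraction FWF from a two-compartment fit with the free
  diffusivity fixed at 3.0×10⁻³ mm²/s.

**Tractometry** (`hdwm.tractometry`) — each metric map is sampled by
trilinear interpolation at every vertex of the seven labeled callosal
segment bundles (rostrum → splenium); the segment summary is the median over
each streamline's vertices followed by the mean over streamlines.

**TBCA** (`hdwm.tbca`) — a per-voxel GLM of the group effect with age and
sex regressed, Freedman–Lane permutation p-values, thresholding at p = .01,
and cluster formation on a *hypervoxel* template: two suprathreshold voxels
join the same cluster when they are 26-adjacent **or** share a streamline.
Cluster mass (Σ t) is tested against the permutation distribution of the
maximum mass for family-wise error (FWE) control.

**Group statistics** (`hdwm.stats`) — PCA with KMO/Bartlett adequacy
checks, varimax rotation and regression scores; Type III ANCOVA with
sum-to-zero coding, group×segment and group×covariate interactions;
simple-slopes moderation; Spearman and partial-Spearman correlation
families with Bonferroni correction; ±3 SD within-group outlier screening;
the disease burden score `DBS = age × (CAG − 35.5)`.

**Synthetic cohorts** (`hdwm.synthetic_data`) — a phantom tractogram (seven
callosal arcs + a corticospinal-tract-like bundle), per-subject maps with
planted effects (anterior-positive/posterior-negative patient MTR pattern,
CAG–MTR slope, group×age interaction, CST FR offset, posterior-high
axon-density gradient), and a 13-outcome cognitive battery with one
dominant factor.

## Worked example

```python
from hdwm.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo", seed=42)   # 12+12 subjects, 24³ grid
out = run_pipeline(cfg)

stats = out["stats"]
print(stats["pca"].component_labels)        # ['FA', 'MTR']
print(stats["simple_slopes"][["segment", "beta", "p"]])
print(out["tbca"]["MTR"].table())
```

With seed 42 this prints an axon-density component (FA/FR/AD loading
positively, RD negatively) and a magnetization-transfer component, the
per-segment group slopes on the MT component

```
   segment      beta         p
0        1  0.943942  0.010922   # patients higher anteriorly
...
6        7 -1.654263  0.000013   # patients lower posteriorly
```

and one FWE-significant MTR-decrease cluster spanning the posterior
callosal bundles:

```
   cluster  size  n_streamlines        mass  p_uncorrected     p_fwe
0        1   236            772  890.210917       0.003322  0.003322
```

`mass` is the summed t-score of the member voxels and `p_fwe` its
permutation family-wise-corrected p-value. A matching run for FR
(patient-greater) isolates the planted corticospinal cluster. The same
stages are exposed on the command line:

```sh
hdwm all --config config.yaml --seed 42
```

## Caveats

Repeated segment measurements per subject are modeled as a crossed fixed
factor (segment), with no subject-level random effect — this mirrors the
reference analysis design rather than the mixed-model treatment a
statistician might prefer. See `docs/methods.md` for the full model
descriptions, parameter defaults, and known limitations.
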