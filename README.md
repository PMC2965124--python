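# motornet

Structural and functional connectivity analysis of the human motor network,
built for studying upper-motor-neuron degeneration in amyotrophic lateral
sclerosis (ALS).  The package combines three views of the same network:

- **Structural connectivity** — diffusion-tensor imaging (DTI).  Each voxel's
  water-diffusion profile is modelled as a 3×3 symmetric tensor `D` fitted from
  the single-tensor signal model `S_i = S0 · exp(−b_i gᵢᵀ D gᵢ)`.  White-matter
  integrity is summarised by the fractional anisotropy of the eigenvalues
  λ₁ ≥ λ₂ ≥ λ₃:

      FA = √(1/2) · √((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₁−λ₃)²) / √(λ₁² + λ₂² + λ₃²)

  Deterministic FACT tractography (fibre assignment by continuous tracking)
  follows each voxel's principal eigenvector to reconstruct streamlines; the
  corticospinal tract (CST) and callosal motor fibres are selected as the
  streamlines touching two ROI masks (precentral gyrus + brainstem, or left +
  right precentral gyrus), and FA is profiled at normalized arc-length
  positions along the tract, cortex end first.
- **Functional connectivity** — resting-state fMRI.  Motor-ROI BOLD series are
  band-pass filtered to 0.01–0.1 Hz, Pearson-correlated, and binarized at a
  correlation threshold.  Network summaries are the number of connections `E`,
  the interhemispheric connection count, the clustering coefficient
  `Cᵢ = 2eᵢ / (kᵢ(kᵢ−1))`, and the normalized clustering coefficient
  `γ = C / ⟨C_random⟩` against degree-preserving (Maslov–Sneppen) rewired
  surrogates.
- **Clinical integration** — the ALSFRS-R functional score (0–48) and disease
  duration give the progression rate `(48 − ALSFRS-R) / duration`; group
  comparisons use a general linear model with age and whole-brain cortical
  thickness as covariates, and pre-registered structure/function/clinic pairs
  are tested by partial correlation.

No patient scans ship with the package.  Instead, `motornet.synth` generates
every input with known ground truth: tube-shaped anisotropic DWI phantoms with
a configurable FA-vs-arc-length profile (to plant a rostral FA deficit),
motor-network BOLD series with a prescribed correlation matrix (8 min at
0.5 s sampling by default), and two-group cohorts (n = 12/12) with a planted
precentral-gyrus thickness deficit and a planted γ–progression-rate relation.
That makes every downstream claim testable: the pipeline must recover what
the generator planted.

## Worked example

Run the bundled small-scale demonstration (two tube phantoms, a six-node
motor network, an n = 12/12 cohort):

```sh
motornet full --seed 42 --out demo
```

`demo/summary.json` then contains, among others:

- Along-tract FA (100 positions, 408 streamlines per phantom): the control
  phantom is flat at FA 0.700 everywhere, while the patient phantom with the
  planted rostral deficit gives rostral-third mean 0.532 vs caudal-third mean
  0.667 — the FA reduction fades as the tract descends from cortex toward
  brainstem.
- Functional graphs for the control group: at threshold 0.30, E = 13 with 7
  interhemispheric connections and γ = 1.00; at threshold 0.40, E = 9 and
  γ = 1.20.  Values near 1 mean the motor network is no more locally
  clustered than a degree-matched random network.
- Cohort statistics: the precentral-thickness GLM (age and whole-brain
  thickness as covariates) estimates a group effect of −0.109 mm
  (t = −3.67, p = 0.0015), recovering the planted 0.09 mm deficit, and the
  γ–progression-rate partial correlation (given E and age) is r = 0.94
  (p = 4.5 × 10⁻⁵), recovering the planted positive relation: more strongly
  interconnected motor networks progress faster.

Re-running with the same seed reproduces every output byte for byte.

The individual stages are also available as subcommands (`motornet simulate`,
`motornet dti`, `motornet fmri`, `motornet stats`) and, more flexibly, as
library functions — see `motornet.synth`, `motornet.dti`,
`motornet.fmri_graph`, `motornet.stats` and `motornet.pipeline`.

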