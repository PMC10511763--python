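# shambhala

Uniformly shaped cross-platform harmonization of bulk gene expression
profiles, with a complete evaluation battery and a synthetic multi-platform
benchmark generator.

## The problem

Merging expression data across platforms (microarray vs RNA-seq, different
library protocols) requires removing platform-specific distortion without
erasing biology. Conventional normalizations are *flexible-output*: the
normalized value of every sample depends on which other samples are in the
batch, so adding data forces re-normalization of everything downstream.
**Shambhala** is *uniformly shaped*: each profile is harmonized
independently into one fixed universal format defined by two auxiliary
datasets — a calibration set *P* (each profile is merged with *P* and
quantile-normalized) and a reference definitive set *Q* (the merged set is
block-transformed into *Q*'s shape, by the block-linear XPN model in
Shambhala-1 or the piecewise-cubic CuBlock transform in Shambhala-2). Per
gene *g*, the extracted profile *LE″* is then rescaled by one of three
modes:

- **PBR** — `LE = μ_gQ + LE″·σ_gQ`
- **QBR** — `LE = μ_gQ + (LE″ − μ_gH)·σ_gQ/σ_gH`
- **RBR** — `LE = μ_gR + (LE″ − μ_gH)·σ_gR/σ_gH`

where (μ, σ) are per-gene means and standard deviations of the reference
*Q*, the harmonized batch *H*, or the raw dataset *R*. Only PBR keeps
per-sample independence.

The package also implements the battery used to judge harmonization
quality: the entropy-based **Watermelon Multisection** (WM) metric on
clustering dendrograms and the ratio `R = WM_S/WM_P` (tissue- vs
platform-driven clustering), concordance regression between score vectors
(Spearman ρ and the geometric-mean slope *k* of the with- and
without-intercept regressions, zeroed when they disagree in sign),
sign-change stability curves, transfer-learning tissue classifiers (1nn,
11nn, linear SVM on 20 PCs), and case-vs-control scoring (per-gene LFC,
role-weighted pathway activation PAL, balanced drug efficiency BES).
Everything is exercised end-to-end on a seeded synthetic generator of
multi-tissue, multi-platform data with planted pathway shifts. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Generate a benchmark, harmonize one platform's data, and score clustering
quality from the shell:

```sh
shambhala simulate --seed 5 --outdir fixtures/
shambhala harmonize --raw fixtures/R_array.tsv --calibration fixtures/P.tsv \
    --reference fixtures/Q.tsv --method sh2 --rescale pbr --seed 17 --out H.tsv
```

or run the whole evaluation from Python:

```python
from shambhala.benchmark import run_benchmark
results = run_benchmark(seed=1)
```

which on the default benchmark (3000 genes, 4 tissues, 2 platforms with
strong monotone distortion, 80 samples) prints, via
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`:

```
quality_ratio_unharmonized: 0.691974 (n=80)
quality_ratio_harmonized: 4.3169 (n=80)
quality_ratio_improvement_factor: 6.23852 (n=80)
wm_platform_unharmonized: 1 (n=80)
wm_platform_harmonized: 0.231648 (n=80)
median_profile_spearman_harmonized: 0.969447 (n=1500)
median_profile_k_harmonized: 1.0191 (n=1500)
pal_sign_recovery_fraction: 1 (n=6)
...
```

Reading: before harmonization the samples cluster by platform
(WM_P = 1.0, quality ratio 0.69 < 1); after Shambhala-2 with P-based
rescaling they cluster by tissue (ratio 4.3, a 6.2× improvement), the
same-tissue median profiles of the two platforms agree (Spearman 0.97,
regression coefficient 1.02), and all six planted pathway-shift signs are
recovered in post-harmonization pathway activation scores.

## Command-line interface

`shambhala <subcommand>`: `simulate`, `harmonize`, `wm`, `concordance`,
`scores`, `classify`. Matrices are TSV (optional GCT 1.2); metric reports
are JSON and record the resolved configuration and seed. Every subcommand
is a thin wrapper over an importable library function with the same
contract.
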