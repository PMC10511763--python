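# Methods

## The harmonization model

Cross-platform expression studies suffer from platform- and protocol-specific
distortion: microarrays compress dynamic range, sequencing depth shifts whole
profiles, per-gene probe effects bias individual genes. Classical batch
correction (quantile normalization of a merged set, ComBat, DESeq2 size
factors) is *flexible-output*: adding one new sample changes the normalized
values of every old sample. Shambhala is *uniformly shaped*: every profile is
transformed, one at a time, into a single fixed universal format defined by
two auxiliary datasets, so previously harmonized data never move.

For each raw profile `r` from dataset R:

1. **Merge + quantile-normalize.** `r` is appended as one extra, equally
   weighted column to the calibration dataset P and the merged set is
   quantile-normalized (ties averaged over the tied reference quantiles),
   giving P′. Any monotone per-sample distortion of `r` — depth, intensity
   scaling, dynamic-range compression — is removed here. An alternative
   `project` mode maps `r` onto P's fixed mean quantiles without perturbing
   them; weight-1 merging is the default.
2. **Block transform into the shape of Q.** P′ is transformed toward the
   reference definitive dataset Q by either
   - **XPN** (Shambhala-1): a block-linear model
     `x_gi ≈ A[α(g), β(i)]·b_g + c_g + σ_g·ε` with genes k-means-clustered
     into K groups on pooled per-gene standardized data and sample clusters
     fitted on Q (P′ samples assigned to the nearest Q centroid). The model
     is fitted per dataset by alternating least squares; P′'s standardized
     residuals are then re-expressed under a convex combination of the two
     fitted parameter sets. The combination weight on Q (`reference_weight`)
     defaults to 1: the output lands in Q's shape, which is what the fixed
     universal format requires. Setting it to 0.5 reproduces the classic
     symmetric cross-platform average. Outputs are averaged over `n_repeats`
     random clustering restarts.
   - **CuBlock** (Shambhala-2): per-gene z-scoring within each dataset,
     k-means blocking of genes on the pooled standardized data (B=8), and a
     per-block least-squares cubic mapping P′'s empirical block quantiles
     onto Q's. The fitted cubic is applied through its monotone envelope
     (values evaluated on a fine grid, made non-decreasing, interpolated),
     which also clamps extrapolation. Blocks with fewer than 8 values fall
     back to a linear fit. The output deliberately stays on the standardized
     scale; restoring magnitudes is the rescaling step's job.
3. **Extract + rescale.** The profile's column of P″ is kept; after all
   profiles are processed the assembled matrix is rescaled per gene g:
   - PBR: `LE = μ_gQ + LE″·σ_gQ` (treats LE″ as standardized; the natural
     pairing with CuBlock),
   - QBR: `LE = μ_gQ + (LE″ − μ_gH)·σ_gQ/σ_gH` (exact moment matching to Q),
   - RBR: `LE = μ_gR + (LE″ − μ_gH)·σ_gR/σ_gH` (moments of the raw dataset).
   Genes with `σ_gH` below `sigma_floor` (1e-8) map to the target mean.
   PBR uses only Q summaries, so each harmonized column is independent of
   the batch; QBR/RBR depend on the batch through the H (and R) summaries.

The output gene list is the sorted intersection of the R, P and Q gene sets.
P's restricted list (the most strongly expressed genes) acts as an implicit
expression filter; an optional top-N-by-median-in-P filter is available but
off by default. Standard deviations use the sample (n−1) denominator
throughout; the working scale is log2 (counts are loaded as `log2(x+1)`), a
convention adopted because the source data's log base is not fixed by the
pipeline itself.

**Determinism.** Every stochastic step derives its seed from
`sha256(master_seed : sample_id)` (mod 2³¹), so a sample's harmonized PBR
profile is bit-identical regardless of batch composition or position — a
positional split would silently break the per-sample independence contract.

## Watermelon Multisection (WM)

Samples are clustered agglomeratively (for general exploration the default
distance is 1−Pearson; average linkage). Walking from the root down, each
split refines the leaf partition; after j splits the normalized information
gain about known class labels is

    IG(j) = [H(labels) − Σ_c (|c|/n)·H(labels | c)] / H(labels).

Splits are applied in reverse merge order, which for monotone linkages equals
decreasing merge height with ties broken by node index. WM compares mean
trajectory heights over j = 1..n−1:

    WM = (A_obs − A_null) / (A_max − A_null),

where the null trajectory is the mean over `n_perm` (default 100) label
permutations on the same tree, and the maximal trajectory is 1 for
j ≥ m−1 classes and, below that, a greedy fastest separation that isolates
the largest classes first. The greedy bound is not always tight, so raw WM
can slightly exceed 1 on strongly separated data; reported WM is clipped to
[0, 1] (the raw value is kept alongside). A perfectly class-separating root
split scores exactly 1; random labels score ≈ 0 before clipping. The
trajectory-area form is one concrete instantiation of the entropy-trajectory
comparison; a terminal-gain variant would weight late splits differently.

**Quality ratio.** For each of 25 repeats, 5 samples per tissue×platform
cell are drawn, clustered, and scored against tissue labels (WM_S) and
platform labels (WM_P); the reported ratio is the median of WM_S/WM_P with
the denominator floored at 1e-3 (a platform WM at or below the null level
means no detectable platform clustering). The quality protocol clusters with
**Euclidean** distance, unlike the general-purpose default: platform batch
structure lives largely in per-sample location and scale, to which
correlation distance is invariant — a correlation-based ratio is blind to
exactly the distortions harmonization removes, and cannot fall below 1 on
data whose batch effect is affine. This choice was made after observing that
a correlation-based protocol rated heavily distorted unharmonized data as
tissue-clustered.

## Concordance and stability statistics

For paired score vectors (v1, v2): Spearman ρ; OLS slope with intercept k1;
through-origin slope k2 = ⟨v1,v2⟩/⟨v1,v1⟩; combined coefficient
k = sign(k1)·√(k1·k2) when k1·k2 > 0, else k = 0. When both slopes are
negative the sign is preserved (k < 0), keeping k continuous and
sign-faithful.

Sign-change curves count components with `v1 < −w/2` and `v2 > w/2` (or vice
versa; strict inequalities, so zeros never flip) as the dead-zone width w
grows. Widths are expressed in units of the median absolute value of the
*pooled* vectors (the two vectors are symmetric in the comparison, so
pooling is the neutral unit). In `divided_by_k` mode v2 is divided by k
before counting, which compensates pure rescaling between computation
routes. Marker screening uses per-gene rank-based two-class AUC with
midpoint tie ranks, folded as max(AUC, 1−AUC), thresholded strictly at 0.8.

## Case-vs-control scoring

LFC_g = case value − median control value (mean available by flag; the
median matches the robust median-vector style used elsewhere in the
battery). Pathway activation is the role-weighted mean
`PAL_p = Σ ARR·LFC / Σ|ARR|` with roles +1 (activator) / −1 (repressor);
drug efficiency is the balanced mean
`BES_d = ½·mean(PAL over linked pathways) + ½·mean(LFC over targets)`,
positive predicting benefit. Both are linear in LFC, which is exactly why a
regression coefficient k between two normalizations propagates from
expression level to BES level. These formulas are documented package
defaults behind a small surface — production drug-scoring systems use
proprietary normalization constants that are out of scope here — but the
sign conventions and the pathways-plus-targets structure are honored.
Drugs whose targets all fail the gene filter are reported, not scored;
drugs with no surviving linked pathway fall back to the target term.

## Classifiers

1nn and 11nn vote in the Euclidean space of per-gene log expression;
distance ties resolve to the smallest training index (stable sort) and vote
ties to the nearest neighbour's class. The SVM classifier projects onto 20
principal components fitted on the training set only (pooled fitting is
available behind a flag but leaks validation structure) and uses a linear
kernel, C=1, one-vs-one multiclass. Genes are centered by PCA but not
rescaled; per-gene variance is informative in expression space.

## Synthetic benchmark

The generator emulates the tissue×platform design the evaluation battery
assumes. Per-gene baselines are a two-component mixture (70% expressed,
N(8, 2²) log2; 30% low tail, N(3, 1²)). Tissue offsets ~ N(0, τ²), τ = 1.0
log2, are shared across platforms. Case samples (half of each cell) carry
planted shifts of Δ = 2 log2 units with alternating signs on six of ten
8-gene pathways, shift direction multiplied by each member's role so the
planted PAL sign is knowable. Platform p renders the globally standardized
noise-free signal z as

    y = center + scale·gain_i·(a_p·z³ + b_p·z) + offset_i + bias_g + ε,

with gain_i ~ N(1, gain_sd²) and offset_i ~ N(0, offset_sd²) emulating
array-intensity / sequencing-depth variation, bias_g ~ N(0, λ_p²) fixed
per-gene platform bias, and ε ~ N(0, 0.4²). Standardization is global (one
center/scale), so the distortion is monotone *within each sample* and rank
structure is preserved — the harmonizer's task is isolated to aligning
distribution shapes. Count-like platforms additionally pass through
`log2(Poisson(2^y)+1)`.

Defaults (the benchmark's study conditions): 3000 genes, 4 tissues, 2
platforms ("array": a=0, b=0.55, λ=0.2, gain 0.12, offset 0.3; "rnaseq":
a=0.35, b=0.9, λ=0.1, gain 0.05, offset 0.5, counts), 10 samples per
tissue×platform cell (80 total). The calibration set P is array-like and
keeps the top 50% of genes by baseline mean (emulating a restricted
strongly-expressed calibration list); the reference set Q is count-like with
the full gene list; each has 24 control samples spanning all tissues. These
sizes run the full battery in well under a minute on one CPU and were chosen
as the package's working scale.

**What the generator does and does not emulate.** It reproduces monotone
cross-platform distortion, per-sample technical variation, count noise, a
low-expression tail, and planted differential signal. It does not emulate
gene–gene correlation structure, compositional library effects, probe-level
saturation (the monotone constraint a, b ≥ 0 forbids true saturating
curves), sex chromosomes, or real cancer-subtype structure. Passing tests
therefore demonstrate that the pipeline removes distribution-shape batch
effects while preserving rank-borne biology — not that it corrects per-gene
probe biases, which survive harmonization by construction (nothing in the
QN + block-transform path can see them), and which are kept small (λ ≤ 0.2)
relative to biological signal, as is realistic for curated gene sets.

## Numerical choices

- `sigma_floor` = 1e-8 everywhere a standard deviation divides.
- QN ties receive the mean of the tied reference quantiles.
- CuBlock quantile fit uses 101 probability points and a 512-point monotone
  envelope grid; degenerate (near-constant) blocks fall back to a mean shift.
- XPN alternating least squares runs at most `max_iter` = 30 sweeps,
  stopping when block means move < 1e-6; non-convergence returns the best
  iterate with a warning rather than failing a sample.
- k-means uses 2 restarts per repeat; repeats (default 30, 3–5 in tests)
  average the transform output, not the parameters.
- Drug ranking breaks BES ties lexicographically; WM split order breaks
  height ties by internal node index; kNN breaks distance ties by training
  index — all for bitwise reproducibility.

## Known limitations

- The XPN and CuBlock internals are faithful-in-spirit instantiations of the
  published block-linear and piecewise-cubic ideas; the original
  implementations differ in details (cluster counts, convergence criteria,
  exact polynomial fitting data) that are configurable here.
- QBR/RBR are batch-dependent by construction; only PBR gives the
  sample-at-a-time independence that uniformly shaped harmonization
  advertises.
- WM's maximal trajectory is greedy, so WM is calibrated (0 at random, 1 at
  perfect) but values between are comparable only within a fixed protocol.
- The PAL/BES formulas are transparent defaults, not a reimplementation of
  any proprietary scoring product.
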