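# Methods

`pleiolink` is a simulation pipeline asking one question: when two traits
map to the same genomic region, can univariate and multivariate mixed-model
GWAS tell a single pleiotropic causal variant (QTN) from two distinct,
trait-specific QTNs in linkage disequilibrium?  This note documents the
models, the synthetic data, the numerical choices, and what the shipped
tests do and do not establish.

## Synthetic genotype panels

Real diversity panels are replaced by a founder-copying simulator.  Per
chromosome, a pool of `n_founder_haplotypes = 8` binary haplotypes is drawn
with per-site minor-allele probabilities from Uniform[0.025, 0.5]; founder
sampling weights come from a flat Dirichlet.  Each gamete copies along the
chromosome from weighted-random founders, switching template between
adjacent markers with probability 1 − exp(−ρ·d), where d is the physical
gap and ρ the per-bp switch rate.  Individuals are two gametes, forced
identical with probability `inbreeding` (default 1.0 — the emulated maize
and soybean panels are inbred lines, so dosages are 0/2).

Design choices worth stating:

* **Weighted founders.**  With uniform founder choice, population allele
  frequencies collapse onto multiples of 1/8, leaving no markers near the
  rare-variant MAF target of 0.05.  Dirichlet weights spread the frequency
  spectrum continuously while keeping the effective founder number small
  enough for a usable short-range r² plateau (~0.15–0.2).
* **Calibration.**  The switch rates are fixed empirically so that mean
  pairwise r² decays to ≈ 0.10 at the distance the detection windows are
  calibrated to: ρ = 3×10⁻⁵/bp for the maize-like preset (0.10 at ~10 kb)
  and ρ = 3×10⁻⁷/bp for the soybean-like preset (0.10 at ~1 Mb), estimated
  over ≥ 8 independent panels of 500 lines × 2,000 markers.  At 50 kb the
  two presets differ by an order of magnitude (r² ≈ 0.15 vs ≈ 0.013).
* **Marker density.**  Mean spacing follows the emulated panels: 45 kb for
  maize-like (≈ 45k filtered GBS SNPs on a ~2.1 Gb genome) and 52 kb for
  soybean-like (≈ 18k array SNPs on ~0.95 Gb).  The maize-like preset
  additionally draws half of the inter-marker gaps from a short 1-kb scale,
  mimicking the clustering of reduced-representation (GBS) markers around
  restriction sites.  Density matters: it sets how many informative markers
  fall inside a detection window, and hence whether single-QTN detection
  sits in a saturated or an informative mid-power regime.  With array-like
  uniform spacing the maize-like panel would have almost no close marker
  pairs and no high-LD pairs to select as "QTNs in high LD".
* **What the generator does not emulate:** population structure and
  admixture, allele-frequency/LD correlation, selection, missing genotypes
  (synthetic panels are complete; the missingness filter exists for
  imported files), multi-allelic sites.  Consequences: passing tests show
  the statistical machinery behaves correctly under a structured but
  exchangeable-relatedness panel; they say nothing about confounding by
  stratification, which the study design deliberately excludes.

Marker filtering mirrors standard practice: ≤ 5% missingness, minor allele
count ≥ 5 (recomputed on the current sample after any subsampling), and
windowed greedy LD pruning at r² ≥ 0.9 (window 100 markers, step 10;
within a window the highest-r² offending pair loses its smaller-MAF
member, ties to the later index).  Sample-size series use nested random
subsamples (each panel a subset of the previous), as in the emulated
study's S₃ ⊂ S₂ ⊂ S₁.

LD is always the squared Pearson correlation of unphased dosage vectors
(composite LD).  Haplotype-phase r² is never computed; every downstream
consumer operates on dosages, and for fully inbred lines the two coincide.

## Trait simulation

Each trait is controlled by exactly one additive QTN with effect size
a = 0.10 per allele copy.  Genetic values are g = a·x; residuals are
i.i.d. Gaussian with variance chosen so the in-sample heritability
Var(g)/(Var(g) + σ²) equals the inputted h² exactly.  Architectures:

* **independent** — both QTNs MAF-selected, resampled until they land on
  different chromosomes; interchromosomal LD is recorded but uncontrolled.
* **ld_direct** — QTN1 MAF-selected; QTN2 is the same-chromosome marker
  within ±100 marker indices maximizing r²(QTN1, ·) subject to r² ≤ the
  threshold (ties: smaller distance, then lower index).  The
  argmax-under-bound rule makes the 0.98 setting a genuinely high-LD
  scenario rather than "any LD below 0.98".
* **ld_indirect** — a middle marker is MAF-selected; each QTN maximizes
  r² with the middle marker under the bound, one strictly upstream and
  one strictly downstream.  The middle marker is *retained* in the GWAS
  marker set (it is not causal); only the QTN-to-middle LD is bounded.
* **pleiotropic** — one MAF-selected marker drives both traits with the
  same (sign-concordant) effect; the sign on trait 2 is a config hook.

MAF selection takes markers within ±0.02 of the target, doubling the
tolerance (with a log note) if the set is empty.  Residuals of the two
traits are independent by default; a residual-correlation hook exists but
the study design keeps it at 0.  QTN markers are removed from the scanned
marker set each replicate (causal variants are typically ungenotyped), and
every replicate draws a fresh QTN set.

Seeding is hierarchical — master seed → SHA-256 of the scenario's
canonical key → replicate index — so any replicate is reproducible in
isolation and results are independent of execution order and worker count.

## Mixed-model scans

Kinship is VanRaden's genomic relationship matrix
K = W Wᵀ / (2 Σⱼ pⱼ(1−pⱼ)) over all polymorphic filtered markers
(including the soon-to-be-removed QTNs: deleting ≤ 2 of ~1,600 columns
perturbs K negligibly, and recomputing it per replicate would dominate the
runtime).  Eigenvalues are clamped at zero; a 10⁻⁶ ridge is added only if
the decomposition fails.

**Univariate.**  y = μ1 + xα + u + e with u ~ N(0, σ²g K), e ~ N(0, σ²e I).
After rotating by K's eigenvectors the profile ML log-likelihood is a
scalar function of δ = σ²g/σ²e, optimized on log δ ∈ [−10, 10].  The null
model uses Brent-style bounded search; the per-marker alternative (default
`per_snp_ml` mode) evaluates a 41-point grid followed by 22 golden-section
iterations, vectorized across all markers simultaneously, which reproduces
a dense-matrix per-marker optimizer to |Δlog₁₀ p| < 10⁻⁴ at a small
fraction of the cost.  The test is the likelihood ratio against χ²₁.  A
`null_based` (EMMAX/P3D) mode fixes δ at the null estimate and uses a GLS
Wald test; on strong signals the two modes agree closely.

**Multivariate.**  Rows of the rotated two-trait matrix are independent
N(·, dᵢ V_g + V_e) with 2×2 genetic and residual covariances, estimated by
ML over a log-Cholesky parameterization (Nelder-Mead from three fixed
starts: genetic fraction 0.1/0.5/0.9 of the sample covariance; best
likelihood wins, ties to the first).  The per-marker test of the 2-vector
of SNP effects uses χ²₂; the default scan fixes (V_g, V_e) at the null
estimates (P3D-style) for runtime, with a `per_snp_ml` validation mode.

**A degeneracy and its treatment.**  Column-centering makes K annihilate
the all-ones vector exactly, so "1" is a zero eigenvector and the rotated
intercept loads on a single rotated row.  The intercept then zeroes that
row's residual for free, and shrinking V_e sends the full ML to +∞ — the
likelihood is unbounded along a singular ridge.  The fit therefore
profiles the mean out by working with the intercept's error contrasts
(equivalently, dropping that one rotated row together with the intercept) —
the exact REML treatment applied to the intercept only; variance
components and the marker LRT remain ML.  The reduction triggers only when
the ones direction is an isolated null eigenvector; for an unstructured or
deliberately zero K the ordinary intercept model is used.  As a second
safety net the optimizer rejects V_e below 10⁻⁸ of the trait scales.

Under a global null (permuted phenotypes), pooled p-values from both scans
are uniform (KS p ≫ 0.01 over > 10⁴ tests) with pointwise type-I error
within [0.035, 0.065] at α = 0.05, provided n ≳ 300; at n ≲ 200 with few
markers the ML-LRT tail is visibly inflated, which is why the calibration
fixtures use n = 300.

No population-structure covariates are fitted anywhere: the simulated
traits contain no structure signal by construction.

## Detection scoring

Per scan and replicate, Benjamini–Hochberg adjustment is applied
genome-wide (the two univariate scans separately, never pooled); markers
with adjusted p < q (q = 0.10 default, 0.05 alternative) are significant.
A QTN counts as detected if any significant marker lies on its chromosome
within the window (inclusive boundary): 10 kb for maize-like, 1 Mb for
soybean-like — the distances at which each panel's LD decays to ≈ 0.10 —
with 1 kb / 10 kb alternates.  Four statistics per scenario × model:
detection of trait 1's QTN, trait 2's QTN, both simultaneously, and the
error rate (any significant marker outside *both* windows — the literal
window-exclusion rule, applied per scan and OR-ed across a model's scans).
Multivariate rates under the independent and linked architectures are
labeled "spurious pleiotropy detection rate".  Regional LD around a chosen
QTN (±20 markers) is available for diagnosing local-LD bias.

## Study orchestration

The full grid crosses six architecture variants (independent; direct and
indirect LD control at r² < 0.01 and < 0.98; pleiotropic) × MAF targets
{0.05, 0.40} × h² pairs {(0.3,0.3), (0.3,0.8), (0.8,0.8)} × sample sizes
{500, 1000, 2815} × two species profiles = 216 scenarios, each with 100
replicate trait pairs; FDR levels and window sizes are evaluation-time
settings, not scenario multipliers.  One panel per species is generated at
the largest sample size and nested-subsampled down.  Per replicate the
kinship, its eigendecomposition, and the rotated marker matrix are computed
once per panel and reused.

The shipped analysis scripts run a reduced design — 6 scenarios × 20
replicates at n = 500, ~1,600 post-filter markers, h² = (0.8, 0.8), MAF
0.40, maize-like — which completes in minutes on one core; the acceptance
checks use the same scale.  Replicate-level failures are logged and
skipped; a scenario aborts if more than 5% of its replicates fail.

## Known limitations

* Detection rates depend strongly on marker density relative to LD decay;
  the presets place the maize-like panel in a mid-power regime and the
  soybean-like panel (40+ in-LD markers per 1 Mb window) near saturation.
  Quantitative rates are not comparable to any real-data study — only the
  qualitative contrasts are.
* The P3D multivariate scan slightly understates per-marker uncertainty
  relative to per-marker ML; on the fixtures checked the log₁₀ p
  differences are ≲ 0.5 and rank order is preserved.
* GEMMA-style per-SNP missingness/MAF side-filters are not reimplemented;
  synthetic panels are pre-filtered so they would be no-ops.
* Only two traits, additive single-QTN architectures, and an intercept-only
  fixed-effect structure are supported.
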