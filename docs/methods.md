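# Methods

## Model

Both scans fit the single-random-effect GWAS mixed model

    y = X b + x g + Z u + e,   u ~ N(0, G σ²ₐ),   e ~ N(0, I σ²ₑ)

per SNP, where y is the generation proxy (continuous age at a reference
date, or true generation number in simulations) or an environmental
variable, x the SNP dosage (copies of allele1, PLINK convention) and G the
standardized GRM

    G = W Wᵀ / m,   W·ⱼ = (xⱼ − 2pⱼ) / √(2pⱼ(1−pⱼ)),

built from SNPs with MAF > 0.01 and missingness ≤ 0.1 (missing dosages are
mean-imputed only here and at scan time; I/O is lossless). The only fixed
effect is the intercept unless covariates are supplied.

### REML and the per-SNP test

σ²ₐ and σ²ₑ are estimated once under the null (no SNP) by profiling the
restricted likelihood over λ = σ²ₐ/σ²ₑ on the eigen-rotated model: a
101-point grid on log λ ∈ [−10, 10] followed by bounded Brent refinement.
Each SNP is then tested by GLS at that fixed λ — the standard EMMAX/GEMMA
Wald compromise that makes scans of 10⁵–10⁶ SNPs linear-time after one
eigendecomposition. It is an approximation: λ is not re-optimized per SNP,
which slightly misstates SEs for SNPs with large effects. The Wald statistic
uses a Student-t with n − c − 1 degrees of freedom and a per-SNP
re-estimated residual scale, matching finite-sample GWAS practice at
moderate n. PVE = σ²ₐ/(σ²ₐ+σ²ₑ) with a delta-method SE from a
finite-difference observed-information matrix; REML software differs in how
it reports this SE, so small discrepancies with other tools are expected.

Multi-GRM partitioning (e.g. significant vs suggestive vs drifting SNP
classes) uses average-information REML with EM fallback steps whenever an
AI step would leave the parameter space, non-negativity by projection onto
a small floor, and SEs from the inverse AI matrix. Identical GRMs are
rejected up front as non-identifiable.

The multivariate scan (≤ 5 traits) estimates genetic and residual trait
covariance matrices at the null by an EM algorithm on the eigen-rotated
data, with the fixed effects re-solved by GLS inside each iteration
(maximum 5,000 iterations, relative tolerance 1e-8). The mean profiling
makes this an ML-flavoured EM; with a single intercept and n in the
hundreds-plus the bias relative to strict REML is negligible. Each SNP's
d-vector of effects is tested by Wald chi-square with d df. A single trait
delegates to the univariate path, so d = 1 reproduces the univariate scan
exactly. Ecoregion membership is analyzed with this same *linear* model on
0/1 indicators — not logistic — deliberately; in the multivariate discrete
fit the largest region is dropped as the reference whenever the kept
indicators are mutually exhaustive.

### Multiple testing and loci

q-values follow Storey–Tibshirani: π₀ estimated from tail counts on
λ = 0.05…0.95 (step 0.05) smoothed by a natural cubic smoothing spline and
evaluated at λ = 0.95, clipped to [1/m, 1]; below 100 p-values the
estimator is unstable, so π₀ = 1 (plain Benjamini–Hochberg) with a warning.
Significant SNPs (default q < 0.1) join loci by single linkage at 1 Mb —
our reading of "more than 1 Mb to the nearest significant SNP" — with the
lead SNP the smallest p, ties broken by position for determinism.

Allele-frequency trajectories regress frequency-coded genotypes (dosage/2,
identically 0/0.5/1) on birth time: the linear slope gives the change per
year, converted to a per-generation ΔAF with a default generation interval
of 5 years (≈ 50 years ≈ 10 generations; the interval is configurable).
The smoothed curve is a tricube-weighted local linear fit (span 0.75) in
place of an unparameterized "loess", evaluated on the observed range only
and clipped to [0, 1]. Candidate genes are all annotated genes within
10 kb of a significant SNP (distance 0 inside a gene; intervals 0-based
half-open internally, 1-based in all user-facing output).

### Environmental scans

Continuous variables are z-scored before fitting (mixed units), so PVE is
reported on the standardized scale. Two permutation schemes: `by_animal`
shuffles environments across animals; `by_zip` permutes the zip→environment
map so animals sharing a zip move together, which tests whether zip-level
oversampling rather than genotype–environment association drives signal.
The significance threshold is empirical: the largest power of ten strictly
below every permuted minimum p (1e-5 when permutations behave like the
source data). Region indicators require ≥ 600 samples by default (an
alternative 1,000-sample profile is exposed for the meta-analysis figures).

### Ecoregions

K-means (k-means++ with 25 restarts at a fixed seed) clusters standardized
temperature / precipitation / elevation normals; K is fixed at 9 by design
— elbow/silhouette diagnostics are advisory only, because downstream
semantics depend on stable regions. Standardization before clustering is
required: the variables differ by orders of magnitude. Animal assignment
rounds coordinates half-up to 0.1°; nearest-centroid ties break to the
lowest region index. Every sample ends in exactly one of three states:
assigned, excluded (multi-region zip; kept for continuous analyses) or
unassigned (off-grid).

### Region meta-analysis

Within-region scans use per-region GRMs (re-standardized inside the
region) rather than slices of the global GRM, keeping each region's
frequency scaling self-consistent; the global-GRM variant is a parameter
away. Fixed-effects combination uses inverse-variance weights; Cochran's
Q has k−1 df. m-values enumerate all 2ᵏ effect configurations (k ≤ 12):
regions with an effect share one true effect with prior N(0, 0.04) and a
Bernoulli(0.5) configuration prior — both exposed, since reference
meta-analysis software leaves its defaults unstated. Trajectory
classification compares the mean |region − pooled| frequency gap over the
last third of the observed time range with the first third: shrinking →
convergent, growing → divergent, ties resolve to convergent and are
logged; regions spanning < 3 years stay unclassified.

The meta-analysis validation fixture constructs region panels with an
explicit region-private frequency trend (one SNP moving 0.3 → 0.7 over ten
years in one region, flat elsewhere, unstructured background) rather than
breeding them forward: on a few-thousand-site simulated genome a large
fraction of all sites co-responds to selection, so the GRM absorbs any
single QTL's temporal signal and no SNP can stand out the way a
few-hundred-loci signature does against an 836K-marker background. The
constructed panels still pass through the entire per-region pipeline
(GRM, REML, scan, q-values) before meta-analysis; scan power under full
forward simulation is validated separately.

## Simulations

### What the generator emulates

The forward simulator reproduces the validation design: 10 chromosomes ×
20,000 sites for 2,000 founders at full scale, with Ne ∈ {50, 100, 250},
200/500/1000 purely additive QTL with N(0,1) or gamma(shape 0.42) effects
(random sign — an unsigned gamma would force directional bias), 1000–8000
crosses from 50 selected sires and 500 dams, 5 generations of
truncation-selection burn-in, then 5–20 generations of truncation or
random selection. Founders carry standing variation with site frequencies
drawn ∝ 1/x on (0.01, 0.99) — the neutral SFS shape — passed through 50
generations of random mating at the target Ne to build LD, in place of a
coalescent founder simulation; an importer accepts externally simulated
haplotypes when coalescent fidelity matters. Chromosomes are 100 Mb with
uniform site placement (map length was a free choice) and meiosis draws
Poisson(1 per 100 Mb) crossovers, uniform positions, random start phase.
Burn-in uses truncation selection — this is what fixes the largest-effect
QTL before sampling begins, the regime the validation depends on. Sex is
assigned half-and-half per cohort so parent quotas are always satisfiable.

Genotype sampling is `even` (equal per generation) or `uneven`
(negative-exponential in age, with the decay rate solved so the most
recent three generations hold ~60% of the panel, approximating commercial
genotyping's recency bias; the rate is exposed).

What it does **not** emulate: mutation, dominance/epistasis, overlapping
generations, genomic-selection breeding, and real coalescent LD structure.
Passing tests therefore demonstrate correct behaviour under drift,
truncation selection and family structure — not under every feature of
real cattle data.

Scoring: a true positive is a simulated QTL at q < 0.1 (also reported at
the locus level — any significant SNP within 1 Mb of the QTL). The
detectable denominator excludes QTL fixed by the end of the run or below
the MAF filter in the panel, since no scan can see a non-segregating site.
Under random mating every significant site is a false positive; under
selection, significant non-QTL sites within 1 Mb of a QTL are attributed
to linkage and not counted (the linkage handling was left open in the
design, so the window is a parameter).

### Gene drop

Founder haplotypes (same SFS construction, no LD) drop through a real or
synthetic pedigree with both parents known or both unknown; transmissions
are Poisson-recombinant gametes at a configurable per-Mb crossover rate.
The default rate of 1 crossover per Mb reproduces the published null
design literally even though it is ~100× the biological map; a
`BIOLOGICAL_CROSSOVER_RATE_PER_MB` constant (0.01) gives the realistic
alternative. The scan's dependent variable in the null is the pedigree
generation number (longest path from a founder). Synthetic pedigrees allow
generation overlap and geometric sire reuse to mimic heavy
artificial-insemination usage.

## Numerical choices and test scales

* GRM eigendecomposition is cached; eigen-reconstruction error is held
  below 1e-8 and trace(G) ≈ n within 2% for the standardized build.
* Rotated dosages are cached (`ScanEngine`) so permutation analyses pay
  the O(n²m) rotation once.
* AI-REML: max 100 iterations, relative tolerance 1e-8, variance floor
  1e-8·var(y); non-convergence raises with the last gradient norm.
* Degenerate inputs fail loudly: constant phenotypes, identity-like GRMs
  (λ unidentifiable), rank-deficient covariates, duplicated multivariate
  traits, K exceeding distinct grid points.
* The test suite and the acceptance script run the scaled simulation grid
  — 2 chromosomes × 2,000 sites, 1,000 founders, 1,000 sampled (the
  permutation-null panel uses 2 × 10,000 sites and 2,000 samples, matching
  the per-Mb marker density and hence the LD regime of dense commercial
  assays) — sizes chosen so the whole validation executes on a laptop
  while preserving each qualitative contrast (selection ≫ drift, even ≥
  uneven sampling, permutation kills PVE).

## Known limitations

* λ fixed at the null slightly biases per-SNP SEs for large effects (the
  exact per-SNP REML variants are deliberately out of scope).
* The multivariate null fit is EM with profiled means, not strict REML.
* At ~10⁴ tests, a q < 0.1 discovery on permuted data is a ~few-percent
  event per permutation for a perfectly calibrated scan (the minimum of
  ~10⁴ uniform p-values crosses the FDR boundary that often); empirical
  "zero hits in 10 permutations" statements are therefore scale-dependent
  luck at desk size even though PVE collapse and p-value calibration hold
  robustly.
* Kolmogorov–Smirnov uniformity checks must run on LD-thinned SNPs: the KS
  null assumes independent draws, and on a dense panel block-correlated
  p-values inflate the statistic even when every marginal is calibrated.
* Gene-drop panels through a *fixed* pedigree weight founders by realized
  descendant counts, so frequency conservation holds in expectation over
  pedigrees, not conditionally on one.
* Storey π₀ smoothing uses a GCV-chosen smoothing spline rather than a
  fixed-df spline; on null data the two agree to ~0.05.
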