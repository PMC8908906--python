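# Methods

This note documents the statistical models implemented in `hetdom`, the
synthetic-population generator used to exercise them, and the numerical and
design choices a maintainer would want spelled out. No empirical claim is
made here that the test suite or `scripts/acceptance.py` does not itself
compute.

## Pedigree coefficients

Breed composition propagates down the pedigree as the parental mean, with
founders carrying supplied purebred (or mixed) compositions. From sire and
dam compositions we compute

* heterosis coefficient: `het = 1 − Σᵢ B_Sᵢ·B_Dᵢ` — the expected fraction
  of loci whose two alleles descend from different breeds, and therefore a
  pedigree proxy for heterozygosity. It is symmetric, bounded in [0, 1],
  zero exactly for a within-breed purebred mating, and one for a fully
  outcrossed mating.
* recombination loss (Dickerson): `rec = 1 − Σᵢ (B_Sᵢ² + B_Dᵢ²)/2`,
  binned into seven right-closed classes (0, (0, 0.10], …, (0.40, 0.50],
  > 0.50). The symmetric (B_Sᵢ² + B_Dᵢ²)/2 form is used; a variant that
  squares only the dam term appears in some printed sources but would make
  the coefficient independent of the sire, which contradicts its
  definition.

Animals with exactly one unknown parent are refused by the coefficient
calculator (the proxy is undefined without both compositions) unless a
phantom purebred composition is configured for the unknown side.

### Numerator relationship matrix with genetic groups

`build_nrm_with_groups` runs the tabular (Henderson) recursion —
`A[i,j] = (A[j,s] + A[j,d])/2`, `A[i,i] = 1 + A[s,d]/2` — over a
parents-first pedigree, founders unrelated and non-inbred. Each founder's
unknown parents are replaced by phantom parents belonging to one genetic
group; the default rule assigns the group of the founder's majority breed
(lexicographic tie-break), and a catch-all `unknown` group absorbs the
unknown side of half-known parentages. The group incidence matrix Q
accumulates expected phantom fractions down the pedigree (founder row =
unit vector, offspring row = parental mean), so each row sums to one.

In the association model the genetic-group means enter as fixed covariates
(columns of Q appended to X, one dropped against the intercept) rather than
through modified mixed-model equations. The expectation shift is
algebraically identical and the implementation is far easier to verify.

## Genomic heterozygosity measures

With dosage 0/1/2 counting copies of allele b and missing calls excluded
from every count:

* **OH** = (# heterozygous called SNPs) / (# called SNPs).
* **E** per locus = 1 − q² − (1 − q)², frequencies from the analysed cohort
  by default (external frequencies can be supplied).
* **HL** = ΣE over homozygous called loci / (ΣE over homozygous + ΣE over
  heterozygous called loci): 0 when fully heterozygous, 1 when fully
  homozygous, weighting each locus by its informativeness.
* **ROHet**: a `window`-SNP (default 50) window slides in 1-SNP steps; a
  window is *heterozygous* iff it holds ≤ 2 missing and ≤ 1 homozygous
  calls. A SNP is flagged when the fraction of windows covering it that
  are heterozygous exceeds `snp_in_run_threshold` (default 0.05; a
  require-every-window mode exists). Maximal stretches of consecutive
  flagged SNPs with inter-SNP gaps ≤ `max_gap_bp` (default 1 Mb) are
  trimmed to start and end on called heterozygous SNPs and kept when the
  span is ≥ `min_length_bp` (default 1 kb) and the SNP density is
  ≥ `min_density`. The density default is one SNP per 50 kb: a literal
  one-SNP-per-50-bp rule is physically impossible alongside a 1-kb minimum
  length at 50-SNP windows on commercial panels, so the conventional
  detector default is used and the parameter is configurable. Chromosomes
  shorter than the window are skipped with a warning by default
  (`short_chrom_policy="shrink"` fits one reduced window instead).

Runs are classed by length as short (≤ 150 kb), intermediate (151–300 kb)
and long (> 300 kb). `subset_measures` recomputes OH/HL on an arbitrary SNP
subset — either one subset for all animals (e.g. the chromosomes carrying
dominance hits, a trait-specific measure) or per-animal subsets (e.g. the
complement of each animal's own ROHet SNPs).

## Mixed models

The association model for a heterozygosity measure is

    y = Xβ + Qg + c·het_measure + Za + e,   a ~ N(0, K σ²ₐ),  e ~ N(0, I σ²ₑ)

with X holding the intercept and the nuisance factors (dam parity 1–5+,
beef/dairy birth-herd type, twin status, recombination-loss class 0–6,
contemporary group) and K = A. Phenotype pre-adjustment for the scan uses
the same machinery with K = G (VanRaden Method I, missing dosages
mean-imputed as 2p before centering) and no heterozygosity covariate; its
residuals `e = y − Xβ̂ − Zâ` feed the per-SNP regressions.

REML estimation profiles the variance ratio λ = σ²ₐ/σ²ₑ on the
eigendecomposition of ZKZᵀ, so each objective evaluation is a diagonal
weighted least squares (the EMMA device). A 51-point log grid over
[10⁻⁶, 10⁶] plus the boundary λ = 0 locates the optimum; bounded Brent
refinement follows (tolerance 10⁻¹⁰ on log λ). The restricted likelihood is
the Patterson–Thompson form without the |XᵀX| constant. Boundary estimates
(σ²ₐ = 0) are returned with a flag rather than an error.

AIC is computed from the **ML** likelihood (maximised separately over the
ratio) with `k = n_fixed + 2`, because the compared association models
differ in their fixed effects and REML likelihoods are not comparable
across fixed-effect structures; commercial REML packages report a different
convention, and like must be compared with like within one software.

Collinearity: design columns are pruned to a maximal independent subset by
pivoted QR; factor levels with fewer than two observations merge into the
reference level with a warning; VIFs (1/(1−R²)) are reported per
heterozygosity covariate, and the OH + HL combination is refused outright —
the two measures track the same genome-wide quantity and their joint fit is
not interpretable.

## Dominance scan and FDR

Per SNP, animals with a missing call are dropped (no imputation in the
scan) and the stage-one residuals are regressed on [1, additive code,
dominance code]. When fewer than three genotype classes are present the
row is flagged NA and excluded from the FDR family rather than fitted with
a reduced model. p-values use the t reference with n_used − 3 degrees of
freedom. The genomic inflation factor is the median of the implied χ²₁
statistics over the null median 0.4549.

q-values follow Storey: π̂₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0, 0.05, …, 0.90, smoothed by a cubic least-squares polynomial
evaluated at λ = 0.90 and clamped to (1/m, 1]; then
q₍ᵢ₎ = min over t ≥ p₍ᵢ₎ of π̂₀·m·t/#{p ≤ t} via a reverse cumulative
minimum. (The reference implementation smooths with an R spline of three
effective degrees of freedom; the cubic polynomial is the closest
deterministic equivalent available here and with π₀ forced to 1 the
procedure is exactly Benjamini–Hochberg, which the tests verify against an
independent oracle.) Additive and dominance families are corrected
separately; significance is q ≤ 0.01.

## QTL regions

For each significant SNP, every same-chromosome SNP within ±0.5 Mb whose
genotypic r² (squared Pearson correlation of dosages over jointly called
animals, phase-free) reaches 0.5 joins its candidate region; the region
span is the min–max position of members. Overlapping or abutting candidate
regions merge transitively. The ±0.5 Mb centered reading of the distance
window is the default (a total-span reading is available by flag), LD is
anchored on the significant SNPs only — transitivity enters solely through
merging — and lead-SNP ties on p break on smaller position, then id.
Regions export as 0-based half-open BED from the internal 1-based closed
coordinates.

## Synthetic populations

The generator produces the structure the analysis assumes, at desk scale:

* **Breeds**: ancestral frequencies Uniform(0.1, 0.9); per-breed
  frequencies Balding–Nichols Beta draws at F_ST = 0.25 (divergent but
  realistic for cattle breeds). A fixed number of 100-SNP blocks (20% of
  blocks, at least one) are breed-differentiated: each breed sits at
  frequency 0.97 or 0.03 for the block, never identically across all
  breeds. Fixation is deliberately *partial*: with ~3% residual
  heterozygosity per parent, a 50-SNP window rarely passes the ≤ 1
  homozygote rule, so run detection is sporadic at the individual level.
  Per-animal run counts then form a weak, noisy correlate of ancestry
  while genome-wide OH remains a strong one — the qualitative relationship
  observed in real multi-breed cattle cohorts. Near-complete fixation
  would instead make run counts a deterministic ancestry readout and
  invert that ordering.
* **Defaults**: 3 breeds, 2 chromosomes × 500 SNPs at 2-kb spacing, 1
  Morgan per chromosome; cohorts of 20 founders per breed, 40 between-breed
  F1s and 40 random-mated second-generation animals (140 total). These are
  the study conditions for every correlation-structure test.
* **Meiosis**: gamete dropping on phased haplotypes; crossover count
  Poisson at the chromosome's Morgan length, breakpoints uniform in
  physical position, no interference. Offspring breed composition is the
  parental mean.
* **Traits**: trait = intercept + uniform-assigned fixed-effect levels +
  Σ additive QTL·dosage + Σ dominance QTL·1[het] + polygenic + N(0, σ²ₑ).
  The polygenic value is gene-dropped down the pedigree (founders
  N(0, σ²ₐ); offspring = parent average + Mendelian sampling at σ²ₐ/2),
  independent of the markers, so marker-QTL and polygenic signals are
  separable in recovery tests. σ²ₐ is derived from `h2_poly` against the
  analytic QTL-plus-residual variance; `analytic_trait_variance` gives the
  HWE target the simulated sample variance is tested against. Contemporary
  groups are randomized blocks (default size 10) — the real grouping
  algorithm (herd × 60-day slaughter window × sex) is emulated only as a
  label.

What the generator does **not** emulate: realistic cattle LD decay and
haplotype structure within breeds (LD exists only through the divergent
blocks and family structure), genotyping and imputation error, sex
chromosomes, selection, and assortative mating. Passing tests therefore
demonstrate correctness of the statistical machinery and the qualitative
behaviour of the measures under controlled genetic structure — not
calibration to any particular real cattle population.

## Problem sizes and determinism

Every stochastic routine is a pure function of its inputs and an integer
seed. The simulation-based checks use cohorts of 140–1,000 animals and
600–5,000 SNPs with 5–200 replicates per property — sizes chosen so the
whole suite exercises every code path at interactive speed while keeping
Monte-Carlo error well inside the asserted tolerances (e.g. 200 replicates
put the SE of the mean REML ĥ² near 0.01 against a ±0.03 band).
`scripts/acceptance.py` reports means over the same kinds of replicates;
all of its randomness derives from `--seed`, and derived per-replicate
seeds stay below 2³¹.

## Known limitations

* The per-SNP scan is OLS on pre-adjusted residuals (the two-stage
  GRAMMAR-style approximation); it does not refit the mixed model at every
  locus, which slightly deflates test statistics for SNPs strongly
  correlated with the polygenic background.
* The REML solver targets dense desk-scale problems (n up to a few
  thousand); it makes no attempt at the sparse-matrix scale of national
  evaluations.
* Dominance enters the scan and the simulator, but no dominance
  relationship matrix is fitted.
* ROHet window semantics at unstated corners (proportion-of-windows
  threshold, maximal gap) follow common detector defaults; both are
  configurable and logged, and the proportion default (0.05) with a 1-Mb
  gap reproduces conventional behaviour on evenly spaced panels.
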