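# Methods

This note records the models implemented in `rhmscan`, the defaults and why
they were chosen, what the synthetic-data generator does and does not emulate,
and the numerical decisions that affect results.

## 1. The windowed variance-component test

Each chromosome is divided into windows of 100 adjacent SNPs shifted by 50
(both configurable), so consecutive windows overlap by half. Windows are
defined on SNP indexes, not base pairs; a tail window keeps whatever SNPs
remain, and a candidate start is emitted only if it adds at least one SNP not
covered by the previous window (so a chromosome with 250 SNPs yields spans
[0,100), [50,150), [100,200), [150,250)). Windows never span chromosomes.

For window *w* the full model fits

y = Xb + g + r + e, with g ~ N(0, σ²g·G), r ~ N(0, σ²r·G_w), e ~ N(0, σ²e·I),

and the null model drops r. The fixed design X is an intercept plus a
population factor; the per-population standardization of the response makes
the factor nearly redundant, but it guards the contract when users feed
unstandardized traits. The LRT is clamped at zero (boundary estimates produce
slightly negative 2·Δlog L numerically) and referred to the half-half mixture
of a point mass at zero and χ²₁, the asymptotic distribution when the tested
variance sits on the boundary of the parameter space.

Two polygenic modes:

- **whole_G** — one genome-wide kernel; a single null fit is shared by every
  window (the scan records its null-fit count so this is testable).
- **loco_G** — the polygenic kernel always excludes the chromosome being
  interrogated ("n−1" kernels, one per chromosome; each chromosome's null fit
  is reused by its windows). This is the mode that rescues QTL in populations
  descended from very few sires: with long intact sire haplotypes the whole-
  genome kernel is strongly correlated with any window on the same chromosome
  and absorbs the regional signal; removing the chromosome from the polygenic
  term lets the window recover it. The package's acceptance suite demonstrates
  this contrast on a 4-sire backcross with a planted QTL.

In loco_G mode the null model uses the same LOCO kernel as the full model;
anything else would compare non-nested models.

### Multiple testing

With step = window/2, adjacent windows overlap half their SNPs, so only half
of the tested windows are counted as independent in the Bonferroni
correction. For n windows and family-wise level α:

- genome-wide threshold T solves mixture-p(T) = α / ⌈n/2⌉,
- suggestive threshold ("one false positive per scan") solves
  mixture-p(T) = 1/n,

both by monotone root-finding on the implemented mixture survival function
(Brent, |Δ| ≤ 1e-10). At n = 788, α = 0.05 these give T = 13.38 and 9.11.
Note a subtlety in how such thresholds are sometimes quoted: the per-test
level paired with the suggestive threshold is occasionally printed as the
plain χ²₁ tail (2.54×10⁻³ at T = 9.11) rather than the mixture tail
(1.27×10⁻³ = 1/788). The implementation defines both thresholds through the
mixture, which reproduces the pair (13.38, 9.11) exactly; the package reports
mixture p-values throughout.

Windows whose REML fits did not converge are reported with a flag and are
never called significant; silently dropping them would bias the scan.

## 2. Genomic relationship matrices

The GRM is the classic first VanRaden construction: dosages centered by twice
the allele frequency, cross-products divided by 2Σp(1−p) over the SNPs used.
Missing dosages are mean-imputed within population at kernel construction
only — the stored panel keeps its missing values.

Frequency scope. The default is **per-population**: frequencies, imputation,
centering and the denominator are computed within each population, and the
kernel is block-diagonal by construction, with one recorded denominator per
population. Rationale: allele-frequency differences between distant
populations would otherwise generate systematic relationship structure exactly
where the block-diagonal assumption says there is none. A **pooled** scope
(single denominator, full matrix) is available; combined with
`block_diagonalize` it reproduces the "compute IBS everywhere, then zero the
cross-population blocks" reading. Regional (window) kernels are treated the
same way as the whole kernel — block-diagonal by default — since fitting a
window kernel with cross-population covariances against a block-diagonal
polygenic kernel would reintroduce the structure the design removes.

The recorded denominators make kernels additive: for disjoint SNP sets A and
B, G(A∪B)·d(A∪B) = G(A)·d(A) + G(B)·d(B) exactly (per population block under
the per-population scope), and in particular the whole kernel decomposes into
any LOCO kernel plus its excluded chromosome. The test suite checks this
identity, plus agreement with a naive double-loop construction at small n, to
1e-10.

Stabilization: before any factorization, each kernel receives
1e-8 × mean(diagonal) on its diagonal. Regional kernels built from 100 SNPs
on many more animals are rank-deficient by construction; the jitter is ~1e-8
of the trait variance and does not move estimates at the reported precision.

## 3. REML

`KernelREML` maximizes the standard restricted log-likelihood

lR = −½[(n−p)·log 2π + log|V| + log|X'V⁻¹X| − log|X'X| + y'Py]

(the |X'X| term makes lR invariant to reparameterizing X). Two solvers:

- **dense AI-REML** (two or more kernels): average-information updates with an
  active-set treatment of the non-negativity bound — a component at the floor
  (1e-8 × var(y)) with an inward gradient is removed from the AI system so it
  cannot pollute the Newton step for the free components. A candidate step is
  accepted only if it does not decrease lR; otherwise an expectation-ratio
  fallback update is tried, then step halving. Accepted iterates are therefore
  monotone (tested). Convergence: |Δ lR| < 1e-6 and max parameter change
  < 1e-6 relative to the total variance; maximum 200 iterations; floored
  components are flagged as boundary estimates. Default initialization is
  deterministic — σ²e = var(y)/2, the kernels sharing the other half — and an
  explicit `init` is accepted; the scan warm-starts each window fit from its
  null fit (null components plus 2% of σ²p as the regional seed), which is
  deterministic and typically halves the iteration count.
- **eigendecomposition shortcut** (single kernel): rotate once by the kernel's
  eigenvectors, profile the likelihood over the ratio λ = σ²g/σ²e (every
  evaluation is then O(n)), optimize by bounded Brent on log λ, and polish by
  rooting the analytic profile score. The polish matters: derivative-free
  search localizes a maximizer only to the width of the floating-point-flat
  region (~1e-8 relative), while the score crossing pins λ to near machine
  precision, keeping scale equivariance (y → c·y leaves h² unchanged) tight.
  The two solvers agree on shared problems (tested to 1e-5 in lR).

Approximate standard errors from the final AI matrix are reported on dense
fits (`REMLFit.se`); they are the usual asymptotic approximation and are not
meaningful for boundary components.

The restricted likelihood itself is verified against a closed form for the
residual-only model, against an independent dense-algebra evaluation, and the
optimizer against variance-grid oracles at small n.

## 4. Phenotype preparation

Pipeline order is fixed: log transform → repeatability model per population
(and per trait) → per-population standardization → assembly.

- Log transform: ln(x + offset), offset 1 by default (the constant is a
  convention; counts of zero are common in FEC data).
- Repeatability model: y = Xb + Za + e with an i.i.d. animal effect — no
  genomic or pedigree relationship among animals at this stage, which keeps
  the phenotype preparation independent of the kernels being tested. REML is
  profiled to one dimension (Z'Z is diagonal, so likelihood, GLS and BLUP are
  closed-form given λ = σ²a/σ²e) and the boundary λ = 0 is checked explicitly.
  The per-animal phenotype is the BLUP of the animal effect ("average animal
  effect"). Whether such an average should be the shrunken BLUP or a plain
  adjusted mean is a modelling choice; the BLUP is the default and a
  within-animal adjusted mean is available (`estimator="adjusted_mean"`) for
  sensitivity checks. Fixed effects are categorical unless declared as
  covariates.
- Standardization is within population, to mean 0 and standard deviation 1
  with the population (divide-by-n) convention, so the unit-variance contract
  is exact. Effects from different populations come from separate models with
  different fixed-effect structures; their locations and scales are not
  comparable, which is why standardization is per population.
- Assembly maps each population to a trait (so one population can contribute,
  say, a Nematodirus-type trait while the others contribute Strongyles-type
  records) and emits one value per genotyped animal. The mapping is
  configuration, not code.

## 5. The synthetic-data generator

The generator's role is to produce data with the statistical features the
joint scan must handle, at sizes where the full pipeline runs in minutes.

- **Founders and divergence.** Each population has two parental lines whose
  allele frequencies drift from a common base by a Balding–Nichols
  reparameterized Beta; the divergence parameter plays the role of Fst. The
  default 0.15 puts the simulated populations at a typical between-breed
  distance — far enough that a principal-component projection separates them
  cleanly (tested), which is the regime motivating the block-diagonal kernel.
- **Crosses.** F1 sires carry one haplotype from each line. F2 mates F1 × F1,
  backcross mates F1 sires to purebred line-A dams, double backcross mates F1
  sires to BC1 dams. Meiosis is Haldane: Poisson crossover counts on the cM
  length, uniform positions, no interference — the simplest defensible model,
  and interference is irrelevant at 100-SNP window scale. Few founder sires
  (the default third population uses 4) produce the long intact haplotypes and
  long-range LD that motivate the LOCO mode; the suite verifies that r² at a
  50-SNP lag is higher in a 4-sire backcross than in a 200-sire cross.
- **Default scale.** Three populations (double backcross with 10 sires,
  backcross with 20, backcross with 4 — mirroring the relative family
  structure of a multi-flock joint analysis), 6 chromosomes × 300 SNPs of
  100 cM for test work; sizes per test are stated in the tests themselves
  (typically 200–800 animals per population, n = 1500 for whole-genome
  heritability recovery).
- **Phenotypes.** Animal genetic value = polygenic part (effects on SNPs
  outside any causal window, so planted fractions are identifiable) plus
  causal-region parts; each part is rescaled so its realized sample variance
  hits the target fraction exactly, making recovery tests sharp. Repeated
  records add a permanent-environment effect (variance = repeatability −
  genetic fraction) and i.i.d. per-record residuals (variance = 1 −
  repeatability). Observation-scale counts are lognormal by default
  (exp(log-mean + latent), log-mean 4.0 so typical counts sit near 50–60);
  a negative-binomial observation model is available when integer counts with
  zeros matter. The pipeline log-transforms immediately, so the lognormal
  default is the cleaner test substrate.
- **What is not emulated.** Real chip SNP names and positions, parasite
  biology and species-specific count distributions, maternal and pedigree
  structure beyond sire families, environmental correlation across time
  points beyond the single permanent-environment term, and selection. Passing
  tests therefore show that the statistical machinery behaves as designed
  under the stated genetic architecture — not that any particular organism's
  data meet these assumptions.

## 6. Quality control and IO

QC filters run in a fixed order: chromosome exclusion (e.g. sex chromosomes)
→ per-population SNP missingness → per-population MAF (a SNP must pass in
every population — the strictest reading when populations are QC'd separately
before intersecting marker sets) → animal missingness. Defaults
(min MAF 0.01, SNP missingness ≤ 0.05, animal missingness ≤ 0.10) are
conventional, not tuned to any particular dataset; real studies often apply
population-specific recipes, which this package expresses as per-population
runs of the same configurable filter. QC is idempotent (tested).

PLINK text and binary formats are both supported. The writer emits
Illumina-style A/B allele calls (A reference, B alternate), which the reader
recognizes, so text round trips are exact even for monomorphic SNPs; for
ACGT-coded text files, where .ped carries no ref/alt designation, the reader
counts the lexicographically last observed allele and treats single-allele
SNPs as monomorphic reference. The binary path is always unambiguous (A1 in
.bim is the alternate). Kernels export as plain text or in the GCTA packed
lower-triangle binary layout (.grm.bin/.grm.id/.grm.N.bin).

## 7. Known limitations

- Two-kernel REML has no joint diagonalization; fits are dense and scale as
  n³ per iteration, fine for desk-scale n (≲ a few thousand animals), not for
  biobank sizes.
- The AI standard errors are asymptotic and meaningless at boundaries; no
  profile-likelihood intervals are provided.
- The mixture null for the LRT is asymptotic; at very small n or with near-
  collinear kernels the boundary weight can deviate from ½ (the type-I
  calibration test bounds this at the sizes used).
- The repeatability model assumes a common residual variance across time
  points within a population.
- No dominance or epistatic kernels, no weighted GRMs, no single-SNP scan.
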