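# rhmscan

Regional heritability mapping (RHM) for joint analyses of genetically distant
populations.

## What this is for

Indicator traits for parasite resistance in livestock — classically the faecal
egg count (FEC) in sheep — are highly polygenic, and single-SNP association
studies of individual populations rarely agree on the loci involved. RHM takes
a different route: the genome is divided into sliding windows of SNPs, and for
each window a mixed model asks how much phenotypic variance the window's own
genomic relationship matrix (GRM) explains on top of the genome-wide polygenic
term. Because the test aggregates evidence over a region, it can detect
architectures a single SNP cannot tag — several causal variants, rare alleles,
or different linkage phases in different populations.

`rhmscan` implements the joint, multi-population form of this analysis:

- genotype panels from PLINK text or binary files, per-population QC, and
  intersection to the common SNP set;
- repeated count phenotypes reduced to one standardized "average animal
  effect" per animal via a repeatability model (log transform, REML, BLUP,
  per-population z-scoring);
- GRMs with **cross-population covariances set to zero** (block-diagonal by
  population), since identity-by-state between unrelated breeds carries no
  useful relationship signal;
- **leave-one-chromosome-out (LOCO, "n−1") polygenic kernels**, so that long
  within-family LD — a few sires contributing long intact haplotypes — cannot
  let the genome-wide term swallow a regional QTL;
- per-window likelihood-ratio tests against the ½χ²₀ + ½χ²₁ boundary mixture,
  with Bonferroni thresholds that count only half of the overlapping windows;
- a synthetic multi-population cross generator (founder drift, Haldane
  meiosis, planted regional QTL, overdispersed repeated counts) so the whole
  pipeline is testable end to end without any external data.

## The model

For a window *w*, with y the vector of standardized animal effects:

    y = Xb + g + r + e,   g ~ N(0, σ²g G),  r ~ N(0, σ²r G_w),  e ~ N(0, σ²e I)

where G is the genome-wide (or LOCO) GRM and G_w the window GRM, both block-
diagonal by population (VanRaden cross-products of centered dosages divided by
2Σp(1−p)). Variance components are estimated by average-information REML with
monotone safeguards. The test statistic

    LRT = max(0, 2·(logL_full − logL_null))

is referred to the half-half mixture of a point mass at zero and χ²₁, the
boundary distribution for a single variance component. Heritabilities are
h² = σ²g/σ²p and h²r = σ²r/σ²p with σ²p = σ²g + σ²r + σ²e. For a scan of
*n* overlapping windows the genome-wide threshold solves
mixture-p = α / ⌈n/2⌉ and the suggestive threshold ("one false positive per
scan") solves mixture-p = 1/n; at the study scale of 788 windows these are
LRT = 13.38 and 9.11.

## Worked example

```python
import rhmscan as rhm

designs = [
    rhm.PopulationDesign("POP1", "double_backcross", 10, 150, founder_freq_divergence=0.15),
    rhm.PopulationDesign("POP2", "backcross", 20, 150, founder_freq_divergence=0.15),
    rhm.PopulationDesign("POP3", "backcross", 4, 150, founder_freq_divergence=0.15),
]
gmap = rhm.default_map(n_chromosomes=4, snps_per_chrom=200)
qtl = rhm.QTLSpec(chrom=2, snp_range=(50, 150), n_causal=5, target_regional_h2=0.15)
trait = rhm.TraitModel(polygenic_h2=0.25, repeatability=0.5, n_time_points=4)
panel, records, truth = rhm.simulate_study(42, designs=designs, gmap=gmap,
                                           qtls=[qtl], trait=trait)

y = rhm.animal_effect_pipeline(records, panel.animal_ids)   # counts -> z-scored BLUPs
result = rhm.scan(panel, y, mode="loco_G")                  # LOCO-mode scan
print(f"windows tested: {result.n_windows}")
print(f"thresholds: genome-wide {result.genomewide_threshold:.2f}, "
      f"suggestive {result.suggestive_threshold:.2f}")
print(rhm.summarize(result, "suggestive").to_string(index=False))
```

Output:

```
windows tested: 12
thresholds: genome-wide 5.73, suggestive 1.91
 chrom  window first_snp  start_bp last_snp   end_bp       lrt     h2_r significance
     1       1    snp1_1     60000 snp1_100  6000000  5.386437 0.071836   suggestive
     1       2   snp1_51   3060000 snp1_150  9000000  5.315248 0.081238   suggestive
     2       1    snp2_1     60000 snp2_100  6000000  3.965302 0.083083   suggestive
     2       2   snp2_51   3060000 snp2_150  9000000 33.037308 0.333942   genomewide
     2       3  snp2_101   6060000 snp2_200 12000000 31.617043 0.304311   genomewide
     4       1    snp4_1     60000 snp4_100  6000000  6.837048 0.104260   genomewide
     4       2   snp4_51   3060000 snp4_150  9000000  6.277552 0.106344   genomewide
     4       3  snp4_101   6060000 snp4_200 12000000  4.588350 0.075239   suggestive
```

The two windows overlapping the planted chromosome-2 QTL dominate the scan
(LRT 33.0 and 31.6 against a genome-wide threshold of 5.73 for this 12-window
toy scan); their estimated regional heritabilities are upward-biased at this
small sample size, which is expected for windows selected at the scan maximum.
The thresholds are small here because only 12 windows are tested — at the
study scale (788 windows) the same arithmetic gives 13.38 and 9.11.

The same pipeline is available from the shell:

```bash
rhmscan simulate --out fixture --seed 42 --qtl 2:50:150:0.15
rhmscan prep --phenotypes fixture/phenotypes.tsv --out effects.tsv
rhmscan scan --genotypes fixture/POP1 --genotypes fixture/POP2 --genotypes fixture/POP3 \
             --labels fixture/populations.tsv --trait effects.tsv \
             --mode loco_G --out scan.tsv --plot profile.png
rhmscan summarize --results scan.tsv
rhmscan thresholds --n-windows 788
```

## Layout

- `rhmscan.sim` — multi-population cross simulator and fixture writer
- `rhmscan.io` — PLINK text/binary, labels, phenotypes, GRM export (GCTA layout)
- `rhmscan.qc` — QC filters and cross-population SNP intersection
- `rhmscan.phenotypes` — log transform, `RepeatabilityModel`, standardization
- `rhmscan.kernels` — VanRaden GRMs, block-diagonalization, LOCO kernels, windows
- `rhmscan.reml` — `KernelREML` (AI-REML with EM fallback and eigen shortcut)
- `rhmscan.scan` — `RegionalHeritabilityScan`, mixture p-values, thresholds,
  summaries, LRT profile plots
- `rhmscan.cli` — `rhmscan` command with the subcommands shown above

See `docs/methods.md` for the modelling choices and their rationale.
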