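"""Synthetic multi-population cross data with planted regional QTL.

The generator emulates the statistical structure a joint windowed variance
scan has to cope with: a few genetically distant populations, each descended
from a handful of F1 sires (so that offspring carry long unrecombined
haplotype blocks and hence long-range LD), an autosome-only SNP map, and
repeated, overdispersed count phenotypes with a repeatability structure.

Meiosis uses the Haldane model: crossover counts are Poisson with mean equal
to the chromosome length in Morgans, positions uniform on the cM map, no
interference. Founder allele-frequency divergence between populations (and
between the two parental lines of a cross) follows a Balding-Nichols
reparameterized Beta around a common base frequency, with the divergence
parameter playing the role of Fst.

Genetic values are built from planted SNP effects and rescaled so that the
realized variance fractions in the sample match the targets exactly, which
makes downstream recovery tests sharp. Observation-scale counts are produced
by a lognormal (default) or negative-binomial model on top of the latent
log-scale record value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel, concat_panels

DESIGN_KINDS = ("F2", "backcross", "double_backcross")


# ---------------------------------------------------------------------------
# design / map / trait types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationDesign:
    """One population of a multi-population cross experiment."""

    name: str
    design_kind: str
    n_founder_sires: int
    n_offspring: int
    family_sizes: tuple | None = None
    founder_freq_divergence: float = 0.0

    def __post_init__(self):
        if self.design_kind not in DESIGN_KINDS:
            raise ValueError(
                f"unknown design_kind {self.design_kind!r}; expected one of {DESIGN_KINDS}")
        if self.n_offspring < 1 or self.n_founder_sires < 1:
            raise ValueError("n_offspring and n_founder_sires must be >= 1")
        if self.family_sizes is not None:
            fam = tuple(int(s) for s in self.family_sizes)
            if len(fam) != self.n_founder_sires:
                raise ValueError("family_sizes must have one entry per sire")
            if sum(fam) != self.n_offspring:
                raise ValueError("family_sizes must sum to n_offspring")
            object.__setattr__(self, "family_sizes", fam)
        if not 0.0 <= self.founder_freq_divergence <= 1.0:
            raise ValueError("founder_freq_divergence must be in [0, 1]")

    def allocate_families(self) -> np.ndarray:
        """Number of offspring per sire."""
        if self.family_sizes is not None:
            return np.asarray(self.family_sizes, dtype=int)
        base, extra = divmod(self.n_offspring, self.n_founder_sires)
        sizes = np.full(self.n_founder_sires, base, dtype=int)
        sizes[:extra] += 1
        return sizes


class GenomeMap:
    """Autosome-only SNP map with bp and cM coordinates.

    Parameters
    ----------
    chromosomes:
        Sequence of ``(chrom_id, n_snps, length_cM)``. SNP bp positions are
        laid out on an even grid and cM positions linearly along the
        chromosome; both are strictly increasing within a chromosome.
    """

    def __init__(self, chromosomes: Sequence[tuple], bp_spacing: int = 60_000):
        if not chromosomes:
            raise ValueError("genome map must contain at least one chromosome")
        rows = []
        self.chromosomes = []
        for chrom, n_snps, length_cm in chromosomes:
            n_snps = int(n_snps)
            if n_snps < 1:
                raise ValueError("each chromosome needs at least one SNP")
            if length_cm < 0:
                raise ValueError("chromosome length must be >= 0 cM")
            self.chromosomes.append((chrom, n_snps, float(length_cm)))
            cm = (np.linspace(0.0, length_cm, n_snps) if n_snps > 1
                  else np.array([0.0]))
            for i in range(n_snps):
                rows.append((f"snp{chrom}_{i + 1}", chrom,
                             (i + 1) * bp_spacing, cm[i]))
        self.snps = pd.DataFrame(rows, columns=["snp", "chrom", "bp", "cM"])

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def chrom_slices(self) -> list:
        """Per chromosome: (chrom_id, slice into the SNP table, cM positions)."""
        out, start = [], 0
        for chrom, n, _length in self.chromosomes:
            sl = slice(start, start + n)
            out.append((chrom, sl, self.snps["cM"].to_numpy()[sl]))
            start += n
        return out


@dataclass(frozen=True)
class QTLSpec:
    """A causal region: ``n_causal`` SNPs inside a SNP-index range on one
    chromosome, contributing ``target_regional_h2`` of phenotypic variance."""

    chrom: object
    snp_range: tuple
    n_causal: int
    target_regional_h2: float
    shared_across_pops: bool = True

    def __post_init__(self):
        lo, hi = self.snp_range
        if not (0 <= lo < hi):
            raise ValueError("snp_range must be a non-empty half-open interval")
        if not 0.0 <= self.target_regional_h2 < 1.0:
            raise ValueError("target_regional_h2 must be in [0, 1)")
        if self.n_causal < 1 or self.n_causal > hi - lo:
            raise ValueError("n_causal must be in [1, range width]")


@dataclass(frozen=True)
class TraitModel:
    """Latent-scale trait structure for repeated count records.

    The latent record value is g + pe + fixed effects + e with, on a total
    latent variance of 1 (excluding fixed effects): genetic fraction
    ``polygenic_h2`` plus the QTL targets, permanent-environment fraction
    ``repeatability - (polygenic_h2 + sum of QTL h2)`` and per-record residual
    fraction ``1 - repeatability``.
    """

    polygenic_h2: float = 0.25
    repeatability: float = 0.5
    n_time_points: int = 4
    fixed_effects: tuple = ()  # (name, n_levels, sd)
    count_model: str = "lognormal"
    overdispersion: float = 2.0
    log_mean: float = 4.0
    population_trait_map: Mapping[str, str] | None = None

    def validate(self, total_qtl_h2: float) -> None:
        genetic = self.polygenic_h2 + total_qtl_h2
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError("polygenic_h2 must be in [0, 1)")
        if genetic >= 1.0:
            raise ValueError("variance fractions sum to >= 1")
        if not genetic <= self.repeatability < 1.0 + 1e-12:
            raise ValueError(
                "repeatability must lie in [polygenic + regional h2, 1)")
        if self.count_model not in ("lognormal", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.n_time_points < 1:
            raise ValueError("n_time_points must be >= 1")


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------

@dataclass
class FounderSet:
    """Phased founders of one population: F1 sires carrying one haplotype from
    each parental line, plus the two line allele-frequency vectors."""

    design: PopulationDesign
    line_a_freqs: np.ndarray
    line_b_freqs: np.ndarray
    sire_haplotypes: np.ndarray  # (n_sires, 2, n_snps) int8; 0 = line A hap


def _drift_freqs(base: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of line frequencies around the base frequency."""
    if fst <= 0.0:
        return base.copy()
    fst = min(fst, 0.999)
    a = base * (1.0 - fst) / fst
    b = (1.0 - base) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def simulate_founders(design: PopulationDesign, gmap: GenomeMap,
                      base_freqs: np.ndarray, seed: int) -> FounderSet:
    """Draw the two parental lines and the F1 sires of one population.

    Line frequencies drift from ``base_freqs`` with Fst equal to the design's
    ``founder_freq_divergence``; each sire carries one haplotype sampled from
    line A and one from line B. Deterministic given the seed.
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    if gmap.n_snps == 0:
        raise ValueError("empty genome map")
    if base_freqs.shape != (gmap.n_snps,):
        raise ValueError("base_freqs length must match the genome map")
    if np.any(base_freqs <= 0.0) or np.any(base_freqs >= 1.0):
        raise ValueError("base frequencies must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    p_a = _drift_freqs(base_freqs, design.founder_freq_divergence, rng)
    p_b = _drift_freqs(base_freqs, design.founder_freq_divergence, rng)
    n, m = design.n_founder_sires, gmap.n_snps
    haps = np.empty((n, 2, m), dtype=np.int8)
    haps[:, 0, :] = rng.random((n, m)) < p_a
    haps[:, 1, :] = rng.random((n, m)) < p_b
    return FounderSet(design=design, line_a_freqs=p_a, line_b_freqs=p_b,
                      sire_haplotypes=haps)


def _gamete_chrom(haps: np.ndarray, cm: np.ndarray, length_cm: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete for one chromosome (Haldane model)."""
    n_cross = rng.poisson(length_cm / 100.0) if length_cm > 0 else 0
    start = rng.integers(2)
    if n_cross == 0:
        return haps[start]
    cuts = np.sort(rng.uniform(0.0, length_cm, n_cross))
    which = (start + np.searchsorted(cuts, cm, side="right")) % 2
    return haps[which, np.arange(haps.shape[1])]


def _meiosis(haps: np.ndarray, chrom_slices, rng: np.random.Generator) -> np.ndarray:
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    for _chrom, sl, cm in chrom_slices:
        length_cm = float(cm[-1]) if len(cm) else 0.0
        gamete[sl] = _gamete_chrom(haps[:, sl], cm, length_cm, rng)
    return gamete


def simulate_cross(founders: FounderSet, design: PopulationDesign,
                   gmap: GenomeMap, seed: int) -> GenotypePanel:
    """Mate the founders according to the design and return offspring genotypes.

    F2: F1 sire x F1 dam. backcross: F1 sire x purebred line-A dam.
    double_backcross: F1 sire x BC1 dam (one recombinant F1 gamete, one pure
    line-A haplotype). Offspring dosages are sums of two recombinant gametes;
    sire family assignment is recorded on the panel.
    """
    if design.design_kind not in DESIGN_KINDS:
        raise ValueError(f"unknown design_kind {design.design_kind!r}")
    if founders.sire_haplotypes.shape[0] != design.n_founder_sires:
        raise ValueError("founder set does not match the design's sire count")
    rng = np.random.default_rng(seed)
    slices = gmap.chrom_slices()
    m = gmap.n_snps
    fam_sizes = design.allocate_families()
    n = design.n_offspring
    dosages = np.empty((n, m), dtype=np.int8)
    sires = np.empty(n, dtype=object)
    p_a = founders.line_a_freqs

    def draw_line_a_hap():
        return (rng.random(m) < p_a).astype(np.int8)

    row = 0
    for s, size in enumerate(fam_sizes):
        sire_haps = founders.sire_haplotypes[s]
        for _ in range(size):
            paternal = _meiosis(sire_haps, slices, rng)
            if design.design_kind == "F2":
                dam = np.stack([(rng.random(m) < founders.line_a_freqs),
                                (rng.random(m) < founders.line_b_freqs)]).astype(np.int8)
            elif design.design_kind == "backcross":
                dam = np.stack([draw_line_a_hap(), draw_line_a_hap()])
            else:  # double_backcross
                f1 = np.stack([(rng.random(m) < founders.line_a_freqs),
                               (rng.random(m) < founders.line_b_freqs)]).astype(np.int8)
                dam = np.stack([_meiosis(f1, slices, rng), draw_line_a_hap()])
            maternal = _meiosis(dam, slices, rng)
            dosages[row] = paternal + maternal
            sires[row] = f"{design.name}_sire{s + 1}"
            row += 1

    ids = np.array([f"{design.name}_{i + 1}" for i in range(n)], dtype=object)
    snps = gmap.snps[["snp", "chrom", "bp"]].copy()
    return GenotypePanel(dosages=dosages.astype(float), animal_ids=ids,
                         populations=np.full(n, design.name, dtype=object),
                         snps=snps, sires=sires)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale so the realized (population) variance is exact."""
    x = x - x.mean()
    sd = x.std()
    if target_var == 0.0 or sd == 0.0:
        return np.zeros_like(x)
    return x * (np.sqrt(target_var) / sd)


def simulate_phenotypes(panel: GenotypePanel, qtls: Sequence[QTLSpec],
                        trait: TraitModel, seed: int):
    """Simulate repeated count records plus a true-values ledger.

    Returns ``(records, truth)`` where ``records`` is a tidy DataFrame with one
    row per (animal, time point) and ``truth`` carries the per-animal genetic
    values (total and per QTL region), the per-animal latent animal effect
    (genetic + permanent environment), and the realized variance fractions.
    """
    qtls = list(qtls)
    total_qtl = sum(q.target_regional_h2 for q in qtls)
    trait.validate(total_qtl)
    rng = np.random.default_rng(seed)
    n, m = panel.n_animals, panel.n_snps

    # causal SNP bookkeeping -------------------------------------------------
    causal_global: list[np.ndarray] = []
    for q in qtls:
        chrom_idx = panel.chrom_snp_indices(q.chrom)
        lo, hi = q.snp_range
        if hi > len(chrom_idx):
            raise ValueError(
                f"QTL range {q.snp_range} exceeds chromosome {q.chrom!r} "
                f"({len(chrom_idx)} SNPs)")
        region = chrom_idx[lo:hi]
        causal_global.append(np.sort(rng.choice(region, q.n_causal, replace=False)))

    # regional genetic values --------------------------------------------------
    pops = panel.populations
    g_regions = []
    for q, snps in zip(qtls, causal_global):
        d = panel.dosages[:, snps]
        d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
        g = np.zeros(n)
        if q.shared_across_pops:
            g = d @ rng.standard_normal(len(snps))
        else:
            for pop in pd.unique(pops):
                rows = pops == pop
                g[rows] = d[rows] @ rng.standard_normal(len(snps))
        g_regions.append(_scale_to_var(g, q.target_regional_h2))

    # polygenic value from SNPs outside all causal windows ---------------------
    window_snps = set()
    for q in qtls:
        chrom_idx = panel.chrom_snp_indices(q.chrom)
        window_snps.update(chrom_idx[q.snp_range[0]:q.snp_range[1]].tolist())
    poly_cols = np.setdiff1d(np.arange(m), np.fromiter(window_snps, dtype=int,
                                                       count=len(window_snps)))
    if trait.polygenic_h2 > 0 and len(poly_cols):
        d = panel.dosages[:, poly_cols]
        d = np.where(np.isnan(d), np.nanmean(d, axis=0), d)
        g_poly = _scale_to_var(d @ rng.standard_normal(len(poly_cols)),
                               trait.polygenic_h2)
    else:
        g_poly = np.zeros(n)

    g_total = g_poly + sum(g_regions, np.zeros(n))
    genetic_frac = trait.polygenic_h2 + total_qtl
    pe_var = trait.repeatability - genetic_frac
    res_var = 1.0 - trait.repeatability
    pe = rng.normal(0.0, np.sqrt(pe_var), n) if pe_var > 0 else np.zeros(n)

    # fixed effects ------------------------------------------------------------
    factor_levels, factor_effects = {}, {}
    for name, n_levels, sd in trait.fixed_effects:
        factor_levels[name] = rng.integers(1, n_levels + 1, n)
        factor_effects[name] = rng.normal(0.0, sd, n_levels)

    trait_map = dict(trait.population_trait_map or {})
    rows = []
    t_points = np.arange(1, trait.n_time_points + 1)
    for t in t_points:
        resid = rng.normal(0.0, np.sqrt(res_var), n) if res_var > 0 else np.zeros(n)
        latent = g_total + pe + resid
        for name in factor_levels:
            latent = latent + factor_effects[name][factor_levels[name] - 1]
        if trait.count_model == "lognormal":
            value = np.exp(trait.log_mean + latent)
        else:
            mean = np.exp(trait.log_mean + latent)
            k = trait.overdispersion
            value = rng.negative_binomial(k, k / (k + mean)).astype(float)
        for i in range(n):
            rows.append((panel.animal_ids[i], pops[i], t,
                         trait_map.get(pops[i], "trait"), value[i],
                         *(factor_levels[nm][i] for nm in factor_levels)))

    cols = ["animal_id", "population", "time_point", "trait", "value",
            *factor_levels.keys()]
    records = pd.DataFrame(rows, columns=cols)

    truth = {
        "genetic_value": pd.Series(g_total, index=panel.animal_ids),
        "animal_effect": pd.Series(g_total + pe, index=panel.animal_ids),
        "regional_values": [pd.Series(g, index=panel.animal_ids) for g in g_regions],
        "causal_snps": [panel.snps["snp"].to_numpy()[idx] for idx in causal_global],
        "variance_fractions": {
            "polygenic_h2": trait.polygenic_h2,
            "regional_h2": [q.target_regional_h2 for q in qtls],
            "permanent_env": pe_var,
            "residual": res_var,
        },
    }
    return records, truth


# ---------------------------------------------------------------------------
# study-scale convenience
# ---------------------------------------------------------------------------

def default_designs(sizes=(400, 600, 500), divergence=0.15) -> list[PopulationDesign]:
    """Three-population desk-scale analogue of the study structure: a
    10-sire double backcross, a larger many-sire backcross, and a 4-sire
    backcross whose long haplotypes make within-family LD blocks long."""
    return [
        PopulationDesign("POP1", "double_backcross", 10, sizes[0],
                         founder_freq_divergence=divergence),
        PopulationDesign("POP2", "backcross", 20, sizes[1],
                         founder_freq_divergence=divergence),
        PopulationDesign("POP3", "backcross", 4, sizes[2],
                         founder_freq_divergence=divergence),
    ]


def default_map(n_chromosomes=6, snps_per_chrom=300, length_cm=100.0) -> GenomeMap:
    return GenomeMap([(c, snps_per_chrom, length_cm)
                      for c in range(1, n_chromosomes + 1)])


def simulate_study(seed: int, designs: Sequence[PopulationDesign] | None = None,
                   gmap: GenomeMap | None = None,
                   qtls: Sequence[QTLSpec] = (),
                   trait: TraitModel | None = None):
    """Simulate a full multi-population study: combined panel, records, truth."""
    designs = list(designs) if designs is not None else default_designs()
    gmap = gmap or default_map()
    trait = trait or TraitModel()
    children = np.random.SeedSequence(seed).spawn(2 * len(designs) + 2)

    def _child_seed(i: int) -> int:
        return int(children[i].generate_state(1)[0] % (2**31))

    base_rng = np.random.default_rng(_child_seed(0))
    base_freqs = base_rng.uniform(0.1, 0.9, gmap.n_snps)
    panels = []
    for k, design in enumerate(designs):
        founders = simulate_founders(design, gmap, base_freqs, _child_seed(2 * k + 1))
        panels.append(simulate_cross(founders, design, gmap, _child_seed(2 * k + 2)))
    panel = concat_panels(panels)
    records, truth = simulate_phenotypes(panel, qtls, trait, _child_seed(-1))
    return panel, records, truth


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(panels: Sequence[GenotypePanel], records: pd.DataFrame,
                  out_dir, truth=None, binary: bool = False) -> dict:
    """Write per-population PLINK files plus phenotype / label / truth tables.

    Returns a dict of written paths. Round-trips losslessly through
    :mod:`rhmscan.io` (see the allele-coding note there).
    """
    from . import io as _io
    from pathlib import Path

    panels = list(panels)
    if not panels:
        raise ValueError("no panels to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"genotypes": []}
    labels = []
    for p in panels:
        pop = p.populations[0]
        prefix = out / str(pop)
        if binary:
            _io.write_bed_bim_fam(p, prefix)
        else:
            _io.write_ped_map(p, prefix)
        paths["genotypes"].append(prefix)
        labels.append(pd.DataFrame({"animal_id": p.animal_ids,
                                    "population": p.populations}))
    label_path = out / "populations.tsv"
    pd.concat(labels).to_csv(label_path, sep="\t", index=False)
    paths["labels"] = label_path
    pheno_path = out / "phenotypes.tsv"
    records.to_csv(pheno_path, sep="\t", index=False)
    paths["phenotypes"] = pheno_path
    if truth is not None:
        ledger = pd.DataFrame({
            "animal_id": truth["genetic_value"].index,
            "genetic_value": truth["genetic_value"].to_numpy(),
            "animal_effect": truth["animal_effect"].to_numpy(),
        })
        truth_path = out / "true_values.tsv"
        ledger.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
    return paths
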