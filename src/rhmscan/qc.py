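"""Genotype quality control and multi-population SNP-set intersection.

Filters run in a fixed order — chromosome exclusion, per-population SNP
missingness, per-population MAF, animal missingness — and a SNP must pass in
every population (the strictest reading of populations being QC'd separately
before their marker sets are intersected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel


class EmptyPanelError(ValueError):
    """All SNPs (or all animals) were removed."""


@dataclass(frozen=True)
class QCConfig:
    min_maf: float = 0.01
    max_snp_missing: float = 0.05
    max_animal_missing: float = 0.10
    exclude_chroms: tuple = ()

    def __post_init__(self):
        for name in ("min_maf", "max_snp_missing", "max_animal_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        object.__setattr__(self, "exclude_chroms", tuple(self.exclude_chroms))


def apply_qc(panel: GenotypePanel, cfg: QCConfig) -> tuple[GenotypePanel, pd.DataFrame]:
    """Filter SNPs and animals; returns the filtered panel and a removal report."""
    report_rows = []
    n_snps0 = panel.n_snps

    # 1. chromosome exclusion
    if cfg.exclude_chroms:
        keep = ~panel.snps["chrom"].isin(cfg.exclude_chroms).to_numpy()
        report_rows.append(("excluded_chromosome", int((~keep).sum())))
        panel = panel.subset_snps(np.flatnonzero(keep))
    else:
        report_rows.append(("excluded_chromosome", 0))

    pops = panel.population_indices()

    # 2. per-population SNP missingness
    if panel.n_snps:
        miss_fail = np.zeros(panel.n_snps, dtype=bool)
        for rows in pops.values():
            rate = np.isnan(panel.dosages[rows]).mean(axis=0)
            miss_fail |= rate > cfg.max_snp_missing
        report_rows.append(("snp_missingness", int(miss_fail.sum())))
        panel = panel.subset_snps(np.flatnonzero(~miss_fail))
    else:
        report_rows.append(("snp_missingness", 0))

    # 3. per-population MAF
    if panel.n_snps:
        maf_fail = np.zeros(panel.n_snps, dtype=bool)
        if cfg.min_maf > 0:
            for rows in pops.values():
                p = panel.allele_freqs(rows=rows)
                maf = np.minimum(p, 1.0 - p)
                # NaN (all-missing within a population) also fails
                maf_fail |= ~(maf >= cfg.min_maf)
        report_rows.append(("maf", int(maf_fail.sum())))
        panel = panel.subset_snps(np.flatnonzero(~maf_fail))
    else:
        report_rows.append(("maf", 0))

    if panel.n_snps == 0 and n_snps0 > 0:
        raise EmptyPanelError("quality control removed every SNP")

    # 4. animal missingness
    rate = np.isnan(panel.dosages).mean(axis=1) if panel.n_snps else np.zeros(panel.n_animals)
    keep_animals = rate <= cfg.max_animal_missing
    report_rows.append(("animal_missingness", int((~keep_animals).sum())))
    if not keep_animals.any():
        raise EmptyPanelError("quality control removed every animal")
    if not keep_animals.all():
        panel = panel.subset_animals(np.flatnonzero(keep_animals))

    report = pd.DataFrame(report_rows, columns=["criterion", "removed"])
    return panel, report


def intersect_snps(panels: list[GenotypePanel]) -> GenotypePanel:
    """Keep SNPs common to every panel and concatenate the animals.

    The combined map is ordered by (chromosome, bp); population labels are
    preserved. Animal id sets must be disjoint.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to intersect")
    all_ids = np.concatenate([p.animal_ids for p in panels])
    if len(np.unique(all_ids)) != len(all_ids):
        raise ValueError("panels share animal ids; they must be disjoint")
    common = set(panels[0].snps["snp"])
    for p in panels[1:]:
        common &= set(p.snps["snp"])
    if not common:
        raise ValueError("no SNPs are common to all panels")
    base = panels[0].snps[panels[0].snps["snp"].isin(common)]
    base = base.sort_values(["chrom", "bp"], kind="stable")
    order_ids = base["snp"].tolist()

    blocks, pops, ids, sires = [], [], [], []
    have_sires = all(p.sires is not None for p in panels)
    for p in panels:
        pos = pd.Series(np.arange(p.n_snps), index=p.snps["snp"])
        cols = pos.loc[order_ids].to_numpy()
        blocks.append(p.dosages[:, cols])
        pops.append(p.populations)
        ids.append(p.animal_ids)
        if have_sires:
            sires.append(p.sires)
    return GenotypePanel(
        dosages=np.vstack(blocks),
        animal_ids=np.concatenate(ids),
        populations=np.concatenate(pops),
        snps=base.reset_index(drop=True),
        sires=np.concatenate(sires) if have_sires else None,
    )
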