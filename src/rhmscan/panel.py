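"""Genotype panel container shared by QC, kernel and scan stages.

A :class:`GenotypePanel` holds an animals x SNPs dosage matrix coded as
alternate-allele counts (0/1/2) with ``numpy.nan`` for missing calls, the SNP
map (id, chromosome, 1-based bp position), one population label per animal and
optionally the sire of each animal (recorded by the simulator so family
structure can be checked).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MAP_COLUMNS = ("snp", "chrom", "bp")


@dataclass
class GenotypePanel:
    dosages: np.ndarray
    animal_ids: np.ndarray
    populations: np.ndarray
    snps: pd.DataFrame
    sires: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.sires is not None:
            self.sires = np.asarray(self.sires, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match dosage rows")
        if len(self.populations) != n:
            raise ValueError("populations length does not match dosage rows")
        if self.sires is not None and len(self.sires) != n:
            raise ValueError("sires length does not match dosage rows")
        if len(np.unique(self.animal_ids)) != n:
            raise ValueError("animal ids must be unique")
        for col in MAP_COLUMNS:
            if col not in self.snps.columns:
                raise ValueError(f"SNP map is missing column {col!r}")
        if len(self.snps) != m:
            raise ValueError("SNP map length does not match dosage columns")
        if self.snps["snp"].duplicated().any():
            dup = self.snps["snp"][self.snps["snp"].duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (nan)")
        self.snps = self.snps.reset_index(drop=True)

    # -- basic shape ---------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.snps["chrom"]))

    def population_indices(self) -> dict:
        """Row indices per population label, in first-appearance order."""
        out: dict = {}
        for i, pop in enumerate(self.populations):
            out.setdefault(pop, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    # -- frequencies ---------------------------------------------------------
    def allele_freqs(self, rows: np.ndarray | None = None,
                     cols: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per SNP over the given animal rows."""
        d = self.dosages
        if rows is not None:
            d = d[rows]
        if cols is not None:
            d = d[:, cols]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(d, axis=0) / 2.0
        return p

    # -- subsetting ----------------------------------------------------------
    def subset_snps(self, cols: np.ndarray) -> "GenotypePanel":
        cols = np.asarray(cols)
        return replace(
            self,
            dosages=self.dosages[:, cols],
            snps=self.snps.iloc[cols].reset_index(drop=True),
        )

    def subset_animals(self, rows: np.ndarray) -> "GenotypePanel":
        rows = np.asarray(rows)
        return replace(
            self,
            dosages=self.dosages[rows],
            animal_ids=self.animal_ids[rows],
            populations=self.populations[rows],
            sires=None if self.sires is None else self.sires[rows],
        )

    def chrom_snp_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())


def concat_panels(panels: Iterable[GenotypePanel]) -> GenotypePanel:
    """Stack panels that share an identical SNP map (animals concatenated)."""
    panels = list(panels)
    first = panels[0]
    for p in panels[1:]:
        if not first.snps[list(MAP_COLUMNS)].equals(p.snps[list(MAP_COLUMNS)]):
            raise ValueError("panels do not share the same SNP map")
    sires = None
    if all(p.sires is not None for p in panels):
        sires = np.concatenate([p.sires for p in panels])
    return GenotypePanel(
        dosages=np.vstack([p.dosages for p in panels]),
        animal_ids=np.concatenate([p.animal_ids for p in panels]),
        populations=np.concatenate([p.populations for p in panels]),
        snps=first.snps.copy(),
        sires=sires,
    )
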