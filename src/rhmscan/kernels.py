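"""Genomic relationship matrices and sliding SNP windows.

The GRM follows the classic first VanRaden construction: dosages centered by
twice the allele frequency and cross-products divided by ``2 * sum p (1 - p)``
over the SNPs used. Two frequency scopes are supported:

``per_population`` (default)
    Frequencies, mean imputation of missing dosages, centering and the
    denominator are all computed within each population; the resulting kernel
    is block diagonal by construction (cross-population entries exactly zero)
    with one recorded denominator per population. This removes the relationship
    structure that cross-population allele-frequency differences would
    otherwise create — the structure the block-diagonal assumption is meant to
    exclude.

``pooled``
    Classic single-scope VanRaden with a scalar denominator; combine with
    :func:`block_diagonalize` to zero cross-population entries.

Leave-one-chromosome-out (LOCO) kernels drop every SNP on the interrogated
chromosome and recompute the denominator over the remainder, so the polygenic
term cannot absorb the tested region's signal. Windows are defined on SNP
indexes (100 SNPs, shifted by 50 by default) and never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class Kernel:
    matrix: np.ndarray
    animal_ids: np.ndarray
    provenance: str           # "whole", "loco(<chrom>)", "region(<chrom>:<idx>)"
    n_snps: int
    block_diagonal: bool
    denominator: float | dict  # scalar (pooled) or {population: value}


@dataclass(frozen=True)
class Window:
    """A SNP-index window on one chromosome (global half-open span on the
    combined map; ``index`` is 1-based within the chromosome)."""

    chrom: object
    index: int
    start: int
    stop: int
    first_snp: str
    last_snp: str
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.stop - self.start


def _impute_center(block: np.ndarray, p: np.ndarray) -> np.ndarray:
    centered = block - 2.0 * p
    return np.where(np.isnan(block), 0.0, centered)  # missing -> population mean


def compute_grm(panel: GenotypePanel, snp_indices=None,
                freq_scope: str = "per_population", freqs=None,
                provenance: str = "whole") -> Kernel:
    """VanRaden GRM over a SNP subset (all SNPs when ``snp_indices`` is None).

    ``freqs`` overrides the allele frequencies (pooled scope only), which is
    useful for worked examples and oracle tests.
    """
    if snp_indices is None:
        snp_indices = np.arange(panel.n_snps)
    snp_indices = np.asarray(snp_indices)
    if snp_indices.size == 0:
        raise ValueError("SNP subset is empty")
    D = panel.dosages[:, snp_indices]
    n = panel.n_animals

    if freq_scope == "pooled" or freqs is not None:
        p = (np.asarray(freqs, dtype=float) if freqs is not None
             else panel.allele_freqs(cols=snp_indices))
        denom = float(2.0 * np.sum(p * (1.0 - p)))
        if denom <= 0:
            raise ValueError("all SNPs in the subset are monomorphic")
        # imputation stays within population even under pooled centering
        C = np.empty_like(D)
        for rows in panel.population_indices().values():
            with np.errstate(invalid="ignore"):
                pop_mean = np.nanmean(D[rows], axis=0)
            pop_mean = np.where(np.isnan(pop_mean), 2.0 * p, pop_mean)
            filled = np.where(np.isnan(D[rows]), pop_mean, D[rows])
            C[rows] = filled - 2.0 * p
        G = (C @ C.T) / denom
        return Kernel(matrix=G, animal_ids=panel.animal_ids.copy(),
                      provenance=provenance, n_snps=len(snp_indices),
                      block_diagonal=False, denominator=denom)

    if freq_scope != "per_population":
        raise ValueError(f"unknown freq_scope {freq_scope!r}")

    G = np.zeros((n, n))
    denoms: dict = {}
    pops = panel.population_indices()
    for pop, rows in pops.items():
        block = D[rows]
        with np.errstate(invalid="ignore"):
            p = np.nanmean(block, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.0, p)
        d = float(2.0 * np.sum(p * (1.0 - p)))
        if d <= 0:
            raise ValueError(
                f"all SNPs in the subset are monomorphic in population {pop!r}")
        C = _impute_center(block, p)
        G[np.ix_(rows, rows)] = (C @ C.T) / d
        denoms[pop] = d
    return Kernel(matrix=G, animal_ids=panel.animal_ids.copy(),
                  provenance=provenance, n_snps=len(snp_indices),
                  block_diagonal=True, denominator=denoms)


def block_diagonalize(kernel: Kernel, populations) -> Kernel:
    """Zero every entry between animals of different populations."""
    populations = np.asarray(populations)
    if len(populations) != len(kernel.animal_ids):
        raise ValueError("labels must cover all animals in the kernel")
    mask = populations[:, None] == populations[None, :]
    return Kernel(matrix=np.where(mask, kernel.matrix, 0.0),
                  animal_ids=kernel.animal_ids.copy(),
                  provenance=kernel.provenance, n_snps=kernel.n_snps,
                  block_diagonal=True, denominator=kernel.denominator)


def loco_kernel(panel: GenotypePanel, exclude_chrom,
                freq_scope: str = "per_population") -> Kernel:
    """GRM from all SNPs not on ``exclude_chrom`` ('n-1' kernel)."""
    chroms = panel.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO kernel needs a panel with at least 2 chromosomes")
    if exclude_chrom not in chroms:
        raise ValueError(f"chromosome {exclude_chrom!r} not in panel")
    keep = np.flatnonzero((panel.snps["chrom"] != exclude_chrom).to_numpy())
    return compute_grm(panel, snp_indices=keep, freq_scope=freq_scope,
                       provenance=f"loco({exclude_chrom})")


def make_windows(snps: pd.DataFrame, window_size: int = 100,
                 step: int = 50) -> list[Window]:
    """Sliding SNP-index windows per chromosome.

    Starts at indexes 0, step, 2*step, ...; each window takes
    ``min(window_size, remaining)`` SNPs; a candidate start is emitted only if
    it covers at least one SNP beyond the previous window. Windows never span
    chromosomes.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if step > window_size:
        raise ValueError("step must be <= window_size")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(snps) == 0:
        raise ValueError("empty SNP map")
    windows: list[Window] = []
    offset = 0
    for chrom in pd.unique(snps["chrom"]):
        sub = snps[snps["chrom"] == chrom]
        n = len(sub)
        prev_stop = 0
        index = 0
        for start in range(0, n, step):
            stop = min(start + window_size, n)
            if stop <= prev_stop:
                break
            index += 1
            windows.append(Window(
                chrom=chrom, index=index,
                start=offset + start, stop=offset + stop,
                first_snp=str(sub["snp"].iloc[start]),
                last_snp=str(sub["snp"].iloc[stop - 1]),
                start_bp=int(sub["bp"].iloc[start]),
                end_bp=int(sub["bp"].iloc[stop - 1]),
            ))
            prev_stop = stop
        offset += n
    return windows


def regional_kernel(panel: GenotypePanel, window: Window,
                    freq_scope: str = "per_population") -> Kernel:
    """GRM over one window's SNPs; block diagonal under the default scope."""
    idx = np.arange(window.start, window.stop)
    return compute_grm(panel, snp_indices=idx, freq_scope=freq_scope,
                       provenance=f"region({window.chrom}:{window.index})")


def windows_table(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.index, w.first_snp, w.last_snp, w.start_bp, w.end_bp, w.n_snps)
         for w in windows],
        columns=["chrom", "window", "first_snp", "last_snp",
                 "start_bp", "end_bp", "n_snps"])
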