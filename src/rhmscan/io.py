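"""Reading and writing PLINK genotype files and the pipeline's text tables.

Supported formats: PLINK text (.ped/.map), PLINK binary (.bed/.bim/.fam,
SNP-major), two-column population label files, tab-separated phenotype tables,
and GRM export both as plain text and in the GCTA packed lower-triangle binary
layout (.grm.bin / .grm.id).

Allele coding: dosages count alternate alleles. The writer emits Illumina-style
A/B calls (``A`` reference, ``B`` alternate), which the reader recognizes: when
a SNP's alleles are a subset of {A, B} the B allele is counted, so round trips
are exact even for monomorphic SNPs. For other letters (ACGT data) PLINK text
carries no ref/alt designation and the reader takes the lexicographically last
observed allele as the alternate; a SNP with a single observed non-A/B allele
is treated as monomorphic reference. The binary path is always unambiguous
because .bim records A1 (alternate) and A2 explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# text PLINK
# ---------------------------------------------------------------------------

def write_ped_map(panel: GenotypePanel, prefix) -> None:
    prefix = Path(prefix)
    gmap = panel.snps
    with open(f"{prefix}.map", "w") as fh:
        for _, row in gmap.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['bp']}\n")
    allele_pairs = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(panel.n_animals):
            fields = [str(panel.populations[i]), str(panel.animal_ids[i]),
                      "0", "0", "0", "-9"]
            for d in panel.dosages[i]:
                fields.append(allele_pairs.get(d, "0 0") if not np.isnan(d) else "0 0")
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    snps = _read_map(f"{prefix}.map")
    m = len(snps)
    ids, pops, rows = [], [], []
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}")
            pops.append(parts[0])
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(rows), m, 2)
    dosages = np.full((len(rows), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if not observed:
            continue
        missing = (col == "0").any(axis=1)
        if set(observed) <= {"A", "B"}:
            alt = "B"  # Illumina A/B coding: B is the alternate allele
        elif len(observed) > 1:
            alt = observed[-1]
        else:
            alt = None  # monomorphic, unknown phase: treat as reference
        if alt is None:
            dosages[:, j] = 0.0
        else:
            dosages[:, j] = (col == alt).sum(axis=1).astype(float)
        dosages[missing, j] = np.nan
    panel = GenotypePanel(dosages=dosages, animal_ids=np.array(ids, dtype=object),
                          populations=np.array(pops, dtype=object), snps=snps)
    return _sort_map(panel)


def _read_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise ParseError(f"{path} line {lineno}: expected 3 or 4 fields")
            chrom, snp = parts[0], parts[1]
            bp = int(parts[-1])
            rows.append((snp, _maybe_int(chrom), bp))
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "bp"])
    if snps["snp"].duplicated().any():
        dup = snps["snp"][snps["snp"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate SNP id {dup!r}")
    return snps


def _maybe_int(x):
    try:
        return int(x)
    except (TypeError, ValueError):
        return x


def _sort_map(panel: GenotypePanel) -> GenotypePanel:
    order = panel.snps.sort_values(["chrom", "bp"], kind="stable").index.to_numpy()
    if np.array_equal(order, np.arange(panel.n_snps)):
        return panel
    return panel.subset_snps(order)


# ---------------------------------------------------------------------------
# binary PLINK
# ---------------------------------------------------------------------------

def write_bed_bim_fam(panel: GenotypePanel, prefix) -> None:
    prefix = Path(prefix)
    with open(f"{prefix}.bim", "w") as fh:
        for _, row in panel.snps.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['bp']}\tB\tA\n")
    with open(f"{prefix}.fam", "w") as fh:
        for i in range(panel.n_animals):
            fh.write(f"{panel.populations[i]} {panel.animal_ids[i]} 0 0 0 -9\n")
    n = panel.n_animals
    # 2-bit codes per sample with A1 = alternate: 00 hom A1 (dosage 2),
    # 01 missing, 10 het, 11 hom A2 (dosage 0)
    code = np.empty((panel.n_snps, n), dtype=np.uint8)
    d = panel.dosages.T
    code[np.isnan(d)] = 0b01
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    n_bytes = (n + 3) // 4
    packed = np.zeros((panel.n_snps, n_bytes), dtype=np.uint8)
    for k in range(4):
        chunk = code[:, k::4]
        packed[:, :chunk.shape[1]] |= chunk << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed_bim_fam(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cM", "bp", "a1", "a2"])
    snps = pd.DataFrame({"snp": bim["snp"].astype(str),
                         "chrom": bim["chrom"].map(_maybe_int),
                         "bp": bim["bp"].astype(int)})
    if snps["snp"].duplicated().any():
        dup = snps["snp"][snps["snp"].duplicated()].iloc[0]
        raise ParseError(f"{prefix}.bim: duplicate SNP id {dup!r}")
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "pheno"],
                      dtype=str)
    n, m = len(fam), len(snps)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes (expected SNP-major bed)")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    dosages = np.empty((n, m))
    lookup = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11 with A1 = alt
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = lookup[codes[:, :n]].T
    panel = GenotypePanel(dosages=dosages,
                          animal_ids=fam["iid"].to_numpy(dtype=object),
                          populations=fam["fid"].to_numpy(dtype=object),
                          snps=snps)
    return _sort_map(panel)


# ---------------------------------------------------------------------------
# high-level panel reading
# ---------------------------------------------------------------------------

def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"animal_id", "population"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns animal_id, population")
    return df.set_index("animal_id")["population"]


def read_panel(prefix, label_file=None) -> GenotypePanel:
    """Read one panel from PLINK text or binary files at ``prefix``.

    Picks .bed/.bim/.fam when present, otherwise .ped/.map. Population labels
    come from ``label_file`` when given, else from the PLINK family id column.
    """
    prefix = Path(prefix)
    if prefix.with_suffix(prefix.suffix + ".bed").exists() or Path(f"{prefix}.bed").exists():
        panel = read_bed_bim_fam(prefix)
    elif Path(f"{prefix}.ped").exists():
        panel = read_ped_map(prefix)
    else:
        raise FileNotFoundError(f"no .bed or .ped file found at prefix {prefix}")
    if label_file is not None:
        labels = read_labels(label_file)
        missing = [a for a in panel.animal_ids if a not in labels.index]
        if missing:
            raise ParseError(f"label file lacks {len(missing)} animals, "
                             f"first missing: {missing[0]!r}")
        panel.populations = labels.loc[list(panel.animal_ids)].to_numpy(dtype=object)
    return panel


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "population", "time_point", "trait", "value"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: phenotype table needs columns {sorted(required)}")
    return df


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# kernel export
# ---------------------------------------------------------------------------

def write_kernel_text(kernel, path) -> None:
    """Symmetric matrix as TSV with animal ids as header and index."""
    pd.DataFrame(kernel.matrix, index=kernel.animal_ids,
                 columns=kernel.animal_ids).to_csv(path, sep="\t")


def write_kernel_gcta(kernel, prefix) -> None:
    """GCTA-style packed storage: .grm.bin (float32 lower triangle including
    the diagonal, row by row), .grm.id (FID IID), .grm.N.bin (SNP count)."""
    prefix = Path(prefix)
    n = len(kernel.animal_ids)
    tri = kernel.matrix[np.tril_indices(n)]
    tri.astype(np.float32).tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, kernel.n_snps, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for aid in kernel.animal_ids:
            fh.write(f"0\t{aid}\n")


def read_kernel_gcta(prefix):
    from .kernels import Kernel
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy(dtype=object)
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype=np.float32).astype(float)
    mat = np.zeros((n, n))
    mat[np.tril_indices(n)] = tri
    mat = mat + np.tril(mat, -1).T
    nbin = Path(f"{prefix}.grm.N.bin")
    n_snps = int(np.fromfile(nbin, dtype=np.float32)[0]) if nbin.exists() else 0
    return Kernel(matrix=mat, animal_ids=ids, provenance="imported",
                  n_snps=n_snps, block_diagonal=False, denominator=float("nan"))
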