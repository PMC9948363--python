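"""Readers, writers and domain containers for the pseudo-bulk eQTL pipeline.

Supported on-disk formats: Matrix Market (MTX triplet with features/barcodes
TSVs) or dense TSV for cell x gene counts; VCF (GT or DS) or a dosage TSV for
genotypes; TSV for covariates, gene annotation and every tabular result.

No scientific computation lives here. MTX indices are 1-based on disk per the
Matrix Market standard and 0-based in memory; the conversion happens only at
this boundary (scipy handles it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("pseudofactor")
if not logger.handlers:  # library default: info to stderr, no double handlers
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Cell x gene non-negative counts with per-cell individual and cell-type labels."""

    counts: sp.csr_matrix  # cells x genes
    cell_ids: np.ndarray  # str, unique
    gene_ids: np.ndarray  # str, unique
    cell_to_individual: np.ndarray  # str per cell
    cell_type: np.ndarray  # str per cell

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_to_individual = np.asarray(self.cell_to_individual, dtype=str)
        self.cell_type = np.asarray(self.cell_type, dtype=str)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValidationError("id vectors do not match counts shape")
        if len(np.unique(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if len(np.unique(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(self.cell_to_individual) != n_cells or len(self.cell_type) != n_cells:
            raise ValidationError("per-cell metadata length mismatch")
        data = self.counts.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            bad = np.flatnonzero(~np.isfinite(data) | (data < 0))[:5]
            raise ValidationError(f"counts must be finite and >= 0 (offending data indices: {bad.tolist()})")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def individuals(self) -> np.ndarray:
        """Unique individual ids in first-appearance order."""
        _, idx = np.unique(self.cell_to_individual, return_index=True)
        return self.cell_to_individual[np.sort(idx)]


@dataclass
class GenotypeMatrix:
    """Individual x SNP ALT-allele dosages in [0, 2] with SNP coordinates (1-based)."""

    dosages: np.ndarray  # individuals x snps, float
    individual_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray  # str per snp
    pos: np.ndarray  # int per snp, 1-based

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=str)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n_ind, n_snp = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValidationError("individual_ids length mismatch")
        if len(np.unique(self.individual_ids)) != n_ind:
            raise ValidationError("duplicate individual ids")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == n_snp):
            raise ValidationError("per-SNP metadata length mismatch")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValidationError("dosages outside [0, 2]")
        if self.pos.size and self.pos.min() < 1:
            raise ValidationError("positions must be positive (1-based)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP: min(f, 1-f) with f = mean(dosage)/2."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        order = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([order[i] for i in ids], dtype=int)
        return GenotypeMatrix(self.dosages[idx], np.asarray(ids), self.snp_ids, self.chrom, self.pos)


@dataclass
class CovariateTable:
    """Known per-individual covariates (sex, age, genotype PCs, ...), one row each."""

    table: pd.DataFrame  # index = individual id, numeric columns

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate individual ids in covariates")
        if self.table.isna().any().any():
            bad = self.table.columns[self.table.isna().any()].tolist()
            raise ValidationError(f"missing covariate values in columns {bad}; imputation is not supported")
        non_num = [c for c in self.table.columns if not np.issubdtype(self.table[c].dtype, np.number)]
        if non_num:
            raise ValidationError(f"non-numeric covariate columns: {non_num}")

    @property
    def individual_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=str)

    def subset_individuals(self, ids: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.table.loc[list(ids)].copy())

    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class GeneAnnotation:
    """Gene coordinates: chrom, 1-based inclusive start/end, optional strand."""

    table: pd.DataFrame  # index = gene_id; columns chrom, start, end [, strand]

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.table.columns):
            raise ValidationError(f"gene annotation needs columns {sorted(need)}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene ids in annotation")
        if (self.table["start"] > self.table["end"]).any():
            raise ValidationError("gene start > end")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=str)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_cell_matrix(path: str | Path, metadata_path: str | Path) -> CellMatrix:
    """Read a cell x gene count matrix plus cell metadata.

    ``path`` is either a directory holding an MTX triplet (``matrix.mtx``,
    ``features.tsv``, ``barcodes.tsv``) or a dense TSV with cells as rows
    (first column = cell id, remaining columns = genes). ``metadata_path`` is a
    TSV with columns cell_id, individual_id, cell_type. Cells absent from the
    metadata are dropped with a logged count.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        bars = path / "barcodes.tsv"
        for f in (mtx, feats, bars):
            if not f.exists():
                raise FileNotFoundError(f"missing {f}")
        counts = sp.csr_matrix(scipy.io.mmread(mtx)).T  # stored genes x cells (10x layout)
        gene_ids = pd.read_csv(feats, sep="\t", header=None)[0].to_numpy(dtype=str)
        cell_ids = pd.read_csv(bars, sep="\t", header=None)[0].to_numpy(dtype=str)
    else:
        if not path.exists():
            raise FileNotFoundError(f"missing {path}")
        dense = pd.read_csv(path, sep="\t", index_col=0)
        counts = sp.csr_matrix(dense.to_numpy(dtype=float))
        cell_ids = dense.index.to_numpy(dtype=str)
        gene_ids = dense.columns.to_numpy(dtype=str)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    need = {"cell_id", "individual_id", "cell_type"}
    if not need.issubset(meta.columns):
        raise ValidationError(f"cell metadata needs columns {sorted(need)}")
    meta = meta.set_index("cell_id")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate cell ids in metadata")

    keep = np.array([c in meta.index for c in cell_ids])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d cells absent from metadata", n_drop)
    cell_ids = cell_ids[keep]
    counts = sp.csr_matrix(counts)[keep]
    meta = meta.loc[cell_ids]
    return CellMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_to_individual=meta["individual_id"].to_numpy(dtype=str),
        cell_type=meta["cell_type"].to_numpy(dtype=str),
    )


def write_cell_matrix(cm: CellMatrix, out_dir: str | Path) -> None:
    """Write a CellMatrix as an MTX triplet plus a cell-metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(cm.counts.T))  # genes x cells on disk
    pd.Series(cm.gene_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame(
        {"cell_id": cm.cell_ids, "individual_id": cm.cell_to_individual, "cell_type": cm.cell_type}
    ).to_csv(out / "cell_metadata.tsv", sep="\t", index=False)


def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    The dosage TSV has columns snp_id, chrom, pos followed by one column per
    individual. VCF GT fields are converted to ALT-allele counts; multiallelic
    sites are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing {path}")
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz") else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"snp_id", "chrom", "pos"}
        if not need.issubset(df.columns):
            raise ValidationError(f"dosage TSV needs columns {sorted(need)}")
        ind_cols = [c for c in df.columns if c not in need]
        dos = df[ind_cols].to_numpy(dtype=float).T
        return GenotypeMatrix(
            dosages=dos,
            individual_ids=np.asarray(ind_cols, dtype=str),
            snp_ids=df["snp_id"].to_numpy(dtype=str),
            chrom=df["chrom"].to_numpy(dtype=str),
            pos=df["pos"].to_numpy(dtype=np.int64),
        )
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=str)
    snp_ids, chroms, poss, rows = [], [], [], []
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        fmts = var.FORMAT
        if "DS" in fmts:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        elif "GT" in fmts or var.gt_types is not None:
            gts = np.asarray(var.genotype.array())[:, :2]
            if (gts < 0).any():
                raise ValidationError(f"missing genotype at VCF record {i + 1} ({var.CHROM}:{var.POS})")
            ds = gts.sum(axis=1).astype(float)
        else:
            raise ValidationError(f"VCF record {i + 1} has neither GT nor DS")
        if ds.min() < 0 or ds.max() > 2:
            raise ValidationError(f"dosage outside [0,2] at VCF record {i + 1}")
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(ds)
    if n_multi:
        logger.warning("skipped %d multiallelic VCF records", n_multi)
    dos = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dos, samples, np.asarray(snp_ids), np.asarray(chroms), np.asarray(poss))


def write_genotypes_tsv(gt: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gt.dosages.T, columns=gt.individual_ids)
    df.insert(0, "snp_id", gt.snp_ids)
    df.insert(1, "chrom", gt.chrom)
    df.insert(2, "pos", gt.pos)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(gt: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call dosages as a minimal VCF v4.2 with GT fields.

    Non-integer dosages are not representable as GT and raise an error.
    """
    dos = gt.dosages
    if not np.allclose(dos, np.round(dos)):
        raise ValidationError("non-integer dosages cannot be written as GT; use write_genotypes_tsv")
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gt.individual_ids) + "\n")
        order = np.lexsort((gt.pos, gt.chrom))
        for j in order:
            calls = "\t".join(gt_codes[int(round(d))] for d in dos[:, j])
            fh.write(f"{gt.chrom[j]}\t{gt.pos[j]}\t{gt.snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_covariates(path: str | Path) -> CovariateTable:
    """Read a covariate TSV: first column individual_id, remaining numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CovariateTable(df)


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation TSV: gene_id, chrom, start, end [, strand]."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    df.index = df.index.astype(str)
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# Result writing and individual intersection
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write any tabular result to TSV: full float precision, deterministic order.

    Rows are sorted by ``sort_by`` (defaults to all non-float columns, i.e. the
    primary key) so that re-runs are byte-identical.
    """
    df = table.copy()
    if sort_by is None:
        sort_by = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.floating)]
    if sort_by and len(df):
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def intersect_individuals(
    expression_ids: Sequence[str],
    gt: GenotypeMatrix | None = None,
    cov: CovariateTable | None = None,
) -> np.ndarray:
    """Individuals present in every provided input, in expression order.

    Logs how many are dropped from each source.
    """
    keep = list(dict.fromkeys(str(i) for i in expression_ids))
    sources: list[tuple[str, set[str]]] = []
    if gt is not None:
        sources.append(("genotypes", set(gt.individual_ids)))
    if cov is not None:
        sources.append(("covariates", set(cov.individual_ids)))
    shared = [i for i in keep if all(i in s for _, s in sources)]
    for name, s in sources:
        n_extra = len(s - set(shared))
        if n_extra:
            logger.info("individual intersection drops %d from %s", n_extra, name)
    n_expr_drop = len(keep) - len(shared)
    if n_expr_drop:
        logger.info("individual intersection drops %d from expression", n_expr_drop)
    if not shared:
        raise ValidationError("no individuals shared across inputs")
    return np.asarray(shared, dtype=str)
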