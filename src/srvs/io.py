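"""Reading, merging and normalizing the genotype / expression / phenotype inputs.

The analysis-ready object is an :class:`OmicsMatrix`: subjects x variables,
expression block first then SNP block, with per-column metadata (variable
id, source type, optional gene symbol / chromosome). Columns are
mean-centered and scaled to unit L2 norm before sparse selection; constant
columns become all-zero and are flagged rather than raising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix", "PhenotypeTable",
    "read_genotypes", "read_expression", "read_phenotypes",
    "merge_and_filter", "normalize_columns",
    "matrix_from_frame",
    "write_omics_matrix", "read_omics_matrix", "write_ranking_tsv",
]

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("SBP", "DBP", "AGE", "SEX", "MS", "SS")


@dataclass
class OmicsMatrix:
    """Subjects x variables design matrix with per-column provenance.

    ``columns`` is a DataFrame with at least ``variable_id`` and ``source``
    (``"SNP"`` or ``"expression"``); ``gene_symbol`` and ``chromosome`` are
    optional annotation. After :func:`normalize_columns`, every non-constant
    column has unit L2 norm and ``normalized`` is set.
    """

    values: np.ndarray
    subject_ids: list[str]
    columns: pd.DataFrame
    normalized: bool = False
    constant_columns: np.ndarray = field(default=None)  # bool mask, set on normalize

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x variables)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count does not match metadata length")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variable_ids(self) -> list[str]:
        return self.columns["variable_id"].tolist()


@dataclass
class PhenotypeTable:
    """Per-subject phenotypes (SBP, DBP in mmHg) and covariates (AGE, SEX, MS, SS)."""

    data: pd.DataFrame  # indexed by subject id

    def __post_init__(self):
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing required column(s): {', '.join(missing)}")
        if self.data["SBP"].isna().any():
            raise ValueError("missing SBP values are not allowed for analyzed subjects")
        for c in ("SEX", "MS", "SS"):
            vals = set(self.data[c].dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"column {c} must be binary 0/1, found {sorted(vals)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data[["AGE", "SEX", "MS", "SS"]]


def matrix_from_frame(frame: pd.DataFrame, source: str,
                       annotation: pd.DataFrame | None = None) -> OmicsMatrix:
    cols = pd.DataFrame({"variable_id": frame.columns.astype(str), "source": source})
    if annotation is not None:
        cols = cols.merge(annotation, on="variable_id", how="left")
    return OmicsMatrix(values=frame.to_numpy(dtype=float),
                       subject_ids=[str(s) for s in frame.index],
                       columns=cols)


def read_genotypes(path: str | Path, format: str = "tsv",
                   annotation: pd.DataFrame | None = None) -> OmicsMatrix:
    """Read genotypes as alt-allele dosage 0/1/2.

    ``format="tsv"``: rows are subjects, header row holds SNP ids; missing
    cells are imputed to the column mean (logged). ``format="vcf"``: a
    VCF 4.x file read with cyvcf2, GT field only; non-biallelic or non-SNV
    records are skipped with a warning.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        bad = frame.apply(lambda c: ~c.isin([0, 1, 2]) & c.notna()).to_numpy()
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"unparseable genotype at subject {frame.index[r]!r}, SNP {frame.columns[c]!r}: "
                f"{frame.iat[r, c]!r} (expected 0/1/2)")
        n_missing = int(frame.isna().to_numpy().sum())
        if n_missing:
            logger.info("imputing %d missing genotype(s) to column means", n_missing)
            frame = frame.fillna(frame.mean())
        return matrix_from_frame(frame, "SNP", annotation)
    if format == "vcf":
        return _read_vcf(path, annotation)
    raise ValueError(f"unknown genotype format {format!r}; expected 'tsv' or 'vcf'")


def _read_vcf(path: Path, annotation: pd.DataFrame | None) -> OmicsMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    subjects = list(vcf.samples)
    ids, chroms, rows = [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping non-biallelic record {rec.CHROM}:{rec.POS}")
            continue
        dosage = rec.gt_types.astype(float)  # 0/1/2, 3 = unknown under gts012
        dosage[dosage == 3] = np.nan
        if np.isnan(dosage).any():
            fill = np.nanmean(dosage) if not np.isnan(dosage).all() else 0.0
            logger.info("imputing %d missing call(s) at %s:%d to %.3f",
                        int(np.isnan(dosage).sum()), rec.CHROM, rec.POS, fill)
            dosage = np.where(np.isnan(dosage), fill, dosage)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        rows.append(dosage)
    values = np.array(rows, dtype=float).T if rows else np.empty((len(subjects), 0))
    cols = pd.DataFrame({"variable_id": ids, "source": "SNP", "chromosome": chroms})
    if annotation is not None:
        cols = cols.merge(annotation, on="variable_id", how="left")
    return OmicsMatrix(values=values, subject_ids=subjects, columns=cols)


def read_expression(path: str | Path,
                    annotation: pd.DataFrame | None = None) -> OmicsMatrix:
    """Read an expression TSV (rows subjects, header probe ids); no missing values allowed."""
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, float_precision="round_trip")
    if frame.isna().to_numpy().any():
        raise ValueError("missing expression values are not allowed")
    return matrix_from_frame(frame, "expression", annotation)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read the phenotype/covariate TSV (columns SBP, DBP, AGE, SEX, MS, SS)."""
    return PhenotypeTable(pd.read_csv(Path(path), sep="\t", index_col=0,
                                      float_precision="round_trip"))


def merge_and_filter(genotypes: OmicsMatrix, expression: OmicsMatrix,
                     phenotypes: PhenotypeTable) -> tuple[OmicsMatrix, PhenotypeTable]:
    """Merge the blocks into one design matrix on the common subjects.

    Subjects are restricted to the intersection of the three inputs, in the
    genotype matrix's order, identically in both outputs. When a block's
    metadata carries a ``gene_symbol`` column, variables without a symbol
    are dropped (mirroring annotation-based filtering); blocks without that
    metadata keep all columns. The expression block precedes the SNP block.
    """
    common = (set(genotypes.subject_ids) & set(expression.subject_ids)
              & set(phenotypes.subject_ids))
    if not common:
        raise ValueError("no subjects shared between genotype, expression and phenotype inputs")
    order = [s for s in genotypes.subject_ids if s in common]

    def take(m: OmicsMatrix) -> OmicsMatrix:
        idx = [m.subject_ids.index(s) for s in order]
        cols = m.columns.reset_index(drop=True)
        vals = m.values[idx, :]
        if "gene_symbol" in cols.columns:
            keep = cols["gene_symbol"].notna() & (cols["gene_symbol"].astype(str) != "")
            vals, cols = vals[:, keep.to_numpy()], cols[keep].reset_index(drop=True)
        return OmicsMatrix(values=vals, subject_ids=order, columns=cols)

    ge, gs = take(expression), take(genotypes)
    merged = OmicsMatrix(values=np.hstack([ge.values, gs.values]),
                         subject_ids=order,
                         columns=pd.concat([ge.columns, gs.columns],
                                           ignore_index=True))
    pheno = PhenotypeTable(phenotypes.data.loc[order].copy())
    return merged, pheno


def normalize_columns(matrix: OmicsMatrix) -> OmicsMatrix:
    """Mean-center each column and scale it to unit L2 norm.

    Constant columns become all-zero and are flagged in
    ``constant_columns`` instead of raising. Idempotent up to numerical
    tolerance: already-normalized input passes through unchanged.
    """
    values = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(values, axis=0)
    constant = norms <= 1e-12 * max(1.0, np.abs(matrix.values).max(initial=0.0))
    safe = np.where(constant, 1.0, norms)
    values = values / safe
    values[:, constant] = 0.0
    return replace(matrix, values=values, normalized=True, constant_columns=constant)


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write values as TSV (full precision); metadata goes to ``<path>.meta.tsv``."""
    path = Path(path)
    pd.DataFrame(matrix.values, index=matrix.subject_ids,
                 columns=matrix.variable_ids).to_csv(
        path, sep="\t", index_label="subject_id", float_format="%.17g")
    matrix.columns.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t", index=False)


def read_omics_matrix(path: str | Path) -> OmicsMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t")
    return OmicsMatrix(values=frame.to_numpy(dtype=float),
                       subject_ids=[str(s) for s in frame.index], columns=meta)


def write_ranking_tsv(ranking, path: str | Path) -> None:
    """Write a ranked-variable TSV: rank, variable_id, source, score, selection_count."""
    ranking.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
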