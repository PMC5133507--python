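"""End-to-end pipeline: merge -> normalize -> covariate regression -> SRVS -> ranking."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

import srvs
from srvs.core import SRVSConfig, SRVSResult, run_srvs
from srvs.covariates import adjustment_report
from srvs.io import OmicsMatrix, PhenotypeTable, merge_and_filter, normalize_columns
from srvs.ranking import VariableRanking, rank_variables, top_n_summary

__all__ = ["SelectionRun", "run_selection", "write_manifest"]


@dataclass
class SelectionRun:
    """Everything one selection run produces."""

    matrix: OmicsMatrix
    phenotypes: PhenotypeTable
    coefficients: pd.DataFrame        # covariate table incl. before/after correlations
    srvs_result: SRVSResult
    ranking: VariableRanking
    phenotype_name: str


def run_selection(genotypes: OmicsMatrix, expression: OmicsMatrix,
                  phenotypes: PhenotypeTable, config: SRVSConfig | None = None,
                  phenotype: str = "SBP",
                  score_mode: str = "coefficient") -> SelectionRun:
    """Run the full biomarker-selection pipeline on already-loaded inputs.

    The chosen blood-pressure phenotype (SBP by default) is adjusted for
    age, sex, medication and smoking status by least squares; the residual
    drives the SRVS ensemble over the merged, column-normalized design.
    """
    if phenotype not in ("SBP", "DBP"):
        raise ValueError("phenotype must be 'SBP' or 'DBP'")
    merged, pheno = merge_and_filter(genotypes, expression, phenotypes)
    normalized = normalize_columns(merged)
    coef_table, models = adjustment_report(pheno)
    residual = models[phenotype].residual
    result = run_srvs(residual, normalized, config)
    ranking = rank_variables(result, normalized.columns, score_mode=score_mode)
    return SelectionRun(matrix=normalized, phenotypes=pheno,
                        coefficients=coef_table, srvs_result=result,
                        ranking=ranking, phenotype_name=phenotype)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, config: SRVSConfig,
                   inputs: dict[str, Path], extra: dict | None = None) -> Path:
    """Write a JSON manifest sufficient to replay the run byte-for-byte."""
    manifest = {
        "package_version": srvs.__version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "inputs": {name: {"path": str(p), "sha256": _digest(Path(p))}
                   for name, p in inputs.items()},
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def write_reports(run: SelectionRun, out_dir: Path,
                  top_n_values: list[int] | None = None) -> dict[str, Path]:
    """Write ranking, top-N composition and coefficient tables as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranking": out / "ranking.tsv",
        "top_n": out / "top_n_summary.tsv",
        "coefficients": out / "coefficients.tsv",
    }
    run.ranking.to_frame().to_csv(paths["ranking"], sep="\t", index=False,
                                  float_format="%.10g")
    n = len(run.ranking)
    cuts = top_n_values or [c for c in range(100, 1001, 100) if c <= n] or [n]
    top_n_summary(run.ranking, cuts).to_csv(paths["top_n"], sep="\t", index=False)
    run.coefficients.to_csv(paths["coefficients"], sep="\t", index=False,
                            float_format="%.6g")
    return paths
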