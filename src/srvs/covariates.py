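"""Least-squares removal of clinical covariates from blood pressure.

Blood pressure is modelled as a linear function of age, sex, medication
status and smoking status; the least-squares residual is the phenotype
handed to sparse variable selection. The model is fit with an intercept by
default so the residual is mean-free; the coefficients and the SBP–DBP
Pearson correlations before and after adjustment reproduce the structure of
a standard covariate-effects table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from srvs.io import PhenotypeTable

__all__ = ["CovariateModel", "fit_lls", "pearson", "adjustment_report"]

COVARIATE_ORDER = ("AGE", "SEX", "MS", "SS")


@dataclass
class CovariateModel:
    """Fitted covariate model: BP = intercept + X @ coefficients + residual.

    ``coefficients`` is ordered (AGE, SEX, MS, SS) in phenotype units per
    covariate unit. ``residual + fitted`` reconstructs the observed
    phenotype exactly, and the residual is orthogonal to every covariate
    column and (with an intercept) to the constant vector.
    """

    coefficients: np.ndarray
    intercept: float
    residual: np.ndarray
    fitted: np.ndarray
    names: tuple[str, ...] = COVARIATE_ORDER

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])


def fit_lls(phenotype: np.ndarray | pd.Series, covariates: pd.DataFrame,
            intercept: bool = True) -> CovariateModel:
    """Ordinary least squares of the phenotype on the four covariates.

    Parameters
    ----------
    phenotype
        Blood-pressure vector, no missing values, length >= 6.
    covariates
        Table with columns AGE, SEX, MS, SS (extra columns ignored).
    intercept
        Include a constant term (default). Without it the residual is not
        mean-free.

    A rank-deficient design (e.g. a constant covariate column) does not
    raise: the minimum-norm pseudoinverse solution is returned with a
    warning.
    """
    y = np.asarray(phenotype, dtype=float)
    X = covariates[list(COVARIATE_ORDER)].to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in phenotype or covariates")
    if len(y) != X.shape[0]:
        raise ValueError("phenotype and covariates have different lengths")
    if len(y) < 6:
        raise ValueError("need at least 6 subjects to fit 4 covariates and an intercept")

    design = np.column_stack([np.ones(len(y)), X]) if intercept else X
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient covariate design; minimum-norm solution returned")
    fitted = design @ beta
    residual = y - fitted
    if intercept:
        b0, coefs = float(beta[0]), beta[1:]
    else:
        b0, coefs = 0.0, beta
    return CovariateModel(coefficients=coefs, intercept=b0,
                          residual=residual, fitted=fitted)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation; raises on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def adjustment_report(phenotypes: PhenotypeTable,
                      intercept: bool = True) -> tuple[pd.DataFrame, dict[str, CovariateModel]]:
    """Fit SBP and DBP covariate models and tabulate coefficients.

    Returns a table with one row per phenotype — covariate coefficients plus
    the SBP–DBP Pearson correlation before and after adjustment — and the
    fitted models (the SBP residual is the downstream selection phenotype;
    the DBP model exists only for this report).
    """
    cov = phenotypes.covariates
    models = {bp: fit_lls(phenotypes.data[bp], cov, intercept=intercept)
              for bp in ("SBP", "DBP")}
    corr_before = pearson(phenotypes.data["SBP"].to_numpy(),
                          phenotypes.data["DBP"].to_numpy())
    corr_after = pearson(models["SBP"].residual, models["DBP"].residual)
    rows = []
    for bp, model in models.items():
        row = {"BP": bp}
        row.update({name: model.coef(name) for name in COVARIATE_ORDER})
        row["corr_before"] = corr_before
        row["corr_after"] = corr_after
        rows.append(row)
    return pd.DataFrame(rows), models
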