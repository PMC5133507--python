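"""Synthetic cohort generator with known causal structure.

Emulates the statistical features the selection pipeline assumes in real
multi-omics cohorts: family-correlated genotypes (Balding–Nichols
beta-binomial allele frequencies), gene-expression probes partly driven by
cis-eQTLs, four clinical covariates with linear effects on blood pressure,
and a sparse set of causal genetic variables. Ground truth (which variables
carry phenotype effects, and how large) is returned alongside the data so
recovery can be scored.

The generative phenotype model is

    BP = age*b_age + sex*b_sex + MS*b_ms + SS*b_ss + Z_causal @ beta + e

where Z_causal holds the causal genotype/expression columns standardized to
zero mean and unit variance, beta is sparse with magnitudes drawn from
``effect_size_range`` and random signs, and e ~ Normal(0, noise_sd^2).
Standardizing causal columns makes effect sizes comparable across minor
allele frequencies, and ``effect_size / noise_sd`` is the standardized
effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "write_dataset",
           "gen_genotypes", "gen_expression", "gen_covariates", "gen_phenotype"]

#: Covariate effects on systolic blood pressure, in mmHg per covariate unit,
#: ordered (age, sex, medication status, smoking status).
DEFAULT_COVARIATE_EFFECTS = (1.7, 25.5, -8.9, 13.4)

#: Corresponding diastolic effects, same order.
DBP_COVARIATE_EFFECTS = (0.8, 19.7, -14.2, 10.7)

# Cohort demographics used as sampling defaults: age 47.7 (SD 14.1) years,
# male fraction 167/397, on-medication 113/397, smokers 66/397.
_AGE_MEAN, _AGE_SD = 47.7, 14.1
_P_MALE, _P_MS, _P_SS = 167 / 397, 113 / 397, 66 / 397


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_subjects, n_snps, n_expr, n_families
        Cohort and variable-block sizes.
    fst
        Balding–Nichols divergence parameter in [0, 1): within-family
        allele-frequency correlation. 0 gives i.i.d. subjects.
    maf_range
        (low, high) bounds for per-SNP global minor-allele frequency,
        within (0, 0.5].
    n_causal_snps, n_causal_expr
        Number of SNP / expression columns with nonzero phenotype effects.
    effect_size_range
        (low, high) magnitude bounds for causal effects, in phenotype units
        (mmHg) per standardized variable; signs are random.
    n_eqtl_links, eqtl_effect
        Number of random (SNP, probe) cis-effects and their size in
        expression units per alternate allele.
    covariate_effects
        (age, sex, MS, SS) effects on the phenotype, mmHg per unit.
    noise_sd
        SD of the phenotype residual noise, mmHg.
    seed
        Seed for all randomness; identical configs give identical datasets.
    """

    n_subjects: int = 397
    n_snps: int = 2000
    n_expr: int = 500
    n_families: int = 46
    fst: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_snps: int = 5
    n_causal_expr: int = 5
    effect_size_range: tuple[float, float] = (5.0, 15.0)
    n_eqtl_links: int = 50
    eqtl_effect: float = 1.0
    covariate_effects: tuple[float, float, float, float] = DEFAULT_COVARIATE_EFFECTS
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if self.n_causal_snps > self.n_snps:
            raise ValueError("n_causal_snps exceeds n_snps")
        if self.n_causal_expr > self.n_expr:
            raise ValueError("n_causal_expr exceeds n_expr")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (1 <= self.n_families <= self.n_subjects):
            raise ValueError("need 1 <= n_families <= n_subjects")
        if self.n_eqtl_links > self.n_expr * self.n_snps:
            raise ValueError("n_eqtl_links exceeds the number of (SNP, probe) pairs")


@dataclass
class SyntheticDataset:
    """A generated cohort plus ground truth.

    ``truth`` maps merged-matrix variable ids (``expr<j>`` for probes,
    ``snp<j>`` for SNPs) to their true effect sizes. ``eqtl_map`` lists the
    simulated (SNP index, probe index) cis links.
    """

    genotypes: pd.DataFrame           # subjects x n_snps, entries in {0,1,2}
    expression: pd.DataFrame          # subjects x n_expr
    covariates: pd.DataFrame          # subjects x 4: AGE, SEX, MS, SS
    phenotype: pd.DataFrame           # subjects x 2: SBP, DBP
    truth: dict[str, float]
    family_ids: np.ndarray
    eqtl_map: list[tuple[int, int]] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.genotypes.index)

    def as_pipeline_inputs(self):
        """Return (genotypes, expression, phenotypes) ready for the selection pipeline."""
        from srvs.io import PhenotypeTable, matrix_from_frame

        geno = matrix_from_frame(self.genotypes, "SNP")
        expr = matrix_from_frame(self.expression, "expression")
        pheno = PhenotypeTable(pd.concat([self.phenotype, self.covariates], axis=1))
        return geno, expr, pheno


def _subject_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def gen_genotypes(config: SyntheticConfig, rng: np.random.Generator):
    """Draw family-structured genotypes under the Balding–Nichols model.

    Per SNP a global allele frequency p is uniform in ``maf_range``; each
    family draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``fst`` (for F = 0 the family frequency equals p exactly), and
    subjects are binomial(2, family frequency).

    Returns
    -------
    genotypes : (n_subjects, n_snps) int8 array
    family_ids : (n_subjects,) array of family labels
    """
    config.validate()
    n, m_snp, n_fam = config.n_subjects, config.n_snps, config.n_families
    # near-equal family sizes, deterministic assignment
    fam_index = np.sort(np.arange(n) % n_fam)
    family_ids = np.array([f"F{i:03d}" for i in fam_index])

    p_global = rng.uniform(*config.maf_range, size=m_snp)
    if config.fst > 0:
        a = p_global * (1 - config.fst) / config.fst
        b = (1 - p_global) * (1 - config.fst) / config.fst
        p_fam = rng.beta(a[None, :], b[None, :], size=(n_fam, m_snp))
    else:
        p_fam = np.broadcast_to(p_global, (n_fam, m_snp))
    geno = rng.binomial(2, p_fam[fam_index, :]).astype(np.int8)
    return geno, family_ids


def gen_expression(genotypes: np.ndarray, config: SyntheticConfig, rng: np.random.Generator):
    """Baseline standard-normal expression plus additive cis-eQTL effects.

    For each of ``n_eqtl_links`` distinct (SNP, probe) pairs the probe gains
    ``eqtl_effect * (genotype - mean genotype)``.

    Returns
    -------
    expression : (n_subjects, n_expr) array
    eqtl_map : list of (snp_index, probe_index)
    """
    n, m_snp = genotypes.shape
    expr = rng.standard_normal((n, config.n_expr))
    if config.n_eqtl_links > config.n_expr * m_snp:
        raise ValueError("n_eqtl_links exceeds the number of (SNP, probe) pairs")
    flat = rng.choice(m_snp * config.n_expr, size=config.n_eqtl_links, replace=False)
    eqtl_map = [(int(f // config.n_expr), int(f % config.n_expr)) for f in flat]
    for snp_j, probe_j in eqtl_map:
        g = genotypes[:, snp_j].astype(float)
        expr[:, probe_j] += config.eqtl_effect * (g - g.mean())
    return expr, eqtl_map


def gen_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample AGE (truncated-positive normal), SEX, MS, SS (Bernoulli)."""
    n = config.n_subjects
    age = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    while (bad := age <= 0).any():          # truncate at zero by resampling
        age[bad] = rng.normal(_AGE_MEAN, _AGE_SD, size=int(bad.sum()))
    return pd.DataFrame(
        {
            "AGE": age,
            "SEX": rng.binomial(1, _P_MALE, size=n),
            "MS": rng.binomial(1, _P_MS, size=n),
            "SS": rng.binomial(1, _P_SS, size=n),
        },
        index=_subject_ids(n),
    )


def _standardize(col: np.ndarray) -> np.ndarray:
    c = col.astype(float) - col.mean()
    sd = c.std()
    return c / sd if sd > 0 else c


def gen_phenotype(genotypes: np.ndarray, expression: np.ndarray,
                  covariates: pd.DataFrame, config: SyntheticConfig,
                  rng: np.random.Generator):
    """Run the generative model forward to produce SBP and the causal truth.

    Causal columns are standardized before their effect is applied, so an
    effect of size b contributes b mmHg per SD of the variable regardless of
    allele frequency. DBP shares the same genetic signal at 60% amplitude,
    uses its own covariate-effect defaults and 60% of the noise SD (diastolic
    spread is roughly 0.6x systolic), so the two residuals are strongly
    correlated as in real cohorts.

    Returns
    -------
    phenotype : DataFrame with SBP, DBP columns
    truth : dict mapping variable id -> true SBP effect
    """
    n = genotypes.shape[0]
    causal_expr = rng.choice(config.n_expr, size=config.n_causal_expr, replace=False)
    causal_snps = rng.choice(config.n_snps, size=config.n_causal_snps, replace=False)
    n_causal = config.n_causal_expr + config.n_causal_snps
    lo, hi = config.effect_size_range
    effects = rng.uniform(lo, hi, size=n_causal) * rng.choice([-1.0, 1.0], size=n_causal)

    genetic = np.zeros(n)
    truth: dict[str, float] = {}
    for j, eff in zip(causal_expr, effects[: config.n_causal_expr]):
        genetic += eff * _standardize(expression[:, j])
        truth[f"expr{j}"] = float(eff)
    for j, eff in zip(causal_snps, effects[config.n_causal_expr:]):
        genetic += eff * _standardize(genotypes[:, j])
        truth[f"snp{j}"] = float(eff)

    def covariate_part(effects):
        b_age, b_sex, b_ms, b_ss = effects
        return (b_age * covariates["AGE"].to_numpy()
                + b_sex * covariates["SEX"].to_numpy()
                + b_ms * covariates["MS"].to_numpy()
                + b_ss * covariates["SS"].to_numpy())

    sbp = covariate_part(config.covariate_effects) + genetic \
        + rng.normal(0, config.noise_sd, size=n)
    dbp = covariate_part(DBP_COVARIATE_EFFECTS) + 0.6 * genetic \
        + rng.normal(0, 0.6 * config.noise_sd, size=n)
    phenotype = pd.DataFrame({"SBP": sbp, "DBP": dbp}, index=_subject_ids(n))
    return phenotype, truth


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic cohort; identical seeds give identical data."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    geno, family_ids = gen_genotypes(config, rng)
    expr, eqtl_map = gen_expression(geno, config, rng)
    covariates = gen_covariates(config, rng)
    phenotype, truth = gen_phenotype(geno, expr, covariates, config, rng)

    ids = _subject_ids(config.n_subjects)
    genotypes = pd.DataFrame(geno, index=ids,
                             columns=[f"snp{j}" for j in range(config.n_snps)])
    expression = pd.DataFrame(expr, index=ids,
                              columns=[f"expr{j}" for j in range(config.n_expr)])
    return SyntheticDataset(genotypes=genotypes, expression=expression,
                            covariates=covariates, phenotype=phenotype,
                            truth=truth, family_ids=family_ids, eqtl_map=eqtl_map)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four TSV inputs the pipeline consumes plus the truth table.

    Files: genotypes.tsv (subjects x SNPs), expression.tsv (subjects x
    probes), phenotypes.tsv (SBP, DBP, AGE, SEX, MS, SS) and truth.tsv
    (variable_id, effect).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out / "genotypes.tsv",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
    }
    dataset.genotypes.to_csv(paths["genotypes"], sep="\t", index_label="subject_id")
    dataset.expression.to_csv(paths["expression"], sep="\t", index_label="subject_id",
                              float_format="%.10g")
    pheno = pd.concat([dataset.phenotype, dataset.covariates], axis=1)
    pheno.to_csv(paths["phenotypes"], sep="\t", index_label="subject_id",
                 float_format="%.10g")
    truth = pd.DataFrame(sorted(dataset.truth.items()),
                         columns=["variable_id", "effect"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
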