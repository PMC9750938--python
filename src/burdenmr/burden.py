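"""Gene-level collapsing burden association and screen diagnostics.

Qualifying variants are collapsed to a per-gene, per-mask 0/1 carrier
indicator (the "dummy genotype": a sample is a carrier iff it holds at
least one qualifying non-missing alt genotype in the gene, regardless of
how many). Association runs in the three-step generalised-linear-model
scheme:

1. a null model regresses the trait (binary traits treated as continuous)
   on covariates only;
2. the preliminary stage regresses the null-model residuals on carrier
   status, gene by gene (closed-form simple OLS, vectorized);
3. genes passing a lenient gate (default p < 1e-4) are refit with a full
   GLM of the trait on carrier status plus covariates, with family
   binomial or gaussian; binary full fits report OR = exp(beta) with
   exp(beta +/- 1.96 SE) confidence limits.

A gene-mask pair is flagged exome-wide significant only if p is below the
threshold (default 6.9e-7) *and* it has at least the carrier-count floor
(default 30). Genomic inflation is summarised by lambda = median chi^2 of
the p-values over the chi^2_1 median 0.4549; effect heterogeneity between
two fits by a normal Z test on the difference of betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, DataError, NumericalError
from .genoqc import MISSING

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45493642...


@dataclass(frozen=True)
class ScreenConfig:
    significance: float = 6.9e-7  # exome-wide threshold
    carrier_floor: int = 30  # minimum carriers for a reportable hit
    gate: float = 1e-4  # lenient preliminary->full threshold
    covariates: tuple[str, ...] = ()
    sample_exclusions: tuple[str, ...] = ()

    def validate(self) -> None:
        if not 0 < self.significance < 1:
            raise ConfigError("significance must be in (0, 1)")
        if not 0 < self.gate < 1:
            raise ConfigError("gate must be in (0, 1)")
        if self.carrier_floor < 0:
            raise ConfigError("carrier_floor must be >= 0")


@dataclass
class CarrierMatrix:
    """Gene x sample 0/1 qualifying-carrier indicators for one mask."""

    mask: str
    genes: list[str]
    samples: list[str]
    matrix: np.ndarray  # bool, genes x samples

    def carrier_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.matrix[self.genes.index(gene)]


@dataclass
class BurdenResult:
    gene: str
    mask: str
    stage: str  # "preliminary" | "full"
    beta: float = np.nan
    se: float = np.nan
    p: float = np.nan
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    carriers: int = 0
    case_carriers: int = 0
    cmaf: float = np.nan
    penetrance: float | None = None
    status: str = "ok"  # "ok" | "skipped" | "flagged"
    note: str = ""


# ---------------------------------------------------------------------------
# collapsing


def collapse_gene_carriers(
    gt: np.ndarray,
    variant_genes: Sequence[str],
    qualifying: np.ndarray,
    samples: Sequence[str],
    mask_name: str,
) -> CarrierMatrix:
    """Collapse qualifying variants to a per-gene carrier indicator.

    ``gt`` is the post-QC genotype matrix (variants x samples);
    ``qualifying`` a per-variant boolean of mask membership. Missing
    genotypes contribute nothing. Genes with no qualifying variants are
    omitted rather than emitted as all-zero rows.
    """
    variant_genes = np.asarray(variant_genes)
    qualifying = np.asarray(qualifying, dtype=bool)
    if gt.shape[0] != len(variant_genes) or len(qualifying) != len(variant_genes):
        raise DataError("genotypes, genes and mask membership are misaligned")
    alt = (gt > 0) & (gt != MISSING)
    genes_out: list[str] = []
    rows: list[np.ndarray] = []
    for gene in pd.unique(variant_genes[qualifying]):
        idx = np.flatnonzero((variant_genes == gene) & qualifying)
        genes_out.append(str(gene))
        rows.append(alt[idx].any(axis=0))
    matrix = (
        np.vstack(rows) if rows else np.empty((0, gt.shape[1]), dtype=bool)
    )
    return CarrierMatrix(mask_name, genes_out, list(samples), matrix)


# ---------------------------------------------------------------------------
# association


def null_residuals(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of the trait (treated as continuous) on covariates."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise NumericalError("covariate matrix is rank deficient")
    return y - X @ coef


def preliminary_scan(
    carrier_matrix: np.ndarray, residuals: np.ndarray
) -> pd.DataFrame:
    """Closed-form OLS of null-model residuals on carrier status, per gene.

    Returns beta, se, p (two-sided t, n-2 df) and carrier counts; genes
    without contrast (0 or all carriers) come back with NaN statistics.
    """
    c = np.asarray(carrier_matrix, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n = c.shape[1]
    if n != len(r):
        raise DataError("carrier matrix and residuals are misaligned")
    csum = c.sum(axis=1)
    rbar = r.mean()
    sxx = csum - csum**2 / n  # binary predictor: sum c^2 == sum c
    sxy = c @ r - csum * rbar
    syy = float(((r - rbar) ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sigma2 = (syy - beta * sxy) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    degenerate = (csum == 0) | (csum == n)
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    p[degenerate] = np.nan
    return pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "carriers": csum.astype(int)}
    )


def _full_glm(
    carriers: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    family: str,
) -> tuple[float, float, float, str, str]:
    """Fit trait ~ carrier + covariates; returns (beta, se, p, status, note)."""
    cols = [np.ones(len(y)), np.asarray(carriers, dtype=float)]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    X = np.column_stack(cols)
    fam = sm.families.Binomial() if family == "binomial" else sm.families.Gaussian()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(np.asarray(y, dtype=float), X, family=fam).fit(maxiter=100)
        notes = [
            str(w.message)
            for w in caught
            if "separation" in str(w.message).lower()
            or "converge" in str(w.message).lower()
        ]
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1])
        if notes or not np.isfinite(se) or se > 1e3:
            return beta, se, p, "flagged", "; ".join(notes) or "unstable fit"
        return beta, se, p, "ok", ""
    except Exception as exc:  # perfect separation raises in some versions
        return np.nan, np.nan, np.nan, "flagged", f"{type(exc).__name__}: {exc}"


def fit_burden(
    carriers: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    family: str = "binomial",
    gate: float = 1e-4,
    residuals: np.ndarray | None = None,
    gene: str = "",
    mask: str = "",
) -> BurdenResult:
    """Three-step burden fit for one gene.

    Runs the preliminary residual-on-carrier regression and, if its p-value
    passes the lenient ``gate``, the full GLM. Zero carriers yield a
    skipped record; a carrier vector without contrast raises.
    """
    if family not in ("binomial", "gaussian"):
        raise ConfigError(f"unknown family {family!r}")
    carriers = np.asarray(carriers, dtype=bool)
    y = np.asarray(phenotype, dtype=float)
    n_car = int(carriers.sum())
    case_car = int((carriers & (y > 0)).sum()) if family == "binomial" else 0
    if n_car == 0:
        return BurdenResult(gene, mask, "preliminary", carriers=0,
                            status="skipped", note="zero carriers")
    if n_car == len(carriers):
        raise NumericalError(f"gene {gene or '?'}: carrier vector has no contrast")
    if residuals is None:
        residuals = null_residuals(y, covariates)
    prelim = preliminary_scan(carriers[None, :], residuals).iloc[0]
    result = BurdenResult(
        gene, mask, "preliminary",
        beta=float(prelim["beta"]), se=float(prelim["se"]), p=float(prelim["p"]),
        carriers=n_car, case_carriers=case_car,
    )
    if np.isfinite(prelim["p"]) and prelim["p"] < gate:
        beta, se, p, status, note = _full_glm(carriers, y, covariates, family)
        result.stage = "full"
        result.beta, result.se, result.p = beta, se, p
        result.status, result.note = status, note
        if family == "binomial" and np.isfinite(beta):
            result.odds_ratio = float(np.exp(min(beta, 700)))
            result.ci_low = float(np.exp(min(beta - 1.96 * se, 700)))
            result.ci_high = float(np.exp(min(beta + 1.96 * se, 700)))
    return result


# ---------------------------------------------------------------------------
# exome-wide screen


def run_exome_screen(
    carrier_matrices: Mapping[str, CarrierMatrix],
    phenotype: pd.DataFrame,
    covariates: np.ndarray | None,
    config: ScreenConfig | None = None,
    trait: str = "t2d",
    family: str = "binomial",
    gene_cmaf: Mapping[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Run the collapsing screen over all masks.

    Returns one row per gene x mask plus per-mask inflation lambdas. A
    row is flagged ``significant`` only when p < threshold and carriers
    >= floor. Sample exclusions in the config are applied before fitting.
    """
    config = config or ScreenConfig()
    config.validate()
    y_all = phenotype[trait].to_numpy(dtype=float)
    samples = list(phenotype["sample"])
    keep = np.array([s not in set(config.sample_exclusions) for s in samples])
    y = y_all[keep]
    cov = covariates[keep] if covariates is not None and covariates.size else covariates
    residuals = null_residuals(y, cov)
    rows: list[dict] = []
    lambdas: dict[str, float] = {}
    for mask_name, cm in carrier_matrices.items():
        if cm.matrix.shape[0] == 0:
            lambdas[mask_name] = np.nan
            continue
        if cm.samples != samples:
            raise DataError(f"mask {mask_name}: samples misaligned with phenotype")
        mat = cm.matrix[:, keep]
        prelim = preliminary_scan(mat, residuals)
        for gi, gene in enumerate(cm.genes):
            carriers = mat[gi]
            n_car = int(prelim["carriers"].iloc[gi])
            rec = BurdenResult(
                gene, mask_name, "preliminary",
                beta=float(prelim["beta"].iloc[gi]),
                se=float(prelim["se"].iloc[gi]),
                p=float(prelim["p"].iloc[gi]),
                carriers=n_car,
                case_carriers=int((carriers & (y > 0)).sum()),
            )
            if n_car == 0:
                rec.status, rec.note = "skipped", "zero carriers"
            elif np.isfinite(rec.p) and rec.p < config.gate:
                beta, se, p, status, note = _full_glm(carriers, y, cov, family)
                rec.stage, rec.status, rec.note = "full", status, note
                rec.beta, rec.se, rec.p = beta, se, p
                if family == "binomial" and np.isfinite(beta):
                    rec.odds_ratio = float(np.exp(min(beta, 700)))
                    rec.ci_low = float(np.exp(min(beta - 1.96 * se, 700)))
                    rec.ci_high = float(np.exp(min(beta + 1.96 * se, 700)))
            if rec.carriers > 0 and family == "binomial":
                rec.penetrance = rec.case_carriers / rec.carriers
            if gene_cmaf is not None:
                rec.cmaf = gene_cmaf.get((mask_name, gene), np.nan)
            rows.append(vars(rec).copy())
        pvals = prelim["p"].to_numpy()
        pvals = pvals[np.isfinite(pvals)]
        lambdas[mask_name] = inflation_lambda(pvals) if len(pvals) else np.nan
    results = pd.DataFrame(rows)
    if len(results):
        results["significant"] = (
            (results["p"] < config.significance)
            & (results["carriers"] >= config.carrier_floor)
            & (results["status"] != "skipped")
        )
    else:
        results["significant"] = pd.Series(dtype=bool)
    return results, lambdas


# ---------------------------------------------------------------------------
# diagnostics and summaries


def inflation_lambda(pvalues: Sequence[float]) -> float:
    """Genomic inflation: median chi^2_1 quantile of 1-p over 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DataError("inflation_lambda: empty p-value vector")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("inflation_lambda: p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, 1)
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def heterogeneity_z(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Normal Z test on the difference of two independent effect estimates."""
    if se1 <= 0 or se2 <= 0:
        raise DataError("heterogeneity_z: standard errors must be positive")
    z = (beta1 - beta2) / np.hypot(se1, se2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def gene_summary(
    carriers: np.ndarray,
    case_status: np.ndarray,
    variant_mafs: Sequence[float],
) -> tuple[float, int, float | None]:
    """(cMAF, carrier count, penetrance) for one gene under one mask.

    cMAF is the sum of qualifying-variant MAFs; penetrance the affected
    fraction of carriers, reported as None (absent) with zero carriers.
    """
    carriers = np.asarray(carriers, dtype=bool)
    case_status = np.asarray(case_status)
    if len(carriers) != len(case_status):
        raise DataError("gene_summary: carriers and case status misaligned")
    cmaf = float(np.sum(variant_mafs))
    n_car = int(carriers.sum())
    if n_car == 0:
        return cmaf, 0, None
    penetrance = float((carriers & (case_status > 0)).sum() / n_car)
    return cmaf, n_car, penetrance


def domain_partition_test(
    carriers_in: np.ndarray,
    carriers_out: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    family: str = "binomial",
) -> tuple[BurdenResult, BurdenResult, float, float]:
    """Compare carrier effects inside vs outside a protein-domain interval.

    The caller partitions a gene's qualifying variants by protein position
    (e.g. a kinase domain) and collapses each side separately; both sides
    are fit as full models and their betas compared with the normal Z test.
    """
    res_in = fit_burden(carriers_in, phenotype, covariates, family, gate=1.0)
    res_out = fit_burden(carriers_out, phenotype, covariates, family, gate=1.0)
    z, p = heterogeneity_z(res_in.beta, res_in.se, res_out.beta, res_out.se)
    return res_in, res_out, z, p
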