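"""Synthetic cohorts, genotypes with read evidence, and GWAS summary stats.

This module states the world the downstream analyses assume:

* a rare-variant site-frequency spectrum (log-uniform / power-law MAFs
  truncated at 0.1%, with a configurable singleton fraction),
* per-genotype read evidence (negative-binomial depth, binomial alt reads
  for true hets, an unbalanced-het error mode and a low-quality error mode
  so the QC filters have true positives to find),
* a binary liability phenotype from a logistic model over covariates
  (age, age^2, sex, ten principal-component surrogates, a 3-level
  sequencing-batch factor) plus per-gene carrier effects, with the
  intercept calibrated to a target marginal prevalence,
* instrument-level exposure/outcome effects for two-sample MR, with
  optional directional pleiotropy and reverse-causal instruments, and
* paired summary-statistic tracks over a locus for colocalization.

No linkage disequilibrium, relatedness or ancestry structure is simulated.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .annotate import FUNCTIONAL_CLASSES
from .errors import AlignmentError, ConfigError
from .genoqc import HET, HOM_ALT, MISSING

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

BATCH_LEVELS = ("50k", "200k", "450k")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CausalGene:
    """A gene with a true carrier effect on disease liability.

    ``carrier_freq`` is the target cumulative carrier frequency of the
    qualifying variants injected for this gene; the default 0.02 gives
    ~400 carriers at n=20,000, enough for an odds ratio of 2.5 to clear an
    exome-wide threshold of 6.9e-7.
    """

    gene: str
    mask_class: str  # functional class of the injected qualifying variants
    beta: float  # log-odds carrier effect
    carrier_freq: float = 0.02

    def __post_init__(self) -> None:
        if self.mask_class not in FUNCTIONAL_CLASSES:
            raise ConfigError(f"causal_genes: unknown mask class {self.mask_class!r}")
        if not 0 < self.carrier_freq < 0.5:
            raise ConfigError("causal_genes: carrier_freq must be in (0, 0.5)")


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds covariate effects on the binary trait."""

    age: float = 0.05  # per year, centred
    age2: float = -5e-4
    sex: float = 0.26  # male vs female
    pcs: tuple[float, ...] = (0.02,) * 10
    batch: tuple[float, ...] = (0.0, 0.05, -0.05)  # 50k / 200k / 450k


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 20_000
    n_genes: int = 500
    mean_variants_per_gene: float = 6.0
    maf_alpha: float = 1.0  # power-law exponent of the frequency spectrum
    maf_max: float = 1e-3  # spectrum truncated at MAF 0.1%
    singleton_fraction: float = 0.5
    depth_mean: float = 30.0
    depth_overdispersion: float = 10.0  # negative-binomial size parameter
    gq_mean: float = 75.0
    gq_sd: float = 20.0
    unbalanced_het_fraction: float = 0.02
    bad_call_fraction: float = 0.005
    indel_fraction: float = 0.1
    causal_genes: tuple[CausalGene, ...] = ()
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    baseline_prevalence: float = 0.077
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.mean_variants_per_gene < 1:
            raise ConfigError("mean_variants_per_gene must be >= 1")
        for name in ("singleton_fraction", "unbalanced_het_fraction",
                     "bad_call_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ConfigError("baseline_prevalence must be in (0, 1)")
        if not 0.0 < self.maf_max <= 0.5:
            raise ConfigError("maf_max must be in (0, 0.5]")
        if self.depth_mean <= 0 or self.depth_overdispersion <= 0:
            raise ConfigError("depth_model parameters must be positive")
        if self.gq_sd <= 0:
            raise ConfigError("gq_model sd must be positive")
        names = [g.gene for g in self.causal_genes]
        if len(names) != len(set(names)):
            raise ConfigError("causal_genes contains duplicate gene ids")


@dataclass(frozen=True)
class MRSimConfig:
    n_instruments: int = 784
    theta: float = 0.1  # causal effect per SD of exposure
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    reverse_causal_fraction: float = 0.0
    se_x: float = 0.003
    se_y: float = 0.01
    n_x: int = 428_525
    n_y: int = 893_130
    seed: int = 0

    def validate(self) -> None:
        if self.n_instruments < 1:
            raise ConfigError("n_instruments must be >= 1")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ConfigError("se_x/se_y must be positive")
        if not 0.0 <= self.reverse_causal_fraction <= 1.0:
            raise ConfigError("reverse_causal_fraction must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")


@dataclass
class GenotypeTable:
    """Dense variants x samples genotype matrix with read evidence."""

    samples: list[str]
    variant_ids: list[str]
    gt: np.ndarray  # int8
    dp: np.ndarray  # int16
    gq: np.ndarray  # int16
    ad_ref: np.ndarray  # int16
    ad_alt: np.ndarray  # int16

    @property
    def shape(self) -> tuple[int, int]:
        return self.gt.shape


# ---------------------------------------------------------------------------
# cohort generator


def _draw_mafs(rng: np.random.Generator, n: int, alpha: float, maf_min: float,
               maf_max: float) -> np.ndarray:
    """Inverse-CDF draw from a density proportional to f^-alpha on
    [maf_min, maf_max]; alpha=1 is the classical 1/f neutral spectrum."""
    u = rng.uniform(size=n)
    if abs(alpha - 1.0) < 1e-12:
        return maf_min * (maf_max / maf_min) ** u
    a = 1.0 - alpha
    return (maf_min**a + u * (maf_max**a - maf_min**a)) ** (1.0 / a)


def _consequence_for_class(rng: np.random.Generator, mask_class: str) -> dict:
    """Annotation fields for an injected causal-gene qualifying variant."""
    if mask_class == "HC_PTV":
        term = rng.choice(
            ["stop_gained", "frameshift_variant",
             "splice_acceptor_variant", "splice_donor_variant"]
        )
        return dict(consequence=str(term), revel=np.nan,
                    cadd=float(np.clip(rng.normal(38, 4), 0, 99)), loftee="HC")
    if mask_class == "missense_REVEL70":
        return dict(consequence="missense_variant",
                    revel=float(rng.uniform(0.7, 1.0)),
                    cadd=float(np.clip(rng.normal(28, 4), 0, 99)), loftee=None)
    if mask_class == "missense_REVEL50":
        return dict(consequence="missense_variant",
                    revel=float(rng.uniform(0.5, 1.0)),
                    cadd=float(np.clip(rng.normal(26, 4), 0, 99)), loftee=None)
    if mask_class == "damaging":
        return dict(consequence="missense_variant",
                    revel=float(rng.uniform(0.3, 1.0)),
                    cadd=float(rng.uniform(25, 45)), loftee=None)
    return dict(consequence="synonymous_variant", revel=np.nan,
                cadd=float(np.clip(rng.normal(5, 3), 0, 99)), loftee=None)


def _background_annotation(rng: np.random.Generator) -> dict:
    r = rng.uniform()
    if r < 0.10:  # PTV
        term = str(rng.choice(
            ["stop_gained", "frameshift_variant",
             "splice_acceptor_variant", "splice_donor_variant"]))
        loftee = "HC" if rng.uniform() < 0.85 else "LC"
        return dict(consequence=term, revel=np.nan,
                    cadd=float(np.clip(rng.normal(35, 5), 0, 99)), loftee=loftee)
    if r < 0.60:  # missense
        return dict(consequence="missense_variant",
                    revel=float(rng.beta(1.2, 1.8)),
                    cadd=float(np.clip(rng.normal(20, 7), 0, 99)), loftee=None)
    if r < 0.90:  # synonymous
        return dict(consequence="synonymous_variant", revel=np.nan,
                    cadd=float(np.clip(rng.normal(6, 3), 0, 99)), loftee=None)
    term = str(rng.choice(["intron_variant", "splice_region_variant",
                           "5_prime_UTR_variant"]))
    return dict(consequence=term, revel=np.nan,
                cadd=float(np.clip(rng.normal(8, 4), 0, 99)), loftee=None)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, GenotypeTable, pd.DataFrame, pd.DataFrame]:
    """Generate (variant table, genotype table, annotation table, covariates).

    Every variant's emitted AC/AN agrees exactly with its genotype matrix;
    singleton variants carry exactly one alt allele.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    samples = [f"S{i:06d}" for i in range(n)]
    genes = [f"GENE{i:04d}" for i in range(g)]
    causal_by_gene = {c.gene: c for c in config.causal_genes}
    for c in config.causal_genes:
        if c.gene not in set(genes):
            raise ConfigError(f"causal_genes: {c.gene} not among simulated genes")

    # --- variant layout ------------------------------------------------
    rows: list[dict] = []
    ann_rows: list[dict] = []
    maf_min = 1.0 / (2 * n)
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        base_pos = 1_000_000 + (gi // 22) * 100_000
        k = 1 + rng.poisson(max(config.mean_variants_per_gene - 1, 0))
        causal = causal_by_gene.get(gene)
        n_extra = 20 if causal is not None else 0
        for vi in range(k + n_extra):
            pos = base_pos + vi * 90 + int(rng.integers(0, 50))
            ref = str(rng.choice(_BASES))
            if rng.uniform() < config.indel_fraction:
                ins = "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
                alt = ref + ins  # simple insertion
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            vid = f"{chrom}:{pos}:{ref}:{alt}"
            injected = vi >= k
            if injected:
                maf = causal.carrier_freq / (2 * n_extra)
                singleton = False
                fields = _consequence_for_class(rng, causal.mask_class)
            else:
                singleton = rng.uniform() < config.singleton_fraction
                maf = maf_min if singleton else float(
                    _draw_mafs(rng, 1, config.maf_alpha, maf_min, config.maf_max)[0]
                )
                fields = _background_annotation(rng)
            rows.append(
                dict(variant_id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     gene=gene, maf_true=maf, singleton=singleton,
                     injected=injected)
            )
            tx = f"ENST{gi:05d}0"
            ann_rows.append(
                dict(variant_id=vid, gene=gene, transcript=tx,
                     protein_coding=True, mane_select=True, canonical=True,
                     protein_pos=int(rng.integers(1, 1500)), **fields)
            )
            if rng.uniform() < 0.2:  # extra non-coding transcript to prioritize away
                ann_rows.append(
                    dict(variant_id=vid, gene=gene, transcript=f"ENST{gi:05d}9",
                         protein_coding=False, mane_select=False, canonical=False,
                         consequence="non_coding_transcript_variant",
                         revel=np.nan, cadd=np.nan, loftee=None,
                         protein_pos=np.nan)
                )
    variants = pd.DataFrame(rows)
    v = len(variants)

    # --- genotypes -----------------------------------------------------
    gt = rng.binomial(
        2, np.asarray(variants["maf_true"])[:, None], size=(v, n)
    ).astype(np.int8)
    singleton_idx = np.flatnonzero(variants["singleton"].to_numpy())
    gt[singleton_idx, :] = 0
    carriers_of_singletons = rng.integers(0, n, size=len(singleton_idx))
    gt[singleton_idx, carriers_of_singletons] = HET

    # --- read evidence -------------------------------------------------
    r = config.depth_overdispersion
    p_nb = r / (r + config.depth_mean)
    dp = rng.negative_binomial(r, p_nb, size=(v, n)).astype(np.int16)
    gq = np.clip(rng.normal(config.gq_mean, config.gq_sd, size=(v, n)), 0, 99
                 ).astype(np.int16)
    bad = rng.uniform(size=(v, n)) < config.bad_call_fraction
    dp[bad] = rng.poisson(4, size=int(bad.sum())).astype(np.int16)
    gq[bad] = rng.integers(0, 25, size=int(bad.sum())).astype(np.int16)

    # background ref-error alt reads everywhere; carriers overwritten sparsely
    ad_alt = rng.binomial(dp.astype(np.int64), 0.002).astype(np.int16)
    het_r, het_c = np.nonzero(gt == HET)
    unbalanced = rng.uniform(size=het_r.size) < config.unbalanced_het_fraction
    frac = np.where(unbalanced, 0.12, 0.5)
    ad_alt[het_r, het_c] = rng.binomial(dp[het_r, het_c].astype(np.int64), frac)
    hom_r, hom_c = np.nonzero(gt == HOM_ALT)
    dph = dp[hom_r, hom_c].astype(np.int64)
    ad_alt[hom_r, hom_c] = (dph - rng.binomial(dph, 0.002)).astype(np.int16)
    ad_ref = (dp - ad_alt).astype(np.int16)

    gtab = GenotypeTable(samples, list(variants["variant_id"]), gt, dp, gq,
                         ad_ref, ad_alt)

    # emitted AC/AN recomputed from the genotypes themselves
    variants["ac"] = ((gt == HET).sum(axis=1) + 2 * (gt == HOM_ALT).sum(axis=1))
    variants["an"] = 2 * (gt != MISSING).sum(axis=1)
    variants["maf"] = variants["ac"] / variants["an"]

    annotations = pd.DataFrame(ann_rows)

    # --- covariates ----------------------------------------------------
    covariates = pd.DataFrame({"sample": samples})
    covariates["age"] = rng.normal(57, 8, size=n).round(1)
    covariates["sex"] = rng.binomial(1, 0.46, size=n)
    for i in range(10):
        covariates[f"pc{i + 1}"] = rng.normal(size=n)
    covariates["batch"] = rng.choice(BATCH_LEVELS, size=n, p=[0.1, 0.35, 0.55])

    return variants, gtab, annotations, covariates


# ---------------------------------------------------------------------------
# phenotypes


def covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept) from the covariate table:
    centred age, age^2, sex, pc1..pc10, batch dummies."""
    age_c = covariates["age"].to_numpy(float) - covariates["age"].mean()
    cols = {"age": age_c, "age2": age_c**2, "sex": covariates["sex"].to_numpy(float)}
    for i in range(10):
        cols[f"pc{i + 1}"] = covariates[f"pc{i + 1}"].to_numpy(float)
    for level in BATCH_LEVELS[1:]:
        cols[f"batch_{level}"] = (covariates["batch"] == level).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def _linear_predictor(
    carriers: dict[str, np.ndarray],
    covariates: pd.DataFrame,
    config: CohortConfig,
) -> np.ndarray:
    eff = config.covariate_effects
    X, names = covariate_design(covariates)
    beta = np.array(
        [eff.age, eff.age2, eff.sex, *eff.pcs, eff.batch[1], eff.batch[2]]
    )
    eta = X @ beta
    causal = {c.gene: c.beta for c in config.causal_genes}
    for gene, ind in carriers.items():
        b = causal.get(gene, 0.0)
        if b:
            eta = eta + b * np.asarray(ind, dtype=float)
    return eta


def calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(expit(c + eta)) equal to the target prevalence."""
    f = lambda c: float(np.mean(expit(c + eta))) - prevalence
    return brentq(f, -30.0, 10.0, xtol=1e-10)


def simulate_phenotypes(
    carriers: dict[str, np.ndarray],
    covariates: pd.DataFrame,
    config: CohortConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Binary disease + one quantitative trait from a logistic liability model.

    ``carriers`` maps gene id -> 0/1 indicator aligned to ``covariates``
    rows; genes without an entry in ``config.causal_genes`` contribute
    nothing. The logistic intercept is calibrated so the marginal
    prevalence matches ``config.baseline_prevalence``.
    """
    n = len(covariates)
    for gene, ind in carriers.items():
        if len(ind) != n:
            raise AlignmentError(
                f"carrier vector for {gene} has length {len(ind)}, expected {n}"
            )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    eta = _linear_predictor(carriers, covariates, config)
    c0 = calibrate_intercept(eta, config.baseline_prevalence)
    prob = expit(c0 + eta)
    disease = rng.binomial(1, prob).astype(np.int8)

    # quantitative companion trait: same carrier effects on an SD scale
    causal = {c.gene: c.beta for c in config.causal_genes}
    quant = 0.01 * (covariates["age"].to_numpy(float) - covariates["age"].mean())
    for gene, ind in carriers.items():
        b = causal.get(gene, 0.0)
        if b:
            quant = quant + 0.5 * b * np.asarray(ind, dtype=float)
    quant = quant + rng.normal(size=n)

    return pd.DataFrame(
        {"sample": covariates["sample"].to_numpy(), "t2d": disease, "quant": quant}
    )


# ---------------------------------------------------------------------------
# MR instruments


def simulate_mr_instruments(config: MRSimConfig) -> pd.DataFrame:
    """Instrument table with exposure and outcome effects.

    Ordinary instruments: beta_y = theta*beta_x_true + pleiotropy + noise.
    Reverse-causal instruments act on the outcome first (large true outcome
    effect, a small induced exposure effect), so their outcome variance
    explained exceeds their exposure variance explained. The table carries
    simulation-truth columns (``true_beta_x``, ``pleiotropy``, ``reverse``)
    for calibration checks; estimators ignore them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_instruments
    reverse = rng.uniform(size=m) < config.reverse_causal_fraction

    bx_true = (np.abs(rng.normal(0.02, 0.01, size=m)) + 0.01) * np.sign(
        rng.uniform(size=m) - 0.5
    )
    pleio = (
        rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=m)
        if (config.pleiotropy_mean or config.pleiotropy_sd)
        else np.zeros(m)
    )
    by_true = config.theta * bx_true + pleio

    # outcome-first structure for reverse-causal instruments
    gamma = rng.normal(0.15, 0.02, size=m) * np.sign(rng.uniform(size=m) - 0.5)
    bx_true = np.where(reverse, 0.3 * gamma, bx_true)
    by_true = np.where(reverse, gamma, by_true)

    beta_x = bx_true + rng.normal(0, config.se_x, size=m)
    beta_y = by_true + rng.normal(0, config.se_y, size=m)

    eaf = rng.uniform(0.05, 0.95, size=m)
    ea = rng.choice(_BASES, size=m)
    oa = np.array([rng.choice([b for b in "ACGT" if b != a]) for a in ea])

    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(m)],
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta_x": beta_x,
            "se_x": config.se_x,
            "n_x": config.n_x,
            "beta_y": beta_y,
            "se_y": config.se_y,
            "n_y": config.n_y,
            "true_beta_x": bx_true,
            "pleiotropy": pleio,
            "reverse": reverse,
        }
    )


def as_two_tables(
    instruments: pd.DataFrame, flip_fraction: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an instrument table into exposure/outcome GWAS tables, with a
    fraction of outcome rows reported on the opposite allele, for
    harmonization round-trips."""
    rng = np.random.default_rng(seed)
    exp = instruments[["snp", "ea", "oa", "eaf", "beta_x", "se_x", "n_x"]].rename(
        columns={"beta_x": "beta", "se_x": "se", "n_x": "n"}
    )
    out = instruments[["snp", "ea", "oa", "eaf", "beta_y", "se_y", "n_y"]].rename(
        columns={"beta_y": "beta", "se_y": "se", "n_y": "n"}
    ).copy()
    flip = rng.uniform(size=len(out)) < flip_fraction
    out.loc[flip, ["ea", "oa"]] = out.loc[flip, ["oa", "ea"]].to_numpy()
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    return exp.reset_index(drop=True), out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# colocalization locus


def simulate_coloc_locus(
    n_snps: int,
    shared: bool,
    effect1: float = 8.0,
    effect2: float = 8.0,
    seed: int = 0,
    se1: float = 0.03,
    se2: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two summary-statistic tracks over one locus (no LD).

    ``effect*`` are causal-SNP z-scores; zero effects give a null locus.
    shared=True drives both tracks from the same causal index SNP,
    shared=False from two distinct ones.
    """
    if n_snps < 2:
        raise ConfigError("n_snps must be >= 2")
    rng = np.random.default_rng(seed)
    snps = [f"rs{i + 1:05d}" for i in range(n_snps)]
    idx1 = int(rng.integers(0, n_snps))
    if shared:
        idx2 = idx1
    else:
        idx2 = int(rng.integers(0, n_snps - 1))
        if idx2 >= idx1:
            idx2 += 1
    z1 = rng.normal(size=n_snps)
    z2 = rng.normal(size=n_snps)
    if effect1:
        z1[idx1] += effect1
    if effect2:
        z2[idx2] += effect2
    t1 = pd.DataFrame({"snp": snps, "beta": z1 * se1, "se": se1})
    t2 = pd.DataFrame({"snp": snps, "beta": z2 * se2, "se": se2})
    return t1, t2, {"causal1": idx1, "causal2": idx2}
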