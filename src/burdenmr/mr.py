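"""Two-sample Mendelian randomization estimators on summary statistics.

Instruments are harmonized so the effect allele is the exposure-increasing
allele (beta_x >= 0), with outcome effects sign-flipped when allele labels
are swapped and ambiguous palindromic SNPs dropped. Estimators:

* Wald ratio per instrument: theta_j = beta_y/beta_x with first-order
  SE = se_y/|beta_x|;
* IVW: inverse-variance weighted meta-analysis of Wald ratios (weights
  beta_x^2/se_y^2), with a multiplicative random-effects SE inflation
  sqrt(Q/df) when Cochran's Q exceeds its degrees of freedom;
* MR-Egger: weighted regression of beta_y on beta_x with a free intercept
  (the intercept tests directional pleiotropy);
* weighted median / penalised weighted median, with parametric-bootstrap
  standard errors;
* radial outlier filtering on per-instrument Q contributions;
* Steiger filtering of instruments explaining more outcome than exposure
  variance;
* multivariable MR (direct effect adjusting for co-exposures).

Heterogeneity is reported as Cochran's Q and I^2 = max(0, (Q-df)/Q)*100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, NumericalError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

INSTRUMENT_COLUMNS = (
    "snp", "ea", "oa", "eaf", "beta_x", "se_x", "n_x", "beta_y", "se_y", "n_y"
)

#: per-SD rescaling for the exposure (one SD of circulating IGF-1 is about
#: 5.5 nmol/L in UK Biobank); used when converting per-unit effects.
DEFAULT_SD_UNITS = 5.5


@dataclass
class MRResult:
    method: str
    theta: float
    se: float
    p: float
    n_instruments: int
    q: float = np.nan
    i2: float = np.nan  # percent
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan
    excluded: list = field(default_factory=list)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    def ci(self) -> tuple[float, float]:
        return self.theta - 1.96 * self.se, self.theta + 1.96 * self.se


def _check(records: pd.DataFrame, minimum: int, method: str) -> pd.DataFrame:
    if len(records) < minimum:
        raise DataError(f"{method} requires >= {minimum} instruments, got {len(records)}")
    if (records["se_y"] <= 0).any() or (records["se_x"] <= 0).any():
        raise DataError(f"{method}: non-positive standard errors")
    return records


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_window: tuple[float, float] = (0.42, 0.58),
    proxy_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge exposure/outcome GWAS tables into harmonized instruments.

    Both tables use columns (snp, ea, oa, eaf, beta, se, n). Outcome rows
    whose alleles are swapped relative to the exposure get their beta
    sign-flipped (and EAF complemented); strand flips are resolved by
    complementing; irreconcilable allele sets are dropped with a reason, as
    are palindromic (A/T, C/G) SNPs with exposure EAF inside the ambiguity
    window. Records are finally oriented so beta_x >= 0 (the
    exposure-increasing allele is the effect allele).

    ``proxy_map`` renames outcome SNP ids (pre-resolved LD proxies) before
    merging. Returns (instrument table, dropped table with reasons).
    """
    out = outcome.copy()
    if proxy_map:
        out["snp"] = out["snp"].replace(proxy_map)
    merged = exposure.merge(out, on="snp", suffixes=("_x", "_y"), how="inner")
    lo, hi = palindromic_window
    kept: list[dict] = []
    dropped: list[dict] = []
    for row in merged.itertuples(index=False):
        ea_x, oa_x = row.ea_x.upper(), row.oa_x.upper()
        ea_y, oa_y = row.ea_y.upper(), row.oa_y.upper()
        beta_y, eaf_y = row.beta_y, row.eaf_y
        if (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            c_ea = _COMPLEMENT.get(ea_y, "?")
            c_oa = _COMPLEMENT.get(oa_y, "?")
            if (c_ea, c_oa) == (ea_x, oa_x):
                pass
            elif (c_ea, c_oa) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            else:
                dropped.append({"snp": row.snp, "reason": "irreconcilable_alleles"})
                continue
        if _is_palindromic(ea_x, oa_x) and lo <= row.eaf_x <= hi:
            dropped.append({"snp": row.snp, "reason": "palindromic_ambiguous"})
            continue
        ea, oa, eaf_x, beta_x = ea_x, oa_x, row.eaf_x, row.beta_x
        if beta_x < 0:  # orient to the exposure-increasing allele
            ea, oa = oa, ea
            eaf_x, eaf_y = 1.0 - eaf_x, 1.0 - eaf_y
            beta_x, beta_y = -beta_x, -beta_y
        kept.append(
            dict(snp=row.snp, ea=ea, oa=oa, eaf=eaf_x,
                 beta_x=beta_x, se_x=row.se_x, n_x=row.n_x,
                 beta_y=beta_y, se_y=row.se_y, n_y=row.n_y)
        )
    instruments = pd.DataFrame(kept, columns=list(INSTRUMENT_COLUMNS))
    drops = pd.DataFrame(dropped, columns=["snp", "reason"])
    return instruments, drops


# ---------------------------------------------------------------------------
# estimators


def wald_ratio(beta_x: float, beta_y: float, se_y: float) -> tuple[float, float]:
    """Per-instrument causal estimate beta_y/beta_x, first-order SE."""
    if beta_x == 0:
        raise DataError("Wald ratio undefined for beta_x = 0")
    return beta_y / beta_x, se_y / abs(beta_x)


def _ratios(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = records["beta_x"].to_numpy(float)
    if np.any(bx == 0):
        raise DataError("instrument with beta_x = 0; Wald ratio undefined")
    by = records["beta_y"].to_numpy(float)
    sey = records["se_y"].to_numpy(float)
    return by / bx, sey / np.abs(bx)


def cochran_q(records: pd.DataFrame, theta: float) -> tuple[float, np.ndarray]:
    """Cochran's Q at ``theta`` and its per-instrument contributions."""
    ratios, ratio_se = _ratios(records)
    w = 1.0 / ratio_se**2  # equals beta_x^2/se_y^2
    qj = w * (ratios - theta) ** 2
    return float(qj.sum()), qj


def ivw(records: pd.DataFrame) -> MRResult:
    """Inverse-variance weighted estimate; the primary MR model.

    The fixed-effect SE is inflated by sqrt(Q/df) when Q/df > 1
    (multiplicative random effects). A single instrument reduces exactly
    to its Wald ratio (Q undefined).
    """
    records = _check(records, 1, "ivw")
    bx = records["beta_x"].to_numpy(float)
    by = records["beta_y"].to_numpy(float)
    sey = records["se_y"].to_numpy(float)
    if np.any(bx == 0):
        raise DataError("ivw: instrument with beta_x = 0")
    w = bx**2 / sey**2
    theta = float(np.sum(bx * by / sey**2) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    n = len(records)
    q, _ = cochran_q(records, theta)
    df = n - 1
    i2 = np.nan
    if df > 0:
        if q / df > 1:
            se *= float(np.sqrt(q / df))
        i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(theta) / se))
    return MRResult("IVW", theta, se, p, n, q=q if df > 0 else np.nan, i2=i2)


def egger(records: pd.DataFrame) -> MRResult:
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    The slope is the pleiotropy-corrected causal estimate; a non-zero
    intercept indicates directional (unbalanced) pleiotropy. Inference uses
    the t distribution with n-2 df, as in the originating implementation.
    """
    records = _check(records, 3, "egger")
    bx = records["beta_x"].to_numpy(float)
    by = records["beta_y"].to_numpy(float)
    w = 1.0 / records["se_y"].to_numpy(float) ** 2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    n = len(records)
    resid_q = float(np.sum(w * fit.resid**2))
    df = n - 2
    i2 = max(0.0, (resid_q - df) / resid_q) * 100 if resid_q > 0 else 0.0
    # WLS bse already scale the weighted residual variance in; floor the
    # overdispersion factor at 1 (no credit for underdispersion)
    inflate = 1.0 if (fit.scale >= 1.0 or fit.scale <= 0) else 1.0 / np.sqrt(fit.scale)
    se_slope = float(fit.bse[1]) * inflate
    se_inter = float(fit.bse[0]) * inflate
    theta = float(fit.params[1])
    p = float(2 * stats.t.sf(abs(theta) / se_slope, df))
    return MRResult(
        "Egger", theta, se_slope, p, n, q=resid_q, i2=i2,
        intercept=float(fit.params[0]), intercept_se=se_inter,
        intercept_p=float(2 * stats.t.sf(abs(fit.params[0] / se_inter), df)),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    t, wt = theta[order], w[order]
    s = (np.cumsum(wt) - 0.5 * wt) / wt.sum()
    if s[0] >= 0.5:
        return float(t[0])
    if s[-1] < 0.5:
        return float(t[-1])
    k = int(np.searchsorted(s, 0.5, side="left"))
    if s[k] == 0.5 and k + 1 < len(t):
        # interpolate through the exact crossing
        return float(t[k])
    k0 = k - 1
    return float(t[k0] + (t[k] - t[k0]) * (0.5 - s[k0]) / (s[k] - s[k0]))


def _penalised_weights(
    ratios: np.ndarray, ratio_se: np.ndarray, theta_ref: float, penalty: float
) -> np.ndarray:
    w = 1.0 / ratio_se**2
    qj = w * (ratios - theta_ref) ** 2
    pj = stats.chi2.sf(qj, 1)
    return w * np.minimum(1.0, penalty * pj)


def weighted_median(
    records: pd.DataFrame,
    penalised: bool = False,
    penalty: float = 20.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted median of Wald ratios; robust to <50% invalid instruments.

    Weights are the inverse variances of the per-instrument ratios; the
    penalised variant multiplies them by min(1, penalty * q_j) with q_j the
    chi^2_1 upper-tail p of the instrument's standardized deviation from
    the IVW estimate. SE comes from a parametric bootstrap (fixed seed).
    """
    records = _check(records, 3, "weighted_median")
    ratios, ratio_se = _ratios(records)
    theta_ivw = ivw(records).theta

    def estimate(r: np.ndarray, rse: np.ndarray) -> float:
        if penalised:
            w = _penalised_weights(r, rse, theta_ivw, penalty)
            if not np.any(w > 0):
                w = 1.0 / rse**2
        else:
            w = 1.0 / rse**2
        return _weighted_median(r, w)

    theta = estimate(ratios, ratio_se)
    rng = np.random.default_rng(seed)
    bx = records["beta_x"].to_numpy(float)
    sx = records["se_x"].to_numpy(float)
    by = records["beta_y"].to_numpy(float)
    sy = records["se_y"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.normal(0, sx)
        by_b = by + rng.normal(0, sy)
        bx_b[bx_b == 0] = 1e-300
        boots[b] = estimate(by_b / bx_b, sy / np.abs(bx_b))
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(theta) / se)) if se > 0 else np.nan
    method = "PWM" if penalised else "WM"
    return MRResult(method, theta, se, p, len(records))


def radial_filter(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Iterative radial outlier exclusion.

    Each round fits IVW, computes per-instrument Q contributions, and drops
    instruments whose chi^2_1 upper-tail p falls below alpha/n (Bonferroni
    within the round); repeats until stable. The procedure is idempotent on
    its own output.
    """
    current = _check(records, 3, "radial_filter").reset_index(drop=True)
    excluded: list[str] = []
    while True:
        if len(current) == 0:
            raise NumericalError("radial_filter excluded every instrument")
        theta = ivw(current).theta
        _, qj = cochran_q(current, theta)
        pj = stats.chi2.sf(qj, 1)
        bad = pj < alpha / len(current)
        if not bad.any():
            return current, excluded
        excluded.extend(current.loc[bad, "snp"].tolist())
        current = current.loc[~bad].reset_index(drop=True)


def steiger_filter(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], int]:
    """Drop instruments explaining more outcome than exposure variance.

    Variance explained is 2*EAF*(1-EAF)*beta^2 on standardized traits.
    Ties are retained. Instruments missing EAF or sample size pass through
    untested; their count is returned as the warning tally.
    """
    if len(records) == 0:
        raise DataError("steiger_filter: empty instrument table")
    eaf = records["eaf"].to_numpy(float)
    nx = records["n_x"].to_numpy(float)
    ny = records["n_y"].to_numpy(float)
    testable = np.isfinite(eaf) & np.isfinite(nx) & np.isfinite(ny)
    het = 2 * eaf * (1 - eaf)
    r2_x = het * records["beta_x"].to_numpy(float) ** 2
    r2_y = het * records["beta_y"].to_numpy(float) ** 2
    drop = testable & (r2_y > r2_x)
    retained = records.loc[~drop].reset_index(drop=True)
    return retained, records.loc[drop, "snp"].tolist(), int((~testable).sum())


def mvmr(
    records: pd.DataFrame,
    exposure_cols: tuple[str, ...] = ("beta_x", "beta_bmi", "beta_height"),
    primary: str = "beta_x",
) -> MRResult:
    """Multivariable MR: direct effect of the primary exposure.

    Weighted least squares of beta_y on all exposure-effect columns with no
    intercept, weights 1/se_y^2; the coefficient on ``primary`` is the
    direct effect adjusted for the co-exposures.
    """
    if primary not in exposure_cols:
        raise DataError(f"primary column {primary!r} not in exposure_cols")
    k = len(exposure_cols)
    records = _check(records, k + 1, "mvmr")
    X = records[list(exposure_cols)].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        collinear = [
            c for i, c in enumerate(exposure_cols)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise NumericalError(f"mvmr: collinear exposure columns {collinear}")
    by = records["beta_y"].to_numpy(float)
    w = 1.0 / records["se_y"].to_numpy(float) ** 2
    fit = sm.WLS(by, X, weights=w).fit()
    i = list(exposure_cols).index(primary)
    theta, se = float(fit.params[i]), float(fit.bse[i])
    df = len(records) - k
    p = float(2 * stats.t.sf(abs(theta) / se, df))
    resid_q = float(np.sum(w * fit.resid**2))
    i2 = max(0.0, (resid_q - df) / resid_q) * 100 if resid_q > 0 else 0.0
    return MRResult("MVMR", theta, se, p, len(records), q=resid_q, i2=i2)


def rescale(result: MRResult, factor: float) -> MRResult:
    """Rescale an additive estimate (e.g. per-unit -> per-SD with
    factor = SD in trait units, default 5.5)."""
    return MRResult(
        result.method, result.theta * factor, result.se * factor, result.p,
        result.n_instruments, q=result.q, i2=result.i2,
        intercept=result.intercept, intercept_se=result.intercept_se,
        intercept_p=result.intercept_p, excluded=list(result.excluded),
    )


def mr_suite(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """All estimators on one harmonized instrument table, one row each."""
    out = []
    for res in (
        ivw(records),
        egger(records),
        weighted_median(records, penalised=False, seed=seed),
        weighted_median(records, penalised=True, seed=seed),
    ):
        lo, hi = res.ci()
        out.append(
            dict(method=res.method, theta=res.theta, se=res.se, p=res.p,
                 odds_ratio=res.odds_ratio, ci_low=lo, ci_high=hi,
                 n_instruments=res.n_instruments, q=res.q, i2=res.i2,
                 intercept=res.intercept, intercept_p=res.intercept_p)
        )
    return pd.DataFrame(out)
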