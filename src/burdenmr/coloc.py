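"""Bayes-factor colocalization of two association tracks over a locus.

For each SNP an asymptotic (Wakefield) Bayes factor against the null is
computed from its effect estimate and standard error under a N(0, W^2)
effect-size prior, and the five locus hypotheses are scored by summing
Bayes-factor products in log space:

* H0 - no causal variant for either trait,
* H1/H2 - a causal variant for one trait only,
* H3 - two distinct causal variants,
* H4 - one shared causal variant.

Per-SNP prior probabilities default to p1 = p2 = 1e-4 (causal for one
trait) and p12 = 1e-5 (shared causal), the conventional single-causal-
variant defaults; the prior effect SD W defaults to 0.15 for quantitative
and 0.2 for case-control tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DataError

PRIOR_SD = {"quantitative": 0.15, "case-control": 0.2}
HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")


@dataclass
class ColocResult:
    pp: np.ndarray  # posteriors over H0..H4, sums to 1
    snp_pp_h4: pd.Series  # per-SNP posterior of being the shared causal SNP
    priors: tuple[float, float, float]
    n_snps: int

    def __getitem__(self, key: str) -> float:
        return float(self.pp[HYPOTHESES.index(key)])

    def as_dict(self) -> dict[str, float]:
        return {h: float(v) for h, v in zip(HYPOTHESES, self.pp)}


def log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Log asymptotic Bayes factor for association at one SNP.

    log ABF = 0.5*log(se^2/(se^2+W^2)) + 0.5*z^2*W^2/(se^2+W^2), z=beta/se.
    Larger-than-null |z| gives log ABF > 0; W -> 0 recovers log ABF -> 0.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DataError("log_abf: standard errors must be positive")
    if prior_sd <= 0:
        raise DataError("log_abf: prior SD must be positive")
    z = beta / se
    shrink = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-shrink) + 0.5 * z**2 * shrink


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)); b can exceed a only by rounding, giving -inf."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    track1: pd.DataFrame,
    track2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    trait1: str = "quantitative",
    trait2: str = "quantitative",
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities PP0-PP4 from two summary-statistic tracks.

    Tracks carry columns (snp, beta, se) and are intersected on SNP id;
    accumulation is in log space, so loci with very large |z| remain
    finite. Posteriors sum to one by construction.
    """
    for p, name in ((p1, "p1"), (p2, "p2"), (p12, "p12")):
        if not 0 < p < 1:
            raise DataError(f"{name} must be in (0, 1)")
    merged = track1.merge(track2, on="snp", suffixes=("_1", "_2"))
    if len(merged) < 2:
        raise DataError("coloc: fewer than 2 shared SNPs between tracks")
    w1 = prior_sd1 if prior_sd1 is not None else PRIOR_SD[trait1]
    w2 = prior_sd2 if prior_sd2 is not None else PRIOR_SD[trait2]
    l1 = log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w1)
    l2 = log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w2)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lh = np.array(
        [
            0.0,  # H0
            np.log(p1) + s1,  # H1
            np.log(p2) + s2,  # H2
            np.log(p1) + np.log(p2) + _logdiffexp(s1 + s2, s12),  # H3
            np.log(p12) + s12,  # H4
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    snp_pp = np.exp(l1 + l2 - s12)
    snp_pp /= snp_pp.sum()
    return ColocResult(
        pp=pp,
        snp_pp_h4=pd.Series(snp_pp, index=merged["snp"], name="snp_pp_h4"),
        priors=(p1, p2, p12),
        n_snps=len(merged),
    )
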