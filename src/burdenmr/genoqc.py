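"""Variant normalization and genotype-level quality control.

Implements the exome QC stage of a rare-variant burden pipeline:

* multi-allelic records are split into biallelic ones and indels are
  left-aligned to their minimal representation;
* genotypes failing read-depth / genotype-quality thresholds are set to
  missing (SNVs: DP < 7 and GQ < 20; indels: DP < 10 and GQ < 20);
* heterozygous SNV calls are tested for 50% alternate-allele contribution
  with an exact two-sided binomial test (calls with p <= 1e-3 set missing);
* per-variant missingness is recomputed after genotype filtering and
  variants with missingness strictly above 50% are dropped.

Genotypes are coded as int8: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DataError

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

# QC thresholds: genotypes with depth below the type-specific minimum AND
# genotype quality below 20 are set to missing ("and" is the literal rule;
# "or" is offered because the disjunctive reading is common practice).
SNV_MIN_DP = 7
INDEL_MIN_DP = 10
MIN_GQ = 20
ALLELE_BALANCE_ALPHA = 1e-3
MAX_MISSINGNESS = 0.5

Gate = Literal["and", "or"]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x variant call with its read evidence.

    ``ad`` is (ref reads, alt reads). Real callers emit AD sums that can
    disagree with DP, so no AD<=DP invariant is enforced.
    """

    sample: str
    gt: int  # HOM_REF / HET / HOM_ALT / MISSING
    dp: int
    gq: int
    ad: tuple[int, int]

    def __post_init__(self) -> None:
        if self.gt != MISSING and (self.dp < 0 or self.gq < 0):
            raise DataError(
                f"negative DP/GQ ({self.dp}, {self.gq}) for sample {self.sample}"
            )


@dataclass(frozen=True)
class NormalizedVariant:
    """A biallelic, minimally represented variant site."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    ac: int = 0
    an: int = 0
    missingness: float = 0.0

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "InDel"

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


# ---------------------------------------------------------------------------
# normalization


def _normalize_allele_pair(
    pos: int, ref: str, alt: str, seq: str, seq_start: int
) -> tuple[int, str, str]:
    """Trim and left-shift one ref/alt pair to minimal leftmost form.

    ``seq`` is the reference context starting at 1-based ``seq_start``.
    The loop is the standard normalization recurrence: truncate shared
    trailing bases (extending left from the reference when an allele
    would empty), then truncate shared leading bases.
    """
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos <= seq_start:
                    break  # cannot extend further left
                pos -= 1
                base = seq[pos - seq_start]
                ref = base + ref[:-1]
                alt = base + alt[:-1]
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return pos, ref, alt


def split_and_left_align(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    ref_seq: str,
    seq_start: int = 1,
    acs: Sequence[int] | None = None,
    an: int = 0,
) -> list[NormalizedVariant]:
    """Split a (possibly multi-allelic) record into normalized biallelic ones.

    Parameters
    ----------
    ref_seq : reference context covering the site, starting at ``seq_start``
        (1-based).  Needed to left-shift indels through repeats.
    acs : per-alt allele counts, carried through unchanged.
    """
    if not ref or not alts:
        raise DataError(f"{chrom}:{pos}: empty REF/ALT")
    offset = pos - seq_start
    if offset < 0 or offset + len(ref) > len(ref_seq):
        raise DataError(f"{chrom}:{pos}: reference context does not cover site")
    if ref_seq[offset : offset + len(ref)].upper() != ref.upper():
        raise DataError(
            f"{chrom}:{pos}: REF {ref} inconsistent with reference context"
        )
    if acs is not None and len(acs) != len(alts):
        raise DataError(f"{chrom}:{pos}: {len(acs)} ACs for {len(alts)} alts")
    out = []
    for i, alt in enumerate(alts):
        if alt == ref:
            raise DataError(f"{chrom}:{pos}: ALT equals REF")
        npos, nref, nalt = _normalize_allele_pair(pos, ref, alt, ref_seq, seq_start)
        out.append(
            NormalizedVariant(
                chrom, npos, nref, nalt, ac=acs[i] if acs is not None else 0, an=an
            )
        )
    return out


# ---------------------------------------------------------------------------
# genotype filtering


def filter_genotype(
    call: GenotypeCall,
    vtype: str,
    gate: Gate = "and",
    min_dp_snv: int = SNV_MIN_DP,
    min_dp_indel: int = INDEL_MIN_DP,
    min_gq: int = MIN_GQ,
) -> GenotypeCall:
    """Return ``call`` with genotype set missing if it fails DP/GQ thresholds.

    Pure function; passing calls are returned unchanged (same object).
    """
    if vtype not in ("SNV", "InDel"):
        raise DataError(f"unknown variant type {vtype!r}")
    if call.gt == MISSING:
        return call
    min_dp = min_dp_snv if vtype == "SNV" else min_dp_indel
    low_dp = call.dp < min_dp
    low_gq = call.gq < min_gq
    fails = (low_dp and low_gq) if gate == "and" else (low_dp or low_gq)
    if fails:
        return replace(call, gt=MISSING)
    return call


def filter_genotypes(
    gt: np.ndarray,
    dp: np.ndarray,
    gq: np.ndarray,
    is_indel: np.ndarray,
    gate: Gate = "and",
    min_dp_snv: int = SNV_MIN_DP,
    min_dp_indel: int = INDEL_MIN_DP,
    min_gq: int = MIN_GQ,
) -> np.ndarray:
    """Vectorized DP/GQ filter over a variants x samples genotype matrix.

    ``is_indel`` is a per-variant boolean vector. Returns a new genotype
    matrix with failing calls set to MISSING.
    """
    if gate not in ("and", "or"):
        raise DataError(f"unknown QC gate {gate!r}")
    if np.any((dp < 0) | (gq < 0)):
        raise DataError("negative DP/GQ in genotype table")
    min_dp = np.where(np.asarray(is_indel)[:, None], min_dp_indel, min_dp_snv)
    low_dp = dp < min_dp
    low_gq = gq < min_gq
    fails = (low_dp & low_gq) if gate == "and" else (low_dp | low_gq)
    out = gt.copy()
    out[fails & (gt != MISSING)] = MISSING
    return out


def allele_balance_p(alt_reads: int, total_reads: int) -> float:
    """Exact two-sided binomial p for alt-read balance at p=0.5.

    Two-sided in the minimum-likelihood sense: sum of P(X=j) over all j with
    pmf(j) <= pmf(observed). For the symmetric p=0.5 binomial this equals
    2*P(X <= min(k, n-k)) (and exactly 1 when 2k = n), which is what is
    computed here.
    """
    if total_reads < 1:
        raise DataError("allele-balance test undefined for zero total reads")
    if not 0 <= alt_reads <= total_reads:
        raise DataError(f"alt reads {alt_reads} outside [0, {total_reads}]")
    if 2 * alt_reads == total_reads:
        return 1.0
    kmin = min(alt_reads, total_reads - alt_reads)
    return float(min(1.0, 2.0 * stats.binom.cdf(kmin, total_reads, 0.5)))


def allele_balance_p_vec(alt_reads: np.ndarray, total_reads: np.ndarray) -> np.ndarray:
    """Vectorized :func:`allele_balance_p`; entries with zero total get NaN."""
    alt = np.asarray(alt_reads, dtype=np.int64)
    tot = np.asarray(total_reads, dtype=np.int64)
    kmin = np.minimum(alt, tot - alt)
    with np.errstate(invalid="ignore"):
        p = np.minimum(1.0, 2.0 * stats.binom.cdf(kmin, np.maximum(tot, 1), 0.5))
    p = np.where(2 * alt == tot, 1.0, p)
    return np.where(tot < 1, np.nan, p)


def apply_allele_balance(
    gt: np.ndarray,
    ad_ref: np.ndarray,
    ad_alt: np.ndarray,
    is_indel: np.ndarray,
    alpha: float = ALLELE_BALANCE_ALPHA,
) -> np.ndarray:
    """Set het SNV genotypes with binomial allele-balance p <= alpha missing.

    Applies only to heterozygous SNV calls; het indel calls are untested.
    Het calls with zero informative reads are left untouched (no evidence
    either way).
    """
    target = (gt == HET) & ~np.asarray(is_indel)[:, None]
    out = gt.copy()
    rows, cols = np.nonzero(target)  # het SNVs are sparse; test only those
    if rows.size == 0:
        return out
    alt = ad_alt[rows, cols].astype(np.int64)
    total = alt + ad_ref[rows, cols].astype(np.int64)
    ok = total >= 1
    p = allele_balance_p_vec(alt[ok], total[ok])
    fail = p <= alpha
    out[rows[ok][fail], cols[ok][fail]] = MISSING
    return out


def variant_missingness(gt: np.ndarray) -> np.ndarray:
    """Per-variant fraction of missing genotypes."""
    if gt.shape[1] == 0:
        raise DataError("missingness undefined with zero samples")
    return (gt == MISSING).mean(axis=1)


def apply_variant_missingness(
    gt: np.ndarray, max_missingness: float = MAX_MISSINGNESS
) -> tuple[np.ndarray, np.ndarray]:
    """Keep/drop decision per variant after genotype filtering.

    Returns (keep mask, missingness). A variant is dropped iff its
    missingness is strictly greater than ``max_missingness``.
    """
    miss = variant_missingness(gt)
    return miss <= max_missingness, miss


def allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recompute (AC, AN) per variant from a genotype matrix."""
    called = gt != MISSING
    ac = (gt == HET).sum(axis=1) + 2 * (gt == HOM_ALT).sum(axis=1)
    an = 2 * called.sum(axis=1)
    return ac.astype(np.int64), an.astype(np.int64)


def minor_allele_frequency(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    """MAF per variant; AN=0 yields NaN."""
    an = np.asarray(an, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.asarray(ac, dtype=float) / an
    maf = np.minimum(af, 1.0 - af)
    return np.where(an > 0, maf, np.nan)
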