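"""Transcript/consequence prioritization and collapsing-mask assignment.

A variant annotated against several transcripts is reduced to a single
annotation: transcripts are ranked protein-coding > MANE-select > canonical
(lowest transcript id breaks remaining ties), and among consequence terms
the most severe wins, using a fixed severity ranking shipped with the
package (``data/consequence_severity.tsv``).

Consequence classes: stop-gained, frameshift and splice acceptor/donor
variants form the protein-truncating (PTV) class; missense and synonymous
are kept as named; everything else is "other".

Collapsing masks cross a functional class with a frequency stratum:

========================  =====================================================
functional class          rule
========================  =====================================================
HC_PTV                    PTV with LOFTEE high-confidence flag
missense_REVEL50          missense with REVEL >= 0.5
missense_REVEL70          missense with REVEL >= 0.7
synonymous                synonymous (negative control)
damaging                  missense with CADD >= 25, or HC PTV
========================  =====================================================

frequency strata: ``MAF_lt_0.1pct`` (MAF < 0.001) and ``singleton`` (AC = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError

PTV_TERMS = frozenset(
    {"stop_gained", "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant"}
)

FUNCTIONAL_CLASSES = (
    "HC_PTV",
    "missense_REVEL50",
    "missense_REVEL70",
    "synonymous",
    "damaging",
)
FREQUENCY_CLASSES = ("MAF_lt_0.1pct", "singleton")

RARE_MAF = 1e-3
CADD_DAMAGING = 25.0


def _load_severity() -> dict[str, int]:
    path = resources.files("burdenmr.data") / "consequence_severity.tsv"
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["term"], table["rank"]))


SEVERITY_RANK: dict[str, int] = _load_severity()


@dataclass(frozen=True)
class AnnotationRecord:
    """One transcript-level annotation of one variant."""

    variant_id: str
    gene: str
    transcript: str
    is_protein_coding: bool
    is_mane_select: bool
    is_canonical: bool
    consequence: str
    revel: float | None = None  # missense only
    cadd: float | None = None
    loftee: str | None = None  # "HC"/"LC", PTV-class only
    protein_pos: int | None = None


@dataclass(frozen=True)
class MaskSpec:
    """A collapsing mask: functional class x frequency stratum."""

    name: str
    functional: str
    frequency: str

    def __post_init__(self) -> None:
        if self.functional not in FUNCTIONAL_CLASSES:
            raise DataError(f"unknown functional class {self.functional!r}")
        if self.frequency not in FREQUENCY_CLASSES:
            raise DataError(f"unknown frequency class {self.frequency!r}")


def default_masks() -> list[MaskSpec]:
    """The default mask set: 5 functional x 2 frequency classes."""
    return [
        MaskSpec(f"{f}-{q}", f, q)
        for f in FUNCTIONAL_CLASSES
        for q in FREQUENCY_CLASSES
    ]


def prioritize_transcript(records: Sequence[AnnotationRecord]) -> AnnotationRecord:
    """Pick the single annotation to keep for a variant.

    Lexicographic priority protein-coding > MANE-select > canonical; ties
    broken deterministically by lowest transcript id, so the result is
    independent of input order.
    """
    if not records:
        raise DataError("prioritize_transcript: no annotation records")
    return min(
        records,
        key=lambda r: (
            not r.is_protein_coding,
            not r.is_mane_select,
            not r.is_canonical,
            r.transcript,
        ),
    )


def severity_rank(term: str) -> int:
    try:
        return SEVERITY_RANK[term]
    except KeyError:
        raise DataError(f"unknown consequence term {term!r}") from None


def prioritize_consequence(terms: Iterable[str]) -> str:
    """Most severe consequence term under the shipped severity ranking."""
    terms = list(terms)
    if not terms:
        raise DataError("prioritize_consequence: no terms")
    return min(terms, key=severity_rank)


def classify_class(term: str) -> str:
    """Collapse a consequence term to {PTV, missense, synonymous, other}."""
    severity_rank(term)  # validates
    if term in PTV_TERMS:
        return "PTV"
    if term == "missense_variant":
        return "missense"
    if term == "synonymous_variant":
        return "synonymous"
    return "other"


@dataclass
class MaskDiagnostics:
    """Tally of variants skipped because a required score was absent."""

    missing_revel: int = 0
    missing_cadd: int = 0
    missing_loftee: int = 0

    def total(self) -> int:
        return self.missing_revel + self.missing_cadd + self.missing_loftee


def _functional_member(
    var_class: str,
    revel: float | None,
    cadd: float | None,
    loftee: str | None,
    functional: str,
    diag: MaskDiagnostics,
) -> bool:
    if functional == "HC_PTV":
        if var_class != "PTV":
            return False
        if loftee is None:
            diag.missing_loftee += 1
            return False
        return loftee == "HC"
    if functional in ("missense_REVEL50", "missense_REVEL70"):
        if var_class != "missense":
            return False
        if revel is None:
            diag.missing_revel += 1
            return False
        return revel >= (0.5 if functional == "missense_REVEL50" else 0.7)
    if functional == "synonymous":
        return var_class == "synonymous"
    if functional == "damaging":
        if var_class == "PTV":
            if loftee is None:
                diag.missing_loftee += 1
                return False
            return loftee == "HC"
        if var_class == "missense":
            if cadd is None:
                diag.missing_cadd += 1
                return False
            return cadd >= CADD_DAMAGING
        return False
    raise DataError(f"unknown functional class {functional!r}")


def mask_membership(
    var_class: str,
    revel: float | None,
    cadd: float | None,
    loftee: str | None,
    ac: int,
    an: int,
    mask: MaskSpec,
    diag: MaskDiagnostics | None = None,
) -> bool:
    """Does a variant (post-QC AC/AN) qualify under ``mask``?

    Membership is the conjunction of the functional rule and the frequency
    stratum (MAF < 0.1% or singleton AC = 1). Variants missing a score the
    functional rule needs are non-members, tallied in ``diag``.
    """
    diag = diag if diag is not None else MaskDiagnostics()
    if an <= 0:
        return False
    af = ac / an
    maf = min(af, 1.0 - af)
    if mask.frequency == "singleton":
        freq_ok = ac == 1
    else:
        freq_ok = maf < RARE_MAF
    if not freq_ok:
        return False
    return _functional_member(var_class, revel, cadd, loftee, mask.functional, diag)


# ---------------------------------------------------------------------------
# table-level convenience


def prioritize_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Reduce a long (multi-transcript) annotation table to one row/variant.

    Expects the annotation TSV schema (see :mod:`burdenmr.io`); adds a
    ``var_class`` column with the collapsed consequence class.
    """
    required = {"variant_id", "gene", "transcript", "protein_coding",
                "mane_select", "canonical", "consequence"}
    missing = required - set(ann.columns)
    if missing:
        raise DataError(f"annotation table missing columns: {sorted(missing)}")
    order = ann.assign(
        _key=list(
            zip(
                ~ann["protein_coding"].astype(bool),
                ~ann["mane_select"].astype(bool),
                ~ann["canonical"].astype(bool),
                ann["transcript"],
            )
        )
    )
    best = order.sort_values("_key").groupby("variant_id", sort=False).head(1)
    best = best.drop(columns="_key").reset_index(drop=True)
    best["var_class"] = [classify_class(t) for t in best["consequence"]]
    return best


def mask_variant_table(
    ann: pd.DataFrame,
    ac: pd.Series,
    an: pd.Series,
    masks: Sequence[MaskSpec] | None = None,
) -> tuple[pd.DataFrame, MaskDiagnostics]:
    """Boolean membership matrix (variants x masks) for prioritized annotations.

    ``ac``/``an`` are indexed by variant_id (post-QC counts).
    """
    masks = list(masks) if masks is not None else default_masks()
    diag = MaskDiagnostics()
    out = pd.DataFrame(index=ann["variant_id"])
    revel = ann["revel"] if "revel" in ann else pd.Series(float("nan"), index=ann.index)
    cadd = ann["cadd"] if "cadd" in ann else pd.Series(float("nan"), index=ann.index)
    loftee = ann["loftee"] if "loftee" in ann else pd.Series(None, index=ann.index)
    for mask in masks:
        member = []
        for vid, vclass, rv, cd, lf in zip(
            ann["variant_id"], ann["var_class"], revel, cadd, loftee
        ):
            rv = None if pd.isna(rv) else float(rv)
            cd = None if pd.isna(cd) else float(cd)
            lf = None if (lf is None or (isinstance(lf, float) and pd.isna(lf))) else lf
            member.append(
                mask_membership(
                    vclass, rv, cd, lf, int(ac[vid]), int(an[vid]), mask, diag
                )
            )
        out[mask.name] = member
    return out, diag
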