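"""GWAS summary-statistics data model, file I/O, and two-sample harmonization.

The central container is :class:`AssociationRecord`, one variant's marginal
association with one trait.  Files are tab-separated with a canonical header
(``variant_id  chr  pos  ea  oa  eaf  beta  se  p  n  n_cases``); arbitrary
source headers are supported through a ``column_map``.

Harmonization re-orients an outcome record onto the exposure's effect allele
following standard two-sample MR practice: direct match, allele swap, strand
flip, or both; palindromic (A/T, C/G) variants whose allele frequency in
either study falls strictly inside a configurable ambiguity window (default
0.42-0.58) are dropped because their strand cannot be resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics TSVs
CANONICAL_COLUMNS = (
    "variant_id", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n", "n_cases",
)

#: default palindromic-EAF ambiguity window (open interval)
PALINDROME_WINDOW = (0.42, 0.58)


@dataclass
class AssociationRecord:
    """One variant's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` — log-odds for a
    binary trait, trait units otherwise.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: int
    n_cases: Optional[int] = None
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: p-value {self.pvalue} outside (0, 1]")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None or not (0 < self.n_cases < self.n):
                raise ValueError(
                    f"{self.variant_id}: binary trait requires 0 < n_cases < n"
                )


@dataclass
class HarmonizedPair:
    """Exposure/outcome records for one variant after allele re-orientation."""

    exposure: AssociationRecord
    outcome: Optional[AssociationRecord]
    action_taken: Optional[str]  # identical | allele_swap | strand_flip | strand_flip_and_swap
    dropped: bool = False
    drop_reason: Optional[str] = None  # palindromic_ambiguous | incompatible_alleles


@dataclass
class GeneAnnotation:
    """Genomic footprint and assay provenance for one protein/transcript assay."""

    gene_id: str
    protein_id: str
    chromosome: str
    start: int
    end: int
    tss: int
    platform: str
    assay_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class LoadReport:
    """Row accounting for one file read: rows in = rows kept + rows skipped."""

    path: str
    n_read: int = 0
    n_kept: int = 0
    skipped: dict = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1

    @property
    def n_skipped(self) -> int:
        return sum(self.skipped.values())


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    a, b = effect_allele.upper(), other_allele.upper()
    for x in (a, b):
        if x not in VALID_ALLELES:
            raise ValueError(f"non-ACGT allele {x!r}")
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _parse_row(row: Mapping, report: LoadReport) -> Optional[AssociationRecord]:
    def get(key, cast=None):
        v = row.get(key)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return cast(v) if cast else v

    ea, oa = get("ea"), get("oa")
    beta, se = get("beta", float), get("se", float)
    if ea is None or oa is None:
        report.skip("missing_alleles")
        return None
    if beta is None or se is None:
        report.skip("missing_beta_or_se")
        return None
    if se <= 0:
        report.skip("nonpositive_se")
        return None
    p = get("p", float)
    if p is None or not (0.0 < p <= 1.0):
        report.skip("invalid_pvalue")
        return None
    n_cases = get("n_cases", lambda v: int(float(v)))
    try:
        return AssociationRecord(
            variant_id=str(get("variant_id")),
            chromosome=str(get("chr")),
            position=int(float(get("pos"))),
            effect_allele=str(ea),
            other_allele=str(oa),
            eaf=get("eaf", float),
            beta=beta,
            se=se,
            pvalue=p,
            n=int(float(get("n"))),
            n_cases=n_cases,
            trait_type="binary" if n_cases is not None else "quantitative",
        )
    except (ValueError, TypeError):
        report.skip("invalid_record")
        return None


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[AssociationRecord], LoadReport]:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Mapping from source header names to canonical field names
        (``variant_id, chr, pos, ea, oa, eaf, beta, se, p, n, n_cases``).
        Omitted when the file already uses the canonical header.

    Returns
    -------
    records, report
        Records in file order (duplicate ``variant_id`` resolved by keeping
        the smallest p-value) and a row-accounting report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    report = LoadReport(path=str(path), n_read=len(df))
    records: list[AssociationRecord] = []
    by_id: dict[str, int] = {}
    for row in df.to_dict(orient="records"):
        rec = _parse_row(row, report)
        if rec is None:
            continue
        prev = by_id.get(rec.variant_id)
        if prev is not None:
            logger.warning("duplicate variant_id %s in %s", rec.variant_id, path)
            report.skip("duplicate_variant_id")
            if rec.pvalue < records[prev].pvalue:
                records[prev] = rec
            continue
        by_id[rec.variant_id] = len(records)
        records.append(rec)
    report.n_kept = len(records)
    logger.info(
        "read %s: %d rows, %d kept, %d skipped %s",
        path, report.n_read, report.n_kept, report.n_skipped, report.skipped,
    )
    return records, report


def write_sumstats(records: Iterable[AssociationRecord], path) -> None:
    """Write records to the canonical TSV, preserving full float precision."""
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id, "chr": r.chromosome, "pos": r.position,
            "ea": r.effect_allele, "oa": r.other_allele,
            "eaf": "" if r.eaf is None else repr(r.eaf),
            "beta": repr(r.beta), "se": repr(r.se), "p": repr(r.pvalue),
            "n": r.n, "n_cases": "" if r.n_cases is None else r.n_cases,
        })
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[GeneAnnotation]:
    """Read a gene/assay annotation TSV (gene_id, protein_id, chr, start, end, tss, platform, assay_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GeneAnnotation(
            gene_id=row["gene_id"], protein_id=row["protein_id"],
            chromosome=str(row["chr"]), start=int(row["start"]), end=int(row["end"]),
            tss=int(row["tss"]), platform=row["platform"], assay_id=row["assay_id"],
        )
        for row in df.to_dict(orient="records")
    ]


def write_annotations(annotations: Iterable[GeneAnnotation], path) -> None:
    rows = [
        {"gene_id": a.gene_id, "protein_id": a.protein_id, "chr": a.chromosome,
         "start": a.start, "end": a.end, "tss": a.tss, "platform": a.platform,
         "assay_id": a.assay_id}
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _flip_outcome(outcome: AssociationRecord) -> AssociationRecord:
    """Re-orient an outcome record to the opposite effect allele."""
    return replace(
        outcome,
        effect_allele=outcome.other_allele,
        other_allele=outcome.effect_allele,
        beta=-outcome.beta,
        eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
    )


def _complement_alleles(rec: AssociationRecord) -> AssociationRecord:
    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def harmonize_pair(
    exposure: AssociationRecord,
    outcome: AssociationRecord,
    palindrome_window: tuple[float, float] = PALINDROME_WINDOW,
) -> HarmonizedPair:
    """Re-orient ``outcome`` onto the exposure's effect/other alleles.

    Non-palindromic variants are matched directly, after an allele swap
    (negating beta and complementing EAF), after a strand flip (A<->T, C<->G),
    or after both.  Palindromic variants cannot be strand-resolved from
    alleles: they are dropped when either study's EAF lies strictly inside
    ``palindrome_window`` or is missing; otherwise orientation is inferred
    from EAF-side agreement (both frequencies on the same side of 0.5 means
    the records are already aligned).
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    exp_alleles = {exposure.effect_allele, exposure.other_allele}
    out_alleles = {outcome.effect_allele, outcome.other_allele}

    if is_palindromic(exposure.effect_allele, exposure.other_allele):
        if exp_alleles != out_alleles:
            return HarmonizedPair(exposure, None, None, True, "incompatible_alleles")
        lo, hi = palindrome_window
        for freq in (exposure.eaf, outcome.eaf):
            if freq is None or lo < freq < hi:
                return HarmonizedPair(exposure, None, None, True, "palindromic_ambiguous")
        # allele labels carry no strand information for A/T & C/G pairs:
        # orientation is decided purely by frequency-side agreement
        same_side = (exposure.eaf < 0.5) == (outcome.eaf < 0.5)
        relabelled = replace(
            outcome,
            effect_allele=exposure.effect_allele,
            other_allele=exposure.other_allele,
        )
        if same_side:
            return HarmonizedPair(exposure, relabelled, "identical")
        reoriented = replace(relabelled, beta=-relabelled.beta, eaf=1.0 - relabelled.eaf)
        return HarmonizedPair(exposure, reoriented, "allele_swap")

    if out_alleles == exp_alleles:
        if outcome.effect_allele == exposure.effect_allele:
            return HarmonizedPair(exposure, outcome, "identical")
        return HarmonizedPair(exposure, _flip_outcome(outcome), "allele_swap")

    flipped = _complement_alleles(outcome)
    if {flipped.effect_allele, flipped.other_allele} == exp_alleles:
        if flipped.effect_allele == exposure.effect_allele:
            return HarmonizedPair(exposure, flipped, "strand_flip")
        return HarmonizedPair(exposure, _flip_outcome(flipped), "strand_flip_and_swap")

    return HarmonizedPair(exposure, None, None, True, "incompatible_alleles")
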