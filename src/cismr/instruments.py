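"""Selection of cis instrumental variables for protein (or mRNA) abundance.

One instrument is retained per assay, and one assay per (protein, platform):
the lead variant, i.e. the cis variant with the smallest association p-value
that survives four conjunctive filters — outside the MHC region (and not
instrumenting an MHC-encoded gene), single-variant F-statistic >= 10,
present in the outcome GWAS, and genome-wide significant within the platform's
cis window.  Platform conventions differ: the Olink catalogue anchors the cis
window on the gene body and uses p < 3.40e-11; the SomaScan catalogue anchors
on the TSS and uses p < 1.80e-9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .sumstats import AssociationRecord, GeneAnnotation

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: MHC exclusion interval (chromosome, start, end)
MHC_INTERVAL = ("6", 26_000_000, 34_000_000)


@dataclass
class PlatformConfig:
    """Cis-window and significance conventions for one exposure source."""

    platform: str
    p_threshold: float
    cis_anchor: str = "gene_body"  # gene_body | tss
    cis_radius: int = 1_000_000
    f_min: float = 10.0
    mhc_interval: tuple = MHC_INTERVAL

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.cis_radius <= 0:
            raise ValueError("cis_radius must be positive")
        if self.cis_anchor not in ("gene_body", "tss"):
            raise ValueError(f"unknown cis_anchor {self.cis_anchor!r}")


#: platform defaults mirroring the source proteogenomic catalogues
DEFAULT_PLATFORM_CONFIGS = {
    "olink": PlatformConfig("olink", p_threshold=3.40e-11, cis_anchor="gene_body"),
    "somascan": PlatformConfig("somascan", p_threshold=1.80e-9, cis_anchor="tss"),
}


def load_platform_configs(path) -> dict[str, PlatformConfig]:
    """Load per-platform configs from a YAML file keyed by platform name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    configs = {}
    for name, entry in raw.items():
        entry = dict(entry)
        entry.setdefault("platform", name)
        if "mhc_interval" in entry:
            entry["mhc_interval"] = tuple(entry["mhc_interval"])
        configs[name] = PlatformConfig(**entry)
    return configs


@dataclass
class Instrument:
    """A selected lead cis variant with its strength and provenance."""

    record: AssociationRecord
    gene: GeneAnnotation
    f_statistic: float
    is_lead: bool = True
    selection_log: list = field(default_factory=list)


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument-strength F-statistic, (beta/se)^2."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def in_mhc(chromosome: str, position: int, config: Optional[PlatformConfig] = None) -> bool:
    """True iff the position falls in the MHC exclusion interval (inclusive)."""
    chrom, start, end = config.mhc_interval if config else MHC_INTERVAL
    return str(chromosome) == chrom and start <= position <= end


def gene_overlaps_mhc(gene: GeneAnnotation, config: Optional[PlatformConfig] = None) -> bool:
    """True iff the gene body overlaps the MHC interval at all."""
    chrom, start, end = config.mhc_interval if config else MHC_INTERVAL
    return str(gene.chromosome) == chrom and gene.start <= end and gene.end >= start


def in_cis_window(
    variant_position: int,
    chromosome: str,
    gene: GeneAnnotation,
    config: PlatformConfig,
) -> bool:
    """True iff the variant lies within the platform's cis window of the gene."""
    if str(chromosome) != str(gene.chromosome):
        return False
    if config.cis_anchor == "tss":
        lo, hi = gene.tss - config.cis_radius, gene.tss + config.cis_radius
    else:
        lo, hi = gene.start - config.cis_radius, gene.end + config.cis_radius
    return lo <= variant_position <= hi


def _lead_sort_key(item: tuple[AssociationRecord, GeneAnnotation]):
    # smallest p first; ties broken by position then variant_id for determinism
    rec = item[0]
    return (rec.pvalue, rec.position, rec.variant_id)


def select_instruments(
    cis_associations: Iterable[tuple[AssociationRecord, GeneAnnotation]],
    outcome_variants: set[str],
    config: PlatformConfig,
) -> list[Instrument]:
    """Apply the four instrument filters and keep one lead variant per assay.

    Filters, in order: (1) variant inside the MHC, or assay gene overlapping
    the MHC; (2) F-statistic below ``config.f_min``; (3) variant absent from
    the outcome GWAS; (4) p above the platform threshold or variant outside
    the cis window.  Among survivors the lowest-p variant per assay becomes
    the lead, and when several assays target the same protein on the same
    platform only the assay with the lowest-p lead is retained.  Every
    exclusion is recorded in the returned instruments' ``selection_log`` and
    in the module logger.
    """
    exclusions: list[tuple[str, str, str]] = []  # (assay_id, variant_id, reason)
    surviving: dict[str, list[tuple[AssociationRecord, GeneAnnotation]]] = {}

    for rec, gene in cis_associations:
        assay = gene.assay_id
        if str(rec.chromosome) not in AUTOSOMES:
            exclusions.append((assay, rec.variant_id, "non_autosomal"))
            continue
        if in_mhc(rec.chromosome, rec.position, config) or gene_overlaps_mhc(gene, config):
            exclusions.append((assay, rec.variant_id, "mhc"))
            continue
        if f_statistic(rec.beta, rec.se) < config.f_min:
            exclusions.append((assay, rec.variant_id, "weak_instrument"))
            continue
        if rec.variant_id not in outcome_variants:
            exclusions.append((assay, rec.variant_id, "absent_from_outcome"))
            continue
        if rec.pvalue >= config.p_threshold:
            exclusions.append((assay, rec.variant_id, "above_p_threshold"))
            continue
        if not in_cis_window(rec.position, rec.chromosome, gene, config):
            exclusions.append((assay, rec.variant_id, "outside_cis_window"))
            continue
        surviving.setdefault(assay, []).append((rec, gene))

    # lead variant per assay
    leads: dict[str, Instrument] = {}
    for assay, items in surviving.items():
        items.sort(key=_lead_sort_key)
        rec, gene = items[0]
        for other_rec, _ in items[1:]:
            exclusions.append((assay, other_rec.variant_id, "not_lead_variant"))
        leads[assay] = Instrument(
            record=rec, gene=gene, f_statistic=f_statistic(rec.beta, rec.se),
        )

    # one assay per (protein_id, platform): keep the assay with the lowest-p lead
    by_protein: dict[tuple[str, str], list[Instrument]] = {}
    for inst in leads.values():
        key = (inst.gene.protein_id, inst.gene.platform)
        by_protein.setdefault(key, []).append(inst)

    selected: list[Instrument] = []
    for key, insts in sorted(by_protein.items()):
        insts.sort(key=lambda i: _lead_sort_key((i.record, i.gene)))
        winner = insts[0]
        for loser in insts[1:]:
            exclusions.append(
                (loser.gene.assay_id, loser.record.variant_id, "duplicate_protein_assay")
            )
        winner.selection_log = [e for e in exclusions if e[0] == winner.gene.assay_id]
        selected.append(winner)

    for assay, variant, reason in exclusions:
        logger.debug("excluded %s / %s: %s", assay, variant, reason)
    logger.info(
        "select_instruments: %d instruments, %d exclusions", len(selected), len(exclusions)
    )
    return selected
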