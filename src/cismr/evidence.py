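"""Integration of MR and colocalization evidence across data sources.

Protein-disease findings supported by a plasma pQTL (MR-significant at 5%
FDR and strong colocalization, PP4 > 0.80) are tiered by corroboration from
expression data: Category 1 adds an MR-significant, strongly colocalizing
brain-region eQTL; Category 2 adds the same from a plasma eQTL; Category 3
rests on the plasma pQTL alone.  Cross-platform deduplication keys on
(protein, outcome); novelty is assessed against a user-supplied list of
known GWAS loci (or a transcribed ``novel`` column on packaged fixtures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .coloc import classify_pp4
from .mr import MREstimate

logger = logging.getLogger(__name__)

classify_coloc = classify_pp4  # tiering uses the coloc thresholds verbatim


@dataclass
class SourceEvidence:
    """MR/coloc status of one (protein, outcome) pair in one data source."""

    available: bool = False
    mr_significant: bool = False
    coloc_class: str = "not_run"  # strong | moderate | none | not_run
    direction: int = 0  # sign of beta_mr


@dataclass
class EvidenceRecord:
    """All per-source evidence slots for one protein-outcome pair."""

    protein_id: str
    outcome_id: str
    plasma_pqtl_olink: SourceEvidence = field(default_factory=SourceEvidence)
    plasma_pqtl_somascan: SourceEvidence = field(default_factory=SourceEvidence)
    plasma_eqtl: SourceEvidence = field(default_factory=SourceEvidence)
    brain_eqtl: dict = field(default_factory=dict)  # region -> SourceEvidence
    category: str = "uncategorized"
    novel: bool = False


@dataclass
class KnownLociList:
    """Previously reported (outcome, gene-or-protein) associations."""

    entries: set = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path) -> "KnownLociList":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(entries={(r["outcome"], r["identifier"]) for _, r in df.iterrows()})

    def is_known(self, outcome_id: str, identifier: str) -> bool:
        return (outcome_id, identifier) in self.entries


def _strong(slot: SourceEvidence) -> bool:
    return slot.available and slot.mr_significant and slot.coloc_class == "strong"


def assign_category(record: EvidenceRecord) -> str:
    """Tier a protein-outcome pair by the breadth of QTL corroboration.

    Precondition: at least one plasma pQTL slot is MR-significant with
    strong colocalization; records failing it stay ``uncategorized``.
    """
    plasma_pqtl = _strong(record.plasma_pqtl_olink) or _strong(record.plasma_pqtl_somascan)
    if not plasma_pqtl:
        return "uncategorized"
    if any(_strong(slot) for slot in record.brain_eqtl.values()):
        return "1"
    if _strong(record.plasma_eqtl):
        return "2"
    return "3"


def directional_concordance(a: MREstimate, b: MREstimate) -> str:
    """``consistent`` iff both effect estimates share a (nonzero) sign."""
    sa = 0 if a.beta_mr == 0 else (1 if a.beta_mr > 0 else -1)
    sb = 0 if b.beta_mr == 0 else (1 if b.beta_mr > 0 else -1)
    return "consistent" if (sa == sb and sa != 0) else "inconsistent"


@dataclass
class DiscoverySummary:
    """Headline accounting of strong-coloc MR discoveries."""

    platform_level_pairs: int
    unique_pairs: int
    unique_proteins: int
    both_platform_pairs: int
    novel_pairs: int
    per_outcome: dict = field(default_factory=dict)


def load_fixture_tables() -> pd.DataFrame:
    """The packaged per-platform tables of strong-coloc MR discoveries.

    Transcriptions of the published per-platform results (Olink and
    SomaScan), one row per (outcome, assay) with the lead variant, odds
    ratio, and novelty flag.
    """
    frames = []
    for name, platform in (("table2_olink.tsv", "olink"),
                           ("table3_somascan.tsv", "somascan")):
        with resources.files("cismr.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype=str)
        df["platform"] = platform
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def load_screen_summary() -> pd.DataFrame:
    """The packaged per-outcome screen summary (tests, hits, inflation)."""
    with resources.files("cismr.data").joinpath("table1_screen_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_screen_families() -> pd.DataFrame:
    """Packaged (tests, discoveries, alpha) per BH family across the study."""
    with resources.files("cismr.data").joinpath("screen_families.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_discoveries(
    strong_pairs: pd.DataFrame,
    known_loci: Optional[KnownLociList] = None,
) -> DiscoverySummary:
    """Count platform-level, unique, both-platform, and novel discoveries.

    ``strong_pairs`` needs columns ``outcome``, ``platform``, ``protein``
    and either a ``novel`` column (Yes/No) or a ``known_loci`` list.
    Duplicate rows are ignored: pairs are counted at the
    (platform, protein, outcome) level, then deduplicated across platforms
    on (protein, outcome).
    """
    if strong_pairs.empty:
        return DiscoverySummary(0, 0, 0, 0, 0, {})
    df = strong_pairs.drop_duplicates(subset=["platform", "protein", "outcome"])
    platform_level = len(df)
    unique = df.drop_duplicates(subset=["protein", "outcome"])
    unique_pairs = len(unique)
    unique_proteins = unique["protein"].nunique()
    both_platform = platform_level - unique_pairs

    if known_loci is not None:
        novel_mask = [
            not known_loci.is_known(r["outcome"], r["protein"])
            for _, r in unique.iterrows()
        ]
        novel_pairs = int(sum(novel_mask))
    elif "novel" in df.columns:
        flags = (
            df.assign(_novel=df["novel"].str.lower().eq("yes"))
            .groupby(["protein", "outcome"])["_novel"]
            .agg("all")
        )
        novel_pairs = int(flags.sum())
    else:
        raise ValueError("need a 'novel' column or a known_loci list")

    per_outcome = {
        outcome: {
            "platform_level_pairs": int(len(sub)),
            "unique_pairs": int(len(sub.drop_duplicates(subset=["protein"]))),
        }
        for outcome, sub in df.groupby("outcome")
    }
    return DiscoverySummary(
        platform_level_pairs=platform_level,
        unique_pairs=unique_pairs,
        unique_proteins=unique_proteins,
        both_platform_pairs=both_platform,
        novel_pairs=novel_pairs,
        per_outcome=per_outcome,
    )
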