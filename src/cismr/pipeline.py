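"""End-to-end study orchestration: instruments -> MR -> FDR -> coloc ->
reverse MR -> evidence tiers, with per-stage TSV outputs and row accounting.

The stages mirror the proteome-wide cis-MR design: select one lead cis
instrument per assay per platform against each outcome's variant panel, test
every instrument-outcome pair with the Wald ratio, control the whole family
at 5% FDR, colocalize the FDR hits over +-1 Mb loci, probe reverse causation
with a clumped multi-variant IVW of outcome-on-exposure, and tier the
surviving evidence.  The pipeline is a pure function of (config, inputs,
seed): rerunning writes byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .coloc import ColocPriors, coloc_window, colocalize
from .evidence import KnownLociList, summarize_discoveries
from .instruments import (
    DEFAULT_PLATFORM_CONFIGS,
    Instrument,
    PlatformConfig,
    select_instruments,
)
from .ld import clump, read_ld_panel
from .mr import MREstimate, bh_fdr, ivw_random, run_mr_screen, wald_ratio
from .sumstats import (
    AssociationRecord,
    GeneAnnotation,
    harmonize_pair,
    read_annotations,
    read_sumstats,
)

logger = logging.getLogger(__name__)

RESULTS_COLUMNS = [
    "exposure_id", "platform", "outcome_id", "variant_id", "ea", "oa", "eaf",
    "beta_mr", "se_mr", "or", "ci_low", "ci_high", "pvalue", "fdr_flag",
]


@dataclass
class PipelineConfig:
    """File paths and analysis settings for one full study run."""

    exposure_paths: dict  # platform -> sumstats TSV
    outcome_paths: dict  # outcome_id -> sumstats TSV
    annotations_path: str
    ld_panel_dir: Optional[str] = None  # stems <dir>/<protein_id>
    known_loci_path: Optional[str] = None
    platform_configs: dict = field(default_factory=lambda: dict(DEFAULT_PLATFORM_CONFIGS))
    coloc_priors: ColocPriors = field(default_factory=ColocPriors)
    alpha: float = 0.05
    coloc_all: bool = False  # run coloc on every pair, not just FDR hits
    reverse_p_max: float = 5e-8
    reverse_r2_max: float = 0.001
    reverse_window_bp: int = 1_000_000
    out_dir: str = "cismr_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pc = {
            name: PlatformConfig(**{**{"platform": name}, **entry})
            for name, entry in (raw.pop("platform_configs", None) or {}).items()
        }
        priors = ColocPriors(**(raw.pop("coloc_priors", None) or {}))
        cfg = cls(**raw, coloc_priors=priors)
        if pc:
            cfg.platform_configs = pc
        return cfg


def _cis_candidates(
    records: list[AssociationRecord],
    annotations: list[GeneAnnotation],
    config: PlatformConfig,
) -> list[tuple[AssociationRecord, GeneAnnotation]]:
    """Pair exposure records with every assay whose cis window contains them."""
    by_chrom: dict[str, list[AssociationRecord]] = {}
    for rec in records:
        by_chrom.setdefault(str(rec.chromosome), []).append(rec)
    pairs = []
    for gene in annotations:
        if gene.platform != config.platform:
            continue
        anchor_lo, anchor_hi = (
            (gene.tss, gene.tss) if config.cis_anchor == "tss" else (gene.start, gene.end)
        )
        lo, hi = anchor_lo - config.cis_radius, anchor_hi + config.cis_radius
        for rec in by_chrom.get(str(gene.chromosome), []):
            if lo <= rec.position <= hi:
                pairs.append((rec, gene))
    return pairs


def _estimates_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


@dataclass
class StudyReport:
    """Bundle of per-stage tables produced by :func:`run_full_study`."""

    instruments: pd.DataFrame
    mr_results: pd.DataFrame
    coloc_results: pd.DataFrame
    reverse_mr: pd.DataFrame
    summary: dict
    counts: dict


def run_full_study(config: PipelineConfig) -> StudyReport:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    annotations = read_annotations(config.annotations_path)
    exposures: dict[str, list[AssociationRecord]] = {}
    for platform, path in config.exposure_paths.items():
        recs, report = read_sumstats(path)
        exposures[platform] = recs
        counts[f"exposure_{platform}_rows"] = {"read": report.n_read,
                                               "kept": report.n_kept,
                                               "skipped": report.skipped}
    outcomes: dict[str, list[AssociationRecord]] = {}
    for outcome_id, path in config.outcome_paths.items():
        recs, report = read_sumstats(path)
        outcomes[outcome_id] = recs
        counts[f"outcome_{outcome_id}_rows"] = {"read": report.n_read,
                                                "kept": report.n_kept,
                                                "skipped": report.skipped}

    # --- stage 1: instrument selection (per platform x outcome) ------------
    instrument_rows = []
    selected: dict[tuple[str, str], list[Instrument]] = {}
    for platform, records in exposures.items():
        pconf = config.platform_configs[platform]
        candidates = _cis_candidates(records, annotations, pconf)
        for outcome_id, outcome_recs in outcomes.items():
            outcome_variants = {r.variant_id for r in outcome_recs}
            insts = select_instruments(candidates, outcome_variants, pconf)
            selected[(platform, outcome_id)] = insts
            for inst in insts:
                instrument_rows.append({
                    "platform": platform, "outcome_id": outcome_id,
                    "protein_id": inst.gene.protein_id,
                    "assay_id": inst.gene.assay_id,
                    "variant_id": inst.record.variant_id,
                    "pvalue": inst.record.pvalue,
                    "f_statistic": inst.f_statistic,
                })
    instruments_df = pd.DataFrame(
        instrument_rows,
        columns=["platform", "outcome_id", "protein_id", "assay_id",
                 "variant_id", "pvalue", "f_statistic"],
    )
    counts["instruments"] = len(instruments_df)

    # --- stage 2: Wald-ratio MR screen, one BH family over all pairs -------
    mr_rows = []
    estimates: list[tuple[str, Instrument, str, MREstimate]] = []
    n_skipped = 0
    for (platform, outcome_id), insts in selected.items():
        outcome_by_variant = {r.variant_id: r for r in outcomes[outcome_id]}
        screen = run_mr_screen(insts, outcome_by_variant, outcome_id,
                               alpha=config.alpha, apply_fdr=False)
        n_skipped += len(screen.skipped)
        skipped_ids = {s[0] for s in screen.skipped}
        kept = [i for i in insts
                if f"{i.gene.protein_id}:{i.gene.platform}" not in skipped_ids]
        assert len(kept) == len(screen.estimates)
        for inst, est in zip(kept, screen.estimates):
            estimates.append((platform, inst, outcome_id, est))
    counts["mr_pairs_tested"] = len(estimates)
    counts["mr_pairs_skipped"] = n_skipped

    fdr = bh_fdr([e.pvalue for _, _, _, e in estimates], config.alpha) if estimates else None
    for i, (platform, inst, outcome_id, est) in enumerate(estimates):
        mr_rows.append({
            "exposure_id": inst.gene.protein_id, "platform": platform,
            "outcome_id": outcome_id,
            "variant_id": est.variant_id,
            "ea": inst.record.effect_allele, "oa": inst.record.other_allele,
            "eaf": inst.record.eaf,
            "beta_mr": est.beta_mr, "se_mr": est.se_mr, "or": est.or_point,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
            "fdr_flag": bool(fdr.flags[i]) if fdr else False,
        })
    mr_df = _estimates_frame(mr_rows)
    counts["mr_fdr_discoveries"] = int(mr_df["fdr_flag"].sum()) if len(mr_df) else 0

    # --- stage 3: colocalization on FDR hits -------------------------------
    coloc_rows = []
    todo = mr_df if config.coloc_all else mr_df[mr_df["fdr_flag"].astype(bool)]
    for _, row in todo.iterrows():
        platform, outcome_id = row["platform"], row["outcome_id"]
        inst = next(
            x for x in selected[(platform, outcome_id)]
            if x.gene.protein_id == row["exposure_id"]
        )
        try:
            t1, t2 = coloc_window(inst, exposures[platform], outcomes[outcome_id])
            res = colocalize(t1, t2, config.coloc_priors)
        except ValueError as exc:
            logger.warning("coloc failed for %s/%s: %s",
                           row["exposure_id"], outcome_id, exc)
            continue
        coloc_rows.append({
            "exposure_id": row["exposure_id"], "platform": platform,
            "outcome_id": outcome_id, "n_variants": res.n_variants,
            "PP0": res.pp[0], "PP1": res.pp[1], "PP2": res.pp[2],
            "PP3": res.pp[3], "PP4": res.pp[4],
            "lead_variant": res.lead_variant,
            "classification": res.classification,
        })
    coloc_df = pd.DataFrame(
        coloc_rows,
        columns=["exposure_id", "platform", "outcome_id", "n_variants",
                 "PP0", "PP1", "PP2", "PP3", "PP4", "lead_variant",
                 "classification"],
    )
    counts["coloc_loci"] = len(coloc_df)
    counts["coloc_strong"] = int((coloc_df["classification"] == "strong").sum()) if len(coloc_df) else 0

    # --- stage 4: bidirectional (reverse-causation) IVW --------------------
    reverse_rows = []
    hit_proteins = (
        mr_df[mr_df["fdr_flag"].astype(bool)][["exposure_id", "platform", "outcome_id"]]
        .drop_duplicates()
    )
    if config.ld_panel_dir is not None and len(hit_proteins):
        for _, row in hit_proteins.iterrows():
            est = _reverse_ivw(row, config, exposures, outcomes)
            if est is not None:
                reverse_rows.append(est)
    reverse_df = pd.DataFrame(
        reverse_rows,
        columns=["outcome_id", "exposure_id", "platform", "n_variants",
                 "beta_mr", "se_mr", "pvalue", "q_statistic", "fdr_flag"],
    )
    if len(reverse_df):
        rfdr = bh_fdr(list(reverse_df["pvalue"]), config.alpha)
        reverse_df["fdr_flag"] = rfdr.flags
    counts["reverse_tests"] = len(reverse_df)

    # --- stage 5: evidence integration -------------------------------------
    strong = coloc_df[coloc_df["classification"] == "strong"].rename(
        columns={"exposure_id": "protein"}
    )
    known = (KnownLociList.from_tsv(config.known_loci_path)
             if config.known_loci_path else KnownLociList(set()))
    if len(strong):
        strong = strong.rename(columns={"outcome_id": "outcome"})
        summary_obj = summarize_discoveries(
            strong[["outcome", "platform", "protein"]], known_loci=known
        )
        summary = {
            "platform_level_pairs": summary_obj.platform_level_pairs,
            "unique_pairs": summary_obj.unique_pairs,
            "unique_proteins": summary_obj.unique_proteins,
            "both_platform_pairs": summary_obj.both_platform_pairs,
            "novel_pairs": summary_obj.novel_pairs,
            "per_outcome": summary_obj.per_outcome,
        }
    else:
        summary = {"platform_level_pairs": 0, "unique_pairs": 0,
                   "unique_proteins": 0, "both_platform_pairs": 0,
                   "novel_pairs": 0, "per_outcome": {}}

    # --- outputs ------------------------------------------------------------
    instruments_df.to_csv(out_dir / "instruments.tsv", sep="\t", index=False)
    mr_df.to_csv(out_dir / "mr_results.tsv", sep="\t", index=False)
    coloc_df.to_csv(out_dir / "coloc_results.tsv", sep="\t", index=False)
    reverse_df.to_csv(out_dir / "reverse_mr.tsv", sep="\t", index=False)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({"summary": summary, "counts": counts}, fh, indent=2, sort_keys=True)
    manifest = {
        "seed": config.seed, "alpha": config.alpha,
        "inputs": {str(k): str(v) for k, v in
                   {**config.exposure_paths, **config.outcome_paths,
                    "annotations": config.annotations_path}.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return StudyReport(instruments=instruments_df, mr_results=mr_df,
                       coloc_results=coloc_df, reverse_mr=reverse_df,
                       summary=summary, counts=counts)


def _reverse_ivw(row, config: PipelineConfig, exposures, outcomes):
    """Disease -> protein IVW over clumped genome-wide-significant variants."""
    protein = row["exposure_id"]
    stem = Path(config.ld_panel_dir) / protein
    try:
        panel = read_ld_panel(stem)
    except OSError:
        logger.warning("no LD panel for %s; reverse MR skipped", protein)
        return None
    outcome_recs = outcomes[row["outcome_id"]]
    index_variants = clump(
        outcome_recs, panel, p_max=config.reverse_p_max,
        window_bp=config.reverse_window_bp, r2_max=config.reverse_r2_max,
    )
    if not index_variants:
        return None
    exposure_by_variant = {r.variant_id: r for r in exposures[row["platform"]]}
    ratios = []
    for iv in index_variants:
        exp_rec = exposure_by_variant.get(iv.variant_id)
        if exp_rec is None:
            continue
        pair = harmonize_pair(iv, exp_rec)  # outcome is now the exposure
        if pair.dropped or pair.exposure.beta == 0:
            continue
        ratios.append(wald_ratio(pair))
    if not ratios:
        return None
    pooled = ivw_random(ratios)
    return {
        "outcome_id": row["outcome_id"], "exposure_id": protein,
        "platform": row["platform"], "n_variants": pooled.n_variants,
        "beta_mr": pooled.beta_mr, "se_mr": pooled.se_mr,
        "pvalue": pooled.pvalue, "q_statistic": pooled.q_statistic,
        "fdr_flag": False,
    }
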