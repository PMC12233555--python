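"""Synthetic GWAS summary statistics with known causal structure.

Marginal z-scores for a locus are drawn from the standard multivariate
normal model under linkage disequilibrium,

    z ~ MVN( sqrt(n_eff) * R @ lam,  R ),

where ``lam`` holds standardized joint (causal) effects, R is the local LD
correlation matrix, and the effective sample size is n for a quantitative
trait and n * phi * (1 - phi) for a binary trait analysed on the log-odds
scale with case fraction phi.  Betas and SEs are put on the per-allele scale
by dividing the standardized quantities by sqrt(2 f (1 - f)) with f the
effect-allele frequency, drawn once per variant and shared between the
exposure and outcome cohorts.

Five causal architectures are supported: ``shared`` (one variant drives both
traits, outcome effect = theta * lambda_exp), ``distinct`` (different causal
variants — the confounding-by-LD failure mode), ``null_outcome``,
``null_both``, and ``reverse`` (the outcome is the causal trait and induces
an exposure effect of theta * lambda_exp at its causal variant).

A small fraction of variants (default 5%) receives strand-ambiguous A/T or
C/G allele pairs to exercise the harmonization paths.  Everything is
deterministic given the scenario's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDPanel, write_ld_panel
from .sumstats import (
    AssociationRecord,
    GeneAnnotation,
    write_annotations,
    write_sumstats,
)

logger = logging.getLogger(__name__)

SCENARIO_KINDS = ("shared", "distinct", "null_outcome", "null_both", "reverse")

#: reference study conditions for recovery and discrimination experiments
REFERENCE = dict(
    n_variants=200, ld_rho=0.9,
    n_exposure=35_000, n_outcome=50_000, case_fraction=0.2,
    lambda_exp=0.15, theta=0.3,
)

_NONPALINDROMIC = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class Scenario:
    """Simulator configuration carrying the ground truth of one locus."""

    kind: str = "shared"
    n_variants: int = 200
    ld_rho: float = 0.9
    n_exposure: int = 35_000
    n_outcome: int = 50_000
    case_fraction: Optional[float] = 0.2  # None => quantitative outcome
    causal_index_exposure: int = 100
    causal_index_outcome: int = 100
    lambda_exp: float = 0.15
    theta: float = 0.3
    lambda_out: Optional[float] = None  # distinct/reverse outcome effect; defaults to lambda_exp
    eaf_range: tuple = (0.05, 0.95)
    palindromic_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "shared" and self.causal_index_exposure != self.causal_index_outcome:
            raise ValueError("shared scenario requires equal causal indices")
        if self.kind == "distinct" and self.causal_index_exposure == self.causal_index_outcome:
            raise ValueError("distinct scenario requires different causal indices")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        for idx in (self.causal_index_exposure, self.causal_index_outcome):
            if not (0 <= idx < self.n_variants):
                raise ValueError("causal index out of range")


def make_ld_panel(
    n_variants: int,
    ld_rho: float,
    chromosome: str = "1",
    start_bp: int = 10_000_000,
    spacing_bp: int = 10_000,
    id_prefix: str = "rs",
) -> LDPanel:
    """AR(1) LD panel: r between variants i, j is ``ld_rho ** |i - j|``."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must be in [0, 1)")
    idx = np.arange(n_variants)
    R = ld_rho ** np.abs(idx[:, None] - idx[None, :]) if ld_rho > 0 else np.eye(n_variants)
    positions = start_bp + idx * spacing_bp
    ids = [f"{id_prefix}{chromosome}_{p}" for p in positions]
    return LDPanel(variant_ids=ids, positions=positions, chromosome=str(chromosome), R=R)


def _effective_n(n: int, case_fraction: Optional[float]) -> float:
    if case_fraction is None:
        return float(n)
    return n * case_fraction * (1.0 - case_fraction)


def _chol_ar1(R: np.ndarray) -> np.ndarray:
    # AR(1) correlation matrices are positive definite for rho in [0, 1)
    return np.linalg.cholesky(R)


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for i in range(n):
        pool = _PALINDROMIC if pal[i] else _NONPALINDROMIC
        ea[i], oa[i] = pool[rng.integers(len(pool))]
    return ea, oa


def _records(
    panel: LDPanel,
    z: np.ndarray,
    n: int,
    case_fraction: Optional[float],
    eaf: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
) -> list[AssociationRecord]:
    n_eff = _effective_n(n, case_fraction)
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    se = 1.0 / (np.sqrt(n_eff) * scale)
    beta = z * se
    logp = np.log(2.0) + stats.norm.logsf(np.abs(z))
    p = np.clip(np.exp(logp), 5e-324, 1.0)
    binary = case_fraction is not None
    n_cases = int(round(n * case_fraction)) if binary else None
    return [
        AssociationRecord(
            variant_id=panel.variant_ids[i], chromosome=panel.chromosome,
            position=int(panel.positions[i]), effect_allele=str(ea[i]),
            other_allele=str(oa[i]), eaf=float(eaf[i]),
            beta=float(beta[i]), se=float(se[i]), pvalue=float(p[i]),
            n=n, n_cases=n_cases,
            trait_type="binary" if binary else "quantitative",
        )
        for i in range(len(z))
    ]


def joint_effects(scenario: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Standardized joint (causal) effect vectors for exposure and outcome."""
    lam_exp = np.zeros(scenario.n_variants)
    lam_out = np.zeros(scenario.n_variants)
    k = scenario.kind
    out_effect = scenario.lambda_out if scenario.lambda_out is not None else scenario.lambda_exp
    if k in ("shared", "distinct", "null_outcome"):
        lam_exp[scenario.causal_index_exposure] = scenario.lambda_exp
    if k == "shared":
        lam_out[scenario.causal_index_outcome] = scenario.theta * scenario.lambda_exp
    elif k == "distinct":
        # confounding by LD: the outcome variant is a genuine association of
        # its own; the exposure has no causal effect on the outcome
        lam_out[scenario.causal_index_outcome] = out_effect
    elif k == "reverse":
        # the outcome is the causal trait; its effect leaks into the exposure
        lam_out[scenario.causal_index_outcome] = out_effect
        lam_exp[scenario.causal_index_outcome] = scenario.theta * out_effect
    return lam_exp, lam_out


def simulate_locus(
    scenario: Scenario,
    panel: Optional[LDPanel] = None,
    chol: Optional[np.ndarray] = None,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Draw exposure and outcome summary statistics for one locus.

    ``panel`` defaults to a fresh AR(1) panel matching the scenario; a
    precomputed Cholesky factor of ``panel.R`` may be supplied to amortise
    the factorisation across replicates.
    """
    if panel is None:
        panel = make_ld_panel(scenario.n_variants, scenario.ld_rho)
    if len(panel.variant_ids) != scenario.n_variants:
        raise ValueError("panel size does not match scenario")
    rng = np.random.default_rng(scenario.seed)
    L = chol if chol is not None else _chol_ar1(panel.R)

    lam_exp, lam_out = joint_effects(scenario)
    mu_exp = np.sqrt(_effective_n(scenario.n_exposure, None)) * (panel.R @ lam_exp)
    mu_out = np.sqrt(_effective_n(scenario.n_outcome, scenario.case_fraction)) * (
        panel.R @ lam_out
    )

    z_exp = mu_exp + L @ rng.standard_normal(scenario.n_variants)
    z_out = mu_out + L @ rng.standard_normal(scenario.n_variants)

    lo, hi = scenario.eaf_range
    eaf = rng.uniform(lo, hi, scenario.n_variants)
    ea, oa = _draw_alleles(rng, scenario.n_variants, scenario.palindromic_fraction)

    exposure = _records(panel, z_exp, scenario.n_exposure, None, eaf, ea, oa)
    outcome = _records(panel, z_out, scenario.n_outcome, scenario.case_fraction,
                       eaf, ea, oa)
    return exposure, outcome


@dataclass
class SyntheticStudy:
    """A full synthetic screen: inputs for every pipeline stage plus truth."""

    annotations: list[GeneAnnotation]
    exposure_records: dict  # platform -> list[AssociationRecord]
    outcome_records: list[AssociationRecord]
    panels: dict  # protein_id -> LDPanel
    truth: pd.DataFrame  # protein_id, scenario, theta, causal_variant
    outcome_id: str = "disease"


def simulate_screen(
    n_proteins: int,
    null_fraction: float,
    scenario_template: Optional[Scenario] = None,
    seed: int = 0,
    platform: str = "olink",
    locus_spacing_bp: int = 50_000_000,
) -> SyntheticStudy:
    """Simulate a multi-protein screen against one binary outcome.

    Each protein gets its own locus on non-overlapping coordinates (cycling
    through the autosomes).  A deterministic ``null_fraction`` of proteins
    is simulated under ``null_outcome`` (no effect on the disease), the rest
    under the template's causal architecture.  The truth table records each
    protein's scenario kind, theta, and causal variant.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not (0.0 <= null_fraction <= 1.0):
        raise ValueError("null_fraction must be in [0, 1]")
    template = scenario_template or Scenario()
    rng = np.random.default_rng(seed)
    n_null = int(round(null_fraction * n_proteins))
    kinds = ["null_outcome"] * n_null + [template.kind] * (n_proteins - n_null)
    rng.shuffle(kinds)

    panel0 = make_ld_panel(template.n_variants, template.ld_rho)
    chol = _chol_ar1(panel0.R)

    annotations: list[GeneAnnotation] = []
    exposure: list[AssociationRecord] = []
    outcome: list[AssociationRecord] = []
    panels: dict[str, LDPanel] = {}
    truth_rows = []
    for i in range(n_proteins):
        chrom = str((i % 22) + 1)
        start = 10_000_000 + (i // 22) * locus_spacing_bp
        panel = make_ld_panel(
            template.n_variants, template.ld_rho, chromosome=chrom,
            start_bp=start, id_prefix=f"rs{i}_",
        )
        kind = kinds[i]
        scen = replace(
            template, kind=kind,
            causal_index_outcome=(
                template.causal_index_exposure
                if kind in ("shared", "null_outcome", "null_both")
                else template.causal_index_outcome
            ),
            seed=int(rng.integers(2**31 - 1)),
        )
        exp_recs, out_recs = simulate_locus(scen, panel, chol=chol)
        protein = f"P{i:04d}"
        gene_start = int(panel.positions[scen.causal_index_exposure]) - 5_000
        annotations.append(GeneAnnotation(
            gene_id=f"GENE{i:04d}", protein_id=protein, chromosome=chrom,
            start=gene_start, end=gene_start + 10_000, tss=gene_start,
            platform=platform, assay_id=f"{platform.upper()}_{i:04d}",
        ))
        exposure.extend(exp_recs)
        outcome.extend(out_recs)
        panels[protein] = panel
        truth_rows.append({
            "protein_id": protein, "scenario": kind,
            # forward (exposure -> outcome) causal effect; zero except under shared
            "theta": scen.theta if kind == "shared" else 0.0,
            "causal_variant": panel.variant_ids[scen.causal_index_exposure],
        })
    truth = pd.DataFrame(truth_rows)
    return SyntheticStudy(
        annotations=annotations,
        exposure_records={platform: exposure},
        outcome_records=outcome,
        panels=panels,
        truth=truth,
    )


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write a synthetic study in the pipeline's canonical input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for platform, records in study.exposure_records.items():
        p = out / f"exposure_{platform}.tsv"
        write_sumstats(records, p)
        paths[f"exposure_{platform}"] = p
    write_sumstats(study.outcome_records, out / "outcome.tsv")
    paths["outcome"] = out / "outcome.tsv"
    write_annotations(study.annotations, out / "annotations.tsv")
    paths["annotations"] = out / "annotations.tsv"
    panel_dir = out / "ld_panels"
    panel_dir.mkdir(exist_ok=True)
    for protein, panel in study.panels.items():
        write_ld_panel(panel, panel_dir / protein)
    paths["ld_panels"] = panel_dir
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    return paths
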