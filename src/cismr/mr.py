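"""Mendelian-randomization estimators, multiplicity control, and diagnostics.

The primary estimator is the single-variant Wald ratio, beta_out / beta_exp,
with a first-order delta-method standard error se_out / |beta_exp| (the
second-order form, which also propagates the exposure SE, is available by
flag).  Multi-variant estimates for the reverse-direction analysis use a
multiplicative random-effects inverse-variance weighted (IVW) model whose SE
inflation is floored at 1 (Cochran's Q / (k - 1)).  Discovery is controlled
by Benjamini-Hochberg FDR within a test family; the genomic inflation factor
lambda summarises residual departure from the null.

P-values are computed from the two-sided normal reference in log space, so
extreme z-scores (|z| > 38, where the survival function underflows in double
precision) still yield a usable log10 p-value; the linear-scale p is clamped
to the smallest positive double.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .instruments import Instrument
from .sumstats import AssociationRecord, HarmonizedPair, harmonize_pair

logger = logging.getLogger(__name__)

_CHI2_1_MEDIAN = 0.4549364231195724  # chi2.ppf(0.5, df=1)
_Z975 = 1.959963984540054
_TINY = 5e-324  # smallest subnormal double; keeps p in (0, 1]


def normal_p_two_sided(z: float) -> tuple[float, float]:
    """Two-sided normal p-value and its log10, stable for extreme ``z``."""
    log_p = math.log(2.0) + stats.norm.logsf(abs(z))
    log10_p = log_p / math.log(10.0)
    p = math.exp(log_p) if log_p > -744 else 0.0
    return max(min(p, 1.0), _TINY), log10_p


@dataclass
class MREstimate:
    """A Wald-ratio or IVW causal-effect estimate."""

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw_random
    beta_mr: float
    se_mr: float
    pvalue: float
    log10_pvalue: float
    ci_low: float
    ci_high: float
    n_variants: int
    outcome_binary: bool = False
    variant_id: Optional[str] = None
    q_statistic: Optional[float] = None

    @property
    def or_point(self) -> float:
        """Odds ratio per exposure unit (meaningful for binary outcomes)."""
        return math.exp(self.beta_mr)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class FDRResult:
    """Benjamini-Hochberg outcome for one test family."""

    m: int
    alpha: float
    k: int
    cutoff: float  # largest BH-passing threshold k * alpha / m
    flags: np.ndarray  # per-test discovery indicator, input order


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Single-variant Wald-ratio estimate from a harmonized pair.

    ``beta_mr = beta_out / beta_exp``.  The default SE is the first-order
    delta-method form ``se_out / |beta_exp|``; with ``second_order=True`` the
    exposure uncertainty is propagated as well:
    ``sqrt(se_out^2/beta_exp^2 + beta_out^2 * se_exp^2 / beta_exp^4)``.
    """
    if pair.dropped or pair.outcome is None:
        raise ValueError("cannot estimate from a dropped pair")
    exp, out = pair.exposure, pair.outcome
    if exp.beta == 0:
        raise ZeroDivisionError("undefined ratio: exposure beta is 0")
    beta = out.beta / exp.beta
    if second_order:
        se = math.sqrt(
            out.se**2 / exp.beta**2 + out.beta**2 * exp.se**2 / exp.beta**4
        )
    else:
        se = out.se / abs(exp.beta)
    p, log10_p = normal_p_two_sided(beta / se)
    return MREstimate(
        exposure_id=exp.variant_id, outcome_id=out.variant_id,
        method="wald_ratio", beta_mr=beta, se_mr=se,
        pvalue=p, log10_pvalue=log10_p,
        ci_low=beta - _Z975 * se, ci_high=beta + _Z975 * se,
        n_variants=1, outcome_binary=(out.trait_type == "binary"),
        variant_id=exp.variant_id,
    )


def ivw_random(ratios: Sequence[MREstimate]) -> MREstimate:
    """Multiplicative random-effects IVW pooling of per-variant Wald ratios.

    Weights are 1/se^2; under heterogeneity the fixed-effect SE is inflated
    by sqrt(max(1, Q/(k-1))) where Q is Cochran's statistic.  With a single
    ratio the input estimate is returned unchanged apart from the method tag.
    """
    if not ratios:
        raise ValueError("ivw_random requires at least one ratio")
    betas = np.array([r.beta_mr for r in ratios])
    ses = np.array([r.se_mr for r in ratios])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    k = len(ratios)
    q: Optional[float] = None
    if k >= 2:
        q = float(np.sum(w * (betas - beta) ** 2))
        se *= math.sqrt(max(1.0, q / (k - 1)))
    p, log10_p = normal_p_two_sided(beta / se)
    return MREstimate(
        exposure_id=ratios[0].exposure_id, outcome_id=ratios[0].outcome_id,
        method="ivw_random", beta_mr=beta, se_mr=se,
        pvalue=p, log10_pvalue=log10_p,
        ci_low=beta - _Z975 * se, ci_high=beta + _Z975 * se,
        n_variants=k, outcome_binary=ratios[0].outcome_binary,
        q_statistic=q,
    )


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up procedure at FDR level ``alpha``.

    The reported ``cutoff`` is k*alpha/m for the largest passing rank k
    (0 when nothing is discovered); every test with p <= p_(k) is flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, m + 1)
    passing = sorted_p <= ranks * alpha / m
    if not passing.any():
        return FDRResult(m=m, alpha=alpha, k=0, cutoff=0.0,
                         flags=np.zeros(m, dtype=bool))
    k = int(np.max(ranks[passing]))
    threshold = sorted_p[k - 1]
    flags = p <= threshold
    return FDRResult(m=m, alpha=alpha, k=int(flags.sum()),
                     cutoff=k * alpha / m, flags=flags)


def bh_implied_cutoff(n_discoveries: int, n_tests: int, alpha: float = 0.05) -> float:
    """The BH threshold k*alpha/m implied by a reported discovery count."""
    return n_discoveries * alpha / n_tests


def inflation_factor(pvalues: Sequence[float]) -> float:
    """Genomic inflation factor lambda from a set of p-values.

    lambda = median(chi2_1 quantiles of 1 - p) / median of chi2_1.  A
    well-calibrated null set gives lambda ~= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("inflation_factor requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


@dataclass
class ScreenResult:
    """MR screen output: per-pair estimates, family-wise FDR, skip log."""

    estimates: list[MREstimate]
    fdr: Optional[FDRResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (exposure, reason)


def run_mr_screen(
    instruments: Sequence[Instrument],
    outcome_records: dict[str, AssociationRecord],
    outcome_id: str,
    alpha: float = 0.05,
    apply_fdr: bool = True,
) -> ScreenResult:
    """Wald-ratio screen of many instruments against one outcome GWAS.

    Each instrument is harmonized against the outcome record for its variant;
    instruments whose variant is absent, or whose pair is dropped in
    harmonization, are skipped with a logged reason.  BH-FDR is applied over
    the screen's estimates when ``apply_fdr`` (families spanning several
    outcomes should instead pool p-values and call :func:`bh_fdr` once).
    """
    estimates: list[MREstimate] = []
    skipped: list[tuple[str, str]] = []
    for inst in instruments:
        exposure_id = f"{inst.gene.protein_id}:{inst.gene.platform}"
        out_rec = outcome_records.get(inst.record.variant_id)
        if out_rec is None:
            skipped.append((exposure_id, "variant_absent_from_outcome"))
            logger.info("skip %s: variant %s absent from %s",
                        exposure_id, inst.record.variant_id, outcome_id)
            continue
        pair = harmonize_pair(inst.record, out_rec)
        if pair.dropped:
            skipped.append((exposure_id, pair.drop_reason or "dropped"))
            continue
        est = wald_ratio(pair)
        est.exposure_id = exposure_id
        est.outcome_id = outcome_id
        est.variant_id = inst.record.variant_id
        estimates.append(est)
    fdr = bh_fdr([e.pvalue for e in estimates], alpha) if (apply_fdr and estimates) else None
    return ScreenResult(estimates=estimates, fdr=fdr, skipped=skipped)
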