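"""Single-causal-variant Bayesian colocalization of two association signals.

Each variant's evidence for association with a trait is summarised by
Wakefield's approximate Bayes factor (ABF), computed from the marginal beta
and SE under a normal effect prior with variance W:

    log ABF = 1/2 * [ log(V / (V + W)) + z^2 * W / (V + W) ],   V = se^2.

Five hypotheses about a locus are compared — H0 no association, H1/H2
association with one trait only, H3 two distinct causal variants, H4 one
shared causal variant — by summing per-configuration likelihoods weighted by
per-variant prior probabilities p1, p2, p12.  All sums are accumulated in
log space.  Posterior PP4 > 0.80 is read as strong evidence of a shared
variant, 0.60 < PP4 <= 0.80 as moderate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .instruments import Instrument
from .sumstats import AssociationRecord, harmonize_pair

logger = logging.getLogger(__name__)

#: prior effect standard deviations of the cited conventions, squared below
W_QUANTITATIVE = 0.2**2
W_BINARY = 0.15**2


@dataclass
class ColocPriors:
    """Per-variant causal priors and per-trait effect-prior variances."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = W_QUANTITATIVE
    w2: float = W_BINARY

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior variances must be positive")

    def swapped(self) -> "ColocPriors":
        return ColocPriors(p1=self.p2, p2=self.p1, p12=self.p12,
                           w1=self.w2, w2=self.w1)


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one locus."""

    n_variants: int
    pp: np.ndarray  # PP0..PP4, sums to 1
    log_abf_1: np.ndarray
    log_abf_2: np.ndarray
    lead_variant: Optional[str]
    classification: str  # strong | moderate | none

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def classify_pp4(pp4: float) -> str:
    """Map PP4 to the evidence tier: strong (> 0.80), moderate (> 0.60)."""
    if pp4 > 0.80:
        return "strong"
    if pp4 > 0.60:
        return "moderate"
    return "none"


def log_abf(beta: float, se: float, w: float) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    Positive values favour association over the null; ``w`` is the prior
    variance of the true effect on the same scale as ``beta``.
    """
    if se <= 0:
        raise ValueError("se must be > 0")
    if w <= 0:
        raise ValueError("prior variance must be > 0")
    v = se * se
    z = beta / se
    r = w / (v + w)
    return 0.5 * (math.log(v / (v + w)) + z * z * r)


def colocalize(
    trait1: Sequence[AssociationRecord],
    trait2: Sequence[AssociationRecord],
    priors: ColocPriors = ColocPriors(),
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``trait1`` and ``trait2`` must be parallel lists over the same variants
    (same order), already harmonized to common effect alleles; use
    :func:`coloc_window` to build them from raw summary statistics.
    """
    if len(trait1) == 0:
        raise ValueError("no shared variants")
    if len(trait1) != len(trait2):
        raise ValueError("trait record lists differ in length")
    for a, b in zip(trait1, trait2):
        if a.variant_id != b.variant_id:
            raise ValueError(f"variant order mismatch at {a.variant_id}/{b.variant_id}")

    la1 = np.array([log_abf(r.beta, r.se, priors.w1) for r in trait1])
    la2 = np.array([log_abf(r.beta, r.se, priors.w2) for r in trait2])

    log_sum1 = logsumexp(la1)
    log_sum2 = logsumexp(la2)
    log_sum12 = logsumexp(la1 + la2)

    log_h = np.empty(5)
    log_h[0] = 0.0
    log_h[1] = math.log(priors.p1) + log_sum1
    log_h[2] = math.log(priors.p2) + log_sum2
    # H3 sums over ordered pairs i != j: sum_i L1_i * sum_j L2_j - sum_i L1_i L2_i
    cross = log_sum1 + log_sum2
    with np.errstate(divide="ignore"):
        diff = cross + np.log1p(-math.exp(min(log_sum12 - cross, 0.0)))
    log_h[3] = math.log(priors.p1) + math.log(priors.p2) + diff
    log_h[4] = math.log(priors.p12) + log_sum12

    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()

    joint = la1 + la2
    lead = trait1[int(np.argmax(joint))].variant_id
    return ColocResult(
        n_variants=len(trait1), pp=pp, log_abf_1=la1, log_abf_2=la2,
        lead_variant=lead, classification=classify_pp4(float(pp[4])),
    )


def coloc_window(
    lead: Instrument,
    trait1_records: Sequence[AssociationRecord],
    trait2_records: Sequence[AssociationRecord],
    radius_bp: int = 1_000_000,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Extract and align the +-``radius_bp`` locus around a lead variant.

    Returns parallel record lists (identical variant order) for the two
    traits, restricted to the lead's chromosome and window, intersected on
    variant_id, and with trait2 harmonized to trait1's effect alleles.
    Palindromic-ambiguous and allele-incompatible variants are dropped with
    a logged count.
    """
    chrom = lead.record.chromosome
    lo = lead.record.position - radius_bp
    hi = lead.record.position + radius_bp

    def in_window(r: AssociationRecord) -> bool:
        return r.chromosome == chrom and lo <= r.position <= hi

    t1 = {r.variant_id: r for r in trait1_records if in_window(r)}
    t2 = {r.variant_id: r for r in trait2_records if in_window(r)}
    shared = [v for v in t1 if v in t2]

    out1: list[AssociationRecord] = []
    out2: list[AssociationRecord] = []
    n_dropped = 0
    for vid in shared:
        pair = harmonize_pair(t1[vid], t2[vid])
        if pair.dropped:
            n_dropped += 1
            continue
        out1.append(pair.exposure)
        out2.append(pair.outcome)
    if n_dropped:
        logger.info("coloc_window: dropped %d unharmonizable variants", n_dropped)
    if not out1:
        raise ValueError("no shared variants in colocalization window")
    return out1, out2
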