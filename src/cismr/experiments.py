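"""Reference Monte-Carlo experiments on the synthetic generator.

These are the package's standard calibration and discrimination studies,
all run at the generator's reference conditions (35,000-sample quantitative
exposure; 50,000-sample binary outcome with 20% cases; standardized exposure
effect 0.15; causal effect theta = 0.3; 200-variant AR(1) locus with
rho = 0.9).  They are used by the test suite and by the acceptance script;
each takes an explicit seed and returns plain dictionaries of results.

The colocalization discrimination experiment mirrors the pipeline's design:
colocalization is applied to loci that pass the MR screen, so the shared-
causal PP4 rate is reported both for screen-significant replicates (the
population the coloc stage actually sees) and unconditionally.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .coloc import ColocPriors, colocalize
from .evidence import load_screen_families
from .mr import bh_implied_cutoff, inflation_factor, wald_ratio
from .simulate import REFERENCE, Scenario, make_ld_panel, simulate_locus, _chol_ar1
from .sumstats import harmonize_pair

TRUE_THETA = REFERENCE["theta"]

#: offset between the distinct scenario's causal variants: 4 steps of the
#: reference AR(1) panel, i.e. r = 0.9^4 ~ 0.66 and r^2 ~ 0.43
DISTINCT_OFFSET = 4


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def pqtl_screen_cutoff() -> float:
    """The main screen's BH-implied significance threshold, recomputed from
    the packaged per-family discovery counts."""
    fam = load_screen_families().set_index("screen")
    row = fam.loc["plasma_pqtl"]
    return bh_implied_cutoff(int(row["n_discoveries"]), int(row["n_tests"]),
                             float(row["alpha"]))


def wald_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Bias and 95% CI coverage of the Wald ratio under shared causality."""
    panel = make_ld_panel(REFERENCE["n_variants"], REFERENCE["ld_rho"])
    chol = _chol_ar1(panel.R)
    estimates, covered = [], []
    for s in _seeds(seed, n_reps):
        sc = Scenario(kind="shared", seed=int(s))
        exp, out = simulate_locus(sc, panel, chol=chol)
        ci = sc.causal_index_exposure
        pair = harmonize_pair(exp[ci], out[ci])
        if pair.dropped:
            continue
        est = wald_ratio(pair)
        estimates.append(est.beta_mr)
        covered.append(est.ci_low <= TRUE_THETA <= est.ci_high)
    estimates = np.asarray(estimates)
    return {
        "n": len(estimates),
        "mean_wald": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / np.sqrt(len(estimates))),
        "ci_coverage": float(np.mean(covered)),
        "true_theta": TRUE_THETA,
    }


def coloc_discrimination(n_reps: int = 300, seed: int = 0) -> dict:
    """Shared-causal PP4 rates, overall and among MR-screen discoveries."""
    panel = make_ld_panel(REFERENCE["n_variants"], REFERENCE["ld_rho"])
    chol = _chol_ar1(panel.R)
    cutoff = pqtl_screen_cutoff()
    priors = ColocPriors()
    pp4_all, pp4_hits = [], []
    for s in _seeds(seed, n_reps):
        sc = Scenario(kind="shared", seed=int(s))
        exp, out = simulate_locus(sc, panel, chol=chol)
        ci = sc.causal_index_exposure
        pair = harmonize_pair(exp[ci], out[ci])
        res = colocalize(exp, out, priors)
        pp4_all.append(res.pp4)
        if not pair.dropped and wald_ratio(pair).pvalue < cutoff:
            pp4_hits.append(res.pp4)
    pp4_all, pp4_hits = np.asarray(pp4_all), np.asarray(pp4_hits)
    return {
        "n": len(pp4_all),
        "n_screen_significant": len(pp4_hits),
        "screen_cutoff": cutoff,
        "pp4_strong_rate_screened": float(np.mean(pp4_hits > 0.80)),
        "pp4_strong_rate_all": float(np.mean(pp4_all > 0.80)),
        "median_pp4": float(np.median(pp4_all)),
    }


def distinct_confounding(n_reps: int = 300, seed: int = 0) -> dict:
    """Confounding by LD: distinct causal variants in moderate LD should be
    flagged by the Wald screen but resolved as PP3 by colocalization."""
    panel = make_ld_panel(REFERENCE["n_variants"], REFERENCE["ld_rho"])
    chol = _chol_ar1(panel.R)
    cutoff = pqtl_screen_cutoff()
    priors = ColocPriors()
    modal, flagged = [], []
    base = Scenario(kind="distinct",
                    causal_index_outcome=100 + DISTINCT_OFFSET)
    for s in _seeds(seed, n_reps):
        sc = replace(base, seed=int(s))
        exp, out = simulate_locus(sc, panel, chol=chol)
        ci = sc.causal_index_exposure
        pair = harmonize_pair(exp[ci], out[ci])
        if not pair.dropped:
            flagged.append(wald_ratio(pair).pvalue < cutoff)
        res = colocalize(exp, out, priors)
        modal.append(int(np.argmax(res.pp)))
    modal = np.asarray(modal)
    return {
        "n": len(modal),
        "r_causal_pair": float(REFERENCE["ld_rho"] ** DISTINCT_OFFSET),
        "pp3_modal_rate": float(np.mean(modal == 3)),
        "screen_flag_rate": float(np.mean(flagged)),
    }


def null_calibration(n_reps: int = 500, n_instruments: int = 10,
                     seed: int = 0, n_variants: int = 25) -> dict:
    """Type-I error and genomic inflation of the Wald screen when the
    exposure has no effect on the outcome (null_outcome architecture)."""
    panel = make_ld_panel(n_variants, REFERENCE["ld_rho"])
    chol = _chol_ar1(panel.R)
    ci = n_variants // 2
    pvals = []
    for s in _seeds(seed, n_reps * n_instruments):
        sc = Scenario(kind="null_outcome", n_variants=n_variants,
                      causal_index_exposure=ci, causal_index_outcome=ci,
                      seed=int(s))
        exp, out = simulate_locus(sc, panel, chol=chol)
        pair = harmonize_pair(exp[ci], out[ci])
        if pair.dropped:
            continue
        pvals.append(wald_ratio(pair).pvalue)
    pvals = np.asarray(pvals)
    return {
        "n_tests": len(pvals),
        "type1_rate": float(np.mean(pvals < 0.05)),
        "lambda": float(inflation_factor(pvals)),
    }
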