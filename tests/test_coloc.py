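"""Colocalization: the Wakefield ABF and the five-hypothesis posterior,
checked against numerical integration and an exhaustive configuration oracle.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from cismr.coloc import ColocPriors, classify_pp4, coloc_window, colocalize, log_abf
from cismr.instruments import Instrument
from cismr.simulate import Scenario, make_ld_panel, simulate_locus
from cismr.sumstats import AssociationRecord


class TestLogABF:
    def test_null_z_favours_the_null(self):
        assert log_abf(0.0, 0.02, 0.04) == pytest.approx(
            0.5 * math.log(0.0004 / 0.0404)
        )
        assert log_abf(0.0, 0.02, 0.04) < 0

    def test_vanishing_prior_gives_zero_evidence(self):
        assert log_abf(0.1, 0.02, 1e-12) == pytest.approx(0.0, abs=1e-6)

    def test_direct_numeric_value(self):
        got = log_abf(0.1, 0.02, 0.04)
        expected = 0.5 * (math.log(0.0004 / 0.0404) + 25 * (0.04 / 0.0404))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(10.069, abs=1e-3)

    def test_matches_numerical_integration_of_marginal_likelihood(self):
        """ABF = integral N(bhat; b, V) N(b; 0, W) db / N(bhat; 0, V)."""
        beta, se, w = 0.05, 0.02, 0.04
        v = se**2

        def integrand(b):
            return stats.norm.pdf(beta, b, math.sqrt(v)) * stats.norm.pdf(b, 0, math.sqrt(w))

        marginal, _ = integrate.quad(integrand, -2, 2)
        expected = math.log(marginal / stats.norm.pdf(beta, 0, math.sqrt(v)))
        assert log_abf(beta, se, w) == pytest.approx(expected, rel=1e-8)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            log_abf(0.1, 0.0, 0.04)
        with pytest.raises(ValueError):
            log_abf(0.1, 0.1, 0.0)


def _locus(record, zs1, zs2, se=0.02):
    t1, t2 = [], []
    for i, (z1, z2) in enumerate(zip(zs1, zs2)):
        kw = dict(variant_id=f"v{i}", position=1_000_000 + i, pvalue=0.5)
        t1.append(record(beta=z1 * se, se=se, **kw))
        t2.append(record(beta=z2 * se, se=se, **kw))
    return t1, t2


def _coloc_oracle(t1, t2, priors):
    """Exhaustive enumeration over all causal configurations: the empty
    configuration, single-trait singletons, ordered distinct pairs, and
    shared singletons, each weighted by its prior."""
    L1 = [math.exp(log_abf(r.beta, r.se, priors.w1)) for r in t1]
    L2 = [math.exp(log_abf(r.beta, r.se, priors.w2)) for r in t2]
    n = len(L1)
    h = np.zeros(5)
    h[0] = 1.0
    for i in range(n):
        h[1] += priors.p1 * L1[i]
        h[2] += priors.p2 * L2[i]
        h[4] += priors.p12 * L1[i] * L2[i]
    for i, j in itertools.permutations(range(n), 2):
        h[3] += priors.p1 * priors.p2 * L1[i] * L2[j]
    return h / h.sum()


class TestColocalize:
    def test_null_locus_prefers_h0(self, record):
        t1, t2 = _locus(record, [0.0], [0.0])
        res = colocalize(t1, t2)
        assert np.argmax(res.pp) == 0

    def test_single_strong_shared_variant_excludes_h3(self, record):
        t1, t2 = _locus(record, [8.0], [7.5])
        res = colocalize(t1, t2)
        assert res.pp[3] == 0.0  # structurally impossible with one variant
        assert res.pp[4] > 0.9

    def test_posteriors_sum_to_one(self, record):
        rng = np.random.default_rng(3)
        t1, t2 = _locus(record, rng.normal(0, 2, 30), rng.normal(0, 2, 30))
        res = colocalize(t1, t2)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-12)
        assert (res.pp >= 0).all()

    @pytest.mark.parametrize("seed,pattern", [
        (0, "null"), (1, "shared"), (2, "distinct"), (3, "trait1_only"),
    ])
    def test_matches_exhaustive_configuration_oracle(self, record, seed, pattern):
        rng = np.random.default_rng(seed)
        n = 50
        z1 = rng.normal(0, 1, n)
        z2 = rng.normal(0, 1, n)
        if pattern == "shared":
            z1[20] += 7
            z2[20] += 6
        elif pattern == "distinct":
            z1[10] += 7
            z2[40] += 6
        elif pattern == "trait1_only":
            z1[5] += 7
        t1, t2 = _locus(record, z1, z2)
        priors = ColocPriors()
        res = colocalize(t1, t2, priors)
        expected = _coloc_oracle(t1, t2, priors)
        np.testing.assert_allclose(res.pp, expected, atol=1e-10)

    def test_label_symmetry(self, record):
        rng = np.random.default_rng(11)
        z1, z2 = rng.normal(0, 2, 20), rng.normal(0, 2, 20)
        z1[4] += 5
        t1, t2 = _locus(record, z1, z2)
        priors = ColocPriors(p1=2e-4, p2=1e-4, p12=5e-5, w1=0.04, w2=0.0225)
        a = colocalize(t1, t2, priors)
        b = colocalize(t2, t1, priors.swapped())
        assert b.pp[1] == pytest.approx(a.pp[2], rel=1e-10)
        assert b.pp[2] == pytest.approx(a.pp[1], rel=1e-10)
        for h in (0, 3, 4):
            assert b.pp[h] == pytest.approx(a.pp[h], rel=1e-10)

    def test_lead_variant_maximizes_joint_abf(self, record):
        z1 = [0.5, 6.0, 1.0]
        z2 = [0.2, 5.5, 0.9]
        t1, t2 = _locus(record, z1, z2)
        res = colocalize(t1, t2)
        assert res.lead_variant == "v1"

    def test_empty_locus_is_an_error(self):
        with pytest.raises(ValueError):
            colocalize([], [])

    def test_scale_shift_of_one_trait_keeps_h4_h3_structure(self, record):
        """Adding a constant c to every log-ABF of trait 2 multiplies H2, H3
        and H4 by e^c, leaving the PP4/(PP3+PP4) ratio invariant."""
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(0, 2, 15), rng.normal(0, 2, 15)
        t1, t2 = _locus(record, z1, z2)
        priors = ColocPriors()
        base = colocalize(t1, t2, priors)
        # emulate the shift by scaling all trait-2 prior odds via p2, p12
        c = -3.0
        shifted = ColocPriors(p1=priors.p1, p2=priors.p2 * math.e**c,
                              p12=priors.p12 * math.e**c,
                              w1=priors.w1, w2=priors.w2)
        res = colocalize(t1, t2, shifted)
        ratio_base = base.pp[4] / (base.pp[3] + base.pp[4])
        ratio_shift = res.pp[4] / (res.pp[3] + res.pp[4])
        assert ratio_shift == pytest.approx(ratio_base, rel=1e-9)


@pytest.mark.parametrize("pp4,expected", [
    (0.85, "strong"), (0.70, "moderate"), (0.80, "moderate"),
    (0.60, "none"), (0.10, "none"),
])
def test_classification_thresholds(pp4, expected):
    assert classify_pp4(pp4) == expected


class TestColocWindow:
    def _inst(self, record, gene, position=10_000_000):
        return Instrument(record=record(position=position), gene=gene(),
                          f_statistic=100.0)

    def test_window_arithmetic(self, record, gene):
        lead = self._inst(record, gene)
        mk = lambda pos, vid: record(variant_id=vid, position=pos)
        t1 = [mk(8_900_000, "a"), mk(9_500_000, "b"), mk(11_100_000, "c"),
              record(position=10_000_000)]
        t2 = [mk(9_500_000, "b"), mk(11_100_000, "c")]
        w1, w2 = coloc_window(lead, t1, t2)
        assert [r.variant_id for r in w1] == ["b"]

    def test_disjoint_traits_raise(self, record, gene):
        lead = self._inst(record, gene)
        t1 = [record(variant_id="a", position=10_000_000)]
        t2 = [record(variant_id="b", position=10_000_500)]
        with pytest.raises(ValueError, match="no shared variants"):
            coloc_window(lead, t1, t2)

    def test_simulated_locus_alignment(self, record, gene):
        sc = Scenario(n_variants=50, causal_index_exposure=25,
                      causal_index_outcome=25, seed=9)
        panel = make_ld_panel(50, 0.9)
        exp, out = simulate_locus(sc, panel)
        lead = Instrument(record=exp[25], gene=gene(), f_statistic=100.0)
        w1, w2 = coloc_window(lead, exp, out)
        assert [r.variant_id for r in w1] == [r.variant_id for r in w2]
        assert all(a.effect_allele == b.effect_allele for a, b in zip(w1, w2))
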