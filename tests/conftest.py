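"""Shared fixtures: record builders, small LD panels, reference scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from cismr.ld import LDPanel
from cismr.simulate import Scenario, make_ld_panel, _chol_ar1
from cismr.sumstats import AssociationRecord, GeneAnnotation


@pytest.fixture
def record():
    """Factory for AssociationRecords with sensible defaults."""

    def make(
        variant_id="rs1", chromosome="1", position=10_000_000,
        ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, pvalue=1e-8,
        n=10_000, n_cases=None,
    ):
        return AssociationRecord(
            variant_id=variant_id, chromosome=chromosome, position=position,
            effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta, se=se,
            pvalue=pvalue, n=n, n_cases=n_cases,
            trait_type="binary" if n_cases is not None else "quantitative",
        )

    return make


@pytest.fixture
def gene():
    """Factory for GeneAnnotations with sensible defaults."""

    def make(
        gene_id="G1", protein_id="P1", chromosome="1",
        start=10_000_000, end=10_100_000, tss=10_000_000,
        platform="olink", assay_id="A1",
    ):
        return GeneAnnotation(
            gene_id=gene_id, protein_id=protein_id, chromosome=chromosome,
            start=start, end=end, tss=tss, platform=platform, assay_id=assay_id,
        )

    return make


@pytest.fixture(scope="session")
def reference_panel() -> LDPanel:
    """The 200-variant, rho=0.9 AR(1) panel of the reference scenario."""
    return make_ld_panel(200, 0.9)


@pytest.fixture(scope="session")
def reference_chol(reference_panel):
    return _chol_ar1(reference_panel.R)
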