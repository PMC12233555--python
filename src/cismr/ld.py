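"""LD correlation panels and greedy p-value clumping of summary statistics.

A panel stores a per-region variant index (id, chromosome, position) and the
corresponding symmetric correlation matrix R.  Panels are exchanged on disk
as a pair of files: ``<stem>.ld.tsv`` (the square matrix, tab-separated, no
header) and ``<stem>.index.tsv`` (variant_id, chr, pos).

Clumping follows the PLINK convention: among variants passing the p-value
cutoff, repeatedly promote the smallest-p unassigned variant to index status
and discard every unassigned variant within the base-pair window whose
squared correlation with it meets the r2 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import AssociationRecord

logger = logging.getLogger(__name__)


@dataclass
class LDPanel:
    """Variant index plus correlation matrix for one genomic region."""

    variant_ids: list[str]
    positions: np.ndarray
    chromosome: str
    R: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.variant_ids)
        if self.R.shape != (n, n):
            raise ValueError(f"R shape {self.R.shape} does not match {n} variants")
        if len(self.positions) != n:
            raise ValueError("positions length does not match variant_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValueError("R is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R diagonal is not 1")
        if np.any(np.abs(self.R) > 1.0 + 1e-8):
            raise ValueError("R entries outside [-1, 1]")

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def r2(self, a: str, b: str) -> float:
        return float(self.R[self.index_of(a), self.index_of(b)] ** 2)


def write_ld_panel(panel: LDPanel, stem) -> tuple[Path, Path]:
    """Write ``<stem>.ld.tsv`` and ``<stem>.index.tsv``."""
    ld_path = Path(str(stem) + ".ld.tsv")
    idx_path = Path(str(stem) + ".index.tsv")
    np.savetxt(ld_path, panel.R, delimiter="\t", fmt="%.10g")
    pd.DataFrame({
        "variant_id": panel.variant_ids,
        "chr": panel.chromosome,
        "pos": panel.positions,
    }).to_csv(idx_path, sep="\t", index=False)
    return ld_path, idx_path


def read_ld_panel(stem) -> LDPanel:
    """Read a panel written by :func:`write_ld_panel`."""
    R = np.loadtxt(str(stem) + ".ld.tsv", delimiter="\t", ndmin=2)
    idx = pd.read_csv(str(stem) + ".index.tsv", sep="\t", dtype=str)
    return LDPanel(
        variant_ids=list(idx["variant_id"]),
        positions=idx["pos"].astype(int).to_numpy(),
        chromosome=str(idx["chr"].iloc[0]),
        R=R,
    )


def clump(
    records: Iterable[AssociationRecord],
    panel: LDPanel,
    p_max: float = 5e-8,
    window_bp: int = 1_000_000,
    r2_max: float = 0.001,
) -> list[AssociationRecord]:
    """Greedy LD clumping; returns index variants in selection order.

    Variants absent from the panel are dropped (logged).  Cross-chromosome
    pairs are never clumped together; the distance test is
    ``|pos_i - pos_j| <= window_bp`` on the panel's chromosome.  Ties in p
    are broken by position then variant_id, so the result is invariant to
    input row order.
    """
    pos_by_id = dict(zip(panel.variant_ids, panel.positions))
    idx_by_id = {v: i for i, v in enumerate(panel.variant_ids)}

    candidates = []
    n_absent = 0
    for rec in records:
        if rec.variant_id not in idx_by_id:
            n_absent += 1
            continue
        if rec.chromosome != panel.chromosome:
            n_absent += 1
            continue
        if rec.pvalue <= p_max:
            candidates.append(rec)
    if n_absent:
        logger.info("clump: %d records absent from panel, dropped", n_absent)

    candidates.sort(key=lambda r: (r.pvalue, r.position, r.variant_id))
    assigned: set[str] = set()
    index_variants: list[AssociationRecord] = []
    for rec in candidates:
        if rec.variant_id in assigned:
            continue
        index_variants.append(rec)
        assigned.add(rec.variant_id)
        i = idx_by_id[rec.variant_id]
        for other in candidates:
            if other.variant_id in assigned:
                continue
            if abs(int(pos_by_id[other.variant_id]) - rec.position) > window_bp:
                continue
            j = idx_by_id[other.variant_id]
            if panel.R[i, j] ** 2 >= r2_max:
                assigned.add(other.variant_id)
    return index_variants
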