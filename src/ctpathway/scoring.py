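"""Gene risk scores and pathway enrichment scores.

RS_j = sum_i C_ij * DE_i  (propagated burden of gene j), and the pathway
score PS is the mean RS over the pathway's genes that are present in the
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .gpcm import Gpcm, PathwaySet
from .profiles import DEVector
from .propagation import CrosstalkMatrix

log = logging.getLogger(__name__)

__all__ = [
    "RiskScores",
    "PathwayScore",
    "compute_risk_scores",
    "membership_matrix",
    "compute_pathway_scores",
]


@dataclass
class RiskScores:
    """Risk score per network gene, aligned with the GPCM node order."""

    genes: list[str]
    values: np.ndarray

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self.genes.index(gene)])


@dataclass
class PathwayScore:
    pathway_id: str
    name: str
    n: int  # member genes present in the network
    ps: float
    coverage: float  # fraction of annotated genes present in the network
    source_db: str = ""


def compute_risk_scores(C: CrosstalkMatrix, de: DEVector) -> RiskScores:
    """RS = C @ DE over all network genes."""
    if C.seed_order != de.genes:
        raise ValueError("crosstalk seed order does not match DE vector gene order")
    rs = C.C @ de.values
    return RiskScores(genes=list(C.genes), values=np.asarray(rs, dtype=float))


def membership_matrix(
    pathways: Sequence[PathwaySet], gpcm: Gpcm, min_size: int = 3
) -> tuple[sp.csr_matrix, list[PathwaySet]]:
    """Row-averaging indicator matrix M (pathways x N) with entries 1/n.

    Pathways with fewer than ``min_size`` network genes are skipped (logged);
    M @ RS yields all pathway scores at once.
    """
    kept: list[PathwaySet] = []
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for pw in pathways:
        members = sorted(g for g in pw.genes if g in gpcm)
        if len(members) < max(min_size, 1):
            log.info("pathway %s skipped: %d network gene(s) < floor %d", pw.id, len(members), min_size)
            continue
        r = len(kept)
        kept.append(pw)
        for g in members:
            rows.append(r)
            cols.append(gpcm.node_index[g])
            data.append(1.0 / len(members))
    M = sp.csr_matrix((data, (rows, cols)), shape=(len(kept), gpcm.n))
    return M, kept


def compute_pathway_scores(
    rs: RiskScores,
    pathways: Sequence[PathwaySet],
    gpcm: Gpcm,
    min_size: int = 3,
) -> list[PathwayScore]:
    """Mean risk score over each pathway's network-covered genes."""
    M, kept = membership_matrix(pathways, gpcm, min_size=min_size)
    ps = M @ rs.values
    out = []
    for pw, score, row in zip(kept, ps, M):
        n = row.nnz
        out.append(
            PathwayScore(
                pathway_id=pw.id,
                name=pw.name,
                n=n,
                ps=float(score),
                coverage=n / len(pw.genes),
                source_db=pw.source_db,
            )
        )
    return out
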