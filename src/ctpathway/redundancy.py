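"""Redundancy reduction of significant pathways.

Significant pathways are linked when their Jaccard gene-set similarity
reaches a cutoff (default 0.3), the weighted similarity network is
partitioned by Markov clustering, the lowest-FDR member represents each
cluster, and display limits cap the output at 20 clusters with at most 10
members each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .gpcm import PathwaySet
from .significance import EnrichmentResult

log = logging.getLogger(__name__)

__all__ = [
    "SimilarityNetwork",
    "ClusterAssignment",
    "DisplaySelection",
    "jaccard",
    "build_similarity_network",
    "mcl_cluster",
    "select_display",
]


@dataclass
class SimilarityNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    cutoff: float = 0.3


@dataclass
class ClusterAssignment:
    """Partition of significant pathways; one representative per cluster."""

    clusters: dict[int, list[str]]
    representative: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, pathway_id: str) -> int:
        for cid, members in self.clusters.items():
            if pathway_id in members:
                return cid
        raise KeyError(pathway_id)


@dataclass
class DisplaySelection:
    """Clusters ranked by representative FDR, trimmed to the display limits."""

    clusters: list[dict]  # {cluster_id, representative, members (trimmed), fdr}
    max_clusters: int = 20
    max_members: int = 10


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard similarity of an empty set is undefined")
    return len(a & b) / len(a | b)


def build_similarity_network(
    significant: Sequence[PathwaySet], cutoff: float = 0.3
) -> SimilarityNetwork:
    """Edge iff Jaccard >= cutoff (so cutoff 0 links every pair)."""
    sets = sorted(significant, key=lambda p: p.id)
    edges = []
    for i, pa in enumerate(sets):
        for pb in sets[i + 1 :]:
            j = jaccard(pa.genes, pb.genes)
            if j >= cutoff:
                edges.append((pa.id, pb.id, j))
    return SimilarityNetwork(nodes=[p.id for p in sets], edges=edges, cutoff=cutoff)


def _mcl_matrix(
    A: np.ndarray,
    inflation: float,
    expansion: int,
    prune: float,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    # self-loops = max incident weight (1 for isolated nodes) keep columns stochastic
    A = A.copy()
    loops = A.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(A, loops)
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        M_new = np.linalg.matrix_power(M, expansion)
        M_new = M_new ** inflation
        M_new[M_new < prune] = 0.0
        colsum = M_new.sum(axis=0)
        colsum[colsum == 0.0] = 1.0
        M_new /= colsum
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < tol:
            return M
    raise RuntimeError(f"MCL did not converge in {max_iter} iterations (delta {delta:.3e})")


def mcl_cluster(
    net: SimilarityNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-8,
    max_iter: int = 200,
    results: Sequence[EnrichmentResult] | None = None,
) -> ClusterAssignment:
    """Markov clustering of the Jaccard-weighted network.

    Attractor rows of the idempotent matrix define the clusters; overlapping
    attractor supports are merged and uncovered nodes become singletons.
    When ``results`` is supplied, each cluster's representative is its
    lowest-FDR member (ties: higher PS, then id); otherwise the smallest id.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        return ClusterAssignment(clusters={}, representative={})
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for a, b, w in net.edges:
        A[idx[a], idx[b]] = w
        A[idx[b], idx[a]] = w
    M = _mcl_matrix(A, inflation, expansion, prune, tol, max_iter)

    raw: list[set[int]] = []
    for i in range(len(nodes)):
        if M[i, i] > tol:  # attractor
            raw.append(set(np.flatnonzero(M[i] > tol)) | {i})
    merged: list[set[int]] = []
    for grp in raw:
        hit = [g for g in merged if g & grp]
        for g in hit:
            merged.remove(g)
            grp |= g
        merged.append(grp)
    covered = set().union(*merged) if merged else set()
    for i in range(len(nodes)):
        if i not in covered:
            merged.append({i})

    member_lists = sorted((sorted(nodes[i] for i in grp) for grp in merged), key=lambda m: m[0])
    clusters = {cid: members for cid, members in enumerate(member_lists)}

    rep_key: dict[str, tuple] = {}
    if results is not None:
        rep_key = {r.pathway_id: (r.fdr, -r.ps) for r in results}
    missing = (float("inf"), 0.0)
    representative = {
        cid: min(members, key=lambda pid: (*rep_key.get(pid, missing), pid))
        for cid, members in clusters.items()
    }
    return ClusterAssignment(clusters=clusters, representative=representative)


def select_display(
    clusters: ClusterAssignment,
    results: Sequence[EnrichmentResult],
    max_clusters: int = 20,
    max_members: int = 10,
) -> DisplaySelection:
    """Rank clusters by representative FDR; keep <=20 clusters, <=10 members each."""
    by_id = {r.pathway_id: r for r in results}

    def res_key(pid: str):
        r = by_id.get(pid)
        return (r.fdr, -r.ps, pid) if r is not None else (np.inf, 0.0, pid)

    ranked = sorted(clusters.clusters.items(), key=lambda kv: res_key(clusters.representative[kv[0]]))
    out = []
    for cid, members in ranked[:max_clusters]:
        trimmed = sorted(members, key=res_key)[:max_members]
        rep = clusters.representative[cid]
        fdr = by_id[rep].fdr if rep in by_id else float("nan")
        out.append({"cluster_id": cid, "representative": rep, "members": trimmed, "fdr": fdr})
    return DisplaySelection(clusters=out, max_clusters=max_clusters, max_members=max_members)
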