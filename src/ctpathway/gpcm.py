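"""Global pathway crosstalk map (GPCM) assembly.

The GPCM is a simple undirected gene graph merged from three classes of
provenance-tagged interactions (pathway-derived edges, protein-protein
interactions, TF->gene regulations).  Its column-normalized adjacency
operator drives the network propagation step.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = [
    "EdgeSource",
    "InteractionEdge",
    "PathwaySet",
    "Gpcm",
    "normalize_gene_id",
    "load_edges",
    "load_mixed_edges",
    "load_gmt",
    "filter_ppi_by_source_count",
    "filter_edges_by_pathway_membership",
    "build_gpcm",
    "write_gpcm_tables",
]


class EdgeSource(str, Enum):
    """Provenance class of an interaction edge."""

    pathway = "pathway"
    ppi = "ppi"
    tf = "tf"


def normalize_gene_id(raw: object) -> str:
    """Normalize a gene identifier.

    Whitespace is stripped; symbols are upper-cased.  All-digit identifiers
    (entrez) are kept verbatim.  No mapping between namespaces is attempted.
    """
    s = str(raw).strip()
    if not s:
        raise ValueError("empty gene identifier")
    return s if s.isdigit() else s.upper()


@dataclass(frozen=True)
class InteractionEdge:
    """One undirected interaction between two genes."""

    a: str
    b: str
    source: EdgeSource
    origin: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        """Canonical (sorted) unordered endpoint pair."""
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class PathwaySet:
    """A named gene set from a pathway database."""

    id: str
    name: str
    genes: frozenset[str]
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.id!r} has no genes")


@dataclass
class Gpcm:
    """Assembled crosstalk map: node ordering, merged edges and operator W.

    ``W[i, j] = 1/degree(j)`` whenever {i, j} is an edge, so every column of
    ``W`` sums to one.  Node order is the sorted identifier list, which makes
    the operator reproducible bit-for-bit.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], dict]
    degree: np.ndarray
    W: sp.csr_matrix
    node_index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.node_index

    def neighbors(self, gene: str) -> list[str]:
        """Sorted neighbor identifiers of ``gene``."""
        i = self.node_index[gene]
        row = self.W.indices[self.W.indptr[i] : self.W.indptr[i + 1]]
        return sorted(self.nodes[j] for j in row)


def _parse_edge_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() == "gene_a":
                continue  # header row
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            yield lineno, fields


def load_edges(path: str | Path, source: EdgeSource | str) -> list[InteractionEdge]:
    """Read a two/three-column edge TSV (gene_a, gene_b[, origin]).

    Identifiers are normalized, self-loops dropped (count logged), and rows
    that repeat an unordered pair within the same origin collapse to one
    record (the pair may still recur across origins).  A header line starting
    with ``gene_a`` is skipped.
    """
    source = EdgeSource(source)
    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str, str]] = set()
    n_loops = 0
    for _, fields in _parse_edge_rows(path):
        a = normalize_gene_id(fields[0])
        b = normalize_gene_id(fields[1])
        if a == b:
            n_loops += 1
            continue
        origin = fields[2].strip() if len(fields) > 2 else ""
        edge = InteractionEdge(a, b, source, origin)
        key = (*edge.pair, origin)
        if key in seen:
            continue
        seen.add(key)
        edges.append(edge)
    if n_loops:
        log.info("dropped %d self-loop(s) from %s", n_loops, path)
    if not edges:
        log.warning("no edges read from %s", path)
    return edges


def load_mixed_edges(path: str | Path) -> dict[EdgeSource, list[InteractionEdge]]:
    """Read a single edge TSV carrying a ``source`` column.

    Expected columns: gene_a, gene_b, source[, origin].  Returns edges
    grouped by source class.
    """
    grouped: dict[EdgeSource, list[InteractionEdge]] = {s: [] for s in EdgeSource}
    n_loops = 0
    for lineno, fields in _parse_edge_rows(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: mixed edge file needs a source column")
        a = normalize_gene_id(fields[0])
        b = normalize_gene_id(fields[1])
        if a == b:
            n_loops += 1
            continue
        src = EdgeSource(fields[2].strip().lower())
        origin = fields[3].strip() if len(fields) > 3 else ""
        grouped[src].append(InteractionEdge(a, b, src, origin))
    if n_loops:
        log.info("dropped %d self-loop(s) from %s", n_loops, path)
    return grouped


def load_gmt(path: str | Path, source_db: str = "") -> list[PathwaySet]:
    """Read pathway gene sets from a GMT file (id TAB description TAB gene...)."""
    sets: list[PathwaySet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need id, description and >=1 gene")
            pid = fields[0].strip()
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            genes = frozenset(normalize_gene_id(g) for g in fields[2:] if g.strip())
            if not genes:
                log.warning("%s:%d: pathway %s has no genes, skipped", path, lineno, pid)
                continue
            sets.append(PathwaySet(id=pid, name=fields[1].strip(), genes=genes, source_db=source_db))
    return sets


def filter_ppi_by_source_count(
    edges: Sequence[InteractionEdge], min_sources: int = 2
) -> list[InteractionEdge]:
    """Keep PPI pairs reported by at least ``min_sources`` distinct origins."""
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    origins: dict[tuple[str, str], set[str]] = defaultdict(set)
    for e in edges:
        origins[e.pair].add(e.origin)
    kept = [e for e in edges if len(origins[e.pair]) >= min_sources]
    log.info("PPI source filter: %d/%d edge records kept", len(kept), len(edges))
    return kept


def filter_edges_by_pathway_membership(
    edges: Sequence[InteractionEdge], pathway_genes: frozenset[str] | set[str]
) -> list[InteractionEdge]:
    """Keep edges with at least one endpoint annotated to some pathway."""
    return [e for e in edges if e.a in pathway_genes or e.b in pathway_genes]


def build_gpcm(
    pathway_edges: Sequence[InteractionEdge] = (),
    ppi_edges: Sequence[InteractionEdge] = (),
    tf_edges: Sequence[InteractionEdge] = (),
) -> Gpcm:
    """Merge the three edge classes into one simple undirected graph.

    Parallel edges collapse to a single edge that retains every provenance
    tag; degree counts each neighbor once.  Raises if the union is empty.
    """
    merged: dict[tuple[str, str], dict] = {}
    for e in [*pathway_edges, *ppi_edges, *tf_edges]:
        info = merged.setdefault(e.pair, {"sources": set(), "origins": set()})
        info["sources"].add(e.source)
        if e.origin:
            info["origins"].add(e.origin)
    if not merged:
        raise ValueError("GPCM has no edges")

    nodes = sorted({g for pair in merged for g in pair})
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)

    rows = np.empty(2 * len(merged), dtype=np.int64)
    cols = np.empty(2 * len(merged), dtype=np.int64)
    for k, (a, b) in enumerate(sorted(merged)):
        i, j = index[a], index[b]
        rows[2 * k], cols[2 * k] = i, j
        rows[2 * k + 1], cols[2 * k + 1] = j, i

    degree = np.bincount(cols, minlength=n).astype(np.int64)
    data = 1.0 / degree[cols]
    W = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    W.sum_duplicates()

    log.info("GPCM built: %d nodes, %d edges", n, len(merged))
    return Gpcm(nodes=nodes, edges=merged, degree=degree, W=W, node_index=index)


def write_gpcm_tables(gpcm: Gpcm, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Serialize the map as a (nodes, edges) TSV pair; W is always rebuilt."""
    with open(nodes_path, "w") as fh:
        fh.write("gene\tdegree\n")
        for g, d in zip(gpcm.nodes, gpcm.degree):
            fh.write(f"{g}\t{d}\n")
    with open(edges_path, "w") as fh:
        fh.write("gene_a\tgene_b\tsources\torigins\n")
        for (a, b), info in sorted(gpcm.edges.items()):
            srcs = ",".join(sorted(s.value for s in info["sources"]))
            origs = ",".join(sorted(info["origins"]))
            fh.write(f"{a}\t{b}\t{srcs}\t{origs}\n")
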