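"""Synthetic networks, pathway collections and DE profiles.

Networks are preferential-attachment (scale-free, connected) graphs;
pathways are sampled as graph neighborhoods so that overlap and crosstalk
exist by construction; profiles draw background fold changes from a
log2-normal noise model and optionally plant an elevated-signal pathway.
Everything is deterministic under the supplied seed, and the generated
files use the same formats the pipeline reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .gpcm import EdgeSource, Gpcm, InteractionEdge, PathwaySet, build_gpcm
from .profiles import DEProfile, GeneRecord

log = logging.getLogger(__name__)

__all__ = ["FixtureSpec", "make_network", "make_pathways", "make_profile", "write_fixture"]


@dataclass
class FixtureSpec:
    n_genes: int = 2000
    attachment: int = 3  # preferential-attachment edges per new node
    n_pathways: int = 200
    size_range: tuple[int, int] = (10, 40)
    planted_pathway: str | None = None
    effect_size: float = 0.0  # mean planted |log2 FC|; 0 disables planting
    effect_log2fc_sd: float = 0.25
    effect_p_max: float = 0.01
    background_sigma: float = 0.5  # sd of background log2 FC
    include_neighbors: bool = False  # also elevate 1-hop neighbors of planted genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_pathways < 1 or self.size_range[0] < 1:
            raise ValueError("sizes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _gene_name(i: int, width: int) -> str:
    return f"G{i + 1:0{width}d}"


def make_network(spec: FixtureSpec) -> Gpcm:
    """Connected scale-free gene graph with deterministic G0001... names."""
    m = min(spec.attachment, spec.n_genes - 1)
    g = nx.barabasi_albert_graph(spec.n_genes, m, seed=spec.seed)
    width = max(4, len(str(spec.n_genes)))
    edges = [
        InteractionEdge(_gene_name(a, width), _gene_name(b, width), EdgeSource.pathway)
        for a, b in g.edges()
    ]
    return build_gpcm(pathway_edges=edges)


def _sample_neighborhood(gpcm: Gpcm, rng: np.random.Generator, size: int) -> frozenset[str]:
    start = gpcm.nodes[int(rng.integers(gpcm.n))]
    members = {start}
    frontier = set(gpcm.neighbors(start))
    while len(members) < size and frontier:
        pick = sorted(frontier)[int(rng.integers(len(frontier)))]
        members.add(pick)
        frontier.update(gpcm.neighbors(pick))
        frontier -= members
    return frozenset(members)


def make_pathways(gpcm: Gpcm, spec: FixtureSpec) -> list[PathwaySet]:
    """Neighborhood-grown gene sets with realistic overlap."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lo, hi = spec.size_range
    width = max(3, len(str(spec.n_pathways)))
    out = []
    for k in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        genes = _sample_neighborhood(gpcm, rng, size)
        out.append(
            PathwaySet(id=f"PW{k + 1:0{width}d}", name=f"synthetic pathway {k + 1}", genes=genes, source_db="synthetic")
        )
    multi = _overlap_fraction(out)
    log.info("generated %d pathways; %.1f%% of covered genes in >1 pathway", len(out), 100 * multi)
    return out


def _overlap_fraction(pathways: Sequence[PathwaySet]) -> float:
    counts: dict[str, int] = {}
    for pw in pathways:
        for g in pw.genes:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        return 0.0
    return sum(1 for c in counts.values() if c > 1) / len(counts)


def make_profile(
    gpcm: Gpcm, pathways: Sequence[PathwaySet], spec: FixtureSpec
) -> DEProfile:
    """Background noise profile over all network genes, with optional planted signal.

    Background: log2 FC ~ Normal(0, sigma), P ~ Uniform(0, 1).  Planted
    pathway members (and optionally their 1-hop neighbors) get
    |log2 FC| ~ Normal(effect_size, sd) with random sign and
    P ~ Uniform(0, effect_p_max).  effect_size = 0 leaves the planted genes
    on the background distributions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    planted: set[str] = set()
    if spec.planted_pathway is not None:
        match = [p for p in pathways if p.id == spec.planted_pathway]
        if not match:
            raise KeyError(f"planted pathway {spec.planted_pathway!r} not in the collection")
        planted = set(match[0].genes)
        if spec.include_neighbors:
            for g in sorted(planted & set(gpcm.nodes)):
                planted.update(gpcm.neighbors(g))

    records: dict[str, GeneRecord] = {}
    for g in gpcm.nodes:
        log2fc = rng.normal(0.0, spec.background_sigma)
        p = rng.uniform(0.0, 1.0)
        if g in planted and spec.effect_size > 0:
            mag = abs(rng.normal(spec.effect_size, spec.effect_log2fc_sd))
            log2fc = mag if rng.uniform() < 0.5 else -mag
            p = rng.uniform(0.0, spec.effect_p_max)
        records[g] = GeneRecord(fc=float(2.0 ** log2fc), p=float(p))
    return DEProfile(records=records, alpha=1, beta=1)


def write_fixture(
    gpcm: Gpcm,
    pathways: Sequence[PathwaySet],
    profile: DEProfile,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write edges.tsv, pathways.gmt and profile.tsv in pipeline formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "gmt": outdir / "pathways.gmt",
        "profile": outdir / "profile.tsv",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(gpcm.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["gmt"], "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.id, pw.name, *sorted(pw.genes)]) + "\n")
    with open(paths["profile"], "w") as fh:
        fh.write("gene\tlog2fc\tpvalue\n")
        for g in sorted(profile.records):
            rec = profile.records[g]
            fh.write(f"{g}\t{np.log2(rec.fc):.10g}\t{rec.p:.10g}\n")
    return paths
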