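"""End-to-end analysis pipeline and result serialization."""

from __future__ import annotations

import hashlib
import logging
import os
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .gpcm import (
    EdgeSource,
    Gpcm,
    PathwaySet,
    build_gpcm,
    filter_edges_by_pathway_membership,
    filter_ppi_by_source_count,
    load_edges,
    load_gmt,
    load_mixed_edges,
)
from .profiles import DEProfile, build_de_vector, load_profile
from .propagation import RwrParams, multi_rwr
from .redundancy import (
    ClusterAssignment,
    DisplaySelection,
    build_similarity_network,
    mcl_cluster,
    select_display,
)
from .scoring import compute_pathway_scores, compute_risk_scores
from .significance import EnrichmentResult, assess_significance, permutation_null

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisResult", "analyze", "run_pipeline", "write_results"]

RESULT_COLUMNS = (
    "pathway_id",
    "name",
    "source_db",
    "n",
    "PS",
    "p_empirical",
    "p_final",
    "FDR",
    "significant",
)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults mirror the published method settings."""

    profile: Path | str
    gmt: Path | str
    outdir: Path | str
    edges: Path | str | None = None  # combined file or pathway-class edges
    edges_ppi: Path | str | None = None
    edges_tf: Path | str | None = None
    fc_scale: str = "log2"
    restart: float = 0.7
    epsilon: int = 3
    tol: float = 1e-10
    permutations: int = 1000
    seed: int = 0
    fdr: float = 0.01
    jaccard: float = 0.3
    min_size: int = 3
    gpd: bool = True
    ppi_min_sources: int = 2


@dataclass
class AnalysisResult:
    results: list[EnrichmentResult]
    clusters: ClusterAssignment
    display: DisplaySelection
    pathways: list[PathwaySet]
    config: dict = field(default_factory=dict)


def analyze(
    gpcm: Gpcm,
    pathways: Sequence[PathwaySet],
    profile: DEProfile,
    *,
    rwr: RwrParams = RwrParams(),
    h: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.01,
    jaccard_cutoff: float = 0.3,
    min_size: int = 3,
    gpd: bool = True,
) -> AnalysisResult:
    """In-memory pipeline: propagate, score, test, cluster."""
    de = build_de_vector(profile, gpcm)
    t0 = time.perf_counter()
    C = multi_rwr(gpcm, de.genes, rwr)
    log.info("multi-RWR over %d seeds in %.2fs", de.L, time.perf_counter() - t0)
    rs = compute_risk_scores(C, de)
    scores = compute_pathway_scores(rs, pathways, gpcm, min_size=min_size)
    null = permutation_null(C, de, pathways, gpcm, h=h, rng_seed=seed, min_size=min_size)
    results = assess_significance(scores, null, gpd=gpd, fdr_threshold=fdr_threshold)

    by_id = {p.id: p for p in pathways}
    sig_sets = [by_id[r.pathway_id] for r in results if r.significant]
    net = build_similarity_network(sig_sets, cutoff=jaccard_cutoff)
    clusters = mcl_cluster(net, results=results)
    display = select_display(clusters, results)
    return AnalysisResult(results=results, clusters=clusters, display=display, pathways=list(pathways))


def _load_all_edges(config: RunConfig) -> dict[EdgeSource, list]:
    grouped: dict[EdgeSource, list] = {s: [] for s in EdgeSource}
    if config.edges is not None:
        with open(config.edges) as fh:
            header = fh.readline().lower()
        if "\tsource" in header or header.rstrip("\n").endswith("source"):
            for src, lst in load_mixed_edges(config.edges).items():
                grouped[src].extend(lst)
        else:
            grouped[EdgeSource.pathway].extend(load_edges(config.edges, EdgeSource.pathway))
    if config.edges_ppi is not None:
        grouped[EdgeSource.ppi].extend(load_edges(config.edges_ppi, EdgeSource.ppi))
    if config.edges_tf is not None:
        grouped[EdgeSource.tf].extend(load_edges(config.edges_tf, EdgeSource.tf))
    return grouped


def _file_hash(path: Path | str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """File-to-file pipeline; writes results atomically into ``config.outdir``."""
    pathways = load_gmt(config.gmt)
    pathway_genes = frozenset(g for p in pathways for g in p.genes)

    grouped = _load_all_edges(config)
    ppi = grouped[EdgeSource.ppi]
    if ppi and any(e.origin for e in ppi) and config.ppi_min_sources > 1:
        ppi = filter_ppi_by_source_count(ppi, config.ppi_min_sources)
    ppi = filter_edges_by_pathway_membership(ppi, pathway_genes)
    tf = filter_edges_by_pathway_membership(grouped[EdgeSource.tf], pathway_genes)
    gpcm = build_gpcm(grouped[EdgeSource.pathway], ppi, tf)

    profile = load_profile(config.profile, fc_scale=config.fc_scale)
    rwr = RwrParams(r=config.restart, tol=config.tol, epsilon=config.epsilon)
    result = analyze(
        gpcm,
        pathways,
        profile,
        rwr=rwr,
        h=config.permutations,
        seed=config.seed,
        fdr_threshold=config.fdr,
        jaccard_cutoff=config.jaccard,
        min_size=config.min_size,
        gpd=config.gpd,
    )

    meta = {
        "version": __version__,
        "profile": str(config.profile),
        "profile_sha256": _file_hash(config.profile),
        "gmt": str(config.gmt),
        "gmt_sha256": _file_hash(config.gmt),
        "fc_scale": config.fc_scale,
        "restart": config.restart,
        "epsilon": config.epsilon,
        "tol": config.tol,
        "permutations": config.permutations,
        "seed": config.seed,
        "fdr": config.fdr,
        "jaccard": config.jaccard,
        "min_size": config.min_size,
        "gpd": config.gpd,
        "n_nodes": gpcm.n,
        "n_edges": gpcm.n_edges,
    }
    for key in ("edges", "edges_ppi", "edges_tf"):
        p = getattr(config, key)
        if p is not None:
            meta[key] = str(p)
            meta[f"{key}_sha256"] = _file_hash(p)
    result.config = meta
    write_results(result, config.outdir)
    return result


def write_results(result: AnalysisResult, outdir: Path | str) -> dict[str, Path]:
    """Write results.tsv, clusters.tsv, map_nodes.tsv, map_edges.tsv, run_meta.tsv.

    Files land in a temp directory first and are moved in at the end, so a
    failing run leaves no partial outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {p.id: p for p in result.pathways}
    rep_flags = set(result.clusters.representative.values())
    cluster_of = {
        pid: cid for cid, members in result.clusters.clusters.items() for pid in members
    }
    if not any(r.significant for r in result.results):
        log.warning("no significant pathways; cluster outputs will be empty")

    tmp = Path(tempfile.mkdtemp(prefix=".ctpathway-", dir=outdir))
    try:
        with open(tmp / "results.tsv", "w") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in result.results:
                fh.write(
                    f"{r.pathway_id}\t{r.name}\t{r.source_db}\t{r.n}\t{r.ps:.10g}\t"
                    f"{r.p_empirical:.10g}\t{r.p_final:.10g}\t{r.fdr:.10g}\t{int(r.significant)}\n"
                )
        with open(tmp / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\tpathway_id\trepresentative\n")
            for cid in sorted(result.clusters.clusters):
                for pid in result.clusters.clusters[cid]:
                    fh.write(f"{cid}\t{pid}\t{int(pid == result.clusters.representative[cid])}\n")
        res_by_id = {r.pathway_id: r for r in result.results}
        with open(tmp / "map_nodes.tsv", "w") as fh:
            fh.write("pathway_id\tcluster_id\trepresentative\tFDR\tPS\n")
            for entry in result.display.clusters:
                for pid in entry["members"]:
                    r = res_by_id[pid]
                    fh.write(
                        f"{pid}\t{entry['cluster_id']}\t{int(pid in rep_flags)}\t"
                        f"{r.fdr:.10g}\t{r.ps:.10g}\n"
                    )
        shown = {pid for entry in result.display.clusters for pid in entry["members"]}
        from .redundancy import jaccard  # local import avoids a cycle at module load

        with open(tmp / "map_edges.tsv", "w") as fh:
            fh.write("id_a\tid_b\tjaccard\n")
            for a in sorted(shown):
                for b in sorted(shown):
                    if a < b:
                        j = jaccard(by_id[a].genes, by_id[b].genes)
                        if j > 0:
                            fh.write(f"{a}\t{b}\t{j:.10g}\n")
        with open(tmp / "run_meta.tsv", "w") as fh:
            for k, v in sorted(result.config.items()):
                fh.write(f"{k}\t{v}\n")
        paths = {}
        for name in ("results.tsv", "clusters.tsv", "map_nodes.tsv", "map_edges.tsv", "run_meta.tsv"):
            os.replace(tmp / name, outdir / name)
            paths[name] = outdir / name
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return paths
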