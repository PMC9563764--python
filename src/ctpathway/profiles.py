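"""Differential-expression profiles and the gene DE score.

The DE score maps a (fold change, P-value) pair onto [0, 1]:

    DE = (1-P)^alpha * [1 - FC^(-1/2)]^beta   for FC >= 1
    DE = (1-P)^alpha * [1 - FC^(+1/2)]^beta   for 0 <= FC < 1

so that fold changes of n and 1/n contribute equally.  alpha/beta flag
profile-level availability of P-values and fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gpcm import Gpcm, normalize_gene_id

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "DEProfile",
    "DEVector",
    "load_profile",
    "compute_de_score",
    "build_de_vector",
]

_GENE_ALIASES = ("gene", "symbol", "entrez", "gene_id", "geneid")
_FC_ALIASES = ("fc", "foldchange", "fold_change", "log2fc", "log2foldchange", "logfc")
_P_ALIASES = ("pvalue", "p", "p_value", "pval", "p.value")


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene inputs; ``None`` marks a missing value inside an available column."""

    fc: float | None = None
    p: float | None = None


@dataclass
class DEProfile:
    """A differential-expression profile with availability flags."""

    records: dict[str, GeneRecord]
    alpha: int  # 1 iff P-values available for this profile
    beta: int  # 1 iff fold changes available for this profile

    def __post_init__(self) -> None:
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("profile carries neither fold changes nor P-values")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class DEVector:
    """DE scores of the profile genes that map into the network (the seeds)."""

    genes: list[str]
    values: np.ndarray

    @property
    def L(self) -> int:
        return len(self.genes)


def _pick_column(columns: Mapping[str, str], aliases: tuple[str, ...]) -> str | None:
    for alias in aliases:
        if alias in columns:
            return columns[alias]
    return None


def load_profile(path: str | Path, fc_scale: str = "log2") -> DEProfile:
    """Parse a profile TSV with header columns {gene|symbol|entrez}, {fc|log2fc}, {pvalue|p}.

    ``fc_scale`` fixes the fold-change interpretation explicitly (``log2``
    converts via FC = 2**x); no heuristic detection is attempted.  Duplicate
    gene rows keep the largest |log2 FC| (ties: smallest P, then first seen).
    """
    if fc_scale not in ("ratio", "log2"):
        raise ValueError(f"fc_scale must be 'ratio' or 'log2', got {fc_scale!r}")
    df = pd.read_csv(path, sep="\t")
    lower = {str(c).strip().lower(): c for c in df.columns}
    gene_col = _pick_column(lower, _GENE_ALIASES)
    fc_col = _pick_column(lower, _FC_ALIASES)
    p_col = _pick_column(lower, _P_ALIASES)
    if gene_col is None:
        raise ValueError(f"{path}: no gene identifier column found")
    if fc_col is None and p_col is None:
        raise ValueError(f"{path}: no usable score column (fc/log2fc or pvalue)")

    alpha = int(p_col is not None)
    beta = int(fc_col is not None)

    work = pd.DataFrame({"gene": df[gene_col].map(normalize_gene_id)})
    if beta:
        raw = pd.to_numeric(df[fc_col], errors="coerce")
        fc = np.power(2.0, raw) if fc_scale == "log2" else raw
        bad = fc.notna() & (fc <= 0)
        if bad.any():
            g = work.loc[bad.idxmax(), "gene"]
            raise ValueError(f"{path}: non-positive fold change for gene {g}")
        work["fc"] = fc
    if alpha:
        p = pd.to_numeric(df[p_col], errors="coerce")
        bad = p.notna() & ((p < 0) | (p > 1))
        if bad.any():
            g = work.loc[bad.idxmax(), "gene"]
            raise ValueError(f"{path}: P-value outside [0, 1] for gene {g}")
        work["p"] = p

    # duplicate resolution: largest |log2 FC|, then smallest P, then first row
    work["_abs"] = np.abs(np.log2(work["fc"])) if beta else 0.0
    work["_p"] = work["p"].fillna(1.0) if alpha else 1.0
    work["_row"] = np.arange(len(work))
    n_before = len(work)
    work = work.sort_values(
        ["gene", "_abs", "_p", "_row"], ascending=[True, False, True, True]
    ).drop_duplicates("gene", keep="first")
    if len(work) < n_before:
        log.warning("%s: resolved %d duplicate gene row(s)", path, n_before - len(work))

    records = {}
    for row in work.itertuples(index=False):
        fc = getattr(row, "fc", None)
        p = getattr(row, "p", None)
        records[row.gene] = GeneRecord(
            fc=None if fc is None or pd.isna(fc) else float(fc),
            p=None if p is None or pd.isna(p) else float(p),
        )
    return DEProfile(records=records, alpha=alpha, beta=beta)


def compute_de_score(fc, p, alpha: int = 1, beta: int = 1):
    """DE score on [0, 1]; symmetric under FC <-> 1/FC; accepts scalars or arrays."""
    if alpha == 0 and beta == 0:
        raise ValueError("at least one of alpha, beta must be 1")
    fc = np.asarray(fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if beta and np.any(fc <= 0):
        raise ValueError("fold changes must be positive")
    if alpha and (np.any(p < 0) or np.any(p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    p_factor = (1.0 - p) if alpha else np.ones_like(p)
    if beta:
        fc_factor = np.where(fc >= 1.0, 1.0 - fc ** -0.5, 1.0 - fc ** 0.5)
    else:
        fc_factor = np.ones_like(fc)
    de = p_factor * fc_factor
    return float(de) if de.ndim == 0 else de


def build_de_vector(profile: DEProfile, gpcm: Gpcm) -> DEVector:
    """DE scores for profile genes present in the network, in sorted gene order."""
    genes = sorted(g for g in profile.records if g in gpcm)
    n_excluded = len(profile.records) - len(genes)
    if not genes:
        raise ValueError("no profile gene maps to the network")
    if n_excluded:
        log.info("%d profile gene(s) absent from the network, excluded", n_excluded)
    fc = np.array(
        [profile.records[g].fc if profile.records[g].fc is not None else 1.0 for g in genes]
    )
    p = np.array(
        [profile.records[g].p if profile.records[g].p is not None else 1.0 for g in genes]
    )
    values = compute_de_score(fc, p, profile.alpha, profile.beta)
    return DEVector(genes=genes, values=np.asarray(values, dtype=float))
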