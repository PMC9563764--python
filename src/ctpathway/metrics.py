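"""Benchmark metrics: rank difference, time difference, rank ratio, stability."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .redundancy import jaccard

log = logging.getLogger(__name__)

__all__ = [
    "BenchmarkRecord",
    "rank_difference",
    "time_difference",
    "rank_ratio",
    "stability",
    "read_records",
    "compute_metrics",
]


@dataclass(frozen=True)
class BenchmarkRecord:
    """Target-pathway rank and wall time before/after an optimization."""

    dataset_id: str
    rank_before: int
    rank_after: int
    time_before: float
    time_after: float

    def __post_init__(self) -> None:
        if self.rank_before < 1 or self.rank_after < 1:
            raise ValueError("ranks must be >= 1")
        if self.time_before <= 0 or self.time_after <= 0:
            raise ValueError("times must be positive")


def rank_difference(records: Sequence[BenchmarkRecord], k: int) -> float:
    """DR = mean over datasets of |rank_before - rank_after| / K."""
    if k <= 0:
        raise ValueError("candidate pathway count K must be positive")
    if not records:
        raise ValueError("no records")
    return sum(abs(r.rank_before - r.rank_after) / k for r in records) / len(records)


def time_difference(records: Sequence[BenchmarkRecord]) -> float:
    """DT = mean relative running-time reduction (negative if slower after)."""
    if not records:
        raise ValueError("no records")
    return sum((r.time_before - r.time_after) / r.time_before for r in records) / len(records)


def rank_ratio(rank: int, denominator: int) -> float:
    """RR = rank / denominator.

    The sensible denominator is the candidate pathway count K; pass the
    dataset count M instead to reproduce the literal printed formula (which
    can exceed 1 and is logged as such).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rr = rank / denominator
    if rr > 1:
        log.warning("rank ratio %.3f exceeds 1 (denominator smaller than rank)", rr)
    return rr


def stability(sig_sets: Sequence[tuple[Iterable[str], Iterable[str]]]) -> float:
    """S = mean Jaccard similarity of significant-set pairs across conditions.

    A pair where both sets are empty contributes 0 with a warning.
    """
    if not sig_sets:
        raise ValueError("no condition pairs")
    total = 0.0
    for a, b in sig_sets:
        a, b = set(a), set(b)
        if not a and not b:
            log.warning("both significant sets empty in a condition pair; J := 0")
            continue
        if not a or not b:
            continue  # one empty: intersection empty, J = 0
        total += jaccard(a, b)
    return total / len(sig_sets)


def read_records(path: str | Path) -> tuple[list[BenchmarkRecord], int]:
    """Read a benchmark record TSV (dataset_id, rank_before, rank_after,
    time_before, time_after, K); returns the records and the shared K."""
    df = pd.read_csv(path, sep="\t")
    required = {"dataset_id", "rank_before", "rank_after", "time_before", "time_after", "K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ks = df["K"].unique()
    if len(ks) != 1:
        raise ValueError(f"{path}: K must be constant across records, got {ks}")
    records = [
        BenchmarkRecord(
            dataset_id=str(r.dataset_id),
            rank_before=int(r.rank_before),
            rank_after=int(r.rank_after),
            time_before=float(r.time_before),
            time_after=float(r.time_after),
        )
        for r in df.itertuples(index=False)
    ]
    return records, int(ks[0])


def compute_metrics(records: Sequence[BenchmarkRecord], k: int) -> dict[str, float]:
    """DR, DT and per-dataset mean RR (after optimization, denominator K)."""
    rr = sum(rank_ratio(r.rank_after, k) for r in records) / len(records)
    return {
        "DR": rank_difference(records, k),
        "DT": time_difference(records),
        "mean_RR": rr,
        "M": float(len(records)),
        "K": float(k),
    }
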