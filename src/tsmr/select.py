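"""Instrument selection from the exposure GWAS.

Three criteria, applied in order: genome-wide significance (p < 5e-8,
strict), LD-clumping independence (conflict when r² > 0.001 within a
10,000 kb window on the same chromosome), and per-SNP instrument strength
F = (beta/se)² > 10 (strict).

Clumping is a deterministic greedy vertex deletion on the conflict graph:
while edges remain, delete the variant of maximum degree — i.e. the one
"correlated with more SNPs" — breaking degree ties by larger p-value,
then by lexicographically larger variant ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import LDMatrix, SummaryStatRecord

__all__ = [
    "SelectionConfig",
    "RemovalLogEntry",
    "SelectionResult",
    "EmptySelectionError",
    "filter_significant",
    "compute_f_statistic",
    "clump",
    "select_instruments",
]


@dataclass(slots=True)
class SelectionConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000
    f_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (self.p_threshold > 0 and self.window_kb > 0 and self.f_threshold > 0):
            raise ValueError("selection thresholds must be positive")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in (0, 1]")


@dataclass(slots=True)
class RemovalLogEntry:
    snp_id: str
    stage: str  # significance | clump | f-statistic
    reason: str


class EmptySelectionError(RuntimeError):
    """No instruments survived a selection stage."""


@dataclass
class SelectionResult:
    instruments: list[SummaryStatRecord]
    removal_log: list[RemovalLogEntry]
    stage_counts: dict[str, int]


def filter_significant(
    records: Sequence[SummaryStatRecord], p_threshold: float = 5e-8
) -> list[SummaryStatRecord]:
    """Keep rows with p strictly below the genome-wide threshold."""
    return [r for r in records if r.pval < p_threshold]


def compute_f_statistic(record: SummaryStatRecord) -> float:
    """Per-SNP instrument strength, the summary-data approximation
    F = (beta / se)²."""
    return (record.beta / record.se) ** 2


def _conflict_edges(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    r2_threshold: float,
    window_kb: float,
) -> dict[str, set[str]]:
    for r in records:
        if r.snp_id not in ld:
            raise KeyError(f"SNP missing from LD matrix: {r.snp_id}")
    window_bp = window_kb * 1000
    adj: dict[str, set[str]] = {r.snp_id: set() for r in records}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            if a.chrom != b.chrom:
                continue
            if abs(a.pos - b.pos) > window_bp:  # inclusive at the boundary
                continue
            if ld.value(a.snp_id, b.snp_id) > r2_threshold:
                adj[a.snp_id].add(b.snp_id)
                adj[b.snp_id].add(a.snp_id)
    return adj


def clump(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> tuple[list[SummaryStatRecord], list[RemovalLogEntry]]:
    """Greedy deletion until the retained set is conflict-free.

    Returns the retained records (input order preserved) and a removal
    log with one entry per deleted variant.
    """
    by_id = {}
    for r in records:
        if r.snp_id in by_id:
            raise ValueError(f"duplicate snp_id: {r.snp_id}")
        by_id[r.snp_id] = r
    adj = _conflict_edges(records, ld, r2_threshold, window_kb)
    removed: list[RemovalLogEntry] = []
    while True:
        candidates = [(s, nb) for s, nb in adj.items() if nb]
        if not candidates:
            break
        # max degree, then larger p, then lexicographically larger ID
        victim, neighbours = max(
            candidates, key=lambda it: (len(it[1]), by_id[it[0]].pval, it[0])
        )
        removed.append(
            RemovalLogEntry(
                victim,
                "clump",
                f"degree={len(neighbours)}; p={by_id[victim].pval:.6g}; "
                f"conflicts={','.join(sorted(neighbours))}",
            )
        )
        for nb in neighbours:
            adj[nb].discard(victim)
        del adj[victim]
    kept_ids = set(adj)
    return [r for r in records if r.snp_id in kept_ids], removed


def select_instruments(
    records: Sequence[SummaryStatRecord],
    ld: LDMatrix,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Apply significance -> clumping -> F-statistic, in that order.

    Raises :class:`EmptySelectionError` naming the stage if any stage
    empties the candidate set.
    """
    config = config or SelectionConfig()
    log: list[RemovalLogEntry] = []
    counts = {"input": len(records)}

    sig = filter_significant(records, config.p_threshold)
    dropped = {r.snp_id for r in records} - {r.snp_id for r in sig}
    for r in records:
        if r.snp_id in dropped:
            log.append(
                RemovalLogEntry(r.snp_id, "significance", f"p={r.pval:.6g} >= {config.p_threshold:g}")
            )
    counts["significant"] = len(sig)
    if not sig:
        raise EmptySelectionError("no instruments after significance filter")

    clumped, clump_log = clump(sig, ld, config.r2_threshold, config.window_kb)
    log.extend(clump_log)
    counts["clumped"] = len(clumped)
    if not clumped:
        raise EmptySelectionError("no instruments after clumping")

    strong = []
    for r in clumped:
        f = compute_f_statistic(r)
        if f > config.f_threshold:
            strong.append(r)
        else:
            log.append(RemovalLogEntry(r.snp_id, "f-statistic", f"F={f:.4g} <= {config.f_threshold:g}"))
    counts["strong"] = len(strong)
    if not strong:
        raise EmptySelectionError("no instruments after F filter")

    return SelectionResult(strong, log, counts)
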