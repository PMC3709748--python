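"""Anti-correlated miRNA-gene pairing with multi-database consensus.

A differentially expressed miRNA is paired with a differentially expressed
gene of the *opposite* direction (miRNAs repress their targets, so an
up-regulated miRNA is matched with down-regulated genes and vice versa).
A pair is kept only when it is predicted by at least ``min_support`` distinct
target-prediction sources; record multiplicity within one source never
counts. Identifiers are matched exactly — reconciling mature-miRNA name
variants (e.g. miR-125b vs miR-125b-5p) is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io import TargetRecord, UsageError

UP = "up"
DOWN = "down"


@dataclass(frozen=True, order=True)
class ConsensusPair:
    mirna_id: str
    gene_id: str
    mirna_direction: str
    gene_direction: str
    support: int
    sources: tuple[str, ...]


def direction_compatible(mirna_direction: str, gene_direction: str) -> bool:
    """True iff the two differential-expression directions are opposite."""
    for d in (mirna_direction, gene_direction):
        if d not in (UP, DOWN):
            raise UsageError(f"direction must be 'up' or 'down', got {d!r}")
    return mirna_direction != gene_direction


def consensus_pairs(
    up_mirnas: Iterable[str],
    down_mirnas: Iterable[str],
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    target_records: Iterable[TargetRecord],
    min_support: int = 2,
) -> list[ConsensusPair]:
    """All oppositely-regulated (miRNA, gene) pairs with enough source support."""
    if min_support < 1:
        raise UsageError("min_support must be >= 1")
    up_m, down_m = set(up_mirnas), set(down_mirnas)
    up_g, down_g = set(up_genes), set(down_genes)
    if up_m & down_m or up_g & down_g:
        raise UsageError("up/down feature sets must be disjoint")
    mirna_dir = {m: UP for m in up_m} | {m: DOWN for m in down_m}
    gene_dir = {g: UP for g in up_g} | {g: DOWN for g in down_g}

    sources_by_pair: dict[tuple[str, str], set[str]] = {}
    for rec in target_records:
        m, g = rec.mirna_id, rec.gene_id
        if m not in mirna_dir or g not in gene_dir:
            continue
        if not direction_compatible(mirna_dir[m], gene_dir[g]):
            continue
        sources_by_pair.setdefault((m, g), set()).add(rec.source)

    pairs = [
        ConsensusPair(
            mirna_id=m,
            gene_id=g,
            mirna_direction=mirna_dir[m],
            gene_direction=gene_dir[g],
            support=len(sources),
            sources=tuple(sorted(sources)),
        )
        for (m, g), sources in sources_by_pair.items()
        if len(sources) >= min_support
    ]
    return sorted(pairs)


def pairs_table(pairs: Iterable[ConsensusPair]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": p.mirna_id,
            "mirna_direction": p.mirna_direction,
            "gene_id": p.gene_id,
            "gene_direction": p.gene_direction,
            "support": p.support,
            "sources": ",".join(p.sources),
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "mirna_direction", "gene_id",
                                       "gene_direction", "support", "sources"])
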