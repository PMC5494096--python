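"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query of n genes drawn from a universe of N, a set with K members in
the universe and k of them in the query scores the upper-tail probability
P(X >= k), X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg adjustment is
applied across all sets of the collection; significance means adjusted
p < alpha.  The universe defaults to the genes of the reference network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .network import normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets over a background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("gene-set names must be unique")

    def restricted(self) -> "GeneSetCollection":
        """Clip every set to the universe."""
        return GeneSetCollection(
            sets={name: s & self.universe for name, s in self.sets.items()},
            universe=self.universe,
            descriptions=dict(self.descriptions),
        )


@dataclass
class EnrichmentRecord:
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float
    overlap_genes: list[str]

    @property
    def is_significant(self) -> bool:
        return self.p_adj < 0.05


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members).

    Without an explicit universe the union of all set members is used.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno}")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} (line {lineno})")
            sets[name] = frozenset(normalize_gene_id(g) for g in members if g.strip())
            descriptions[name] = desc
    if universe is None:
        uni = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        uni = frozenset(normalize_gene_id(g) for g in universe)
    return GeneSetCollection(sets=sets, universe=uni, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); p = 1 at k = 0."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_sets(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Score every set of the collection against the query.

    Query genes outside the universe are dropped (count logged); an empty
    restricted query is an error naming the dropped genes.  Records are BH
    adjusted across the whole collection and sorted by (p_adj, set_name).
    """
    q_raw = {normalize_gene_id(g) for g in query}
    q = q_raw & collection.universe
    dropped = sorted(q_raw - collection.universe)
    if dropped:
        logger.info("dropped %d query genes outside the universe", len(dropped))
    if not q:
        raise ValueError(
            f"query is empty after restriction to the universe; dropped: {dropped}"
        )
    N = len(collection.universe)
    n = len(q)
    names = sorted(collection.sets)
    p_raw = []
    rows = []
    for name in names:
        members = collection.sets[name] & collection.universe
        K = len(members)
        overlap = sorted(q & members)
        k = len(overlap)
        p = hypergeometric_tail(N, K, n, k)
        p_raw.append(p)
        rows.append((name, K, k, overlap, p))
    p_adj = bh_adjust(p_raw)
    records = [
        EnrichmentRecord(
            set_name=name,
            N=N,
            K=K,
            n=n,
            k=k,
            p_raw=p,
            p_adj=float(pa),
            overlap_genes=overlap,
        )
        for (name, K, k, overlap, p), pa in zip(rows, p_adj)
    ]
    records.sort(key=lambda r: (r.p_adj, r.set_name))
    return records


def top_k_report(records: Sequence[EnrichmentRecord], k: int = 10) -> list[EnrichmentRecord]:
    """First k records of an already-sorted enrichment table."""
    return list(records[:k])


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in records],
            "N": [r.N for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "k": [r.k for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "overlap_genes": [";".join(r.overlap_genes) for r in records],
        }
    )


def write_records(records: Sequence[EnrichmentRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.6g")
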