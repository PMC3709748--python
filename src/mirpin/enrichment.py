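"""Level-filtered hypergeometric GO over-representation with BY adjustment.

For a network with n genes inside an N-gene annotation universe, a term
annotating K universe genes of which k fall in the network is scored with
the upper-tail hypergeometric probability P(X >= k). Terms closer than
``min_level`` is_a steps to their namespace root are excluded as overly
generic (the level of a term is the shortest is_a path from the root, root
at level 0). Because the tested term families overlap heavily, p-values are
adjusted with the Benjamini-Yekutieli step-up procedure — valid under
arbitrary dependence — separately within each network's family of tested
terms. Networks with fewer than ``min_pin_size`` genes are not tested at
all.

A term is flagged cancer-related when its name contains any of a fixed list
of keyword substrings (case-insensitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSet, Ontology, StructuralError, UsageError
from .network import PIN

DEFAULT_KEYWORDS = (
    "cell proliferation",
    "cell death",
    "apoptosis",
    "signaling",
    "microtubule",
    "actin",
)


@dataclass(frozen=True)
class KeywordRule:
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS

    def __post_init__(self) -> None:
        if not self.keywords:
            raise UsageError("keyword list must be non-empty")
        if any(k != k.lower() for k in self.keywords):
            raise UsageError("keywords must be lowercase")


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    term_id: str
    term_name: str
    level: int
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    member_genes: frozenset[str]
    cancer_related: bool


def compute_term_levels(ontology: Ontology) -> dict[str, int]:
    """Shortest is_a distance from the (namespace) root; unreachable terms omitted.

    Terms carrying a namespace take their level from that namespace's roots;
    terms without one take the minimum over all roots.
    """
    roots = ontology.roots
    if not roots:
        raise StructuralError("ontology has no root (term without parents)")
    children: dict[str, list[str]] = {t: [] for t in ontology.terms}
    for term in ontology.terms.values():
        for parent in term.parents:
            children[parent].append(term.term_id)

    def bfs(sources: Sequence[str]) -> dict[str, int]:
        dist = {s: 0 for s in sources}
        frontier = list(sources)
        while frontier:
            nxt = []
            for u in frontier:
                for v in children[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    by_namespace: dict[str | None, dict[str, int]] = {}
    root_ns = {r: ontology.terms[r].namespace for r in roots}
    for ns in set(root_ns.values()):
        by_namespace[ns] = bfs([r for r in roots if root_ns[r] == ns])
    all_dist = bfs(roots)

    levels: dict[str, int] = {}
    for term in ontology.terms.values():
        ns = term.namespace
        if ns is not None and ns in by_namespace and term.term_id in by_namespace[ns]:
            levels[term.term_id] = by_namespace[ns][term.term_id]
        elif term.term_id in all_dist:
            levels[term.term_id] = all_dist[term.term_id]
    return levels


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise UsageError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_benjamini_yekutieli(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """BY step-up adjusted p-values (order-preserving, >= the raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def classify_cancer_related(term_name: str, rule: KeywordRule = KeywordRule()) -> bool:
    if not term_name:
        raise UsageError("term_name must be non-empty")
    lowered = term_name.lower()
    return any(k in lowered for k in rule.keywords)


def enrich_pin(
    pin: PIN,
    annotations: AnnotationSet,
    ontology: Ontology,
    *,
    min_pin_size: int = 6,
    min_level: int = 5,
    alpha: float = 1e-4,
    keyword_rule: KeywordRule = KeywordRule(),
    keep_all: bool = False,
) -> list[EnrichmentResult]:
    """Score every eligible term against one network.

    Returns results with p_adj < alpha sorted by (p_adj, p, term_id), or every
    tested term when ``keep_all``. Networks smaller than ``min_pin_size`` are
    skipped entirely (empty result).
    """
    universe = annotations.universe
    if not universe:
        raise UsageError("annotation universe is empty")
    if len(pin.nodes) < min_pin_size:
        return []
    levels = compute_term_levels(ontology)
    N = len(universe)
    pin_in_universe = pin.nodes & universe
    n = len(pin_in_universe)

    tested: list[tuple[str, int, int, frozenset[str], float]] = []
    for term_id in sorted(annotations.mapping):
        level = levels.get(term_id)
        if level is None or level < min_level:
            continue
        genes = annotations.mapping[term_id] & universe
        K = len(genes)
        if K < 1:
            continue
        members = frozenset(pin_in_universe & genes)
        p = hypergeometric_upper_tail(len(members), K, n, N)
        tested.append((term_id, level, K, members, p))
    if not tested:
        return []

    p_adj = adjust_benjamini_yekutieli([t[4] for t in tested])
    results = []
    for (term_id, level, K, members, p), adj in zip(tested, p_adj):
        if not keep_all and adj >= alpha:
            continue
        name = ontology.terms[term_id].name
        results.append(EnrichmentResult(
            mirna_id=pin.mirna_id,
            term_id=term_id,
            term_name=name,
            level=level,
            k=len(members),
            K=K,
            n=n,
            N=N,
            p=p,
            p_adj=float(adj),
            member_genes=members,
            cancer_related=classify_cancer_related(name, keyword_rule) if name else False,
        ))
    return sorted(results, key=lambda r: (r.p_adj, r.p, r.term_id))


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": r.mirna_id, "term_id": r.term_id, "term_name": r.term_name,
            "level": r.level, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "p": r.p, "p_adj": r.p_adj, "cancer_related": r.cancer_related,
            "member_genes": ",".join(sorted(r.member_genes)),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["mirna_id", "term_id", "term_name", "level",
                                       "k", "K", "n", "N", "p", "p_adj",
                                       "cancer_related", "member_genes"])
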