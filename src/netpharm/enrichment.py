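"""Hypergeometric over-representation analysis with kappa-statistic term grouping.

The enrichment test is one-sided (over-representation): for a query of size
``n`` drawn from a universe of ``M`` genes, a term annotating ``K`` universe
genes, and ``k`` query hits, the p-value is the upper hypergeometric tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(M-K, n-i) / C(M, n)

evaluated exactly in log space. Significant terms are grouped by Cohen's
kappa agreement of their query-hit membership vectors: terms whose pairwise
kappa meets the threshold are linked, and groups are the connected
components, each labeled by its most significant member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph_io import GeneSetLibrary
from .target_assembly import TargetSet

__all__ = [
    "EnrichmentTerm",
    "TermGroup",
    "hypergeom_ora",
    "correct_pvalues",
    "kappa_score",
    "group_terms",
]

_CORRECTIONS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}


@dataclass
class EnrichmentTerm:
    """Per-term over-representation statistics."""

    term_id: str
    description: str
    k: int  # query hits in the term
    K: int  # term size within the universe
    n: int  # query size within the universe
    M: int  # universe size
    p: float
    p_adj: float = float("nan")
    hit_genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"{self.term_id}: k={self.k} outside [0, min(K={self.K}, n={self.n})]")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"{self.term_id}: p={self.p} outside [0, 1]")
        if self.p_adj == self.p_adj:  # not NaN
            if not (0.0 <= self.p_adj <= 1.0):
                raise ValueError(f"{self.term_id}: p_adj={self.p_adj} outside [0, 1]")
            if self.p_adj < self.p - 1e-12:
                raise ValueError(f"{self.term_id}: p_adj < p")


@dataclass
class TermGroup:
    """A kappa-connected group of enriched terms."""

    members: list[str]
    leading_term: str
    kappa_edges: dict[tuple[str, str], float] = field(default_factory=dict)


def hypergeom_ora(
    query: TargetSet | set[str],
    lib: GeneSetLibrary,
    universe: set[str] | None = None,
) -> list[EnrichmentTerm]:
    """Upper-tail hypergeometric over-representation of a query against a library.

    The universe defaults to all genes in the library. Query genes outside
    the universe are dropped (an empty restricted query is an error); term
    genes are restricted to the universe, and terms empty after restriction
    are skipped.
    """
    symbols = query.symbols if isinstance(query, TargetSet) else set(query)
    if universe is None:
        universe = lib.gene_universe()
    if not universe:
        raise ValueError("empty gene universe")
    restricted = symbols & universe
    if not restricted:
        raise ValueError("query is empty after restriction to the universe")
    M = len(universe)
    n = len(restricted)
    out: list[EnrichmentTerm] = []
    for term_id in sorted(lib.terms):
        desc, genes = lib.terms[term_id]
        term_genes = genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        hits = restricted & term_genes
        k = len(hits)
        # survival function at k-1 = P(X >= k); hypergeom.sf works in log space
        p = float(hypergeom.sf(k - 1, M, K, n))
        p = min(max(p, 0.0), 1.0)
        term = EnrichmentTerm(term_id, desc, k, K, n, M, p, hit_genes=hits)
        term.validate()
        out.append(term)
    return out


def correct_pvalues(terms: list[EnrichmentTerm], method: str = "holm") -> list[EnrichmentTerm]:
    """Attach multiplicity-adjusted p-values (holm, bonferroni, or bh) in place."""
    if method not in _CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}; choose from {sorted(_CORRECTIONS)}")
    if not terms:
        raise ValueError("no terms to correct")
    pvals = [t.p for t in terms]
    _, p_adj, _, _ = multipletests(pvals, method=_CORRECTIONS[method])
    for t, adj in zip(terms, p_adj):
        t.p_adj = float(min(adj, 1.0))
        t.validate()
    return terms


def kappa_score(hits_a: set[str], hits_b: set[str], query_size: int) -> float:
    """Cohen's kappa between two terms' hit-membership over the query.

    With ``a = |A ∩ B|``, ``b = |A \\ B|``, ``c = |B \\ A|``,
    ``d = q - a - b - c``: observed agreement ``po = (a + d)/q``, chance
    agreement ``pe = ((a+b)(a+c) + (c+d)(b+d))/q^2``, and
    ``kappa = (po - pe)/(1 - pe)``; by convention kappa is 1 when ``pe = 1``
    (both sets empty or both the full query).
    """
    if query_size < 1:
        raise ValueError("query_size must be >= 1")
    a = len(hits_a & hits_b)
    b = len(hits_a - hits_b)
    c = len(hits_b - hits_a)
    d = query_size - a - b - c
    if d < 0:
        raise ValueError(
            f"hit sets exceed the query: |A u B| = {a + b + c} > query_size = {query_size}"
        )
    q = float(query_size)
    po = (a + d) / q
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (q * q)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def group_terms(
    terms: list[EnrichmentTerm],
    kappa_min: float = 0.4,
    query_size: int | None = None,
) -> list[TermGroup]:
    """Single-linkage kappa grouping of significant terms.

    Builds a term graph with an edge wherever pairwise kappa >= ``kappa_min``
    and returns the connected components as groups (singletons included).
    The leading term has the smallest p_adj, ties broken by larger ``k``,
    then lexicographic term id. ``query_size`` defaults to each pair's shared
    ``n``.
    """
    if not terms:
        return []
    ids = [t.term_id for t in terms]
    by_id = {t.term_id: t for t in terms}
    if len(by_id) != len(ids):
        raise ValueError("duplicate term ids")
    parent = {tid: tid for tid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    kappa_edges: dict[tuple[str, str], float] = {}
    for i, ta in enumerate(terms):
        for tb in terms[i + 1:]:
            q = query_size if query_size is not None else ta.n
            kappa = kappa_score(ta.hit_genes, tb.hit_genes, q)
            if kappa >= kappa_min:
                kappa_edges[(ta.term_id, tb.term_id)] = kappa
                ra, rb = find(ta.term_id), find(tb.term_id)
                if ra != rb:
                    parent[ra] = rb

    clusters: dict[str, list[str]] = {}
    for tid in ids:
        clusters.setdefault(find(tid), []).append(tid)
    groups = []
    for members in clusters.values():
        members.sort()
        leading = min(members, key=lambda tid: (by_id[tid].p_adj, -by_id[tid].k, tid))
        edges = {
            pair: kappa for pair, kappa in kappa_edges.items()
            if pair[0] in members and pair[1] in members
        }
        groups.append(TermGroup(members=members, leading_term=leading, kappa_edges=edges))
    groups.sort(key=lambda g: (by_id[g.leading_term].p_adj, g.leading_term))
    return groups
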