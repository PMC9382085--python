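"""Readers and writers for every external format the pipeline touches.

All gene identifiers pass through :func:`normalize_symbol` (trim + uppercase,
the human gene-symbol convention), and every parsed graph satisfies the
simple-graph contract: no self-loops, no duplicate edges, every edge endpoint
registered as a node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "GeneSetLibrary",
    "SymbolMap",
    "GraphIOError",
    "normalize_symbol",
    "canonical_edge",
    "read_edge_list",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mapping_table",
]


class GraphIOError(ValueError):
    """Raised for malformed input files or I/O contract violations."""


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and uppercase a gene symbol.

    Idempotent; raises :class:`GraphIOError` on an empty result.
    """
    s = symbol.strip().upper()
    if not s:
        raise GraphIOError(f"empty gene symbol after normalization: {symbol!r}")
    return s


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order an undirected edge lexicographically so unordered pairs are unique."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Undirected simple graph over gene symbols with optional node attributes.

    Invariants: no self-loops; edges stored as lexicographically ordered
    tuples so unordered pairs are unique; every endpoint is in ``nodes``.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    node_attrs: dict[str, dict[str, str]] = field(default_factory=dict)
    name: str = ""

    def add_node(self, symbol: str, **attrs: str) -> None:
        self.nodes.add(symbol)
        if attrs:
            self.node_attrs.setdefault(symbol, {}).update(attrs)

    def add_edge(self, a: str, b: str) -> bool:
        """Add an undirected edge; self-loops are rejected (returns False)."""
        if a == b:
            return False
        self.nodes.add(a)
        self.nodes.add(b)
        self.edges.add(canonical_edge(a, b))
        return True

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def degree(self) -> dict[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def induced_subgraph(self, keep: Iterable[str], name: str = "") -> "Network":
        keep_set = set(keep) & self.nodes
        sub = Network(name=name or self.name)
        for v in keep_set:
            sub.add_node(v, **self.node_attrs.get(v, {}))
        sub.edges = {e for e in self.edges if e[0] in keep_set and e[1] in keep_set}
        return sub

    def validate(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise GraphIOError(f"self-loop on {a}")
            if (a, b) != canonical_edge(a, b):
                raise GraphIOError(f"non-canonical edge {(a, b)}")
            if a not in self.nodes or b not in self.nodes:
                raise GraphIOError(f"edge endpoint missing from node set: {(a, b)}")
        if not set(self.node_attrs) <= self.nodes:
            raise GraphIOError("node_attrs key outside node set")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class GeneSetLibrary:
    """GMT-style library: term id -> (description, gene-symbol set)."""

    terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class SymbolMap:
    """One-to-one-per-source symbol translation (e.g. mouse -> human ortholog).

    Source symbols are matched on trimmed, case-preserved strings because
    mouse symbols are case-significant; target symbols are normalized.
    """

    pairs: dict[str, str] = field(default_factory=dict)

    def get(self, symbol: str) -> str | None:
        return self.pairs.get(symbol.strip())

    def __len__(self) -> int:
        return len(self.pairs)


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) skipping blanks and '#' comments."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_edge_list(path: str | Path, dialect: str = "tsv2col") -> Network:
    """Parse an undirected edge list in SIF or two-column TSV dialect.

    SIF lines are ``A <relation> B [B2 ...]`` and fan out to one edge per
    trailing node; TSV lines are ``A<TAB>B``. Duplicate and reversed-duplicate
    edges collapse; self-loop lines are dropped with a warning; ``#`` comments
    and blank lines are ignored. An empty file yields an empty network.
    """
    path = Path(path)
    if dialect not in ("sif", "tsv2col"):
        raise GraphIOError(f"unknown edge-list dialect: {dialect!r}")
    net = Network(name=path.stem)
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if dialect == "tsv2col" else line.split()
        if dialect == "tsv2col":
            if len(fields) != 2:
                raise GraphIOError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            a, b = (normalize_symbol(f) for f in fields)
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                net.add_node(a)
            else:
                net.add_edge(a, b)
        else:  # sif
            if len(fields) < 3:
                raise GraphIOError(
                    f"{path}:{lineno}: SIF line needs 'A relation B [B2 ...]', got {len(fields)} fields"
                )
            src = normalize_symbol(fields[0])
            for tgt_raw in fields[2:]:
                tgt = normalize_symbol(tgt_raw)
                if src == tgt:
                    logger.warning("%s:%d: dropping self-loop on %s", path, lineno, src)
                    net.add_node(src)
                else:
                    net.add_edge(src, tgt)
    net.validate()
    return net


def write_network(net: Network, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv`` in canonical order.

    Node rows sorted by symbol with attribute columns; edge rows sorted
    lexicographically. ``read_edge_list`` on the edges file reproduces the
    edge set exactly; the node file restores isolated nodes and attributes.
    """
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    attr_keys = sorted({k for attrs in net.node_attrs.values() for k in attrs})
    try:
        with open(nodes_path, "w") as fh:
            fh.write("\t".join(["node", *attr_keys]) + "\n")
            for v in sorted(net.nodes):
                attrs = net.node_attrs.get(v, {})
                fh.write("\t".join([v, *(attrs.get(k, "") for k in attr_keys)]) + "\n")
        with open(edges_path, "w") as fh:
            fh.write("# source\ttarget\n")
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\n")
    except OSError as exc:
        raise GraphIOError(f"cannot write network to {prefix}: {exc}") from exc
    return nodes_path, edges_path


def read_network(prefix: str | Path) -> Network:
    """Inverse of :func:`write_network`: rebuild a network from its two files."""
    prefix = Path(prefix)
    nodes_path = prefix.with_name(prefix.name + ".nodes.tsv")
    edges_path = prefix.with_name(prefix.name + ".edges.tsv")
    net = Network(name=prefix.stem)
    with open(nodes_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        attr_keys = header[1:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            attrs = {k: v for k, v in zip(attr_keys, fields[1:]) if v != ""}
            net.add_node(fields[0], **attrs)
    with open(edges_path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise GraphIOError(f"{edges_path}:{lineno}: expected 2 columns")
            net.add_edge(fields[0], fields[1])
    net.validate()
    return net


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT gene-set library: term, description, genes... (>=3 fields)."""
    path = Path(path)
    lib = GeneSetLibrary()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise GraphIOError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
            )
        term_id = fields[0].strip()
        if not term_id:
            raise GraphIOError(f"{path}:{lineno}: empty term id")
        if term_id in lib.terms:
            raise GraphIOError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
        if not genes:
            raise GraphIOError(f"{path}:{lineno}: term {term_id!r} has no genes")
        lib.terms[term_id] = (fields[1].strip(), genes)
    return lib


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term_id in sorted(lib.terms):
            desc, genes = lib.terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")
    return path


def read_expression_matrix(path: str | Path, labels_path: str | Path):
    """Load a genes x samples TSV plus a two-column sample->group label file.

    The matrix header row holds sample ids; the first column holds gene
    symbols. Exactly two group labels must cover all samples, each with at
    least two samples. Duplicate gene symbols keep the row with the highest
    mean (the drop is logged).

    Returns a :class:`netpharm.deg_screen.ExpressionDataset`.
    """
    import numpy as np
    import pandas as pd

    from .deg_screen import ExpressionDataset

    path = Path(path)
    labels_path = Path(labels_path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] < 4:
        raise GraphIOError(f"{path}: need at least 4 samples (2 per group)")
    df.index = [normalize_symbol(str(g)) for g in df.index]

    groups: dict[str, str] = {}
    for lineno, line in _data_lines(labels_path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphIOError(f"{labels_path}:{lineno}: expected 2 columns")
        groups[fields[0].strip()] = fields[1].strip()
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise GraphIOError(f"{path}: samples missing from labels file: {missing}")
    groups = {s: groups[s] for s in df.columns}
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise GraphIOError(f"{labels_path}: need exactly 2 group labels, got {levels}")
    for lv in levels:
        if sum(g == lv for g in groups.values()) < 2:
            raise GraphIOError(f"{labels_path}: group {lv!r} has fewer than 2 samples")

    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        dropped = df.index[df.index.duplicated(keep="first")]
        logger.warning("%s: dropping %d lower-mean duplicate gene rows", path, len(dropped))
        df = df[~df.index.duplicated(keep="first")].sort_index()

    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise GraphIOError(f"{path}: non-finite expression values")
    ds = ExpressionDataset(
        genes=list(df.index),
        samples=list(df.columns),
        values=values,
        groups=groups,
        name=path.stem,
    )
    ds.validate()
    return ds


def write_expression_matrix(ds, matrix_path: str | Path, labels_path: str | Path) -> None:
    """Write an ExpressionDataset as matrix TSV + label TSV (inverse of the reader)."""
    import pandas as pd

    df = pd.DataFrame(ds.values, index=ds.genes, columns=ds.samples)
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", float_format="%.6f")
    with open(labels_path, "w") as fh:
        for s in ds.samples:
            fh.write(f"{s}\t{ds.groups[s]}\n")


def read_mapping_table(path: str | Path) -> SymbolMap:
    """Parse a two-column source->target symbol map (e.g. mouse->human orthologs).

    Repeated identical pairs collapse; conflicting duplicate sources are an
    error. Source case is preserved (mouse symbols are case-significant);
    targets are normalized.
    """
    path = Path(path)
    pairs: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
        src = fields[0].strip()
        if not src:
            raise GraphIOError(f"{path}:{lineno}: empty source symbol")
        tgt = normalize_symbol(fields[1])
        if src in pairs and pairs[src] != tgt:
            raise GraphIOError(
                f"{path}:{lineno}: conflicting mapping for {src!r}: {pairs[src]!r} vs {tgt!r}"
            )
        pairs[src] = tgt
    return SymbolMap(pairs=pairs)
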