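"""Assembly of drug-side and disease-side target sets.

Builds deduplicated target sets with per-symbol provenance from compound
-> target evidence tables (score-filtered for prediction servers, passed
through for curated databases), merges multi-database disease target lists,
constructs the herb-compound-target tripartite network, and translates
symbol sets through an ortholog map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .graph_io import GraphIOError, Network, SymbolMap, _data_lines, normalize_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundTargetRecord",
    "TargetSet",
    "filter_predicted_targets",
    "merge_target_sets",
    "build_tripartite",
    "map_orthologs",
    "read_compound_target_table",
    "read_pair_table",
    "read_disease_target_table",
    "write_target_set",
    "read_target_set",
]


@dataclass(frozen=True)
class CompoundTargetRecord:
    """One evidence row: a compound predicted or curated to hit a target.

    ``score`` is the prediction score in the source database's own units
    (None for curated sources that report no score); ``source`` labels the
    database of origin.
    """

    compound: str
    target: str
    score: float | None = None
    source: str = ""

    def __post_init__(self):
        if not self.source:
            raise ValueError("CompoundTargetRecord.source must be non-empty")
        if self.score is not None and not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"non-finite score for {self.compound}->{self.target}")


@dataclass
class TargetSet:
    """Deduplicated gene-symbol set with per-symbol source provenance."""

    symbols: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def add(self, symbol: str, *sources: str) -> None:
        self.symbols.add(symbol)
        self.provenance.setdefault(symbol, set()).update(sources)

    def validate(self) -> None:
        if not set(self.provenance) <= self.symbols:
            raise ValueError("provenance keys outside symbol set")
        for sym in self.symbols:
            if not self.provenance.get(sym):
                raise ValueError(f"symbol {sym} has no provenance source")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def filter_predicted_targets(
    records: list[CompoundTargetRecord],
    score_min: float = 60.0,
    top_k: int = 50,
) -> TargetSet:
    """Apply the per-compound prediction-score screen.

    Per compound: scored records pass when ``score > score_min`` (strict);
    when no scored record clears the bar, the ``top_k`` highest-scored
    records are kept instead — the two rules are alternatives. Unscored
    (curated-database) records always pass. Returns the union with
    provenance.
    """
    if top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    out = TargetSet()
    by_compound: dict[str, list[CompoundTargetRecord]] = {}
    for rec in records:
        by_compound.setdefault(rec.compound, []).append(rec)
    for compound, recs in by_compound.items():
        scored = [r for r in recs if r.score is not None]
        for r in recs:
            if r.score is None:
                out.add(normalize_symbol(r.target), r.source)
        passing = [r for r in scored if r.score > score_min]
        if scored and not passing:
            # Fallback rule: nothing clears the score bar, keep the best top_k.
            passing = sorted(scored, key=lambda r: (-r.score, r.target))[:top_k]
            logger.info(
                "compound %s: no score > %s; falling back to top %d of %d",
                compound, score_min, top_k, len(scored),
            )
        for r in passing:
            out.add(normalize_symbol(r.target), r.source)
    out.validate()
    return out


def merge_target_sets(sets: list[TargetSet]) -> TargetSet:
    """Union of target sets with per-symbol provenance unions (dedup rule)."""
    out = TargetSet()
    for ts in sets:
        for sym in ts.symbols:
            out.add(sym, *ts.provenance.get(sym, set()))
    out.validate()
    return out


def build_tripartite(
    herb_compound: list[tuple[str, str]],
    compound_target: list[tuple[str, str]],
) -> Network:
    """Build the herb-compound-target network with a ``layer`` node attribute.

    Edges run only herb-compound and compound-target; a symbol appearing in
    two layers is an error. Compounds with no targets remain as herb-linked
    degree-1 nodes.
    """
    if not herb_compound or not compound_target:
        raise ValueError("herb_compound and compound_target pair lists must be non-empty")
    layers: dict[str, str] = {}

    def claim(symbol: str, layer: str) -> str:
        prev = layers.get(symbol)
        if prev is not None and prev != layer:
            raise ValueError(f"symbol {symbol!r} appears in layers {prev!r} and {layer!r}")
        layers[symbol] = layer
        return symbol

    net = Network(name="herb-compound-target")
    for herb, compound in herb_compound:
        h = claim(herb.strip(), "herb")
        c = claim(compound.strip(), "compound")
        net.add_edge(h, c)
    for compound, target in compound_target:
        c = claim(compound.strip(), "compound")
        t = claim(normalize_symbol(target), "target")
        net.add_edge(c, t)
    for sym, layer in layers.items():
        net.add_node(sym, layer=layer)
    net.validate()
    return net


def map_orthologs(genes: TargetSet, symbol_map: SymbolMap, policy: str = "drop") -> TargetSet:
    """Translate a target set through an ortholog/symbol map.

    Unmapped symbols are dropped (``policy='drop'``, default) or kept after
    normalization (``policy='keep'``). Provenance follows each symbol;
    sources merge when two inputs map to one output.
    """
    if policy not in ("drop", "keep"):
        raise ValueError(f"unknown policy {policy!r}")
    out = TargetSet()
    for sym in genes.symbols:
        mapped = symbol_map.get(sym)
        if mapped is None:
            if policy == "drop":
                continue
            mapped = normalize_symbol(sym)
        out.add(mapped, *genes.provenance.get(sym, set()))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Evidence-table I/O


def read_compound_target_table(path: str | Path) -> list[CompoundTargetRecord]:
    """Parse compound_target.tsv: compound, target, score (may be blank), source."""
    path = Path(path)
    records = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise GraphIOError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        compound, target, score_raw, source = (f.strip() for f in fields)
        if compound == "compound" and target == "target":
            continue  # header
        score = float(score_raw) if score_raw else None
        records.append(CompoundTargetRecord(compound, target, score, source))
    return records


def read_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Parse a two-column pair table (e.g. herb_compound.tsv), skipping a header."""
    path = Path(path)
    pairs = []
    for lineno, (_, line) in enumerate(_data_lines(path)):
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphIOError(f"{path}: expected 2 columns on data line {lineno + 1}")
        if lineno == 0 and fields[0].lower() in ("herb", "compound", "source"):
            continue
        pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


def read_disease_target_table(path: str | Path) -> TargetSet:
    """Parse disease_targets.tsv (target, source) into a TargetSet."""
    path = Path(path)
    out = TargetSet()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphIOError(f"{path}:{lineno}: expected 2 columns")
        if fields[0].strip().lower() == "target":
            continue
        out.add(normalize_symbol(fields[0]), fields[1].strip())
    out.validate()
    return out


def write_target_set(ts: TargetSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("target\tsources\n")
        for sym in sorted(ts.symbols):
            fh.write(f"{sym}\t{','.join(sorted(ts.provenance[sym]))}\n")
    return path


def read_target_set(path: str | Path) -> TargetSet:
    path = Path(path)
    out = TargetSet()
    for _, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise GraphIOError(f"{path}: expected 2 columns")
        if fields[0].strip().lower() == "target":
            continue
        out.add(normalize_symbol(fields[0]), *fields[1].split(","))
    out.validate()
    return out
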