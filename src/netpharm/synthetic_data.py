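"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Stands in for the proprietary evidence databases and omics series: a
scale-free interactome with degree-boosted planted hubs, multi-dataset
two-group expression matrices with planted differential genes (a fixed
subset shared across all datasets), compound/herb/disease evidence tables
whose targets overlap, and a gene-set library with one planted enriched
term. Every generator is a pure function of (config, seed): identical
configs produce byte-identical outputs, and each generator's manifest is
sufficient to recover every planted ground truth without re-generation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .deg_screen import ExpressionDataset
from .graph_io import (
    GeneSetLibrary,
    Network,
    write_expression_matrix,
    write_gmt,
)
from .target_assembly import CompoundTargetRecord, TargetSet

__all__ = [
    "SyntheticConfig",
    "generate_interactome",
    "generate_expression_bundle",
    "generate_evidence_tables",
    "generate_geneset_library",
    "write_fixture_bundle",
]

_DISEASE_SOURCES = ("DB_A", "DB_B", "DB_C", "DB_D", "DB_E")


@dataclass
class SyntheticConfig:
    """All knobs of the fixture generators, with study-scale defaults.

    Expression defaults (10 vs 10 samples, log2 effect 2, unit noise, five
    datasets sharing 66 planted differential genes) mirror the multi-series
    microarray screen the pipeline targets. The interactome is a
    preferential-attachment scaffold (n=2000, m=2) carrying two planted
    structures: a clique of ``hub_count`` degree-boosted hub genes (the
    ground-truth core module) and ``complex_count`` pendant cliques
    emulating protein complexes, which dominate the hub subnetwork the way
    complex-derived dense neighborhoods dominate real interactome cores.
    """

    seed: int = 0
    # interactome
    n_nodes: int = 2000
    attachment_m: int = 2
    hub_count: int = 20
    hub_extra_degree: int = 30
    complex_count: int = 40
    complex_size: int = 9
    complex_spokes: int = 3
    # expression bundle
    n_genes: int = 2000
    n_per_group: int = 10
    planted_deg_count: int = 120
    shared_deg_count: int = 66
    effect_log2fc: float = 2.0
    sigma: float = 1.0
    n_datasets: int = 5
    baseline_mean: float = 8.0
    # evidence tables
    n_compounds: int = 22
    targets_per_compound: int = 18
    n_herbs: int = 10
    scored_fraction: float = 0.5
    score_low: float = 0.0
    score_high: float = 100.0
    n_disease_targets: int = 150
    disease_overlap: float = 0.3
    module_targets_per_side: int = 10
    # gene-set library
    n_background_terms: int = 41
    term_size_min: int = 10
    term_size_max: int = 60
    planted_term_size: int = 30
    planted_overlap: int = 20

    def validate(self) -> list[str]:
        problems = []
        n_reserved = self.hub_count + self.complex_count * self.complex_size
        if self.n_nodes - n_reserved <= self.attachment_m or self.attachment_m < 1:
            problems.append(
                "need n_nodes - hub_count - complex_count*complex_size > attachment_m >= 1"
            )
        for name in ("hub_count", "hub_extra_degree", "complex_count",
                     "complex_size", "complex_spokes"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        for name in ("n_genes", "n_per_group",
                     "planted_deg_count", "shared_deg_count", "n_datasets",
                     "n_compounds", "targets_per_compound", "n_herbs",
                     "n_disease_targets", "n_background_terms", "term_size_min",
                     "term_size_max", "planted_term_size", "planted_overlap"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be positive")
        if self.shared_deg_count > self.planted_deg_count:
            problems.append("shared_deg_count must be <= planted_deg_count")
        if self.planted_deg_count > self.n_genes:
            problems.append("planted_deg_count must be <= n_genes")
        if self.sigma <= 0:
            problems.append("sigma must be positive")
        if not (0.0 <= self.scored_fraction <= 1.0):
            problems.append("scored_fraction must be in [0, 1]")
        if not (0.0 <= self.disease_overlap <= 1.0):
            problems.append("disease_overlap must be in [0, 1]")
        if self.module_targets_per_side < 0:
            problems.append("module_targets_per_side must be non-negative")
        if self.term_size_min > self.term_size_max:
            problems.append("term_size_min must be <= term_size_max")
        if self.planted_overlap > self.planted_term_size:
            problems.append("planted_overlap must be <= planted_term_size")
        return problems

    def check(self) -> "SyntheticConfig":
        problems = self.validate()
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))
        return self


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng([int(cfg.seed) % (2**31), stage])


def _symbol(i: int) -> str:
    return f"G{i + 1:05d}"


def generate_interactome(cfg: SyntheticConfig) -> tuple[Network, dict]:
    """Scale-free interactome with a planted hub module and pendant complexes.

    Three layers, emulating the composition of real protein-interaction
    networks:

    1. A preferential-attachment scaffold over the non-reserved nodes (each
       new node attaches to ``attachment_m`` distinct existing nodes with
       probability proportional to degree) — the sparse heavy-tailed bulk.
    2. ``hub_count`` planted hub genes forming a clique, each degree-boosted
       with ``hub_extra_degree`` spoke edges to low-degree scaffold nodes —
       a densely interconnected high-degree core module, the ground truth
       the two-stage screen should recover.
    3. ``complex_count`` pendant cliques of ``complex_size`` members
       (protein-complex analogues), each anchored to two of the ten
       highest-degree scaffold nodes and degree-boosted with
       ``complex_spokes`` spokes per member so the whole complex clears
       degree-based hub screens.

    Spoke partners are drawn from scaffold nodes of degree <= attachment_m+1
    with at most 3 spokes each, keeping them below typical hub thresholds.
    Returns the network and a manifest naming planted hubs and complexes.
    """
    import itertools

    cfg.check()
    rng = _rng(cfg, 1)
    n, m = cfg.n_nodes, cfg.attachment_m
    n_pa = n - cfg.hub_count - cfg.complex_count * cfg.complex_size
    edges: set[tuple[int, int]] = set()
    repeated: list[int] = []  # node listed once per incident edge endpoint
    degree: dict[int, int] = {}

    def add_edge(u: int, v: int) -> bool:
        if u == v:
            return False
        key = (u, v) if u < v else (v, u)
        if key in edges:
            return False
        edges.add(key)
        repeated.append(u)
        repeated.append(v)
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
        return True

    # scaffold: connect node m to each of 0..m-1, then preferential growth
    for u in range(m):
        add_edge(u, m)
    for v in range(m + 1, n_pa):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(0, len(repeated))])
        for u in targets:
            add_edge(u, v)

    low_pool = [v for v in range(n_pa) if degree.get(v, 0) <= m + 1]
    spoke_count = dict.fromkeys(low_pool, 0)

    def spoke_partner() -> int:
        while True:
            p = low_pool[rng.integers(0, len(low_pool))]
            if spoke_count[p] < 3:
                spoke_count[p] += 1
                return p

    top_scaffold = sorted(range(n_pa), key=lambda v: (-degree.get(v, 0), v))[:10]

    def add_spokes(node: int, count: int) -> None:
        added = attempts = 0
        while added < count and attempts < 20 * count + 100:
            attempts += 1
            if add_edge(node, spoke_partner()):
                added += 1

    hubs = list(range(n_pa, n_pa + cfg.hub_count))
    for a, b in itertools.combinations(hubs, 2):
        add_edge(a, b)
    for h in hubs:
        add_spokes(h, cfg.hub_extra_degree)

    complexes: list[list[int]] = []
    nxt = n_pa + cfg.hub_count
    for _ in range(cfg.complex_count):
        members = list(range(nxt, nxt + cfg.complex_size))
        nxt += cfg.complex_size
        complexes.append(members)
        for a, b in itertools.combinations(members, 2):
            add_edge(a, b)
        for _ in range(2):  # redundant anchoring keeps complexes attached in subnetworks
            anchor = members[int(rng.integers(0, len(members)))]
            add_edge(anchor, top_scaffold[int(rng.integers(0, len(top_scaffold)))])
        for mem in members:
            add_spokes(mem, cfg.complex_spokes)

    net = Network(name="synthetic-interactome")
    for i in range(n):
        net.add_node(_symbol(i))
    for u, v in edges:
        net.add_edge(_symbol(u), _symbol(v))
    for h in hubs:
        net.node_attrs.setdefault(_symbol(h), {})["planted_hub"] = "1"
    net.validate()
    manifest = {
        "planted_hubs": [_symbol(h) for h in hubs],
        "planted_complexes": [[_symbol(v) for v in c] for c in complexes],
    }
    return net, manifest


def generate_expression_bundle(
    cfg: SyntheticConfig,
    universe: list[str] | None = None,
) -> tuple[list[ExpressionDataset], dict]:
    """K two-group log2 expression matrices with planted differential genes.

    Baseline values are N(baseline_mean, sigma^2); planted genes are shifted
    by ±effect_log2fc in the case group (sign drawn per gene per dataset).
    Exactly ``shared_deg_count`` planted genes are common to every dataset;
    the remainder of each dataset's ``planted_deg_count`` is private. The
    manifest lists shared and per-dataset planted genes with signs.
    """
    cfg.check()
    rng = _rng(cfg, 2)
    genes = list(universe) if universe is not None else [_symbol(i) for i in range(cfg.n_genes)]
    if len(genes) < cfg.n_genes:
        raise ValueError("universe smaller than n_genes")
    genes = genes[: cfg.n_genes]

    shared = sorted(rng.choice(genes, size=cfg.shared_deg_count, replace=False).tolist())
    non_shared = sorted(set(genes) - set(shared))
    n_private = cfg.planted_deg_count - cfg.shared_deg_count
    n_samp = cfg.n_per_group
    datasets: list[ExpressionDataset] = []
    manifest: dict = {"shared_degs": shared, "datasets": {}}
    for d in range(cfg.n_datasets):
        name = f"DS{d + 1}"
        private = sorted(rng.choice(non_shared, size=n_private, replace=False).tolist())
        planted = sorted(shared + private)
        signs = {g: int(s) for g, s in zip(planted, rng.choice([-1, 1], size=len(planted)))}
        samples = [f"{name}C{i + 1:02d}" for i in range(n_samp)] + [
            f"{name}T{i + 1:02d}" for i in range(n_samp)
        ]
        groups = {s: ("control" if i < n_samp else "case") for i, s in enumerate(samples)}
        values = rng.normal(cfg.baseline_mean, cfg.sigma, size=(cfg.n_genes, 2 * n_samp))
        gene_index = {g: i for i, g in enumerate(genes)}
        for g in planted:
            values[gene_index[g], n_samp:] += signs[g] * cfg.effect_log2fc
        ds = ExpressionDataset(genes=list(genes), samples=samples, values=values,
                               groups=groups, name=name, case_group="case")
        ds.validate()
        datasets.append(ds)
        manifest["datasets"][name] = {"planted_degs": planted, "signs": signs}
    return datasets, manifest


def generate_evidence_tables(
    cfg: SyntheticConfig,
    interactome: Network,
    planted_hubs: list[str] | None = None,
    planted_complexes: list[list[str]] | None = None,
) -> tuple[list[CompoundTargetRecord], list[tuple[str, str]], TargetSet, dict]:
    """Compound-target records, herb-compound pairs, and curated disease targets.

    The planted structures are drug- and disease-relevant by construction —
    the premise of network pharmacology is that compound targets and
    disease targets converge on shared interactome modules. Each planted
    complex therefore contributes one randomly chosen member to the drug
    target pool and one to the disease target pool, and
    ``module_targets_per_side`` planted hub-module members appear on each
    side; all remaining targets are uniform interactome draws. A
    ``scored_fraction`` of compound-target records carries a prediction
    score ~ Uniform(score_low, score_high) under a prediction-server source
    label, the rest are curated and unscored. Disease targets additionally
    overlap the drug target pool at rate ``disease_overlap``; source labels
    cycle over five database names.
    """
    cfg.check()
    rng = _rng(cfg, 3)
    nodes = sorted(interactome.nodes)
    hubs = [h for h in (planted_hubs or []) if h in interactome.nodes]
    complexes = [
        [v for v in c if v in interactome.nodes] for c in (planted_complexes or [])
    ]
    compounds = [f"CMP{i + 1:02d}" for i in range(cfg.n_compounds)]
    herbs = [f"HRB{i + 1:02d}" for i in range(cfg.n_herbs)]
    herb_compound = [
        (herbs[int(rng.integers(0, cfg.n_herbs))], c) for c in compounds
    ]

    def structure_picks() -> list[str]:
        picks = [c[int(rng.integers(0, len(c)))] for c in complexes if c]
        if hubs:
            k = min(cfg.module_targets_per_side, len(hubs))
            picks.extend(rng.choice(hubs, size=k, replace=False).tolist())
        return picks

    # drug side: guaranteed structure picks round-robin over compounds as
    # curated (unscored) records, then uniform fills up to
    # targets_per_compound each with the scored/curated source mix
    guaranteed = structure_picks()
    per_compound: dict[str, set[str]] = {c: set() for c in compounds}
    curated_guaranteed: set[tuple[str, str]] = set()
    for i, t in enumerate(guaranteed):
        c = compounds[i % len(compounds)]
        per_compound[c].add(t)
        curated_guaranteed.add((c, t))
    for c in compounds:
        while len(per_compound[c]) < cfg.targets_per_compound:
            per_compound[c].add(nodes[int(rng.integers(0, len(nodes)))])

    records: list[CompoundTargetRecord] = []
    drug_pool: set[str] = set()
    for c in compounds:
        for t in sorted(per_compound[c]):
            drug_pool.add(t)
            if (c, t) not in curated_guaranteed and rng.random() < cfg.scored_fraction:
                score = float(rng.uniform(cfg.score_low, cfg.score_high))
                records.append(CompoundTargetRecord(c, t, round(score, 3), "PRED"))
            else:
                records.append(CompoundTargetRecord(c, t, None, "CURATED"))

    # disease side: its own structure picks, plus overlap with the drug pool,
    # plus uniform fills
    disease_picks = set(structure_picks())
    drug_sorted = sorted(drug_pool)
    n_overlap = min(int(round(cfg.disease_overlap * cfg.n_disease_targets)), len(drug_sorted))
    disease_picks |= set(rng.choice(drug_sorted, size=n_overlap, replace=False).tolist())
    while len(disease_picks) < cfg.n_disease_targets:
        disease_picks.add(nodes[int(rng.integers(0, len(nodes)))])
    disease = TargetSet()
    for i, t in enumerate(sorted(disease_picks)):
        disease.add(t, _DISEASE_SOURCES[i % len(_DISEASE_SOURCES)])
    disease.validate()
    manifest = {
        "compounds": compounds,
        "herbs": herbs,
        "drug_target_pool": sorted(drug_pool),
        "disease_targets": sorted(disease.symbols),
        "n_overlap_targets": n_overlap,
    }
    return records, herb_compound, disease, manifest


def generate_geneset_library(
    cfg: SyntheticConfig,
    universe: list[str],
    query: set[str],
) -> tuple[GeneSetLibrary, dict]:
    """Background terms drawn uniformly from the universe plus one planted term.

    The planted term takes ``planted_overlap`` genes from the designated
    query and the rest from outside it, so it is genuinely over-represented;
    background terms are uniform draws. The manifest records the planted
    term id and its intended query overlap.
    """
    cfg.check()
    if len(universe) < cfg.term_size_max:
        raise ValueError("universe smaller than the maximum term size")
    rng = _rng(cfg, 4)
    universe = sorted(universe)
    lib = GeneSetLibrary()
    for i in range(cfg.n_background_terms):
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        genes = set(rng.choice(universe, size=size, replace=False).tolist())
        lib.terms[f"T{i + 1:04d}"] = (f"background term {i + 1}", genes)

    query_sorted = sorted(set(query) & set(universe))
    n_hit = min(cfg.planted_overlap, len(query_sorted))
    hit = set(rng.choice(query_sorted, size=n_hit, replace=False).tolist()) if n_hit else set()
    non_query = sorted(set(universe) - set(query_sorted))
    n_fill = cfg.planted_term_size - n_hit
    fill = set(rng.choice(non_query, size=min(n_fill, len(non_query)), replace=False).tolist())
    lib.terms["T_PLANTED"] = ("planted enriched term", hit | fill)
    manifest = {
        "planted_term": "T_PLANTED",
        "planted_overlap": sorted(hit),
        "n_background_terms": cfg.n_background_terms,
    }
    return lib, manifest


def write_fixture_bundle(cfg: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate and write every fixture file the pipeline consumes.

    Emits ``interactome.tsv`` (2-column edge list), ``compound_targets.tsv``,
    ``herb_compounds.tsv``, ``disease_targets.tsv``, per-dataset expression
    matrices + label files, ``library.gmt``, and ``manifest.json``; returns
    the manifest (which also records all file paths, relative to outdir).
    """
    cfg.check()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, net_manifest = generate_interactome(cfg)
    with open(outdir / "interactome.tsv", "w") as fh:
        fh.write("# synthetic interactome edge list\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")

    records, herb_compound, disease, ev_manifest = generate_evidence_tables(
        cfg, net,
        planted_hubs=net_manifest["planted_hubs"],
        planted_complexes=net_manifest["planted_complexes"],
    )
    with open(outdir / "compound_targets.tsv", "w") as fh:
        fh.write("compound\ttarget\tscore\tsource\n")
        for r in records:
            score = "" if r.score is None else f"{r.score:g}"
            fh.write(f"{r.compound}\t{r.target}\t{score}\t{r.source}\n")
    with open(outdir / "herb_compounds.tsv", "w") as fh:
        fh.write("herb\tcompound\n")
        for h, c in herb_compound:
            fh.write(f"{h}\t{c}\n")
    with open(outdir / "disease_targets.tsv", "w") as fh:
        fh.write("target\tsource\n")
        for t in sorted(disease.symbols):
            for s in sorted(disease.provenance[t]):
                fh.write(f"{t}\t{s}\n")

    universe = sorted(net.nodes)
    datasets, expr_manifest = generate_expression_bundle(cfg, universe=universe)
    expression_files = []
    for ds in datasets:
        mat = outdir / f"expr_{ds.name}.tsv"
        lab = outdir / f"labels_{ds.name}.tsv"
        write_expression_matrix(ds, mat, lab)
        expression_files.append({"matrix": mat.name, "labels": lab.name})

    query = set(net_manifest["planted_hubs"])
    lib, lib_manifest = generate_geneset_library(cfg, universe, query)
    write_gmt(lib, outdir / "library.gmt")

    manifest = {
        "config": asdict(cfg),
        "interactome": {"file": "interactome.tsv", **net_manifest,
                        "n_nodes": net.n_nodes, "n_edges": net.n_edges},
        "evidence": {
            "compound_targets": "compound_targets.tsv",
            "herb_compounds": "herb_compounds.tsv",
            "disease_targets": "disease_targets.tsv",
            **ev_manifest,
        },
        "expression": {"files": expression_files, **expr_manifest},
        "library": {"file": "library.gmt", **lib_manifest},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
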