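"""End-to-end orchestration: synth -> targets -> degs -> screen -> enrich.

Every stage reads and writes plain TSV/JSON files under the output
directory, so any stage can be re-run or inspected independently. A run is
a pure function of (config, seed): reports and artifacts are byte-identical
across repeated runs. The machine-readable ``report.json`` records
per-stage counts, the thresholds actually applied, and the stage order; it
contains no timestamps.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

from . import __version__
from .deg_screen import de_test, intersect_degs, threshold_degs
from .enrichment import correct_pvalues, group_terms, hypergeom_ora
from .graph_io import (
    Network,
    read_edge_list,
    read_expression_matrix,
    read_gmt,
    write_network,
)
from .ppi_centrality import (
    INDEX_NAMES,
    expand_subnetwork,
    intersect_networks,
    two_stage_screen,
)
from .synthetic_data import SyntheticConfig, write_fixture_bundle
from .target_assembly import (
    TargetSet,
    build_tripartite,
    filter_predicted_targets,
    merge_target_sets,
    read_compound_target_table,
    read_disease_target_table,
    read_pair_table,
    write_target_set,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_THRESHOLDS", "PipelineError", "validate_config", "run_pipeline"]

DEFAULT_THRESHOLDS: dict[str, Any] = {
    "score_min": 60.0,
    "top_k": 50,
    "fc_min_log2": 1.0,
    "p_max": 0.05,
    "multiplier": 2.0,
    "kappa_min": 0.4,
    "p_sig": 0.05,
    "depth": 1,
    "de_test": "welch_t",
    "correction": "holm",
}

STAGES = (
    "synth",
    "drug_targets",
    "disease_targets",
    "expand",
    "intersect",
    "screen",
    "enrich",
    "deg_drug_intersection",
    "report",
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the partial report."""

    def __init__(self, stage: str, message: str, report: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.report = report or {}


def validate_config(cfg: dict) -> list[str]:
    """Return every violated constraint; an empty list means runnable."""
    problems: list[str] = []
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    if thresholds["score_min"] < 0:
        problems.append("score_min must be >= 0")
    if int(thresholds["top_k"]) <= 0:
        problems.append("top_k must be positive")
    if thresholds["fc_min_log2"] < 0:
        problems.append("fc_min_log2 must be >= 0")
    for key in ("p_max", "p_sig"):
        if not (0 < thresholds[key] <= 1):
            problems.append(f"{key} must be in (0, 1]")
    if thresholds["multiplier"] < 0:
        problems.append("multiplier must be >= 0")
    if not (-1 <= thresholds["kappa_min"] <= 1):
        problems.append("kappa_min must be in [-1, 1]")
    if int(thresholds["depth"]) < 0:
        problems.append("depth must be >= 0")
    if thresholds["de_test"] not in ("welch_t", "student_t"):
        problems.append("de_test must be welch_t or student_t")
    if thresholds["correction"] not in ("holm", "bonferroni", "bh"):
        problems.append("correction must be holm, bonferroni, or bh")

    if "synthetic" in cfg:
        synth = SyntheticConfig(seed=int(cfg.get("seed", 0)), **cfg["synthetic"])
        problems.extend(synth.validate())
    else:
        inputs = cfg.get("inputs", {})
        for key in ("interactome", "compound_targets", "herb_compounds",
                    "disease_targets", "gmt"):
            path = inputs.get(key)
            if path is None:
                problems.append(f"inputs.{key} missing")
            elif not Path(path).exists():
                problems.append(f"inputs.{key} does not exist: {path}")
        expr = inputs.get("expression", [])
        if len(expr) < 2:
            problems.append("inputs.expression needs at least 2 datasets")
        for item in expr:
            for key in ("matrix", "labels"):
                path = item.get(key)
                if path is None or not Path(path).exists():
                    problems.append(f"expression {key} missing or absent: {path}")
    return problems


def _counts(net: Network) -> dict[str, int]:
    return {"nodes": net.n_nodes, "edges": net.n_edges}


def run_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Execute the full network-pharmacology pipeline and return the run report.

    ``cfg`` holds ``seed``, optional ``synthetic`` generator overrides (or
    explicit ``inputs`` paths), and ``thresholds`` overrides. All artifacts
    land under ``outdir``; the report is also written as ``report.json``.
    """
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    report: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "thresholds": {k: thresholds[k] for k in sorted(thresholds)},
        "stages": [],
        "counts": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ synth
        if "synthetic" in cfg:
            stage = "synth"
            synth_cfg = SyntheticConfig(seed=seed, **cfg["synthetic"]).check()
            fixtures = outdir / "fixtures"
            manifest = write_fixture_bundle(synth_cfg, fixtures)
            inputs = {
                "interactome": fixtures / "interactome.tsv",
                "interactome_dialect": "tsv2col",
                "compound_targets": fixtures / "compound_targets.tsv",
                "herb_compounds": fixtures / "herb_compounds.tsv",
                "disease_targets": fixtures / "disease_targets.tsv",
                "expression": [
                    {"matrix": fixtures / f["matrix"], "labels": fixtures / f["labels"]}
                    for f in manifest["expression"]["files"]
                ],
                "gmt": fixtures / "library.gmt",
            }
            report["stages"].append("synth")
        else:
            inputs = dict(cfg["inputs"])

        interactome = read_edge_list(
            inputs["interactome"], dialect=inputs.get("interactome_dialect", "tsv2col")
        )
        report["counts"]["interactome"] = _counts(interactome)

        # ----------------------------------------------------- drug targets
        stage = "drug_targets"
        records = read_compound_target_table(inputs["compound_targets"])
        herb_compound = read_pair_table(inputs["herb_compounds"])
        drug_targets = filter_predicted_targets(
            records, score_min=thresholds["score_min"], top_k=int(thresholds["top_k"])
        )
        write_target_set(drug_targets, outdir / "drug_targets.tsv")
        compound_target_pairs = sorted(
            {(r.compound, r.target) for r in records if r.target in drug_targets.symbols}
        )
        tripartite = build_tripartite(herb_compound, compound_target_pairs)
        write_network(tripartite, outdir / "tripartite")
        report["counts"]["drug_targets"] = len(drug_targets)
        report["counts"]["tripartite"] = _counts(tripartite)
        report["stages"].append("drug_targets")

        # -------------------------------------------------- disease targets
        stage = "disease_targets"
        curated = read_disease_target_table(inputs["disease_targets"])
        deg_sets: list[TargetSet] = []
        deg_counts = {}
        for item in inputs["expression"]:
            ds = read_expression_matrix(item["matrix"], item["labels"])
            res = de_test(ds, test=thresholds["de_test"])
            degs = threshold_degs(res, thresholds["fc_min_log2"], thresholds["p_max"])
            deg_sets.append(degs)
            deg_counts[ds.name] = len(degs)
            with open(outdir / f"de_{ds.name}.tsv", "w") as fh:
                fh.write("gene\tlog2fc\tp\tpass\n")
                passing = degs.symbols
                for g, fc, p in zip(res.genes, res.log2fc, res.p):
                    fh.write(f"{g}\t{fc:.6g}\t{p:.6g}\t{int(g in passing)}\n")
        shared_degs, venn = intersect_degs(deg_sets)
        with open(outdir / "venn.json", "w") as fh:
            json.dump({"regions": venn, "intersection": sorted(shared_degs.symbols)},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")
        disease_targets = merge_target_sets([curated, shared_degs])
        write_target_set(disease_targets, outdir / "disease_targets.tsv")
        report["counts"]["degs_per_dataset"] = deg_counts
        report["counts"]["shared_degs"] = len(shared_degs)
        report["counts"]["curated_disease_targets"] = len(curated)
        report["counts"]["disease_targets"] = len(disease_targets)
        report["stages"].append("disease_targets")

        # ------------------------------------------------------------ expand
        stage = "expand"
        depth = int(thresholds["depth"])
        drug_net = expand_subnetwork(interactome, drug_targets, depth=depth)
        disease_net = expand_subnetwork(interactome, disease_targets, depth=depth)
        write_network(drug_net, outdir / "drug_network")
        write_network(disease_net, outdir / "disease_network")
        report["counts"]["drug_network"] = _counts(drug_net)
        report["counts"]["disease_network"] = _counts(disease_net)
        report["stages"].append("expand")

        # --------------------------------------------------------- intersect
        stage = "intersect"
        merged = intersect_networks(drug_net, disease_net)
        write_network(merged, outdir / "intersection_network")
        report["counts"]["intersection_network"] = _counts(merged)
        report["stages"].append("intersect")

        # ------------------------------------------------------------ screen
        stage = "screen"
        screening = two_stage_screen(merged, multiplier=thresholds["multiplier"])
        write_network(screening.hub_network, outdir / "hub_network")
        write_network(screening.core_network, outdir / "core_network")
        screening.stage2_table.to_frame().to_csv(
            outdir / "hub_centralities.tsv", sep="\t", float_format="%.8g"
        )
        with open(outdir / "screen_thresholds.json", "w") as fh:
            json.dump(
                {
                    "stage1_DC": screening.stage1_threshold,
                    "stage2": {k: screening.stage2_thresholds[k] for k in INDEX_NAMES},
                    "multiplier": thresholds["multiplier"],
                },
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        report["counts"]["hub_network"] = _counts(screening.hub_network)
        report["counts"]["core_network"] = _counts(screening.core_network)
        report["screen_thresholds"] = {
            "stage1_DC": screening.stage1_threshold,
            "stage2": {k: screening.stage2_thresholds[k] for k in INDEX_NAMES},
        }
        report["stages"].append("screen")

        # ------------------------------------------------------------ enrich
        stage = "enrich"
        lib = read_gmt(inputs["gmt"])
        core_targets = TargetSet()
        for v in screening.core_network.nodes:
            core_targets.add(v, "core")
        write_target_set(core_targets, outdir / "core_targets.tsv")
        terms = hypergeom_ora(core_targets, lib)
        terms = correct_pvalues(terms, method=thresholds["correction"])
        significant = [t for t in terms if t.p_adj <= thresholds["p_sig"]]
        groups = group_terms(significant, kappa_min=thresholds["kappa_min"])
        group_of = {tid: i + 1 for i, g in enumerate(groups) for tid in g.members}
        leading = {g.leading_term for g in groups}
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("term\tk\tK\tn\tM\tp\tp_adj\tgroup\tleading\thit_genes\n")
            for t in sorted(terms, key=lambda t: (t.p, t.term_id)):
                fh.write(
                    f"{t.term_id}\t{t.k}\t{t.K}\t{t.n}\t{t.M}\t{t.p:.6g}\t{t.p_adj:.6g}\t"
                    f"{group_of.get(t.term_id, 0)}\t{int(t.term_id in leading)}\t"
                    f"{','.join(sorted(t.hit_genes))}\n"
                )
        with open(outdir / "enrichment_groups.json", "w") as fh:
            json.dump(
                [
                    {"leading_term": g.leading_term, "members": g.members}
                    for g in groups
                ],
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        report["counts"]["terms_tested"] = len(terms)
        report["counts"]["terms_significant"] = len(significant)
        report["counts"]["term_groups"] = len(groups)
        report["stages"].append("enrich")

        # ---------------------------------------- DEG x drug-target network
        stage = "deg_drug_intersection"
        overlap = shared_degs.symbols & drug_targets.symbols
        if overlap:
            overlap_net = interactome.induced_subgraph(overlap, name="deg-drug")
        else:
            overlap_net = Network(name="deg-drug")
        write_network(overlap_net, outdir / "deg_drug_network")
        report["counts"]["deg_drug_overlap"] = len(overlap)
        report["counts"]["deg_drug_network"] = _counts(overlap_net)
        report["stages"].append("deg_drug_intersection")

        # ------------------------------------------------------------ report
        stage = "report"
        report["stages"].append("report")
        _check_report(report)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context added deliberately
        report["failed_stage"] = stage
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise PipelineError(stage, str(exc), report) from exc


def _check_report(report: dict) -> None:
    """Cross-stage consistency: core <= hub <= intersection <= min(inputs)."""
    c = report["counts"]
    if not (
        c["core_network"]["nodes"]
        <= c["hub_network"]["nodes"]
        <= c["intersection_network"]["nodes"]
        <= min(c["drug_network"]["nodes"], c["disease_network"]["nodes"])
    ):
        raise ValueError(f"inconsistent stage counts: {c}")
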