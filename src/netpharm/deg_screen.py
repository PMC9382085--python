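"""Two-group differential-expression screening and multi-dataset Venn intersection.

Expression values are assumed to already be on a log2 scale (log2 microarray
intensity or log2(count+1)), so the effect size per gene is the difference of
group means — the log2 fold change. The per-gene test is Welch's t by default
(Student's t optional); significance thresholds are applied on raw p-values,
and fold-change thresholds on |log2fc|, both strictly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .target_assembly import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "DEResult",
    "de_test",
    "threshold_degs",
    "intersect_degs",
]


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with a two-level group factor."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), log2 scale
    groups: dict[str, str]  # sample id -> group label
    name: str = ""
    case_group: str | None = None  # defaults to the lexicographically larger label

    def validate(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        levels = sorted(set(self.groups[s] for s in self.samples))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {levels}")
        for lv in levels:
            if sum(self.groups[s] == lv for s in self.samples) < 2:
                raise ValueError(f"group {lv!r} has fewer than 2 samples")

    def group_levels(self) -> tuple[str, str]:
        """(case, control) labels; 'case' wins if literally present."""
        levels = sorted(set(self.groups[s] for s in self.samples))
        if self.case_group is not None:
            if self.case_group not in levels:
                raise ValueError(f"case_group {self.case_group!r} not in {levels}")
            case = self.case_group
        elif "case" in levels:
            case = "case"
        else:
            case = levels[-1]
        control = next(lv for lv in levels if lv != case)
        return case, control

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """(case submatrix, control submatrix), columns in sample order."""
        case, control = self.group_levels()
        case_idx = [i for i, s in enumerate(self.samples) if self.groups[s] == case]
        ctrl_idx = [i for i, s in enumerate(self.samples) if self.groups[s] == control]
        return self.values[:, case_idx], self.values[:, ctrl_idx]


@dataclass
class DEResult:
    """Per-gene differential-expression statistics: log2fc and two-sided p."""

    genes: list[str]
    log2fc: np.ndarray
    p: np.ndarray
    dataset: str = ""

    def validate(self) -> None:
        n = len(self.genes)
        if self.log2fc.shape != (n,) or self.p.shape != (n,):
            raise ValueError("result arrays do not match gene list")
        if len(set(self.genes)) != n:
            raise ValueError("duplicate genes in result")
        if not np.all(np.isfinite(self.log2fc)):
            raise ValueError("non-finite log2fc")
        if np.any((self.p < 0) | (self.p > 1)) or not np.all(np.isfinite(self.p)):
            raise ValueError("p-values outside [0, 1]")


def de_test(ds: ExpressionDataset, test: str = "welch_t") -> DEResult:
    """Per-gene two-group t-test on log2 values.

    ``log2fc = mean(case) - mean(control)``. Degenerate genes where both
    groups have zero variance get ``p=1`` when the means are equal and
    ``p=0`` (logged) when they differ — the evidence is then noiseless.
    Deterministic for fixed input.
    """
    if test not in ("welch_t", "student_t"):
        raise ValueError(f"unknown test {test!r}")
    ds.validate()
    case, control = ds.split()
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, control, axis=1, equal_var=(test == "student_t"))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        zero_fc = np.isclose(log2fc[degenerate], 0.0)
        p[degenerate] = np.where(zero_fc, 1.0, 0.0)
        n_forced = int(np.sum(~zero_fc))
        if n_forced:
            logger.info(
                "%s: %d genes with zero within-group variance and unequal means; p set to 0",
                ds.name, n_forced,
            )
    out = DEResult(genes=list(ds.genes), log2fc=log2fc, p=p, dataset=ds.name)
    out.validate()
    return out


def threshold_degs(res: DEResult, fc_min_log2: float, p_max: float) -> TargetSet:
    """Select genes with |log2fc| > fc_min_log2 AND p < p_max (both strict).

    The microarray screen uses ``fc_min_log2=1``; the RNA-seq screen uses
    ``fc_min_log2=log2(1.5)``. Provenance records the dataset and direction
    (up/down by sign of log2fc).
    """
    if fc_min_log2 < 0:
        raise ValueError(f"fc_min_log2 must be >= 0, got {fc_min_log2}")
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    res.validate()
    out = TargetSet()
    label = res.dataset or "de"
    for gene, fc, p in zip(res.genes, res.log2fc, res.p):
        if abs(fc) > fc_min_log2 and p < p_max:
            direction = "up" if fc > 0 else "down"
            out.add(gene, f"{label}:{direction}")
    out.validate()
    return out


def intersect_degs(sets: list[TargetSet]) -> tuple[TargetSet, dict[str, int]]:
    """Venn intersection of K DEG sets plus the size of every Venn region.

    Returns the symbols common to all sets (provenance merged) and a dict
    keyed by membership mask (e.g. ``'101'`` = in sets 1 and 3 only, ordered
    as given) mapping to the exclusive region size — all 2^K - 1 regions.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    common = set.intersection(*(ts.symbols for ts in sets))
    out = TargetSet()
    for sym in common:
        sources: set[str] = set()
        for ts in sets:
            sources |= ts.provenance.get(sym, set())
        out.add(sym, *sources)
    out.validate()

    k = len(sets)
    regions: dict[str, int] = {}
    all_symbols = set().union(*(ts.symbols for ts in sets))
    membership: dict[str, int] = {}
    for sym in all_symbols:
        mask = 0
        for i, ts in enumerate(sets):
            if sym in ts.symbols:
                mask |= 1 << i
        membership[sym] = mask
    counts: dict[int, int] = {}
    for mask in membership.values():
        counts[mask] = counts.get(mask, 0) + 1
    for bits in itertools.product("01", repeat=k):
        key = "".join(bits)
        mask = sum(1 << i for i, b in enumerate(bits) if b == "1")
        if mask == 0:
            continue
        regions[key] = counts.get(mask, 0)
    return out, regions


def expected_null_pass_rate(
    fc_min_log2: float,
    p_max: float,
    sigma: float,
    n_per_group: int,
) -> float:
    """Closed-form expected pass rate of the screen under the gene-level null.

    Under N(0, sigma^2) noise with n per group, log2fc ~ N(0, 2 sigma^2 / n)
    and the t statistic is independent-ish of |log2fc| only asymptotically;
    this returns the independence approximation
    ``p_max * P(|log2fc| > fc_min_log2)`` used as a sanity scale for the
    calibration property (the test itself compares against simulation).
    """
    se = sigma * math.sqrt(2.0 / n_per_group)
    p_fc = 2.0 * stats.norm.sf(fc_min_log2 / se)
    return p_max * p_fc
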