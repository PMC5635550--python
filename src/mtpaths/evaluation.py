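"""Validation of recovered gene lists against curated gene-set collections.

Networks are hard to validate directly, so recovered genes are compared with
external collections (GO terms, oncogenic signatures, known cancer genes):
raw overlap counts per drug, hypergeometric enrichment, and ranking quality
via normalized discounted cumulative gain (nDCG).  A generic grid search
over objective weights scores each setting by total validation overlap.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

from scipy import stats

from .network import Condition
from .objective import ObjectiveParams
from .ranking import RankedGeneList
from .solver import SolverConfig, greedy_optimize

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "overlap_count",
    "average_overlap",
    "hypergeometric_pvalue",
    "ndcg",
    "grid_search",
]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, genes per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has < 3 fields")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name}")
            sets[name] = genes
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = sorted(gene_sets[name])
            fh.write("\t".join([name, "na"] + genes) + "\n")


def overlap_count(genes: set[str], validation: set[str]) -> int:
    """|genes ∩ validation|."""
    return len(set(genes) & set(validation))


def average_overlap(
    per_drug_gene_sets: Mapping[str, set[str]], validation: set[str]
) -> float:
    """Mean overlap with the validation set across drugs."""
    if not per_drug_gene_sets:
        raise ValueError("need at least one drug")
    counts = [overlap_count(g, validation) for g in per_drug_gene_sets.values()]
    return float(sum(counts)) / len(counts)


def hypergeometric_pvalue(
    overlap: int, list_size: int, set_size: int, universe_size: int
) -> float:
    """P(X >= overlap) drawing ``list_size`` genes from the universe."""
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, set_size, list_size)
    )


def ndcg(
    ranked: RankedGeneList | list[str],
    relevant: set[str],
    depth: int | None = None,
) -> float:
    """Normalized discounted cumulative gain with binary relevance.

    DCG@depth = Σ_i rel_i / log2(i + 1) over 1-based positions i, divided by
    the ideal DCG attainable with the same number of relevant genes.
    Returns 0 when no relevant gene exists.  ``depth`` defaults to the list
    length.
    """
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else list(ranked)
    if depth is None:
        depth = len(genes)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not relevant:
        return 0.0
    dcg = sum(
        1.0 / math.log2(i + 1)
        for i, g in enumerate(genes[:depth], start=1)
        if g in relevant
    )
    n_rel = min(len(relevant), depth)
    idcg = sum(1.0 / math.log2(i + 1) for i in range(1, n_rel + 1))
    return dcg / idcg if idcg > 0 else 0.0


def grid_search(
    conditions: list[Condition],
    param_grid: list[ObjectiveParams],
    gene_sets: Mapping[str, set[str]],
    cfg: SolverConfig | None = None,
) -> list[tuple[ObjectiveParams, float]]:
    """Score each parameter setting by validation overlap of its solution.

    Runs the multi-task solver per setting, pools the selected genes over
    conditions, and scores the pool by its total overlap with all validation
    sets (raw counts).  Returns settings sorted by descending score (stable
    w.r.t. grid order).  A setting whose solve fails is kept with score 0.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    results: list[tuple[ObjectiveParams, float]] = []
    for params in param_grid:
        try:
            solution, _ = greedy_optimize(conditions, params, cfg)
            selected = solution.union_nodes()
            score = float(
                sum(overlap_count(selected, vs) for vs in gene_sets.values())
            )
        except Exception:
            logger.exception("solver failed for %s; scored 0", params)
            score = 0.0
        results.append((params, score))
    order = sorted(range(len(results)), key=lambda i: (-results[i][1], i))
    return [results[i] for i in order]
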