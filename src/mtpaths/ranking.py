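"""Gene prioritization within reconstructed networks.

Genes are ranked by the number of selected paths that traverse them;
promiscuous hub genes are removed by comparison with rankings from a
background panel of unrelated (non-cancer) drugs; and cross-task
cell-type-specificity scores aggregate per-drug inverse ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import Path

__all__ = [
    "RankedGeneList",
    "SpecificityMatrices",
    "rank_nodes",
    "filter_background",
    "specificity_scores",
]


@dataclass
class RankedGeneList:
    """Ordered (gene, score) pairs, scores non-increasing, genes unique."""

    items: list[tuple[str, float]]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.items]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene in ranked list")
        scores = [s for _, s in self.items]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.items]

    def rank_of(self, gene: str) -> int | None:
        """1-based position of ``gene``, or None if absent."""
        for i, (g, _) in enumerate(self.items, start=1):
            if g == gene:
                return i
        return None

    def top(self, n: int) -> set[str]:
        return {g for g, _ in self.items[:n]}

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, s, i) for i, (g, s) in enumerate(self.items, start=1)],
            columns=["gene", "score", "rank"],
        )


def rank_nodes(
    solution_paths: Iterable[Path], include_targets: bool = True
) -> RankedGeneList:
    """Score every node by the number of selected paths through it.

    Sources, intermediates, TFs and targets all count (set
    ``include_targets=False`` to exclude the terminal target genes).  Sorted
    by descending score, lexicographic gene for ties.
    """
    counts: dict[str, int] = {}
    for p in solution_paths:
        nodes = p.nodes if include_targets else p.nodes[:-1]
        for n in nodes:
            counts[n] = counts.get(n, 0) + 1
    items = sorted(counts.items(), key=lambda gs: (-gs[1], gs[0]))
    return RankedGeneList([(g, float(s)) for g, s in items])


def filter_background(
    ranked: RankedGeneList,
    background_rankings: list[RankedGeneList],
    top_n: int = 100,
) -> RankedGeneList:
    """Drop genes that rank in the top ``top_n`` of any background list.

    The background lists come from running the same reconstruction on a
    panel of unrelated drugs; genes prominent there are promiscuous hubs
    rather than drug-specific signal.  Survivor order is preserved.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    hubs: set[str] = set()
    for bg in background_rankings:
        hubs |= bg.top(top_n)
    return RankedGeneList([(g, s) for g, s in ranked.items if g not in hubs])


@dataclass
class SpecificityMatrices:
    """Inverse-rank aggregation across drugs and cell types.

    ``m3[g, d, c]`` is 1/rank of gene g in the ranking for drug d in cell
    type c (0 when absent); ``m2`` (cell x gene) holds the per-cell sums
    s_{g,c} over drugs; ``f`` (cell x gene) holds s_{g,c} divided by the
    gene's mean s over cell types, so a ubiquitous gene scores ~1 everywhere
    and a cell-type-specific gene scores ≫1 in its cell type.
    """

    genes: list[str]
    drugs: list[str]
    cell_types: list[str]
    m3: np.ndarray  # gene x drug x cell
    m2: pd.DataFrame  # cell x gene
    f: pd.DataFrame  # cell x gene


def specificity_scores(
    rankings: Mapping[tuple[str, str], RankedGeneList],
) -> SpecificityMatrices:
    """Aggregate single-task (drug, cell type) rankings into specificity.

    ``rankings`` maps (drug, cell_type) to the per-network ranked gene list
    obtained in the single-task scenario.  Genes absent from a ranking
    contribute 0 for that entry; genes with zero total score get f = 0.
    """
    drugs = sorted({d for d, _ in rankings})
    cells = sorted({c for _, c in rankings})
    genes = sorted({g for rl in rankings.values() for g in rl.genes})
    gi = {g: i for i, g in enumerate(genes)}
    m3 = np.zeros((len(genes), len(drugs), len(cells)))
    for (d, c), rl in rankings.items():
        di, ci = drugs.index(d), cells.index(c)
        for pos, (g, _) in enumerate(rl.items, start=1):
            m3[gi[g], di, ci] = 1.0 / pos
    s = m3.sum(axis=1)  # gene x cell
    mean_s = s.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mean_s > 0, s / mean_s, 0.0)
    m2 = pd.DataFrame(s.T, index=cells, columns=genes)
    fdf = pd.DataFrame(f.T, index=cells, columns=genes)
    return SpecificityMatrices(
        genes=genes, drugs=drugs, cell_types=cells, m3=m3, m2=m2, f=fdf
    )
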