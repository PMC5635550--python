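"""Confidence-weighted interaction network and candidate-path enumeration.

The network mixes two edge classes: undirected protein--protein (PPI) edges
and directed protein--DNA (TF -> gene) regulatory edges, each carrying a
confidence probability in (0, 1].  A candidate path runs from a *source*
protein (a putative direct drug target) through zero or more signaling
intermediates to a transcription factor, and finally crosses one regulatory
edge into a differentially expressed target gene.  The weight of a path,
h(p), is the product of the probabilities of its edges, so longer or less
confident routes always weigh less.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "InteractionNetwork",
    "Path",
    "Condition",
    "PathEnumerationConfig",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "path_weight",
    "enumerate_candidate_paths",
]

EDGE_COLUMNS = ("node_a", "node_b", "probability", "edge_type")


class NetworkValidationError(ValueError):
    """Raised when an edge table or path violates the network invariants."""


@dataclass(frozen=True)
class Path:
    """A simple source->...->TF->target path.

    ``nodes`` is the ordered node sequence; ``weight`` is h(p), the product
    of the edge confidence probabilities along the path.  The penultimate
    node is the path's transcription factor.
    """

    nodes: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise NetworkValidationError("a path needs at least two nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError(f"path repeats a node: {self.nodes}")
        if not 0.0 < self.weight <= 1.0:
            raise NetworkValidationError(
                f"path weight {self.weight} outside (0, 1]"
            )

    @property
    def tf(self) -> str:
        """The transcription factor: the penultimate node."""
        return self.nodes[-2]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def source(self) -> str:
        return self.nodes[0]

    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def sort_key(self) -> tuple:
        # descending weight, then lexicographic node sequence
        return (-self.weight, self.nodes)


class InteractionNetwork:
    """Genes/proteins as nodes; probabilistic PPI and regulatory edges.

    PPI edges are stored under a sorted node pair and are traversable in
    both directions; regulatory edges are directed TF -> gene.  Probabilities
    lie strictly in (0, 1] and self-loops are rejected.
    """

    def __init__(
        self,
        ppi_edges: Mapping[tuple[str, str], float] | None = None,
        regulatory_edges: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        self.ppi_edges: dict[tuple[str, str], float] = {}
        self.regulatory_edges: dict[tuple[str, str], float] = {}
        self.nodes: set[str] = set()
        # adjacency: node -> {neighbor: prob} for traversal (PPI symmetric,
        # regulatory forward only)
        self._adj: dict[str, dict[str, float]] = {}
        self._reg_in: dict[str, dict[str, float]] = {}
        if ppi_edges:
            for (a, b), p in ppi_edges.items():
                self.add_ppi_edge(a, b, p)
        if regulatory_edges:
            for (tf, g), p in regulatory_edges.items():
                self.add_regulatory_edge(tf, g, p)

    @staticmethod
    def _check_prob(a: str, b: str, probability: float) -> None:
        if not 0.0 < probability <= 1.0:
            raise NetworkValidationError(
                f"edge {a}-{b}: probability {probability} outside (0, 1]"
            )

    def add_ppi_edge(self, a: str, b: str, probability: float) -> None:
        if a == b:
            raise NetworkValidationError(f"self-loop on {a} not allowed")
        self._check_prob(a, b, probability)
        key = (a, b) if a <= b else (b, a)
        old = self.ppi_edges.get(key)
        if old is None or probability > old:
            self.ppi_edges[key] = probability
            self.nodes.update(key)
            self._adj.setdefault(a, {})[b] = max(
                probability, self._adj.get(a, {}).get(b, 0.0)
            )
            self._adj.setdefault(b, {})[a] = max(
                probability, self._adj.get(b, {}).get(a, 0.0)
            )

    def add_regulatory_edge(self, tf: str, gene: str, probability: float) -> None:
        if tf == gene:
            raise NetworkValidationError(f"self-loop on {tf} not allowed")
        self._check_prob(tf, gene, probability)
        key = (tf, gene)
        old = self.regulatory_edges.get(key)
        if old is None or probability > old:
            self.regulatory_edges[key] = probability
            self.nodes.update(key)
            self._adj.setdefault(tf, {})
            self._adj.setdefault(gene, {})
            cur = self._adj[tf].get(gene, 0.0)
            self._adj[tf][gene] = max(probability, cur)
            self._reg_in.setdefault(gene, {})[tf] = probability

    # -- queries -----------------------------------------------------------

    def neighbors(self, node: str) -> dict[str, float]:
        """Traversable successors of ``node`` with edge probabilities."""
        return self._adj.get(node, {})

    def regulators_of(self, gene: str) -> dict[str, float]:
        """TFs with a regulatory edge into ``gene``."""
        return self._reg_in.get(gene, {})

    def step_probability(self, a: str, b: str) -> float | None:
        """Probability of traversing a->b, or None if no such step exists."""
        return self._adj.get(a, {}).get(b)

    def is_regulatory(self, a: str, b: str) -> bool:
        return (a, b) in self.regulatory_edges

    def tf_motif_targets(self) -> dict[str, set[str]]:
        """Map TF -> set of genes it has a regulatory edge into."""
        out: dict[str, set[str]] = {}
        for (tf, g) in self.regulatory_edges:
            out.setdefault(tf, set()).add(g)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (
            self.ppi_edges == other.ppi_edges
            and self.regulatory_edges == other.regulatory_edges
        )

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork({len(self.nodes)} nodes, "
            f"{len(self.ppi_edges)} ppi, {len(self.regulatory_edges)} regulatory)"
        )


@dataclass
class PathEnumerationConfig:
    """Bounds for candidate-path generation.

    max_path_edges: maximum number of edges in a path (default 5).
    paths_per_pair: best m paths kept per (source, target) pair (default 20).
    """

    max_path_edges: int = 5
    paths_per_pair: int = 20

    def __post_init__(self) -> None:
        if self.max_path_edges < 1 or self.paths_per_pair < 1:
            raise ValueError("path enumeration bounds must be >= 1")


@dataclass
class Condition:
    """One reconstruction task: a cell type treated with a drug.

    ``tf_targets`` maps each TF to all of its predicted targets T(tf);
    ``tf_de_targets`` to the subset differentially expressed in this
    condition, DE(c, tf).  ``candidate_paths`` holds, per DE target t, the
    candidate path set P_c^t ordered by descending weight.
    """

    condition_id: str
    sources: set[str]
    targets: set[str]
    tf_targets: dict[str, set[str]]
    tf_de_targets: dict[str, set[str]]
    candidate_paths: dict[str, tuple[Path, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        for tf, de in self.tf_de_targets.items():
            allowed = self.tf_targets.get(tf, set()) & self.targets
            if not de <= allowed:
                raise NetworkValidationError(
                    f"{self.condition_id}: DE targets of {tf} not a subset of "
                    "T(tf) ∩ T_c"
                )
        for t, paths in self.candidate_paths.items():
            for p in paths:
                if p.source not in self.sources or p.target != t:
                    raise NetworkValidationError(
                        f"{self.condition_id}: path {p.nodes} is not a "
                        f"source->{t} path"
                    )


# ---------------------------------------------------------------------------
# IO


def load_network(edge_table) -> InteractionNetwork:
    """Build a validated network from an edge table.

    ``edge_table`` is a path to a tab-separated file (header row, ``#``
    comments) or a DataFrame with columns node_a, node_b, probability,
    edge_type (``ppi`` or ``regulatory``).  Duplicate edges are collapsed
    keeping the maximum probability; self-loops are dropped with a warning.
    """
    if isinstance(edge_table, pd.DataFrame):
        df = edge_table
    else:
        df = pd.read_csv(
            edge_table,
            sep="\t",
            comment="#",
            dtype={0: str, 1: str},
            float_precision="round_trip",
        )
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkValidationError(f"edge table missing columns: {missing}")
    net = InteractionNetwork()
    for row in df.itertuples(index=True):
        a, b = str(row.node_a), str(row.node_b)
        p = float(row.probability)
        etype = row.edge_type
        if not 0.0 < p <= 1.0:
            raise NetworkValidationError(
                f"row {row.Index}: probability {p} outside (0, 1]"
            )
        if a == b:
            warnings.warn(
                f"row {row.Index}: dropping self-loop on {a}", stacklevel=2
            )
            continue
        if etype == "ppi":
            net.add_ppi_edge(a, b, p)
        elif etype == "regulatory":
            net.add_regulatory_edge(a, b, p)
        else:
            raise NetworkValidationError(
                f"row {row.Index}: unknown edge_type {etype!r}"
            )
    return net


def write_network(network: InteractionNetwork, path) -> None:
    """Write the network back to the 4-column tab-separated edge list."""
    rows = [
        (a, b, p, "ppi") for (a, b), p in sorted(network.ppi_edges.items())
    ] + [
        (tf, g, p, "regulatory")
        for (tf, g), p in sorted(network.regulatory_edges.items())
    ]
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    # repr round-trips float64 exactly; pandas' default CSV float path does not
    df["probability"] = df["probability"].map(repr)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Path weighting and enumeration


def path_weight(path, network: InteractionNetwork) -> float:
    """h(p): product of edge probabilities along ``path``.

    ``path`` may be a :class:`Path` or a bare node sequence.  Raises if any
    consecutive pair is not a traversable edge.
    """
    nodes = path.nodes if isinstance(path, Path) else tuple(path)
    w = 1.0
    for a, b in zip(nodes, nodes[1:]):
        p = network.step_probability(a, b)
        if p is None:
            raise NetworkValidationError(f"no edge {a} -> {b} in network")
        w *= p
    return w


def enumerate_candidate_paths(
    network: InteractionNetwork,
    sources: Iterable[str],
    targets: Iterable[str],
    cfg: PathEnumerationConfig | None = None,
) -> dict[str, tuple[Path, ...]]:
    """Enumerate the best candidate paths from sources into each target.

    For every (source, target) pair the search keeps the ``paths_per_pair``
    highest-weight simple paths with at most ``max_path_edges`` edges whose
    final edge is regulatory (so each path ends TF -> target).  The search is
    an exhaustive bounded-depth walk over simple paths — exact, and
    equivalent to a k-shortest-paths search under additive -log(probability)
    costs restricted to the length bound.  Output is deterministic: per
    target, paths sort by descending weight then lexicographic node sequence.
    Unreachable targets map to an empty tuple.
    """
    cfg = cfg or PathEnumerationConfig()
    src_sorted = sorted(set(sources))
    out: dict[str, tuple[Path, ...]] = {}
    for t in sorted(set(targets)):
        regulators = network.regulators_of(t)
        found: list[Path] = []
        for s in src_sorted:
            if s == t or not regulators:
                continue
            per_pair: list[Path] = []
            # walk simple paths s -> ... -> tf avoiding t, then cross the
            # regulatory edge tf -> t; `depth` counts edges walked so far,
            # so the finished path has depth + 1 edges
            stack: list[str] = [s]
            on_stack = {s, t}

            def dfs(node: str, weight: float, depth: int) -> None:
                rp = regulators.get(node)
                if rp is not None:
                    per_pair.append(Path(tuple(stack) + (t,), weight * rp))
                if depth + 1 >= cfg.max_path_edges:
                    return
                nbrs = network.neighbors(node)
                for nxt in sorted(nbrs):
                    if nxt in on_stack:
                        continue
                    stack.append(nxt)
                    on_stack.add(nxt)
                    dfs(nxt, weight * nbrs[nxt], depth + 1)
                    on_stack.discard(nxt)
                    stack.pop()

            dfs(s, 1.0, 0)
            per_pair.sort(key=Path.sort_key)
            found.extend(per_pair[: cfg.paths_per_pair])
        # drop duplicate node sequences (a path can tie via two sources only
        # if sequences differ, but be safe), then order deterministically
        uniq = {p.nodes: p for p in found}
        out[t] = tuple(sorted(uniq.values(), key=Path.sort_key))
    return out


def write_paths(solution_paths: Mapping[str, Iterable[Path]], path) -> None:
    """Write per-condition selected paths as a tab-separated table.

    Columns: condition_id, target, weight, path (nodes joined by '|').
    """
    rows = []
    for cid in sorted(solution_paths):
        for p in sorted(solution_paths[cid], key=Path.sort_key):
            rows.append((cid, p.target, f"{p.weight:.10g}", "|".join(p.nodes)))
    pd.DataFrame(
        rows, columns=["condition_id", "target", "weight", "path"]
    ).to_csv(path, sep="\t", index=False)
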