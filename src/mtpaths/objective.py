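"""The five-term multi-task objective over selected path sets.

A solution assigns each condition c a set of selected candidate paths S_c;
S is the union of all S_c (deduplicated by node sequence).  The objective
rewards per-condition target coverage (λ1), TF/DE consistency (λ2) and path
reliability (λ3), penalizes the total node count of the union (λ4), and
rewards node sharing between selected paths (λ5):

    λ1 Σ_c Σ_{t∈T_c} 1[|S_c ∩ P_c^t| > 0]
  + λ2 Σ_c Σ_{tf∈TF(S_c)} |DE(c,tf)| / |T(tf)|
  + λ3 Σ_c Σ_{p∈S_c} h(p)
  - λ4 N(S)
  + λ5 Σ_{{p_i,p_j}⊆S, i≠j} n(p_i,p_j)^α

where h(p) is the path weight, N(S) the number of distinct nodes in the
union, and n(p_i,p_j) the number of nodes two paths share.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .network import Condition, Path

__all__ = [
    "ObjectiveParams",
    "Solution",
    "coverage_term",
    "tf_consistency_term",
    "path_weight_term",
    "node_count_penalty",
    "shared_path_term",
    "objective_value",
    "objective_terms",
]


@dataclass(frozen=True)
class ObjectiveParams:
    """Weights λ1..λ5 and the sharing exponent α.

    Defaults balance the terms on the synthetic fixtures so that the node
    penalty can overrule redundant-but-consistent TF additions; all are
    configurable.
    """

    lambda1: float = 1.0
    lambda2: float = 0.5
    lambda3: float = 0.2
    lambda4: float = 0.25
    lambda5: float = 0.01
    alpha: float = 0.5
    cross_condition_pairs_only: bool = False

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")

    def single_task(self, drop_node_penalty: bool = False) -> "ObjectiveParams":
        """Params with the multi-task coupling removed (λ5=0; optionally λ4)."""
        return ObjectiveParams(
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            lambda3=self.lambda3,
            lambda4=0.0 if drop_node_penalty else self.lambda4,
            lambda5=0.0,
            alpha=self.alpha,
            cross_condition_pairs_only=self.cross_condition_pairs_only,
        )


class Solution:
    """Per-condition selected path sets S_c with union S.

    The union deduplicates identical node sequences selected by several
    conditions, so a path shared across tasks counts once in the node-count
    penalty and the shared-path reward.
    """

    def __init__(self, per_condition: Mapping[str, Iterable[Path]] | None = None):
        self.per_condition: dict[str, frozenset[Path]] = {}
        if per_condition:
            for cid, paths in per_condition.items():
                self.per_condition[cid] = frozenset(paths)

    def paths_for(self, condition_id: str) -> frozenset[Path]:
        return self.per_condition.get(condition_id, frozenset())

    def union_paths(self) -> list[Path]:
        """Distinct selected paths (by node sequence), deterministic order."""
        uniq = {p.nodes: p for paths in self.per_condition.values() for p in paths}
        return [uniq[k] for k in sorted(uniq)]

    def union_nodes(self) -> set[str]:
        return {n for p in self.union_paths() for n in p.nodes}

    def is_empty(self) -> bool:
        return all(not s for s in self.per_condition.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Solution):
            return NotImplemented
        a = {c: frozenset(p.nodes for p in s) for c, s in self.per_condition.items() if s}
        b = {c: frozenset(p.nodes for p in s) for c, s in other.per_condition.items() if s}
        return a == b

    def __repr__(self) -> str:
        n = sum(len(s) for s in self.per_condition.values())
        return f"Solution({len(self.per_condition)} conditions, {n} paths)"


# ---------------------------------------------------------------------------
# Terms


def coverage_term(solution: Solution, conditions: list[Condition]) -> float:
    """Count of (condition, target) pairs covered by >= 1 selected path."""
    covered = 0
    for cond in conditions:
        selected = solution.paths_for(cond.condition_id)
        if not selected:
            continue
        hit = {p.target for p in selected}
        covered += sum(1 for t in cond.targets if t in hit)
    return float(covered)


def tf_consistency_term(solution: Solution, conditions: list[Condition]) -> float:
    """Sum over conditions and used TFs of |DE(c,tf)| / |T(tf)|."""
    total = 0.0
    for cond in conditions:
        tfs = sorted({p.tf for p in solution.paths_for(cond.condition_id)})
        for tf in tfs:
            all_targets = cond.tf_targets.get(tf, set())
            if not all_targets:
                raise ValueError(
                    f"TF {tf} selected in {cond.condition_id} has no predicted "
                    "targets; it should never be a candidate"
                )
            total += len(cond.tf_de_targets.get(tf, set())) / len(all_targets)
    return total


def path_weight_term(solution: Solution) -> float:
    """Sum of h(p) over selected paths of every condition."""
    total = 0.0
    for cid in sorted(solution.per_condition):
        for p in sorted(solution.per_condition[cid], key=Path.sort_key):
            total += p.weight
    return total


def node_count_penalty(solution: Solution) -> float:
    """N(S): number of distinct nodes in the union of selected paths."""
    return float(len(solution.union_nodes()))


def shared_path_term(
    solution: Solution,
    alpha: float,
    cross_condition_only: bool = False,
) -> float:
    """Sum over unordered pairs of distinct union paths of n(p_i, p_j)^α.

    With ``cross_condition_only`` a pair contributes only when the two paths
    are selected by at least two different conditions.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    union = solution.union_paths()
    membership: dict[tuple[str, ...], set[str]] = {}
    if cross_condition_only:
        for cid, paths in solution.per_condition.items():
            for p in paths:
                membership.setdefault(p.nodes, set()).add(cid)
    total = 0.0
    for p, q in combinations(union, 2):
        if cross_condition_only:
            conds = membership[p.nodes] | membership[q.nodes]
            if len(conds) < 2:
                continue
        n = len(p.node_set() & q.node_set())
        if n:
            total += n ** alpha
    return total


def objective_terms(
    solution: Solution,
    conditions: list[Condition],
    params: ObjectiveParams,
) -> dict[str, float]:
    """All five raw term values plus the weighted total."""
    cov = coverage_term(solution, conditions)
    cons = tf_consistency_term(solution, conditions)
    pw = path_weight_term(solution)
    nodes = node_count_penalty(solution)
    shared = shared_path_term(
        solution, params.alpha, params.cross_condition_pairs_only
    )
    total = (
        params.lambda1 * cov
        + params.lambda2 * cons
        + params.lambda3 * pw
        - params.lambda4 * nodes
        + params.lambda5 * shared
    )
    return {
        "coverage": cov,
        "tf_consistency": cons,
        "path_weight": pw,
        "node_count": nodes,
        "shared_paths": shared,
        "objective": total,
    }


def objective_value(
    solution: Solution,
    conditions: list[Condition],
    params: ObjectiveParams,
) -> float:
    """λ1·coverage + λ2·consistency + λ3·weights − λ4·N(S) + λ5·sharing."""
    return objective_terms(solution, conditions, params)["objective"]
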