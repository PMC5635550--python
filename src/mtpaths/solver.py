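"""Greedy TF add/remove optimization of the multi-task objective.

Targets are covered through transcription factors: every candidate path ends
with a regulatory TF -> target edge, so selecting paths reduces to selecting
a TF subset per condition plus, for each selected TF, one path per reachable
target.  The solver performs steepest-ascent local search: in each iteration
it evaluates, over all (condition, TF) pairs, the best single TF addition
(with the TF's best paths re-determined against the current solution) and
the best single TF removal, applies the highest-gain move, and stops when no
move improves the objective by more than ``min_gain``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Condition, Path
from .objective import ObjectiveParams, Solution

__all__ = [
    "SolverConfig",
    "MoveRecord",
    "SolverTrace",
    "candidate_tfs",
    "best_paths_for_tf",
    "greedy_optimize",
    "single_task_optimize",
]

# strict-inequality guard when comparing candidate gains, so that float noise
# cannot override the deterministic (weight, lexicographic) tie-break
_TIE_EPS = 1e-12


@dataclass
class SolverConfig:
    max_iterations: int = 200
    min_gain: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")


@dataclass(frozen=True)
class MoveRecord:
    index: int
    move: str  # "add" or "remove"
    condition_id: str
    tf: str
    n_paths: int
    gain: float
    objective_before: float
    objective_after: float


@dataclass
class SolverTrace:
    records: list[MoveRecord] = field(default_factory=list)
    converged: bool = True
    hit_max_iterations: bool = False

    @property
    def objective_sequence(self) -> list[float]:
        return [r.objective_after for r in self.records]


def candidate_tfs(condition: Condition) -> set[str]:
    """All TFs appearing as the penultimate node of any candidate path."""
    return {
        p.tf for paths in condition.candidate_paths.values() for p in paths
    }


# ---------------------------------------------------------------------------
# Incremental solution state


class _State:
    """Mutable solution with O(|union|) add/remove gain computation.

    Maintains the five raw objective terms incrementally.  The shared-path
    term is maintained pair-wise against the deduplicated union, matching
    :func:`mtpaths.objective.shared_path_term` with default pair semantics;
    for ``cross_condition_pairs_only`` the solver falls back to full
    recomputation of that term.
    """

    def __init__(self, conditions: list[Condition], params: ObjectiveParams):
        self.conditions = {c.condition_id: c for c in conditions}
        self.params = params
        self.sel: dict[str, dict[tuple[str, ...], Path]] = {
            c.condition_id: {} for c in conditions
        }
        self.cover: dict[str, dict[str, int]] = {
            c.condition_id: {} for c in conditions
        }
        self.tf_count: dict[str, dict[str, int]] = {
            c.condition_id: {} for c in conditions
        }
        self.union_count: dict[tuple[str, ...], int] = {}
        self.union_paths: dict[tuple[str, ...], Path] = {}
        self.union_sets: dict[tuple[str, ...], frozenset[str]] = {}
        self.node_refs: dict[str, int] = {}
        # raw terms
        self.cov = 0.0
        self.cons = 0.0
        self.pw = 0.0
        self.nnodes = 0.0
        self.shared = 0.0

    def objective(self) -> float:
        p = self.params
        return (
            p.lambda1 * self.cov
            + p.lambda2 * self.cons
            + p.lambda3 * self.pw
            - p.lambda4 * self.nnodes
            + p.lambda5 * self.shared
        )

    def _shared_delta_add(self, path: Path) -> float:
        """Sharing contribution of adding ``path`` as a new union member."""
        ps = path.node_set()
        delta = 0.0
        for qs in self.union_sets.values():
            n = len(ps & qs)
            if n:
                delta += n ** self.params.alpha
        return delta

    def add_path(self, cid: str, path: Path) -> float:
        """Apply the addition and return the objective gain."""
        p = self.params
        cond = self.conditions[cid]
        assert path.nodes not in self.sel[cid]
        gain = 0.0
        # coverage
        c = self.cover[cid].get(path.target, 0)
        if c == 0 and path.target in cond.targets:
            self.cov += 1.0
            gain += p.lambda1
        self.cover[cid][path.target] = c + 1
        # TF consistency
        tc = self.tf_count[cid].get(path.tf, 0)
        if tc == 0:
            frac = len(cond.tf_de_targets.get(path.tf, set())) / len(
                cond.tf_targets[path.tf]
            )
            self.cons += frac
            gain += p.lambda2 * frac
        self.tf_count[cid][path.tf] = tc + 1
        # path weight (per-condition sum)
        self.pw += path.weight
        gain += p.lambda3 * path.weight
        # union terms
        uc = self.union_count.get(path.nodes, 0)
        if uc == 0:
            if p.lambda5 and not p.cross_condition_pairs_only:
                ds = self._shared_delta_add(path)
                self.shared += ds
                gain += p.lambda5 * ds
            self.union_paths[path.nodes] = path
            self.union_sets[path.nodes] = path.node_set()
            new_nodes = 0
            for n in path.nodes:
                r = self.node_refs.get(n, 0)
                if r == 0:
                    new_nodes += 1
                self.node_refs[n] = r + 1
            self.nnodes += new_nodes
            gain -= p.lambda4 * new_nodes
        self.union_count[path.nodes] = uc + 1
        self.sel[cid][path.nodes] = path
        if p.cross_condition_pairs_only and p.lambda5:
            gain += self._recompute_cross_shared()
        return gain

    def remove_path(self, cid: str, path: Path) -> float:
        """Apply the removal and return the objective gain (usually < 0)."""
        p = self.params
        cond = self.conditions[cid]
        assert path.nodes in self.sel[cid]
        gain = 0.0
        del self.sel[cid][path.nodes]
        c = self.cover[cid][path.target] - 1
        if c == 0:
            del self.cover[cid][path.target]
            if path.target in cond.targets:
                self.cov -= 1.0
                gain -= p.lambda1
        else:
            self.cover[cid][path.target] = c
        tc = self.tf_count[cid][path.tf] - 1
        if tc == 0:
            del self.tf_count[cid][path.tf]
            frac = len(cond.tf_de_targets.get(path.tf, set())) / len(
                cond.tf_targets[path.tf]
            )
            self.cons -= frac
            gain -= p.lambda2 * frac
        else:
            self.tf_count[cid][path.tf] = tc
        self.pw -= path.weight
        gain -= p.lambda3 * path.weight
        uc = self.union_count[path.nodes] - 1
        if uc == 0:
            del self.union_count[path.nodes]
            del self.union_paths[path.nodes]
            del self.union_sets[path.nodes]
            if p.lambda5 and not p.cross_condition_pairs_only:
                ds = self._shared_delta_add(path)
                self.shared -= ds
                gain -= p.lambda5 * ds
            gone = 0
            for n in path.nodes:
                r = self.node_refs[n] - 1
                if r == 0:
                    del self.node_refs[n]
                    gone += 1
                else:
                    self.node_refs[n] = r
            self.nnodes -= gone
            gain += p.lambda4 * gone
        else:
            self.union_count[path.nodes] = uc
        if p.cross_condition_pairs_only and p.lambda5:
            gain += self._recompute_cross_shared()
        return gain

    def _recompute_cross_shared(self) -> float:
        """Recompute the cross-condition-only sharing term from scratch.

        Returns λ5 times the change, and updates the stored raw term.
        """
        from .objective import shared_path_term

        new = shared_path_term(self.to_solution(), self.params.alpha, True)
        delta = self.params.lambda5 * (new - self.shared)
        self.shared = new
        return delta

    def to_solution(self) -> Solution:
        return Solution(
            {cid: list(paths.values()) for cid, paths in self.sel.items()}
        )


# ---------------------------------------------------------------------------
# Moves


def _best_paths_for_tf_state(
    tf: str, cond: Condition, state: _State
) -> tuple[list[Path], float]:
    """Best path per target through ``tf`` with its total marginal gain.

    Paths are chosen greedily per target (targets in lexicographic order)
    against the current solution plus the paths already chosen in this call;
    a path is kept when it newly covers its target or has positive marginal
    gain.  Ties break by higher weight, then lexicographic node sequence
    (the candidate order).  The state is restored before returning.
    """
    cid = cond.condition_id
    chosen: list[Path] = []
    total = 0.0
    for t in sorted(cond.candidate_paths):
        best_path = None
        best_gain = 0.0
        for p in cond.candidate_paths[t]:
            if p.tf != tf or p.nodes in state.sel[cid]:
                continue
            g = state.add_path(cid, p)
            state.remove_path(cid, p)
            if best_path is None or g > best_gain + _TIE_EPS:
                best_path, best_gain = p, g
        if best_path is None:
            continue
        newly_covers = (
            state.cover[cid].get(t, 0) == 0 and t in cond.targets
        )
        if newly_covers or best_gain > 0:
            total += state.add_path(cid, best_path)
            chosen.append(best_path)
    for p in reversed(chosen):
        state.remove_path(cid, p)
    return chosen, total


def best_paths_for_tf(
    tf: str,
    condition: Condition,
    current: Solution,
    params: ObjectiveParams,
    all_conditions: list[Condition] | None = None,
) -> list[Path]:
    """Public wrapper: best paths through ``tf`` given an existing solution.

    ``all_conditions`` defaults to ``[condition]``; pass the full task list
    when the current solution spans several conditions (the union terms see
    all of them).
    """
    conds = all_conditions if all_conditions is not None else [condition]
    if condition.condition_id not in {c.condition_id for c in conds}:
        conds = list(conds) + [condition]
    state = _State(conds, params)
    for cid, paths in current.per_condition.items():
        if cid not in state.sel:
            continue
        for p in sorted(paths, key=Path.sort_key):
            state.add_path(cid, p)
    chosen, _ = _best_paths_for_tf_state(tf, condition, state)
    return chosen


def _tf_removal(state: _State, cid: str, tf: str) -> tuple[list[Path], float]:
    """Evaluate removing every selected path through ``tf``; restore state."""
    paths = [
        p for p in state.sel[cid].values() if p.tf == tf
    ]
    paths.sort(key=Path.sort_key)
    gain = 0.0
    for p in paths:
        gain += state.remove_path(cid, p)
    for p in reversed(paths):
        state.add_path(cid, p)
    return paths, gain


def greedy_optimize(
    conditions: list[Condition],
    params: ObjectiveParams,
    cfg: SolverConfig | None = None,
) -> tuple[Solution, SolverTrace]:
    """Steepest-ascent TF selection across all conditions.

    Returns a locally optimal solution (no single TF add or remove gains
    more than ``cfg.min_gain``) and the move trace.  Fully deterministic:
    moves are scanned in (condition_id, TF) order and ties keep the first
    candidate encountered.
    """
    cfg = cfg or SolverConfig()
    state = _State(conditions, params)
    trace = SolverTrace()
    cond_by_id = {c.condition_id: c for c in conditions}
    tf_universe = {
        cid: sorted(candidate_tfs(c)) for cid, c in cond_by_id.items()
    }
    for it in range(cfg.max_iterations):
        best = None  # (gain, cid, tf, move, paths)
        for cid in sorted(cond_by_id):
            cond = cond_by_id[cid]
            for tf in tf_universe[cid]:
                if state.tf_count[cid].get(tf, 0) > 0:
                    paths, gain = _tf_removal(state, cid, tf)
                    move = "remove"
                else:
                    paths, gain = _best_paths_for_tf_state(tf, cond, state)
                    move = "add"
                if not paths:
                    continue
                if best is None or gain > best[0] + _TIE_EPS:
                    best = (gain, cid, tf, move, paths)
        if best is None or best[0] <= cfg.min_gain:
            break
        gain, cid, tf, move, paths = best
        before = state.objective()
        if move == "add":
            for p in paths:
                state.add_path(cid, p)
        else:
            for p in paths:
                state.remove_path(cid, p)
        trace.records.append(
            MoveRecord(
                index=it,
                move=move,
                condition_id=cid,
                tf=tf,
                n_paths=len(paths),
                gain=gain,
                objective_before=before,
                objective_after=state.objective(),
            )
        )
    else:
        trace.converged = False
        trace.hit_max_iterations = True
    return state.to_solution(), trace


def single_task_optimize(
    condition: Condition,
    params: ObjectiveParams,
    cfg: SolverConfig | None = None,
    drop_node_penalty: bool = False,
) -> Solution:
    """Optimize one condition with the cross-task coupling removed.

    The shared-path reward (λ5) is zeroed; the node-count penalty is kept as
    a per-task sparsity penalty unless ``drop_node_penalty`` is set.
    """
    solution, _ = greedy_optimize(
        [condition], params.single_task(drop_node_penalty), cfg
    )
    return solution
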