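"""Independent reference implementations used only as test oracles.

Everything here is written as plain loops (or delegated to networkx), with
no reuse of the package's objective/solver/enumeration code paths, so
agreement between the two routes is informative.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def eq2_objective(
    per_condition: dict[str, set],
    conditions: list,
    l1: float,
    l2: float,
    l3: float,
    l4: float,
    l5: float,
    alpha: float,
) -> float:
    """Direct evaluation of the five-term objective from its definition."""
    total = 0.0
    # term 1: covered (condition, target) pairs
    for cond in conditions:
        sel = per_condition.get(cond.condition_id, set())
        for t in cond.targets:
            cand = set(cond.candidate_paths.get(t, ()))
            if any(p in cand and p.nodes[-1] == t for p in sel):
                total += l1
    # term 2: TF consistency
    for cond in conditions:
        sel = per_condition.get(cond.condition_id, set())
        tfs = set()
        for p in sel:
            tfs.add(p.nodes[-2])
        for tf in sorted(tfs):
            total += l2 * (
                len(cond.tf_de_targets.get(tf, set()))
                / len(cond.tf_targets[tf])
            )
    # term 3: path weights per condition
    for cond in conditions:
        for p in per_condition.get(cond.condition_id, set()):
            total += l3 * p.weight
    # union of distinct node sequences
    union = {}
    for sel in per_condition.values():
        for p in sel:
            union[p.nodes] = p
    # term 4: node count of the union
    nodes = set()
    for seq in union:
        nodes.update(seq)
    total -= l4 * len(nodes)
    # term 5: pairwise sharing
    seqs = sorted(union)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            n = len(set(seqs[i]) & set(seqs[j]))
            if n > 0:
                total += l5 * n ** alpha
    return total


def exhaustive_tf_optimum(conditions: list, params) -> float:
    """Best objective over all per-condition TF subsets (tiny instances).

    For a selected TF, the filled-in paths are, per target, the highest
    weight candidate through that TF (lexicographic node tie-break).
    Returns the maximum of the evaluated objectives and the empty solution.
    """
    per_cond_tfs = []
    for cond in conditions:
        tfs = sorted(
            {p.nodes[-2] for ps in cond.candidate_paths.values() for p in ps}
        )
        per_cond_tfs.append(tfs)
    best = 0.0
    subset_lists = [
        list(
            itertools.chain.from_iterable(
                itertools.combinations(tfs, r) for r in range(len(tfs) + 1)
            )
        )
        for tfs in per_cond_tfs
    ]
    for combo in itertools.product(*subset_lists):
        sel_map = {}
        for cond, tf_subset in zip(conditions, combo):
            sel = set()
            for t in sorted(cond.candidate_paths):
                for tf in tf_subset:
                    cands = [
                        p for p in cond.candidate_paths[t] if p.nodes[-2] == tf
                    ]
                    if cands:
                        sel.add(
                            max(cands, key=lambda p: (p.weight, p.nodes))
                        )
            sel_map[cond.condition_id] = sel
        val = eq2_objective(
            sel_map,
            conditions,
            params.lambda1,
            params.lambda2,
            params.lambda3,
            params.lambda4,
            params.lambda5,
            params.alpha,
        )
        best = max(best, val)
    return best


def nx_bounded_paths(edge_df, sources, targets, max_edges):
    """All bounded simple source->TF->target paths via networkx.

    Returns {target: {(node sequence): weight}} using a DiGraph built
    directly from the edge table (PPI edges in both directions).
    """
    g = nx.DiGraph()
    reg = {}
    for row in edge_df.itertuples():
        a, b, p = row.node_a, row.node_b, float(row.probability)
        if a == b:
            continue
        if row.edge_type == "ppi":
            for u, v in ((a, b), (b, a)):
                if not g.has_edge(u, v) or g[u][v]["p"] < p:
                    g.add_edge(u, v, p=p)
        else:
            if not g.has_edge(a, b) or g[a][b]["p"] < p:
                g.add_edge(a, b, p=p)
            reg[(a, b)] = max(p, reg.get((a, b), 0.0))
    out = {}
    for t in targets:
        found = {}
        for s in sources:
            if s not in g or t not in g:
                continue
            for nodes in nx.all_simple_paths(g, s, t, cutoff=max_edges):
                if (nodes[-2], nodes[-1]) not in reg:
                    continue
                w = math.prod(
                    g[u][v]["p"] for u, v in zip(nodes, nodes[1:])
                )
                # the final hop must use the regulatory probability
                w = w / g[nodes[-2]][nodes[-1]]["p"] * reg[(nodes[-2], nodes[-1])]
                found[tuple(nodes)] = w
        out[t] = found
    return out


def dcg_oracle(flags: list[int], depth: int) -> float:
    """Hand-rolled DCG with binary relevance flags, 1-based log2 discount."""
    return sum(
        rel / math.log2(i + 1)
        for i, rel in enumerate(flags[:depth], start=1)
    )
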