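"""Self-contained synthetic instances: network, signatures, gene sets, truth.

The generator emulates the statistical structure the multi-task model
assumes: each task (cell type) responds to a drug through planted
source -> intermediate -> TF -> target chains, a controllable fraction of
which is common to all tasks, while each task also has access to a
task-specific *decoy* route that explains most of the same targets with a
slightly higher path weight.  One planted target per shared pathway group is
differentially expressed only in that group's "anchor" task, so the shared
route explains more of the response there.  A single-task solver, seeing one
cell type at a time, prefers the heavier decoy route; the multi-task solver
can amortize the shared route's node cost across tasks and recover the
common pathway.  Knock-down signatures for the planted sources are the drug
signature plus noise (decoy knock-downs are independent noise), and gene-set
collections are enriched for planted genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    Condition,
    InteractionNetwork,
    Path,
    PathEnumerationConfig,
    enumerate_candidate_paths,
)
from .objective import Solution
from .signatures import SignatureMatrix, select_de_genes

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "SynthInstance",
    "generate_instance",
    "recovery_report",
    "random_small_instance",
]


@dataclass
class SynthConfig:
    """Controls for the synthetic instance generator.

    ``shared_fraction`` is the fraction of each task's planted pathways that
    is common to all tasks; ``noise_sd`` the z-score noise level;
    ``edge_prob_range`` the confidence range of background edges (planted
    chains use ``planted_edge_prob``, decoy routes the slightly higher
    ``decoy_edge_prob``).
    """

    n_genes: int = 200
    n_tfs: int = 16
    n_sources: int = 3
    n_tasks: int = 3
    n_drugs: int = 1
    ppi_density: float = 0.02
    shared_fraction: float = 0.6
    noise_sd: float = 0.1
    edge_prob_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0
    n_pathways_per_task: int = 10
    planted_edge_prob: float = 0.9
    decoy_edge_prob: float = 0.95
    de_z: float = 3.0
    z_threshold: float = 2.0
    n_kd_decoys: int = 8
    path_config: PathEnumerationConfig = field(
        default_factory=PathEnumerationConfig
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.n_tasks < 1 or self.n_drugs < 1:
            raise ValueError("need at least one task and one drug")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.edge_prob_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("edge_prob_range must be within (0, 1]")
        if self.n_sources < 3:
            raise ValueError(
                "n_sources must be >= 3 (shared, task and decoy source)"
            )


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, per cell type.

    ``paths_by_cell`` lists every planted chain structurally available to a
    task (shared chains plus its task-specific chains);
    ``active_paths_by_cell`` restricts to chains whose target is
    differentially expressed in that task, which is what a solver can
    recover.  Recovery denominators use the active sets.
    """

    shared_paths: list[tuple[str, ...]]
    shared_nodes: set[str]
    # per cell type
    shared_nodes_by_cell: dict[str, set[str]]
    paths_by_cell: dict[str, list[tuple[str, ...]]]
    active_paths_by_cell: dict[str, list[tuple[str, ...]]]
    decoy_paths_by_cell: dict[str, list[tuple[str, ...]]]
    nodes_by_cell: dict[str, set[str]]
    sources_by_cell: dict[str, set[str]]
    tfs_by_cell: dict[str, set[str]]
    targets_by_cell: dict[str, set[str]]
    anchors: dict[int, str]


@dataclass
class SynthInstance:
    config: SynthConfig
    network: InteractionNetwork
    conditions: list[Condition]
    signatures: SignatureMatrix
    metadata: pd.DataFrame
    gene_sets: dict[str, set[str]]
    planted: PlantedTruth
    cells: list[str]
    drugs: list[str]

    def conditions_for_drug(self, drug: str) -> list[Condition]:
        prefix = f"{drug}|"
        return [c for c in self.conditions if c.condition_id.startswith(prefix)]


def _grouped(items: list, size: int) -> list[list]:
    """Split into groups of ``size``; avoid a trailing singleton group."""
    groups = [items[i : i + size] for i in range(0, len(items), size)]
    if len(groups) >= 2 and len(groups[-1]) == 1:
        groups[-1] = [groups[-2][-1]] + groups[-1]
        groups[-2] = groups[-2][:-1]
    return groups


def generate_instance(cfg: SynthConfig | None = None) -> SynthInstance:
    """Generate a fully reproducible synthetic instance from ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    cells = [f"cell{c}" for c in range(cfg.n_tasks)]
    drugs = [f"drug{d}" for d in range(cfg.n_drugs)]

    n_shared = round(cfg.shared_fraction * cfg.n_pathways_per_task)
    n_specific = cfg.n_pathways_per_task - n_shared

    # ---- planted layout --------------------------------------------------
    shared_groups = _grouped(list(range(n_shared)), 3)
    specific_groups = _grouped(list(range(n_specific)), 2)

    net = InteractionNetwork()
    p_pl, p_dc = cfg.planted_edge_prob, cfg.decoy_edge_prob
    truth = PlantedTruth(
        shared_paths=[],
        shared_nodes=set(),
        shared_nodes_by_cell={c: set() for c in cells},
        paths_by_cell={c: [] for c in cells},
        active_paths_by_cell={c: [] for c in cells},
        decoy_paths_by_cell={c: [] for c in cells},
        nodes_by_cell={c: set() for c in cells},
        sources_by_cell={c: set() for c in cells},
        tfs_by_cell={c: set() for c in cells},
        targets_by_cell={c: set() for c in cells},
        anchors={},
    )

    s_shared = "S0"
    src_task = {c: f"SRC_{c}" for c in cells}
    src_decoy = {c: f"DSRC_{c}" for c in cells}
    # sources beyond the three structural roles are auxiliary drug targets:
    # they get a correlated knock-down profile but no planted chain
    src_extra = {
        c: [f"SRCE_{c}_{i}" for i in range(cfg.n_sources - 3)] for c in cells
    }
    for c in cells:
        truth.sources_by_cell[c] = (
            {s_shared, src_task[c], src_decoy[c]} | set(src_extra[c])
        )

    motif_targets: dict[str, set[str]] = {}
    pad_pool = [f"PAD{i:02d}" for i in range(40)]
    pad_iter = iter(pad_pool)
    used_tfs: list[str] = []

    def new_tf(name: str, planted: list[str], n_pads: int) -> None:
        used_tfs.append(name)
        pads = [next(pad_iter) for _ in range(n_pads)]
        motif_targets[name] = set(planted) | set(pads)
        for t in planted:
            net.add_regulatory_edge(name, t, p_pl if not name.startswith("DTF") else p_dc)
        for t in pads:
            net.add_regulatory_edge(name, t, p_pl)

    # DE structure: de_in[cell] = set of planted DE targets for that cell
    de_in: dict[str, set[str]] = {c: set() for c in cells}

    for g, members in enumerate(shared_groups):
        k = len(members)
        anchor = cells[int(rng.integers(cfg.n_tasks))]
        truth.anchors[g] = anchor
        u, f = f"MID{g}", f"TFS{g}"
        targets = [f"T{g}_{j}" for j in range(k)]
        net.add_ppi_edge(s_shared, u, p_pl)
        net.add_ppi_edge(u, f, p_pl)
        new_tf(f, targets, k)
        # last target of the group is DE only in the anchor task
        common_t, anchor_only = targets[:-1], targets[-1]
        for c in cells:
            de_in[c].update(common_t)
            avail = list(common_t) + ([anchor_only] if c == anchor else [])
            for t in targets:
                truth.paths_by_cell[c].append((s_shared, u, f, t))
            for t in avail:
                truth.active_paths_by_cell[c].append((s_shared, u, f, t))
                truth.nodes_by_cell[c].update((s_shared, u, f, t))
            truth.shared_nodes_by_cell[c].update([s_shared, u, f, *avail])
        de_in[anchor].add(anchor_only)
        for t in targets:
            truth.shared_paths.append((s_shared, u, f, t))
        truth.shared_nodes.update([s_shared, u, f, *targets])
        for c in cells:
            truth.tfs_by_cell[c].add(f)
        # decoy route per non-anchor task: covers the common targets only,
        # with heavier edges but task-private intermediate/TF/source
        if k >= 2:
            for c in cells:
                if c == anchor:
                    continue
                du, df = f"DMID{g}_{c}", f"DTF{g}_{c}"
                net.add_ppi_edge(src_decoy[c], du, p_dc)
                net.add_ppi_edge(du, df, p_dc)
                used_tfs.append(df)
                pads = [next(pad_iter) for _ in range(len(common_t))]
                motif_targets[df] = set(common_t) | set(pads)
                for t in common_t:
                    net.add_regulatory_edge(df, t, p_dc)
                for t in pads:
                    net.add_regulatory_edge(df, t, p_dc)
                for t in common_t:
                    truth.decoy_paths_by_cell[c].append(
                        (src_decoy[c], du, df, t)
                    )

    for c in cells:
        for g, members in enumerate(specific_groups):
            if not members:
                continue
            k = len(members)
            u, f = f"MIDX{g}_{c}", f"TFX{g}_{c}"
            targets = [f"TX{g}_{c}_{j}" for j in range(k)]
            net.add_ppi_edge(src_task[c], u, p_pl)
            net.add_ppi_edge(u, f, p_pl)
            new_tf(f, targets, k)
            de_in[c].update(targets)
            for t in targets:
                truth.paths_by_cell[c].append((src_task[c], u, f, t))
                truth.active_paths_by_cell[c].append((src_task[c], u, f, t))
                truth.nodes_by_cell[c].update((src_task[c], u, f, t))
            truth.tfs_by_cell[c].add(f)
        truth.nodes_by_cell[c] |= truth.shared_nodes_by_cell[c]

    # ---- background ------------------------------------------------------
    n_bg_tfs = cfg.n_tfs - len(used_tfs)
    if n_bg_tfs < 0:
        raise ValueError(
            f"infeasible config: planted structure needs {len(used_tfs)} TFs "
            f"but n_tfs={cfg.n_tfs}"
        )
    aux_sources = sorted({s for c in cells for s in src_extra[c]})
    roster = (
        set(net.nodes)
        | {s_shared}
        | set(src_task.values())
        | set(src_decoy.values())
        | set(aux_sources)
    )
    filler_needed = max(0, cfg.n_genes - len(roster) - n_bg_tfs)
    fillers = [f"F{i:03d}" for i in range(filler_needed)]
    bg_tfs = [f"TFB{i}" for i in range(n_bg_tfs)]
    lo, hi = cfg.edge_prob_range
    for tf in bg_tfs:
        n_t = int(rng.integers(3, 7))
        picks = rng.choice(len(fillers), size=min(n_t, len(fillers)), replace=False)
        motif_targets[tf] = {fillers[i] for i in picks}
        for t in sorted(motif_targets[tf]):
            net.add_regulatory_edge(tf, t, float(rng.uniform(lo, hi)))
    protein_layer = sorted(
        set(fillers)
        | set(bg_tfs)
        | {s_shared}
        | set(src_task.values())
        | set(src_decoy.values())
        | {n for n in net.nodes if n.startswith(("MID", "TFS", "DMID", "DTF", "TFX"))}
    )
    for a, b in itertools.combinations(protein_layer, 2):
        if rng.random() < cfg.ppi_density:
            net.add_ppi_edge(a, b, float(rng.uniform(lo, hi)))
    all_genes = sorted(roster | set(net.nodes) | set(fillers))
    if len(all_genes) > cfg.n_genes:
        raise ValueError(
            f"infeasible config: {len(all_genes)} genes needed but "
            f"n_genes={cfg.n_genes}"
        )
    extra = [f"X{i:03d}" for i in range(cfg.n_genes - len(all_genes))]
    all_genes = sorted(all_genes + extra)

    # ---- signatures ------------------------------------------------------
    gene_index = pd.Index(all_genes, name="gene")
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, str]] = []
    drug_sig: dict[tuple[str, str], np.ndarray] = {}
    for d in drugs:
        for c in cells:
            z = rng.normal(0.0, cfg.noise_sd, size=len(all_genes))
            for t in sorted(de_in[c]):
                sign = 1.0 if rng.random() < 0.5 else -1.0
                z[gene_index.get_loc(t)] = sign * (
                    cfg.de_z + rng.normal(0.0, cfg.noise_sd)
                )
            eid = f"DRUG_{d}_{c}"
            columns[eid] = z
            meta_rows.append((eid, d, "drug", c))
            drug_sig[(d, c)] = z
    for c in cells:
        base = drug_sig[(drugs[0], c)]
        for src in sorted(truth.sources_by_cell[c]):
            eid = f"KD_{src}_{c}"
            columns[eid] = base + rng.normal(0.0, cfg.noise_sd, len(all_genes))
            meta_rows.append((eid, src, "knockdown", c))
        decoy_pool = [g for g in fillers if g not in de_in[c]]
        picks = rng.choice(
            len(decoy_pool), size=min(cfg.n_kd_decoys, len(decoy_pool)),
            replace=False,
        )
        for i in sorted(picks):
            gene = decoy_pool[i]
            eid = f"KD_{gene}_{c}"
            columns[eid] = rng.normal(0.0, 1.0, len(all_genes))
            meta_rows.append((eid, gene, "knockdown", c))
    signatures = SignatureMatrix(pd.DataFrame(columns, index=gene_index))
    metadata = pd.DataFrame(
        meta_rows, columns=["experiment_id", "perturbagen", "ptype", "cell_line"]
    )

    # ---- conditions ------------------------------------------------------
    conditions: list[Condition] = []
    for d in drugs:
        for c in cells:
            sig = pd.Series(drug_sig[(d, c)], index=gene_index)
            targets = select_de_genes(sig, cfg.z_threshold)
            truth.targets_by_cell[c] = targets | truth.targets_by_cell.get(c, set())
            tf_de = {
                tf: motif_targets[tf] & targets for tf in motif_targets
            }
            cond = Condition(
                condition_id=f"{d}|{c}",
                sources=set(truth.sources_by_cell[c]),
                targets=targets,
                tf_targets={tf: set(v) for tf, v in motif_targets.items()},
                tf_de_targets=tf_de,
                candidate_paths=enumerate_candidate_paths(
                    net, truth.sources_by_cell[c], targets, cfg.path_config
                ),
            )
            cond.validate()
            conditions.append(cond)

    # ---- gene sets -------------------------------------------------------
    gene_sets: dict[str, set[str]] = {}
    for c in cells:
        gene_sets[f"planted_{c}"] = set(truth.nodes_by_cell[c])
    gene_sets["planted_shared"] = set(truth.shared_nodes)
    for i in range(3):
        picks = rng.choice(len(all_genes), size=15, replace=False)
        gene_sets[f"decoy_set_{i}"] = {all_genes[j] for j in sorted(picks)}

    return SynthInstance(
        config=cfg,
        network=net,
        conditions=conditions,
        signatures=signatures,
        metadata=metadata,
        gene_sets=gene_sets,
        planted=truth,
        cells=cells,
        drugs=drugs,
    )


# ---------------------------------------------------------------------------
# Recovery metrics


def _prec_rec(selected: set[str], truth: set[str]) -> tuple[float, float]:
    if not selected:
        return 0.0, 0.0
    tp = len(selected & truth)
    prec = tp / len(selected)
    rec = tp / len(truth) if truth else 0.0
    return prec, rec


def recovery_report(instance: SynthInstance, solution: Solution) -> dict:
    """Precision/recall of planted nodes, TFs and covered targets.

    Reported per condition and overall; ``shared_node_recall`` measures
    recovery of the planted nodes common to all tasks (restricted, per task,
    to the shared nodes reachable in that task).
    """
    per_condition: dict[str, dict[str, float]] = {}
    truth = instance.planted
    for cond in instance.conditions:
        cell = cond.condition_id.split("|")[1]
        paths = solution.paths_for(cond.condition_id)
        sel_nodes = {n for p in paths for n in p.nodes}
        sel_tfs = {p.tf for p in paths}
        covered = {p.target for p in paths}
        node_p, node_r = _prec_rec(sel_nodes, truth.nodes_by_cell[cell])
        tf_p, tf_r = _prec_rec(sel_tfs, truth.tfs_by_cell[cell])
        planted_targets = {p[-1] for p in truth.active_paths_by_cell[cell]}
        _, tgt_r = _prec_rec(covered, planted_targets)
        shared_truth = truth.shared_nodes_by_cell[cell]
        _, shared_r = _prec_rec(sel_nodes, shared_truth)
        per_condition[cond.condition_id] = {
            "node_precision": node_p,
            "node_recall": node_r,
            "tf_precision": tf_p,
            "tf_recall": tf_r,
            "covered_target_recall": tgt_r,
            "shared_node_recall": shared_r if shared_truth else 0.0,
        }
    overall = {
        key: float(np.mean([m[key] for m in per_condition.values()]))
        for key in next(iter(per_condition.values()))
    } if per_condition else {}
    return {"per_condition": per_condition, "overall": overall}


# ---------------------------------------------------------------------------
# Instance IO


def write_instance(instance: SynthInstance, outdir) -> None:
    """Write a complete instance directory consumable by the pipeline.

    Files: network.tsv (edge list), signatures.tsv, metadata.tsv,
    gene_sets.gmt, truth.json (planted ground truth).
    """
    import json
    from pathlib import Path as _P

    from .evaluation import write_gmt
    from .network import write_network

    out = _P(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(instance.network, out / "network.tsv")
    instance.signatures.to_tsv(out / "signatures.tsv")
    instance.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    write_gmt(instance.gene_sets, out / "gene_sets.gmt")
    t = instance.planted
    truth_json = {
        "cells": instance.cells,
        "drugs": instance.drugs,
        "shared_paths": [list(p) for p in t.shared_paths],
        "shared_nodes": sorted(t.shared_nodes),
        "shared_nodes_by_cell": {
            c: sorted(v) for c, v in t.shared_nodes_by_cell.items()
        },
        "paths_by_cell": {
            c: [list(p) for p in v] for c, v in t.paths_by_cell.items()
        },
        "active_paths_by_cell": {
            c: [list(p) for p in v] for c, v in t.active_paths_by_cell.items()
        },
        "sources_by_cell": {c: sorted(v) for c, v in t.sources_by_cell.items()},
        "tfs_by_cell": {c: sorted(v) for c, v in t.tfs_by_cell.items()},
        "anchors": {str(k): v for k, v in t.anchors.items()},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Tiny random instances (for oracle comparisons at enumerable scale)


def random_small_instance(
    rng: np.random.Generator,
    n_conditions: int = 2,
    n_tfs: int = 4,
    n_targets: int = 3,
    max_paths_per_condition: int = 10,
) -> list[Condition]:
    """Random tiny conditions with directly constructed candidate paths.

    Path weights are arbitrary in (0, 1] (no backing network): suitable for
    enumerable oracle checks of the objective and solver at small scale.
    """
    tfs = [f"F{i}" for i in range(n_tfs)]
    targets = [f"T{i}" for i in range(n_targets)]
    sources = ["S0", "S1"]
    mids = [f"M{i}" for i in range(4)]
    conditions = []
    for ci in range(n_conditions):
        cid = f"c{ci}"
        cond_targets = set(
            rng.choice(targets, size=max(1, n_targets - 1), replace=False)
        )
        paths: dict[str, list[Path]] = {}
        n_paths = int(rng.integers(2, max_paths_per_condition + 1))
        made = set()
        for _ in range(n_paths):
            t = str(rng.choice(sorted(cond_targets)))
            f = str(rng.choice(tfs))
            s = str(rng.choice(sources))
            use_mid = rng.random() < 0.6
            nodes = (s, str(rng.choice(mids)), f, t) if use_mid else (s, f, t)
            if len(set(nodes)) != len(nodes) or nodes in made:
                continue
            made.add(nodes)
            w = float(rng.uniform(0.2, 0.95))
            paths.setdefault(t, []).append(Path(nodes, w))
        tf_targets = {f: set(targets) | {f"pad_{f}"} for f in tfs}
        tf_de = {
            f: set(
                rng.choice(
                    sorted(tf_targets[f] & cond_targets),
                    size=int(rng.integers(0, len(tf_targets[f] & cond_targets) + 1)),
                    replace=False,
                )
            )
            if tf_targets[f] & cond_targets
            else set()
            for f in tfs
        }
        conditions.append(
            Condition(
                condition_id=cid,
                sources=set(sources),
                targets=cond_targets,
                tf_targets=tf_targets,
                tf_de_targets=tf_de,
                candidate_paths={
                    t: tuple(sorted(ps, key=Path.sort_key))
                    for t, ps in paths.items()
                },
            )
        )
    return conditions
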