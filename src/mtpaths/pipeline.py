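"""End-to-end orchestration: signatures -> paths -> solver -> rankings.

The pipeline reads an instance directory (network edge list, signature
matrix, experiment metadata, gene-set collection), derives per-condition
inputs, runs the multi-task solver per drug (one unified model across cell
lines, as well as the single-task baseline per condition), ranks and
filters genes, computes cell-type specificity from the single-task
rankings, evaluates against the gene-set collection, and writes all
artifacts plus a JSON run report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .evaluation import hypergeometric_pvalue, ndcg, overlap_count, read_gmt
from .network import Condition, enumerate_candidate_paths, load_network, write_paths
from .objective import Solution, objective_terms
from .ranking import RankedGeneList, filter_background, rank_nodes, specificity_scores
from .signatures import (
    collapse_by_perturbagen,
    extend_tf_targets,
    identify_sources,
    read_metadata,
    read_signatures,
    select_de_genes,
)
from .solver import greedy_optimize, single_task_optimize

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "build_conditions", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("conditions")
def build_conditions(cfg: RunConfig, network, signatures, metadata):
    """Derive per-(drug, cell line) conditions from the signatures.

    Sources are the top-k knock-down perturbagens by correlation with the
    drug signature; targets the DE genes at the configured z threshold; TF
    target sets are motif targets extended with each TF knock-down's top-d
    DE genes.
    """
    drug_rows = metadata[metadata["ptype"] == "drug"]
    motif = network.tf_motif_targets()
    conditions: list[Condition] = []
    by_drug: dict[str, list[str]] = {}
    source_report: dict[str, list] = {}
    for _, row in drug_rows.sort_values("experiment_id").iterrows():
        drug, cell = row["perturbagen"], row["cell_line"]
        cid = f"{drug}|{cell}"
        sig = signatures.column(row["experiment_id"])
        targets = select_de_genes(sig, cfg.z_threshold)
        kd = collapse_by_perturbagen(signatures, metadata, "knockdown", cell)
        if kd.shape[1] == 0:
            raise ValueError(f"no knock-down experiments for cell {cell}")
        ranked_sources = identify_sources(
            sig, kd, cfg.k_sources, cfg.correlation_mode, cfg.correlation_method
        )
        sources = {g for g, _ in ranked_sources}
        tf_targets = extend_tf_targets(motif, kd, cfg.d_extension)
        tf_de = {tf: tf_targets[tf] & targets for tf in tf_targets}
        cond = Condition(
            condition_id=cid,
            sources=sources,
            targets=targets,
            tf_targets=tf_targets,
            tf_de_targets=tf_de,
            candidate_paths=enumerate_candidate_paths(
                network, sources, targets, cfg.paths
            ),
        )
        cond.validate()
        conditions.append(cond)
        by_drug.setdefault(drug, []).append(cid)
        source_report[cid] = [[g, round(r, 6)] for g, r in ranked_sources]
    return conditions, by_drug, source_report


@_stage("evaluate")
def _evaluate(rankings: dict[str, RankedGeneList], gene_sets, universe_size):
    rows = []
    for cid in sorted(rankings):
        genes = set(rankings[cid].genes)
        for name in sorted(gene_sets):
            ov = overlap_count(genes, gene_sets[name])
            rows.append(
                {
                    "condition_id": cid,
                    "gene_set": name,
                    "overlap": ov,
                    "hypergeom_p": hypergeometric_pvalue(
                        ov, len(genes), len(gene_sets[name]), universe_size
                    ),
                    "ndcg": ndcg(rankings[cid], gene_sets[name]),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report (also written).

    All outputs are deterministic functions of the config and seed; rerunning
    with the same inputs reproduces every file byte-for-byte.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        network = load_network(cfg.network)
        signatures = read_signatures(cfg.signatures)
        metadata = read_metadata(cfg.metadata)
        gene_sets = read_gmt(cfg.gene_sets)
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    conditions, by_drug, source_report = build_conditions(
        cfg, network, signatures, metadata
    )
    cond_by_id = {c.condition_id: c for c in conditions}

    # one unified multi-task model per drug, plus single-task baselines
    multi = Solution({})
    report_terms: dict[str, dict] = {}
    trace_summary: dict[str, dict] = {}
    single_rankings: dict[tuple[str, str], RankedGeneList] = {}
    try:
        for drug in sorted(by_drug):
            conds = [cond_by_id[cid] for cid in sorted(by_drug[drug])]
            sol, trace = greedy_optimize(conds, cfg.objective, cfg.solver)
            for cid, paths in sol.per_condition.items():
                multi.per_condition[cid] = paths
            report_terms[drug] = objective_terms(sol, conds, cfg.objective)
            trace_summary[drug] = {
                "moves": len(trace.records),
                "converged": trace.converged,
                "final_objective": trace.records[-1].objective_after
                if trace.records
                else 0.0,
            }
            for cond in conds:
                st = single_task_optimize(cond, cfg.objective, cfg.solver)
                cell = cond.condition_id.split("|", 1)[1]
                single_rankings[(drug, cell)] = rank_nodes(
                    st.paths_for(cond.condition_id)
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'solve' failed: {exc}") from exc

    try:
        backgrounds = []
        for bg_path in cfg.background_rankings:
            df = pd.read_csv(bg_path, sep="\t")
            backgrounds.append(
                RankedGeneList(list(zip(df["gene"], df["score"].astype(float))))
            )
        rankings = {
            cid: filter_background(
                rank_nodes(multi.paths_for(cid)), backgrounds, cfg.filter_top_n
            )
            for cid in sorted(cond_by_id)
        }
    except Exception as exc:
        raise PipelineError(f"stage 'rank' failed: {exc}") from exc

    spec = specificity_scores(single_rankings) if single_rankings else None
    evaluation = _evaluate(rankings, gene_sets, len(signatures.genes))

    # ---- artifacts -------------------------------------------------------
    write_paths(
        {cid: multi.paths_for(cid) for cid in sorted(cond_by_id)},
        out / "selected_paths.tsv",
    )
    single_by_cid = {
        f"{d}|{c}": rl for (d, c), rl in single_rankings.items()
    }
    rank_rows = []
    for cid in sorted(rankings):
        for i, (g, s) in enumerate(rankings[cid].items, start=1):
            rank_rows.append((cid, g, s, i))
    pd.DataFrame(
        rank_rows, columns=["condition_id", "gene", "score", "rank"]
    ).to_csv(out / "node_rankings.tsv", sep="\t", index=False)
    if spec is not None:
        spec.f.round(9).to_csv(out / "specificity.tsv", sep="\t")
    evaluation.round(9).to_csv(out / "evaluation.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "conditions": {
            cid: {
                "n_sources": len(cond_by_id[cid].sources),
                "n_targets": len(cond_by_id[cid].targets),
                "n_selected_paths": len(multi.paths_for(cid)),
                "n_ranked_genes": len(rankings[cid]),
                "n_single_task_genes": len(single_by_cid.get(cid, [])),
            }
            for cid in sorted(cond_by_id)
        },
        "objective_terms": report_terms,
        "trace": trace_summary,
        "sources": source_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return report
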