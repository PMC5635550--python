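# mtpaths

Multi-task reconstruction of drug-response signaling and regulatory
networks from perturbation expression signatures.

When several cancer cell types are treated with the same drug, much of the
transcriptional response is driven by shared pathways, while part of it is
cell-type specific. Reconstructing a response network separately per cell
type wastes that shared signal; pooling everything loses the specific
pathways. `mtpaths` treats each cell type as one *task* and reconstructs
all response networks jointly: it selects, per condition, paths that run
from a **source** (a protein the drug acts on directly) through signaling
intermediates to a **transcription factor** and finally across a regulatory
edge into a **differentially expressed target gene**, coupling the tasks so
that pathway sharing is rewarded.

## The objective

Given per-condition candidate path sets `P_c^t` (condition `c`, target
`t`), the solver selects path sets `S_c` (union `S`) maximizing

```
  λ₁ Σ_c Σ_{t∈T_c} 1[|S_c ∩ P_c^t| > 0]        target coverage
+ λ₂ Σ_c Σ_{tf∈TF(S_c)} |DE(c,tf)| / |T(tf)|   TF/DE consistency
+ λ₃ Σ_c Σ_{p∈S_c} h(p)                        path reliability
− λ₄ N(S)                                      union size (nodes)
+ λ₅ Σ_{{p_i,p_j}⊆S} n(p_i,p_j)^α              cross-path sharing
```

where `h(p)` is the product of edge confidence probabilities along `p`,
`N(S)` the number of distinct nodes in the union, `T(tf)` a TF's predicted
targets, `DE(c,tf)` the subset differentially expressed in `c`, and
`n(p_i,p_j)` the node overlap of two selected paths. Because every path
must end TF → target, optimization reduces to greedily adding and removing
TFs per condition — re-deciding each TF's best paths against the current
solution — until no single move improves the objective.

Around the solver the package provides the full workflow:

- **Source inference** — rank gene knock-down signatures by (Spearman)
  correlation with the drug signature; the top-k knock-downs are candidate
  direct targets of the drug.
- **TF target extension** — extend motif-derived TF target sets with the
  top-d DE genes of each TF knock-down.
- **Gene ranking** — score genes by the number of selected paths through
  them; filter promiscuous hubs seen in the top-100 of background (non
  cancer) drug rankings.
- **Cell-type specificity** — aggregate single-task inverse ranks across
  drugs (`s_{g,c} = Σ_d 1/r_d`) and normalize by the gene's cross-cell mean
  (`f_{g,c}`), so ubiquitous genes score ≈1 and specific genes ≫1.
- **Evaluation** — overlap counts, hypergeometric enrichment and nDCG
  against GMT gene-set collections; a grid-search utility for the λ's.
- **Synthetic benchmark** — a generator that plants partially shared
  source→intermediate→TF→target chains with per-task decoy explanations,
  so every claim above is testable without external downloads.

## Worked example

```python
from mtpaths import (SynthConfig, generate_instance, ObjectiveParams,
                     greedy_optimize, single_task_optimize, recovery_report)
from mtpaths.objective import Solution, objective_terms

inst = generate_instance(SynthConfig(seed=1))   # 3 cell types, 1 drug
params = ObjectiveParams()
multi, trace = greedy_optimize(inst.conditions, params)
single = Solution({})
for cond in inst.conditions:
    s = single_task_optimize(cond, params)
    single.per_condition[cond.condition_id] = s.paths_for(cond.condition_id)

print(objective_terms(multi, inst.conditions, params))
for label, sol in (("multi-task", multi), ("single-task", single)):
    r = recovery_report(inst, sol)["overall"]
    print(label, round(r["shared_node_recall"], 3))
```

Output:

```
objective terms: {'coverage': 26.0, 'tf_consistency': 9.833,
 'path_weight': 14.928, 'node_count': 43.0, 'shared_paths': 453.093,
 'objective': 27.683}
multi-task  0.963
single-task 0.636
```

The joint solver covers all 26 (condition, target) pairs and recovers 96%
of the planted shared-pathway nodes; the single-task baseline — the same
objective without the cross-task sharing term — is pulled toward each cell
type's higher-weight decoy route and recovers only 64%.

The same workflow is available from the shell:

```bash
mtpaths simulate --seed 1 -o instance/
mtpaths init-config -o config.yaml        # edit paths/parameters
mtpaths run -c config.yaml                # writes selected_paths.tsv,
                                          # node_rankings.tsv, specificity.tsv,
                                          # evaluation.tsv, report.json
```

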