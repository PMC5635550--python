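# Methods

## Model

A drug response in one cell type (a *condition* or *task*) is modeled as a
set of simple paths in a mixed interaction network: undirected
protein–protein edges and directed TF→gene regulatory edges, each with a
confidence probability in (0, 1]. A valid path starts at a source (a
candidate direct drug target), traverses signaling intermediates over PPI
edges (regulatory edges may also be traversed, TF→gene only), and ends by
crossing one regulatory edge into a differentially expressed target gene —
so the penultimate node of every path is its transcription factor. The
path weight `h(p)` is the product of its edge probabilities; extending a
path can never increase its weight.

The five-term objective (README) trades off per-task explanation quality
(coverage of DE targets, TF/DE consistency, path weight) against the node
count of the cross-task union and in favor of node sharing between
selected paths. Identical node sequences selected by several conditions
count **once** in the union: re-using a path in a second task is free under
the node penalty, which is the mechanism that couples the tasks. Pairs in
the sharing term range over distinct paths of the union, including pairs
selected within one condition (the literal reading of the sum); a config
switch (`cross_condition_pairs_only`) restricts it to pairs spanning two
conditions for users who want the strictly multi-task reading.

## Candidate paths

The enumeration keeps, per (source, target) pair, the `m = 20` best-weight
simple paths with at most 5 edges whose last edge is regulatory. Because
maximizing a product of probabilities is minimizing an additive
−log-probability cost, this is a k-shortest-paths problem; at the bounded
length we solve it exactly with a depth-limited walk over simple paths,
which is also what makes the enumeration directly comparable to a
brute-force oracle in tests. Output order is deterministic: descending
weight, then lexicographic node sequence. Unreachable targets get empty
candidate sets, not errors.

## Greedy solver

Since each target must be explained through a TF, path selection reduces
to TF subset selection per condition. The solver is a steepest-ascent
local search: each iteration evaluates, for every (condition, TF) pair,
the best single addition (choosing, per reachable target, the candidate
path through that TF with the largest marginal gain against the *current*
solution — so the best path for a TF is re-decided every iteration) and
the best single removal (dropping all of the TF's selected paths in that
condition), then applies the highest-gain move. It stops when no move
gains more than `min_gain` (1e-9, a float-cycling guard), or after
`max_iterations` (200) with a flag in the trace. Tie-breaks are
deterministic everywhere: gain, then path weight, then lexicographic
identifiers; moves are scanned in (condition, TF) order and the first of
equals wins. Objective bookkeeping is incremental (O(|union|) per path
add/remove) and is checked against a direct evaluation of the objective in
the tests.

Exactness is not claimed: the objective generalizes weighted set cover, so
we verify empirically that the greedy value stays above 0.63× (≈ 1 − 1/e)
of the exhaustive TF-subset optimum on enumerable instances.

The single-task baseline runs the same solver on one condition with the
sharing term (λ₅) removed. The node-count penalty is kept: per task it is
an ordinary sparsity penalty, and without any size penalty the greedy
would accept every TF with a positive consistency or weight contribution,
making the baseline trivially exhaustive. A keyword (`drop_node_penalty`)
zeroes λ₄ as well for users who want the fully uncoupled variant; the
λ₄=λ₅=0 setting is also the regime where the joint optimization provably
decomposes into independent per-task runs (asserted file-exactly in the
tests).

## Signature-derived inputs

- DE targets: `|z| ≥ z_threshold`, default 2.0 (configurable; the value is
  a conventional two-sigma cut).
- Sources: knock-down profiles are averaged per perturbagen, zero-variance
  profiles dropped with a warning, and candidates ranked by Spearman
  correlation with the drug signature (robust to scale differences between
  experiments; Pearson available). Default mode ranks by signed
  correlation — appropriate when the drugs studied are inhibitors, whose
  targets' knock-downs mimic the drug — with an `absolute` mode for the
  general case. Defaults k = 100 and d = 100 (TF target extension with the
  top-d |z| genes of a TF knock-down) follow the published study design.
- Ties in top-k/top-d: larger |z| first, then lexicographic gene id.

## Ranking and specificity

Genes are scored by the number of selected paths through them; all roles
count (source, intermediate, TF, target — a switch excludes targets). The
hub filter removes genes appearing in the top `top_n = 100` of any
background ranking (unrelated drugs). Specificity aggregates *single-task*
rankings: `M₃[g,d,c] = 1/rank` (1-based rank in the filtered list; absent
genes contribute 0, the plainest reading of "inverse rank"),
`s_{g,c} = Σ_d M₃[g,d,c]`, and `f_{g,c} = s_{g,c} / mean_c'(s_{g,c'})`,
with f = 0 for genes never ranked. For every scored gene, mean over cell
types of f is exactly 1.

nDCG uses binary relevance with the standard `1/log₂(i+1)` discount at
1-based position i, normalized by the ideal ordering at the chosen depth
(default: full list length); it returns 0 when the relevant set is empty.

## Parameter defaults

| parameter | default | role |
|---|---|---|
| λ₁ | 1.0 | per-(condition, target) coverage reward |
| λ₂ | 0.5 | TF/DE-consistency reward, per used TF |
| λ₃ | 0.2 | per-path weight reward |
| λ₄ | 0.25 | per-node penalty on the union |
| λ₅ | 0.01 | pairwise sharing reward |
| α | 0.5 | sublinear overlap exponent |

The λ's are dimensionless and instance-dependent; these defaults were set
from the move-gain algebra on the synthetic fixtures so that the terms are
commensurate: a covering path (4 nodes) is always worth selecting
(λ₁ > 4λ₄ − λ₂ − λ₃), but a *redundant* explanation of already-covered
targets is not (λ₂ + 3λ₃·h < 3λ₄ for a 3-edge path with h ≤ 0.9³). With a
much larger λ₃ or λ₅ the node penalty can no longer discourage redundant
TFs and solutions grow dense. For real data the grid-search utility
(`mtpaths.evaluation.grid_search`) scores settings by validation-set
overlap, mirroring how such weights are usually trained.

## Synthetic benchmark

The generator plants, per task, `n_pathways_per_task = 10` chains of 3
edges (source → intermediate → TF → target, edge probability 0.90), of
which a `shared_fraction` (default 0.6) is common to all tasks. Shared
chains are grouped ~3 targets per TF. Each group has one **anchor task**
in which all of its targets are DE; in the other tasks one target is
silent, and those tasks additionally have a **decoy route** — a private
source, intermediate and TF with heavier edges (0.95) covering the common
targets. The decoy is the locally better explanation (higher weight, equal
consistency), so a single-task solver takes it; the multi-task solver,
having selected the shared route in the anchor task (where it explains
strictly more), re-uses it elsewhere because a re-used path adds zero
nodes to the union. This is the phenomenon the method is built around —
shared response pathways versus task-specific alternative explanations —
reduced to its minimal form.

Signatures put planted DE targets at |z| = 3 (clearing the threshold of 2
with margin) plus N(0, noise_sd) noise, noise_sd = 0.1 by default;
knock-down profiles of planted sources are the drug signature plus the
same noise, and decoy knock-downs are independent N(0, 1), giving
correlation-based source inference a well-defined negative class.
Background structure (Erdős–Rényi PPI at density 0.02 with probabilities
U(0.3, 0.7), background TFs with non-DE motif targets) provides weak
alternative routes for the enumerator without perturbing the planted
economics.

What the generator does **not** emulate: L1000 plate effects, inference of
non-landmark genes, realistic degree distributions or edge-probability
calibration, dose/time structure, and correlated noise between
experiments. Passing the recovery tests therefore demonstrates that the
optimization behaves as designed under its own assumptions, not that those
assumptions hold for any particular real dataset.

## Numerical and degenerate-input choices

- Duplicate edges collapse to the maximum probability; self-loops are
  dropped with a warning; probabilities outside (0, 1] are errors naming
  the offending row.
- Candidate-gain comparisons use a 1e-12 guard so float noise cannot
  override the deterministic tie-break.
- Objective terms are accumulated in sorted order so results are identical
  across processes (Python's per-process hash randomization would otherwise
  permute set iteration and perturb the last bits of float sums).
- Edge probabilities are serialized via `repr` and parsed with pandas'
  round-trip float mode, making network IO lossless.
- A TF with an empty predicted-target set cannot be scored for consistency
  and is rejected as an error rather than treated as 0/0.
- Empty solutions give objective 0; empty target sets give empty solutions;
  unreachable targets give empty candidate sets.

## Scale of the shipped experiments

The test suite and the acceptance script run everything on instances of
200 genes, 3 tasks and ≤ 16 TFs (tiny-instance oracles use 2–3 conditions
with ≤ 12 candidate paths), with 20–50 replicate seeds per claim. These
sizes keep the exhaustive oracles enumerable and the full suite in the
seconds range while leaving every planted effect far from the decision
thresholds; the method itself has no dependence on these sizes beyond run
time.

## Known limitations

- Steepest ascent offers no approximation guarantee for the full
  objective; the 0.63 figure is an empirical check motivated by the
  set-cover connection.
- The sharing reward is myopic: a shared path pays off only after some
  task has selected it, so sharing is discovered through tasks where the
  shared route is also locally competitive (the anchor mechanism above).
- Specificity requires single-task rankings by construction; running it on
  multi-task rankings would double-count the coupling.
- Hyperparameter training on external gene-set collections is out of
  scope; `grid_search` provides the generic mechanism only.
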