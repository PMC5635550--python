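"""Per-condition inputs derived from perturbation expression signatures.

Signatures are gene x experiment matrices of z-scores (drug treatments and
single-gene knock-downs, as in L1000-style landmark-gene assays).  From them
we derive, per condition: the differentially expressed target genes, the
inferred drug sources (proteins whose knock-down signature correlates with
the drug signature), and extended TF target sets (motif targets plus the
top-d DE genes of each TF's knock-down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "read_signatures",
    "read_metadata",
    "select_de_genes",
    "collapse_by_perturbagen",
    "identify_sources",
    "extend_tf_targets",
]

METADATA_COLUMNS = ("experiment_id", "perturbagen", "ptype", "cell_line")


@dataclass
class SignatureMatrix:
    """Gene x experiment z-score matrix with validation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in signature matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate experiment identifiers")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("signature matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def experiments(self) -> list[str]:
        return list(self.data.columns)

    def column(self, experiment_id: str) -> pd.Series:
        return self.data[experiment_id]

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")


def read_signatures(path) -> SignatureMatrix:
    """Read a tab-separated gene x experiment matrix (first column 'gene')."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return SignatureMatrix(df)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if meta["experiment_id"].duplicated().any():
        raise ValueError("metadata has duplicate experiment rows")
    return meta


def select_de_genes(signature: pd.Series, z_threshold: float = 2.0) -> set[str]:
    """Genes with |z| >= z_threshold in one experiment's signature."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if len(signature) == 0:
        raise ValueError("empty signature")
    return set(signature.index[signature.abs() >= z_threshold])


def collapse_by_perturbagen(
    signatures: SignatureMatrix,
    metadata: pd.DataFrame,
    ptype: str = "knockdown",
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Average replicate experiments into one column per perturbagen.

    Restricts to experiments of the given ``ptype`` (and ``cell_line`` when
    given); replicate z-score columns for the same perturbagen are averaged
    so that each candidate source gets a single profile.
    """
    rows = metadata[metadata["ptype"] == ptype]
    if cell_line is not None:
        rows = rows[rows["cell_line"] == cell_line]
    cols: dict[str, list[str]] = {}
    for _, r in rows.iterrows():
        if r["experiment_id"] in signatures.data.columns:
            cols.setdefault(r["perturbagen"], []).append(r["experiment_id"])
    out = {
        pert: signatures.data[ids].mean(axis=1)
        for pert, ids in sorted(cols.items())
    }
    return pd.DataFrame(out, index=signatures.data.index)


def identify_sources(
    drug_signature: pd.Series,
    kd_signatures: pd.DataFrame,
    k: int = 100,
    mode: str = "positive",
    method: str = "spearman",
) -> list[tuple[str, float]]:
    """Rank knock-down perturbagens by correlation with the drug signature.

    A protein whose knock-down signature resembles the drug's response is a
    candidate direct target (source).  ``mode='positive'`` ranks by the
    signed correlation (appropriate for inhibitors, the default);
    ``mode='absolute'`` ranks by |correlation|.  Spearman is the default
    statistic, robust to scale differences between experiments; Pearson is
    available via ``method``.  Returns the top ``k`` (perturbagen,
    correlation) pairs; zero-variance profiles are excluded with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("positive", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = drug_signature.index.intersection(kd_signatures.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes between signatures")
    drug = drug_signature.loc[shared].to_numpy(dtype=float)
    if np.std(drug) == 0:
        raise ValueError("drug signature has zero variance")
    scores: list[tuple[str, float]] = []
    for pert in kd_signatures.columns:
        kd = kd_signatures.loc[shared, pert].to_numpy(dtype=float)
        if np.std(kd) == 0:
            logger.warning(
                "excluding zero-variance knock-down profile for %s", pert
            )
            continue
        if method == "spearman":
            r = stats.spearmanr(drug, kd).statistic
        else:
            r = stats.pearsonr(drug, kd).statistic
        scores.append((pert, float(r)))
    key = (lambda s: (-abs(s[1]), s[0])) if mode == "absolute" else (
        lambda s: (-s[1], s[0])
    )
    scores.sort(key=key)
    return scores[:k]


def extend_tf_targets(
    motif_targets: dict[str, set[str]],
    kd_signatures: pd.DataFrame,
    d: int = 100,
) -> dict[str, set[str]]:
    """Extend each TF's motif target set with its knock-down's top-d genes.

    For every TF with a knock-down column in ``kd_signatures`` (columns keyed
    by TF name), the d genes with the largest |z| in that column are unioned
    into its predicted target set; ties break by larger |z| then
    lexicographic gene id.  TFs without a knock-down keep their motif targets
    unchanged; the TF itself is never added as its own target.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    out = {tf: set(targets) for tf, targets in motif_targets.items()}
    if d == 0:
        return out
    for tf in out:
        if tf not in kd_signatures.columns:
            continue
        col = kd_signatures[tf]
        order = sorted(
            ((g, abs(z)) for g, z in col.items() if g != tf),
            key=lambda gz: (-gz[1], gz[0]),
        )
        out[tf] |= {g for g, _ in order[:d]}
    return out
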