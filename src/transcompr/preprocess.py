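"""Per-study normalization and gene selection ahead of the cross-species step.

The order fixed by the pipeline is: probe collapse -> homolog filter ->
(differential expression on unstandardized values, optional) -> z-score.
Each study is normalized internally, never jointly with the other
species, so that cross-species combination happens only through the
principal-component projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy, HomologMap

logger = logging.getLogger(__name__)

DEFAULT_PHENOTYPE_MAP = {"WT": 0, "HET": 1, "HO": 2}


class ModelError(ValueError):
    """Design-matrix problem (rank deficiency, unusable covariates)."""


def zscore_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Standardize every gene row to mean 0, sample standard deviation 1.

    Zero-variance genes cannot be standardized and are dropped (count
    logged). Raises if fewer than two samples or nothing survives.
    """
    if study.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    v = study.values
    sd = v.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("zscore_genes: dropped %d zero-variance genes", n_dropped)
    v = v.loc[keep]
    z = v.sub(v.mean(axis=1), axis=0).div(sd[keep], axis=0)
    partner = None
    if study.partner_ids is not None:
        partner = study.partner_ids.loc[z.index]
    return ExpressionStudy(
        values=z, metadata=study.metadata, species=study.species, partner_ids=partner
    )


def encode_sex(sex: pd.Series) -> np.ndarray:
    """M -> 1, F -> 0."""
    mapping = {"M": 1.0, "F": 0.0}
    bad = sorted(set(sex.astype(str)) - set(mapping))
    if bad:
        raise ValueError(f"unknown sex labels {bad}; expected M/F")
    return sex.astype(str).map(mapping).to_numpy()


_CONTROL_SYNONYMS = {"control", "ctrl", "wt", "normal", "healthy", "none"}


def disease_reference_level(levels: list[str]) -> str:
    """Reference (baseline) level: a recognized control label, else the
    first in sorted order."""
    for lev in levels:
        if lev.lower() in _CONTROL_SYNONYMS:
            return lev
    return levels[0]


def _disease_covariate(metadata: pd.DataFrame) -> np.ndarray:
    """Binary disease covariate from disease_code, else from two labels
    (1 marks the non-reference level)."""
    if "disease_code" in metadata.columns and metadata["disease_code"].notna().all():
        d = metadata["disease_code"].astype(float).to_numpy()
    else:
        labels = metadata["disease_label"].astype(str)
        levels = sorted(labels.unique())
        if len(levels) != 2:
            raise ModelError(
                f"binary disease status required, found levels {levels}"
            )
        ref = disease_reference_level(levels)
        d = (labels != ref).astype(float).to_numpy()
    if len(np.unique(d)) < 2:
        raise ModelError("disease covariate is constant")
    return d


@dataclass
class DEGResult:
    """Per-gene disease-term statistics from the covariate-adjusted fit.

    ``table`` is indexed by gene with columns ``coef``, ``t``, ``p``,
    ``p_adj`` (Benjamini-Hochberg) and ``selected``.
    """

    table: pd.DataFrame
    alpha: float
    cap: int | None

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def select_degs(
    study: ExpressionStudy,
    alpha: float = 0.20,
    cap: int | None = None,
    disease: np.ndarray | None = None,
) -> DEGResult:
    """Permissive differential-expression screen on the disease term.

    Per gene, fits expression ~ intercept + age + sex + disease by
    ordinary least squares; the p-value is the two-sided t-test on the
    disease coefficient, Benjamini-Hochberg adjusted across all genes.
    Genes with adjusted p < ``alpha`` are selected (``alpha >= 1``
    disables the filter, since adjusted p saturates at exactly 1); if
    ``cap`` is given only the ``cap`` smallest by adjusted p (ties:
    raw p, then gene id) are kept.
    """
    meta = study.metadata
    age = meta["age"].astype(float).to_numpy()
    sex = encode_sex(meta["sex"])
    d = _disease_covariate(meta) if disease is None else np.asarray(disease, float)
    n = study.n_samples
    X = np.column_stack([np.ones(n), age, sex, d])
    names = ["intercept", "age", "sex", "disease"]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ModelError(f"design matrix rank-deficient; aliased columns: {aliased}")
    if n <= X.shape[1]:
        raise ModelError(f"need more than {X.shape[1]} samples, have {n}")

    Y = study.values.to_numpy()  # genes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv  # genes x 4
    resid = Y - B @ X.T
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[3, 3], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[:, 3] / np.where(se > 0, se, 1.0), np.inf * np.sign(B[:, 3]))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {"coef": B[:, 3], "t": t, "p": p, "p_adj": p_adj},
        index=study.gene_ids,
    )
    if alpha >= 1.0:
        selected = np.ones(len(table), dtype=bool)
    else:
        selected = (table["p_adj"] < alpha).to_numpy()
    if cap is not None and int(selected.sum()) > cap:
        sel_tbl = table[selected].copy()
        sel_tbl["_gene"] = sel_tbl.index.astype(str)
        keep = set(sel_tbl.sort_values(["p_adj", "p", "_gene"]).head(cap).index)
        selected = selected & table.index.isin(keep)
    table["selected"] = selected
    return DEGResult(table=table, alpha=alpha, cap=cap)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal does not drop the design rank."""
    full = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j])
    return out


def homolog_filter(study: ExpressionStudy, hmap: HomologMap) -> ExpressionStudy:
    """Restrict a study to genes with a one-to-one cross-species partner.

    Human studies keep their original row order; mouse studies are
    re-ordered to follow the map's human-side listing so they can later
    be row-aligned against a human model. The partner id of each
    retained gene is recorded on the returned study.
    """
    pairs = hmap.one_to_one_pairs()
    own, partner = ("human", "mouse") if study.species == "human" else ("mouse", "human")
    pairs = pairs[pairs[own].isin(set(study.gene_ids))]
    if pairs.empty:
        raise ValueError("no overlap between study genes and homolog map")
    partner_of = dict(zip(pairs[own], pairs[partner]))
    if study.species == "human":
        genes = [g for g in study.gene_ids if g in partner_of]
    else:
        genes = pairs[own].tolist()  # map's human-gene listing order
    partner_ids = pd.Series([partner_of[g] for g in genes], index=pd.Index(genes))
    return study.subset_genes(genes, partner_ids=partner_ids)


def encode_phenotype(
    metadata: pd.DataFrame, label_map: dict[str, int] | None = None
) -> np.ndarray:
    """Map genotype labels to the ordinal dose encoding WT->0, HET->1, HO->2."""
    label_map = DEFAULT_PHENOTYPE_MAP if label_map is None else label_map
    labels = metadata["disease_label"].astype(str)
    bad = sorted(set(labels) - set(label_map))
    if bad:
        raise ValueError(f"unknown phenotype labels {bad}; map covers {sorted(label_map)}")
    return labels.map(label_map).to_numpy(dtype=int)
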