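"""Biological interpretation of translatable components.

Loading-tail over-representation: for a chosen component, the genes in
the top and bottom 20% of its loadings are tested for enrichment of
each gene set against the background of all genes in the PCA model
(one-sided Fisher / hypergeometric upper tail), Benjamini-Hochberg
adjusted within each (component, tail) family.

Gene-level follow-up: pairwise two-sample t-tests of HET-vs-WT and
HO-vs-WT mouse expression with BH adjustment over the gene x comparison
family (FDR < 0.05), and a secreted-factor filter driven by a supplied
annotation table as a proxy for therapeutically accessible
receptor-ligand biology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable, ExpressionStudy, GeneSetCollection
from .pca import PCAModel

logger = logging.getLogger(__name__)

__all__ = [
    "ora_tails",
    "gene_level_tests",
    "secreted_filter",
    "tail_genes",
]


def tail_genes(
    loadings: pd.Series, tail_frac: float = 0.20
) -> tuple[list[str], list[str]]:
    """Top and bottom loading tails, each of size ceil(tail_frac * G).

    The top tail holds the largest signed loadings, the bottom tail the
    most negative; ties at the boundary break deterministically by gene
    id.
    """
    g = len(loadings)
    t = math.ceil(tail_frac * g - 1e-9)  # guard against 0.2*G landing above G/5
    frame = pd.DataFrame({"loading": loadings.to_numpy(), "gene": loadings.index.astype(str)})
    top = frame.sort_values(["loading", "gene"], ascending=[False, True])["gene"].head(t)
    bottom = frame.sort_values(["loading", "gene"], ascending=[True, True])["gene"].head(t)
    return top.tolist(), bottom.tolist()


def _component_index(model: PCAModel, component) -> int:
    if isinstance(component, str):
        try:
            return model.component_ids.index(component)
        except ValueError:
            raise KeyError(f"{component!r} not among {model.component_ids}") from None
    j = int(component)
    if not 0 <= j < model.n_components:
        raise KeyError(f"component index {j} outside 0..{model.n_components - 1}")
    return j


def ora_tails(
    model: PCAModel,
    component,
    sets: GeneSetCollection,
    tail_frac: float = 0.20,
) -> pd.DataFrame:
    """Loading-tail over-representation analysis for one component.

    Returns one row per (tail, gene set) with the overlap count, the
    tail and in-model set sizes, the one-sided Fisher p (hypergeometric
    upper tail) and the BH-adjusted p within the tail's family, plus the
    contributing genes. Sets with no member in the model are skipped
    (logged).
    """
    j = _component_index(model, component)
    comp_name = model.component_ids[j]
    loadings = pd.Series(model.loadings[:, j], index=model.gene_order)
    top, bottom = tail_genes(loadings, tail_frac)
    g_total = len(loadings)
    model_genes = set(model.gene_order.astype(str))

    rows = []
    for tail_name, tail in (("top", top), ("bottom", bottom)):
        tail_set = set(tail)
        for set_name, members in sets:
            in_model = members & model_genes
            if not in_model:
                logger.info("ora_tails: set %r has no genes in model; skipped", set_name)
                continue
            overlap_genes = sorted(tail_set & in_model)
            k = len(overlap_genes)
            # P(X >= k), X ~ Hypergeom(N=g_total, K=|in_model|, n=|tail|)
            p = float(stats.hypergeom.sf(k - 1, g_total, len(in_model), len(tail)))
            rows.append(
                {
                    "component": comp_name,
                    "tail": tail_name,
                    "set": set_name,
                    "overlap": k,
                    "tail_size": len(tail),
                    "set_in_model": len(in_model),
                    "model_size": g_total,
                    "p": p,
                    "genes": overlap_genes,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["fdr"] = np.nan
    for tail_name in ("top", "bottom"):
        mask = result["tail"] == tail_name
        if mask.any():
            result.loc[mask, "fdr"] = multipletests(
                result.loc[mask, "p"].to_numpy(), method="fdr_bh"
            )[1]
            logger.info(
                "ora_tails: BH family %s/%s has %d sets", comp_name, tail_name, int(mask.sum())
            )
    return result.reset_index(drop=True)


def _group_matrix(study: ExpressionStudy, label: str, genes: list[str]) -> np.ndarray:
    cols = study.metadata.index[study.metadata["disease_label"].astype(str) == label]
    return study.values.loc[genes, cols].to_numpy()


def gene_level_tests(
    mouse: ExpressionStudy,
    genes=None,
    groups: tuple[str, str, str] = ("WT", "HET", "HO"),
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Pairwise t-tests of HET-vs-WT and HO-vs-WT per gene.

    Two-sided, pooled-variance by default (``welch=True`` for unequal
    variances). BH adjustment runs over the full gene x {HET-vs-WT,
    HO-vs-WT} family; a gene is ``significant`` when either adjusted p
    is below ``alpha``. HET-vs-HO is reported unadjusted for reference
    but never feeds the flag.
    """
    wt_label, het_label, ho_label = groups
    genes = list(mouse.gene_ids) if genes is None else [g for g in genes]
    missing = [g for g in genes if g not in mouse.gene_ids]
    if missing:
        raise KeyError(f"genes absent from study: {missing[:5]}")
    mats = {}
    for label in groups:
        m = _group_matrix(mouse, label, genes)
        if m.shape[1] < 2:
            raise ValueError(f"group {label!r} has {m.shape[1]} samples; need >= 2")
        mats[label] = m

    equal_var = not welch
    t_het, p_het = stats.ttest_ind(mats[het_label], mats[wt_label], axis=1, equal_var=equal_var)
    t_ho, p_ho = stats.ttest_ind(mats[ho_label], mats[wt_label], axis=1, equal_var=equal_var)
    t_hh, p_hh = stats.ttest_ind(mats[het_label], mats[ho_label], axis=1, equal_var=equal_var)

    q = multipletests(np.concatenate([p_het, p_ho]), method="fdr_bh")[1]
    q_het, q_ho = q[: len(genes)], q[len(genes):]
    table = pd.DataFrame(
        {
            "t_het_vs_wt": t_het,
            "p_het_vs_wt": p_het,
            "q_het_vs_wt": q_het,
            "t_ho_vs_wt": t_ho,
            "p_ho_vs_wt": p_ho,
            "q_ho_vs_wt": q_ho,
            "t_het_vs_ho": t_hh,
            "p_het_vs_ho": p_hh,
        },
        index=pd.Index(genes, name="gene"),
    )
    table["significant"] = np.minimum(q_het, q_ho) < alpha
    return table


def secreted_filter(result: pd.DataFrame, annot: AnnotationTable) -> list[str]:
    """Significant genes annotated as secreted.

    Genes the annotation does not cover are excluded (logged).
    """
    significant = result.index[result["significant"]].astype(str)
    uncovered = [g for g in significant if not annot.covers(g)]
    if uncovered:
        logger.info(
            "secreted_filter: %d significant genes lack annotation: %s",
            len(uncovered),
            uncovered[:5],
        )
    return [g for g in significant if annot.covers(g) and annot.is_secreted(g)]
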