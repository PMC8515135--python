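"""End-to-end translatable-components workflow.

Chains the pipeline stages in their fixed order: homolog filter ->
(optional differential-expression screen on unstandardized values) ->
z-score -> human PCA -> mouse projection -> consensus LASSO -> final
linear model -> per-component age-decoupling F-test -> three-way
intersection. Returned as a single result object so examples, tests and
the acceptance script share one entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .age import age_decoupling_table
from .io import ExpressionStudy, HomologMap
from .pca import PCAModel, ProjectedScores, fit_pca, project
from .preprocess import encode_phenotype, homolog_filter, select_degs, zscore_genes
from .selection import (
    ConsensusSelection,
    TranslatableModel,
    consensus_lasso,
    fit_final_model,
    intersect_translatable,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one human-vs-mouse case study."""

    pca: PCAModel
    projected: ProjectedScores
    phenotype: pd.Series
    consensus: ConsensusSelection
    final_model: TranslatableModel | None
    age_table: pd.DataFrame | None
    translatable: list[str]

    @property
    def selection_failed(self) -> bool:
        return self.final_model is None


def run_pipeline(
    human: ExpressionStudy,
    mouse: ExpressionStudy,
    hmap: HomologMap,
    *,
    deg_alpha: float | None = None,
    deg_cap: int | None = None,
    var_cum: float = 0.95,
    var_each: float = 0.01,
    repeats: int = 10,
    folds: int = 5,
    lasso_per_fold: int = 1,
    threshold: float = 0.40,
    coef_alpha: float = 0.05,
    age_threshold: float = 0.01,
    phenotype_map: dict[str, int] | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full cross-species case study.

    ``deg_alpha=None`` skips the differential-expression screen and
    feeds all homolog-mapped genes to the PCA (the exploratory variant);
    a float enables the permissive screen at that BH threshold, with
    ``deg_cap`` optionally trimming the list.
    """
    human_f = homolog_filter(human, hmap)
    if deg_alpha is not None:
        degs = select_degs(human_f, alpha=deg_alpha, cap=deg_cap)
        keep = degs.selected_genes
        partner = human_f.partner_ids.loc[keep] if human_f.partner_ids is not None else None
        human_f = human_f.subset_genes(keep, partner_ids=partner)
    human_z = zscore_genes(human_f)
    model = fit_pca(human_z, var_cum=var_cum, var_each=var_each)

    mouse_z = zscore_genes(mouse)
    projected = project(model, mouse_z, hmap)

    y = encode_phenotype(mouse.metadata, phenotype_map)
    phenotype = pd.Series(y, index=mouse.sample_ids, name="phenotype")

    consensus = consensus_lasso(
        projected,
        y,
        repeats=repeats,
        folds=folds,
        lasso_per_fold=lasso_per_fold,
        threshold=threshold,
        seed=seed,
    )
    if not consensus.selected:
        return PipelineResult(
            pca=model,
            projected=projected,
            phenotype=phenotype,
            consensus=consensus,
            final_model=None,
            age_table=None,
            translatable=[],
        )

    final_model = fit_final_model(projected, y, consensus.selected)
    age_table = age_decoupling_table(
        projected.scores[consensus.selected],
        mouse.metadata["age"].to_numpy(),
        y,
        threshold=age_threshold,
    )
    translatable = intersect_translatable(final_model, age_table, coef_alpha=coef_alpha)
    return PipelineResult(
        pca=model,
        projected=projected,
        phenotype=phenotype,
        consensus=consensus,
        final_model=final_model,
        age_table=age_table,
        translatable=translatable,
    )
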