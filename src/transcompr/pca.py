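"""Human PCA space construction and cross-species projection.

A PCA model is fitted on a z-scored human study with genes as variables
and samples as observations. The number of retained components follows
the more restrictive of two criteria: enough components to cumulatively
explain at least ``var_cum`` of the total variance, but only components
individually explaining at least ``var_each``. Mouse samples are then
projected into the human space through a one-to-one homolog map, which
is the step that combines the two species.

Because z-scoring already centers every gene across samples, no further
centering is applied before the singular-value decomposition. PCA signs
are arbitrary, so each loading column is flipped to make its
largest-magnitude entry positive; this keeps loading tails reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionStudy, HomologMap
from .preprocess import ModelError, disease_reference_level, encode_sex

__all__ = [
    "PCAModel",
    "ProjectedScores",
    "RetentionError",
    "ProjectionError",
    "retained_components",
    "fit_pca",
    "phenotype_regression",
    "project",
]


class RetentionError(ValueError):
    """The retention rule keeps zero components."""


class ProjectionError(ValueError):
    """Projection impossible (missing partner genes)."""


@dataclass
class PCAModel:
    """Fitted principal-component model of one human study.

    ``loadings`` is genes x K with orthonormal columns; ``sample_scores``
    is samples x K; ``explained_fraction`` are the K retained variance
    fractions of the full (untruncated) decomposition, which sums to 1
    over ``full_fractions``.
    """

    gene_order: pd.Index
    loadings: np.ndarray
    explained_fraction: np.ndarray
    full_fractions: np.ndarray
    sample_scores: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def component_ids(self) -> list[str]:
        return list(self.sample_scores.columns)


@dataclass
class ProjectedScores:
    """Mouse sample scores along retained human components."""

    scores: pd.DataFrame  # samples x K
    projected_variance_fraction: pd.Series  # per component, sums to 1

    @property
    def component_ids(self) -> list[str]:
        return list(self.scores.columns)


def retained_components(
    fractions, var_cum: float = 0.95, var_each: float = 0.01
) -> int:
    """Number of components kept by the two-criterion retention rule.

    K_cum is the smallest count whose cumulative explained fraction
    reaches ``var_cum``; K_each counts components individually at or
    above ``var_each``. The more restrictive (minimum) wins.
    """
    fr = np.asarray(fractions, dtype=float)
    cum = np.cumsum(fr)
    reached = np.nonzero(cum >= var_cum - 1e-12)[0]
    k_cum = int(reached[0]) + 1 if reached.size else len(fr)
    k_each = int((fr >= var_each - 1e-12).sum())
    return min(k_cum, k_each)


def fit_pca(
    study: ExpressionStudy, var_cum: float = 0.95, var_each: float = 0.01
) -> PCAModel:
    """Fit the PCA model of a z-scored study.

    Raises :class:`RetentionError` if the retention rule keeps nothing.
    """
    if study.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples")
    A = study.values.to_numpy().T  # samples x genes; genes already centered
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    ss = s**2
    fractions = ss / ss.sum()
    k = retained_components(fractions, var_cum=var_cum, var_each=var_each)
    if k == 0:
        raise RetentionError(
            f"retention rule keeps 0 components (top fraction {fractions[0]:.4g})"
        )
    loadings = Vt[:k].T.copy()  # genes x k
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAModel(
        gene_order=study.gene_ids.copy(),
        loadings=loadings,
        explained_fraction=fractions[:k].copy(),
        full_fractions=fractions.copy(),
        sample_scores=pd.DataFrame(scores, index=study.sample_ids, columns=cols),
    )


def phenotype_regression(model: PCAModel, metadata: pd.DataFrame) -> pd.DataFrame:
    """Relate per-sample component scores to age, sex and disease.

    For each retained component, fits score ~ intercept + age + sex +
    disease by ordinary least squares and reports each term's t-value
    and p-value. Disease enters numerically when binary (t reported);
    with more than two levels it enters as treatment-coded indicators
    and the reported p is the omnibus partial F-test (t is NaN).
    """
    meta = metadata.loc[model.sample_scores.index]
    age = meta["age"].astype(float).to_numpy()
    sex = encode_sex(meta["sex"])

    if "disease_code" in meta.columns and meta["disease_code"].notna().all():
        dvals = meta["disease_code"].astype(float)
    else:
        dvals = meta["disease_label"].astype(str)
    levels = sorted(pd.unique(dvals))
    if len(levels) < 2:
        raise ModelError("disease has a single level")
    binary = len(levels) == 2
    if isinstance(levels[0], str):
        ref = disease_reference_level(levels)
    else:
        ref = levels[0]  # numeric codes: baseline is the smallest
    others = [lev for lev in levels if lev != ref]
    dcols = [(dvals == lev).astype(float).to_numpy() for lev in others]

    n = len(meta)
    X = np.column_stack([np.ones(n), age, sex, *dcols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("phenotype design matrix is rank-deficient")
    Xn = X[:, :3]  # intercept + age + sex, for the disease partial F
    q_dis = X.shape[1] - 3

    rows = []
    for pc in model.sample_scores.columns:
        y = model.sample_scores[pc].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        rss_full = resid @ resid
        beta_n, _, _, _ = np.linalg.lstsq(Xn, y, rcond=None)
        rss_null = np.sum((y - Xn @ beta_n) ** 2)
        if sigma2 > 0:
            f_dis = ((rss_null - rss_full) / q_dis) / (rss_full / dof)
            p_dis_omnibus = float(stats.f.sf(max(f_dis, 0.0), q_dis, dof))
        else:
            p_dis_omnibus = 0.0
        rows.append(
            {
                "component": pc,
                "t_age": tvals[1],
                "p_age": pvals[1],
                "t_sex": tvals[2],
                "p_sex": pvals[2],
                "t_disease": tvals[3] if binary else np.nan,
                "p_disease": pvals[3] if binary else p_dis_omnibus,
            }
        )
    return pd.DataFrame(rows).set_index("component")


def project(
    model: PCAModel, mouse: ExpressionStudy, hmap: HomologMap
) -> ProjectedScores:
    """Project a z-scored mouse study into the human component space.

    Mouse rows are re-ordered to the model's human gene order through
    the one-to-one homolog map; scores are the matrix product of the
    aligned sample profiles with the human loadings. The per-component
    projected-variance fraction uses the total over retained components
    as its denominator.
    """
    h2m = hmap.human_to_mouse()
    mouse_genes = set(mouse.gene_ids)
    missing = [
        g for g in model.gene_order if h2m.get(g) not in mouse_genes
    ]
    if missing:
        raise ProjectionError(
            f"{len(missing)} model genes lack a mouse partner in the study; "
            f"first few: {missing[:5]}"
        )
    aligned = mouse.values.loc[[h2m[g] for g in model.gene_order]].to_numpy()
    S = aligned.T @ model.loadings  # samples x K
    total = float((S**2).sum())
    if total <= 0:
        raise ProjectionError("projected scores are identically zero")
    pvf = (S**2).sum(axis=0) / total
    cols = model.sample_scores.columns
    return ProjectedScores(
        scores=pd.DataFrame(S, index=mouse.sample_ids, columns=cols),
        projected_variance_fraction=pd.Series(pvf, index=cols),
    )
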