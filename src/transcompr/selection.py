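"""Translatable-component selection.

Mouse scores along human components are regressed against the ordinal
mouse phenotype (WT/HET/HO -> 0/1/2) with L1-penalized least squares
inside a repeated, stratified cross-validation scheme. A component is
consensus-selected when its coefficient is nonzero in at least a fixed
fraction (default 40%) of the repeats x folds runs. The surviving
components feed an ordinary least-squares final model whose quality
metric is the root mean square error over leave-one-out predictions.

Within each run the penalty is chosen once by inner 5-fold
cross-validation on the training fold — by default the one-standard-
error rule (the largest penalty whose mean CV error is within one
standard error of the minimum), the parsimonious convention of
cross-validated LASSO workflows; ``alpha_rule="min"`` selects the
error-minimizing penalty instead. The run's selection is the nonzero
coefficient set of a single fit on the training fold at that penalty
(``lasso_per_fold > 1`` instead unions nonzero sets over that many
bootstrap refits). Under the 1-SE rule a phenotype carrying no signal
drives the penalty to its null-model maximum and the run selects
nothing, which is what makes permutation nulls informative; bootstrap
refits deliberately perturb the data away from the penalty that was
tuned for it and therefore re-activate features even on pure noise,
which is why the single-fit run is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .pca import ProjectedScores

__all__ = [
    "SelectionError",
    "ConsensusSelection",
    "TranslatableModel",
    "consensus_lasso",
    "fit_final_model",
    "intersect_translatable",
]


class SelectionError(ValueError):
    """Consensus selection cannot run or produced nothing usable."""


def _as_frame(scores) -> pd.DataFrame:
    if isinstance(scores, ProjectedScores):
        return scores.scores
    if isinstance(scores, pd.DataFrame):
        return scores
    arr = np.asarray(scores, dtype=float)
    return pd.DataFrame(arr, columns=[f"PC{j + 1}" for j in range(arr.shape[1])])


def stratified_fold_assignment(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign samples to folds keeping phenotype classes represented.

    Members of each class are shuffled and dealt round-robin, with a
    rotating starting fold so fold sizes stay balanced. Classes smaller
    than the fold count trigger a warning and best-effort placement.
    """
    y = np.asarray(y)
    assign = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < folds:
            warnings.warn(
                f"phenotype class {cls!r} has {len(idx)} samples for {folds} folds; "
                "stratification is best-effort",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i, ix in enumerate(idx):
            assign[ix] = (i + offset) % folds
        offset += len(idx)
    return assign


@dataclass
class ConsensusSelection:
    """Selection frequencies over all cross-validation runs."""

    frequencies: pd.Series  # per component, in [0, 1]
    threshold: float
    selected: list[str]
    n_runs: int
    run_log: list[dict] = field(default_factory=list, repr=False)


def _choose_alpha(cv_fit: LassoCV, rule: str) -> float:
    """Penalty from a fitted CV path: error-minimizing or 1-SE rule."""
    if rule == "min":
        return float(cv_fit.alpha_)
    if rule != "1se":
        raise ValueError(f"alpha_rule must be 'min' or '1se', got {rule!r}")
    mse = cv_fit.mse_path_  # n_alphas x n_folds, alphas descending
    mean = mse.mean(axis=1)
    i_min = int(np.argmin(mean))
    se = mse[i_min].std(ddof=1) / np.sqrt(mse.shape[1])
    within = np.nonzero(mean <= mean[i_min] + se)[0]
    return float(cv_fit.alphas_[within[0]])  # largest qualifying penalty


def consensus_lasso(
    scores,
    phenotype,
    repeats: int = 10,
    folds: int = 5,
    lasso_per_fold: int = 1,
    threshold: float = 0.40,
    seed: int = 0,
    alpha_rule: str = "1se",
    n_alphas: int = 50,
    max_iter: int = 20_000,
) -> ConsensusSelection:
    """Consensus feature selection over repeats x folds LASSO runs.

    Fold partitions are re-drawn per repeat. A component counts as
    selected in a run when its coefficient is nonzero at the
    inner-CV-chosen penalty (with ``lasso_per_fold > 1``, in any of that
    many bootstrap refits); components whose run frequency reaches
    ``threshold`` (ties count as selected) are returned.
    Bit-reproducible for a fixed ``seed``.
    """
    frame = _as_frame(scores)
    X = frame.to_numpy(dtype=float)
    comp_ids = list(frame.columns)
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(X):
        raise SelectionError("phenotype length does not match score rows")
    if np.unique(y).size < 2:
        raise SelectionError("phenotype is constant; nothing to select against")
    if len(y) < folds * 2:
        raise SelectionError(f"need at least {folds * 2} samples for {folds} folds")

    rng = np.random.default_rng(seed)
    counts = np.zeros(len(comp_ids))
    run_log: list[dict] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(repeats):
            assign = stratified_fold_assignment(y, folds, rng)
            for f in range(folds):
                tr = assign != f
                Xtr, ytr = X[tr], y[tr]
                inner = KFold(
                    n_splits=min(5, len(ytr)), shuffle=True,
                    random_state=int(rng.integers(2**31)),
                )
                cv_fit = LassoCV(
                    cv=inner, alphas=n_alphas, max_iter=max_iter
                ).fit(Xtr, ytr)
                alpha = _choose_alpha(cv_fit, alpha_rule)
                sel = np.zeros(len(comp_ids), dtype=bool)
                if lasso_per_fold <= 1:
                    fit = Lasso(alpha=alpha, max_iter=max_iter).fit(Xtr, ytr)
                    sel |= fit.coef_ != 0
                else:
                    for _ in range(lasso_per_fold):
                        bs = rng.integers(0, len(ytr), len(ytr))
                        fit = Lasso(alpha=alpha, max_iter=max_iter).fit(Xtr[bs], ytr[bs])
                        sel |= fit.coef_ != 0
                counts += sel
                run_log.append(
                    {
                        "repeat": r,
                        "fold": f,
                        "alpha": alpha,
                        "nonzero": [c for c, s in zip(comp_ids, sel) if s],
                    }
                )
    n_runs = repeats * folds
    freq = pd.Series(counts / n_runs, index=comp_ids)
    selected = [c for c in comp_ids if freq[c] >= threshold - 1e-12]
    return ConsensusSelection(
        frequencies=freq,
        threshold=threshold,
        selected=selected,
        n_runs=n_runs,
        run_log=run_log,
    )


@dataclass
class TranslatableModel:
    """Final ordinary least-squares model on consensus-selected components."""

    selected: list[str]
    intercept: float
    coefficients: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    loo_rmse: float
    loo_predictions: pd.Series
    in_sample_rmse: float


def fit_final_model(scores, phenotype, selected_ids: list[str]) -> TranslatableModel:
    """OLS of phenotype on the selected component scores, with LOO RMSE.

    Leave-one-out predictions use the exact hat-matrix identity
    e_loo = e / (1 - h), which agrees with refitting on n-1 samples.
    Raises :class:`SelectionError` when the selection is empty — a
    meaningful outcome the significance machinery records as a failure.
    """
    if not selected_ids:
        raise SelectionError("selection failed: no components selected")
    frame = _as_frame(scores)
    missing = [c for c in selected_ids if c not in frame.columns]
    if missing:
        raise SelectionError(f"unknown component ids: {missing}")
    X = frame[list(selected_ids)].to_numpy(dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise SelectionError(f"need n > {k + 1} samples for {k} components, have {n}")
    Xd = np.column_stack([np.ones(n), X])
    Q, R = np.linalg.qr(Xd)
    beta = np.linalg.solve(R, Q.T @ y)
    fitted = Xd @ beta
    resid = y - fitted
    h = (Q**2).sum(axis=1)
    loo_resid = resid / (1.0 - h)
    loo_pred = y - loo_resid
    loo_rmse = float(np.sqrt(np.mean(loo_resid**2)))
    in_rmse = float(np.sqrt(np.mean(resid**2)))

    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof
    Rinv = np.linalg.inv(R)
    cov = sigma2 * (Rinv @ Rinv.T)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    names = list(selected_ids)
    return TranslatableModel(
        selected=names,
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=names),
        tvalues=pd.Series(tvals[1:], index=names),
        pvalues=pd.Series(pvals[1:], index=names),
        loo_rmse=loo_rmse,
        loo_predictions=pd.Series(loo_pred, index=frame.index),
        in_sample_rmse=in_rmse,
    )


def intersect_translatable(
    model: TranslatableModel,
    age_results: pd.DataFrame,
    coef_alpha: float = 0.05,
) -> list[str]:
    """Components surviving all three criteria.

    (a) consensus-selected (they are the model's inputs), (b)
    significant in the final model at ``coef_alpha``, and (c) passing
    the age-decoupling F-test (``passed`` column of ``age_results``).
    An empty intersection is a valid result, not an error.
    """
    out = []
    for comp in model.selected:
        if model.pvalues[comp] >= coef_alpha:
            continue
        if comp not in age_results.index or not bool(age_results.loc[comp, "passed"]):
            continue
        out.append(comp)
    return out
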