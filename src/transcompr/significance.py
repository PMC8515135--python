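"""Empirical significance of the translatable model.

Two null constructions, both scored by leave-one-out RMSE against the
observed model:

* random-component nulls — size-matched random subsets of the retained
  components, fitted by OLS exactly like the true model (up to a cap,
  default 1000; when the subset space is small enough every non-true
  subset is enumerated instead);
* phenotype-permutation nulls — unique shuffles of the phenotype vector
  pushed through the *full* consensus-LASSO + final-model pipeline.
  Permuted runs where no component reaches the consensus threshold are
  recorded as failures and excluded from the RMSE distribution; all
  runs failing is itself an informative outcome.

The empirical p-value uses the add-one rule
p = (1 + #{null RMSE <= observed}) / (1 + #successful nulls),
so p is never zero and ties count against the observed model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .selection import SelectionError, consensus_lasso, fit_final_model

__all__ = ["NullDistribution", "empirical_p_value", "random_pc_null", "permutation_null"]


def empirical_p_value(observed: float, null_values) -> float:
    """Add-one empirical p: (1 + #{null <= observed}) / (1 + #null)."""
    null_values = np.asarray(list(null_values), dtype=float)
    return (1.0 + int((null_values <= observed).sum())) / (1.0 + len(null_values))


@dataclass
class NullDistribution:
    """Null RMSE values from one scheme plus the resulting empirical p."""

    scheme: str  # "random_pc" | "permuted_phenotype"
    rmses: np.ndarray
    failures: int
    n_attempted: int
    observed_rmse: float
    empirical_p: float | None
    status: str = "ok"
    notes: dict = field(default_factory=dict, repr=False)


def random_pc_null(
    scores,
    phenotype,
    selected_ids: list[str],
    cap: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Size-matched random-component null distribution.

    Draws up to ``cap`` distinct k-subsets of the available components
    (k = size of the true selection), never including the true set; if
    there are at most ``cap`` non-true subsets they are enumerated
    exhaustively. Each subset gets the same OLS + LOO-RMSE treatment as
    the true model.
    """
    from .selection import _as_frame  # local import to avoid cycle at module load

    frame = _as_frame(scores)
    comp_ids = list(frame.columns)
    k = len(selected_ids)
    if k == 0:
        raise SelectionError("true selection is empty; no size to match")
    if k > len(comp_ids):
        raise SelectionError("selection larger than available components")
    true_set = frozenset(selected_ids)
    total = math.comb(len(comp_ids), k)
    if total == 1:
        raise SelectionError(
            "only one size-matched subset exists; empirical p undefined"
        )
    observed = fit_final_model(frame, phenotype, list(selected_ids)).loo_rmse

    rng = np.random.default_rng(seed)
    subsets: list[tuple[str, ...]] = []
    if total - 1 <= cap:
        for combo in combinations(comp_ids, k):
            if frozenset(combo) != true_set:
                subsets.append(combo)
    else:
        seen = {true_set}
        while len(subsets) < cap:
            draw = frozenset(rng.choice(len(comp_ids), size=k, replace=False))
            key = frozenset(comp_ids[i] for i in draw)
            if key in seen:
                continue
            seen.add(key)
            subsets.append(tuple(sorted(key, key=comp_ids.index)))

    rmses = np.array(
        [fit_final_model(frame, phenotype, list(sub)).loo_rmse for sub in subsets]
    )
    p = empirical_p_value(observed, rmses)
    return NullDistribution(
        scheme="random_pc",
        rmses=rmses,
        failures=0,
        n_attempted=len(subsets),
        observed_rmse=observed,
        empirical_p=p,
        notes={"k": k, "enumerated": total - 1 <= cap},
    )


def _count_distinct_permutations(y: np.ndarray) -> int:
    _, counts = np.unique(y, return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permutation_null(
    scores,
    phenotype,
    n: int = 100,
    seed: int = 0,
    observed_rmse: float | None = None,
    repeats: int = 10,
    folds: int = 5,
    lasso_per_fold: int = 1,
    threshold: float = 0.40,
) -> NullDistribution:
    """Phenotype-permutation null distribution.

    Each of ``n`` unique permutations (none equal to the observed
    vector) goes through consensus LASSO and, if any component survives
    the threshold, the final OLS model; otherwise the run is a failure.
    If fewer than ``n`` distinct non-observed permutations exist, all
    of them are used. When ``observed_rmse`` is not supplied it is
    computed by running the same pipeline on the true phenotype.
    """
    from .selection import _as_frame

    frame = _as_frame(scores)
    y = np.asarray(phenotype, dtype=float)
    if np.unique(y).size < 2:
        raise SelectionError("phenotype is constant; cannot permute")
    rng = np.random.default_rng(seed)

    if observed_rmse is None:
        sel = consensus_lasso(
            frame, y, repeats=repeats, folds=folds,
            lasso_per_fold=lasso_per_fold, threshold=threshold,
            seed=int(rng.integers(2**31)),
        )
        if not sel.selected:
            raise SelectionError("true phenotype fails consensus selection")
        observed_rmse = fit_final_model(frame, y, sel.selected).loo_rmse

    total = _count_distinct_permutations(y)
    perms: list[np.ndarray] = []
    y_key = tuple(y)
    if total - 1 <= n:
        for perm in multiset_permutations(list(y)):
            if tuple(perm) != y_key:
                perms.append(np.asarray(perm, dtype=float))
    else:
        seen = {y_key}
        while len(perms) < n:
            draw = rng.permutation(y)
            key = tuple(draw)
            if key in seen:
                continue
            seen.add(key)
            perms.append(draw)

    rmses: list[float] = []
    failures = 0
    for perm in perms:
        sel = consensus_lasso(
            frame, perm, repeats=repeats, folds=folds,
            lasso_per_fold=lasso_per_fold, threshold=threshold,
            seed=int(rng.integers(2**31)),
        )
        if not sel.selected:
            failures += 1
            continue
        rmses.append(fit_final_model(frame, perm, sel.selected).loo_rmse)

    rmse_arr = np.asarray(rmses, dtype=float)
    if len(rmse_arr):
        p = empirical_p_value(observed_rmse, rmse_arr)
        status = "ok"
    else:
        p = None
        status = "no successful nulls"
    return NullDistribution(
        scheme="permuted_phenotype",
        rmses=rmse_arr,
        failures=failures,
        n_attempted=len(perms),
        observed_rmse=observed_rmse,
        empirical_p=p,
        status=status,
        notes={"distinct_permutations": total},
    )
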