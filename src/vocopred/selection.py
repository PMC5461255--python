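"""VIP-based variable selection nested in leave-one-out cross-validation.

The inference engine of the pipeline: for each candidate variable count j,
every leave-one-out fold re-ranks the 13 predictors by VIP on its own
training set, keeps the top j, refits a two-component PLS model and predicts
the held-out subject with 0 (training mean), 1 and 2 components.  Component
significance is assessed by a paired sign-flip permutation test on the
squared out-of-fold prediction errors; model fit by the mean squared error
of prediction (MSEP).

Selection inside the training fold is the point: ranking variables on the
full sample before cross-validating leaks the held-out response into the
model choice and optimistically biases the MSEP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls

__all__ = [
    "SelectionCVResult",
    "FinalEvaluation",
    "rank_by_vip",
    "loocv_with_selection",
    "paired_permutation_test",
    "msep",
    "rmsep",
    "sweep_variable_counts",
    "subgroup_tests",
    "evaluate_final",
    "univariate_correlations",
    "rerun_excluding_zero_scores",
    "exhaustive_subset_regression",
]


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _prep(X, y, variable_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = (
            list(variable_names)
            if variable_names is not None
            else [f"x{j + 1}" for j in range(X.shape[1])]
        )
    y = np.asarray(y, dtype=float).ravel()
    return X, y, names


def msep(predictions, y) -> float:
    """Mean squared error of prediction."""
    predictions = np.asarray(predictions, float)
    y = np.asarray(y, float)
    return float(np.mean((predictions - y) ** 2))


def rmsep(predictions, y) -> float:
    """Root mean squared error of prediction."""
    return float(np.sqrt(msep(predictions, y)))


def rank_by_vip(X_train, y_train, *, n_components: int = 2, scale: bool = True,
                variable_names=None) -> np.ndarray:
    """Variable ordering by descending VIP of a preliminary PLS model fitted
    with ``n_components`` components on the full candidate set.

    Ties are broken by canonical (input) variable order.  Returns column
    indices into ``X_train``.
    """
    X, y, names = _prep(X_train, y_train, variable_names)
    model = pls.fit(X, y, n_components, scale=scale, variable_names=names)
    scores = pls.vip(model)
    # stable sort on -VIP keeps canonical order among ties
    return np.argsort(-scores, kind="stable")


@dataclass
class SelectionCVResult:
    """Out-of-fold results of one selection-inside-LOOCV run at a fixed
    variable count j."""

    j: int
    predictions: dict[int, np.ndarray]  # components -> per-subject oof preds
    selected_sets: list[list[int]]      # per-fold selected column indices
    msep: dict[int, float]              # components -> MSEP
    p_component1: float | None = None   # 1-component model vs null
    p_component2: float | None = None   # 2-component model vs 1-component
    group_pvalues: dict | None = None
    n_perm: int = 0
    seed: int | None = None
    y: np.ndarray | None = field(default=None, repr=False)

    def errors(self, a: int) -> np.ndarray:
        return self.predictions[a] - self.y


def paired_permutation_test(errors_model, errors_reference, n_perm: int = 10000,
                            seed=None) -> float:
    """One-sided sign-flip permutation test on paired squared prediction
    errors.

    The statistic is the mean of ``d_i = e_ref,i^2 - e_model,i^2`` (reference
    minus candidate); large positive values mean the candidate model reduces
    the prediction error.  The null distribution is generated by independent
    random sign flips of the ``d_i``; ``p = (#{permuted >= observed} + 1) /
    (n_perm + 1)``, so p can never fall below ``1/(n_perm+1)``.
    """
    ea = np.asarray(errors_model, float)
    eb = np.asarray(errors_reference, float)
    if ea.shape != eb.shape:
        raise ValueError("paired error vectors must have equal length")
    d = eb**2 - ea**2
    observed = d.mean()
    rng = np.random.default_rng(seed)
    n = len(d)
    # batched sign flips; 10000 x n fits comfortably in memory at n ~ 40
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    permuted = signs @ d / n
    return float((np.count_nonzero(permuted >= observed) + 1) / (n_perm + 1))


def _loocv_predictions(X, y, max_components: int, *, scale: bool = True,
                       columns=None) -> np.ndarray:
    """Leave-one-out out-of-fold predictions without selection.

    Returns an ``(n, max_components+1)`` array; column a holds the
    a-component predictions (column 0 is the training-fold mean)."""
    n = len(y)
    cols = np.arange(X.shape[1]) if columns is None else np.asarray(columns)
    out = np.empty((n, max_components + 1))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = pls.fit(X[mask][:, cols], y[mask], max_components, scale=scale)
        out[i, 0] = y[mask].mean()
        for a in range(1, max_components + 1):
            out[i, a] = pls.predict(model, X[i : i + 1, cols],
                                    min(a, model.n_components))[0]
        mask[i] = True
    return out


def loocv_with_selection(X, y, j: int, *, n_components: int = 2,
                         scale: bool = True, leaky: bool = False,
                         n_perm: int = 10000, seed=None, groups=None,
                         variable_names=None) -> SelectionCVResult:
    """Leave-one-out cross-validation with VIP selection inside each
    training fold.

    For each held-out subject: rank the variables by VIP of a preliminary
    2-component PLS model fitted on the training fold only, keep the top
    ``j``, refit on the training fold and predict the held-out subject with
    the null (training-mean), 1- and 2-component models.

    ``leaky=True`` deliberately ranks once on the full sample — the biased
    variant the nested design exists to avoid; it is provided for the
    anti-leakage diagnostic only.

    With ``n_perm > 0`` the component p-values (1-component vs null,
    2-component vs 1-component) are attached, and per-age-group p-values
    when ``groups`` is given.
    """
    X, y, names = _prep(X, y, variable_names)
    n, p = X.shape
    if not 2 <= j <= p:
        raise ValueError(f"j must lie in [2, {p}], got {j}")
    if n < 4:
        raise ValueError("need at least 4 subjects for nested LOOCV")
    if X.std(axis=0, ddof=1).min() < 1e-12:
        raise ValueError("degenerate (zero-variance) predictor in the data")

    leak_order = rank_by_vip(X, y, n_components=n_components, scale=scale) if leaky else None

    preds = np.empty((n, n_components + 1))
    selected_sets: list[list[int]] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        if yt.std() < 1e-12:
            raise ValueError("degenerate training response (zero variance)")
        order = leak_order if leaky else rank_by_vip(
            Xt, yt, n_components=n_components, scale=scale
        )
        keep = np.sort(order[:j])
        selected_sets.append(keep.tolist())
        model = pls.fit(Xt[:, keep], yt, n_components, scale=scale)
        preds[i, 0] = yt.mean()
        for a in range(1, n_components + 1):
            preds[i, a] = pls.predict(model, X[i : i + 1, keep],
                                      min(a, model.n_components))[0]
        mask[i] = True

    predictions = {a: preds[:, a].copy() for a in range(n_components + 1)}
    msep_by_a = {a: msep(predictions[a], y) for a in predictions}
    result = SelectionCVResult(
        j=j,
        predictions=predictions,
        selected_sets=selected_sets,
        msep=msep_by_a,
        n_perm=n_perm,
        seed=seed,
        y=y,
    )
    if n_perm > 0:
        ss = _seedseq(seed)
        s1, s2 = ss.spawn(2)
        e0 = predictions[0] - y
        e1 = predictions[1] - y
        result.p_component1 = paired_permutation_test(e1, e0, n_perm, s1)
        if n_components >= 2:
            e2 = predictions[2] - y
            result.p_component2 = paired_permutation_test(e2, e1, n_perm, s2)
        if groups is not None:
            result.group_pvalues = subgroup_tests(result, groups, n_perm=n_perm,
                                                  seed=ss.spawn(1)[0])
    return result


def subgroup_tests(result: SelectionCVResult, groups, *, n_perm: int = 10000,
                   seed=None) -> dict:
    """Component permutation tests restricted to each age group.

    The model is always trained on the whole sample (the out-of-fold
    predictions in ``result`` already embody that); only the paired error
    differences entering the test are restricted to one group at a time.
    """
    groups = np.asarray(groups)
    if result.y is None or len(groups) != len(result.y):
        raise ValueError("groups must align with the cross-validated subjects")
    labels = pd.unique(groups)
    out: dict = {}
    ss = _seedseq(seed)
    children = ss.spawn(2 * len(labels))
    for k, lab in enumerate(labels):
        sel = groups == lab
        if sel.sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")
        e0 = result.errors(0)[sel]
        e1 = result.errors(1)[sel]
        entry = {
            "component1": paired_permutation_test(e1, e0, n_perm, children[2 * k])
        }
        if 2 in result.predictions:
            e2 = result.errors(2)[sel]
            entry["component2"] = paired_permutation_test(
                e2, e1, n_perm, children[2 * k + 1]
            )
        out[lab] = entry
    return out


def sweep_variable_counts(X, y, j_range=None, *, n_components: int = 2,
                          scale: bool = True, n_perm: int = 10000, seed=None,
                          groups=None, variable_names=None) -> pd.DataFrame:
    """Repeat the nested-selection LOOCV for every candidate variable count.

    Starts at the two variables with highest VIP and ends with the full set.
    Returns a tidy table with one row per (j, component) holding the
    permutation p-value and the MSEP; the null-model MSEP per j is in the
    ``msep_null`` column.  ``df.attrs['results']`` keeps the per-j
    :class:`SelectionCVResult` objects.
    """
    X, y, names = _prep(X, y, variable_names)
    p = X.shape[1]
    js = list(j_range) if j_range is not None else list(range(2, p + 1))
    ss = _seedseq(seed)
    children = ss.spawn(len(js))
    rows = []
    results = {}
    for jj, child in zip(js, children):
        res = loocv_with_selection(
            X, y, jj, n_components=n_components, scale=scale,
            n_perm=n_perm, seed=child, groups=groups, variable_names=names,
        )
        results[jj] = res
        pvals = {1: res.p_component1, 2: res.p_component2}
        for a in range(1, n_components + 1):
            rows.append(
                {
                    "j": jj,
                    "component": a,
                    "p_value": pvals.get(a),
                    "msep": res.msep[a],
                    "msep_null": res.msep[0],
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    return df


@dataclass
class FinalEvaluation:
    """Selection-free LOOCV evaluation of a fixed variable set."""

    variables: list
    r: dict[int, float]              # components -> Pearson r(oof pred, y)
    p: dict[int, float | None]       # permutation p per component count
    rmsep: dict[int, float]          # 0 (null), 1, 2 components
    predictions: dict[int, np.ndarray]


def evaluate_final(X, y, selected_variables, *, n_components: int = 2,
                   scale: bool = True, n_perm: int = 10000,
                   seed=None) -> FinalEvaluation:
    """Cross-validate the chosen variable set without re-selection.

    Reports the Pearson correlation between out-of-fold predictions and the
    measured response for the 1- and 2-component models, the rMSEP of the
    null/1/2-component models, and a permutation p-value per correlation.
    The null recomputes the full LOOCV for each permuted response, so the
    reference distribution is itself cross-validated (an honest null for a
    cross-validated r at n of a few dozen).
    """
    X, y, names = _prep(X, y)
    if isinstance(selected_variables[0], str):
        cols = [names.index(v) for v in selected_variables]
        var_labels = list(selected_variables)
    else:
        cols = list(selected_variables)
        var_labels = [names[c] for c in cols]

    preds = _loocv_predictions(X, y, n_components, scale=scale, columns=cols)
    r_obs = {
        a: float(np.corrcoef(preds[:, a], y)[0, 1])
        for a in range(1, n_components + 1)
    }
    rms = {a: rmsep(preds[:, a], y) for a in range(n_components + 1)}

    pvals: dict[int, float | None] = {a: None for a in r_obs}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = {a: 0 for a in r_obs}
        for _ in range(n_perm):
            yp = rng.permutation(y)
            pp = _loocv_predictions(X, yp, n_components, scale=scale, columns=cols)
            for a in r_obs:
                sd = pp[:, a].std()
                r_perm = float(np.corrcoef(pp[:, a], yp)[0, 1]) if sd > 1e-12 else 0.0
                if r_perm >= r_obs[a]:
                    exceed[a] += 1
        pvals = {a: (exceed[a] + 1) / (n_perm + 1) for a in r_obs}

    return FinalEvaluation(
        variables=var_labels,
        r=r_obs,
        p=pvals,
        rmsep=rms,
        predictions={a: preds[:, a].copy() for a in range(n_components + 1)},
    )


def univariate_correlations(X, y, variables=None, *, n_perm: int = 10000,
                            seed=None) -> pd.DataFrame:
    """Pearson correlation of each named variable with the response, with a
    two-sided permutation p-value (response labels shuffled)."""
    X, y, names = _prep(X, y)
    if variables is None:
        cols = list(range(X.shape[1]))
    elif isinstance(variables[0], str):
        cols = [names.index(v) for v in variables]
    else:
        cols = list(variables)
    sub = X[:, cols]
    n = len(y)
    xz = (sub - sub.mean(0)) / sub.std(0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    r = xz.T @ yz / (n - 1)
    p = np.full(len(cols), np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        r_perm = np.abs(yz[perm_idx] @ xz / (n - 1))  # (n_perm, k)
        p = (np.count_nonzero(r_perm >= np.abs(r), axis=0) + 1) / (n_perm + 1)
    return pd.DataFrame({"variable": [names[c] for c in cols], "r": r, "p": p})


def rerun_excluding_zero_scores(X, y, *, groups=None, j_range=None,
                                n_selected: int = 6, n_components: int = 2,
                                scale: bool = True, n_perm: int = 10000,
                                seed=None, variable_names=None) -> dict:
    """Robustness rerun: drop subjects with a response of exactly zero and
    repeat the sweep and the selection-free final evaluation.

    Returns the primary and filtered sweeps, the two top-``n_selected``
    variable sets ranked by full-sample VIP, and their overlap.
    """
    X, y, names = _prep(X, y, variable_names)
    keep = y != 0
    ss = _seedseq(seed)
    s_primary, s_sub = ss.spawn(2)

    def one_run(Xr, yr, gr, sd):
        s1, s2 = _seedseq(sd).spawn(2)
        sweep = sweep_variable_counts(
            Xr, yr, j_range, n_components=n_components, scale=scale,
            n_perm=n_perm, seed=s1, groups=gr, variable_names=names,
        )
        order = rank_by_vip(Xr, yr, n_components=n_components, scale=scale)
        selected = [names[c] for c in order[:n_selected]]
        final = evaluate_final(
            pd.DataFrame(Xr, columns=names), yr, selected,
            n_components=n_components, scale=scale, n_perm=n_perm, seed=s2,
        )
        return {"sweep": sweep, "selected": selected, "final": final}

    groups_arr = None if groups is None else np.asarray(groups)
    primary = one_run(X, y, groups_arr, s_primary)
    sub_groups = None if groups_arr is None else groups_arr[keep]
    filtered = one_run(X[keep], y[keep], sub_groups, s_sub)
    overlap = sorted(set(primary["selected"]) & set(filtered["selected"]))
    return {
        "primary": primary,
        "excluding_zero": filtered,
        "n_removed": int(np.count_nonzero(~keep)),
        "selection_overlap": overlap,
    }


def exhaustive_subset_regression(X, y, max_size: int, *,
                                 variable_names=None) -> pd.DataFrame:
    """Enumerate all predictor subsets up to ``max_size`` and rank them by
    LOOCV MSEP of an ordinary least squares fit.

    The leave-one-out residuals use the PRESS identity
    ``e_i^{loo} = e_i / (1 - h_ii)``; an independent cross-check of the PLS
    selection, not part of the primary inference chain.
    """
    X, y, names = _prep(X, y, variable_names)
    n, p = X.shape
    if not 1 <= max_size <= p:
        raise ValueError(f"max_size must lie in [1, {p}]")
    rows = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(range(p), size):
            Z = np.column_stack([np.ones(n), X[:, subset]])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            resid = y - Z @ coef
            h = np.einsum("ij,ij->i", Z @ np.linalg.pinv(Z.T @ Z), Z)
            loo = resid / (1.0 - h)
            rows.append(
                {
                    "variables": tuple(names[c] for c in subset),
                    "size": size,
                    "msep": float(np.mean(loo**2)),
                }
            )
    return pd.DataFrame(rows).sort_values("msep").reset_index(drop=True)
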