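"""Partial least squares regression for a single response.

Implements the orthogonal-scores (NIPALS) algorithm, variable importance in
projection (VIP), and explained-variance accounting.  For a single response
the weight vector of each component has the closed form ``w = X'y / ||X'y||``,
so the fit involves no inner iteration.

Predictors are standardized to unit variance by default (the battery mixes
counts, milliseconds and seconds); the response is centered only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "fit",
    "predict",
    "vip",
    "explained_variance",
    "loadings_report",
]

_EPS = 1e-12


@dataclass
class PLSModel:
    """A fitted single-response PLS regression model.

    Attributes
    ----------
    x_center, x_scale : per-variable centering and scaling constants.
        ``x_scale`` is all ones when the model was fitted unscaled.
    y_center : response mean.
    weights : ``(p, A)`` weight matrix W (each column unit norm).
    x_loadings : ``(p, A)`` X-loading matrix P.
    y_loadings : ``(A,)`` response loadings q.
    scores : ``(n, A)`` mutually orthogonal score matrix T.
    n_components : number of components actually extracted (may be fewer
        than requested when the data are rank deficient or the response
        residual vanishes).
    variable_names : optional predictor names, aligned with the columns.
    """

    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    n_components: int
    scaled: bool = True
    variable_names: list[str] | None = None
    # Frobenius norms of the centered training data, kept for the
    # explained-variance accounting.
    _x_ss: float = field(default=0.0, repr=False)
    _y_ss: float = field(default=0.0, repr=False)

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    def coefficients(self, a: int | None = None) -> np.ndarray:
        """Regression coefficient vector on the centered/scaled data using
        the first ``a`` components: ``b = W (P'W)^{-1} q``."""
        a = self.n_components if a is None else a
        if a == 0:
            return np.zeros(self.n_variables)
        W = self.weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self) -> str:
        payload = {
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": float(self.y_center),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "n_components": self.n_components,
            "scaled": self.scaled,
            "variable_names": self.variable_names,
            "x_ss": self._x_ss,
            "y_ss": self._y_ss,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        d = json.loads(text)
        return cls(
            x_center=np.asarray(d["x_center"], float),
            x_scale=np.asarray(d["x_scale"], float),
            y_center=d["y_center"],
            weights=np.asarray(d["weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            scores=np.asarray(d["scores"], float),
            n_components=d["n_components"],
            scaled=d["scaled"],
            variable_names=d["variable_names"],
            _x_ss=d["x_ss"],
            _y_ss=d["y_ss"],
        )


def _as_matrix(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array (subjects x variables)")
    if np.isnan(X).any():
        raise ValueError("X contains missing values; exclude or impute first")
    if y is None:
        return X
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("X and y have different numbers of subjects")
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    return X, y


def fit(
    X,
    y,
    n_components: int = 2,
    *,
    scale: bool = True,
    variable_names: list[str] | None = None,
) -> PLSModel:
    """Fit a single-response PLS regression by orthogonal-scores deflation.

    Per component: ``w = X'y/||X'y||``, ``t = Xw``, ``p = X't/t't``,
    ``q = y't/t't``; X is deflated by ``t p'`` and y by ``q t``.

    Raises
    ------
    ValueError
        On missing values, fewer than 3 subjects, or a zero-variance
        variable (named in the message) when scaling is requested.
    """
    X, y = _as_matrix(X, y)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if n_components < 0:
        raise ValueError("n_components must be nonnegative")

    names = list(variable_names) if variable_names is not None else None
    x_center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scale:
        dead = np.flatnonzero(sd < _EPS)
        if dead.size:
            label = names[dead[0]] if names else f"column {dead[0]}"
            raise ValueError(f"zero-variance variable: {label}")
        x_scale = sd.copy()
    else:
        x_scale = np.ones(p)

    Xc = (X - x_center) / x_scale
    y_center = float(y.mean())
    yc = y - y_center
    x_ss = float(np.sum(Xc**2))
    y_ss = float(np.sum(yc**2))

    max_rank = min(n - 1, p)
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components exceeds the rank bound "
            f"min(n-1, p) = {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))

    Xd, yd = Xc.copy(), yc.copy()
    a_done = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < _EPS * max(1.0, np.sqrt(y_ss)):
            break  # response residual orthogonal to X: nothing left to model
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        Xd -= np.outer(t, pa)
        yd -= qa * t
        a_done += 1

    return PLSModel(
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        weights=W[:, :a_done],
        x_loadings=P[:, :a_done],
        y_loadings=q[:a_done],
        scores=T[:, :a_done],
        n_components=a_done,
        scaled=scale,
        variable_names=names,
        _x_ss=x_ss,
        _y_ss=y_ss,
    )


def predict(model: PLSModel, X_new, a: int | None = None) -> np.ndarray:
    """Predict the response for new subjects using ``a`` components.

    ``a = 0`` gives the training-mean (intercept) prediction for every row.
    """
    X_new = _as_matrix(X_new)
    a = model.n_components if a is None else a
    if a > model.n_components:
        raise ValueError(
            f"requested {a} components but the model holds {model.n_components}"
        )
    Xc = (X_new - model.x_center) / model.x_scale
    return model.y_center + Xc @ model.coefficients(a)


def fitted_values(model: PLSModel, a: int | None = None) -> np.ndarray:
    """Training-set predictions, ``y_center + T q`` restricted to ``a``
    components."""
    a = model.n_components if a is None else a
    return model.y_center + model.scores[:, :a] @ model.y_loadings[:a]


def _component_ss(model: PLSModel) -> np.ndarray:
    """Response sum of squares explained by each component,
    ``SS_a = q_a^2 t_a' t_a``."""
    tt = np.sum(model.scores**2, axis=0)
    return model.y_loadings**2 * tt


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection (Wold / Chong–Jun).

    ``VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )`` where
    ``SS_a`` is the response variance explained by component ``a``.  The
    scores satisfy ``sum_j VIP_j^2 = p``.
    """
    if model.n_components == 0:
        raise ValueError("cannot compute VIP for a zero-component model")
    p = model.n_variables
    ss = _component_ss(model)
    wnorm2 = np.sum(model.weights**2, axis=0)
    contrib = (model.weights**2 / wnorm2) @ ss
    return np.sqrt(p * contrib / ss.sum())


def explained_variance(model: PLSModel) -> dict[str, np.ndarray]:
    """Percent of predictor-space and response variance captured per
    component.

    X-share of component a is ``||t_a||^2 ||p_a||^2`` over the total centered
    (and scaled, if applicable) X sum of squares; the y-share is
    ``SS_a = q_a^2 t_a't_a`` over the centered y sum of squares.
    """
    tt = np.sum(model.scores**2, axis=0)
    pp = np.sum(model.x_loadings**2, axis=0)
    x_share = 100.0 * tt * pp / model._x_ss if model._x_ss > 0 else np.zeros_like(tt)
    y_share = (
        100.0 * _component_ss(model) / model._y_ss
        if model._y_ss > 0
        else np.zeros_like(tt)
    )
    return {"x_pct": x_share, "y_pct": y_share}


def loadings_report(model: PLSModel, variable_names: list[str] | None = None):
    """Named X-loading table for the first two components.

    Returns a pandas DataFrame with one row per variable and one column per
    component (``comp1``, ``comp2`` when available).  Reaction-time variables
    are expected to load negatively on the first component when the model is
    fitted to battery data, since low times mean good performance.
    """
    import pandas as pd

    names = variable_names or model.variable_names
    if names is None:
        names = [f"x{j + 1}" for j in range(model.n_variables)]
    n_show = min(2, model.n_components)
    data = {f"comp{a + 1}": model.x_loadings[:, a] for a in range(n_show)}
    return pd.DataFrame(data, index=list(names))
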