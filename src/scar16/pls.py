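"""Partial least squares regression with VIP-based model reduction.

The workflow mirrors the published analysis: encode mixed clinical /
biochemical predictors (continuous variables standardized, categorical
factors effect-coded with one column per level), fit a NIPALS PLS model of
one or more responses, pick the factor count by leave-one-out PRESS, drop
predictors with VIP <= 0.8, refit once, and export each response as a
raw-scale :class:`~scar16.equations.LinearEquation` whose categorical
offsets sum to zero.

The estimator :class:`PLSVIPRegressor` wraps the whole sequence in
scikit-learn fit/predict conventions; the module-level functions
(:func:`encode_design`, :func:`fit_pls`, :func:`loo_select`, :func:`vip`,
:func:`reduce_and_refit`) expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .equations import CategoricalTerm, ContinuousTerm, LinearEquation

__all__ = [
    "DesignMatrix",
    "PLSModel",
    "NipalsConvergenceError",
    "encode_design",
    "fit_pls",
    "loo_select",
    "vip",
    "reduce_and_refit",
    "PLSVIPRegressor",
]


class NipalsConvergenceError(RuntimeError):
    """NIPALS inner loop failed to converge for some factor."""


# ------------------------------------------------------------------ design

@dataclass
class DesignMatrix:
    """Standardized numeric design with the metadata needed to undo it.

    ``column_predictor``/``column_level`` map each numeric column back to
    its source predictor (and factor level for effect-coded columns), so a
    fitted model can be exported to a raw-scale equation.
    """

    X: np.ndarray
    columns: list[str]
    column_predictor: list[str]
    column_level: list[str | None]
    centers: np.ndarray
    scales: np.ndarray
    predictor_types: dict[str, str]
    factor_levels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        """Encode new rows with the training centers and scales.

        A categorical level unseen in training contributes zero to every
        indicator before centering (baseline-like handling for
        leave-one-out folds on small cohorts).
        """
        cols = []
        for j, name in enumerate(self.columns):
            pred = self.column_predictor[j]
            if self.column_level[j] is None:
                raw = pd.to_numeric(data[pred], errors="coerce").to_numpy(float)
            else:
                raw = (data[pred].astype(str) == self.column_level[j]).to_numpy(float)
            cols.append((raw - self.centers[j]) / self.scales[j])
        return np.column_stack(cols) if cols else np.empty((len(data), 0))


def encode_design(
    data: pd.DataFrame,
    predictors: Sequence[str],
    var_types: Mapping[str, str] | None = None,
) -> DesignMatrix:
    """Build a standardized design matrix from mixed-type predictors.

    Continuous predictors are centered at the sample mean and scaled by
    the sample SD (ddof=1); a k-level factor becomes k effect-coded
    indicator columns, each likewise standardized.  A constant column is
    an error (zero scale).
    """
    var_types = dict(var_types or {})
    columns: list[str] = []
    col_pred: list[str] = []
    col_level: list[str | None] = []
    raw_cols: list[np.ndarray] = []
    factor_levels: dict[str, list[str]] = {}
    ptypes: dict[str, str] = {}
    for name in predictors:
        series = data[name]
        ptype = var_types.get(name) or (
            "continuous" if series.dtype.kind in "iufc" else "categorical"
        )
        ptypes[name] = ptype
        if ptype == "continuous":
            vals = pd.to_numeric(series, errors="coerce").to_numpy(float)
            if np.isnan(vals).any():
                raise ValueError(f"predictor {name!r} has missing values")
            columns.append(name)
            col_pred.append(name)
            col_level.append(None)
            raw_cols.append(vals)
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has a single level")
            factor_levels[name] = levels
            for lvl in levels:
                columns.append(f"{name}[{lvl}]")
                col_pred.append(name)
                col_level.append(lvl)
                raw_cols.append((series.astype(str) == lvl).to_numpy(float))
    if not raw_cols:
        return DesignMatrix(
            np.empty((len(data), 0)), [], [], [],
            np.empty(0), np.empty(0), ptypes, factor_levels,
        )
    M = np.column_stack(raw_cols)
    centers = M.mean(axis=0)
    scales = M.std(axis=0, ddof=1)
    bad = [columns[j] for j in np.nonzero(scales == 0)[0]]
    if bad:
        raise ValueError(f"constant column(s) in design: {bad}")
    return DesignMatrix(
        (M - centers) / scales, columns, col_pred, col_level,
        centers, scales, ptypes, factor_levels,
    )


# ------------------------------------------------------------------- model

@dataclass
class PLSModel:
    """Fitted NIPALS PLS decomposition and its derived quantities.

    W/P are X-weights/loadings, C the Y-loadings, T the orthogonal score
    matrix; ``ss`` holds the Y-variance (on the internal standardized
    scale) explained per factor, which weights the VIP statistic.
    """

    design: DesignMatrix
    responses: list[str]
    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    T: np.ndarray
    n_factors: int
    ss: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    coef_scaled: np.ndarray  # (p, m) on standardized X and Y scales
    vip_: np.ndarray
    press_curve: list[float] | None = None

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X = self.design.transform(data)
        return self.y_mean + (X @ self.coef_scaled) * self.y_scale

    def r2(self, data: pd.DataFrame, y: pd.DataFrame) -> dict[str, float]:
        pred = self.predict(data)
        out = {}
        for r, name in enumerate(self.responses):
            resid = y[name].to_numpy(float) - pred[:, r]
            tot = y[name].to_numpy(float) - y[name].mean()
            out[name] = 1.0 - float(resid @ resid) / float(tot @ tot)
        return out

    def equation(self, response: str) -> LinearEquation:
        """Export one response as a raw-scale equation.

        Continuous terms keep the training center/scale; categorical
        factors get per-level offsets recentered to sum to zero, with the
        removed mean folded into the intercept.  Evaluation of the
        exported equation is exactly the model prediction.
        """
        r = self.responses.index(response)
        b = self.coef_scaled[:, r] * self.y_scale[r]
        intercept = float(self.y_mean[r])
        continuous: list[ContinuousTerm] = []
        categorical: list[CategoricalTerm] = []
        d = self.design
        for name in dict.fromkeys(d.column_predictor):
            idx = [j for j, p in enumerate(d.column_predictor) if p == name]
            if d.column_level[idx[0]] is None:
                j = idx[0]
                continuous.append(
                    ContinuousTerm(name, float(b[j]), float(d.centers[j]),
                                   float(d.scales[j]))
                )
            else:
                offsets = {}
                for lvl in d.factor_levels[name]:
                    contrib = 0.0
                    for j in idx:
                        ind = 1.0 if d.column_level[j] == lvl else 0.0
                        contrib += b[j] * (ind - d.centers[j]) / d.scales[j]
                    offsets[lvl] = contrib
                shift = float(np.mean(list(offsets.values())))
                intercept += shift
                categorical.append(
                    CategoricalTerm(name, {k: v - shift for k, v in offsets.items()})
                )
        return LinearEquation(response, intercept, continuous, categorical)


def _nipals(X: np.ndarray, Y: np.ndarray, n_factors: int,
            tol: float = 1e-10, max_iter: int = 500):
    """Classical NIPALS PLS2 on centered/scaled X, Y; deflates both blocks."""
    n, p = X.shape
    m = Y.shape[1]
    Xa, Ya = X.copy(), Y.copy()
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    C = np.zeros((m, n_factors))
    T = np.zeros((n, n_factors))
    ss = np.zeros(n_factors)
    actual = 0
    for a in range(n_factors):
        col_norms = (Ya**2).sum(axis=0)
        if col_norms.max() < 1e-12 or (Xa**2).sum() < 1e-12:
            break  # residual variance exhausted
        u = Ya[:, int(np.argmax(col_norms))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                break
            w /= nw
            t = Xa @ w
            tt = t @ t
            if tt < 1e-14:
                break
            c = Ya.T @ t / tt
            cc = c @ c
            if cc < 1e-14:
                break
            u = Ya @ c / cc
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1e-30):
                break
            t_old = t
        else:
            raise NipalsConvergenceError(
                f"inner loop did not converge for factor {a + 1}"
            )
        tt = t @ t
        if tt < 1e-14 or np.linalg.norm(w) < 1e-14:
            break
        p_load = Xa.T @ t / tt
        Xa -= np.outer(t, p_load)
        Ya -= np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_load, c, t
        ss[a] = tt * (c @ c)
        actual = a + 1
    return W[:, :actual], P[:, :actual], C[:, :actual], T[:, :actual], ss[:actual]


def _vip_from(W: np.ndarray, ss: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    if W.shape[1] == 0 or ss.sum() <= 0:
        return np.zeros(p)
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), 1e-300)
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def fit_pls(
    design: DesignMatrix,
    y: pd.DataFrame | pd.Series,
    n_factors: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a PLS model with ``n_factors`` latent factors.

    Y is centered and scaled internally; coefficients are stored on the
    standardized scale together with the transform needed to predict on
    the raw response scale.  Requesting more factors than the design can
    support raises.
    """
    Y_df = y.to_frame() if isinstance(y, pd.Series) else pd.DataFrame(y)
    responses = [str(c) for c in Y_df.columns]
    Yraw = Y_df.to_numpy(float)
    n, p = design.X.shape
    max_rank = min(n - 1, p)
    if n_factors < 0 or n_factors > max_rank:
        raise ValueError(f"n_factors={n_factors} exceeds design capacity {max_rank}")
    y_mean = Yraw.mean(axis=0)
    y_scale = Yraw.std(axis=0, ddof=1)
    y_scale[y_scale == 0] = 1.0
    Ys = (Yraw - y_mean) / y_scale
    W, P, C, T, ss = _nipals(design.X, Ys, n_factors, tol=tol, max_iter=max_iter)
    if W.shape[1]:
        coef = W @ np.linalg.solve(P.T @ W, C.T)
    else:
        coef = np.zeros((p, Ys.shape[1]))
    return PLSModel(
        design=design, responses=responses, W=W, P=P, C=C, T=T,
        n_factors=W.shape[1], ss=ss, y_mean=y_mean, y_scale=y_scale,
        coef_scaled=coef, vip_=_vip_from(W, ss),
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection, one value per design column.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with unit-norm
    weight vectors; the mean of VIP^2 over columns is 1 by construction.
    """
    return model.vip_.copy()


# ------------------------------------------------------------- selection

def loo_select(
    data: pd.DataFrame,
    y: pd.DataFrame | pd.Series,
    predictors: Sequence[str],
    max_factors: int | None = None,
    var_types: Mapping[str, str] | None = None,
) -> tuple[int, list[float]]:
    """Choose the factor count by leave-one-out PRESS (first-minimum rule).

    PRESS(A) sums squared LOO prediction errors over rows and responses on
    a per-response standardized scale (full-data SD), so multi-response
    fits weight responses comparably.  A = 0 is the intercept-only model;
    the selected A is the last one before PRESS stops improving.
    """
    Y_df = y.to_frame() if isinstance(y, pd.Series) else pd.DataFrame(y)
    n = len(data)
    full_design = encode_design(data, predictors, var_types)
    if max_factors is None:
        max_factors = min(full_design.n_columns, n - 2, 15)
    max_factors = max(int(max_factors), 0)
    y_sd = Y_df.to_numpy(float).std(axis=0, ddof=1)
    y_sd[y_sd == 0] = 1.0
    press = np.zeros(max_factors + 1)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        sub = data.iloc[train]
        ysub = Y_df.iloc[train]
        try:
            design = encode_design(sub, predictors, var_types)
        except ValueError:
            # fold lost all variation in some column; fall back to mean-only
            err = (Y_df.iloc[[i]].to_numpy(float) - ysub.to_numpy(float).mean(0)) / y_sd
            press += float((err**2).sum())
            continue
        cap = min(max_factors, min(len(sub) - 1, design.n_columns))
        model = fit_pls(design, ysub, cap)
        Xi = design.transform(data.iloc[[i]])
        y_i = Y_df.iloc[[i]].to_numpy(float)
        # cumulative predictions for A = 0..cap from one decomposition
        for A in range(max_factors + 1):
            a_eff = min(A, model.n_factors)
            if a_eff == 0:
                pred = model.y_mean[None, :]
            else:
                Wp = model.W[:, :a_eff]
                coef = Wp @ np.linalg.solve(model.P[:, :a_eff].T @ Wp,
                                            model.C[:, :a_eff].T)
                pred = model.y_mean + (Xi @ coef) * model.y_scale
            err = (y_i - pred) / y_sd
            press[A] += float((err**2).sum())
    selected = 0
    for A in range(max_factors):
        if press[A + 1] < press[A] * (1.0 - 1e-9):
            selected = A + 1
        else:
            break
    return selected, press.tolist()


def reduce_and_refit(
    data: pd.DataFrame,
    y: pd.DataFrame | pd.Series,
    predictors: Sequence[str],
    cutoff: float = 0.8,
    var_types: Mapping[str, str] | None = None,
    n_factors: int | None = None,
) -> tuple[PLSModel, dict[str, LinearEquation]]:
    """One-pass VIP reduction: fit all predictors, drop VIP <= cutoff, refit.

    Returns the reduced model and one exported raw-scale equation per
    response.  See :class:`PLSVIPRegressor` for the estimator form.
    """
    est = PLSVIPRegressor(n_components=n_factors, vip_cutoff=cutoff,
                          var_types=dict(var_types) if var_types else None)
    est.fit(data[list(predictors)], y)
    return est.model_, dict(est.equations_)


# ---------------------------------------------------------------- sklearn

class PLSVIPRegressor(BaseEstimator, RegressorMixin):
    """PLS regression with LOO factor selection and one-pass VIP reduction.

    Parameters
    ----------
    n_components : int or None
        Latent factor count; ``None`` selects it by leave-one-out PRESS
        (first minimum).
    max_components : int or None
        Upper bound for the LOO search (default: design capacity, <= 15).
    vip_cutoff : float or None
        Predictors whose best column VIP is <= this are dropped before a
        single refit; a categorical factor is kept if any of its level
        columns clears the cutoff.  ``None`` disables reduction.
    var_types : mapping or None
        Optional per-predictor override, ``"continuous"`` or
        ``"categorical"`` (default: inferred from dtype).

    Attributes (after fit)
    ----------------------
    initial_model_, model_ : PLSModel for the all-predictor and reduced fits
    vip_ : VIP per design column of the initial fit
    predictor_vip_ : max column VIP per predictor
    support_ : retained predictor names
    n_components_ : factor count of the reduced fit
    press_curve_ : LOO PRESS per candidate factor count (initial fit)
    equations_ : response -> exported raw-scale LinearEquation
    r2_ : response -> training R^2 of the reduced model
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_components: int | None = None,
        vip_cutoff: float | None = 0.8,
        tol: float = 1e-10,
        max_iter: int = 500,
        var_types: dict | None = None,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.vip_cutoff = vip_cutoff
        self.tol = tol
        self.max_iter = max_iter
        self.var_types = var_types

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        Y_df = y.to_frame() if isinstance(y, pd.Series) else pd.DataFrame(y)
        if len(X) != len(Y_df):
            raise ValueError("X and y have different lengths")
        predictors = [str(c) for c in X.columns]
        if not predictors:
            raise ValueError("at least one predictor required")
        design = encode_design(X, predictors, self.var_types)

        self.press_curve_ = None
        if self.n_components is None:
            A0, press = loo_select(X, Y_df, predictors,
                                   max_factors=self.max_components,
                                   var_types=self.var_types)
            A0 = max(A0, 1)  # keep at least one factor for VIP screening
            self.press_curve_ = press
        else:
            A0 = int(self.n_components)

        initial = fit_pls(design, Y_df, A0, tol=self.tol, max_iter=self.max_iter)
        self.initial_model_ = initial
        self.vip_ = initial.vip_.copy()
        pv: dict[str, float] = {}
        for j, pred in enumerate(design.column_predictor):
            pv[pred] = max(pv.get(pred, 0.0), float(self.vip_[j]))
        self.predictor_vip_ = pv

        if self.vip_cutoff is None:
            retained = predictors
        else:
            retained = [p for p in predictors if pv[p] > self.vip_cutoff]
            if not retained:  # degenerate: keep the single most important
                retained = [max(pv, key=pv.get)]
        self.support_ = retained

        if set(retained) == set(predictors):
            model = initial
        else:
            red_design = encode_design(X, retained, self.var_types)
            if self.n_components is None:
                A1, _ = loo_select(X, Y_df, retained,
                                   max_factors=min(initial.n_factors,
                                                   red_design.n_columns),
                                   var_types=self.var_types)
                A1 = min(max(A1, 1), initial.n_factors)
            else:
                A1 = min(int(self.n_components), red_design.n_columns)
            model = fit_pls(red_design, Y_df, A1, tol=self.tol,
                            max_iter=self.max_iter)
        self.model_ = model
        self.n_components_ = model.n_factors
        self.responses_ = model.responses
        self.equations_ = {r: model.equation(r) for r in model.responses}
        self.coef_ = model.coef_scaled * model.y_scale
        self.r2_ = model.r2(X, Y_df)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        pred = self.model_.predict(pd.DataFrame(X))
        return pred[:, 0] if pred.shape[1] == 1 else pred
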