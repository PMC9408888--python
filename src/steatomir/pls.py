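"""PLS1 regression with autoscaling, LOOCV, VIP scores and permutation testing.

Single-response partial least squares (PLS1) fitted by NIPALS deflation; for
one response this is algebraically equivalent to SIMPLS.  PLS projects the
predictors onto a small number of latent variables maximizing covariance
with the response, which makes it the standard choice for p >> n collinear
omics tables (here ~154 miRNAs vs 20-23 samples).

Conventions
-----------
* Features and response are autoscaled (mean 0, unit sample SD, n-1
  denominator) before fitting; reported regression vectors are in
  autoscaled units.
* Cross-validation is leave-one-out; autoscaling is recomputed inside every
  training fold, so no information about the held-out sample leaks into the
  scaling.  RMSECV is reported in the original response units.
* The number of latent variables is chosen as the argmin of RMSECV over
  1..max_components, ties resolved toward the smaller count.
* Permutation p-values are the plain fraction of permuted models with lower
  RMSECV than the observed model (can be exactly zero); a smoothed
  (b+1)/(B+1) variant is available via ``smoothed=True``.

The user-facing surface follows the Model/Results idiom: build a
:class:`PLS1Model` from data, call :meth:`~PLS1Model.fit`, and interrogate
the returned :class:`PLS1Results`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ValidationError

__all__ = [
    "autoscale",
    "pls1_fit",
    "vip_scores",
    "loocv_rmsecv",
    "select_components",
    "permutation_test",
    "PLSFit",
    "CVResult",
    "PermutationResult",
    "PLS1Model",
    "PLS1Results",
]

_EPS = 1e-12


def autoscale(X: np.ndarray, feature_names: Optional[Sequence[str]] = None):
    """Standardize each column to mean 0, sample SD 1 (n-1 denominator).

    Returns ``(scaled, mean, sd)``.  A constant column is an error naming
    the offending feature.
    """
    X = np.asarray(X, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[:, None]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= _EPS)
    if bad.size:
        name = feature_names[bad[0]] if feature_names is not None else f"column {bad[0]}"
        raise ValidationError(f"constant feature cannot be autoscaled: {name}")
    scaled = (X - mean) / sd
    if one_d:
        return scaled[:, 0], mean[0], sd[0]
    return scaled, mean, sd


@dataclass
class PLSFit:
    """Raw NIPALS PLS1 state on autoscaled data.

    ``W`` holds unit-norm weight vectors, ``P`` the X-loadings, ``q`` the
    response loadings and ``T`` the (mutually orthogonal) score vectors, one
    column per latent variable.  Fewer than the requested number of
    components may be stored if the residual covariance vanishes.
    """

    W: np.ndarray  # (p, A)
    P: np.ndarray  # (p, A)
    q: np.ndarray  # (A,)
    T: np.ndarray  # (n, A)
    n_components: int  # requested

    @property
    def n_components_effective(self) -> int:
        return self.W.shape[1]

    def coef(self, n_components: Optional[int] = None) -> np.ndarray:
        """Regression vector b (autoscaled units) for a component truncation."""
        a = self.n_components_effective if n_components is None else min(
            n_components, self.n_components_effective
        )
        p = self.W.shape[0]
        if a == 0:
            return np.zeros(p)
        W, P, q = self.W[:, :a], self.P[:, :a], self.q[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict_components(self, Xs: np.ndarray) -> np.ndarray:
        """Cumulative predictions (scaled units) for truncations 1..A_requested.

        Returns an (n_new, n_components) matrix; if deflation stopped early
        the last attainable prediction is carried forward.
        """
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        n_new = Xs.shape[0]
        preds = np.zeros((n_new, self.n_components))
        Xd = Xs.copy()
        cum = np.zeros(n_new)
        for a in range(self.n_components):
            if a < self.n_components_effective:
                t = Xd @ self.W[:, a]
                cum = cum + t * self.q[a]
                Xd -= np.outer(t, self.P[:, a])
            preds[:, a] = cum
        return preds


def pls1_fit(Xs: np.ndarray, ys: np.ndarray, n_components: int) -> PLSFit:
    """NIPALS PLS1 on already-autoscaled X (n x p) and y (n,)."""
    Xs = np.asarray(Xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, p = Xs.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)="
            f"{min(n - 1, p)}"
        )
    Xd, yd = Xs.copy(), ys.copy()
    W, P, T, q = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        norm_w = np.linalg.norm(w)
        if norm_w <= _EPS * max(1.0, np.abs(Xd).max() * np.abs(yd).max()):
            break  # residual covariance exhausted (e.g. y orthogonal to X)
        w /= norm_w
        t = Xd @ w
        tt = t @ t
        if tt <= _EPS:
            break
        p_load = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_load)
        yd = yd - q_a * t
        W.append(w)
        P.append(p_load)
        T.append(t)
        q.append(q_a)
    a_eff = len(W)
    return PLSFit(
        W=np.column_stack(W) if a_eff else np.zeros((p, 0)),
        P=np.column_stack(P) if a_eff else np.zeros((p, 0)),
        q=np.asarray(q),
        T=np.column_stack(T) if a_eff else np.zeros((n, 0)),
        n_components=n_components,
    )


def vip_scores(fit: PLSFit, n_components: Optional[int] = None) -> np.ndarray:
    """Variable importance in projection; satisfies sum(VIP^2) = n_features.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 ||t_a||^2 the response variance explained by component a
    (weights are unit-norm, so w_aj / ||w_a|| = w_aj).
    """
    a = fit.n_components_effective if n_components is None else min(
        n_components, fit.n_components_effective
    )
    if a == 0:
        raise ValidationError("VIP requires a fitted model with >= 1 component")
    W, q, T = fit.W[:, :a], fit.q[:a], fit.T[:, :a]
    ssy = q**2 * np.einsum("ij,ij->j", T, T)
    total = ssy.sum()
    if total <= _EPS:
        raise ValidationError("zero explained response variance; VIP undefined")
    p = W.shape[0]
    return np.sqrt(p * (W**2) @ ssy / total)


def _max_feasible_components(n: int, p: int, max_components: Optional[int]) -> int:
    """Component cap under LOOCV: every fold has n-1 samples, so A <= n-2."""
    cap = min(n - 2, p)
    if max_components is not None:
        cap = min(cap, max_components)
    else:
        cap = min(cap, 10)
    if cap < 1:
        raise ValidationError("too few samples/features for cross-validated PLS")
    return cap


def _loocv_prediction_matrix(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """LOOCV predictions in raw response units, one column per component count.

    Each fold re-autoscales X and y on the n-1 training samples, fits NIPALS
    once with ``max_components`` latent variables, and reads off predictions
    for every truncation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    preds = np.empty((n, max_components))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xs, xm, xs = autoscale(X[tr])
        ys, ym, ysd = autoscale(y[tr])
        fit = pls1_fit(Xs, ys, max_components)
        x_new = (X[i] - xm) / xs
        preds[i] = ym + ysd * fit.predict_components(x_new[None, :])[0]
    return preds


@dataclass
class CVResult:
    """Leave-one-out cross-validation summary."""

    rmsecv: float
    n_components: int
    per_sample_predictions: np.ndarray  # response units, observation order


@dataclass
class PermutationResult:
    """Null distribution of RMSECV under response permutation."""

    observed_rmsecv: float
    permuted_rmsecvs: np.ndarray
    p_value: float
    B: int
    seed: int


def loocv_rmsecv(X: np.ndarray, y: np.ndarray, n_components: int) -> CVResult:
    """RMSECV at a fixed latent-variable count, leakage-free LOOCV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_components > min(n - 2, p):
        raise ValidationError(
            f"n_components={n_components} infeasible in LOOCV folds "
            f"(max {min(n - 2, p)})"
        )
    preds = _loocv_prediction_matrix(X, y, n_components)[:, n_components - 1]
    rmsecv = float(np.sqrt(np.mean((y - preds) ** 2)))
    return CVResult(rmsecv=rmsecv, n_components=n_components, per_sample_predictions=preds)


def _rmsecv_curve(X: np.ndarray, y: np.ndarray, max_components: Optional[int] = None) -> np.ndarray:
    n, p = np.asarray(X).shape
    cap = _max_feasible_components(n, p, max_components)
    preds = _loocv_prediction_matrix(X, y, cap)
    return np.sqrt(np.mean((np.asarray(y, dtype=float)[:, None] - preds) ** 2, axis=0))


def select_components(X: np.ndarray, y: np.ndarray, max_components: Optional[int] = None) -> int:
    """Latent-variable count minimizing RMSECV; ties go to the smaller count."""
    curve = _rmsecv_curve(X, y, max_components)
    return int(np.argmin(curve)) + 1  # argmin returns the first (smallest) minimizer


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_components: Optional[int] = None,
    B: int = 500,
    seed: int = 0,
    max_components: Optional[int] = None,
    smoothed: bool = False,
) -> PermutationResult:
    """Model significance by response permutation.

    Each of the B permuted responses repeats the full procedure (component
    selection by LOOCV when ``n_components`` is None, then RMSECV); the
    p-value is the fraction of permuted models with RMSECV strictly below
    the observed one.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def _rmsecv(yy: np.ndarray) -> float:
        curve = _rmsecv_curve(X, yy, max_components)
        if n_components is not None:
            return float(curve[n_components - 1])
        return float(curve.min())

    observed = _rmsecv(y)
    rng = np.random.default_rng(seed)
    permuted = np.array([_rmsecv(rng.permutation(y)) for _ in range(B)])
    better = int((permuted < observed).sum())
    p = (better + 1) / (B + 1) if smoothed else better / B
    return PermutationResult(
        observed_rmsecv=observed, permuted_rmsecvs=permuted, p_value=p, B=B, seed=seed
    )


class PLS1Model:
    """PLS1 regression model for a continuous response on a feature table.

    Parameters
    ----------
    endog : array-like, (n,)
        Response in its natural units (e.g. liver TG ug/mg protein, fat %).
    exog : array-like or DataFrame, (n, p)
        Feature table, samples in rows.  Column names become feature names.
    feature_names : sequence of str, optional
        Overrides/provides feature names for plain arrays.
    max_components : int, optional
        Cap on the latent-variable search (default min(10, n-2, p)).
    """

    def __init__(self, endog, exog, feature_names=None, max_components=None):
        if isinstance(exog, pd.DataFrame):
            if feature_names is None:
                feature_names = list(exog.columns)
            exog = exog.to_numpy()
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValidationError("exog must be (n_samples, n_features) matching endog")
        n, p = self.exog.shape
        self.feature_names = (
            list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
        )
        self.max_components = max_components

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, **kwargs) -> "PLS1Model":
        """Build from a tidy samples-by-columns DataFrame naming the response column."""
        y = data[response]
        X = data.drop(columns=[response])
        return cls(y.to_numpy(), X, **kwargs)

    def fit(self, n_components: Optional[int] = None) -> "PLS1Results":
        """Fit; when ``n_components`` is None it is selected by LOOCV RMSECV."""
        if n_components is None:
            n_components = select_components(self.exog, self.endog, self.max_components)
        Xs, xm, xsd = autoscale(self.exog, self.feature_names)
        ys, ym, ysd = autoscale(self.endog)
        fit = pls1_fit(Xs, ys, n_components)
        return PLS1Results(self, fit, (xm, xsd), (ym, ysd))


class PLS1Results:
    """Fitted PLS1 state: regression vector, VIP scores, CV error, significance."""

    def __init__(self, model: PLS1Model, fit: PLSFit, x_scale, y_scale):
        self.model = model
        self.fit_state = fit
        self.x_mean, self.x_sd = x_scale
        self.y_mean, self.y_sd = y_scale
        self.n_components = fit.n_components
        self._cv: Optional[CVResult] = None

    @property
    def params(self) -> pd.Series:
        """Regression vector on autoscaled features, autoscaled response units."""
        return pd.Series(self.fit_state.coef(), index=self.model.feature_names, name="coef")

    def predict(self, exog=None) -> np.ndarray:
        """Predictions in response units for raw-unit features (default: training data)."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            X = exog[self.model.feature_names].to_numpy()
        Xs = (np.atleast_2d(X) - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.fit_state.coef())

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def vip(self) -> pd.Series:
        """VIP scores; descending importance, sum of squares equals n_features."""
        return pd.Series(vip_scores(self.fit_state), index=self.model.feature_names, name="VIP")

    def loocv(self) -> CVResult:
        if self._cv is None:
            self._cv = loocv_rmsecv(self.model.exog, self.model.endog, self.n_components)
        return self._cv

    @property
    def rmsecv(self) -> float:
        return self.loocv().rmsecv

    def permutation_test(self, B: int = 500, seed: int = 0, smoothed: bool = False) -> PermutationResult:
        return permutation_test(
            self.model.exog,
            self.model.endog,
            n_components=None,
            B=B,
            seed=seed,
            max_components=self.model.max_components,
            smoothed=smoothed,
        )

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: model dimensions, RMSECV, top-VIP features."""
        from statsmodels.iolib.table import SimpleTable

        n, p = self.model.exog.shape
        cv = self.loocv()
        info = SimpleTable(
            [
                ["No. samples", n],
                ["No. features", p],
                ["Latent variables", self.n_components],
                ["RMSECV (LOOCV)", f"{cv.rmsecv:.4g}"],
            ],
            headers=["", ""],
            title="PLS1 regression",
        )
        vip = self.vip().sort_values(ascending=False).head(top)
        coefs = self.params
        rows = [[name, f"{vip[name]:.3f}", f"{coefs[name]:+.4f}"] for name in vip.index]
        feat = SimpleTable(rows, headers=["feature", "VIP", "coef (autoscaled)"])
        return str(info) + "\n" + str(feat)
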