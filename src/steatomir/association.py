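"""Univariate Pearson screening against the phenotype and PCA of miRNA profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import NormalizedMatrix, PhenotypeVector, ValidationError
from .pls import autoscale

__all__ = ["pearson_screen", "pca_scores", "PCAResult"]


def pearson_screen(
    values: NormalizedMatrix,
    y: PhenotypeVector,
    alpha: float = 0.05,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-miRNA Pearson correlation with the phenotype.

    The two-sided p-value comes from the exact t transform
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.  No
    multiple-testing correction is applied; ``significant`` marks p < alpha.
    A zero-variance miRNA (or phenotype) yields ``undefined = 1`` and is
    never flagged significant.

    Returns a DataFrame with columns
    ``mirna_id, r, p_value, n, significant, undefined``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must be in (0, 1]")
    mat = values.log2p1() if log_transform else values
    X = mat.values.to_numpy(dtype=float)  # miRNA x sample
    yv = y.align(mat.sample_ids)
    n = X.shape[1]
    if n < 3:
        raise ValidationError("Pearson screening needs >= 3 samples")

    yc = yv - yv.mean()
    y_ss = float(yc @ yc)
    Xc = X - X.mean(axis=1, keepdims=True)
    x_ss = np.einsum("ij,ij->i", Xc, Xc)
    undefined = (x_ss <= 0) | (y_ss <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / np.sqrt(x_ss * y_ss)
    r = np.clip(r, -1.0, 1.0)
    r[undefined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |r| = 1 exactly
    p[undefined] = np.nan

    out = pd.DataFrame(
        {
            "mirna_id": mat.mirna_ids,
            "r": r,
            "p_value": p,
            "n": n,
            "significant": ((p < alpha) & ~undefined).astype(int),
            "undefined": undefined.astype(int),
        }
    )
    return out


@dataclass
class PCAResult:
    """Sample scores and per-component explained-variance fractions."""

    scores: pd.DataFrame  # samples x components
    explained_variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        frac = self.explained_variance_fraction
        if np.any(np.diff(frac) > 1e-12) or frac.sum() > 1 + 1e-9:
            raise ValidationError("explained fractions must be nonincreasing, sum <= 1")


def pca_scores(values: NormalizedMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the autoscaled samples-by-miRNA table via SVD.

    The explained fraction of a component is its squared singular value over
    the total.  Sign convention: each component's largest-magnitude loading
    is made positive, so repeated runs are identical.
    """
    X = values.values.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)={min(n - 1, p)}"
        )
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 1e-12):
        j = int(np.flatnonzero(sd <= 1e-12)[0])
        raise ValidationError(
            f"constant feature {values.mirna_ids[j]!r}: drop constant miRNAs before PCA"
        )
    Xs, _, _ = autoscale(X)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    scores = (U * s)[:, :n_components]
    frac = (s**2 / (s**2).sum())[:n_components]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=values.sample_ids,
            columns=[f"PC{k+1}" for k in range(n_components)],
        ),
        explained_variance_fraction=frac,
    )
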