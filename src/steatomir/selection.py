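"""VIP-driven recursive feature elimination and exhaustive small-panel search.

RFE repeatedly refits a PLS1 model (latent-variable count re-selected by
LOOCV at every step), scores features by VIP, and drops the single least
important one, recording the RMSECV trajectory from the full feature set
down to one feature.  The optimal subset is read off that trace either at a
requested size or at the global RMSECV minimum.

For a small candidate panel (e.g. the 19 miRNAs selected in both tissue
arms) every 2- and 3-feature combination is fitted exhaustively and ranked
by RMSECV; a 19-feature panel yields C(19,2)=171 and C(19,3)=969 models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ValidationError
from .pls import autoscale, pls1_fit, vip_scores, _rmsecv_curve

__all__ = [
    "RFETrace",
    "CombinationModel",
    "rfe",
    "optimal_subset",
    "intersect_panels",
    "exhaustive_search",
    "combinations_to_frame",
]

_VIP_TIE_TOL = 1e-9


@dataclass
class RFEStep:
    retained_ids: tuple[str, ...]
    rmsecv: float
    n_components: int


@dataclass
class RFETrace:
    """Ordered elimination record: step sizes run p, p-1, ..., 1."""

    steps: list[RFEStep]
    eliminated_order: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, step in enumerate(self.steps):
            eliminated = self.eliminated_order[k] if k < len(self.eliminated_order) else ""
            rows.append(
                {
                    "step": k,
                    "n_features": len(step.retained_ids),
                    "rmsecv": step.rmsecv,
                    "n_components": step.n_components,
                    "eliminated_id": eliminated,
                }
            )
        return pd.DataFrame(rows)


def _as_matrix(X, feature_names):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if feature_names is None:
        raise ValidationError("feature_names required when X is a plain array")
    return np.asarray(X, dtype=float), list(feature_names)


def rfe(X, y, feature_names: Optional[Sequence[str]] = None, max_components: Optional[int] = None) -> RFETrace:
    """Recursive feature elimination by lowest VIP.

    At each step the latent-variable count is re-selected by LOOCV, the
    model refitted on all samples, and the single lowest-VIP feature
    dropped; VIP ties eliminate the lexicographically later ID first.
    """
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    if Xm.shape[1] < 2:
        raise ValidationError("RFE needs at least 2 features")

    retained = list(names)
    col = {name: j for j, name in enumerate(names)}
    steps: list[RFEStep] = []
    eliminated: list[str] = []
    while True:
        Xcur = Xm[:, [col[name] for name in retained]]
        curve = _rmsecv_curve(Xcur, y, max_components)
        a = int(np.argmin(curve)) + 1
        steps.append(RFEStep(tuple(retained), float(curve[a - 1]), a))
        if len(retained) == 1:
            break
        Xs, _, _ = autoscale(Xcur, retained)
        ys, _, _ = autoscale(y)
        vip = vip_scores(pls1_fit(Xs, ys, a))
        worst = vip.min()
        ties = [name for name, v in zip(retained, vip) if v <= worst + _VIP_TIE_TOL]
        drop = max(ties)  # lexicographically later ID goes first
        eliminated.append(drop)
        retained.remove(drop)
    return RFETrace(steps=steps, eliminated_order=eliminated)


def optimal_subset(trace: RFETrace, target_size: Optional[int] = None) -> list[str]:
    """Retained IDs at a requested size, or at the global RMSECV minimum
    (ties resolved toward the smaller subset)."""
    if not trace.steps:
        raise ValidationError("empty RFE trace")
    if target_size is not None:
        for step in trace.steps:
            if len(step.retained_ids) == target_size:
                return list(step.retained_ids)
        raise ValidationError(f"no RFE step of size {target_size} in trace")
    best = None
    for step in trace.steps:
        if (
            best is None
            or step.rmsecv < best.rmsecv
            or (step.rmsecv == best.rmsecv and len(step.retained_ids) < len(best.retained_ids))
        ):
            best = step
    return list(best.retained_ids)


def intersect_panels(a: Iterable[str], b: Iterable[str]) -> list[str]:
    """Order-stable intersection (order of ``a``)."""
    b_set = set(b)
    return [x for x in a if x in b_set]


@dataclass
class CombinationModel:
    """One exhaustively evaluated 2- or 3-miRNA PLS model.

    ``coefficients`` are in response units per autoscaled intensity; the
    training-set prediction is ``intercept + sum(coef * autoscaled value)``.
    """

    mirna_ids: tuple[str, ...]
    rmsecv: float
    n_components: int
    coefficients: pd.Series
    intercept: float


def exhaustive_search(
    X,
    y,
    panel: Sequence[str],
    subset_sizes: Iterable[int] = (2, 3),
    feature_names: Optional[Sequence[str]] = None,
) -> list[CombinationModel]:
    """Fit every panel subset of the requested sizes and rank by RMSECV.

    The latent-variable count of each model is selected by LOOCV, capped at
    the subset size.  Ties in RMSECV rank by the lexicographic ID tuple.
    """
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    col = {name: j for j, name in enumerate(names)}
    missing = [mid for mid in panel if mid not in col]
    if missing:
        raise ValidationError(f"panel features absent from X: {missing[:5]}")
    sizes = sorted(set(int(s) for s in subset_sizes))
    if not sizes:
        raise ValidationError("subset_sizes must be nonempty")
    if len(panel) < max(sizes):
        raise ValidationError(
            f"panel of {len(panel)} smaller than requested subset size {max(sizes)}"
        )

    models: list[CombinationModel] = []
    for size in sizes:
        for combo in itertools.combinations(panel, size):
            cols = [col[mid] for mid in combo]
            Xsub = Xm[:, cols]
            curve = _rmsecv_curve(Xsub, y, max_components=size)
            a = int(np.argmin(curve)) + 1
            Xs, _, _ = autoscale(Xsub, combo)
            ys, ym, ysd = autoscale(y)
            b = pls1_fit(Xs, ys, a).coef()
            models.append(
                CombinationModel(
                    mirna_ids=combo,
                    rmsecv=float(curve[a - 1]),
                    n_components=a,
                    coefficients=pd.Series(ysd * b, index=list(combo)),
                    intercept=float(ym),
                )
            )
    models.sort(key=lambda m: (m.rmsecv, tuple(sorted(m.mirna_ids))))
    return models


def combinations_to_frame(models: Sequence[CombinationModel]) -> pd.DataFrame:
    """Ranked table mirroring the panel-combination report layout."""
    rows = []
    for rank, m in enumerate(models, start=1):
        row = {"rank": rank, "rmsecv": m.rmsecv, "n_components": m.n_components}
        for k, mid in enumerate(m.mirna_ids, start=1):
            row[f"mirna_{k}"] = mid
            row[f"coef_{k}"] = m.coefficients[mid]
        rows.append(row)
    return pd.DataFrame(rows)
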