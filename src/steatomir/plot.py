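"""Diagnostic plots for fitted models and elimination traces."""

from __future__ import annotations

import numpy as np


def plot_rfe_trace(trace, ax=None):
    """RMSECV versus retained feature count along an RFE trace."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sizes = [len(s.retained_ids) for s in trace.steps]
    errors = [s.rmsecv for s in trace.steps]
    ax.plot(sizes, errors, marker=".", lw=1)
    ax.set_xlabel("retained miRNAs")
    ax.set_ylabel("RMSECV")
    ax.invert_xaxis()
    return ax


def plot_loocv_predictions(results, ax=None):
    """Observed vs LOOCV-predicted response, with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = results.model.endog
    yhat = results.loocv().per_sample_predictions
    ax.scatter(y, yhat, s=25)
    lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
    ax.plot(lims, lims, color="grey", lw=1, ls="--")
    ax.set_xlabel("observed")
    ax.set_ylabel("LOOCV predicted")
    ax.set_title(f"RMSECV = {results.rmsecv:.3g}")
    return ax
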