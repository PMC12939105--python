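"""Figure helpers: ROC, calibration, score distributions, DCA, KM.

Each function draws onto a fresh axes and, given ``out``, saves the figure
(PNG/SVG by extension) and closes it; otherwise the axes is returned for
composition.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from sklearn.metrics import roc_curve  # noqa: E402

from .interpret import NetBenefitCurve  # noqa: E402
from .survival import KMResult  # noqa: E402


def _finish(fig, ax, out):
    if out is None:
        return ax
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return None


def roc_plot(scores, labels, out=None, label="rad-PDL1"):
    fpr, tpr, _ = roc_curve(labels, scores)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return _finish(fig, ax, out)


def calibration_plot(curve, out=None):
    """``curve`` rows are (mean predicted, observed fraction, count)."""
    pred = [c[0] for c in curve]
    obs = [c[1] for c in curve]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.plot(pred, obs, "o-")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed fraction")
    return _finish(fig, ax, out)


def score_box_plot(scores, labels, out=None):
    s = np.asarray(scores)
    y = np.asarray(labels).astype(int)
    fig, ax = plt.subplots(figsize=(3.5, 4))
    ax.boxplot([s[y == 0], s[y == 1]], tick_labels=["PD-L1 low",
                                                    "PD-L1 high"])
    ax.set_ylabel("rad-PDL1 score")
    return _finish(fig, ax, out)


def dca_plot(curve: NetBenefitCurve, out=None, highlight=(0.25, 0.68)):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.thresholds, curve.model, label="model")
    ax.plot(curve.thresholds, curve.treat_all, label="treat all")
    ax.plot(curve.thresholds, curve.treat_none, "k-", lw=0.8,
            label="treat none")
    if highlight:
        ax.axvspan(*highlight, alpha=0.1)
    ax.set_ylim(bottom=-0.1)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    return _finish(fig, ax, out)


def km_plot(groups: dict[str, KMResult], out=None):
    """Step curves with censor ticks for named groups."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, km in groups.items():
        t = np.r_[0.0, km.times]
        s = np.r_[1.0, km.survival]
        ax.step(t, s, where="post", label=name)
        if km.censor_times.size:
            s_at = np.interp(km.censor_times, t, s)
            ax.plot(km.censor_times, s_at, "|", ms=8)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return _finish(fig, ax, out)
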