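"""Four-panel diagnostic figures: ROC, sens/spec vs cutoff, KDE, scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .diagnostics import CutoffReport, RocCurve, kde_fit

__all__ = ["marker_panels"]


def marker_panels(
    roc: RocCurve, report: CutoffReport, scores, labels, marker_name: str, path=None
):
    """ROC curve, sensitivity/specificity trends, class KDEs and a scatter
    of the marker by group — the standard presentation of a single-marker
    diagnostic test. Saves to ``path`` when given, else returns the figure.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = np.isin(y, ("CD", "positive", "pos", "1", "True"))
    y = y.astype(bool)

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    (ax_roc, ax_ss), (ax_kde, ax_sc) = axes

    ax_roc.plot(roc.fpr, roc.sens, "k-", lw=1.5)
    ax_roc.plot([0, 1], [0, 1], "--", color="grey", lw=1, label="line of equality")
    ax_roc.plot(1 - report.specificity, report.sensitivity, "ko", ms=7)
    ax_roc.set_xlabel("1 - specificity")
    ax_roc.set_ylabel("sensitivity")
    ax_roc.set_title(f"ROC {marker_name}  AUC={roc.auc:.5f}")

    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    ax_ss.plot(thr, roc.sens[finite], "r-", label="sensitivity")
    ax_ss.plot(thr, 1 - roc.fpr[finite], "b-", label="specificity")
    ax_ss.axvline(report.cutoff, ls=":", color="k")
    ax_ss.set_xlabel(marker_name)
    ax_ss.legend()
    ax_ss.set_title("sensitivity / specificity vs cutoff")

    for mask, color, lab in ((~y, "tab:blue", "nonCD"), (y, "tab:red", "CD")):
        if np.unique(scores[mask]).size >= 2:
            grid, dens = kde_fit(scores[mask])
            ax_kde.plot(grid, dens, color=color, label=lab)
    ax_kde.axvline(report.cutoff, ls=":", color="k")
    ax_kde.set_xlabel(marker_name)
    ax_kde.set_ylabel("density")
    ax_kde.legend()
    ax_kde.set_title("kernel distribution fit")

    rng = np.random.default_rng(0)  # jitter only, cosmetic
    x_jit = y.astype(float) + rng.uniform(-0.08, 0.08, size=y.size)
    ax_sc.scatter(x_jit[~y], scores[~y], c="tab:blue", s=18, label="nonCD")
    ax_sc.scatter(x_jit[y], scores[y], c="tab:red", s=18, label="CD")
    ax_sc.axhline(report.cutoff, ls=":", color="k")
    ax_sc.set_xticks([0, 1], ["nonCD", "CD"])
    ax_sc.set_ylabel(marker_name)
    ax_sc.set_title("scatter distribution")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
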