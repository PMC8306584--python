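"""ROC analysis, Youden-optimal cutoffs, and exact binomial intervals.

The empirical ROC curve is built over all distinct observed marker values
(plus infinite endpoints), with a subject called positive when its score
strictly exceeds the threshold. The area under the curve is computed by
the trapezoid rule, which for this construction equals the tie-corrected
Mann-Whitney statistic U / (n_pos * n_neg). The optimal cutoff maximizes
the Youden index J = sensitivity + specificity - 1 over the observed
thresholds; sensitivity and specificity at that cutoff carry exact
Clopper-Pearson 95% intervals. AUC confidence intervals come from a
stratified bootstrap (default) or the DeLong asymptotic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DataError

__all__ = [
    "RocCurve",
    "CutoffReport",
    "roc_curve",
    "auc_ci",
    "youden_optimal",
    "clopper_pearson",
    "kde_fit",
    "accuracy_at_cutoff",
]


@dataclass
class RocCurve:
    """Empirical ROC curve with AUC; retains the scores for resampling."""

    thresholds: np.ndarray  # descending, +inf first, -inf last
    sens: np.ndarray  # nondecreasing along the array
    fpr: np.ndarray  # nondecreasing along the array
    auc: float
    n_pos: int
    n_neg: int
    auc_ci: tuple[float, float] | None = None
    positive_direction: str = "greater"
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class CutoffReport:
    """Youden-optimal operating point for one marker."""

    marker_name: str
    cutoff: float
    cutoff_midpoint: float
    youden_j: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = np.isin(y, ("CD", "positive", "pos", "1", "True"))
    y = y.astype(bool)
    if scores.shape != y.shape or scores.ndim != 1:
        raise DataError("scores and labels must be matching 1-D sequences")
    if np.any(~np.isfinite(scores)):
        raise DataError("scores must be finite")
    if y.all() or (~y).all():
        raise DataError("need at least one positive and one negative subject")
    return scores, y


def roc_curve(scores, labels, positive_direction: str = "greater") -> RocCurve:
    """Empirical ROC over all distinct observed thresholds.

    ``labels`` may be booleans, 0/1, or the strings ``CD``/``nonCD`` (CD is
    the positive class). With ``positive_direction="greater"`` a subject is
    called positive at threshold t when score > t; ``"less"`` flips the
    scale (equivalent to negating the scores).
    """
    if positive_direction not in ("greater", "less"):
        raise ConfigError(f"positive_direction must be 'greater' or 'less'")
    scores, y = _check_scores_labels(scores, labels)
    s = scores if positive_direction == "greater" else -scores
    pos, neg = s[y], s[~y]
    n_pos, n_neg = pos.size, neg.size

    thr = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    sens = np.array([(pos > t).mean() for t in thr])
    fpr = np.array([(neg > t).mean() for t in thr])
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(
        thresholds=thr,
        sens=sens,
        fpr=fpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        positive_direction=positive_direction,
        scores=scores,
        labels=y,
    )


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    # midrank formulation; O((n+m) log(n+m))
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_ci(
    roc: RocCurve,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
    conf: float = 0.95,
) -> tuple[float, float]:
    """95% confidence interval for the AUC, clipped to [0, 1].

    ``bootstrap`` resamples positives and negatives separately (stratified)
    and takes the 2.5/97.5 percentiles of the recomputed AUCs; ``delong``
    uses the asymptotic placement-value variance.
    """
    if method not in ("bootstrap", "delong"):
        raise ConfigError("method must be 'bootstrap' or 'delong'")
    s = roc.scores if roc.positive_direction == "greater" else -roc.scores
    pos, neg = s[roc.labels], s[~roc.labels]
    alpha = 1.0 - conf
    if method == "bootstrap":
        if n_boot < 100:
            raise ConfigError(f"n_boot must be >= 100, got {n_boot}")
        rng = np.random.default_rng(seed)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            pb = rng.choice(pos, size=pos.size, replace=True)
            nb = rng.choice(neg, size=neg.size, replace=True)
            aucs[b] = _auc_mann_whitney(pb, nb)
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    else:
        lo, hi = _delong_ci(pos, neg, conf)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, conf: float) -> tuple[float, float]:
    """DeLong variance via placement values (midranks for ties)."""
    m, n = pos.size, neg.size
    # V10[i]: fraction of negatives each positive beats (ties count 1/2)
    v10 = np.array([((p > neg).sum() + 0.5 * (p == neg).sum()) / n for p in pos])
    v01 = np.array([((pos > q).sum() + 0.5 * (pos == q).sum()) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + conf / 2)
    return auc - z * se, auc + z * se


def youden_optimal(
    roc: RocCurve, marker_name: str = "", conf: float = 0.95
) -> CutoffReport:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    The scan runs over the observed score values (the finite thresholds of
    the curve). Ties on J are broken toward higher specificity, then lower
    cutoff. The report carries the raw observed threshold — the value the
    strict ">" rule and all sens/spec estimates use — plus a supplementary
    midpoint between that threshold and the next lower observed score.
    """
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.sens[finite]
    spec = 1.0 - roc.fpr[finite]
    j = sens + spec - 1.0
    # lexicographic argmax: J desc, specificity desc, cutoff asc
    order = np.lexsort((thr, -spec, -j))
    best = order[0]
    cutoff = float(thr[best])

    lower = roc.thresholds[finite][roc.thresholds[finite] < cutoff]
    midpoint = float((cutoff + lower.max()) / 2.0) if lower.size else cutoff

    s = roc.scores if roc.positive_direction == "greater" else -roc.scores
    pos, neg = s[roc.labels], s[~roc.labels]
    tp = int((pos > cutoff).sum())
    fn = pos.size - tp
    tn = int((neg <= cutoff).sum())
    fp = neg.size - tn
    sens_hat = tp / pos.size
    spec_hat = tn / neg.size
    return CutoffReport(
        marker_name=marker_name,
        cutoff=cutoff,
        cutoff_midpoint=midpoint,
        youden_j=float(j[best]),
        sensitivity=sens_hat,
        specificity=spec_hat,
        sens_ci=clopper_pearson(tp, pos.size, conf),
        spec_ci=clopper_pearson(tn, neg.size, conf),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def clopper_pearson(successes: int, trials: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles.

    lower = Beta(alpha/2; s, n-s+1), upper = Beta(1-alpha/2; s+1, n-s),
    with the conventional endpoints 0 (s = 0) and 1 (s = n).
    """
    if trials < 1:
        raise DataError(f"trials must be >= 1, got {trials}")
    if not (0 <= successes <= trials):
        raise DataError(f"successes {successes} outside [0, {trials}]")
    if not (0.0 < conf < 1.0):
        raise DataError(f"conf must be in (0, 1), got {conf}")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lower, upper


def kde_fit(
    values, bandwidth="silverman", grid_size: int = 512, pad_bw: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of a marker distribution.

    ``bandwidth`` is ``"silverman"``, ``"scott"`` or a positive scalar
    factor (scipy's bw_method convention). Returns (grid, density); the
    density integrates to ~1 over the returned grid, which extends the
    sample range by ``pad_bw`` kernel bandwidths on each side.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("need a 1-D sample of at least 2 values")
    if np.unique(x).size < 2:
        raise DataError("all values identical; density is degenerate")
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - pad_bw * bw, x.max() + pad_bw * bw, grid_size)
    return grid, kde(grid)


def accuracy_at_cutoff(records, cutoff: float, marker_name: str) -> float:
    """(TP + TN) / N for the strict ">" decision rule on one marker.

    ``records`` is an iterable of :class:`~ramancd.markers.MarkerRecord`
    with known labels (CD = positive class).
    """
    records = list(records)
    if not records:
        raise DataError("empty record set")
    correct = 0
    for r in records:
        if r.label not in ("CD", "nonCD"):
            raise DataError(f"subject {r.subject_id}: label {r.label!r} is not CD/nonCD")
        score = getattr(r, marker_name)
        predicted_cd = score > cutoff
        correct += predicted_cd == (r.label == "CD")
    return correct / len(records)
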