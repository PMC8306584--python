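"""Scikit-learn style estimators wrapping the deconvolution and ROC stages.

``GaussianBandAreaTransformer`` turns a list of spectra into the (n, 3)
matrix of deconvolved band areas, ``MarkerRatioTransformer`` divides the
amide I and CH2 areas by the Phe internal standard, and
``YoudenThresholdClassifier`` learns the Youden-optimal cutoff on a single
marker and predicts CD status with the strict ">" rule. All three compose
with :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import diagnostics
from .deconvolution import DEFAULT_K, DEFAULT_WINDOWS, deconvolve_spectrum
from .exceptions import DataError, NormalizationError

__all__ = [
    "GaussianBandAreaTransformer",
    "MarkerRatioTransformer",
    "YoudenThresholdClassifier",
]


class GaussianBandAreaTransformer(TransformerMixin, BaseEstimator):
    """Deconvolve each spectrum's diagnostic windows into band areas.

    ``transform`` maps a sequence of :class:`~ramancd.spectra.Spectrum`
    to an (n_subjects, n_windows) array of overall band areas, columns
    ordered as ``windows`` (default: amide I, CH2, Phe). Stateless: fit
    only validates parameters.
    """

    def __init__(self, windows=DEFAULT_WINDOWS, k_by_window=None, max_iter=2000, tol=1e-10):
        self.windows = windows
        self.k_by_window = k_by_window
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        k = dict(DEFAULT_K)
        if self.k_by_window:
            k.update(self.k_by_window)
        self.k_by_window_ = k
        self.window_names_ = [w.name for w in self.windows]
        return self

    def transform(self, X):
        if not hasattr(self, "window_names_"):
            self.fit(X)
        areas = np.empty((len(X), len(self.windows)))
        for i, spectrum in enumerate(X):
            fits = deconvolve_spectrum(
                spectrum,
                windows=tuple(self.windows),
                k_by_window=self.k_by_window_,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            for j, w in enumerate(self.windows):
                areas[i, j] = fits[w.name].area
        return areas


class MarkerRatioTransformer(TransformerMixin, BaseEstimator):
    """Normalize band areas by the internal-standard column.

    Input columns follow :class:`GaussianBandAreaTransformer`:
    (A_amideI, A_ch2, A_phe). Output columns are the two markers
    (r1450, r1650) = (A_ch2 / A_phe, A_amideI / A_phe).
    """

    def __init__(self, standard_col: int = 2):
        self.standard_col = standard_col

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise DataError("expected an (n, >=2) area matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        std = X[:, self.standard_col]
        if np.any(~np.isfinite(std)) or np.any(std <= 0):
            bad = int(np.argmax(~(np.isfinite(std) & (std > 0))))
            raise NormalizationError(
                f"subject index {bad}: internal-standard area {std[bad]!r} "
                "must be finite and > 0"
            )
        others = [j for j in range(X.shape[1]) if j != self.standard_col]
        # (r1450, r1650) ordering: CH2 ratio first, then amide I
        ratios = X[:, others] / std[:, None]
        return ratios[:, ::-1] if others == [0, 1] else ratios


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-marker threshold classifier with a Youden-learned cutoff.

    ``fit`` computes the empirical ROC of the marker scores against the
    binary labels, the trapezoid AUC with a confidence interval, and the
    cutoff maximizing J = sensitivity + specificity - 1; ``predict``
    applies the strict ">" rule (score must exceed the cutoff to be
    called positive). A fixed ``cutoff`` bypasses the Youden search,
    mirroring the use of published thresholds on new subjects.

    Attributes (after fit): ``cutoff_``, ``youden_j_``, ``auc_``,
    ``auc_ci_``, ``sensitivity_``, ``specificity_``, ``sensitivity_ci_``,
    ``specificity_ci_``, ``roc_``, ``report_``, ``classes_``.
    """

    def __init__(
        self,
        cutoff: float | None = None,
        positive_direction: str = "greater",
        ci_method: str = "bootstrap",
        n_boot: int = 2000,
        conf: float = 0.95,
        random_state: int | None = None,
    ):
        self.cutoff = cutoff
        self.positive_direction = positive_direction
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.conf = conf
        self.random_state = random_state

    @staticmethod
    def _scores(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise DataError("expected a single marker column")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        scores = self._scores(X)
        roc = diagnostics.roc_curve(scores, y, self.positive_direction)
        roc.auc_ci = diagnostics.auc_ci(
            roc, method=self.ci_method, n_boot=self.n_boot,
            seed=self.random_state, conf=self.conf,
        )
        report = diagnostics.youden_optimal(roc, conf=self.conf)
        if self.cutoff is not None:
            report = self._report_at(roc, float(self.cutoff))
        self.roc_ = roc
        self.report_ = report
        self.cutoff_ = report.cutoff
        self.youden_j_ = report.youden_j
        self.auc_ = roc.auc
        self.auc_ci_ = roc.auc_ci
        self.sensitivity_ = report.sensitivity
        self.specificity_ = report.specificity
        self.sensitivity_ci_ = report.sens_ci
        self.specificity_ci_ = report.spec_ci
        self.classes_ = np.array([0, 1])
        return self

    def _report_at(self, roc, cutoff: float):
        s = roc.scores if roc.positive_direction == "greater" else -roc.scores
        pos, neg = s[roc.labels], s[~roc.labels]
        tp = int((pos > cutoff).sum())
        tn = int((neg <= cutoff).sum())
        sens, spec = tp / pos.size, tn / neg.size
        from .diagnostics import CutoffReport, clopper_pearson

        return CutoffReport(
            marker_name="",
            cutoff=cutoff,
            cutoff_midpoint=cutoff,
            youden_j=sens + spec - 1.0,
            sensitivity=sens,
            specificity=spec,
            sens_ci=clopper_pearson(tp, pos.size, self.conf),
            spec_ci=clopper_pearson(tn, neg.size, self.conf),
            tp=tp,
            fn=pos.size - tp,
            tn=tn,
            fp=neg.size - tn,
        )

    def decision_function(self, X):
        s = self._scores(X)
        return s - self.cutoff_ if self.positive_direction == "greater" else self.cutoff_ - s

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def score(self, X, y):
        """Diagnostic accuracy (TP + TN) / N at the fitted cutoff."""
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            y = np.isin(y, ("CD", "positive", "pos", "1", "True"))
        return float((self.predict(X) == y.astype(int)).mean())
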