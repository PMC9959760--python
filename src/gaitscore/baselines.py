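"""Comparison models: SVM, Gaussian naive Bayes, multiple linear regression.

These are the three traditional approaches the nonlinear scorer is
benchmarked against.  The SVM is linear one-vs-rest with C = 1 (no kernel
is mandated by the comparison; RBF is available through ``svm_kernel``),
naive Bayes uses Gaussian likelihoods for the continuous gait features,
and MLR regresses the level on the features with predictions clamped to
the valid score range [-0.5, 4.5] before rounding.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .estimator import HyperplaneGaitScorer
from .model import SCORE_LOWER, SCORE_UPPER, round_to_level

MODEL_KINDS = ("nonlinear", "svm", "nb", "mlr")


class BoundedLinearRegression(BaseEstimator, RegressorMixin):
    """Least-squares regression of level on features, clamped to [-0.5, 4.5].

    ``predict_score`` returns the clamped continuous prediction;
    ``predict`` rounds it to an integer level (half-points round up).
    """

    def fit(self, X, y):
        self.lr_ = LinearRegression().fit(np.asarray(X, float), np.asarray(y, float))
        self.coef_ = self.lr_.coef_
        self.intercept_ = self.lr_.intercept_
        self.n_features_in_ = self.lr_.n_features_in_
        return self

    def predict_score(self, X):
        check_is_fitted(self, "lr_")
        return np.clip(self.lr_.predict(np.asarray(X, float)),
                       SCORE_LOWER, SCORE_UPPER)

    def predict(self, X):
        return round_to_level(self.predict_score(X))


def make_model(kind: str, svm_kernel: str = "linear", svm_c: float = 1.0,
               nb_var_smoothing: float = 1e-9, **scorer_kwargs):
    """Factory for the four comparison models by short name."""
    if kind == "nonlinear":
        return HyperplaneGaitScorer(**scorer_kwargs)
    if kind == "svm":
        return SVC(kernel=svm_kernel, C=svm_c, decision_function_shape="ovr")
    if kind == "nb":
        return GaussianNB(var_smoothing=nb_var_smoothing)
    if kind == "mlr":
        return BoundedLinearRegression()
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
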