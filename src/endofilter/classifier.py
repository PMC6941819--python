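"""Stage 2 of the noise filter: a logistic model on read-level features.

Two features separate fragmentation artifacts from genuine somatic calls: the
positional-bias KS p-value (transformed to -log10(p + eps)) and the
soft-clipped-read ratio. A logistic regression of P(artifact | x_bias,
x_clip) is fitted by maximum likelihood, and the decision threshold on the
predicted probability is chosen to maximize sensitivity + specificity on the
labeled training data. A cut on predicted probability corresponds to a
straight threshold line in feature space.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

#: Guards log10 of an exactly-zero p-value.
P_EPS = 1e-300

LABEL_ARTIFACT = 1
LABEL_GENUINE = 0


def bias_feature(ks_p: np.ndarray | float, eps: float = P_EPS) -> np.ndarray | float:
    """x_bias = -log10(ks_p + eps); 0 for non-evaluable variants (p = 1)."""
    return -np.log10(np.asarray(ks_p, dtype=float) + eps)


def youden_threshold(probs: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Cut point on predicted probabilities maximizing sensitivity + specificity.

    Candidates are the distinct predicted probabilities (the rule is
    ``noise iff p >= t``); ties in the objective break toward the larger
    threshold, i.e. fewer removals. Returns (t, sensitivity, specificity).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    pos, neg = y == LABEL_ARTIFACT, y == LABEL_GENUINE
    best = (-np.inf, -np.inf)  # (J, t)
    for t in np.unique(probs):
        pred = probs >= t
        sens = pred[pos].mean() if pos.any() else 0.0
        spec = (~pred[neg]).mean() if neg.any() else 0.0
        j = sens + spec
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t)
    t = float(best[1])
    pred = probs >= t
    sens = float(pred[pos].mean()) if pos.any() else 0.0
    spec = float((~pred[neg]).mean()) if neg.any() else 0.0
    return t, sens, spec


class LogisticNoiseClassifier(BaseEstimator, ClassifierMixin):
    """Logistic artifact-vs-genuine classifier with a Youden-style threshold.

    Parameters
    ----------
    ridge : float
        L2 penalty applied only as a fallback when the training data are
        perfectly separated (the MLE diverges); keeps coefficients finite.
    threshold : float or None
        Fixed decision threshold on P(artifact). When None (default) the
        threshold maximizing sensitivity + specificity on the training data is
        chosen during :meth:`fit`.
    tol : float
        Convergence tolerance of the maximum-likelihood fit.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (2,)
        Slopes for (x_bias, x_clip).
    bse_ : ndarray or None
        Standard errors of (intercept, slopes) from the observed information;
        None when the separation fallback was used.
    threshold_ : float
        Decision threshold on predicted probability.
    sensitivity_, specificity_ : float
        Training sensitivity/specificity at ``threshold_``.
    separable_ : bool
        True when the ridge fallback was triggered.
    """

    def __init__(self, ridge: float = 1e-6, threshold: float | None = None, tol: float = 1e-8):
        self.ridge = ridge
        self.threshold = threshold
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both artifact and genuine labels")
        if not set(classes) <= {LABEL_GENUINE, LABEL_ARTIFACT}:
            raise ValueError("labels must be 0 (genuine) or 1 (artifact)")
        for cls in classes:
            if (y == cls).sum() < 10:
                warnings.warn(f"fewer than 10 training examples with label {cls}")
        self.classes_ = np.array([LABEL_GENUINE, LABEL_ARTIFACT])
        self.n_features_in_ = X.shape[1]

        params = bse = None
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, method="newton", tol=self.tol, maxiter=200
                )
                if np.isfinite(res.params).all() and np.isfinite(res.bse).all():
                    params, bse = res.params, res.bse
            except (PerfectSeparationError, np.linalg.LinAlgError):
                pass
            separated = params is None or any(
                issubclass(w.category, PerfectSeparationWarning) for w in caught
            )
        if separated and params is not None:
            params = None  # quasi-separated Newton estimates are unreliable
        if params is None:
            warnings.warn(
                "perfect separation in training data; falling back to ridge-penalized fit"
            )
            lr = LogisticRegression(
                C=1.0 / self.ridge, solver="lbfgs", max_iter=10_000, tol=self.tol
            ).fit(X, y)
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
            bse = None
            self.separable_ = True
        else:
            self.separable_ = False

        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.bse_ = None if bse is None else np.asarray(bse, dtype=float)

        probs = self._proba(X)
        if self.threshold is None:
            self.threshold_, self.sensitivity_, self.specificity_ = youden_threshold(probs, y)
        else:
            self.threshold_ = float(self.threshold)
            pred = probs >= self.threshold_
            self.sensitivity_ = float(pred[y == LABEL_ARTIFACT].mean())
            self.specificity_ = float((~pred[y == LABEL_GENUINE]).mean())
        return self

    # -- prediction --------------------------------------------------------

    def _proba(self, X) -> np.ndarray:
        z = self.intercept_ + X @ self.coef_
        return 1.0 / (1.0 + np.exp(-z))

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        p = self._proba(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        """1 (noise) iff P(artifact) >= threshold (boundary points are noise)."""
        check_is_fitted(self, "threshold_")
        X = check_array(X)
        if np.isnan(X).any():
            raise ValueError("missing feature values")
        return (self._proba(X) >= self.threshold_).astype(int)

    def decision_line(self) -> tuple[float, float, float]:
        """(a, b, c) with a + b*x_bias + c*x_clip = 0 the threshold line."""
        check_is_fitted(self, "threshold_")
        t = np.clip(self.threshold_, 1e-12, 1 - 1e-12)
        logit_t = float(np.log(t / (1 - t)))
        return (self.intercept_ - logit_t, float(self.coef_[0]), float(self.coef_[1]))

    def roc_curve(self, X, y) -> tuple[np.ndarray, np.ndarray, float]:
        """(sensitivities, specificities) over all cut points, plus the AUROC."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        y = np.asarray(y)
        probs = self._proba(X)
        cuts = np.concatenate([np.unique(probs), [np.inf]])
        sens = np.array([(probs >= t)[y == LABEL_ARTIFACT].mean() for t in cuts])
        spec = np.array([(probs < t)[y == LABEL_GENUINE].mean() for t in cuts])
        return sens, spec, float(roc_auc_score(y, probs))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "threshold_")
        return {
            "model": "logistic_noise_classifier",
            "features": ["x_bias", "x_clip"],
            "transform": {"x_bias": "-log10(ks_p + eps)", "eps": P_EPS},
            "intercept": self.intercept_,
            "coef": list(map(float, self.coef_)),
            "threshold": self.threshold_,
            "training": {
                "sensitivity": self.sensitivity_,
                "specificity": self.specificity_,
                "separable": self.separable_,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticNoiseClassifier":
        obj = cls(threshold=d["threshold"])
        obj.intercept_ = float(d["intercept"])
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.bse_ = None
        obj.threshold_ = float(d["threshold"])
        obj.sensitivity_ = float(d.get("training", {}).get("sensitivity", float("nan")))
        obj.specificity_ = float(d.get("training", {}).get("specificity", float("nan")))
        obj.separable_ = bool(d.get("training", {}).get("separable", False))
        obj.classes_ = np.array([LABEL_GENUINE, LABEL_ARTIFACT])
        obj.n_features_in_ = len(obj.coef_)
        return obj

    @classmethod
    def load(cls, path: str | Path) -> "LogisticNoiseClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_model(X, y, **kwargs) -> LogisticNoiseClassifier:
    return LogisticNoiseClassifier(**kwargs).fit(X, y)


def choose_threshold(model: LogisticNoiseClassifier, X, y) -> float:
    t, model.sensitivity_, model.specificity_ = youden_threshold(
        model.predict_proba(X)[:, 1], np.asarray(y)
    )
    model.threshold_ = t
    return t


def classify(model: LogisticNoiseClassifier, X) -> np.ndarray:
    """Per-variant "noise" / "signal" decisions."""
    return np.where(model.predict(X) == LABEL_ARTIFACT, "noise", "signal")


def roc_curve(model: LogisticNoiseClassifier, X, y):
    return model.roc_curve(X, y)
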