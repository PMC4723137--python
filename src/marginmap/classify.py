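"""Binary logistic classification of bins (tumor vs normal) and ROC analysis.

A bin with features x = (area fraction, average diameter, average shape) is
scored with p = 1 / (1 + exp(-(b0 + sum_k bk xk))) and declared tumor when
p > alpha (strict). Muscle and adipose bins are pooled as the negative class.
Empty bins (no segmented nuclei) are excluded from fitting and are assigned
probability 0 at prediction: with the shipped coefficients a zero-filled
feature vector would otherwise score logistic(b0) ~ 0.93, a spurious positive
for bins containing nothing.

Four coefficient sets estimated on the original AO-SIM sarcoma training data
ship as named built-in models (:data:`REFERENCE_MODELS`), one per subset of
the three variables, so prediction is possible without refitting. They are
declared in pixel units (diameter in px, shape in 1/px, the regionprops
convention); features computed in micrometers are converted via the pixel
pitch at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import BinFeatures

__all__ = [
    "FEATURE_NAMES",
    "LogisticModel",
    "REFERENCE_MODELS",
    "reference_model",
    "BinLogisticRegression",
    "fit_logistic",
    "predict_prob",
    "predict_probs",
    "ROCResult",
    "roc",
    "classify_bins",
]

FEATURE_NAMES = ("area_fraction", "avg_diameter", "avg_shape")


class SingleClassError(ValueError):
    """Fitting or ROC analysis requires both classes to be present."""


@dataclass(frozen=True)
class LogisticModel:
    """Logistic coefficients over a declared subset of the three bin features.

    ``units`` records the scale of the diameter/shape features the
    coefficients apply to: ``"um"`` (um and 1/um) or ``"px"`` (px and 1/px).
    Area fraction is dimensionless either way.
    """

    feature_subset: tuple[str, ...]
    beta0: float
    betas: tuple[float, ...]
    units: str = "um"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        unknown = set(self.feature_subset) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features {sorted(unknown)}")
        if len(self.betas) != len(self.feature_subset):
            raise ValueError("one coefficient required per included feature")
        if self.units not in ("um", "px"):
            raise ValueError(f"units must be 'um' or 'px', got {self.units!r}")

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        """b0 + sum_k bk * x_k for feature vectors in this model's own units."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        return self.beta0 + x @ np.asarray(self.betas)

    def prob(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.linear_predictor(x))

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_subset": list(self.feature_subset),
                "beta0": self.beta0,
                "betas": list(self.betas),
                "units": self.units,
                "meta": self.meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        return cls(
            feature_subset=tuple(d["feature_subset"]),
            beta0=float(d["beta0"]),
            betas=tuple(float(b) for b in d["betas"]),
            units=d.get("units", "um"),
            meta=d.get("meta", {}),
        )


#: Built-in coefficient sets (pixel-unit features), one per variable subset.
REFERENCE_MODELS: dict[str, LogisticModel] = {
    "af_diameter_shape": LogisticModel(
        ("area_fraction", "avg_diameter", "avg_shape"),
        2.659,
        (44.074, -0.962, -0.8652),
        units="px",
    ),
    "af_diameter": LogisticModel(
        ("area_fraction", "avg_diameter"), 1.374, (43.818, -0.870), units="px"
    ),
    "af_shape": LogisticModel(
        ("area_fraction", "avg_shape"), -4.460, (30.12, 12.09), units="px"
    ),
    "diameter_shape": LogisticModel(
        ("avg_diameter", "avg_shape"), 1.3587, (-0.2114, -5.1622), units="px"
    ),
}


def reference_model(name: str = "af_diameter_shape") -> LogisticModel:
    """Look up a built-in coefficient set by name."""
    try:
        return REFERENCE_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(REFERENCE_MODELS)}"
        ) from None


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=np.float64)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class BinLogisticRegression(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood binary logistic regression via IRLS (Newton-Raphson).

    Unpenalized, matching the original model fit. Convergence is declared
    when the largest coefficient update falls below ``tol`` (default 1e-8)
    or after ``max_iter`` (default 100) iterations. Complete separation is
    detected through diverging coefficient norms; the last stable estimate
    is kept and flagged via ``separated_``, with an optional ridge refit
    (``ridge_on_separation``) for callers that need finite coefficients.

    Attributes (after fit)
    ----------------------
    intercept_ : float
    coef_ : ndarray, per-feature coefficients
    bse_ : ndarray, estimated standard errors of (intercept, coef)
    n_iter_ : int
    converged_ : bool
    separated_ : bool
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        ridge_on_separation: float | None = None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge_on_separation = ridge_on_separation

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        classes = np.unique(y)
        if classes.size < 2:
            raise SingleClassError("need both classes present to fit")
        if not np.all(np.isin(classes, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1")

        n, k = X.shape
        X1 = np.column_stack([np.ones(n), X])
        beta = np.zeros(k + 1)
        ridge = 0.0
        self.separated_ = False
        beta, n_iter, converged = self._irls(X1, y, beta, ridge)
        if self.separated_ and self.ridge_on_separation:
            beta, n_iter, converged = self._irls(
                X1, y, np.zeros(k + 1), float(self.ridge_on_separation)
            )
        eta = X1 @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        info = X1.T @ (X1 * w[:, None])
        try:
            cov = np.linalg.inv(info)
            self.bse_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            self.bse_ = np.full(k + 1, np.nan)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.classes_ = np.array([0.0, 1.0])
        return self

    def _irls(self, X1, y, beta, ridge):
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X1 @ beta
            p = _sigmoid(eta)
            w = np.clip(p * (1 - p), 1e-12, None)
            grad = X1.T @ (y - p) - ridge * beta
            hess = X1.T @ (X1 * w[:, None]) + ridge * np.eye(beta.size)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                self.separated_ = True
                break
            new_beta = beta + step
            if not np.all(np.isfinite(new_beta)) or np.linalg.norm(new_beta) > 1e8:
                self.separated_ = True  # diverging norms: keep last estimate
                break
            beta = new_beta
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        if not converged and not self.separated_ and ridge == 0:
            # coefficients still drifting outward at max_iter; if the current
            # estimate already classifies every observation correctly the
            # likelihood has no maximum (complete separation)
            eta = X1 @ beta
            if np.all((eta > 0) == (y == 1)) or np.linalg.norm(beta) > 1e3:
                self.separated_ = True
        return beta, it, converged

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        p = _sigmoid(self.intercept_ + X @ self.coef_)
        return np.column_stack([1 - p, p])

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.intercept_ + X @ self.coef_

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(float)


# ---------------------------------------------------------------------------
# BinFeatures-level interface
# ---------------------------------------------------------------------------


def feature_matrix(
    feats: Sequence[BinFeatures],
    feature_subset: Sequence[str] = FEATURE_NAMES,
    units: str = "um",
    pitch_um: float = 1.5,
) -> np.ndarray:
    """Stack bin features into an (n, k) design matrix in the requested units."""
    cols = []
    for name in feature_subset:
        if name == "area_fraction":
            cols.append([f.area_fraction for f in feats])
        elif name == "avg_diameter":
            v = np.array([f.avg_diameter_um for f in feats])
            cols.append(v / pitch_um if units == "px" else v)
        elif name == "avg_shape":
            v = np.array([f.avg_shape_per_um for f in feats])
            cols.append(v * pitch_um if units == "px" else v)
        else:
            raise ValueError(f"unknown feature {name!r}")
    return np.column_stack(cols) if cols else np.empty((len(feats), 0))


def fit_logistic(
    feats: Sequence[BinFeatures],
    labels: Sequence[int],
    feature_subset: Sequence[str] = FEATURE_NAMES,
    units: str = "um",
    pitch_um: float = 1.5,
    **estimator_kwargs,
) -> LogisticModel:
    """Fit a LogisticModel on non-empty bins (empty bins are dropped)."""
    labels = np.asarray(labels)
    keep = np.array([not f.empty for f in feats], dtype=bool)
    feats_kept = [f for f, k in zip(feats, keep) if k]
    y = labels[keep]
    if np.unique(y).size < 2:
        raise SingleClassError("need both classes among non-empty bins")
    X = feature_matrix(feats_kept, feature_subset, units=units, pitch_um=pitch_um)
    est = BinLogisticRegression(**estimator_kwargs).fit(X, y)
    return LogisticModel(
        feature_subset=tuple(feature_subset),
        beta0=est.intercept_,
        betas=tuple(float(b) for b in est.coef_),
        units=units,
        meta={
            "converged": est.converged_,
            "separated": est.separated_,
            "n_iter": est.n_iter_,
            "n_obs": int(y.size),
            "bse": [float(s) for s in est.bse_],
        },
    )


def predict_probs(
    model: LogisticModel,
    feats: Sequence[BinFeatures],
    pitch_um: float = 1.5,
) -> np.ndarray:
    """Tumor probability per bin.

    Bins with no centroid-assigned region (which includes all empty bins)
    return 0 by convention: their diameter and shape are undefined, and a
    zero-filled feature vector would spuriously score near logistic(b0).
    """
    if not feats:
        return np.empty(0)
    X = feature_matrix(feats, model.feature_subset, units=model.units, pitch_um=pitch_um)
    p = model.prob(X)
    unscored = np.array([f.empty or f.n_regions == 0 for f in feats], dtype=bool)
    p[unscored] = 0.0
    return p


def predict_prob(
    model: LogisticModel, binf: BinFeatures, pitch_um: float = 1.5
) -> float:
    return float(predict_probs(model, [binf], pitch_um=pitch_um)[0])


# ---------------------------------------------------------------------------
# ROC / Youden analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC over all distinct score thresholds.

    thresholds are descending (∞ first, -∞ last, midpoints between
    consecutive distinct scores in between); a case is called positive when
    its score strictly exceeds the threshold. auc is the trapezoid-rule area,
    equal to the tie-corrected Mann-Whitney concordance probability.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_alpha: float
    youden_index: float

    def sens_spec_at(self, alpha: float) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.thresholds - alpha)))
        return float(self.sensitivity[i]), float(self.specificity[i])


def roc(probs: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve, AUC and Youden-optimal threshold (ties break to lower alpha)."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if p.size != y.size or p.size == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC needs both classes present")

    distinct = np.unique(p)
    mids = (distinct[1:] + distinct[:-1]) / 2.0
    thresholds = np.r_[np.inf, mids[::-1], -np.inf]

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, a in enumerate(thresholds):
        calls = p > a
        sens[i] = (calls & (y == 1)).sum() / n_pos
        spec[i] = (~calls & (y == 0)).sum() / n_neg

    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1.0
    # ties -> lower alpha (thresholds descending, so latest max)
    best = thresholds.size - 1 - int(np.argmax(j[::-1]))
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_alpha=float(thresholds[best]),
        youden_index=float(j[best]),
    )


def classify_bins(probs: Sequence[float], alpha: float) -> np.ndarray:
    """Binary tumor calls: 1 where p > alpha (strict)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return (np.asarray(probs, dtype=np.float64) > alpha).astype(int)
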