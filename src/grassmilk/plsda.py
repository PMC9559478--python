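"""Two-class PLS discriminant analysis with VIP scores.

The classifier is PLS1 regression on a 0/1-coded class response (GRASS = 1),
fitted by sequential NIPALS extraction on the mean-centred, unit-variance
predictor matrix.  For a two-class problem this is equivalent, up to an
affine transform of the prediction, to the two-column dummy coding used by
classical PLS-DA, and yields identical rankings and ROC curves.

The continuous PLS prediction is mapped to a GRASS-membership probability by
a logistic (Platt-style) calibration fitted on the training scores; any
strictly monotone map leaves AUC — the component-selection criterion —
unchanged, so the calibration only affects probability scale, not ranking.

Variable importance in projection (VIP) for predictor j over A components:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

with SS_a the response variance explained by component a.  The mean of
VIP_j^2 over the p predictors is identically 1.  Because the interpretive
thresholds used downstream (50, 60) live on a 0–100 scale, a scaled VIP
(100 · raw / max raw) is reported alongside the raw score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySubsetError, InputError, SchemaError

__all__ = [
    "PlsDaModel",
    "VipTable",
    "fit_pls",
    "select_n_components",
    "compute_vip",
    "reduce_by_vip",
    "save_model",
    "load_model",
    "MAX_COMPONENTS",
]

MAX_COMPONENTS = 30
_RESIDUAL_TOL = 1e-12

FORMAT_VERSION = 1


def _platt_fit(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit P(class=1 | s) = sigmoid(alpha*s + beta) by Newton iterations.

    Uses regularised targets (N+1)/(N+2)-style so the fit stays finite under
    perfect separation.
    """
    y = (np.asarray(y, dtype=float) > 0.5).astype(float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    alpha, beta = 0.0, np.log((n_pos + 1.0) / (n_neg + 1.0))
    X = np.column_stack([scores, np.ones_like(scores)])
    theta = np.array([alpha, beta])
    for _ in range(100):
        z = X @ theta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
        grad = X.T @ (p - t)
        w = np.maximum(p * (1 - p), 1e-12)
        hess = (X * w[:, None]).T @ X + 1e-10 * np.eye(2)
        step = np.linalg.solve(hess, grad)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-10:
            break
    return float(theta[0]), float(theta[1])


@dataclass
class PlsDaModel:
    """Fitted centred/scaled PLS1 discriminant model.

    Attributes use the conventional chemometric notation: ``W`` the
    (p × A) predictor weights (unit columns), ``P`` the predictor loadings,
    ``q`` the response loadings, ``R = W (PᵀW)⁻¹`` so the coefficient vector
    for the first a components is ``R[:, :a] @ q[:a]``.
    """

    predictor_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    R: np.ndarray
    score_ss: np.ndarray          # tᵀt per component
    n_components: int             # requested A
    effective_components: int     # achieved A (early stop on zero residual)
    y_mean: float
    calibration: tuple[float, float] = (1.0, 0.0)
    classes: tuple[str, str] = ("NOGRASS", "GRASS")
    dropped: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Regression coefficients b on the scaled predictors (full A)."""
        return self.coefficients_for(self.effective_components)

    def coefficients_for(self, a: int) -> np.ndarray:
        a = min(int(a), self.effective_components)
        if a < 1:
            raise InputError("need at least 1 component")
        return self.R[:, :a] @ self.q[:a]

    def _design(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.predictor_names if c not in X.columns]
            if missing:
                raise SchemaError(missing)
            X = X[self.predictor_names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.shape[1] != len(self.predictor_names):
                raise SchemaError(
                    message=f"expected {len(self.predictor_names)} predictor "
                    f"columns, got {X.shape[1]}"
                )
        return (X - self.means) / self.scales

    def decision_scores(
        self, X: pd.DataFrame | np.ndarray, n_components: int | None = None
    ) -> np.ndarray:
        """Continuous PLS prediction of the 0/1 response."""
        a = self.effective_components if n_components is None else n_components
        return self._design(X) @ self.coefficients_for(a) + self.y_mean

    def predict_grass_probability(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """P(GRASS) per row, via the training-set logistic calibration."""
        alpha, beta = self.calibration
        z = alpha * self.decision_scores(X) + beta
        return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))

    def predict_modality(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Hard class by the 0.5 probability threshold (= argmax class)."""
        prob = self.predict_grass_probability(X)
        return np.where(prob >= 0.5, self.classes[1], self.classes[0])


def fit_pls(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    n_components: int,
    predictor_names: list[str] | None = None,
) -> PlsDaModel:
    """Fit a PLS1 discriminant model with ``n_components`` latent variables.

    Constant (zero-variance) predictors are dropped with a warning before
    scaling.  Extraction stops early, recording the effective component
    count, once the predictor or response residual is numerically zero.
    """
    if isinstance(X, pd.DataFrame):
        predictor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if predictor_names is None:
            predictor_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise InputError("X and y length mismatch")
    A = int(n_components)
    if A < 1:
        raise InputError("n_components must be >= 1")
    if A > min(p, n - 1):
        raise InputError(
            f"n_components={A} exceeds min(p, n-1) = {min(p, n - 1)}"
        )

    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    keep = scales > 1e-12
    dropped = [name for name, k in zip(predictor_names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant predictor(s): {dropped}",
            stacklevel=2,
        )
        X = X[:, keep]
        means, scales = means[keep], scales[keep]
        predictor_names = [name for name, k in zip(predictor_names, keep) if k]
        p = X.shape[1]
        if p == 0:
            raise InputError("all predictors constant")
        A = min(A, p)

    Xc = (X - means) / scales
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, A))
    Pl = np.zeros((p, A))
    q = np.zeros(A)
    Rm = np.zeros((p, A))
    tt = np.zeros(A)
    eff = 0
    x_norm0 = np.linalg.norm(Xc)
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < _RESIDUAL_TOL * max(x_norm0, 1.0):
            break
        w /= nw
        t = Xc @ w
        ss = float(t @ t)
        if ss < _RESIDUAL_TOL:
            break
        p_load = Xc.T @ t / ss
        q_a = float(yc @ t / ss)
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q_a * t
        # r_a spans the same prediction as w_a in original (undeflated) space
        r = w - Rm[:, :a] @ (Pl[:, :a].T @ w)
        W[:, a], Pl[:, a], q[a], Rm[:, a], tt[a] = w, p_load, q_a, r, ss
        eff = a + 1
    if eff == 0:
        raise InputError("response carries no covariance with the predictors")

    model = PlsDaModel(
        predictor_names=predictor_names,
        means=means,
        scales=scales,
        W=W[:, :eff],
        P=Pl[:, :eff],
        q=q[:eff],
        R=Rm[:, :eff],
        score_ss=tt[:eff],
        n_components=int(n_components),
        effective_components=eff,
        y_mean=y_mean,
        dropped=dropped,
    )
    model.calibration = _platt_fit(model.decision_scores(X), y)
    return model


def select_n_components(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    max_components: int = MAX_COMPONENTS,
    k: int = 10,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count by stratified k-fold CV AUC.

    Returns ``(A*, mean_auc)`` where ``mean_auc[a-1]`` is the mean
    cross-validated AUC with a components.  The component count is capped
    (default 30) to limit over-fitting; ties are broken toward fewer
    components.  One NIPALS fit per fold at the cap supplies predictions for
    every smaller count.
    """
    from .evaluation import roc_auc, stratified_folds

    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_A = min(int(max_components), MAX_COMPONENTS, X.shape[1], X.shape[0] - 2)
    folds = stratified_folds(y, k=k, seed=seed)
    aucs = np.full((k, max_A), np.nan)
    for fold in range(k):
        test = folds == fold
        model = fit_pls(X[~test], y[~test], max_A)
        for a in range(1, max_A + 1):
            scores = model.decision_scores(X[test], n_components=a)
            aucs[fold, a - 1] = roc_auc(scores, y[test])
    mean_auc = aucs.mean(axis=0)
    best = int(np.argmax(mean_auc)) + 1  # argmax takes the first (smallest) max
    return best, mean_auc


@dataclass
class VipTable:
    """Per-predictor VIP scores: raw (mean-square-1) and 0–100 scaled."""

    predictor_names: list[str]
    raw: np.ndarray
    scaled: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": self.predictor_names, "vip": self.raw, "vip_scaled": self.scaled}
        ).sort_values("vip", ascending=False, ignore_index=True)


def compute_vip(model: PlsDaModel) -> VipTable:
    """VIP score of every predictor over the model's latent variables."""
    W = model.W
    p = W.shape[0]
    # response sum of squares explained by each component: q_a^2 * t_a't_a
    ss = model.q**2 * model.score_ss
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    raw = np.sqrt(p * (wnorm2 @ ss) / ss.sum())
    scaled = 100.0 * raw / raw.max()
    return VipTable(list(model.predictor_names), raw, scaled)


def reduce_by_vip(
    vip: VipTable, threshold: float, X: pd.DataFrame | None = None
) -> list[str]:
    """Predictors whose scaled VIP (0–100) meets the threshold.

    Returns the retained predictor names (refitting on the subset is the
    caller's task); raises :class:`EmptySubsetError` if nothing survives.
    """
    if not 0.0 <= threshold <= 100.0:
        raise InputError("threshold must lie in [0, 100]")
    retained = [
        name for name, s in zip(vip.predictor_names, vip.scaled) if s >= threshold
    ]
    if not retained:
        raise EmptySubsetError(f"VIP threshold {threshold} removed every predictor")
    if X is not None:
        missing = [c for c in retained if c not in X.columns]
        if missing:
            raise SchemaError(missing)
    return retained


def save_model(model: PlsDaModel, path: str | Path) -> None:
    """Serialise a fitted model to a versioned plain-text (JSON) file."""
    payload = {
        "format": "grassmilk-plsda",
        "version": FORMAT_VERSION,
        "predictor_names": model.predictor_names,
        "means": model.means.tolist(),
        "scales": model.scales.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "R": model.R.tolist(),
        "score_ss": model.score_ss.tolist(),
        "n_components": model.n_components,
        "effective_components": model.effective_components,
        "y_mean": model.y_mean,
        "calibration": list(model.calibration),
        "classes": list(model.classes),
        "dropped": model.dropped,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> PlsDaModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "grassmilk-plsda":
        raise InputError(f"{path}: not a grassmilk PLS-DA model file")
    if payload.get("version") != FORMAT_VERSION:
        raise InputError(f"{path}: unsupported model format version")
    return PlsDaModel(
        predictor_names=list(payload["predictor_names"]),
        means=np.array(payload["means"]),
        scales=np.array(payload["scales"]),
        W=np.array(payload["W"]),
        P=np.array(payload["P"]),
        q=np.array(payload["q"]),
        R=np.array(payload["R"]),
        score_ss=np.array(payload["score_ss"]),
        n_components=int(payload["n_components"]),
        effective_components=int(payload["effective_components"]),
        y_mean=float(payload["y_mean"]),
        calibration=tuple(payload["calibration"]),  # type: ignore[arg-type]
        classes=tuple(payload["classes"]),  # type: ignore[arg-type]
        dropped=list(payload["dropped"]),
    )
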