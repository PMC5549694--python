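"""Orthogonal projections to latent structures (O-PLS) for a single response.

The model splits the predictor matrix into one predictive component, whose
scores t1 carry all response-correlated variation, and k orthogonal
components carrying systematic variation uncorrelated with the response:

    X = t1 p1' + To Po' + E
    y = t1 q1  + F

Fitting uses the NIPALS-style deflation scheme: at each orthogonal round the
response-weight vector w is computed, the loading p of the current predictive
score is split into its w-parallel and w-orthogonal parts, and the orthogonal
score/loading pair is deflated from X. Columns of X and y are centred and
(by default) scaled to unit variance before fitting; all constants are stored
on the model so that new samples are projected with training statistics only.

Cross-validated predictive ability Q2Y uses deterministic venetian-blind
folds (row i -> fold i mod folds) with the full centring/scaling/deflation
pipeline refit in every fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "OplsModel",
    "EvalReport",
    "DiagnosticResult",
    "center_scale",
    "fit_opls",
    "predict_opls",
    "cross_validate_q2",
    "autofit",
    "dmodx",
    "hotelling_t2",
    "loading_correlations",
    "classify",
    "confusion_metrics",
]

CLASS_THRESHOLD = 0.5  # malignant iff y_hat >= 0.5 (0 = benign, 1 = malignant)


class OplsError(ValueError):
    pass


@dataclass
class OplsModel:
    """Fitted O-PLS model: predictive + orthogonal parts and scaling state."""

    n_ortho: int
    w: np.ndarray          # (m,) predictive weights, unit norm
    p1: np.ndarray         # (m,) predictive loading
    q1: float              # scalar response loading (scaled space)
    t1: np.ndarray         # (n,) predictive scores
    To: np.ndarray         # (n, k) orthogonal scores
    Po: np.ndarray         # (m, k) orthogonal loadings
    Wo: np.ndarray         # (m, k) orthogonal weights, unit-norm columns
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    E: np.ndarray          # (n, m) X residual
    F: np.ndarray          # (n,) y residual (scaled space)
    score_variances: np.ndarray  # variance (ddof=1) of [t1, To columns]
    scaling_mode: str = "uv"
    y_kind: str = "class"
    degenerate_columns: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        """Total components A = 1 predictive + k orthogonal."""
        return 1 + self.n_ortho

    @property
    def n_samples(self) -> int:
        return self.t1.size

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "model": "opls",
            "scaling_mode": self.scaling_mode,
            "y_kind": self.y_kind,
            "n_ortho": self.n_ortho,
            "q1": self.q1,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
        }
        for name in ("w", "p1", "t1", "To", "Po", "Wo", "x_mean", "x_scale",
                     "E", "F", "score_variances"):
            doc[name] = getattr(self, name).tolist()
        doc["degenerate_columns"] = (
            self.degenerate_columns.tolist()
            if self.degenerate_columns is not None else None
        )
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OplsModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        k = doc["n_ortho"]
        m = len(doc["w"])
        n = len(doc["t1"])

        def arr(name):
            return np.asarray(doc[name], dtype=float)

        def mat(name, rows, cols):
            return np.asarray(doc[name], dtype=float).reshape(rows, cols)
        return cls(
            n_ortho=k,
            w=arr("w"), p1=arr("p1"), q1=float(doc["q1"]), t1=arr("t1"),
            To=mat("To", n, k), Po=mat("Po", m, k), Wo=mat("Wo", m, k),
            x_mean=arr("x_mean"), x_scale=arr("x_scale"),
            y_mean=float(doc["y_mean"]), y_scale=float(doc["y_scale"]),
            E=mat("E", n, m), F=arr("F"),
            score_variances=arr("score_variances"),
            scaling_mode=doc["scaling_mode"], y_kind=doc["y_kind"],
            degenerate_columns=(
                np.asarray(doc["degenerate_columns"], dtype=bool)
                if doc["degenerate_columns"] is not None else None
            ),
        )


@dataclass
class EvalReport:
    """Fit / validation metrics; confusion fields populated for class models."""

    r2y: float | None = None
    q2y: float | None = None
    folds: int | None = None
    confusion: tuple[int, int, int, int] | None = None  # (TP, FP, TN, FN)
    sensitivity: float | None = None  # percent
    specificity: float | None = None  # percent


@dataclass
class DiagnosticResult:
    dmodx: np.ndarray | None = None
    t2: np.ndarray | None = None
    t2_crit: float | None = None
    dmodx_crit: float | None = None


def center_scale(
    X: np.ndarray, y: np.ndarray, mode: str = "uv"
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Centre columns of X and y; scale per ``mode``.

    ``uv`` divides by the column SD (ddof=1), ``pareto`` by its square root,
    ``none`` centres only. Zero-variance columns keep scale 1 and are
    flagged, not fatal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 3:
        raise OplsError(f"need n >= 3 samples, got {X.shape[0]}")
    if mode not in ("uv", "pareto", "none"):
        raise OplsError(f"unknown scaling mode {mode!r}")
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    if mode == "uv":
        x_scale = np.where(degenerate, 1.0, sd)
    elif mode == "pareto":
        x_scale = np.where(degenerate, 1.0, np.sqrt(sd))
    else:
        x_scale = np.ones_like(sd)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if mode == "uv":
        y_scale = y_sd if y_sd > 0 else 1.0
    elif mode == "pareto":
        y_scale = np.sqrt(y_sd) if y_sd > 0 else 1.0
    else:
        y_scale = 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    constants = {
        "x_mean": x_mean, "x_scale": x_scale,
        "y_mean": y_mean, "y_scale": y_scale,
        "degenerate": degenerate,
    }
    return Xs, ys, constants


def fit_opls(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 3,
    mode: str = "uv",
    y_kind: str = "class",
) -> OplsModel:
    """Fit a single-response O-PLS model with ``n_ortho`` orthogonal rounds.

    The sign convention is fixed so q1 >= 0: higher t1 corresponds to higher
    response values (for 0/1 class coding, malignant samples score high).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.size != n:
        raise OplsError("X row count and y length differ")
    if np.ptp(y) == 0:
        raise OplsError("response is constant; cannot fit")
    if n_ortho < 0 or n_ortho >= min(n, m) - 1:
        raise OplsError(
            f"n_ortho must satisfy 0 <= k < min(n, m) - 1, got {n_ortho}"
        )
    Xs, ys, const = center_scale(X, y, mode)

    Xw = Xs.copy()
    Wo = np.zeros((m, n_ortho))
    Po = np.zeros((m, n_ortho))
    To = np.zeros((n, n_ortho))
    yy = float(ys @ ys)
    for a in range(n_ortho):
        w = Xw.T @ ys / yy
        nw = np.linalg.norm(w)
        if nw == 0:
            raise OplsError("degenerate weight vector during deflation")
        w /= nw
        t = Xw @ w
        p = Xw.T @ t / (t @ t)
        wo = p - (w @ p) * w  # w has unit norm
        nwo = np.linalg.norm(wo)
        if nwo == 0:
            raise OplsError(
                f"no orthogonal variation left at component {a + 1}"
            )
        wo /= nwo
        to = Xw @ wo
        po = Xw.T @ to / (to @ to)
        Xw = Xw - np.outer(to, po)
        Wo[:, a], Po[:, a], To[:, a] = wo, po, to

    w = Xw.T @ ys / yy
    w /= np.linalg.norm(w)
    t1 = Xw @ w
    p1 = Xw.T @ t1 / (t1 @ t1)
    q1 = float(ys @ t1 / (t1 @ t1))
    if q1 < 0:  # orient: high t1 = high response (malignant for 0/1 coding)
        w, t1, p1, q1 = -w, -t1, -p1, -q1
    E = Xw - np.outer(t1, p1)
    F = ys - t1 * q1
    scores = np.column_stack([t1, To]) if n_ortho else t1[:, None]
    return OplsModel(
        n_ortho=n_ortho, w=w, p1=p1, q1=q1, t1=t1, To=To, Po=Po, Wo=Wo,
        x_mean=const["x_mean"], x_scale=const["x_scale"],
        y_mean=const["y_mean"], y_scale=const["y_scale"],
        E=E, F=F,
        score_variances=scores.var(axis=0, ddof=1),
        scaling_mode=mode, y_kind=y_kind,
        degenerate_columns=const["degenerate"],
    )


def _project(model: OplsModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale new rows with training constants and strip orthogonal variation.

    Returns (deflated scaled X, t1_new, To_new)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.w.size:
        raise OplsError(
            f"column count {X_new.shape[1]} does not match model ({model.w.size})"
        )
    Xs = (X_new - model.x_mean) / model.x_scale
    To_new = np.zeros((Xs.shape[0], model.n_ortho))
    for a in range(model.n_ortho):
        to = Xs @ model.Wo[:, a]
        Xs = Xs - np.outer(to, model.Po[:, a])
        To_new[:, a] = to
    t1_new = Xs @ model.w
    return Xs, t1_new, To_new


def predict_opls(
    model: OplsModel, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project new samples: returns (t1_new, To_new, y_hat in response units)."""
    _, t1_new, To_new = _project(model, X_new)
    y_hat = t1_new * model.q1 * model.y_scale + model.y_mean
    return t1_new, To_new, y_hat


def _r2y(model: OplsModel) -> float:
    ss_res = float(model.F @ model.F)
    ys = model.F + model.t1 * model.q1  # centred/scaled y
    ss_tot = float(ys @ ys)
    return 1.0 - ss_res / ss_tot


def cross_validate_q2(
    X: np.ndarray,
    y: np.ndarray,
    n_ortho: int = 3,
    folds: int = 7,
    mode: str = "uv",
    y_kind: str = "class",
) -> EvalReport:
    """R2Y on the full fit and venetian-blind cross-validated Q2Y.

    Fold assignment is deterministic: row i belongs to fold i mod folds. The
    entire centring/scaling/deflation pipeline is refit on each training
    split; PRESS accumulates squared out-of-fold errors in response units and
    Q2Y = 1 - PRESS / SS_tot with SS_tot about the full-data mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if folds < 2:
        raise OplsError("need at least 2 folds")
    fold_id = np.arange(n) % folds
    counts = np.bincount(fold_id, minlength=folds)
    if counts.min() < 1 or (n - counts.max()) < 3:
        raise OplsError("a fold has too few samples for refitting")
    press = 0.0
    for f in range(folds):
        test = fold_id == f
        if test.sum() == 0:
            raise OplsError(f"fold {f} is empty")
        sub = fit_opls(X[~test], y[~test], n_ortho, mode, y_kind)
        _, _, y_hat = predict_opls(sub, X[test])
        press += float(((y[test] - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    full = fit_opls(X, y, n_ortho, mode, y_kind)
    return EvalReport(r2y=_r2y(full), q2y=1.0 - press / ss_tot, folds=folds)


def autofit(
    X: np.ndarray,
    y: np.ndarray,
    max_ortho: int = 10,
    folds: int = 7,
    mode: str = "uv",
    y_kind: str = "class",
    min_gain: float = 0.01,
) -> int:
    """Number of orthogonal components: add while Q2Y improves by > min_gain."""
    best_k = 0
    best_q2 = cross_validate_q2(X, y, 0, folds, mode, y_kind).q2y
    k = 0
    while k < max_ortho:
        k += 1
        try:
            q2 = cross_validate_q2(X, y, k, folds, mode, y_kind).q2y
        except OplsError:
            break
        if q2 - best_q2 > min_gain:
            best_k, best_q2 = k, q2
        else:
            break
    return best_k


def dmodx(model: OplsModel, X_new: np.ndarray | None = None) -> np.ndarray:
    """Normalized residual distance to the model plane.

    s_i = sqrt(sum_j e_ij^2 / (m - A)); the pooled training residual SD
    s_0 = sqrt(sum e^2 / ((n - A - 1)(m - A))) normalizes both training and
    new samples. A = 1 + k total components.
    """
    A = model.n_components
    m = model.w.size
    n = model.n_samples
    if m <= A:
        raise OplsError(f"m = {m} must exceed A = {A}")
    if n <= A + 1:
        raise OplsError(f"n = {n} too small for DModX normalization")
    s0 = np.sqrt(float((model.E ** 2).sum()) / ((n - A - 1) * (m - A)))
    if X_new is None:
        E = model.E
    else:
        Xs, t1_new, _ = _project(model, X_new)
        E = Xs - np.outer(t1_new, model.p1)
    s = np.sqrt((E ** 2).sum(axis=1) / (m - A))
    if s0 == 0.0:
        return np.where(s == 0.0, 0.0, np.inf)
    return s / s0


def hotelling_t2(
    model: OplsModel,
    scores: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Hotelling's T2 of score vectors with its F-distribution control limit.

    T2_i = sum_a t_ia^2 / var(t_a) over the A = 1 + k components, variances
    taken from training scores (ddof=1);
    T2_crit = A (n-1) / (n - A) * F_{1-alpha}(A, n - A).
    """
    A = model.n_components
    n = model.n_samples
    if n <= A:
        raise OplsError(f"n = {n} must exceed A = {A}")
    if scores is None:
        scores = np.column_stack([model.t1, model.To]) if model.n_ortho \
            else model.t1[:, None]
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != A:
        raise OplsError(f"scores must have {A} columns")
    var = model.score_variances
    t2 = ((scores ** 2) / var).sum(axis=1)
    t2_crit = A * (n - 1) / (n - A) * stats.f.ppf(1 - alpha, A, n - A)
    return t2, float(t2_crit)


def loading_correlations(
    model: OplsModel,
    X: np.ndarray,
    orient_benign_positive: bool = True,
) -> dict[str, np.ndarray]:
    """Per-bin Pearson correlation and covariance with the predictive score.

    Computed on training-scaled X columns against t1 (the p(corr)/covariance
    pair of an S-plot). With ``orient_benign_positive`` the sign is flipped
    so that bins elevated in benign samples (low t1) plot positive.
    Zero-variance bins return 0 and are flagged.
    """
    Xs = (np.asarray(X, dtype=float) - model.x_mean) / model.x_scale
    t1 = model.t1
    if Xs.shape[0] != t1.size:
        raise OplsError("X row count does not match training scores")
    tc = t1 - t1.mean()
    xc = Xs - Xs.mean(axis=0)
    n = t1.size
    cov = xc.T @ tc / (n - 1)
    sx = xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    degenerate = (sx == 0.0) | (st == 0.0)
    denom = np.where(degenerate, 1.0, sx * st)
    corr = np.where(degenerate, 0.0, cov / denom)
    cov = np.where(degenerate, 0.0, cov)
    if orient_benign_positive:
        corr, cov = -corr, -cov
    return {"correlation": corr, "covariance": cov, "degenerate": degenerate}


def classify(y_hat: np.ndarray, model: OplsModel | None = None) -> np.ndarray:
    """0/1 class calls at the 0.5 threshold; ties call malignant (1)."""
    if model is not None and model.y_kind != "class":
        raise OplsError("classify requires a class-response model")
    y_hat = np.asarray(y_hat, dtype=float)
    return (y_hat >= CLASS_THRESHOLD).astype(int)


def confusion_metrics(
    y_true: np.ndarray, y_call: np.ndarray
) -> tuple[tuple[int, int, int, int], float, float]:
    """(TP, FP, TN, FN), sensitivity %, specificity % (malignant positive)."""
    y_true = np.asarray(y_true).astype(int)
    y_call = np.asarray(y_call).astype(int)
    tp = int(((y_true == 1) & (y_call == 1)).sum())
    fp = int(((y_true == 0) & (y_call == 1)).sum())
    tn = int(((y_true == 0) & (y_call == 0)).sum())
    fn = int(((y_true == 1) & (y_call == 0)).sum())
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
    return (tp, fp, tn, fn), sens, spec
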