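"""Multivariate engines: MCR-ALS, PLS regression, and epsilon-SVR.

MCR-ALS (multivariate curve resolution by alternating least squares)
decomposes a spectral matrix X (n_samples x n_wavenumbers) into non-negative
scores C and component spectra S with X ~ C @ S, reporting per-component and
cumulative percent variance fitted.

PLS and SVR quantify the four alcohols from preprocessed (scaled-subtracted,
area-normalized) spectra.  Both are cross-validated with a venetian-blinds
split (sample i -> fold (i // thickness) mod n_splits).  PLS uses a
NIPALS-equivalent factorization with Q-residual and Hotelling T^2 diagnostics;
SVR uses the epsilon-insensitive loss with a Gaussian RBF kernel, one
independent model per alcohol, with (C, gamma) chosen by grid search on the
cross-validation RMSE (ties broken toward smaller C, then smaller gamma).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR as _SkSVR

from .spectra import ALCOHOLS, WavenumberGrid


@dataclass
class SpectralMatrix:
    """Row-wise preprocessed spectra ready for multivariate modelling."""

    X: np.ndarray
    row_ids: List[str]
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples x n_wavenumbers)")
        if self.X.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match X rows")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("X columns must match the wavenumber grid")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must not contain missing/non-finite values")


# ---------------------------------------------------------------------------
# cross-validation layout


def venetian_blinds(n_samples: int, n_splits: int = 39, thickness: int = 1) -> np.ndarray:
    """Fold assignment: sample i belongs to fold (i // thickness) mod n_splits."""
    if n_splits < 2 or thickness < 1:
        raise ValueError("need n_splits >= 2 and thickness >= 1")
    i = np.arange(n_samples)
    return (i // thickness) % n_splits


# ---------------------------------------------------------------------------
# MCR-ALS


@dataclass
class McrModel:
    n_components: int
    C: np.ndarray  # (n, k) >= 0
    S: np.ndarray  # (k, p) >= 0
    cumulative_fit: float  # percent variance explained
    per_component_fit: np.ndarray  # percent per component, sorted descending
    converged: bool
    n_iter: int
    objective_history: List[float]

    def reconstruct(self) -> np.ndarray:
        return self.C @ self.S


def _fnnls(AtA: np.ndarray, Atb: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Fast non-negative least squares on the normal equations (Bro & De Jong).

    Solves min ||A x - b||^2 s.t. x >= 0 given AtA = A'A and Atb = A'b; exact
    active-set method, suitable for the small k of MCR problems.
    """
    k = AtA.shape[0]
    passive = np.zeros(k, dtype=bool)
    x = np.zeros(k)
    w = Atb - AtA @ x
    tol = 1e-12 * max(1.0, float(np.abs(Atb).max(initial=0.0)))
    it = 0
    while (not passive.all()) and np.any(w[~passive] > tol) and it < max_iter:
        it += 1
        j = int(np.argmax(np.where(~passive, w, -np.inf)))
        passive[j] = True
        while True:
            idx = np.flatnonzero(passive)
            s = np.zeros(k)
            s[idx] = np.linalg.solve(AtA[np.ix_(idx, idx)], Atb[idx])
            if np.all(s[idx] > tol):
                x = s
                break
            neg = idx[s[idx] <= tol]
            alpha = np.min(x[neg] / (x[neg] - s[neg] + 1e-300))
            x = x + alpha * (s - x)
            passive[np.abs(x) < tol] = False
            x[~passive] = 0.0
        w = Atb - AtA @ x
    return x


def _nnls_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Solve min ||basis @ coef_i - target_i|| with coef >= 0 for each row of
    ``targets``; basis is (m x k)."""
    AtA = basis.T @ basis
    AtB = basis.T @ targets.T  # (k, n_targets)
    out = np.empty((targets.shape[0], basis.shape[1]))
    for i in range(targets.shape[0]):
        out[i] = _fnnls(AtA, AtB[:, i])
    return out


def _purest_rows(X: np.ndarray, k: int) -> np.ndarray:
    """SIMPLISMA-style initial spectra: iteratively pick the rows least
    representable by those already selected (orthogonal-projection purity)."""
    Xn = X / (np.linalg.norm(X, axis=1, keepdims=True) + 1e-300)
    chosen: List[int] = [int(np.argmax(np.linalg.norm(X, axis=1)))]
    R = Xn.copy()
    for _ in range(1, k):
        v = Xn[chosen[-1]]
        v = v / (np.linalg.norm(v) + 1e-300)
        R = R - np.outer(R @ v, v)
        nxt = int(np.argmax(np.linalg.norm(R, axis=1)))
        chosen.append(nxt)
    return np.clip(X[chosen], 0.0, None)


def mcr_als(
    X: SpectralMatrix | np.ndarray,
    k: int,
    init: str = "simplisma",
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: Optional[int] = None,
) -> McrModel:
    """Non-negative alternating least squares decomposition X ~ C S.

    The squared-residual objective is non-increasing across iterations (each
    half-step is an exact constrained least-squares solve); convergence is
    declared when the relative fit change drops below ``tol``.  Components are
    sorted by explained variance.
    """
    mat = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    n, p = mat.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k must be in [1, min(n, p)] = [1, {min(n, p)}]")
    if init == "simplisma":
        S = _purest_rows(mat, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        S = rng.random((k, p)) * float(np.abs(mat).max())
    else:
        raise ValueError("init must be 'simplisma' or 'random'")
    S = np.clip(S, 0.0, None) + 1e-12

    total = float(np.sum(mat * mat))
    history: List[float] = []
    converged = False
    C = np.zeros((n, k))
    it = 0
    for it in range(1, max_iter + 1):
        C = _nnls_rows(S.T, mat)  # rows of C: min ||S' c - x||
        # guard collapsed components so the next solve is well-posed
        dead = np.linalg.norm(C, axis=0) <= 0
        if np.any(dead):
            C[:, dead] = 1e-12
        S = _nnls_rows(C, mat.T).T  # columns of S
        obj = float(np.sum((mat - C @ S) ** 2))
        history.append(obj)
        if len(history) > 1 and abs(history[-2] - obj) <= tol * max(history[-2], 1e-300):
            converged = True
            break

    fit = 100.0 * (1.0 - history[-1] / total) if total > 0 else 100.0
    # per-component shares partition the cumulative fit in proportion to each
    # rank-1 term's energy (cross terms between non-negative components are
    # folded in proportionally, so the shares sum to the cumulative fit)
    per = np.array([float(np.sum(np.outer(C[:, j], S[j]) ** 2)) for j in range(k)])
    per = fit * per / per.sum() if per.sum() > 0 else per
    order = np.argsort(per)[::-1]
    return McrModel(
        n_components=k, C=C[:, order], S=S[order], cumulative_fit=fit,
        per_component_fit=per[order], converged=converged, n_iter=it,
        objective_history=history,
    )


def match_components(S: np.ndarray, references: Mapping[str, np.ndarray]) -> List[Tuple[str, float]]:
    """Greedy one-to-one assignment of components to named reference spectra
    by maximal cosine similarity (Hungarian-equivalent for our small k)."""
    names = list(references)
    R = np.array([references[nm] / (np.linalg.norm(references[nm]) + 1e-300) for nm in names])
    Sn = S / (np.linalg.norm(S, axis=1, keepdims=True) + 1e-300)
    sim = Sn @ R.T  # (k, n_refs)
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-sim)
    out: List[Tuple[str, float]] = [("", 0.0)] * S.shape[0]
    for r, c in zip(rows, cols):
        out[r] = (names[c], float(sim[r, c]))
    return out


# ---------------------------------------------------------------------------
# PLS


@dataclass
class PlsModel:
    n_lv: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    coef: np.ndarray  # (p, m)
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    targets: List[str]
    x_variance: np.ndarray  # cumulative fraction of X variance per LV
    cv_rmse: Optional[np.ndarray] = None  # per target, % v/v
    cv_r2: Optional[np.ndarray] = None
    q_residuals: Optional[np.ndarray] = None
    hotelling_t2: Optional[np.ndarray] = None
    q_limit: Optional[float] = None
    t2_limit: Optional[float] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_x) @ self.coef + self.mean_y


def _fit_pls_core(X: np.ndarray, Y: np.ndarray, n_lv: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, Y)
    return pls


def fit_pls(
    X: np.ndarray | SpectralMatrix,
    Y: np.ndarray,
    n_lv: int,
    cv_splits: int = 39,
    cv_thickness: int = 1,
    targets: Optional[Sequence[str]] = None,
    compute_cv: bool = True,
) -> PlsModel:
    """Mean-centered PLS regression with venetian-blinds cross-validation.

    X rows are preprocessed spectra; Y columns are % v/v responses per alcohol.
    Q residuals and Hotelling T^2 (with 95% limits) are reported per training
    sample for diagnostics only.
    """
    Xm = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Xm.shape
    if n_lv >= n:
        raise ValueError("n_lv must be smaller than the number of samples")
    rank = np.linalg.matrix_rank(Xm - Xm.mean(axis=0))
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds the rank {rank} of centered X")
    targets = list(targets) if targets is not None else list(ALCOHOLS)[: Y.shape[1]]

    pls = _fit_pls_core(Xm, Y, n_lv)
    mean_x, mean_y = Xm.mean(axis=0), Y.mean(axis=0)
    Xc = Xm - mean_x
    T = pls.x_scores_
    P = pls.x_loadings_
    total_x = float(np.sum(Xc * Xc))
    cum = []
    recon = np.zeros_like(Xc)
    for a in range(n_lv):
        recon += np.outer(T[:, a], P[:, a])
        cum.append(float(np.sum(recon * recon)) / total_x if total_x > 0 else 1.0)
    x_variance = np.array(cum)

    E = Xc - T @ P.T
    q = np.sum(E * E, axis=1)
    lam = np.var(T, axis=0, ddof=1)
    t2 = np.sum((T / np.sqrt(lam + 1e-300)) ** 2, axis=1)
    # 95% limits: F-based for T^2, Box chi-square approximation for Q
    t2_lim = n_lv * (n - 1) / max(n - n_lv, 1) * stats.f.ppf(0.95, n_lv, max(n - n_lv, 1))
    th1, th2 = float(np.mean(q)), float(np.var(q, ddof=1)) if n > 1 else 0.0
    if th1 > 0 and th2 > 0:
        g, h = th2 / (2 * th1), 2 * th1 * th1 / th2
        q_lim = float(g * stats.chi2.ppf(0.95, h))
    else:
        q_lim = 0.0

    cv_rmse = cv_r2 = None
    if compute_cv:
        folds = venetian_blinds(n, cv_splits, cv_thickness)
        pred = np.empty_like(Y)
        for f in np.unique(folds):
            tr, te = folds != f, folds == f
            sub = _fit_pls_core(Xm[tr], Y[tr], n_lv)
            pred[te] = sub.predict(Xm[te])
        resid = pred - Y
        cv_rmse = np.sqrt(np.mean(resid**2, axis=0))
        sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        cv_r2 = 1.0 - np.sum(resid**2, axis=0) / np.where(sst > 0, sst, np.inf)

    return PlsModel(
        n_lv=n_lv, mean_x=mean_x, mean_y=mean_y,
        coef=pls.coef_.T if pls.coef_.shape[0] == Y.shape[1] else pls.coef_,
        x_weights=pls.x_weights_, x_loadings=P, x_scores=T,
        targets=targets, x_variance=x_variance,
        cv_rmse=cv_rmse, cv_r2=cv_r2,
        q_residuals=q, hotelling_t2=t2, q_limit=q_lim, t2_limit=float(t2_lim),
    )


# ---------------------------------------------------------------------------
# SVR


@dataclass(frozen=True)
class SvrHyperparams:
    C_cost: float
    gamma: float
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if self.C_cost <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")


#: default grid-search ranges (log-spaced); the study's exact ranges are not
#: published, these are declared method defaults
DEFAULT_C_GRID: Tuple[float, ...] = tuple(np.logspace(0, 4, 6))
DEFAULT_GAMMA_GRID: Tuple[float, ...] = tuple(np.logspace(-4, 1, 6))
DEFAULT_EPSILON = 0.5  # % v/v insensitivity tube half-width


@dataclass
class SvrModel:
    """Per-alcohol epsilon-SVR ensemble with shared preprocessing state."""

    targets: List[str]
    estimators: Dict[str, _SkSVR]
    hyperparams: Dict[str, SvrHyperparams]
    mean_x: np.ndarray
    scale_x: float
    cv_rmse: Optional[np.ndarray] = None
    cv_r2: Optional[np.ndarray] = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_x) / self.scale_x

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform(X)
        return np.column_stack([self.estimators[t].predict(Z) for t in self.targets])


def fit_svr(
    X: np.ndarray | SpectralMatrix,
    Y: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    epsilon: float = DEFAULT_EPSILON,
    cv_splits: int = 39,
    cv_thickness: int = 1,
    targets: Optional[Sequence[str]] = None,
) -> SvrModel:
    """Grid-searched Gaussian-RBF epsilon-SVR, one model per alcohol.

    X is mean-centered and scaled by one global standard deviation (preserving
    relative spectral structure).  For each target the (C, gamma) pair with
    the lowest venetian-blinds CV RMSE is selected (ties toward smaller C,
    then smaller gamma) and the final model is refit on all training data.
    """
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    Xm = X.X if isinstance(X, SpectralMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Xm.shape[0]
    targets = list(targets) if targets is not None else list(ALCOHOLS)[: Y.shape[1]]
    for j in range(Y.shape[1]):
        if np.unique(Y[:, j]).size < 2:
            # constant response: SVR degenerates to the constant; still allowed
            pass

    mean_x = Xm.mean(axis=0)
    Xc = Xm - mean_x
    scale = float(np.std(Xc))
    if scale <= 0:
        scale = 1.0
    Z = Xc / scale
    folds = venetian_blinds(n, cv_splits, cv_thickness)
    uniq = np.unique(folds)

    estimators: Dict[str, _SkSVR] = {}
    chosen: Dict[str, SvrHyperparams] = {}
    cv_rmse = np.empty(Y.shape[1])
    cv_r2 = np.empty(Y.shape[1])
    for j, name in enumerate(targets):
        y = Y[:, j]
        best: Tuple[float, float, float] | None = None  # (rmse, C, gamma)
        best_pred: Optional[np.ndarray] = None
        for C in sorted(c_grid):
            for gamma in sorted(gamma_grid):
                pred = np.empty(n)
                for f in uniq:
                    tr, te = folds != f, folds == f
                    est = _SkSVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
                    est.fit(Z[tr], y[tr])
                    pred[te] = est.predict(Z[te])
                rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
                if best is None or rmse < best[0] - 1e-12:
                    best = (rmse, C, gamma)
                    best_pred = pred
        assert best is not None and best_pred is not None
        rmse, C, gamma = best
        hp = SvrHyperparams(C_cost=C, gamma=gamma, epsilon=epsilon)
        est = _SkSVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
        est.fit(Z, y)
        estimators[name] = est
        chosen[name] = hp
        cv_rmse[j] = rmse
        sst = float(np.sum((y - y.mean()) ** 2))
        cv_r2[j] = 1.0 - float(np.sum((best_pred - y) ** 2)) / sst if sst > 0 else 0.0

    return SvrModel(targets=targets, estimators=estimators, hyperparams=chosen,
                    mean_x=mean_x, scale_x=scale, cv_rmse=cv_rmse, cv_r2=cv_r2)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class RegressionReport:
    targets: List[str]
    rmse: np.ndarray  # % v/v per target
    r2: np.ndarray
    split: str  # cross_validation | prediction

    def as_dict(self) -> Dict[str, Dict[str, float]]:
        return {
            t: {"rmse": float(self.rmse[i]), "r2": float(self.r2[i])}
            for i, t in enumerate(self.targets)
        }


def evaluate(model, X_test: np.ndarray, Y_test: np.ndarray,
             split: str = "prediction") -> RegressionReport:
    """Per-alcohol RMSE and R^2 = 1 - SSres/SStot of model predictions."""
    Y_test = np.asarray(Y_test, dtype=float)
    if Y_test.ndim == 1:
        Y_test = Y_test[:, None]
    pred = model.predict(X_test)
    pred = np.asarray(pred, dtype=float)
    if pred.ndim == 1:
        pred = pred[:, None]
    if pred.shape != Y_test.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {Y_test.shape}")
    resid = pred - Y_test
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    sst = np.sum((Y_test - Y_test.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - np.sum(resid**2, axis=0) / sst
    r2 = np.where(sst > 0, r2, 0.0)
    targets = getattr(model, "targets", None) or [f"y{j}" for j in range(Y_test.shape[1])]
    return RegressionReport(targets=list(targets), rmse=rmse, r2=r2, split=split)


# ---------------------------------------------------------------------------
# persistence (versioned JSON)

_FORMAT_VERSION = 1


def _model_payload(model) -> Dict:
    if hasattr(model, "mask") and hasattr(model, "model"):  # masked wrapper
        return {
            "format_version": _FORMAT_VERSION, "kind": "masked",
            "mask": np.flatnonzero(np.asarray(model.mask)).tolist(),
            "n_channels": int(np.asarray(model.mask).size),
            "inner": _model_payload(model.model),
        }
    return _plain_payload(model)


def save_model(model, path) -> None:
    """Persist a PLS or SVR model (optionally channel-masked) as versioned JSON."""
    with open(path, "w") as fh:
        json.dump(_model_payload(model), fh)


def _plain_payload(model) -> Dict:
    if isinstance(model, PlsModel):
        payload = {
            "format_version": _FORMAT_VERSION, "kind": "pls",
            "n_lv": model.n_lv, "targets": model.targets,
            "mean_x": model.mean_x.tolist(), "mean_y": np.asarray(model.mean_y).tolist(),
            "coef": model.coef.tolist(),
        }
    elif isinstance(model, SvrModel):
        ests = {}
        for t, est in model.estimators.items():
            ests[t] = {
                "support_vectors": est.support_vectors_.tolist(),
                "dual_coef": est.dual_coef_.tolist(),
                "intercept": est.intercept_.tolist(),
                "gamma": model.hyperparams[t].gamma,
                "C": model.hyperparams[t].C_cost,
                "epsilon": model.hyperparams[t].epsilon,
            }
        payload = {
            "format_version": _FORMAT_VERSION, "kind": "svr",
            "targets": model.targets, "mean_x": model.mean_x.tolist(),
            "scale_x": model.scale_x, "estimators": ests,
        }
    else:
        raise TypeError(f"cannot persist model of type {type(model).__name__}")
    return payload


class _LoadedSvr:
    """Kernel-expansion predictor reconstructed from persisted SVR state:
    f(x) = sum_i alpha_i exp(-gamma ||x - x_i||^2) + b."""

    def __init__(self, sv: np.ndarray, dual: np.ndarray, intercept: float, gamma: float):
        self.sv, self.dual, self.intercept, self.gamma = sv, dual, intercept, gamma

    def predict(self, Z: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(Z * Z, axis=1)[:, None]
            + np.sum(self.sv * self.sv, axis=1)[None, :]
            - 2.0 * Z @ self.sv.T
        )
        return np.exp(-self.gamma * d2) @ self.dual + self.intercept


@dataclass
class LoadedModel:
    kind: str
    targets: List[str]
    _predict: "callable"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._predict(np.asarray(X, dtype=float))


def load_model(path) -> LoadedModel:
    with open(path) as fh:
        payload = json.load(fh)
    return _load_payload(payload)


def _load_payload(payload) -> LoadedModel:
    version = payload.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    if payload["kind"] == "masked":
        inner = _load_payload(payload["inner"])
        cols = np.array(payload["mask"], dtype=int)
        return LoadedModel(inner.kind, inner.targets,
                           lambda X, _i=inner, _c=cols: _i.predict(X[:, _c]))
    if payload["kind"] == "pls":
        mean_x = np.array(payload["mean_x"])
        mean_y = np.array(payload["mean_y"])
        coef = np.array(payload["coef"])
        return LoadedModel("pls", payload["targets"],
                           lambda X: (X - mean_x) @ coef + mean_y)
    if payload["kind"] == "svr":
        mean_x = np.array(payload["mean_x"])
        scale = float(payload["scale_x"])
        preds = {}
        for t, e in payload["estimators"].items():
            preds[t] = _LoadedSvr(np.array(e["support_vectors"]),
                                  np.array(e["dual_coef"]).ravel(),
                                  float(np.ravel(e["intercept"])[0]),
                                  float(e["gamma"]))
        targets = payload["targets"]

        def _p(X: np.ndarray) -> np.ndarray:
            Z = (X - mean_x) / scale
            return np.column_stack([preds[t].predict(Z) for t in targets])

        return LoadedModel("svr", targets, _p)
    raise ValueError(f"unknown model kind {payload['kind']!r}")
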