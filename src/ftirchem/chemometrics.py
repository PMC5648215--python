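"""Multivariate core: column scaling, NIPALS partial least squares,
cross-validated predictability (Q2Y), VIP scores, PCA, and error metrics.

The PLS fit is the classic NIPALS algorithm with X (and Y) deflation per
component.  For a single-column response the inner loop is closed-form
(weight vector proportional to X'y), so PLS1 fits cost one pass per
component; PLS2 iterates to a 1e-10 tolerance.  Regression coefficients
B reproduce the component-wise recursion exactly, and predictions carry
the stored column scaling so models apply directly to new raw
(preprocessed) spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


class FitError(RuntimeError):
    """Raised when a model cannot be fitted as requested."""


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingSpec:
    """Column centering/scaling learned on training data.

    ``uv`` divides by the column standard deviation (autoscaling);
    ``pareto`` by its square root; ``center_only`` centers without
    scaling.  Standard deviations use the n-1 (sample) convention.
    """

    method: str
    column_means: np.ndarray
    column_scales: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.column_means) / self.column_scales


def scale_columns(X: np.ndarray, method: str = "uv") -> tuple[np.ndarray, ScalingSpec]:
    """Center and scale columns; returns the scaled matrix and the spec."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FitError("scaling requires a 2-D matrix with at least 2 samples")
    if method not in ("uv", "pareto", "center_only"):
        raise ValueError(f"unknown scaling method {method!r}")
    means = X.mean(axis=0)
    if method == "center_only":
        scales = np.ones(X.shape[1])
    else:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise FitError(
                f"{int((sd <= 0).sum())} constant column(s); drop them before "
                "uv/pareto scaling")
        scales = sd if method == "uv" else np.sqrt(sd)
    spec = ScalingSpec(method, means, scales)
    return spec.apply(X), spec


def dummy_code(labels: Sequence) -> tuple[np.ndarray, list]:
    """Dummy-code class labels for PLS-DA.

    Two classes give a single 0/1 column (first class in sorted order = 0),
    which keeps RMSE in class units; k > 2 classes give k one-hot columns.
    Returns ``(Y, class_order)``.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for discriminant coding")
    if len(classes) == 2:
        y = (labels == classes[1]).astype(float)[:, None]
    else:
        y = np.array([[1.0 if lab == c else 0.0 for c in classes] for lab in labels])
    return y, classes


# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray          # W: p x A, unit columns
    x_loadings: np.ndarray       # P: p x A
    y_loadings: np.ndarray       # C: m x A
    scores: np.ndarray           # T: n x A (training scores)
    coefficients: np.ndarray     # B: p x m, for scaled X and centered Y
    ssy_per_component: np.ndarray
    r2y_cum: float
    q2y_cum: float | None
    x_scaling: ScalingSpec
    y_means: np.ndarray
    variable_ids: np.ndarray | None = None
    class_labels: list | None = None
    n_train: int = 0

    def predict(self, X_new: np.ndarray, variable_ids=None) -> np.ndarray:
        """Predict responses for raw (preprocessed, unscaled) spectra."""
        X_new = np.atleast_2d(np.asarray(X_new, float))
        if variable_ids is not None and self.variable_ids is not None:
            want = np.asarray(self.variable_ids)
            have = np.asarray(variable_ids)
            if want.shape != have.shape or not np.allclose(want, have):
                missing = sorted(set(np.round(want, 6)) - set(np.round(have, 6)))
                raise ValueError(f"wavenumber mismatch; missing {missing[:10]}")
        if X_new.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"expected {self.coefficients.shape[0]} variables, got {X_new.shape[1]}")
        return self.x_scaling.apply(X_new) @ self.coefficients + self.y_means

    def classify(self, X_new: np.ndarray, variable_ids=None):
        """Hard class calls: 0.5 threshold for 2-class, argmax otherwise."""
        if self.class_labels is None:
            raise ValueError("not a discriminant model: no class labels stored")
        yhat = self.predict(X_new, variable_ids)
        if len(self.class_labels) == 2:
            idx = (yhat[:, 0] > 0.5).astype(int)
        else:
            idx = np.argmax(yhat, axis=1)
        return [self.class_labels[i] for i in idx]


def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """One NIPALS component on deflated matrices; returns w, t, c."""
    if Y.shape[1] == 1:
        w = X.T @ Y[:, 0]
        nw = np.linalg.norm(w)
        if nw == 0:
            raise FitError("zero covariance between X and Y; cannot extract component")
        w = w / nw
        t = X @ w
        c = Y.T @ t / (t @ t)
        return w, t, c
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    t_old = None
    for _ in range(NIPALS_MAX_ITER):
        w = X.T @ u / (u @ u)
        w /= np.linalg.norm(w)
        t = X @ w
        c = Y.T @ t / (t @ t)
        u = Y @ c / (c @ c)
        if t_old is not None and np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
            return w, t, c
        t_old = t
    raise FitError(f"NIPALS inner loop did not converge in {NIPALS_MAX_ITER} iterations")


def _fix_sign(w: np.ndarray, t: np.ndarray, c: np.ndarray):
    """Make the largest-|w| element positive for reproducible output."""
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        return -w, -t, -c
    return w, t, c


def fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int,
            x_scaling: ScalingSpec | None = None,
            y_means: np.ndarray | None = None,
            variable_ids=None, class_labels=None) -> PLSModel:
    """NIPALS PLS2 on a scaled X and centered Y.

    ``X`` and ``Y`` are assumed already centered/scaled (use
    :func:`scale_columns` and subtract the Y mean); pass the specs so the
    model can be applied to new raw data.  ``n_components`` must not
    exceed ``min(n_samples - 1, n_variables)``.
    """
    X = np.asarray(X, float).copy()
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    Y = Y.copy()
    n, p = X.shape
    m = Y.shape[1]
    A = int(n_components)
    if A < 1 or A > min(n - 1, p):
        raise FitError(
            f"n_components={A} outside [1, min(n-1={n - 1}, p={p})]")

    ss_tot = float((Y ** 2).sum())
    if ss_tot == 0:
        raise FitError("response has zero variance")

    W = np.empty((p, A))
    P = np.empty((p, A))
    C = np.empty((m, A))
    T = np.empty((n, A))
    ssy = np.empty(A)
    Yd = Y.copy()
    for a in range(A):
        try:
            w, t, c = _nipals_component(X, Yd)
        except FitError as exc:
            raise FitError(f"component {a + 1}: {exc}") from exc
        w, t, c = _fix_sign(w, t, c)
        tt = float(t @ t)
        pvec = X.T @ t / tt
        X -= np.outer(t, pvec)
        ssy_before = float((Yd ** 2).sum())
        Yd -= np.outer(t, c)
        ssy[a] = ssy_before - float((Yd ** 2).sum())
        W[:, a], P[:, a], C[:, a], T[:, a] = w, pvec, c, t

    # B = W (P'W)^-1 C'
    B = W @ np.linalg.solve(P.T @ W, C.T)
    r2y = 1.0 - float((Yd ** 2).sum()) / ss_tot
    return PLSModel(
        n_components=A, weights=W, x_loadings=P, y_loadings=C, scores=T,
        coefficients=B, ssy_per_component=ssy, r2y_cum=r2y, q2y_cum=None,
        x_scaling=x_scaling or ScalingSpec("center_only", np.zeros(p), np.ones(p)),
        y_means=np.zeros(m) if y_means is None else np.asarray(y_means, float),
        variable_ids=None if variable_ids is None else np.asarray(variable_ids),
        class_labels=class_labels, n_train=n)


def fit_pls_raw(X_raw: np.ndarray, Y_raw: np.ndarray, n_components: int,
                scaling: str = "uv", variable_ids=None,
                class_labels=None) -> PLSModel:
    """Convenience: scale X, center Y, and fit in one call."""
    Xs, spec = scale_columns(X_raw, scaling)
    Y_raw = np.atleast_2d(np.asarray(Y_raw, float))
    if Y_raw.shape[0] != np.asarray(X_raw).shape[0]:
        Y_raw = Y_raw.T
    ym = Y_raw.mean(axis=0)
    return fit_pls(Xs, Y_raw - ym, n_components, x_scaling=spec, y_means=ym,
                   variable_ids=variable_ids, class_labels=class_labels)


# ---------------------------------------------------------------------------
# Cross-validated Q2Y
# ---------------------------------------------------------------------------

def venetian_blinds_folds(n: int, n_folds: int) -> list[np.ndarray]:
    """Interleaved fold assignment: fold k gets samples k, k+n_folds, ..."""
    idx = np.arange(n)
    return [idx[k::n_folds] for k in range(n_folds)]


def q2y(X_raw: np.ndarray, Y_raw: np.ndarray, n_components: int,
        n_folds: int = 7, scaling: str = "uv",
        fold_scheme: str = "venetian", seed: int | None = None) -> float:
    """Cross-validated predictability, Q2Y = 1 - PRESS/SS_tot.

    Folds are contiguous-interleaved ("venetian blinds") over sample order
    by default, or a seeded random partition with ``fold_scheme='random'``.
    Column scaling and Y centering are refit inside every training fold.
    """
    X_raw = np.asarray(X_raw, float)
    Y_raw = np.atleast_2d(np.asarray(Y_raw, float))
    if Y_raw.shape[0] != X_raw.shape[0]:
        Y_raw = Y_raw.T
    n = X_raw.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds={n_folds} outside [2, n={n}]")
    if fold_scheme == "venetian":
        folds = venetian_blinds_folds(n, n_folds)
    elif fold_scheme == "random":
        order = np.random.default_rng(seed).permutation(n)
        folds = [order[k::n_folds] for k in range(n_folds)]
    else:
        raise ValueError(f"unknown fold_scheme {fold_scheme!r}")

    # a fold whose removal leaves a constant response (single class in
    # discriminant use) cannot be fitted; merge it into its neighbour
    def trainable(test_idx):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        return Y_raw[mask].std(axis=0).min() > 0

    merged: list[np.ndarray] = []
    for test_idx in folds:
        if merged and not trainable(test_idx):
            import warnings
            warnings.warn("fold leaves a constant response; merging folds")
            merged[-1] = np.concatenate([merged[-1], test_idx])
        else:
            merged.append(test_idx)

    press = 0.0
    for test_idx in merged:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        A = min(n_components, int(mask.sum()) - 1)
        model = fit_pls_raw(X_raw[mask], Y_raw[mask], A, scaling=scaling)
        yhat = model.predict(X_raw[test_idx])
        press += float(((Y_raw[test_idx] - yhat) ** 2).sum())
    ss_tot = float(((Y_raw - Y_raw.mean(axis=0)) ** 2).sum())
    return 1.0 - press / ss_tot


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def rmsee(model: PLSModel, X_train_raw: np.ndarray, Y_train_raw: np.ndarray) -> float:
    """Root-mean-square error of estimation on the training set, with the
    chemometric degrees-of-freedom divisor n - 1 - A."""
    Y_train_raw = np.atleast_2d(np.asarray(Y_train_raw, float))
    if Y_train_raw.shape[0] != np.asarray(X_train_raw).shape[0]:
        Y_train_raw = Y_train_raw.T
    n = Y_train_raw.shape[0]
    if n <= model.n_components + 1:
        raise FitError(f"RMSEE undefined: n={n} <= A+1={model.n_components + 1}")
    resid = Y_train_raw - model.predict(X_train_raw)
    return float(np.sqrt((resid ** 2).sum() / (n - 1 - model.n_components)))


def rmsep(model: PLSModel, X_test_raw: np.ndarray, Y_test_raw: np.ndarray) -> float:
    """Root-mean-square error of prediction on held-out samples."""
    Y_test_raw = np.atleast_2d(np.asarray(Y_test_raw, float))
    if Y_test_raw.shape[0] != np.asarray(X_test_raw).shape[0]:
        Y_test_raw = Y_test_raw.T
    resid = Y_test_raw - model.predict(X_test_raw)
    return float(np.sqrt((resid ** 2).mean()))


def rmse_to_months(rmse: float, class_gap_months: float = 12.0) -> float:
    """Convert a class-unit RMSE to months for 0/1 age coding of classes
    ``class_gap_months`` apart (5- vs 6-year-old: 12 months)."""
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    return rmse * class_gap_months


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

@dataclass
class VIPResult:
    vip: np.ndarray
    cutoff: float | None = None
    retained_mask: np.ndarray | None = None

    @property
    def retained_count(self) -> int:
        return 0 if self.retained_mask is None else int(self.retained_mask.sum())


def vip_scores(model: PLSModel) -> VIPResult:
    """Variable influence on projection.

    VIP_j = sqrt( p * sum_a[ ssy_a * (w_aj/||w_a||)^2 ] / sum_a ssy_a ),
    where ssy_a is the Y sum of squares explained by component a.  The
    mean of VIP^2 over variables is exactly 1.
    """
    W = model.weights
    ssy = model.ssy_per_component
    total = ssy.sum()
    if total <= 0:
        raise FitError("no explained Y variance; VIP undefined")
    wnorm2 = (W / np.linalg.norm(W, axis=0)) ** 2
    p = W.shape[0]
    vip = np.sqrt(p * (wnorm2 @ ssy) / total)
    return VIPResult(vip=vip)


def select_by_vip(vip: VIPResult | np.ndarray, cutoff: float) -> VIPResult:
    """Retain variables with VIP strictly greater than ``cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    scores = vip.vip if isinstance(vip, VIPResult) else np.asarray(vip, float)
    mask = scores > cutoff
    return VIPResult(vip=scores, cutoff=cutoff, retained_mask=mask)


class EmptySelectionError(ValueError):
    """Raised when a VIP cutoff retains no variables (infeasible cell)."""


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: np.ndarray, n_components: int):
    """PCA by SVD of the column-centered matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` with
    loadings as columns.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} > min(n-1, p)")
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    # reproducible sign: largest-|loading| element positive per component
    for a in range(n_components):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U[:, :n_components] * sv[:n_components]
    loadings = Vt[:n_components].T
    frac = (sv ** 2) / (sv ** 2).sum()
    return scores, loadings, frac[:n_components]


# ---------------------------------------------------------------------------
# Model serialization (structured text, JSON)
# ---------------------------------------------------------------------------

def save_model(model: PLSModel, path) -> None:
    import json
    d = {
        "n_components": model.n_components,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "coefficients": model.coefficients.tolist(),
        "ssy_per_component": model.ssy_per_component.tolist(),
        "r2y_cum": model.r2y_cum,
        "q2y_cum": model.q2y_cum,
        "scaling": {"method": model.x_scaling.method,
                    "column_means": model.x_scaling.column_means.tolist(),
                    "column_scales": model.x_scaling.column_scales.tolist()},
        "y_means": model.y_means.tolist(),
        "variable_ids": None if model.variable_ids is None else model.variable_ids.tolist(),
        "class_labels": model.class_labels,
        "n_train": model.n_train,
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_model(path) -> PLSModel:
    import json
    with open(path) as fh:
        d = json.load(fh)
    spec = ScalingSpec(d["scaling"]["method"],
                       np.asarray(d["scaling"]["column_means"]),
                       np.asarray(d["scaling"]["column_scales"]))
    p = len(d["coefficients"])
    return PLSModel(
        n_components=d["n_components"],
        weights=np.asarray(d["weights"]),
        x_loadings=np.asarray(d["x_loadings"]),
        y_loadings=np.asarray(d["y_loadings"]),
        scores=np.empty((0, d["n_components"])),
        coefficients=np.asarray(d["coefficients"]).reshape(p, -1),
        ssy_per_component=np.asarray(d["ssy_per_component"]),
        r2y_cum=d["r2y_cum"], q2y_cum=d["q2y_cum"], x_scaling=spec,
        y_means=np.asarray(d["y_means"]),
        variable_ids=None if d["variable_ids"] is None else np.asarray(d["variable_ids"]),
        class_labels=d["class_labels"], n_train=d["n_train"])
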