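"""Permutation-test model validation with R2Y/Q2Y intercepts.

A PLS(-DA) fit can look good by chance on wide spectral matrices, so a
model is accepted only after a response-permutation test: the response
rows are shuffled many times, the model refit each time with identical
settings, and R2Y and Q2Y plotted against the correlation between the
permuted and original responses.  Straight lines fit separately to the
R2Y and Q2Y point clouds (permuted points plus the unpermuted model at
correlation 1) are read at correlation 0; a model is "valid" when the
R2Y intercept is below 0.4 and the Q2Y intercept below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemometrics import fit_pls_raw, q2y

R2Y_INTERCEPT_LIMIT = 0.4
Q2Y_INTERCEPT_LIMIT = 0.05


def is_valid_model(r2y_intercept: float, q2y_intercept: float) -> bool:
    """Strict validity gate: R2Y intercept < 0.4 and Q2Y intercept < 0.05."""
    if not (np.isfinite(r2y_intercept) and np.isfinite(q2y_intercept)):
        raise ValueError("intercepts must be finite")
    return r2y_intercept < R2Y_INTERCEPT_LIMIT and q2y_intercept < Q2Y_INTERCEPT_LIMIT


@dataclass
class PermutationResult:
    n_permutations: int
    points: np.ndarray        # (n_permutations + 1, 3): correlation, r2y, q2y
    r2y_intercept: float
    q2y_intercept: float
    valid: bool
    seed: int | None

    def to_table(self):
        import pandas as pd
        return pd.DataFrame(self.points, columns=["correlation", "r2y", "q2y"])


def _label_correlation(Y_perm: np.ndarray, Y_orig: np.ndarray) -> float:
    """Mean over response columns of |Pearson r(permuted, original)|."""
    corrs = []
    for j in range(Y_orig.shape[1]):
        a, b = Y_perm[:, j], Y_orig[:, j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            corrs.append(1.0 if np.allclose(a, b) else 0.0)
            continue
        corrs.append(abs(float(np.corrcoef(a, b)[0, 1])))
    return float(np.mean(corrs))


def _line_intercept(x: np.ndarray, y: np.ndarray, through_point=None) -> float:
    """Intercept at x=0 of a least-squares line.

    ``through_point=(x0, y0)`` instead forces the line through that point
    and fits only the slope.
    """
    if through_point is not None:
        x0, y0 = through_point
        dx, dy = x - x0, y - y0
        denom = float(dx @ dx)
        slope = float(dx @ dy) / denom if denom > 0 else 0.0
        return y0 - slope * x0
    if np.ptp(x) == 0:
        return float(y.mean())
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def permutation_test(X_raw: np.ndarray, Y_raw: np.ndarray, n_components: int,
                     n_permutations: int = 400, seed: int | None = None,
                     scaling: str = "uv", n_folds: int = 7,
                     anchor_line: bool = False) -> PermutationResult:
    """Response-permutation validity test for one PLS configuration.

    For each permutation the rows of Y are shuffled with a seeded
    generator, the model refit with the same number of components,
    scaling, and cross-validation scheme, and (correlation, R2Y, Q2Y)
    recorded; the unpermuted model contributes the point at correlation 1.
    Intercepts are ordinary least-squares lines through all points,
    evaluated at zero correlation (``anchor_line=True`` instead forces
    each line through the unpermuted point).
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be at least 20")
    X_raw = np.asarray(X_raw, float)
    Y_raw = np.atleast_2d(np.asarray(Y_raw, float))
    if Y_raw.shape[0] != X_raw.shape[0]:
        Y_raw = Y_raw.T
    if np.allclose(Y_raw.std(axis=0), 0):
        raise ValueError("constant response; permutation test undefined")

    def evaluate(Y):
        model = fit_pls_raw(X_raw, Y, n_components, scaling=scaling)
        q2 = q2y(X_raw, Y, n_components, n_folds=n_folds, scaling=scaling)
        return model.r2y_cum, q2

    r2_orig, q2_orig = evaluate(Y_raw)
    rng = np.random.default_rng(seed)
    n = X_raw.shape[0]
    pts = np.empty((n_permutations + 1, 3))
    for k in range(n_permutations):
        perm = rng.permutation(n)
        Yp = Y_raw[perm]
        r2p, q2p = evaluate(Yp)
        pts[k] = (_label_correlation(Yp, Y_raw), r2p, q2p)
    pts[-1] = (1.0, r2_orig, q2_orig)

    anchor = (1.0, r2_orig) if anchor_line else None
    r2_int = _line_intercept(pts[:, 0], pts[:, 1], anchor)
    anchor_q = (1.0, q2_orig) if anchor_line else None
    q2_int = _line_intercept(pts[:, 0], pts[:, 2], anchor_q)
    return PermutationResult(
        n_permutations=n_permutations, points=pts,
        r2y_intercept=r2_int, q2y_intercept=q2_int,
        valid=is_valid_model(r2_int, q2_int), seed=seed)
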