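"""Multi-response partial least squares (PLS2) regression, from scratch.

PLS2 decomposes mean-centered predictor and response matrices into a shared
low-dimensional latent space,

    X = T P' + E,      Y = U Q' + F,

where the score vectors t_a are chosen sequentially to maximize covariance
with the response under orthogonality constraints.  Prediction uses the
regression form Y ≈ 1 b0' + X B, packaged as an augmented coefficient
matrix B~ of shape (P+1) × Q whose first row is the intercept, so that
Yhat = [1 | X_new] B~.

Two extraction algorithms are provided:

* ``simpls`` (default): de Jong's SIMPLS, the statistically direct
  formulation in which each weight vector maximizes covariance with the
  deflated cross-product matrix.  X-scores are mutually orthogonal.
* ``nipals``: the classical iterative NIPALS PLS2 loop, kept behind a flag
  and cross-checked against SIMPLS for single-response problems (the two
  coincide when Q = 1).

Both operate on mean-centered data with no variance scaling; the intercept
absorbs the centering.  Constant predictor columns are centered to zero and
therefore receive zero weight (an implicit column drop); a fully constant X
raises :class:`DegeneracyError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold

from ._exceptions import ConfigError, DegeneracyError, RankError

#: Deflation vectors shorter than this terminate component extraction.
DEFLATION_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS2 state.

    ``B_tilde`` stacks the intercept ``b0`` (row 0) on top of the P×Q
    coefficient matrix ``B``; ``b0 = y_mean − x_mean · B``.
    """

    A: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray      # P × A (X-weights R: T = Xc R)
    x_loadings: np.ndarray   # P × A
    y_loadings: np.ndarray   # Q × A
    x_scores: np.ndarray     # N × A
    B: np.ndarray            # P × Q
    b0: np.ndarray           # Q
    algorithm: str = "simpls"

    @property
    def B_tilde(self) -> np.ndarray:
        return np.vstack([self.b0[None, :], self.B])

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


@dataclass
class ComponentSelection:
    """Cross-validated choice of the number of latent components."""

    ranks: list[int]
    cv_rmse: dict[int, float]
    chosen: int


def _validate_fit_inputs(X: np.ndarray, Y: np.ndarray, A: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    if not 1 <= A <= min(n - 1, p):
        raise RankError(
            f"A={A} infeasible: must satisfy 1 <= A <= min(N-1, P) = "
            f"{min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise DegeneracyError("X has zero variance in every column")
    const = np.all(np.isclose(Xc, 0.0, atol=1e-300), axis=0)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant predictor column(s) carry zero "
            "weight after centering",
            stacklevel=3,
        )
    return X, Y


def _simpls(Xc: np.ndarray, Yc: np.ndarray, A: int):
    """SIMPLS component extraction on centered matrices."""
    n, p = Xc.shape
    q = Yc.shape[1]
    S = Xc.T @ Yc
    R = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    V = np.zeros((p, A))  # orthonormal basis of X-loadings, for deflation
    a_eff = A
    for a in range(A):
        # dominant left singular vector of the deflated cross-product
        u, sv, _ = np.linalg.svd(S, full_matrices=False)
        if sv[0] < DEFLATION_TOL:
            warnings.warn(
                f"deflated covariance exhausted at component {a}; capping "
                f"A at {a}",
                stacklevel=4,
            )
            a_eff = a
            break
        r = u[:, 0]
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm < DEFLATION_TOL:
            warnings.warn(
                f"score vector degenerate at component {a}; capping A at {a}",
                stacklevel=4,
            )
            a_eff = a
            break
        t /= tnorm
        r /= tnorm
        pload = Xc.T @ t
        qload = Yc.T @ t
        v = pload.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pload)
        vnorm = np.linalg.norm(v)
        if vnorm < DEFLATION_TOL:
            warnings.warn(
                f"deflation basis degenerate at component {a}; capping A at {a}",
                stacklevel=4,
            )
            a_eff = a
            break
        v /= vnorm
        S = S - v[:, None] @ (v[None, :] @ S)
        R[:, a], T[:, a], P[:, a], Q[:, a], V[:, a] = r, t, pload, qload, v
    if a_eff == 0:
        raise DegeneracyError("no latent component could be extracted")
    return R[:, :a_eff], T[:, :a_eff], P[:, :a_eff], Q[:, :a_eff]


def _nipals(Xc: np.ndarray, Yc: np.ndarray, A: int, max_iter: int = 500,
            tol: float = 1e-10):
    """NIPALS PLS2 on centered matrices; returns R with T = Xc R."""
    n, p = Xc.shape
    q = Yc.shape[1]
    Xw, Yw = Xc.copy(), Yc.copy()
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    Q = np.zeros((q, A))
    a_eff = A
    for a in range(A):
        # start u from the Y column with largest variance
        u = Yw[:, int(np.argmax(Yw.var(axis=0)))].copy()
        if np.linalg.norm(Yw) < DEFLATION_TOL or np.linalg.norm(Xw) < DEFLATION_TOL:
            warnings.warn(
                f"residual exhausted at component {a}; capping A at {a}",
                stacklevel=4,
            )
            a_eff = a
            break
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xw.T @ u
            wn = np.linalg.norm(w)
            if wn < DEFLATION_TOL:
                break
            w /= wn
            t_new = Xw @ w
            qv = Yw.T @ t_new
            qn = np.linalg.norm(qv)
            if qn < DEFLATION_TOL:
                t = t_new
                break
            u = Yw @ (qv / qn)
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                break
            t = t_new
        tt = t @ t
        if tt < DEFLATION_TOL:
            warnings.warn(
                f"score vector degenerate at component {a}; capping A at {a}",
                stacklevel=4,
            )
            a_eff = a
            break
        pload = Xw.T @ t / tt
        qload = Yw.T @ t / tt
        Xw = Xw - np.outer(t, pload)
        Yw = Yw - np.outer(t, qload)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, pload, qload
    if a_eff == 0:
        raise DegeneracyError("no latent component could be extracted")
    W, T, P, Q = W[:, :a_eff], T[:, :a_eff], P[:, :a_eff], Q[:, :a_eff]
    # rotate W so scores are computed directly from centered X: T = Xc R
    R = W @ np.linalg.pinv(P.T @ W)
    return R, T, P, Q


def fit_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    algorithm: Literal["simpls", "nipals"] = "simpls",
) -> PLSModel:
    """Fit a PLS2 model with ``A`` latent components.

    Parameters
    ----------
    X : (N, P) predictor matrix (e.g. transcutaneous spectra).
    Y : (N, Q) response matrix (e.g. exposed-bone spectra); a 1-D vector is
        treated as Q = 1.
    A : number of latent components; must satisfy 1 ≤ A ≤ min(N−1, P).
    algorithm : ``simpls`` (default) or ``nipals``.
    """
    X, Y = _validate_fit_inputs(X, Y, A)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if algorithm == "simpls":
        R, T, P, Q = _simpls(Xc, Yc, A)
    elif algorithm == "nipals":
        R, T, P, Q = _nipals(Xc, Yc, A)
    else:
        raise ConfigError(f"unknown PLS algorithm: {algorithm!r}")
    # With T = Xc R (SIMPLS: T orthonormal, Q = Yc'T; NIPALS: Q from
    # normalized scores) the fitted map is Yhat_c = T Q' = Xc (R Q').
    B = R @ Q.T
    b0 = y_mean - x_mean @ B
    return PLSModel(
        A=R.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=R,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        B=B,
        b0=b0,
        algorithm=algorithm,
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: ``[1 | X_new] @ B_tilde``."""
    X_new = np.asarray(X_new, dtype=float)
    one_dim = X_new.ndim == 1
    if one_dim:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.B.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns; model expects "
            f"{model.B.shape[0]}"
        )
    out = model.b0[None, :] + X_new @ model.B
    return out[0] if one_dim else out


def save_model(model: PLSModel, path) -> None:
    """Serialize a fitted model to a JSON bundle (arrays as nested lists)."""
    import json
    from pathlib import Path

    payload = {
        "A": model.A,
        "algorithm": model.algorithm,
        **{
            k: getattr(model, k).tolist()
            for k in ("x_mean", "y_mean", "weights", "x_loadings",
                      "y_loadings", "x_scores", "B", "b0")
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> PLSModel:
    """Load a model serialized by :func:`save_model`."""
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return PLSModel(
        A=d["A"],
        algorithm=d["algorithm"],
        **{
            k: np.asarray(d[k], dtype=float)
            for k in ("x_mean", "y_mean", "weights", "x_loadings",
                      "y_loadings", "x_scores", "B", "b0")
        },
    )


def select_components(
    X: np.ndarray,
    Y: np.ndarray,
    groups: Sequence[str],
    ranks: Sequence[int] = range(1, 16),
    k_folds: int = 5,
    algorithm: Literal["simpls", "nipals"] = "simpls",
) -> ComponentSelection:
    """Choose the number of latent components by grouped K-fold CV.

    Folds are defined by subject identity so no subject ever appears in
    both the training and validation split of a fold.  The CV error per
    rank is the root mean squared prediction error pooled over all held-out
    rows and response channels; the chosen rank attains the minimum with
    ties broken toward the smallest rank (parsimony).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ConfigError("need at least two distinct groups")
    if uniq.size < k_folds:
        raise ConfigError(
            f"{k_folds} folds requested but only {uniq.size} groups available"
        )
    cand = sorted(set(int(r) for r in ranks))
    if not cand or cand[0] < 1:
        raise RankError("candidate ranks must be positive integers")

    splitter = GroupKFold(n_splits=k_folds)
    folds = list(splitter.split(X, Y, groups))
    max_feasible = min(
        min(len(tr) for tr, _ in folds) - 1, X.shape[1]
    )
    cand = [r for r in cand if r <= max_feasible]
    if not cand:
        raise RankError(
            f"no candidate rank feasible (max feasible is {max_feasible})"
        )

    sq_err = {r: 0.0 for r in cand}
    n_pred = {r: 0 for r in cand}
    for tr, te in folds:
        for r in cand:
            model = fit_pls2(X[tr], Y[tr], r, algorithm=algorithm)
            resid = predict(model, X[te]) - Y[te]
            sq_err[r] += float(np.sum(resid**2))
            n_pred[r] += resid.size
    cv_rmse = {r: float(np.sqrt(sq_err[r] / n_pred[r])) for r in cand}
    chosen = min(cand, key=lambda r: (cv_rmse[r], r))
    return ComponentSelection(ranks=cand, cv_rmse=cv_rmse, chosen=chosen)
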