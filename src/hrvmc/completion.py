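"""Constrained low-rank matrix completion.

Two solvers for filling hidden entries of an approximately low-rank matrix:

* :class:`IZMAImputer` / :func:`complete_matrix` — an interest-zone
  approximation: alternate a projection onto a norm ball with restoration of
  the observed entries, wrapped in a bisection that finds the smallest ball
  radius ``lambda`` at which the observed entries can still be matched to
  the fidelity tolerance ``e_tol``.  The default ball is the nuclear-norm
  ball, the convex surrogate for rank; a spectral-norm ball
  (:func:`clip_spectral`) is also available, but because the zero-filled
  matrix is itself a feasible point of small spectral norm that mode cannot
  impute and is provided for completeness only.
* :class:`SVTImputer` / :func:`svt_complete` — the classic singular value
  thresholding baseline for nuclear-norm completion.

Both are scikit-learn transformers treating NaN as the missing-entry marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ObservationMask",
    "CompletionConfig",
    "CompletionResult",
    "DivergenceError",
    "project",
    "clip_spectral",
    "project_nuclear",
    "izma_update",
    "izma_iterate",
    "complete_matrix",
    "svt_complete",
    "IZMAImputer",
    "SVTImputer",
]


class DivergenceError(RuntimeError):
    """SVT iteration diverged (observed-entry residual keeps growing)."""


@dataclass
class ObservationMask:
    """Boolean matrix marking the known (observed) entries."""

    known: np.ndarray

    def __post_init__(self) -> None:
        self.known = np.asarray(self.known, dtype=bool)
        if not self.known.any():
            raise ValueError("observation mask has no known entries")

    @property
    def hidden(self) -> np.ndarray:
        return ~self.known


@dataclass
class CompletionConfig:
    """Tolerances of the bisection completion.

    ``e_tol`` (Frobenius fidelity on observed entries) and ``lambda_tol``
    (resolution of the norm-bound interval) default to 1e-8 and 10; both are
    absolute, so the data scale must be large against ``lambda_tol`` (HRV
    PSDs in ms^2/Hz are).  The inner tolerances control the alternating
    projection at a fixed lambda.
    """

    e_tol: float = 1e-8
    lambda_tol: float = 10.0
    inner_tol: float = 1e-12
    inner_max_iter: int = 2000
    outer_max_iter: int = 200
    constraint: str = "nuclear"  # "nuclear" | "spectral"
    warm_start: bool = True

    def __post_init__(self) -> None:
        for name in ("e_tol", "lambda_tol", "inner_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("inner_max_iter", "outer_max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.constraint not in ("nuclear", "spectral"):
            raise ValueError("constraint must be 'nuclear' or 'spectral'")


@dataclass
class CompletionResult:
    X: np.ndarray
    lambda_final: float
    epsilon_history: list[float] = field(default_factory=list)
    outer_iterations: int = 0
    converged: bool = False


def _as_known(mask: ObservationMask | np.ndarray) -> np.ndarray:
    """Boolean known-entry grid; empty masks are allowed for the plain
    operators (complete_matrix validates non-degeneracy itself)."""
    if isinstance(mask, ObservationMask):
        return mask.known
    return np.asarray(mask, dtype=bool)


def project(X: np.ndarray, mask: ObservationMask | np.ndarray,
            H: np.ndarray) -> np.ndarray:
    """Observation projection: H's values on known entries, 0 elsewhere."""
    X = np.asarray(X, dtype=float)
    H = np.asarray(H, dtype=float)
    known = _as_known(mask)
    if X.shape != H.shape or X.shape != known.shape:
        raise ValueError("project: shape mismatch")
    return np.where(known, H, 0.0)


def _restrict(X: np.ndarray, known: np.ndarray) -> np.ndarray:
    """X's own values on known entries, 0 elsewhere (used for epsilon)."""
    return np.where(known, X, 0.0)


def clip_spectral(H: np.ndarray, lam: float) -> np.ndarray:
    """Frobenius projection onto the spectral-norm ball of radius ``lam``.

    SVD H = U diag(sigma) V*, return U diag(min(sigma, lam)) V*.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite entries")
    if lam == 0:
        return np.zeros_like(H)
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    return (U * np.minimum(s, lam)) @ Vt


def project_nuclear(H: np.ndarray, lam: float) -> np.ndarray:
    """Frobenius projection onto the nuclear-norm ball of radius ``lam``.

    Projects the singular values onto the simplex {sum <= lam}, i.e. soft
    thresholding with the data-dependent threshold that makes the values sum
    to ``lam`` (no-op if the nuclear norm is already within the ball).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("non-finite entries")
    if lam == 0:
        return np.zeros_like(H)
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    if s.sum() <= lam:
        return H
    # Euclidean projection of s (already sorted desc) onto the simplex
    css = np.cumsum(s)
    idx = np.arange(1, s.size + 1)
    rho = np.nonzero(s - (css - lam) / idx > 0)[0][-1]
    theta = (css[rho] - lam) / (rho + 1.0)
    return (U * np.maximum(s - theta, 0.0)) @ Vt


def izma_update(X_tilde: np.ndarray, mask: ObservationMask | np.ndarray,
                H: np.ndarray) -> np.ndarray:
    """Restore the observed entries of H into the current estimate."""
    X_tilde = np.asarray(X_tilde, dtype=float)
    H = np.asarray(H, dtype=float)
    known = _as_known(mask)
    if X_tilde.shape != H.shape or X_tilde.shape != known.shape:
        raise ValueError("izma_update: shape mismatch")
    return np.where(known, H, X_tilde)


def izma_iterate(
    H: np.ndarray,
    mask: ObservationMask | np.ndarray,
    lam: float,
    cfg: CompletionConfig | None = None,
    X0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Fixed-point iteration T(H, lambda) at a fixed norm bound.

    Starting from the observed entries (hidden entries zero, or ``X0`` for a
    warm start), alternate the norm-ball projection with known-entry
    restoration until the fidelity epsilon = ||restrict(X) - restrict(H)||_F
    stops changing by more than ``inner_tol``.  Returns the last projected
    estimate and its epsilon; the epsilon sequence is nonincreasing (both
    sets are convex, so this is a POCS iteration).
    """
    cfg = cfg or CompletionConfig()
    known = _as_known(mask)
    H = np.asarray(H, dtype=float)
    proj = project_nuclear if cfg.constraint == "nuclear" else clip_spectral
    X = np.where(known, H, 0.0) if X0 is None else np.where(known, H, X0)
    H_known = _restrict(H, known)
    eps_prev = np.inf
    Xt, eps = X, float(np.linalg.norm(H_known))
    for _ in range(cfg.inner_max_iter):
        Xt = proj(X, lam)
        eps = float(np.linalg.norm(_restrict(Xt, known) - H_known))
        X = np.where(known, H, Xt)
        if eps <= 0.5 * cfg.e_tol or abs(eps - eps_prev) < cfg.inner_tol:
            break
        eps_prev = eps
    return Xt, eps


class IZMAImputer(TransformerMixin, BaseEstimator):
    """Interest-zone completion via norm-bound bisection (scikit-learn API).

    Missing entries are NaN.  ``transform`` bisects the norm bound lambda on
    [0, ||restrict(S)||_*]: bounds whose fixed point matches the observed
    entries to ``e_tol`` shrink the interval from above, infeasible ones
    from below, until the interval is resolved to ``lambda_tol``; the
    lowest-lambda feasible estimate is returned.  Consecutive bounds reuse
    the previous estimate as the starting point when ``warm_start`` is on.

    Attributes (set by ``transform``)
    ---------------------------------
    lambda_ : final norm bound
    epsilon_history_ : observed-entry fidelity per outer iteration
    n_outer_ : number of bisection iterations
    converged_ : whether a feasible estimate was found
    """

    def __init__(
        self,
        e_tol: float = 1e-8,
        lambda_tol: float = 10.0,
        inner_tol: float = 1e-12,
        inner_max_iter: int = 2000,
        outer_max_iter: int = 200,
        constraint: str = "nuclear",
        warm_start: bool = True,
    ):
        self.e_tol = e_tol
        self.lambda_tol = lambda_tol
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.outer_max_iter = outer_max_iter
        self.constraint = constraint
        self.warm_start = warm_start

    def _config(self) -> CompletionConfig:
        return CompletionConfig(
            e_tol=self.e_tol,
            lambda_tol=self.lambda_tol,
            inner_tol=self.inner_tol,
            inner_max_iter=self.inner_max_iter,
            outer_max_iter=self.outer_max_iter,
            constraint=self.constraint,
            warm_start=self.warm_start,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        self._config()  # validates parameters
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        known = ~np.isnan(X)
        if known.all():
            self.lambda_, self.epsilon_history_ = float("nan"), []
            self.n_outer_, self.converged_ = 0, True
            return X.copy()
        S = np.where(known, X, 0.0)
        result = _bisect_complete(S, known, self._config())
        self.lambda_ = result.lambda_final
        self.epsilon_history_ = result.epsilon_history
        self.n_outer_ = result.outer_iterations
        self.converged_ = result.converged
        return np.where(known, X, result.X)


def _bisect_complete(
    S: np.ndarray, known: np.ndarray, cfg: CompletionConfig
) -> CompletionResult:
    """Bisection driver shared by IZMAImputer and complete_matrix.

    ``S`` must already be zero-filled on hidden entries.
    """
    A = _restrict(S, known)
    lam_min, lam_max = 0.0, float(np.linalg.svd(A, compute_uv=False).sum())
    lam, lam_prev = 0.0, 1e6
    eps = np.inf
    X = A.copy()
    X_warm = None
    best: tuple[np.ndarray, float, float] | None = None
    history: list[float] = []
    n = 0
    while (best is None or abs(lam - lam_prev) > cfg.lambda_tol) and n < cfg.outer_max_iter:
        lam_prev = lam
        lam = 0.5 * (lam_min + lam_max)
        X, eps = izma_iterate(A, known, lam, cfg, X0=X_warm)
        if cfg.warm_start:
            X_warm = X
        history.append(eps)
        n += 1
        if eps > cfg.e_tol:
            lam_min = lam
        else:
            lam_max = lam
            best = (X, lam, eps)
    if best is not None and eps > cfg.e_tol:
        X, lam, eps = best  # lowest feasible bound evaluated
    return CompletionResult(
        X=X,
        lambda_final=lam,
        epsilon_history=history,
        outer_iterations=n,
        converged=best is not None,
    )


def complete_matrix(
    S: np.ndarray,
    mask: ObservationMask | np.ndarray,
    cfg: CompletionConfig | None = None,
) -> CompletionResult:
    """Complete the hidden entries of ``S``.

    Same driver as :class:`IZMAImputer`; this wrapper keeps the raw norm-ball
    iterate in ``CompletionResult.X`` (observed entries deviate from ``S`` by
    at most the achieved epsilon) so the fidelity is auditable, whereas the
    imputer's ``transform`` re-imposes the observed values exactly.
    """
    known = _as_known(mask)
    S = np.asarray(S, dtype=float)
    if S.shape != known.shape:
        raise ValueError("matrix/mask shape mismatch")
    if known.all():
        raise ValueError("mask has no hidden entries")
    cfg = cfg or CompletionConfig()
    return _bisect_complete(np.where(known, S, 0.0), known, cfg)


class SVTImputer(TransformerMixin, BaseEstimator):
    """Classic singular value thresholding completion (Cai-Candes-Shen).

    Iterates X_k = shrink(Y_k, tau); Y_{k+1} = Y_k + step * P_Omega(S - X_k)
    until the relative observed-entry residual drops below ``tol``.  Defaults
    tau = 5 sqrt(m n) and step = 1.2 m n / |Omega| are the standard choices.
    Missing entries are NaN.
    """

    def __init__(
        self,
        tau: float | None = None,
        step: float | None = None,
        tol: float = 1e-4,
        max_iter: int = 500,
    ):
        self.tau = tau
        self.step = step
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")
        if (self.tau is not None and self.tau <= 0) or (
            self.step is not None and self.step <= 0
        ):
            raise ValueError("tau and step must be positive")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        known = ~np.isnan(X)
        S = np.where(known, X, 0.0)
        m, n_cols = S.shape
        tau = self.tau if self.tau is not None else 5.0 * np.sqrt(m * n_cols)
        step = (
            self.step
            if self.step is not None
            else 1.2 * m * n_cols / max(int(known.sum()), 1)
        )
        norm_obs = float(np.linalg.norm(_restrict(S, known)))
        if norm_obs == 0.0:
            self.n_iter_, self.residuals_ = 0, []
            return S
        Y = np.zeros_like(S)
        Xhat = Y
        residuals: list[float] = []
        for k in range(self.max_iter):
            U, s, Vt = np.linalg.svd(Y, full_matrices=False)
            Xhat = (U * np.maximum(s - tau, 0.0)) @ Vt
            R = np.where(known, S - Xhat, 0.0)
            rel = float(np.linalg.norm(R)) / norm_obs
            residuals.append(rel)
            if rel < self.tol:
                break
            if len(residuals) > 50 and rel > 10.0 * residuals[-51]:
                raise DivergenceError(
                    f"SVT residual grew 10x over 50 iterations (now {rel:.3g})"
                )
            Y = Y + step * R
        self.n_iter_ = len(residuals)
        self.residuals_ = residuals
        return np.where(known, X, Xhat)


def svt_complete(
    S: np.ndarray,
    mask: ObservationMask | np.ndarray,
    tau: float | None = None,
    step: float | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """SVT baseline completion (thin wrapper over SVTImputer).

    Returns the thresholded estimate itself (observed entries approximate
    the data to within ``tol`` relative Frobenius error).
    """
    known = _as_known(mask)
    S = np.asarray(S, dtype=float)
    if S.shape != known.shape:
        raise ValueError("matrix/mask shape mismatch")
    imputer = SVTImputer(tau=tau, step=step, tol=tol, max_iter=max_iter)
    X_nan = np.where(known, S, np.nan)
    return imputer.fit(X_nan).transform(X_nan)
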