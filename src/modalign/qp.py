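"""Quadratic-program engine for the diagonal metric-learning objective.

The feature weights ``w`` (squares of the scaling transform ``u``) maximize

    sum_j gamma_j * Cov(Dw, rho_j)  -  alpha * Var(Dw)  -  lam * ||w - 1||^2
    subject to  Cov(Dw, rho_primary) >= beta,   w >= 0

where ``D`` is the per-feature squared-difference matrix over sampled pairs
and ``rho_j`` the distance vector of secondary modality ``j``.  Covariance is
linear in ``w`` and variance quadratic, so the problem is a convex QP:

    Cov(w, rho_l) = ((1/|P|) a_l - (1/|P|^2) b_l)^T w
    Var(Dw)       = w^T ((1/|P|) S - (1/|P|^2) T) w

with ``a_l = sum_p rho_l[p] D[p,:]``, ``b_l = (sum_p rho_l[p]) (sum_p D[p,:])``,
``S = sum_p D[p,:] D[p,:]^T`` and ``T`` the outer product of the column sums.
All normalizations are population (1/|P|) ones.

The user-facing knobs are ``s`` (minimum Pearson correlation between the
transformed and original primary distances — the distortion budget) and ``q``
(cap on ||w||_inf / ||w||_1 relative to 1/k).  Neither appears directly in the
QP; a grid search over (lam, alpha, beta) keeps the solutions that satisfy
them and returns the one with the best gamma-weighted correlation.

The QP itself — strictly convex with nonnegativity bounds plus one linear
inequality — is solved exactly by reducing the bound-constrained subproblem to
nonnegative least squares (Cholesky factor of the Hessian) and tracking the
covariance-constraint multiplier parametrically, with a final KKT polish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .exceptions import (
    DegenerateModalityError,
    InvalidInputError,
    NoFeasibleSolutionError,
    SolverError,
)

DEFAULT_S = 0.99  # minimum primary-distance correlation (distortion budget)
DEFAULT_Q = 1e3  # weight-concentration cap, deliberately non-binding


@dataclass
class QPTerms:
    """Sufficient statistics of the QP: everything downstream is O(k), not O(|P|)."""

    a: np.ndarray  # (r, k): a_l = sum_p rho_l[p] * D[p, :]
    b: np.ndarray  # (r, k): b_l = (sum_p rho_l[p]) * (sum_p D[p, :])
    S: np.ndarray  # (k, k): sum_p outer(D[p], D[p])
    T: np.ndarray  # (k, k): outer(colsum(D), colsum(D))
    P_size: int
    gammas: np.ndarray  # (r,) signed secondary weights
    a_primary: np.ndarray  # a with rho = row sums of D (unweighted primary dist)
    b_primary: np.ndarray
    rho_vars: np.ndarray  # (r,) population variances of each secondary rho
    primary_var: float  # population variance of the unweighted primary distances

    @property
    def k(self) -> int:
        return self.S.shape[0]

    @property
    def n_secondary(self) -> int:
        return self.a.shape[0]

    @property
    def V(self) -> np.ndarray:
        """Population covariance matrix of the columns of D (symmetrized psd)."""
        V = self.S / self.P_size - self.T / self.P_size**2
        return (V + V.T) / 2.0

    def cov_vec(self, l: int) -> np.ndarray:
        """Vector c_l with Cov(Dw, rho_l) = c_l @ w."""
        return self.a[l] / self.P_size - self.b[l] / self.P_size**2

    @property
    def cov_vecs(self) -> np.ndarray:
        return self.a / self.P_size - self.b / self.P_size**2

    @property
    def primary_cov_vec(self) -> np.ndarray:
        return self.a_primary / self.P_size - self.b_primary / self.P_size**2


@dataclass
class HyperParams:
    """Grid-search configuration around the user-facing s and q constraints.

    ``s`` defaults to 0.99 (values >= 0.9 recommended); ``q`` defaults to 1e3
    so it is rarely a binding constraint.  ``None`` grids are replaced by
    scale-normalized defaults derived from the QP terms.
    """

    s: float = DEFAULT_S
    q: float = DEFAULT_Q
    lambda_grid: Sequence[float] | None = None
    alpha_grid: Sequence[float] | None = None
    beta_grid: Sequence[float] | None = None
    regularizer: str = "ones"  # "ones": ||w-1||^2; "zero": ||w||^2

    def __post_init__(self) -> None:
        if not (0 <= self.s < 1):
            raise InvalidInputError(f"s must be in [0, 1), got {self.s}")
        if self.q <= 0:
            raise InvalidInputError("q must be positive")
        for name in ("lambda_grid", "alpha_grid"):
            grid = getattr(self, name)
            if grid is not None:
                if len(grid) == 0 or min(grid) <= 0:
                    raise InvalidInputError(f"{name} must be non-empty and positive")
        if self.beta_grid is not None and len(self.beta_grid) == 0:
            raise InvalidInputError("beta_grid must be non-empty")
        if self.regularizer not in ("ones", "zero"):
            raise InvalidInputError("regularizer must be 'ones' or 'zero'")


# the top lambda values act as near-identity anchors: w ~= 1 is feasible for
# any s < 1, so a tight distortion budget always has a grid point to fall to
DEFAULT_LAMBDA_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0, 1e4, 1e6)
DEFAULT_ALPHA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
DEFAULT_BETA_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class WeightSolution:
    """Optimal feature weights and everything needed to audit them."""

    w: np.ndarray  # raw solver weights, clipped to be >= 0 exactly
    u: np.ndarray  # elementwise sqrt of w: the scaling transform
    achieved_corr: np.ndarray  # Pearson correlations, primary first
    chosen: tuple[float, float, float]  # (lam, alpha, beta)
    feasible: bool
    objective_value: float  # on the maximization scale
    w_mean1: np.ndarray = field(default=None)  # w rescaled to mean 1 (reporting)
    feasibility_table: list[dict] = field(default_factory=list)
    s: float | None = None
    q: float | None = None
    feature_names: list[str] | None = None
    loadings: np.ndarray | None = None  # d x G back-mapping when fit in reduced space

    def __post_init__(self) -> None:
        if self.w_mean1 is None:
            m = self.w.mean()
            self.w_mean1 = self.w / m if m > 0 else self.w.copy()


def build_qp_terms(
    D: np.ndarray, rhos: Sequence[np.ndarray], gammas: Sequence[float]
) -> QPTerms:
    """Accumulate the covariance/variance building blocks over sampled pairs."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.size == 0:
        raise InvalidInputError("D must be a non-empty |P| x k matrix")
    P_size = D.shape[0]
    rhos = [np.asarray(r, dtype=float) for r in rhos]
    gammas = np.asarray(list(gammas), dtype=float)
    if len(rhos) != len(gammas):
        raise InvalidInputError("one gamma per secondary distance vector required")
    for i, r in enumerate(rhos):
        if r.shape != (P_size,):
            raise InvalidInputError(
                f"rho[{i}] has length {r.shape}, expected ({P_size},)"
            )
    colsum = D.sum(axis=0)
    S = D.T @ D
    T = np.outer(colsum, colsum)
    if rhos:
        R = np.stack(rhos)  # (r, |P|)
        a = R @ D
        b = np.outer(R.sum(axis=1), colsum)
        rho_vars = R.var(axis=1)
    else:
        k = D.shape[1]
        a = np.empty((0, k))
        b = np.empty((0, k))
        rho_vars = np.empty(0)
    rho1 = D.sum(axis=1)
    return QPTerms(
        a=a,
        b=b,
        S=S,
        T=T,
        P_size=P_size,
        gammas=gammas,
        a_primary=rho1 @ D,
        b_primary=rho1.sum() * colsum,
        rho_vars=rho_vars,
        primary_var=float(rho1.var()),
    )


def pearson_corr(w: np.ndarray, D: np.ndarray, rho: np.ndarray) -> float:
    """Population Pearson correlation of the reweighted distances Dw with rho.

    Invariant to positive rescaling of ``w``; raises if either side has zero
    variance.
    """
    dw = np.asarray(D, dtype=float) @ np.asarray(w, dtype=float)
    rho = np.asarray(rho, dtype=float)
    vd = dw.var()
    vr = rho.var()
    if vd <= 0 or vr <= 0:
        raise DegenerateModalityError(
            "zero variance on one side; correlation undefined"
        )
    cov = ((dw - dw.mean()) * (rho - rho.mean())).mean()
    return float(cov / np.sqrt(vd * vr))


def _nnqp(R: np.ndarray, c: np.ndarray) -> np.ndarray:
    """argmin_{w >= 0} (1/2) w^T H w - c^T w with H = R^T R (R upper Cholesky)."""
    z = scipy.linalg.solve_triangular(R, c, trans="T")
    w, _ = scipy.optimize.nnls(R, z)
    return w


def _terms_corrs(terms: QPTerms, w: np.ndarray) -> np.ndarray:
    """Correlations (primary first) from the QP sufficient statistics."""
    var_dw = float(w @ terms.V @ w)
    out = np.full(terms.n_secondary + 1, np.nan)
    if var_dw <= 0:
        return out
    sd = np.sqrt(var_dw)
    if terms.primary_var > 0:
        out[0] = (terms.primary_cov_vec @ w) / (sd * np.sqrt(terms.primary_var))
    for l in range(terms.n_secondary):
        if terms.rho_vars[l] > 0:
            out[l + 1] = (terms.cov_vec(l) @ w) / (sd * np.sqrt(terms.rho_vars[l]))
    return out


def solve_fixed(
    terms: QPTerms,
    lam: float,
    alpha: float,
    beta: float,
    regularizer: str = "ones",
) -> WeightSolution:
    """Solve the QP at fixed (lam, alpha, beta).

    Returns the maximizer of the regularized covariance objective subject to
    ``Cov(Dw, rho_primary) >= beta`` and ``w >= 0``.  An unattainable ``beta``
    is reported through ``feasible=False`` rather than an exception.
    """
    if lam <= 0 or alpha <= 0:
        raise InvalidInputError("lam and alpha must be positive")
    if terms.primary_var <= 0:
        raise DegenerateModalityError(
            "primary distances have zero variance (D may be all zeros)"
        )
    k = terms.k
    V = terms.V
    Q = alpha * V + lam * np.eye(k)
    try:
        R = scipy.linalg.cholesky(2.0 * Q, lower=False)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - lam > 0 guards
        raise SolverError(f"QP Hessian not positive definite: {exc}") from exc

    gamma_cov = terms.gammas @ terms.cov_vecs if terms.n_secondary else np.zeros(k)
    c = gamma_cov + (2.0 * lam * np.ones(k) if regularizer == "ones" else 0.0)
    g = terms.primary_cov_vec

    def solve_at(mu: float) -> np.ndarray:
        return _nnqp(R, c + mu * g)

    w = solve_at(0.0)
    tol = 1e-9 * max(1.0, abs(beta), float(np.abs(g) @ np.maximum(w, 1.0)))
    mu_star = 0.0
    if g @ w < beta - tol:
        if g.max() <= 0 and beta > 0:
            return _package(terms, None, lam, alpha, beta, regularizer)
        w, mu_star, ok = _track_constraint(solve_at, g, beta, w, tol)
        if not ok:
            return _package(terms, None, lam, alpha, beta, regularizer)
        w = _kkt_polish(Q, c, g, beta, w, mu_star)
    np.clip(w, 0.0, None, out=w)
    return _package(terms, w, lam, alpha, beta, regularizer)


def _track_constraint(solve_at, g, beta, w0, tol, max_iter=200):
    """Find mu >= 0 with g @ w(mu) = beta; w(mu) is the NNQP path solution.

    g @ w(mu) is nondecreasing and piecewise linear in mu, so a doubling
    bracket followed by bisection (with a piecewise-linear secant accelerator)
    converges quickly.
    """
    mu_lo, w = 0.0, w0
    mu_hi = 1.0
    for _ in range(max_iter):
        w_hi = solve_at(mu_hi)
        if g @ w_hi >= beta:
            break
        mu_lo = mu_hi
        mu_hi *= 4.0
        if mu_hi > 1e18:
            return w, mu_hi, False
    else:  # pragma: no cover
        return w, mu_hi, False
    w_lo = solve_at(mu_lo)
    for _ in range(max_iter):
        f_lo, f_hi = g @ w_lo - beta, g @ w_hi - beta
        if abs(f_hi) <= tol:
            return w_hi, mu_hi, True
        if mu_hi - mu_lo <= 1e-15 * max(1.0, mu_hi):
            return w_hi, mu_hi, True
        # secant step on the piecewise-linear response, safeguarded by bisection
        if f_hi > f_lo > -np.inf and f_hi != f_lo:
            mu_mid = mu_lo + (mu_hi - mu_lo) * (-f_lo) / (f_hi - f_lo)
            if not (mu_lo < mu_mid < mu_hi):
                mu_mid = 0.5 * (mu_lo + mu_hi)
        else:
            mu_mid = 0.5 * (mu_lo + mu_hi)
        w_mid = solve_at(mu_mid)
        if g @ w_mid >= beta:
            mu_hi, w_hi = mu_mid, w_mid
        else:
            mu_lo, w_lo = mu_mid, w_mid
    return w_hi, mu_hi, True  # pragma: no cover


def _kkt_polish(Q, c, g, beta, w, mu):
    """Exact equality-constrained solve on the active set identified numerically."""
    k = len(w)
    free = w > 1e-9 * max(1.0, w.max())
    if not free.any():
        return w
    H = 2.0 * Q
    nf = int(free.sum())
    K = np.zeros((nf + 1, nf + 1))
    K[:nf, :nf] = H[np.ix_(free, free)]
    K[:nf, nf] = -g[free]
    K[nf, :nf] = g[free]
    rhs = np.concatenate([c[free], [beta]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        return w
    w_new = np.zeros(k)
    w_new[free] = sol[:nf]
    mu_new = sol[nf]
    if w_new.min() < -1e-10 or mu_new < -1e-8:
        return w
    # stationarity on the clamped coordinates: gradient must be nonnegative
    grad = H @ w_new - c - mu_new * g
    if grad[~free].size and grad[~free].min() < -1e-6 * max(1.0, np.abs(grad).max()):
        return w
    return np.clip(w_new, 0.0, None)


def _objective_value(terms, w, lam, alpha, beta, regularizer):
    gamma_cov = (
        float(terms.gammas @ (terms.cov_vecs @ w)) if terms.n_secondary else 0.0
    )
    var = float(w @ terms.V @ w)
    if regularizer == "ones":
        reg = float(np.sum((w - 1.0) ** 2))
    else:
        reg = float(np.sum(w**2))
    return gamma_cov - alpha * var - lam * reg


def _package(terms, w, lam, alpha, beta, regularizer) -> WeightSolution:
    if w is None:
        k = terms.k
        return WeightSolution(
            w=np.zeros(k),
            u=np.zeros(k),
            achieved_corr=np.full(terms.n_secondary + 1, np.nan),
            chosen=(lam, alpha, beta),
            feasible=False,
            objective_value=-np.inf,
        )
    return WeightSolution(
        w=w,
        u=np.sqrt(w),
        achieved_corr=_terms_corrs(terms, w),
        chosen=(lam, alpha, beta),
        feasible=True,
        objective_value=_objective_value(terms, w, lam, alpha, beta, regularizer),
    )


def default_grids(terms: QPTerms, hp: HyperParams):
    """Scale-free default grids for (lam, alpha, beta).

    The covariance terms scale as scale(D) * scale(rho_j) while the variance
    term scales as scale(D)^2, so fixed numeric grids are meaningless across
    datasets.  The grids are anchored to ``cov_unit``, the gamma-weighted
    covariance magnitude at w = 1: alpha is expressed in units of
    cov_unit / Var(D @ 1) (alpha = 1 puts the two penalties on equal footing
    at the all-ones weights) and lambda in units of cov_unit / k (the
    regularizer is a dimensionless O(k) quantity).  Multiplying the data or
    any secondary metric by a constant then leaves the selected weights
    unchanged.
    """
    tiny = np.finfo(float).tiny
    cov_unit = float(
        np.abs(terms.gammas * (terms.cov_vecs @ np.ones(terms.k))).sum()
    )
    if cov_unit <= 0:
        # orthogonal secondary at w=1; fall back to the primary's own scale
        cov_unit = max(terms.primary_var, tiny)
    if hp.lambda_grid is not None:
        lam_grid = tuple(hp.lambda_grid)
    else:
        lam_unit = cov_unit / terms.k
        lam_grid = tuple(l * lam_unit for l in DEFAULT_LAMBDA_GRID)
    if hp.alpha_grid is not None:
        alpha_grid = tuple(hp.alpha_grid)
    else:
        alpha_unit = cov_unit / max(terms.primary_var, tiny)
        alpha_grid = tuple(a * alpha_unit for a in DEFAULT_ALPHA_GRID)
    if hp.beta_grid is not None:
        beta_grid = tuple(hp.beta_grid)
    else:
        # Cov(1, rho_primary) = Var of the unweighted primary distances
        beta_grid = tuple(f * terms.primary_var for f in DEFAULT_BETA_FRACTIONS)
    return lam_grid, alpha_grid, beta_grid


def grid_search(terms: QPTerms, hp: HyperParams) -> WeightSolution:
    """Solve the QP across the hyperparameter grid and apply the s/q filter.

    Among grid points whose solutions satisfy ``Corr(Dw, rho_primary) >= s``
    and ``||w||_inf / ||w||_1 <= q/k``, returns the one maximizing the
    gamma-weighted sum of secondary correlations (correlation, not covariance:
    model selection should be scale-free).  Ties keep the first grid point.
    """
    if terms.n_secondary == 0:
        raise InvalidInputError("at least one secondary modality is required")
    lam_grid, alpha_grid, beta_grid = default_grids(terms, hp)
    k = terms.k
    best: WeightSolution | None = None
    best_score = -np.inf
    best_primary = -np.inf
    table: list[dict] = []
    for lam in lam_grid:
        for alpha in alpha_grid:
            for beta in beta_grid:
                sol = solve_fixed(terms, lam, alpha, beta, hp.regularizer)
                corr = sol.achieved_corr
                primary_corr = corr[0]
                wsum = sol.w.sum()
                conc = sol.w.max() / wsum if wsum > 0 else np.inf
                ok = (
                    sol.feasible
                    and np.isfinite(primary_corr)
                    and primary_corr >= hp.s - 1e-6
                    and conc <= hp.q / k + 1e-9
                )
                score = (
                    float(terms.gammas @ corr[1:])
                    if np.all(np.isfinite(corr[1:]))
                    else -np.inf
                )
                table.append(
                    {
                        "lambda": lam,
                        "alpha": alpha,
                        "beta": beta,
                        "qp_feasible": sol.feasible,
                        "feasible": bool(ok),
                        "primary_corr": float(primary_corr)
                        if np.isfinite(primary_corr)
                        else np.nan,
                        **{
                            f"secondary_corr_{j}": float(corr[j + 1])
                            if np.isfinite(corr[j + 1])
                            else np.nan
                            for j in range(terms.n_secondary)
                        },
                        "selection_score": score if np.isfinite(score) else np.nan,
                        "objective": sol.objective_value,
                    }
                )
                if np.isfinite(primary_corr):
                    best_primary = max(best_primary, primary_corr)
                if ok and score > best_score:
                    best, best_score = sol, score
    if best is None:
        raise NoFeasibleSolutionError(
            f"no grid point satisfied s={hp.s} and q={hp.q}; best primary "
            f"correlation attained was {best_primary:.4f} — consider lowering s",
            best_primary_corr=float(best_primary),
        )
    best.feasibility_table = table
    best.s = hp.s
    best.q = hp.q
    return best
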