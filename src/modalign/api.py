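"""End-to-end fit/transform interface.

``fit`` runs the whole pipeline — pair sampling, feature-difference
decomposition, secondary distance evaluation, QP term assembly, and the
hyperparameter grid search — for a single minimum-correlation constraint
``s``.  ``run_ensemble`` repeats the fit over a range of ``s`` values and
averages min-max-normalized weights across sub-runs, which is the recommended
mode for feature selection.  ``transform`` applies the learned scaling
``u = sqrt(w)`` to (possibly unseen) data, and ``softmax_feature_scores`` maps
reduced-space weights back to original variables through factor loadings.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import preprocessing as prep
from .distance import (
    DEFAULT_PAIR_COUNT,
    PrimaryModality,
    SecondaryModality,
    feature_diffs,
    sample_pairs,
    secondary_distances,
)
from .exceptions import (
    InvalidInputError,
    ModalignError,
    NoFeasibleSolutionError,
)
from .qp import (
    DEFAULT_Q,
    DEFAULT_S,
    HyperParams,
    WeightSolution,
    build_qp_terms,
    grid_search,
)

#: Ensemble default: a wide range of distortion budgets for feature selection.
DEFAULT_ENSEMBLE_S = (0.90, 0.925, 0.95, 0.975, 0.99)


@dataclass
class FitConfig:
    """Options shared by :func:`fit` and :func:`run_ensemble`.

    ``s_values`` holds the minimum primary-distance correlation(s): a single
    value for :func:`fit` (default 0.99), several for an ensemble.  ``gammas``
    optionally overrides the per-modality signed importance weights.
    """

    s_values: Sequence[float] = (DEFAULT_S,)
    gammas: Sequence[float] | None = None
    pair_count: int = DEFAULT_PAIR_COUNT
    seed: int = 0
    preprocessing: prep.ReductionSpec | None = None
    q: float = DEFAULT_Q
    lambda_grid: Sequence[float] | None = None
    alpha_grid: Sequence[float] | None = None
    beta_grid: Sequence[float] | None = None
    regularizer: str = "ones"

    def __post_init__(self) -> None:
        if len(self.s_values) == 0:
            raise InvalidInputError("s_values must be non-empty")
        for s in self.s_values:
            if not (0 <= s < 1):
                raise InvalidInputError(f"every s must be in [0, 1), got {s}")
        if self.pair_count < 1:
            raise InvalidInputError("pair_count must be >= 1")


@dataclass
class EnsembleResult:
    """Aggregated feature weights across sub-runs at different ``s`` values."""

    per_run_weights: np.ndarray  # (runs, k), each min-max normalized to [0, 1]
    mean_weights: np.ndarray  # (k,) mean of the normalized rows
    orientation: str = "direct"  # or "inverted": 1 - mean_weights
    raw_weights: np.ndarray | None = None  # (runs, k) un-normalized solver weights
    raw_mean_weights: np.ndarray | None = None
    s_values_used: list[float] = field(default_factory=list)
    s_values_dropped: list[float] = field(default_factory=list)
    feature_names: list[str] | None = None
    solutions: list[WeightSolution] = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        if self.orientation == "inverted":
            return 1.0 - self.mean_weights
        return self.mean_weights


@contextmanager
def _stage(name: str):
    """Re-raise package errors with a pipeline-stage label."""
    try:
        yield
    except ModalignError as exc:
        if not str(exc).startswith("["):
            exc.args = (f"[{name}] {exc}",) + exc.args[1:]
        raise


def _prepare(
    primary: PrimaryModality,
    secondaries: Sequence[SecondaryModality],
    config: FitConfig,
):
    """Shared front half of fit/ensemble: decompose distances, assemble terms."""
    if len(secondaries) == 0:
        raise InvalidInputError(
            "[inputs] at least one secondary modality is required: "
            "nothing to synthesize"
        )
    for m in secondaries:
        if m.n_obs != primary.n_obs:
            raise InvalidInputError(
                f"[inputs] modality {m.name!r} has {m.n_obs} observations, "
                f"primary has {primary.n_obs} (modalities must be row-aligned)"
            )
    loadings = None
    with _stage("preprocessing"):
        if config.preprocessing is not None and config.preprocessing.method != "none":
            factors, loadings = prep.reduce(
                primary.X, config.preprocessing, seed=config.seed
            )
            method = config.preprocessing.method
            primary = PrimaryModality(
                X=factors,
                feature_names=[f"{method}_{i}" for i in range(factors.shape[1])],
                metric_kind="euclidean_sq",
            )
    with _stage("primary-validation"):
        primary = primary.drop_constant_features()
    with _stage("pair-sampling"):
        pairs = sample_pairs(primary.n_obs, config.pair_count, config.seed)
    with _stage("feature-diffs"):
        D = feature_diffs(primary, pairs)
    with _stage("secondary-distances"):
        rhos = [secondary_distances(m, pairs) for m in secondaries]
    gammas = (
        list(config.gammas)
        if config.gammas is not None
        else [m.gamma for m in secondaries]
    )
    if len(gammas) != len(secondaries):
        raise InvalidInputError("[inputs] one gamma per secondary modality required")
    with _stage("qp-terms"):
        terms = build_qp_terms(D, rhos, gammas)
    return primary, terms, loadings


def _hp(config: FitConfig, s: float) -> HyperParams:
    return HyperParams(
        s=s,
        q=config.q,
        lambda_grid=config.lambda_grid,
        alpha_grid=config.alpha_grid,
        beta_grid=config.beta_grid,
        regularizer=config.regularizer,
    )


def fit(
    primary: PrimaryModality,
    secondaries: Sequence[SecondaryModality],
    config: FitConfig | None = None,
) -> WeightSolution:
    """Learn feature weights for one minimum-correlation constraint.

    Uses the first (or only) entry of ``config.s_values``.  Deterministic for
    a fixed seed: the pair sample, any reduction, and the grid search all
    derive their randomness from ``config.seed``.
    """
    config = config or FitConfig()
    primary, terms, loadings = _prepare(primary, secondaries, config)
    with _stage("grid-search"):
        solution = grid_search(terms, _hp(config, config.s_values[0]))
    solution.feature_names = list(primary.feature_names)
    solution.loadings = loadings
    return solution


def transform(X: np.ndarray, solution: WeightSolution) -> np.ndarray:
    """Scale each column of ``X`` by ``u = sqrt(w)``.

    Pairwise squared Euclidean distances of the output equal the reweighted
    distances ``D @ w`` for rows drawn from the fit set.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != solution.u.shape[0]:
        raise InvalidInputError(
            f"X has shape {X.shape}; expected (*, {solution.u.shape[0]})"
        )
    return X * solution.u


def run_ensemble(
    primary: PrimaryModality,
    secondaries: Sequence[SecondaryModality],
    config: FitConfig | None = None,
) -> EnsembleResult:
    """Fit at every ``s`` in ``config.s_values`` and average normalized weights.

    Each sub-run's weight vector is min-max normalized (lowest weight to 0,
    highest to 1) before averaging.  Sub-runs with no feasible grid point are
    dropped with a warning and recorded in ``s_values_dropped``.
    """
    config = config or FitConfig(s_values=DEFAULT_ENSEMBLE_S)
    if len(config.s_values) < 2:
        warnings.warn(
            "ensemble with a single s value: averaging over one run",
            UserWarning,
            stacklevel=2,
        )
    primary, terms, _ = _prepare(primary, secondaries, config)
    normalized, raw, used, dropped, sols = [], [], [], [], []
    for s in config.s_values:
        try:
            sol = grid_search(terms, _hp(config, s))
        except NoFeasibleSolutionError as exc:
            warnings.warn(
                f"sub-run s={s} infeasible and dropped: {exc}",
                UserWarning,
                stacklevel=2,
            )
            dropped.append(float(s))
            continue
        w = sol.w
        span = np.ptp(w)
        if span <= 0:
            warnings.warn(
                f"sub-run s={s} produced a constant weight vector; dropped "
                "(min-max normalization undefined)",
                UserWarning,
                stacklevel=2,
            )
            dropped.append(float(s))
            continue
        normalized.append((w - w.min()) / span)
        raw.append(w)
        used.append(float(s))
        sol.feature_names = list(primary.feature_names)
        sols.append(sol)
    if not normalized:
        raise NoFeasibleSolutionError(
            "all ensemble sub-runs were infeasible; consider lowering s"
        )
    per_run = np.vstack(normalized)
    raw_arr = np.vstack(raw)
    return EnsembleResult(
        per_run_weights=per_run,
        mean_weights=per_run.mean(axis=0),
        orientation="direct",
        raw_weights=raw_arr,
        raw_mean_weights=raw_arr.mean(axis=0),
        s_values_used=used,
        s_values_dropped=dropped,
        feature_names=list(primary.feature_names),
        solutions=sols,
    )


def softmax_feature_scores(
    solution: WeightSolution | np.ndarray, loadings: np.ndarray
) -> np.ndarray:
    """Rank original variables by an exp(w)-weighted average of factor loadings.

    ``score_g = sum_i e^{w_i} loadings[i, g] / sum_i e^{w_i}`` — parameter-free
    and dominated by the highest-weight factors.  ``w`` is taken on the mean-1
    reporting scale so the exponentiation is comparable across runs.  Cell
    loadings can be scored identically by passing the observation-factor
    matrix transposed.
    """
    w = solution.w_mean1 if isinstance(solution, WeightSolution) else np.asarray(solution, float)
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 2 or loadings.shape[0] != w.shape[0]:
        raise InvalidInputError(
            f"loadings has shape {loadings.shape}; expected ({w.shape[0]}, *)"
        )
    e = np.exp(w - w.max())  # shift-invariant softmax, numerically safe
    probs = e / e.sum()
    return probs @ loadings


def invert_orientation(scores: np.ndarray) -> np.ndarray:
    """Flip normalized scores so variability-tolerant features rank highest.

    A high feature weight means variation in that feature matters to the
    alignment (the feature is conserved); subtracting the normalized scores
    from 1 re-orients them to measure tolerance to variation, matching the
    convention of per-position variability scores for sequence data.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < -1e-12 or scores.max() > 1 + 1e-12):
        raise InvalidInputError("scores must lie in [0, 1] before inversion")
    return 1.0 - np.clip(scores, 0.0, 1.0)
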