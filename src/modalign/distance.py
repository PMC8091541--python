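"""Pairwise-distance decomposition of the primary modality and secondary metrics.

Every quantity the optimizer touches is built from a sampled set of
observation pairs ``P``.  For the primary modality the squared distance of a
pair decomposes feature-by-feature: row ``p`` of the feature-difference matrix
``D`` holds the per-feature squared differences (or 0/1 mismatch indicators
for symbolic data), so the weighted squared distance of pair ``p`` under a
diagonal reweighting ``w`` is simply ``D[p, :] @ w``.  Secondary modalities
contribute one distance value per pair under their own metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .exceptions import DegenerateModalityError, InvalidInputError

#: Sentinel used to pad symbolic (sequence) features to a fixed width.  It is
#: distinct from every amino-acid letter; two pads compare equal (distance 0).
NULL_SYMBOL = "-"

MetricKind = Literal["euclidean_sq", "absolute_diff", "categorical_mismatch", "hamming"]

#: Default cap on the number of sampled pairs.  Sample correlation between
#: distance vectors concentrates quickly, so a fixed budget of 2e5 pairs keeps
#: term assembly fast at any dataset size without hurting the estimate.
DEFAULT_PAIR_COUNT = 200_000


@dataclass
class PrimaryModality:
    """The reference modality whose features are reweighted.

    Parameters
    ----------
    X
        ``N x k`` data matrix.  Numeric for ``euclidean_sq``; symbolic
        (single characters, with :data:`NULL_SYMBOL` padding) for ``hamming``.
    feature_names
        Length-``k`` identifiers carried through to the weight report.
    metric_kind
        ``"euclidean_sq"`` or ``"hamming"``.
    """

    X: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    metric_kind: Literal["euclidean_sq", "hamming"] = "euclidean_sq"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise InvalidInputError("primary modality must be a 2-D matrix")
        n, k = self.X.shape
        if n < 3:
            raise InvalidInputError(
                f"primary modality needs at least 3 observations, got {n}"
            )
        if k < 1:
            raise InvalidInputError("primary modality needs at least 1 feature")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(k)]
        if len(self.feature_names) != k:
            raise InvalidInputError(
                f"feature_names has length {len(self.feature_names)}, expected {k}"
            )
        if self.metric_kind == "euclidean_sq":
            self.X = self.X.astype(float)
            if not np.all(np.isfinite(self.X)):
                bad = np.argwhere(~np.isfinite(self.X))[0]
                raise InvalidInputError(
                    f"non-finite entry in primary modality at row {bad[0]}, "
                    f"column {bad[1]}"
                )
        elif self.metric_kind == "hamming":
            if np.issubdtype(self.X.dtype, np.number):
                raise InvalidInputError(
                    "metric_kind='hamming' requires symbolic entries"
                )
        else:
            raise InvalidInputError(f"unknown primary metric {self.metric_kind!r}")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def drop_constant_features(self) -> "PrimaryModality":
        """Return a copy without zero-variance features (warns if any dropped).

        Constant features contribute nothing to any pairwise distance, make
        the weight for that coordinate unidentifiable, and are common in
        reduced representations with dead components.
        """
        keep = np.array(
            [len(np.unique(self.X[:, i])) > 1 for i in range(self.n_features)]
        )
        if keep.all():
            return self
        dropped = [n for n, k_ in zip(self.feature_names, keep) if not k_]
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s): {dropped[:5]}"
            + ("..." if len(dropped) > 5 else ""),
            UserWarning,
            stacklevel=2,
        )
        if not keep.any():
            raise InvalidInputError("all primary features are constant")
        return PrimaryModality(
            X=self.X[:, keep],
            feature_names=[n for n, k_ in zip(self.feature_names, keep) if k_],
            metric_kind=self.metric_kind,
        )


@dataclass
class SecondaryModality:
    """A supplementary per-cell measurement contributing a distance metric.

    ``payload`` may be a numeric matrix (``euclidean_sq``), a scalar vector
    (``absolute_diff``), a categorical label vector (``categorical_mismatch``),
    or a symbolic/Boolean matrix (``hamming`` / ``euclidean_sq``).  ``gamma``
    is the signed importance weight: negative values ask for anti-correlation
    (confounder suppression).  ``post_transform`` is an optional monotone
    scalar function applied elementwise to the distances, e.g. to invert the
    direction of alignment or emphasize local distances.
    """

    payload: np.ndarray
    metric_kind: MetricKind
    gamma: float = 1.0
    post_transform: Callable[[np.ndarray], np.ndarray] | None = None
    name: str = "secondary"

    def __post_init__(self) -> None:
        self.payload = np.asarray(self.payload)
        if self.gamma == 0:
            raise InvalidInputError(
                f"modality {self.name!r}: gamma must be nonzero"
            )
        if self.metric_kind not in (
            "euclidean_sq",
            "absolute_diff",
            "categorical_mismatch",
            "hamming",
        ):
            raise InvalidInputError(
                f"modality {self.name!r}: unknown metric {self.metric_kind!r}"
            )
        if self.metric_kind == "absolute_diff" and self.payload.ndim != 1:
            raise InvalidInputError(
                f"modality {self.name!r}: absolute_diff needs a scalar vector"
            )
        if self.metric_kind == "categorical_mismatch" and self.payload.ndim != 1:
            raise InvalidInputError(
                f"modality {self.name!r}: categorical_mismatch needs a label vector"
            )

    @property
    def n_obs(self) -> int:
        return self.payload.shape[0]


@dataclass(frozen=True)
class PairSample:
    """A seeded, reproducible sample of distinct unordered observation pairs."""

    pairs: np.ndarray  # (|P|, 2) int array with pairs[:, 0] < pairs[:, 1]
    seed: int
    requested_count: int

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def left(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def right(self) -> np.ndarray:
        return self.pairs[:, 1]


def _decode_pair_indices(lin: np.ndarray, N: int) -> np.ndarray:
    """Map linear indices in [0, N(N-1)/2) to (n, m) pairs in lexicographic order."""
    # row n starts at offset n*N - n*(n+1)/2; invert with the quadratic formula
    lin = lin.astype(np.int64)
    n = np.floor((2 * N - 1 - np.sqrt((2 * N - 1) ** 2 - 8 * lin.astype(float))) / 2)
    n = n.astype(np.int64)
    np.clip(n, 0, N - 2, out=n)

    def row_start(nn: np.ndarray) -> np.ndarray:
        return nn * (2 * N - nn - 1) // 2

    # float round-off can land one row off in either direction; fix up
    n[row_start(n) > lin] -= 1
    n[row_start(n + 1) <= lin] += 1
    start = row_start(n)
    m = lin - start + n + 1
    return np.column_stack([n, m])


def sample_pairs(N: int, requested_count: int, seed: int) -> PairSample:
    """Draw a uniform without-replacement sample of distinct index pairs.

    When ``requested_count`` meets or exceeds ``N(N-1)/2`` all pairs are
    returned in deterministic lexicographic order (seed-free).  Identical
    ``(N, requested_count, seed)`` always reproduces the identical list.
    """
    if N < 3:
        raise InvalidInputError(f"need at least 3 observations to sample pairs, got {N}")
    if requested_count < 1:
        raise InvalidInputError("requested_count must be >= 1")
    total = N * (N - 1) // 2
    if requested_count >= total:
        n, m = np.triu_indices(N, k=1)
        return PairSample(
            pairs=np.column_stack([n, m]).astype(np.int64),
            seed=seed,
            requested_count=requested_count,
        )
    rng = np.random.default_rng(seed)
    if total <= 20_000_000:
        lin = rng.choice(total, size=requested_count, replace=False)
    else:
        # rejection sampling keeps memory independent of N^2
        chosen: set[int] = set()
        while len(chosen) < requested_count:
            draw = rng.integers(0, total, size=requested_count - len(chosen))
            chosen.update(int(x) for x in draw)
        lin = np.fromiter(chosen, dtype=np.int64, count=len(chosen))[:requested_count]
    return PairSample(
        pairs=_decode_pair_indices(np.asarray(lin), N),
        seed=seed,
        requested_count=requested_count,
    )


def feature_diffs(primary: PrimaryModality, pairs: PairSample) -> np.ndarray:
    """Per-feature squared differences (or mismatch indicators) over pairs.

    Returns the ``|P| x k`` matrix ``D`` with ``D[p, i] = (X[n,i] - X[m,i])**2``
    for numeric data, or the 0/1 disagreement indicator for symbolic data.
    Row sums reproduce the unweighted primary squared (resp. Hamming) distance.
    """
    if pairs.pairs.size and pairs.pairs.max() >= primary.n_obs:
        raise InvalidInputError("pair indices out of range for primary modality")
    left = primary.X[pairs.left]
    right = primary.X[pairs.right]
    if primary.metric_kind == "euclidean_sq":
        return np.square(left - right)
    return (left != right).astype(float)


def secondary_distances(modality: SecondaryModality, pairs: PairSample) -> np.ndarray:
    """Distances between sampled pairs under a secondary modality's metric.

    The declared ``post_transform`` is applied last, elementwise.  A constant
    output vector is rejected: its correlation with anything is undefined.
    """
    if pairs.pairs.size and pairs.pairs.max() >= modality.n_obs:
        raise InvalidInputError(
            f"pair indices out of range for modality {modality.name!r}"
        )
    left = modality.payload[pairs.left]
    right = modality.payload[pairs.right]
    kind = modality.metric_kind
    if kind == "euclidean_sq":
        d = np.square(
            np.asarray(left, dtype=float) - np.asarray(right, dtype=float)
        )
        rho = d.sum(axis=1) if d.ndim == 2 else d
    elif kind == "absolute_diff":
        rho = np.abs(np.asarray(left, dtype=float) - np.asarray(right, dtype=float))
    elif kind == "categorical_mismatch":
        rho = (left != right).astype(float)
    elif kind == "hamming":
        neq = left != right
        rho = neq.sum(axis=1).astype(float) if neq.ndim == 2 else neq.astype(float)
    else:  # pragma: no cover - guarded in __post_init__
        raise InvalidInputError(f"unknown metric {kind!r}")
    if modality.post_transform is not None:
        rho = np.asarray(modality.post_transform(rho), dtype=float)
    if not np.all(np.isfinite(rho)):
        raise InvalidInputError(
            f"modality {modality.name!r} produced non-finite distances"
        )
    if rho.size and np.ptp(rho) == 0:
        raise DegenerateModalityError(
            f"modality {modality.name!r} yields a constant distance vector; "
            "correlation with it is undefined"
        )
    return rho


def precomputed_distances(values: Sequence[float], name: str = "precomputed") -> np.ndarray:
    """Escape hatch: validate a user-supplied per-pair distance vector."""
    rho = np.asarray(values, dtype=float)
    if rho.ndim != 1:
        raise InvalidInputError("precomputed distances must be a 1-D vector")
    if not np.all(np.isfinite(rho)):
        raise InvalidInputError(f"non-finite entries in {name!r}")
    if rho.size and np.ptp(rho) == 0:
        raise DegenerateModalityError(f"{name!r} is a constant distance vector")
    return rho
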