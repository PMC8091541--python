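"""Builders for the secondary (and sequence-primary) modalities used in
spatial-density and T-cell-receptor analyses.

- :func:`kde_density` scores each cell by the local packing density of its
  spatial neighborhood (2-D Gaussian kernel density estimate), yielding a
  scalar modality under the absolute-difference metric: two cells are similar
  if their neighborhoods are similarly dense.
- :func:`encode_cdr3` turns CDR3 amino-acid strings into a fixed-width
  positional matrix (Hamming-decomposable primary modality) and per-position
  one-hot Boolean matrices.
- :func:`label_modality` wraps categorical annotations (e.g. cell types) with
  the mismatch metric, for alignment (positive gamma) or confounder
  suppression (negative gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import NULL_SYMBOL, SecondaryModality
from .exceptions import DegenerateModalityError, InvalidInputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SpatialDensityScore:
    """Per-cell spatial density; higher value means a denser neighborhood."""

    values: np.ndarray
    bandwidth: float

    def as_modality(self, gamma: float = 1.0, name: str = "spatial_density") -> SecondaryModality:
        return SecondaryModality(
            payload=self.values,
            metric_kind="absolute_diff",
            gamma=gamma,
            name=name,
        )


def kde_density(
    xy: np.ndarray,
    bandwidth: float | str = "auto",
    fit_indices: np.ndarray | None = None,
) -> SpatialDensityScore:
    """Gaussian-kernel density estimate evaluated at each cell's own location.

    ``density_i = (1 / (M 2 pi h^2)) * sum_j exp(-||x_i - y_j||^2 / (2 h^2))``
    over the ``M`` fit points ``y`` (all cells, or the ``fit_indices`` subset,
    e.g. to learn the density of one cell type and infer it for the rest).
    ``bandwidth="auto"`` uses Scott's rule for two dimensions,
    ``h = M^(-1/6) * sigma`` with ``sigma`` the root-mean of the coordinate
    variances, which keeps the estimate translation- and rotation-invariant.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InvalidInputError("xy must be an N x 2 coordinate matrix")
    if xy.shape[0] < 2:
        raise InvalidInputError("need at least 2 points for a density estimate")
    if not np.all(np.isfinite(xy)):
        raise InvalidInputError("non-finite coordinates")
    pts = xy if fit_indices is None else xy[np.asarray(fit_indices)]
    m = pts.shape[0]
    if m < 2:
        raise InvalidInputError("need at least 2 fit points")
    if bandwidth == "auto":
        sigma2 = pts.var(axis=0, ddof=1).mean()
        if sigma2 <= 0:
            raise DegenerateModalityError(
                "all fit points coincide; density is degenerate"
            )
        h = float(m ** (-1.0 / 6.0) * np.sqrt(sigma2))
    else:
        h = float(bandwidth)
        if h <= 0:
            raise InvalidInputError("bandwidth must be positive")
    # O(N*M) exact evaluation; fine at the sizes this package targets
    d2 = ((xy[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    dens = np.exp(-d2 / (2.0 * h * h)).sum(axis=1) / (m * 2.0 * np.pi * h * h)
    return SpatialDensityScore(values=dens, bandwidth=h)


@dataclass
class EncodedSequenceSet:
    """Fixed-width positional and one-hot views of a CDR3 sequence table."""

    positional: np.ndarray  # N x max_len array of single characters
    max_len: int = 20
    _onehot_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_obs(self) -> int:
        return self.positional.shape[0]

    def onehot_at(self, position: int) -> np.ndarray:
        """N x 20 Boolean matrix of the residue at a (0-based) position.

        Rows are all-zero where the sequence is shorter than the position.
        """
        if not (0 <= position < self.max_len):
            raise InvalidInputError(
                f"position {position} out of range [0, {self.max_len})"
            )
        if position not in self._onehot_cache:
            col = self.positional[:, position]
            out = np.zeros((self.n_obs, len(AMINO_ACIDS)), dtype=bool)
            for aa, j in _AA_INDEX.items():
                out[col == aa, j] = True
            self._onehot_cache[position] = out
        return self._onehot_cache[position]

    def decode(self) -> list[str]:
        """Recover the (truncated) input sequences, stripping null padding."""
        return ["".join(row).rstrip(NULL_SYMBOL) for row in self.positional]


def encode_cdr3(
    sequences: list[str], max_len: int = 20, strict: bool = False,
    invalid_policy: str = "error",
) -> EncodedSequenceSet:
    """Truncate/pad CDR3 strings to ``max_len`` residues with null padding.

    Longer sequences are silently truncated (they are rare in real
    repertoires) unless ``strict=True``.  Residues outside the 20-letter
    alphabet raise, or map to the null symbol with
    ``invalid_policy="null"``.
    """
    if invalid_policy not in ("error", "null"):
        raise InvalidInputError("invalid_policy must be 'error' or 'null'")
    n = len(sequences)
    out = np.full((n, max_len), NULL_SYMBOL, dtype="<U1")
    for i, seq in enumerate(sequences):
        if strict and len(seq) > max_len:
            raise InvalidInputError(
                f"sequence {i} has length {len(seq)} > max_len={max_len}"
            )
        for j, ch in enumerate(seq[:max_len]):
            if ch not in _AA_INDEX:
                if invalid_policy == "error":
                    raise InvalidInputError(
                        f"sequence {i} position {j}: non-standard residue {ch!r}"
                    )
                ch = NULL_SYMBOL
            out[i, j] = ch
    return EncodedSequenceSet(positional=out, max_len=max_len)


def label_modality(
    labels: np.ndarray,
    target: str | None = None,
    gamma: float = 1.0,
    name: str = "labels",
) -> SecondaryModality:
    """Categorical-mismatch modality from per-cell labels.

    With ``target`` given, labels collapse to the binary is-target indicator
    (the usual way to align with, or suppress, a single cell type).
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise InvalidInputError("labels must be a 1-D vector")
    if len(np.unique(labels)) < 2:
        raise DegenerateModalityError("labels contain a single category")
    payload = labels
    if target is not None:
        payload = labels == target
        if len(np.unique(payload)) < 2:
            raise DegenerateModalityError(
                f"target {target!r} covers all or none of the observations"
            )
    return SecondaryModality(
        payload=payload,
        metric_kind="categorical_mismatch",
        gamma=gamma,
        name=name,
    )
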