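"""Seeded multimodal fixtures with planted ground-truth feature importance.

The generators emulate the method's statistical premise — a secondary modality
that reflects a feature subspace of the primary — without attempting realistic
count distributions.  A latent per-cell signal is copied into a random subset
of "informative" primary features; the secondary modality observes that same
signal (optionally with Gaussian noise on the per-cell value, so the metric
axioms of the resulting distances stay intact).  A fit should up-weight
exactly the informative features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .builders import label_modality
from .distance import PrimaryModality, SecondaryModality
from .exceptions import InvalidInputError


@dataclass
class PlantedFixture:
    primary: PrimaryModality
    secondaries: list[SecondaryModality]
    true_weights: np.ndarray  # length-k, 1 on the informative subset
    seed: int
    informative_idx: np.ndarray = field(default=None)
    latent: np.ndarray | None = None  # per-cell scalar driving the secondary
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.informative_idx is None:
            self.informative_idx = np.flatnonzero(self.true_weights)


def make_planted_fixture(
    N: int,
    k: int,
    n_informative: int,
    noise_sd: float,
    seed: int,
    with_labels: bool = False,
) -> PlantedFixture:
    """Gaussian primary with a scalar secondary driven by a planted subspace.

    A latent ``t ~ N(0, 1)`` is written into ``n_informative`` randomly chosen
    primary columns (the rest are independent noise features).  The secondary
    is the scalar ``t + eps`` with ``eps ~ N(0, noise_sd)``, measured under the
    absolute-difference metric with a squaring post-transform, so its pair
    distances are ``(dt + deps)^2`` — at ``noise_sd=0`` exactly proportional
    to the true-weighted primary squared distances (Pearson correlation 1).
    With ``with_labels=True`` a categorical secondary is added by thresholding
    ``t`` at its median.
    """
    if not (1 <= n_informative <= k):
        raise InvalidInputError("need 1 <= n_informative <= k")
    if N < 3:
        raise InvalidInputError("need N >= 3")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.standard_normal(N)
    X = rng.standard_normal((N, k))
    idx = np.sort(rng.choice(k, size=n_informative, replace=False))
    X[:, idx] = t[:, None]
    true_w = np.zeros(k)
    true_w[idx] = 1.0
    v = t + (rng.normal(0.0, noise_sd, size=N) if noise_sd > 0 else 0.0)
    secondaries = [
        SecondaryModality(
            payload=v,
            metric_kind="absolute_diff",
            gamma=1.0,
            post_transform=np.square,
            name="planted_scalar",
        )
    ]
    labels = None
    if with_labels:
        labels = np.where(t > np.median(t), "high", "low")
        secondaries.append(label_modality(labels, gamma=1.0, name="planted_labels"))
    return PlantedFixture(
        primary=PrimaryModality(X=X, metric_kind="euclidean_sq"),
        secondaries=secondaries,
        true_weights=true_w,
        seed=seed,
        informative_idx=idx,
        latent=t,
        labels=labels,
    )


def make_categorical_fixture(
    N: int,
    k: int,
    n_types: int,
    seed: int,
    n_informative: int = 4,
    shift: float = 3.0,
) -> PlantedFixture:
    """Gaussian-mixture primary with cell-type labels as the secondary.

    Types are assigned uniformly; on each informative feature the types are
    split into two groups offset by ``+shift/2`` and ``-shift/2`` (a balanced
    sign design, so every informative feature separates the types by ``shift``
    and carries comparable label signal).  The remaining features are pure
    noise.  ``shift=0`` makes the labels uninformative about the primary — a
    null fixture where the fit should leave the weights near 1.
    """
    if n_types < 2:
        raise InvalidInputError("need n_types >= 2")
    if not (1 <= n_informative <= k):
        raise InvalidInputError("need 1 <= n_informative <= k")
    if N < max(3, n_types):
        raise InvalidInputError("N too small for the requested number of types")
    rng = np.random.default_rng(seed)
    # round-robin assignment guarantees every type occurs
    types = np.arange(N) % n_types
    rng.shuffle(types)
    X = rng.standard_normal((N, k))
    idx = np.sort(rng.choice(k, size=n_informative, replace=False))
    if shift > 0:
        signs = rng.choice([-1.0, 1.0], size=(n_types, n_informative))
        for j in range(n_informative):
            if np.all(signs[:, j] == signs[0, j]):  # force both groups present
                signs[rng.integers(n_types), j] *= -1.0
        X[:, idx] += (shift / 2.0) * signs[types]
    true_w = np.zeros(k)
    true_w[idx] = 1.0
    labels = np.array([f"type{t}" for t in types])
    return PlantedFixture(
        primary=PrimaryModality(X=X, metric_kind="euclidean_sq"),
        secondaries=[label_modality(labels, gamma=1.0, name="cell_type")],
        true_weights=true_w,
        seed=seed,
        informative_idx=idx,
        labels=labels,
    )
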