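"""Pixel-sampling strategies for approximate movie PCA.

Three probability assignments over pixels (columns of the centered movie
matrix ``A``):

* **uniform** — every pixel equally likely; the naive baseline.
* **norm** — ``p_j = |A_Ij|^2 / ||A||_Fr^2``, the Monte-Carlo column-sampling
  distribution under which the approximate-SVD error bounds hold.
* **covariation** — ``p_j = |L_Ij|^2 / ||L||_Fr^2`` where ``L`` is the pixel
  covariance matrix with all non-neighbour entries zeroed.  Pixels inside a
  spatially extended source (a glomerulus) covary with their neighbours and
  get high probability; isolated noisy pixels do not.

Two sampling procedures: with replacement plus Monte-Carlo rescaling
(``1/sqrt(c p_j)`` per drawn column), or without replacement by sequential
draws with renormalisation over the not-yet-selected pixels.  The
*covariation energy* of a sample is the fraction of ``||L||_Fr^2`` carried by
its unique pixels — a precomputable proxy for how much biological signal the
sample retains; adaptive sampling draws until the energy passes a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .movie import MovieMatrix, PixelGrid

__all__ = [
    "SamplingProbabilities",
    "PixelSample",
    "uniform_probabilities",
    "norm_probabilities",
    "local_covariation_norms",
    "covariation_probabilities",
    "make_probabilities",
    "sample_with_replacement",
    "sample_without_replacement",
    "covariation_energy",
    "adaptive_sample",
    "probability_table",
    "probability_image",
]

_STRATEGIES = ("uniform", "norm", "covariation")


@dataclass
class SamplingProbabilities:
    """A probability vector over pixels plus the strategy that produced it."""

    p: np.ndarray
    strategy: str
    local_norms: np.ndarray | None = None  # |L_Ij|, kept for energy computation
    total_local_norm: float | None = None  # ||L||_Fr

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.p.ndim != 1:
            raise ValueError("p must be a vector")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.isclose(self.p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"probabilities sum to {self.p.sum()}, not 1")
        if self.strategy == "covariation" and self.local_norms is None:
            raise ValueError("covariation probabilities require local_norms")

    @property
    def n(self) -> int:
        return self.p.size


@dataclass
class PixelSample:
    """Sampled sub-matrix ``C`` (m x c) and the pixel indices behind its columns."""

    C: np.ndarray
    indices: np.ndarray
    with_replacement: bool
    rescaled: bool

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.C.ndim != 2 or self.C.shape[1] != self.indices.size:
            raise ValueError("C columns must match indices")
        if self.indices.size < 1:
            raise ValueError("sample must contain at least one column")
        if not self.with_replacement and np.unique(self.indices).size != self.indices.size:
            raise ValueError("without-replacement sample has duplicate indices")
        if self.rescaled != self.with_replacement:
            raise ValueError("rescaling applies exactly to with-replacement samples")

    @property
    def c(self) -> int:
        return self.indices.size


def uniform_probabilities(movie: MovieMatrix) -> SamplingProbabilities:
    """Uniform pixel probabilities — the baseline strategy."""
    n = movie.n
    return SamplingProbabilities(np.full(n, 1.0 / n), "uniform")


def norm_probabilities(movie: MovieMatrix) -> SamplingProbabilities:
    """Column-norm probabilities ``p_j = |A_Ij|^2 / ||A||_Fr^2``."""
    if not movie.centered:
        warnings.warn("norm probabilities computed on an uncentered movie")
    colsq = np.einsum("ij,ij->j", movie.data, movie.data)
    total = colsq.sum()
    if total <= 0:
        raise ValueError("all-zero movie: norm probabilities undefined")
    return SamplingProbabilities(colsq / total, "norm")


def local_covariation_norms(movie: MovieMatrix) -> tuple[np.ndarray, float]:
    """Column norms of the local covariance matrix, without materialising it.

    ``L = f(A^T A)`` zeroes every entry of the pixel covariance whose pixel
    pair are not grid neighbours.  The norm of column ``j`` is then

        |L_Ij| = sqrt( sum_r (A_Ij . A_Ir)^2 )

    with ``r`` ranging over the Moore neighbours of ``j``.  Computed by
    shifting the frame stack along each neighbour offset and accumulating
    squared temporal inner products, O(m n) per offset.  Returns the length-n
    vector of norms and ``||L||_Fr``.
    """
    grid = movie.grid
    shape = grid.shape
    stack = movie.data.reshape((movie.m, *shape))
    norm_sq = np.zeros(shape)
    for off in grid.neighbour_offsets():
        sl_j = tuple(
            slice(max(0, -o), d - max(0, o)) for o, d in zip(off, shape)
        )
        sl_r = tuple(
            slice(max(0, o), d - max(0, -o)) for o, d in zip(off, shape)
        )
        dots = np.einsum(
            "t...,t...->...", stack[(slice(None), *sl_j)], stack[(slice(None), *sl_r)]
        )
        norm_sq[sl_j] += dots**2
    norms = np.sqrt(norm_sq.ravel())
    total = float(np.sqrt(norm_sq.sum()))
    return norms, total


def covariation_probabilities(movie: MovieMatrix) -> SamplingProbabilities:
    """Neighbourhood-covariation probabilities ``p_j = |L_Ij|^2 / ||L||_Fr^2``."""
    norms, total = local_covariation_norms(movie)
    if total <= 0:
        raise ValueError(
            "local covariation norm is zero everywhere; covariation "
            "probabilities undefined (no silent fallback)"
        )
    p = (norms / total) ** 2
    p /= p.sum()  # guard rounding; already 1 analytically
    return SamplingProbabilities(p, "covariation", local_norms=norms, total_local_norm=total)


def make_probabilities(movie: MovieMatrix, strategy: str) -> SamplingProbabilities:
    """Dispatch on strategy name: uniform, norm, or covariation."""
    if strategy == "uniform":
        return uniform_probabilities(movie)
    if strategy == "norm":
        return norm_probabilities(movie)
    if strategy == "covariation":
        return covariation_probabilities(movie)
    raise ValueError(f"unknown strategy {strategy!r}")


def sample_with_replacement(
    movie: MovieMatrix, c: int, probs: SamplingProbabilities, seed: int
) -> PixelSample:
    """Draw ``c`` pixel-timeseries with replacement and Monte-Carlo rescaling.

    Each drawn column ``j`` is scaled by ``1/sqrt(c p_j)`` so that
    ``C C^T`` is an unbiased estimator of ``A A^T``; with norm probabilities
    this is the sampling scheme the approximate-SVD error bounds assume.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if probs.n != movie.n:
        raise ValueError("probability vector does not match movie")
    if probs.strategy == "covariation":
        warnings.warn(
            "with-replacement rescaled sampling is intended for norm "
            "probabilities; the Monte-Carlo guarantees assume them"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(movie.n, size=c, replace=True, p=probs.p)
    scale = 1.0 / np.sqrt(c * probs.p[idx])
    C = movie.data[:, idx] * scale
    return PixelSample(C=C, indices=idx, with_replacement=True, rescaled=True)


def _sequential_draws(
    p: np.ndarray, rng: np.random.Generator, stop: "callable"
) -> list[int]:
    """Sequential weighted draws without replacement, renormalising each step.

    ``stop(drawn)`` is consulted after every draw; drawing also stops when no
    positive-probability pixel remains.
    """
    p_work = p.astype(np.float64).copy()
    drawn: list[int] = []
    while True:
        total = p_work.sum()
        if total <= 0:
            break
        cum = np.cumsum(p_work)
        u = rng.random() * cum[-1]
        j = int(np.searchsorted(cum, u, side="right"))
        j = min(j, p_work.size - 1)
        while p_work[j] <= 0:  # float-boundary guard
            j -= 1
        drawn.append(j)
        p_work[j] = 0.0
        if stop(drawn):
            break
    return drawn


def sample_without_replacement(
    movie: MovieMatrix, c: int, probs: SamplingProbabilities, seed: int
) -> PixelSample:
    """Draw ``c`` distinct pixel-timeseries, each draw proportional to ``p``
    restricted to the not-yet-selected pixels; columns are copied unscaled.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if probs.n != movie.n:
        raise ValueError("probability vector does not match movie")
    n_positive = int(np.count_nonzero(probs.p > 0))
    if c > n_positive:
        raise ValueError(
            f"cannot draw {c} distinct pixels: only {n_positive} have p > 0"
        )
    rng = np.random.default_rng(seed)
    drawn = _sequential_draws(probs.p, rng, stop=lambda d: len(d) >= c)
    idx = np.asarray(drawn, dtype=np.int64)
    return PixelSample(
        C=movie.data[:, idx].copy(), indices=idx, with_replacement=False, rescaled=False
    )


def covariation_energy(
    indices: Iterable[int] | Sequence[int],
    local_norms: np.ndarray,
    total: float,
) -> float:
    """Fraction of ``||L||_Fr^2`` accounted for by the sample's unique pixels."""
    if total <= 0:
        raise ValueError("total local covariation norm is zero")
    uniq = np.unique(np.asarray(list(indices), dtype=np.int64)) if not isinstance(
        indices, np.ndarray
    ) else np.unique(indices)
    if uniq.size == 0:
        return 0.0
    return float(np.sum(local_norms[uniq] ** 2) / total**2)


def adaptive_sample(
    movie: MovieMatrix, threshold: float, seed: int
) -> PixelSample:
    """Sample without replacement until covariation energy reaches ``threshold``.

    The "safe" strategy: draw pixels under covariation probabilities and stop
    at the first sample size whose energy is at least ``threshold`` (e.g.
    0.95).  If every positive-probability pixel is exhausted first, the full
    set is returned (its energy is 1 by construction).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    probs = covariation_probabilities(movie)
    norms_sq = probs.local_norms**2
    total_sq = probs.total_local_norm**2
    rng = np.random.default_rng(seed)
    acc = {"energy": 0.0}

    def stop(drawn: list[int]) -> bool:
        acc["energy"] += norms_sq[drawn[-1]] / total_sq
        return acc["energy"] >= threshold

    drawn = _sequential_draws(probs.p, rng, stop=stop)
    if not drawn:  # threshold == 0: a sample still has at least one pixel
        drawn = _sequential_draws(probs.p, rng, stop=lambda d: True)
    idx = np.asarray(drawn, dtype=np.int64)
    return PixelSample(
        C=movie.data[:, idx].copy(), indices=idx, with_replacement=False, rescaled=False
    )


def probability_table(probs: SamplingProbabilities) -> pd.DataFrame:
    """Two-column table (pixel index, probability); adds |L_Ij| when known."""
    d = {"pixel": np.arange(probs.n), "p": probs.p}
    if probs.local_norms is not None:
        d["local_norm"] = probs.local_norms
    return pd.DataFrame(d)


def probability_image(probs: SamplingProbabilities, grid: PixelGrid) -> np.ndarray:
    """Probability vector reshaped to the grid for map-style visualisation."""
    if probs.n != grid.n_pixels:
        raise ValueError("probability vector does not match grid")
    return probs.p.reshape(grid.shape)
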