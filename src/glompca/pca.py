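"""NIPALS-style PCA: exact baseline and sampled approximation.

NIPALS extracts the top-k principal components sequentially: each component
is a power-style iteration alternating between a score (temporal) vector and
a loading (spatial) vector, followed by deflation of the rank-1 fit.  Unlike
a full SVD it never computes components beyond the k requested, which is the
point — k of 20-30 suffices for glomerular movies while m and n are large.

The approximate variant runs NIPALS on the sampled sub-matrix ``C`` only and
recovers full-size spatial components through the pseudoinverse,
``S = T^+ A``: the temporal subspace is estimated from the pixel sample, the
images are then a single least-squares projection of the whole movie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .movie import MovieMatrix, PCADecomposition
from .sampling import PixelSample

__all__ = [
    "NipalsConfig",
    "nipals_pca",
    "exact_pca",
    "approximate_pca",
    "frobenius_error",
]


@dataclass(frozen=True)
class NipalsConfig:
    """Rank and convergence settings for NIPALS component extraction.

    ``tol`` bounds the relative Euclidean change of the score vector between
    successive iterations; typical runs converge in well under max_iter.
    """

    k: int = 30
    tol: float = 1e-9
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def nipals_pca(C: np.ndarray, cfg: NipalsConfig) -> tuple[np.ndarray, dict]:
    """Extract the top-k score vectors of ``C`` by NIPALS iteration.

    Per component: initialise the score ``t`` from the residual column of
    maximal norm (lowest index on ties), iterate

        s = C^T t / (t^T t);  t = C s / (s^T s)

    until the relative change of ``t`` drops below ``cfg.tol`` or
    ``cfg.max_iter`` is reached, then deflate ``C <- C - t s^T``.  Columns of
    the returned ``T`` (m x k) are pairwise orthogonal by deflation.  Each
    component is sign-flipped so the largest-magnitude entry of its loading
    vector is positive.

    Returns ``(T, info)`` where ``info`` records iterations per component and
    a ``rank_deficient`` flag; if the residual vanishes before k components,
    fewer columns are returned.
    """
    C = np.array(C, dtype=np.float64)  # working copy; deflated in place
    if C.ndim != 2:
        raise ValueError("C must be a matrix")
    if not np.all(np.isfinite(C)):
        raise ValueError("C contains non-finite values")
    m, c = C.shape
    k = cfg.k
    if k > min(m, c):
        raise ValueError(f"k={k} exceeds min(m, c) = {min(m, c)}")

    scale = np.linalg.norm(C)
    T = np.zeros((m, k))
    iters: list[int] = []
    rank_deficient = False
    n_extracted = 0
    for l in range(k):
        col_norms = np.linalg.norm(C, axis=0)
        j0 = int(np.argmax(col_norms))  # argmax -> lowest index on ties
        if col_norms[j0] <= 1e-12 * max(scale, 1.0):
            rank_deficient = True
            warnings.warn(
                f"residual vanished after {l} components (rank deficiency); "
                f"returning fewer than k={k}"
            )
            break
        t = C[:, j0].copy()
        n_iter = 0
        for n_iter in range(1, cfg.max_iter + 1):
            s = C.T @ t / (t @ t)
            t_new = C @ s / (s @ s)
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < cfg.tol:
                break
        s = C.T @ t / (t @ t)
        # canonical sign: largest-|entry| of the loading vector positive
        pivot = int(np.argmax(np.abs(s)))
        if s[pivot] < 0:
            s = -s
            t = -t
        C -= np.outer(t, s)
        T[:, l] = t
        iters.append(n_iter)
        n_extracted += 1
    T = T[:, :n_extracted]
    info = {"iterations": iters, "rank_deficient": rank_deficient}
    return T, info


def _spatial_components(T: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Full-size spatial components via the Moore-Penrose pseudoinverse,
    ``S = T^+ A`` (least-squares images for the given temporal loadings)."""
    return np.linalg.pinv(T) @ A


def exact_pca(movie: MovieMatrix, cfg: NipalsConfig) -> PCADecomposition:
    """NIPALS PCA of the full movie matrix — the exact baseline."""
    if not movie.centered:
        warnings.warn("PCA on an uncentered movie; components will absorb means")
    T, info = nipals_pca(movie.data, cfg)
    S = _spatial_components(T, movie.data)
    return PCADecomposition(
        T=T,
        S=S,
        k=T.shape[1],
        grid=movie.grid,
        meta={"method": "exact", "nipals": info},
    )


def approximate_pca(
    movie: MovieMatrix, sample: PixelSample, cfg: NipalsConfig
) -> PCADecomposition:
    """Approximate PCA from a pixel sample.

    NIPALS runs on the sampled sub-matrix ``sample.C`` only; the spatial
    components are recovered at full image size as ``S = T^+ A``.  The
    effective rank may be below ``cfg.k`` if the sample is rank deficient.
    """
    if not movie.centered:
        warnings.warn("PCA on an uncentered movie; components will absorb means")
    T, info = nipals_pca(sample.C, cfg)
    S = _spatial_components(T, movie.data)
    return PCADecomposition(
        T=T,
        S=S,
        k=T.shape[1],
        grid=movie.grid,
        meta={
            "method": "approximate",
            "c": int(sample.c),
            "with_replacement": bool(sample.with_replacement),
            "nipals": info,
        },
    )


def frobenius_error(movie: MovieMatrix, dec: PCADecomposition) -> float:
    """Reconstruction error ``||A - T S||_Fr`` of a rank-k decomposition."""
    if dec.m != movie.m or dec.n != movie.n:
        raise ValueError(
            f"decomposition is {dec.m} x {dec.n}, movie is {movie.m} x {movie.n}"
        )
    return float(np.linalg.norm(movie.data - dec.T @ dec.S))
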