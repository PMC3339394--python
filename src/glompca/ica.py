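"""Source separation of the PCA-reduced movie with fastICA.

Once the movie is reduced to ``A_k = T S`` the unmixing problem is only
k-dimensional: ICA rotates the reduced space so that the basis vectors are
statistically independent rather than merely uncorrelated.  Two readings of
"source": **spatial** mode treats the k component images (rows of S) as
mixtures of independent images — useful for locating glomeruli; **temporal**
mode treats the k component timeseries (columns of T) as mixtures of
independent timeseries — useful for isolating odor-response transients from
artifacts such as dye bleaching.

The fixed-point fastICA estimator comes from scikit-learn (symmetric
estimation, log-cosh contrast).  The learned square unmixing matrix is
applied directly to the uncentered PCA factors, so the ICA pair reconstructs
exactly the same rank-k matrix: ``T_ica S_ica = T S``.  Sign and order of
ICA components are arbitrary; components are reported in decreasing
non-Gaussianity and matching is done on absolute correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .movie import PCADecomposition, PixelGrid

__all__ = [
    "ICADecomposition",
    "fastica_unmix",
    "match_components",
    "component_masks",
]


@dataclass
class ICADecomposition:
    """Paired independent/mixing factors with ``T_ica S_ica = T^PCA S^PCA``."""

    T_ica: np.ndarray  # m x k
    S_ica: np.ndarray  # k x n
    mode: str  # "spatial": rows of S_ica are the sources; "temporal": cols of T_ica
    converged: bool
    grid: PixelGrid | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("spatial", "temporal"):
            raise ValueError(f"mode must be 'spatial' or 'temporal', got {self.mode!r}")
        if self.T_ica.shape[1] != self.S_ica.shape[0]:
            raise ValueError("T_ica / S_ica rank mismatch")

    @property
    def k(self) -> int:
        return self.T_ica.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.T_ica @ self.S_ica

    def component_image(self, l: int) -> np.ndarray:
        if self.grid is None:
            raise ValueError("decomposition carries no grid geometry")
        return self.S_ica[l].reshape(self.grid.shape)


def _gauss_logcosh() -> float:
    # E[log cosh(x)] for x ~ N(0,1), via Gauss-Hermite quadrature
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    return float(np.sum(weights * np.log(np.cosh(nodes))) / np.sqrt(2 * np.pi))


def _contrast(sources: np.ndarray) -> np.ndarray:
    """Non-Gaussianity proxy per source (rows): |E[log cosh s] - gaussian value|."""
    s = sources - sources.mean(axis=1, keepdims=True)
    sd = s.std(axis=1)
    sd[sd == 0] = 1.0
    s = s / sd[:, None]
    return np.abs(np.mean(np.log(np.cosh(s)), axis=1) - _gauss_logcosh())


def fastica_unmix(
    dec: PCADecomposition,
    mode: str = "temporal",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ICADecomposition:
    """Unmix a rank-k PCA decomposition with symmetric fixed-point fastICA.

    Fits the unmixing on rows of ``S`` (spatial mode) or columns of ``T``
    (temporal mode) after whitening, then applies the resulting square
    unmixing matrix ``W`` to the uncentered factors:

    * spatial:  ``S_ica = W S``,     ``T_ica = T W^{-1}``
    * temporal: ``T_ica = T W^T``,   ``S_ica = (W^T)^{-1} S``

    so the rank-k reconstruction is preserved exactly.  Deterministic given
    ``seed`` (random orthogonal initial unmixing).  On non-convergence the
    last iterate is returned with ``converged = False``.
    """
    if dec.k < 2:
        raise ValueError("ICA needs at least 2 components")
    if mode not in ("spatial", "temporal"):
        raise ValueError(f"mode must be 'spatial' or 'temporal', got {mode!r}")

    X = dec.S.T if mode == "spatial" else dec.T  # samples x k features
    rng = np.random.default_rng(seed)
    w_init, _ = np.linalg.qr(rng.standard_normal((dec.k, dec.k)))

    ica = FastICA(
        n_components=dec.k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        w_init=w_init,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False

    W = ica.components_  # k x k, includes whitening
    if mode == "spatial":
        S_ica = W @ dec.S
        T_ica = dec.T @ np.linalg.inv(W)
        order = np.argsort(-_contrast(S_ica))
        T_ica, S_ica = T_ica[:, order], S_ica[order]
    else:
        T_ica = dec.T @ W.T
        S_ica = np.linalg.inv(W.T) @ dec.S
        order = np.argsort(-_contrast(T_ica.T))
        T_ica, S_ica = T_ica[:, order], S_ica[order]

    return ICADecomposition(
        T_ica=T_ica,
        S_ica=S_ica,
        mode=mode,
        converged=converged,
        grid=dec.grid,
        meta={"seed": seed, "n_iter": int(ica.n_iter_), "tol": tol},
    )


def _component_matrix(dec, on: str) -> np.ndarray:
    """Components as rows: images (k x n) or timeseries (k x m)."""
    if on == "images":
        S = dec.S_ica if isinstance(dec, ICADecomposition) else dec.S
        return S
    if on == "timeseries":
        T = dec.T_ica if isinstance(dec, ICADecomposition) else dec.T
        return T.T
    raise ValueError(f"on must be 'images' or 'timeseries', got {on!r}")


def _abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(abs(xc @ yc) / denom)


def match_components(X, Y, on: str = "images") -> pd.DataFrame:
    """Greedily pair components of two decompositions by absolute correlation.

    ``X`` and ``Y`` are PCA or ICA decompositions (ranks may differ; matching
    stops at the smaller).  ``on`` selects component images or timeseries.
    Returns a table with columns ``x``, ``y``, ``abs_r``, best matches first.
    """
    MX = _component_matrix(X, on)
    MY = _component_matrix(Y, on)
    if MX.shape[1] != MY.shape[1]:
        raise ValueError("components have different lengths; cannot correlate")
    corr = np.array([[_abs_corr(mx, my) for my in MY] for mx in MX])
    pairs = []
    avail_x = set(range(MX.shape[0]))
    avail_y = set(range(MY.shape[0]))
    work = corr.copy()
    for _ in range(min(len(avail_x), len(avail_y))):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j), float(corr[i, j])))
        work[i, :] = -1.0
        work[:, j] = -1.0
    return pd.DataFrame(pairs, columns=["x", "y", "abs_r"])


def component_masks(
    dec: ICADecomposition, quantile: float = 0.99
) -> np.ndarray:
    """Threshold each component image at a quantile of |coefficient|.

    Returns a boolean array (k x n) marking, per component, the pixels whose
    absolute coefficient exceeds the given quantile — a simple extraction of
    candidate glomerulus positions from ICA images.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    S = np.abs(dec.S_ica)
    thresh = np.quantile(S, quantile, axis=1, keepdims=True)
    return S > thresh
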