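"""Data model and I/O for calcium-imaging movies.

A movie is an ``m x n`` real matrix: ``m`` timepoints (frames) by ``n``
pixels, each frame flattened into a row.  The :class:`PixelGrid` records the
image geometry so flattened pixel indices can be mapped back to grid
coordinates, and defines the Moore neighbourhood used by covariation
sampling.

Flattening convention (fixed throughout the package): pixel indices are
0-based and row-major over ``(y, x)`` in 2D and ``(z, y, x)`` in 3D, i.e. for
dims ``(width, height)`` the pixel at ``(x, y)`` has index ``y * width + x``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PixelGrid",
    "MovieMatrix",
    "PCADecomposition",
    "read_movie",
    "write_movie",
    "center_movie",
    "neighbours",
    "save_decomposition",
    "load_decomposition",
]


@dataclass(frozen=True)
class PixelGrid:
    """Image geometry: ``(width, height)`` or ``(width, height, depth)``."""

    dims: tuple[int, ...]

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) not in (2, 3):
            raise ValueError(f"dims must have length 2 or 3, got {self.dims!r}")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must be positive, got {self.dims!r}")
        object.__setattr__(self, "dims", dims)

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def shape(self) -> tuple[int, ...]:
        """Array shape for reshaping a flat pixel vector: (h, w) or (d, h, w)."""
        if self.ndim == 2:
            w, h = self.dims
            return (h, w)
        w, h, d = self.dims
        return (d, h, w)

    def coords(self, j: int) -> tuple[int, ...]:
        """Grid coordinates ``(x, y[, z])`` of flat pixel index ``j``."""
        if not 0 <= j < self.n_pixels:
            raise IndexError(f"pixel index {j} out of range [0, {self.n_pixels})")
        if self.ndim == 2:
            w, _ = self.dims
            return (j % w, j // w)
        w, h, _ = self.dims
        z, rem = divmod(j, w * h)
        return (rem % w, rem // w, z)

    def index(self, *coords: int) -> int:
        """Flat pixel index of grid coordinates ``(x, y[, z])``."""
        if len(coords) != self.ndim:
            raise ValueError(f"expected {self.ndim} coordinates, got {len(coords)}")
        for c, d in zip(coords, self.dims):
            if not 0 <= c < d:
                raise IndexError(f"coordinate {coords} outside grid {self.dims}")
        if self.ndim == 2:
            x, y = coords
            return y * self.dims[0] + x
        x, y, z = coords
        w, h, _ = self.dims
        return z * w * h + y * w + x

    def neighbours(self, j: int) -> list[int]:
        """Moore neighbourhood of pixel ``j``, truncated at the border.

        Up to 8 neighbours in 2D and 26 in 3D; a pixel is never its own
        neighbour.  Border pixels simply get fewer neighbours (no padding).
        """
        c = self.coords(j)
        out = []
        for off in itertools.product((-1, 0, 1), repeat=self.ndim):
            if all(o == 0 for o in off):
                continue
            q = tuple(ci + oi for ci, oi in zip(c, off))
            if all(0 <= qi < di for qi, di in zip(q, self.dims)):
                out.append(self.index(*q))
        return sorted(out)

    def neighbour_offsets(self) -> list[tuple[int, ...]]:
        """Nonzero offsets of the Moore neighbourhood in array-axis order."""
        return [
            off
            for off in itertools.product((-1, 0, 1), repeat=self.ndim)
            if any(o != 0 for o in off)
        ]


def neighbours(grid: PixelGrid, j: int) -> list[int]:
    """Moore neighbours of flat pixel index ``j`` on ``grid`` (see PixelGrid)."""
    return grid.neighbours(j)


@dataclass
class MovieMatrix:
    """A calcium-imaging movie: ``m`` timepoints x ``n`` pixels, plus geometry."""

    data: np.ndarray
    grid: PixelGrid
    centered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("movie data must be a 2D (timepoints x pixels) matrix")
        m, n = self.data.shape
        if m < 2 or n < 2:
            raise ValueError(f"movie needs m >= 2 and n >= 2, got {m} x {n}")
        if n != self.grid.n_pixels:
            raise ValueError(
                f"movie has {n} pixels but grid {self.grid.dims} implies "
                f"{self.grid.n_pixels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def frame(self, t: int) -> np.ndarray:
        """Frame ``t`` reshaped to grid shape (h, w) or (d, h, w)."""
        return self.data[t].reshape(self.grid.shape)


def center_movie(movie: MovieMatrix, tol: float = 1e-9) -> MovieMatrix:
    """Subtract each pixel's temporal mean (column means) from the movie.

    Centering per pixel makes the right singular vectors of the movie the
    principal components of the pixel covariance.  Idempotent within ``tol``.
    """
    means = movie.data.mean(axis=0, keepdims=True)
    return MovieMatrix(movie.data - means, movie.grid, centered=True)


@dataclass
class PCADecomposition:
    """Rank-k factorisation ``A_k = T S``: temporal loadings and spatial components.

    ``T`` is ``m x k`` (component timeseries), ``S`` is ``k x n`` (component
    images, full pixel size even when T came from a pixel sample).
    """

    T: np.ndarray
    S: np.ndarray
    k: int
    grid: PixelGrid | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        if self.T.ndim != 2 or self.S.ndim != 2:
            raise ValueError("T and S must be 2D matrices")
        if self.T.shape[1] != self.S.shape[0]:
            raise ValueError(
                f"rank mismatch: T is {self.T.shape}, S is {self.S.shape}"
            )
        if self.k != self.T.shape[1]:
            raise ValueError(f"k={self.k} but T has {self.T.shape[1]} columns")

    @property
    def m(self) -> int:
        return self.T.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.T @ self.S

    def component_image(self, l: int) -> np.ndarray:
        if self.grid is None:
            raise ValueError("decomposition carries no grid geometry")
        return self.S[l].reshape(self.grid.shape)


# ---------------------------------------------------------------------------
# I/O

_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_movie(path: str | Path, dims: tuple[int, ...]) -> MovieMatrix:
    """Read a movie from a multi-page TIFF stack or a dense text matrix.

    TIFF stacks hold one frame per page; text files hold one flattened frame
    per row (whitespace- or comma-separated).  ``dims`` gives the grid
    geometry and must match the per-frame pixel count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grid = PixelGrid(tuple(dims))
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        stack = tifffile.imread(path)
        if stack.ndim == len(grid.shape):  # single frame
            stack = stack[None]
        m = stack.shape[0]
        if int(np.prod(stack.shape[1:])) != grid.n_pixels:
            raise ValueError(
                f"TIFF frames have {int(np.prod(stack.shape[1:]))} pixels, "
                f"dims {grid.dims} imply {grid.n_pixels}"
            )
        data = stack.reshape(m, grid.n_pixels).astype(np.float64)
    else:
        data = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
        data = np.atleast_2d(np.asarray(data, dtype=np.float64))
        if data.shape[1] != grid.n_pixels:
            raise ValueError(
                f"matrix rows have {data.shape[1]} pixels, dims {grid.dims} "
                f"imply {grid.n_pixels}"
            )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite values")
    return MovieMatrix(data, grid, centered=False)


def write_movie(movie: MovieMatrix, path: str | Path) -> None:
    """Write a movie as a TIFF stack (float32) or a dense text matrix."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        stack = movie.data.reshape((movie.m, *movie.grid.shape))
        tifffile.imwrite(path, stack.astype(np.float32))
    else:
        np.savetxt(path, movie.data, delimiter="," if path.suffix == ".csv" else " ")


def save_decomposition(dec: PCADecomposition, prefix: str | Path) -> None:
    """Persist T and S as text matrices plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_T.csv", dec.T, delimiter=",")
    np.savetxt(f"{prefix}_S.csv", dec.S, delimiter=",")
    meta = {"k": dec.k, "dims": list(dec.grid.dims) if dec.grid else None}
    meta.update(dec.meta)
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def load_decomposition(prefix: str | Path) -> PCADecomposition:
    T = np.atleast_2d(np.loadtxt(f"{prefix}_T.csv", delimiter=","))
    S = np.atleast_2d(np.loadtxt(f"{prefix}_S.csv", delimiter=","))
    if T.shape[1] != S.shape[0] and T.shape[0] == S.shape[0]:
        # single-component edge case: loadtxt drops the unit dimension
        T = T.T
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    grid = PixelGrid(tuple(meta["dims"])) if meta.get("dims") else None
    extra = {k: v for k, v in meta.items() if k not in ("k", "dims")}
    return PCADecomposition(T=T, S=S, k=T.shape[1], grid=grid, meta=extra)
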