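import dataclasses

import numpy as np
import pytest

from glompca import (
    Glomerulus,
    MovieMatrix,
    PixelGrid,
    SyntheticMovieSpec,
    center_movie,
    default_spec,
    generate_movie,
)


@pytest.fixture(scope="session")
def reference_movie():
    """Default 64x64 synthetic movie (5 glomeruli, bleach, noise), centered."""
    movie, truth = generate_movie(default_spec(seed=0))
    return center_movie(movie), truth


@pytest.fixture(scope="session")
def small_movie():
    """Fast 16x16 two-glomerulus movie for unit tests, centered."""
    spec = SyntheticMovieSpec(
        dims=(16, 16),
        n_measurements=3,
        frames_per_measurement=30,
        glomeruli=(
            Glomerulus((5, 5), 3.0, (2.0, 0.0, 0.3)),
            Glomerulus((11, 11), 3.0, (0.0, 1.8, 0.2)),
        ),
        noise_sd=0.2,
        seed=42,
    )
    movie, truth = generate_movie(spec)
    return center_movie(movie), truth


@pytest.fixture()
def random_movie():
    """Unstructured random movie on a 4x5 grid (centered)."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((10, 20))
    return center_movie(MovieMatrix(data, PixelGrid((4, 5))))


def explicit_local_matrix(movie):
    """Oracle: materialise L = f(A^T A) with non-neighbour entries zeroed."""
    A = movie.data
    n = movie.n
    G = A.T @ A
    L = np.zeros((n, n))
    for j in range(n):
        for r in movie.grid.neighbours(j):
            L[r, j] = G[r, j]
    return L
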