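"""Monte-Carlo sample-size rule and empirical verification of the error bounds.

For norm-probability sampling with replacement and rescaling, the
approximate-SVD theory gives two guarantees relating the sampled
approximation to the optimal rank-k one:

* deterministic, per sample:
  ``||A - H_k H_k^T A||_Fr^2 <= ||A - A_k||_Fr^2 + 2 sqrt(k) ||A A^T - C C^T||_Fr``
* in expectation, provided ``c >= 4k / eps^2`` columns are drawn:
  ``E ||A - H_k H_k^T A||_Fr^2 <= ||A - A_k||_Fr^2 + eps ||A||_Fr^2``

where ``H_k`` is an orthonormal basis of the top-k left subspace of the
sample matrix ``C``.  The bounds are loose in practice — observed errors sit
far below them — so this module reports both sides rather than a bare
pass/fail, making the slack visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .movie import MovieMatrix
from .pca import NipalsConfig, nipals_pca
from .sampling import PixelSample, norm_probabilities, sample_with_replacement

__all__ = [
    "BoundReport",
    "required_sample_size",
    "covariance_error",
    "verify_bounds",
]


@dataclass
class BoundReport:
    """Both sides of the deterministic bound for one sampled run."""

    k: int
    epsilon: float
    c_required: int
    approx_error_sq: float
    exact_error_sq: float
    cov_error: float  # ||A A^T - C C^T||_Fr
    bound_rhs: float
    satisfied: bool


def required_sample_size(k: int, epsilon: float) -> int:
    """Smallest integer ``c`` with ``c >= 4 k / epsilon^2``.

    The with-replacement sample size guaranteeing the expectation bound at
    error fraction ``epsilon``.  E.g. k=20, epsilon=0.05 -> 32,000 pixels.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return math.ceil(4 * k / epsilon**2)


def covariance_error(movie: MovieMatrix, sample: PixelSample) -> float:
    """``||A A^T - C C^T||_Fr`` over the m x m time-covariance matrices."""
    if sample.C.shape[0] != movie.m:
        raise ValueError("sample and movie disagree on the number of timepoints")
    G_A = movie.data @ movie.data.T
    G_C = sample.C @ sample.C.T
    return float(np.linalg.norm(G_A - G_C))


def _orthonormal_basis(T: np.ndarray) -> np.ndarray:
    """Orthonormalise NIPALS scores (orthogonal by deflation, not unit norm)."""
    Q, _ = np.linalg.qr(T)
    return Q


def verify_bounds(
    movie: MovieMatrix,
    k: int,
    epsilon: float,
    repetitions: int = 30,
    seed: int = 0,
    c_cap: int | None = 100_000,
    cfg: NipalsConfig | None = None,
) -> list[BoundReport]:
    """Empirically check both error bounds over repeated sampled runs.

    Each repetition draws a rescaled with-replacement sample of
    ``required_sample_size(k, epsilon)`` columns under norm probabilities,
    builds ``H_k`` from NIPALS on the sample, and evaluates the deterministic
    bound; the caller can check the expectation bound against the mean
    ``approx_error_sq`` (see :func:`expectation_bound_holds`).

    ``c_cap`` guards against impractically large sample sizes (the rule grows
    as 1/epsilon^2); pass ``None`` to override.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    c = required_sample_size(k, epsilon)
    if c_cap is not None and c > c_cap:
        raise ValueError(
            f"required sample size c={c} exceeds cap {c_cap}; "
            "pass c_cap=None to override"
        )
    if cfg is None:
        # a c-column sample spans at most c directions; the bound's k is
        # unchanged, H just has fewer columns in that degenerate regime
        cfg = NipalsConfig(k=min(k, c, movie.m))
    A = movie.data
    # optimal rank-k baseline: the bound is stated against the SVD truncation
    svals = np.linalg.svd(A, compute_uv=False)
    exact_error_sq = float(np.sum(svals[k:] ** 2))
    A_fro_sq = float(np.sum(svals**2))
    probs = norm_probabilities(movie)
    seeds = np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)

    reports: list[BoundReport] = []
    for rep_seed in seeds:
        sample = sample_with_replacement(movie, c, probs, int(rep_seed))
        T, _ = nipals_pca(sample.C, cfg)
        H = _orthonormal_basis(T)
        proj = H.T @ A
        approx_error_sq = A_fro_sq - float(np.sum(proj**2))
        cov_err = covariance_error(movie, sample)
        rhs = exact_error_sq + 2.0 * math.sqrt(k) * cov_err
        reports.append(
            BoundReport(
                k=k,
                epsilon=epsilon,
                c_required=c,
                approx_error_sq=approx_error_sq,
                exact_error_sq=exact_error_sq,
                cov_error=cov_err,
                bound_rhs=rhs,
                satisfied=bool(approx_error_sq <= rhs * (1 + 1e-9) + 1e-9),
            )
        )
    return reports


def expectation_bound_holds(
    reports: list[BoundReport], movie: MovieMatrix
) -> tuple[bool, float, float]:
    """Check the expectation bound against the empirical mean of the runs.

    Returns ``(holds, mean_lhs, rhs)`` with
    ``rhs = exact_error_sq + epsilon * ||A||_Fr^2``.
    """
    if not reports:
        raise ValueError("no reports")
    mean_lhs = float(np.mean([r.approx_error_sq for r in reports]))
    r0 = reports[0]
    rhs = r0.exact_error_sq + r0.epsilon * float(np.sum(movie.data**2))
    return mean_lhs <= rhs, mean_lhs, rhs
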