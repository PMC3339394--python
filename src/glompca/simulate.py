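"""Synthetic glomerular calcium-imaging movies with ground truth.

The generator emulates the structure of antennal-lobe recordings: a movie is
a concatenation of measurements; in the middle of each measurement an odor
is presented and responding glomeruli show a transient — a sharp rise in
fluorescence followed by an exponential return that undershoots below
baseline.  Glomeruli are spatially compact (isotropic Gaussian blobs
truncated at a radius), respond with measurement-specific amplitudes
(different odors activate different glomeruli differentially), and the dye
bleaches under measurement light: an additive exponential downward trend
shared by all pixels that restarts with every measurement.  Independent
Gaussian noise is added per pixel and frame, so neighbourhood covariation is
carried by signal and trend only.

Every movie comes with a :class:`GroundTruth` carrying each glomerulus's
pixel mask, clean timecourse, and the trend — the reference for testing
sampling, PCA and ICA recovery end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .movie import MovieMatrix, PixelGrid

__all__ = [
    "ResponseTemplate",
    "Glomerulus",
    "SyntheticMovieSpec",
    "GroundTruth",
    "response_timecourse",
    "generate_movie",
    "default_spec",
    "spec_from_json",
    "spec_to_json",
    "save_ground_truth",
]


@dataclass(frozen=True)
class ResponseTemplate:
    """Shape of the odor-response transient within one measurement.

    A pulse rises over ``rise_frames`` frames (exponential saturation with
    time constant ``rise_tau``) to a normalised peak of 1, then relaxes as
    ``(1 + u) exp(-d/decay_tau) - u exp(-d/undershoot_tau)`` with
    ``u = undershoot_frac`` — a fast decay that crosses below baseline and
    creeps back.  ``n_pulses`` pulses are spaced ``pulse_interval`` frames
    apart, mimicking repeated odor pulses within one presentation.
    All frame counts are in frames; time constants in frames too.
    """

    onset: int = 10
    rise_frames: int = 3
    rise_tau: float = 1.0
    decay_tau: float = 4.0
    undershoot_frac: float = 0.35
    undershoot_tau: float = 12.0
    n_pulses: int = 2
    pulse_interval: int = 10

    def __post_init__(self) -> None:
        if self.onset < 0 or self.rise_frames < 1:
            raise ValueError("onset must be >= 0 and rise_frames >= 1")
        if min(self.rise_tau, self.decay_tau, self.undershoot_tau) <= 0:
            raise ValueError("time constants must be positive")
        if self.undershoot_frac < 0:
            raise ValueError("undershoot_frac must be >= 0")
        if self.n_pulses < 1 or self.pulse_interval < 1:
            raise ValueError("need n_pulses >= 1 and pulse_interval >= 1")


def response_timecourse(
    template: ResponseTemplate, n_frames: int, amplitude: float = 1.0
) -> np.ndarray:
    """Transient timecourse over one measurement: baseline 0, per-pulse rise
    to ``amplitude``, exponential return crossing below baseline."""
    out = np.zeros(n_frames)
    if amplitude == 0:
        return out
    u = template.undershoot_frac
    for p in range(template.n_pulses):
        onset = template.onset + p * template.pulse_interval
        peak_frame = onset + template.rise_frames - 1
        for t in range(onset, min(onset + template.rise_frames, n_frames)):
            # saturating rise, normalised to reach 1 at the last rise frame
            num = 1.0 - np.exp(-(t - onset + 1) / template.rise_tau)
            den = 1.0 - np.exp(-template.rise_frames / template.rise_tau)
            out[t] += num / den
        for t in range(peak_frame + 1, n_frames):
            d = t - peak_frame
            out[t] += (1.0 + u) * np.exp(-d / template.decay_tau) - u * np.exp(
                -d / template.undershoot_tau
            )
    return amplitude * out


@dataclass(frozen=True)
class Glomerulus:
    """A compact source: centre ``(x, y[, z])``, radius in pixels, and one
    response amplitude per measurement (0 = this odor does not activate it)."""

    centre: tuple[int, ...]
    radius: float
    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1 pixel")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class SyntheticMovieSpec:
    """Full description of a synthetic movie; deterministic given ``seed``."""

    # defaults describe a desk-scale two-photon AL recording: response peaks
    # near 2 fluorescence units, residual per-measurement bleach ~5% of that,
    # per-pixel noise giving peak SNR ~13 at a glomerulus centre
    dims: tuple[int, ...] = (64, 64)
    n_measurements: int = 6
    frames_per_measurement: int = 40
    glomeruli: tuple[Glomerulus, ...] = ()
    response_template: ResponseTemplate = field(default_factory=ResponseTemplate)
    bleach_amplitude: float = 0.1
    bleach_tau: float = 20.0
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        grid = PixelGrid(self.dims)
        t = self.response_template
        if self.frames_per_measurement < t.onset + t.rise_frames:
            raise ValueError(
                "frames_per_measurement must cover response onset + rise"
            )
        if self.n_measurements < 1:
            raise ValueError("need at least one measurement")
        if self.bleach_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("bleach_amplitude and noise_sd must be >= 0")
        for g in self.glomeruli:
            if len(g.centre) != grid.ndim:
                raise ValueError(f"glomerulus centre {g.centre} does not match dims")
            if len(g.amplitudes) != self.n_measurements:
                raise ValueError(
                    "each glomerulus needs one amplitude per measurement"
                )
            for c, d in zip(g.centre, grid.dims):
                if c - g.radius < 0 or c + g.radius > d - 1:
                    raise ValueError(
                        f"glomerulus at {g.centre} (radius {g.radius}) exceeds "
                        f"grid {grid.dims}"
                    )

    @property
    def grid(self) -> PixelGrid:
        return PixelGrid(self.dims)

    @property
    def n_frames(self) -> int:
        return self.n_measurements * self.frames_per_measurement


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic movie."""

    masks: np.ndarray  # G x n bool, truncated blob supports
    profiles: np.ndarray  # G x n float, spatial blob weights
    timecourses: np.ndarray  # G x m float, clean (noise-free) glomerular signals
    trend: np.ndarray  # m float, shared bleach trend
    overlapping: bool

    @property
    def n_sources(self) -> int:
        return self.masks.shape[0]


def _blob(grid: PixelGrid, centre: tuple[int, ...], radius: float) -> np.ndarray:
    """Isotropic Gaussian profile (sigma = radius / 2) truncated at radius."""
    axes = np.indices(grid.shape)  # (y, x) or (z, y, x) order
    coords = centre[::-1]  # grid coords are (x, y[, z]); axes are reversed
    dist_sq = np.zeros(grid.shape)
    for ax, c in zip(axes, coords):
        dist_sq += (ax - c) ** 2
    sigma = radius / 2.0
    prof = np.exp(-dist_sq / (2.0 * sigma**2))
    prof[dist_sq > radius**2] = 0.0
    return prof.ravel()


def generate_movie(spec: SyntheticMovieSpec) -> tuple[MovieMatrix, GroundTruth]:
    """Render a spec into a movie matrix plus its ground truth.

    ``movie = sum_g blob_g x timecourse_g + trend + noise``; the trend is an
    exponential decay restarting each measurement, added identically to every
    pixel; noise is independent N(0, noise_sd) per entry.
    """
    grid = spec.grid
    m, n = spec.n_frames, grid.n_pixels
    G = len(spec.glomeruli)
    fpm = spec.frames_per_measurement

    profiles = np.zeros((G, n))
    masks = np.zeros((G, n), dtype=bool)
    timecourses = np.zeros((G, m))
    for gi, g in enumerate(spec.glomeruli):
        profiles[gi] = _blob(grid, g.centre, g.radius)
        masks[gi] = profiles[gi] > 0
        for mi in range(spec.n_measurements):
            timecourses[gi, mi * fpm : (mi + 1) * fpm] = response_timecourse(
                spec.response_template, fpm, amplitude=g.amplitudes[mi]
            )

    overlapping = False
    if G > 1 and np.any(masks.sum(axis=0) > 1):
        overlapping = True
        warnings.warn("glomerulus supports overlap")

    within = np.arange(fpm)
    trend_one = spec.bleach_amplitude * np.exp(-within / spec.bleach_tau)
    trend = np.tile(trend_one, spec.n_measurements)

    data = timecourses.T @ profiles if G else np.zeros((m, n))
    data += trend[:, None]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=(m, n))

    movie = MovieMatrix(data, grid, centered=False)
    truth = GroundTruth(
        masks=masks,
        profiles=profiles,
        timecourses=timecourses,
        trend=trend,
        overlapping=overlapping,
    )
    return movie, truth


# default amplitude patterns: odors have sparse glomerular codes, so each
# glomerulus responds strongly to mostly one odor with weak side responses —
# timecourses are near-orthogonal, matching the independence the ICA model
# assumes of genuine sources
_DEFAULT_AMPLITUDES = (
    (2.0, 0.0, 0.3, 0.0, 0.0, 0.2),
    (0.0, 1.8, 0.0, 0.2, 0.0, 0.0),
    (0.2, 0.0, 2.0, 0.0, 0.3, 0.0),
    (0.0, 0.3, 0.0, 1.9, 0.0, 0.2),
    (0.0, 0.0, 0.2, 0.0, 2.0, 0.3),
)

_DEFAULT_CENTRES_64 = ((14, 15), (44, 12), (25, 36), (50, 44), (12, 50))


def default_spec(
    noise_sd: float = 0.15, seed: int = 0, n_glomeruli: int = 5
) -> SyntheticMovieSpec:
    """The package's reference synthetic movie: 64 x 64 pixels, 6 measurements
    of 40 frames, five glomeruli of radius 5 with distinct odor-response
    patterns, bleach trend, and additive noise."""
    if not 1 <= n_glomeruli <= len(_DEFAULT_AMPLITUDES):
        raise ValueError(f"n_glomeruli must be in [1, {len(_DEFAULT_AMPLITUDES)}]")
    gloms = tuple(
        Glomerulus(centre=c, radius=5.0, amplitudes=a)
        for c, a in zip(_DEFAULT_CENTRES_64[:n_glomeruli], _DEFAULT_AMPLITUDES)
    )
    return SyntheticMovieSpec(glomeruli=gloms, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# serialisation

def spec_to_json(spec: SyntheticMovieSpec, path: str | Path) -> None:
    d = {
        "dims": list(spec.dims),
        "n_measurements": spec.n_measurements,
        "frames_per_measurement": spec.frames_per_measurement,
        "glomeruli": [
            {"centre": list(g.centre), "radius": g.radius, "amplitudes": list(g.amplitudes)}
            for g in spec.glomeruli
        ],
        "response_template": vars(spec.response_template).copy(),
        "bleach_amplitude": spec.bleach_amplitude,
        "bleach_tau": spec.bleach_tau,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    Path(path).write_text(json.dumps(d, indent=2))


def spec_from_json(path: str | Path) -> SyntheticMovieSpec:
    d = json.loads(Path(path).read_text())
    return SyntheticMovieSpec(
        dims=tuple(d["dims"]),
        n_measurements=d["n_measurements"],
        frames_per_measurement=d["frames_per_measurement"],
        glomeruli=tuple(
            Glomerulus(
                centre=tuple(g["centre"]),
                radius=g["radius"],
                amplitudes=tuple(g["amplitudes"]),
            )
            for g in d["glomeruli"]
        ),
        response_template=ResponseTemplate(**d.get("response_template", {})),
        bleach_amplitude=d.get("bleach_amplitude", 0.1),
        bleach_tau=d.get("bleach_tau", 20.0),
        noise_sd=d.get("noise_sd", 0.15),
        seed=d.get("seed", 0),
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist masks, profiles, timecourses and trend to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=truth.masks)
        f.create_dataset("profiles", data=truth.profiles)
        f.create_dataset("timecourses", data=truth.timecourses)
        f.create_dataset("trend", data=truth.trend)
        f.attrs["overlapping"] = truth.overlapping
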