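"""Seeded synthetic tachograms and low-rank spectrum matrices.

The generator emulates the two structural facts the completion method rests
on: 5-minute HRV segments whose PSD shows a Mayer-wave lobe near 0.1 Hz (LF)
and a respiratory RSA lobe near 0.25 Hz (HF), and a segment-by-frequency
matrix whose rows are mixtures of a few latent prototype spectra and is
therefore approximately low rank.  Spectra are generated in ms^2/Hz, the
conventional HRV unit (prototype LF areas of a few hundred ms^2), which also
keeps matrix nuclear norms large against the completion's absolute
lambda-interval tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GaussianComponent, gaussian_eval
from .preprocess import RRSeries
from .spectral import SpectrumMatrix

__all__ = [
    "SynthTachogramParams",
    "SynthMatrixParams",
    "synth_tachogram",
    "synth_spectrum_matrix",
    "default_freq_grid",
    "random_prototypes",
]

#: Physiological floor for a generated RR interval (s); intervals below it
#: are clipped so beat times stay strictly monotone without rejection
#: sampling.
MIN_RR_S = 0.2


def default_freq_grid() -> np.ndarray:
    """0 to 1 Hz in steps of 1/256 Hz (the Welch default's resolution)."""
    return np.arange(0, 256 + 1) / 256.0


@dataclass
class SynthTachogramParams:
    """Sinusoidally modulated RR series.

    rr_i = mean_rr + lf_amp sin(2 pi lf_freq t_i) + hf_amp sin(2 pi hf_freq t_i) + noise.

    Defaults give a 5-minute segment at 75 bpm with ~30 ms Mayer-wave and
    ~25 ms respiratory modulation plus 10 ms beat-to-beat noise — an
    unremarkable short-term recording of a healthy adult.
    """

    duration_s: float = 300.0
    mean_rr_s: float = 0.8
    lf_amp: float = 0.03
    hf_amp: float = 0.025
    lf_freq_hz: float = 0.1
    hf_freq_hz: float = 0.25
    noise_sd_s: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.mean_rr_s <= 0:
            raise ValueError("duration_s and mean_rr_s must be positive")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd_s < 0:
            raise ValueError("amplitudes and noise SD must be nonnegative")
        if not 0 < self.lf_freq_hz < self.hf_freq_hz:
            raise ValueError("need 0 < lf_freq_hz < hf_freq_hz")


@dataclass
class SynthMatrixParams:
    """Mixture-of-prototypes spectrum matrix.

    Each of the ``n_prototypes`` prototype spectra is a sum of one LF and
    one HF Gaussian lobe; every row is a convex combination of the
    prototypes (Dirichlet(alpha) weights, or near-pure cluster weights with
    ``mixing="cluster"``) plus additive measurement noise, clipped at zero.
    """

    n_rows: int = 60
    n_prototypes: int = 3
    freq_grid: np.ndarray = field(default_factory=default_freq_grid)
    prototypes: list[list[GaussianComponent]] | None = None
    mixing: str = "dirichlet"  # "dirichlet" | "cluster"
    dirichlet_alpha: float = 1.0
    mixing_noise_sd: float = 0.0
    additive_noise_sd: float = 10.0  # ms^2/Hz, ~0.5% of a typical LF peak
    seed: int = 0

    def __post_init__(self) -> None:
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.freq_grid.size == 0:
            raise ValueError("freq_grid must not be empty")
        if np.any(np.diff(self.freq_grid) <= 0) or np.any(self.freq_grid < 0):
            raise ValueError("freq_grid must be strictly increasing and nonnegative")
        if not 1 <= self.n_prototypes <= self.n_rows:
            raise ValueError("need 1 <= n_prototypes <= n_rows")
        if self.mixing not in ("dirichlet", "cluster"):
            raise ValueError("mixing must be 'dirichlet' or 'cluster'")
        if self.mixing_noise_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


def synth_tachogram(params: SynthTachogramParams) -> RRSeries:
    """Generate a seeded sinusoidally modulated RR series.

    Beat times accumulate from the intervals; each interval is evaluated at
    the time of the previous beat.  Intervals are clipped at 0.2 s.
    """
    rng = np.random.default_rng(params.seed)
    times: list[float] = []
    intervals: list[float] = []
    t = 0.0
    while t < params.duration_s:
        rr = (
            params.mean_rr_s
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq_hz * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq_hz * t)
        )
        if params.noise_sd_s > 0:
            rr += rng.normal(0.0, params.noise_sd_s)
        rr = max(rr, MIN_RR_S)
        t += rr
        times.append(t)
        intervals.append(rr)
    return RRSeries(np.asarray(times), np.asarray(intervals))


def random_prototypes(
    n_prototypes: int, rng: np.random.Generator
) -> list[list[GaussianComponent]]:
    """Draw LF+HF Gaussian prototype components at physiological positions.

    LF lobes: area 300-800 ms^2 centred in 0.08-0.12 Hz (Mayer wave);
    HF lobes: area 150-500 ms^2 centred in 0.20-0.30 Hz (RSA at typical
    resting respiratory rates).
    """
    protos = []
    for _ in range(n_prototypes):
        lf = GaussianComponent(
            amplitude=float(rng.uniform(300.0, 800.0)),
            center=float(rng.uniform(0.08, 0.12)),
            sigma=float(rng.uniform(0.015, 0.03)),
        )
        hf = GaussianComponent(
            amplitude=float(rng.uniform(150.0, 500.0)),
            center=float(rng.uniform(0.20, 0.30)),
            sigma=float(rng.uniform(0.02, 0.04)),
        )
        protos.append([lf, hf])
    return protos


def synth_spectrum_matrix(
    params: SynthMatrixParams,
) -> tuple[SpectrumMatrix, np.ndarray]:
    """Generate the mixture matrix and return it with the mixing weights.

    With zero additive noise the matrix rank is at most ``n_prototypes`` by
    construction; the returned weights give the ground-truth mixture (their
    argmax is the row's cluster).
    """
    rng = np.random.default_rng(params.seed)
    prototypes = params.prototypes
    if prototypes is None:
        prototypes = random_prototypes(params.n_prototypes, rng)
    if len(prototypes) != params.n_prototypes:
        raise ValueError("prototypes length does not match n_prototypes")
    proto_rows = np.vstack(
        [
            np.sum([gaussian_eval(c, params.freq_grid) for c in comps], axis=0)
            if comps
            else np.zeros_like(params.freq_grid)
            for comps in prototypes
        ]
    )
    if params.mixing == "dirichlet":
        weights = rng.dirichlet(
            np.full(params.n_prototypes, params.dirichlet_alpha),
            size=params.n_rows,
        )
    else:
        weights = np.zeros((params.n_rows, params.n_prototypes))
        weights[np.arange(params.n_rows), np.arange(params.n_rows) % params.n_prototypes] = 1.0
    if params.mixing_noise_sd > 0:
        weights = weights + np.abs(rng.normal(0, params.mixing_noise_sd, weights.shape))
        weights = weights / weights.sum(axis=1, keepdims=True)
    rows = weights @ proto_rows
    if params.additive_noise_sd > 0:
        rows = rows + rng.normal(0, params.additive_noise_sd, rows.shape)
    rows = np.clip(rows, 0.0, None)
    return SpectrumMatrix(freqs=params.freq_grid, rows=rows), weights
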