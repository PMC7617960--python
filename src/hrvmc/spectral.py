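"""Welch spectra, the segment-by-frequency spectrum matrix, and band metrics.

Each 5-minute tachogram segment yields one power spectral density (PSD) on a
shared frequency grid; stacking the rows gives the spectrum matrix whose
approximate low rank the completion machinery exploits.  Band powers (LF, HF
and their ratio) are the standard frequency-domain HRV summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import UniformSeries

__all__ = [
    "PSDSpectrum",
    "SpectrumMatrix",
    "BandDefinition",
    "BandMetrics",
    "LF_BAND",
    "HF_BAND",
    "FULL_BAND",
    "welch_psd",
    "build_spectrum_matrix",
    "band_power",
    "band_metrics",
    "cumulative_singular_ratio",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_left, f_right] in Hz."""

    name: str
    f_left: float
    f_right: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_left < self.f_right:
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_left < f_right, "
                f"got [{self.f_left}, {self.f_right}]"
            )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of grid points inside the closed band interval."""
        freqs = np.asarray(freqs, dtype=float)
        return (freqs >= self.f_left) & (freqs <= self.f_right)


#: Standard short-term HRV bands.  The Mayer-wave (baroreflex) oscillation
#: falls in LF, respiratory sinus arrhythmia in HF.
LF_BAND = BandDefinition("LF", 0.04, 0.15)
HF_BAND = BandDefinition("HF", 0.15, 0.40)
#: Default column range of the spectrum matrix (LF + HF).
FULL_BAND = BandDefinition("LF+HF", 0.04, 0.40)


@dataclass
class PSDSpectrum:
    """One-sided PSD of a single segment, power density in ms^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    segment_id: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if self.freqs.size and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be nonnegative")


@dataclass
class SpectrumMatrix:
    """Per-segment PSD rows on a shared frequency grid."""

    freqs: np.ndarray
    rows: np.ndarray
    row_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[1] != self.freqs.size:
            raise ValueError("row length does not match frequency grid")
        if not self.row_ids:
            self.row_ids = list(range(self.rows.shape[0]))
        if len(self.row_ids) != self.rows.shape[0]:
            raise ValueError("row_ids length does not match number of rows")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("spectrum matrix entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows.shape

    def restrict(self, band: BandDefinition) -> "SpectrumMatrix":
        """Columns inside the closed band interval, same rows."""
        keep = band.mask(self.freqs)
        if not keep.any():
            raise ValueError(f"band {band.name!r} contains no grid points")
        return SpectrumMatrix(
            freqs=self.freqs[keep], rows=self.rows[:, keep],
            row_ids=list(self.row_ids),
        )


@dataclass
class BandMetrics:
    """Integrated LF and HF power (ms^2) and their ratio."""

    lf_power: float
    hf_power: float
    lf_hf_ratio: float


def welch_psd(
    series: UniformSeries,
    nperseg: int = 256,
    overlap: float = 0.5,
    window: str = "hamming",
    nfft: int = 1024,
    detrend: str = "constant",
    segment_id: int = 0,
) -> PSDSpectrum:
    """Welch PSD of a uniformly resampled tachogram.

    Averages modified periodograms over ``overlap``-fraction overlapping
    windows (50% by default).  With density scaling the one-sided spectrum
    integrates to the variance of the (detrended) series.  The tachogram
    values are taken in seconds and the returned density is in ms^2/Hz,
    the conventional HRV unit.

    Raises
    ------
    ValueError
        If the series is shorter than ``nperseg``.
    """
    values = np.asarray(series.values, dtype=float)
    if values.size < nperseg:
        raise ValueError(
            f"series of length {values.size} is shorter than nperseg={nperseg}"
        )
    freqs, power = signal.welch(
        values * 1e3,  # s -> ms so the density is in ms^2/Hz
        fs=series.sampling_rate_hz,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        nfft=max(nfft, nperseg),
        detrend=detrend,
        scaling="density",
    )
    return PSDSpectrum(freqs=freqs, power=power, segment_id=segment_id)


def build_spectrum_matrix(
    spectra: list[PSDSpectrum],
    band: BandDefinition = FULL_BAND,
) -> SpectrumMatrix:
    """Stack per-segment spectra into a matrix restricted to ``band``.

    All spectra must share an identical frequency grid; columns outside the
    closed interval [band.f_left, band.f_right] are dropped.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ref = spectra[0].freqs
    for spec in spectra[1:]:
        if spec.freqs.shape != ref.shape or not np.allclose(spec.freqs, ref):
            raise ValueError("spectra are not on identical frequency grids")
    keep = band.mask(ref)
    if not keep.any():
        raise ValueError(f"band {band.name!r} contains no grid points")
    rows = np.vstack([spec.power[keep] for spec in spectra])
    return SpectrumMatrix(
        freqs=ref[keep], rows=rows, row_ids=[spec.segment_id for spec in spectra]
    )


def band_power(spec: PSDSpectrum, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over a band, in ms^2."""
    keep = band.mask(spec.freqs)
    if keep.sum() < 2:
        raise ValueError(f"band {band.name!r} lies outside the frequency grid")
    return float(np.trapezoid(spec.power[keep], spec.freqs[keep]))


def band_metrics(
    spec: PSDSpectrum,
    lf: BandDefinition = LF_BAND,
    hf: BandDefinition = HF_BAND,
) -> BandMetrics:
    """LF power, HF power and the sympathovagal LF/HF balance index."""
    lf_p = band_power(spec, lf)
    hf_p = band_power(spec, hf)
    ratio = lf_p / hf_p if hf_p > 0 else float("nan")
    return BandMetrics(lf_power=lf_p, hf_power=hf_p, lf_hf_ratio=ratio)


def cumulative_singular_ratio(matrix: SpectrumMatrix | np.ndarray) -> np.ndarray:
    """Cumulative singular values normalised by the nuclear norm.

    The r-th element is the fraction of the nuclear norm carried by the top
    r singular values; an early approach to 1 indicates effective low rank.
    """
    rows = matrix.rows if isinstance(matrix, SpectrumMatrix) else np.atleast_2d(matrix)
    if rows.size == 0:
        raise ValueError("empty matrix")
    sigma = np.linalg.svd(rows, compute_uv=False)
    total = sigma.sum()
    if total == 0:
        raise ValueError("singular-value ratio undefined for the zero matrix")
    return np.cumsum(sigma) / total
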