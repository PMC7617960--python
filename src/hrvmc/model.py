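"""Parametric Gaussian modelling of HRV spectra.

Each band of an HRV PSD is dominated by a single lobe — the Mayer-wave peak
near 0.1 Hz in LF, the respiratory (RSA) peak in HF — and is well described
by a normalised Gaussian A * N(f0, sigma^2) whose area A is the band power.
The fitted models serve two purposes: they synthesize prototype spectra for
the generator, and they provide the smooth per-segment summaries whose
correlations drive the refined-completion row selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectral import BandDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianComponent",
    "SpectrumModel",
    "FitFailureError",
    "gaussian_eval",
    "eval_model",
    "fit_band_model",
    "model_spectrum",
]


class FitFailureError(RuntimeError):
    """Raised when a band fit cannot be performed or does not converge.

    Carries the best parameters found so far (possibly None).
    """

    def __init__(self, message: str, best_params: list["GaussianComponent"] | None = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian spectral lobe: area ``amplitude`` (ms^2), centre ``center``
    and width ``sigma`` (Hz)."""

    amplitude: float
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.center <= 0 or self.sigma <= 0:
            raise ValueError(
                f"Gaussian parameters must be positive, got "
                f"(A={self.amplitude}, f0={self.center}, sigma={self.sigma})"
            )


@dataclass
class SpectrumModel:
    """A sum of Gaussian components, grouped by the band each was fit in."""

    components: dict[str, list[GaussianComponent]] = field(default_factory=dict)
    freqs: np.ndarray | None = None

    def all_components(self) -> list[GaussianComponent]:
        return [c for comps in self.components.values() for c in comps]

    def __call__(self, freqs: np.ndarray) -> np.ndarray:
        return eval_model(self, freqs)


def gaussian_eval(comp: GaussianComponent, freqs: np.ndarray | float) -> np.ndarray:
    """Normalised Gaussian density A / (sqrt(2 pi) sigma) exp(-(f-f0)^2 / 2 sigma^2).

    The integral over all frequencies equals the area weight A, so A carries
    the band power of the lobe.
    """
    f = np.asarray(freqs, dtype=float)
    return (
        comp.amplitude
        / (np.sqrt(2.0 * np.pi) * comp.sigma)
        * np.exp(-((f - comp.center) ** 2) / (2.0 * comp.sigma**2))
    )


def eval_model(model: SpectrumModel, freqs: np.ndarray) -> np.ndarray:
    """Evaluate the full model (sum over all bands' components) on a grid."""
    f = np.asarray(freqs, dtype=float)
    out = np.zeros_like(f)
    for comp in model.all_components():
        out += gaussian_eval(comp, f)
    return out


def _multi_gauss(f: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(f)
    for a, f0, s in params.reshape(-1, 3):
        out += a / (np.sqrt(2.0 * np.pi) * s) * np.exp(-((f - f0) ** 2) / (2 * s * s))
    return out


def fit_band_model(
    freqs: np.ndarray,
    power: np.ndarray,
    band: BandDefinition,
    n_components: int = 1,
) -> list[GaussianComponent]:
    """Nonlinear least-squares fit of Gaussian lobes to one band of a spectrum.

    Deterministic initialisation: centres at the band argmax (spread evenly
    for multiple components), areas at the trapezoidal band power split
    equally, widths at a sixth of the band width.  Bounds keep centres inside
    the band and widths between one grid step and the band width, preventing
    degenerate spikes.

    Raises
    ------
    FitFailureError
        If the band holds fewer than 5 grid points, the spectrum is
        degenerate (zero band power), or the solver fails to converge
        within its evaluation budget.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    keep = band.mask(freqs)
    fb, yb = freqs[keep], power[keep]
    if fb.size < 5:
        raise FitFailureError(
            f"band {band.name!r} holds only {fb.size} grid points (need >= 5)"
        )
    if np.any(yb < 0):
        raise FitFailureError(f"negative power in band {band.name!r}")
    bp = float(np.trapezoid(yb, fb))
    if bp <= 0 or yb.max() <= 0:
        raise FitFailureError(f"zero spectrum in band {band.name!r}")

    width = band.f_right - band.f_left
    df = float(np.min(np.diff(fb)))
    n = max(int(n_components), 1)
    f_peak = fb[int(np.argmax(yb))]
    if n == 1:
        centers0 = np.array([f_peak])
    else:  # spread starts across the band, keeping one at the argmax
        centers0 = np.linspace(band.f_left + width / (n + 1),
                               band.f_right - width / (n + 1), n)
        centers0[np.argmin(np.abs(centers0 - f_peak))] = f_peak
    p0 = np.column_stack(
        [np.full(n, bp / n), centers0, np.full(n, width / 6.0)]
    ).ravel()
    lower = np.tile([1e-12, band.f_left, df], n)
    upper = np.tile([10.0 * bp, band.f_right, width], n)
    p0 = np.clip(p0, lower, upper)

    result = least_squares(
        lambda p: _multi_gauss(fb, p) - yb,
        p0,
        bounds=(lower, upper),
        xtol=1e-10, ftol=1e-10, gtol=1e-10,
        max_nfev=2000,
    )
    comps = [
        GaussianComponent(amplitude=a, center=f0, sigma=s)
        for a, f0, s in result.x.reshape(-1, 3)
    ]
    if result.status <= 0:
        raise FitFailureError(
            f"band {band.name!r} fit did not converge within budget", comps
        )
    residual = float(np.linalg.norm(result.fun))
    logger.debug("band %s fit: residual %.3g, %d nfev", band.name, residual, result.nfev)
    return comps


def model_spectrum(
    freqs: np.ndarray,
    power: np.ndarray,
    bands: list[BandDefinition],
    n_components: int = 1,
) -> SpectrumModel:
    """Fit every band of a spectrum and combine into one evaluable model.

    Bands must be disjoint.  Fit errors are re-raised tagged with the band
    name and the bands fit so far.
    """
    for a in bands:
        for b in bands:
            if a is not b and a.f_left < b.f_right and b.f_left < a.f_right:
                raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")
    model = SpectrumModel(freqs=np.asarray(freqs, dtype=float))
    for band in bands:
        try:
            model.components[band.name] = fit_band_model(
                freqs, power, band, n_components=n_components
            )
        except FitFailureError as err:
            raise FitFailureError(f"band {band.name!r}: {err}", err.best_params) from err
    return model
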