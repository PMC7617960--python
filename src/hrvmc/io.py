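"""Delimited-text I/O for RR series, annotations, spectrum matrices and masks.

All formats are plain text so fixtures and results stay diffable:

* RR series — two columns ``time_s`` and ``rr_s`` (header, whitespace/CSV).
* Annotations — one column ``sample_index``; the sampling rate is supplied
  separately.
* Spectrum matrix — first row the frequency bin centres (Hz), one row per
  segment.
* Mask — 0/1 grid, same shape as its matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .completion import ObservationMask
from .preprocess import PeakAnnotations, RRSeries
from .spectral import SpectrumMatrix

__all__ = [
    "read_rr_series",
    "write_rr_series",
    "read_annotations",
    "read_spectrum_matrix",
    "write_spectrum_matrix",
    "read_mask",
    "write_mask",
]


def read_rr_series(path: str | Path, delimiter: str | None = None) -> RRSeries:
    df = pd.read_csv(path, sep=delimiter, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        time_col, rr_col = cols["time_s"], cols["rr_s"]
    except KeyError as err:
        raise ValueError(f"{path}: need columns time_s and rr_s") from err
    return RRSeries(df[time_col].to_numpy(float), df[rr_col].to_numpy(float))


def write_rr_series(rr: RRSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": rr.beat_times, "rr_s": rr.intervals}).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_annotations(path: str | Path, sampling_rate_hz: float) -> PeakAnnotations:
    df = pd.read_csv(path, sep=None, engine="python")
    col = next(
        (c for c in df.columns if c.lower().strip() == "sample_index"),
        df.columns[0],
    )
    return PeakAnnotations(df[col].to_numpy(np.int64), sampling_rate_hz)


def read_spectrum_matrix(path: str | Path) -> SpectrumMatrix:
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[0] < 2:
        raise ValueError(f"{path}: need a frequency header row plus >=1 spectrum row")
    return SpectrumMatrix(freqs=data[0], rows=data[1:])


def write_spectrum_matrix(matrix: SpectrumMatrix, path: str | Path) -> None:
    np.savetxt(
        path,
        np.vstack([matrix.freqs, matrix.rows]),
        delimiter="\t",
        fmt="%.9g",
    )


def read_mask(path: str | Path) -> ObservationMask:
    grid = np.loadtxt(path, delimiter="\t")
    return ObservationMask(np.atleast_2d(grid).astype(bool))


def write_mask(mask: ObservationMask, path: str | Path) -> None:
    np.savetxt(path, mask.known.astype(int), delimiter="\t", fmt="%d")
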