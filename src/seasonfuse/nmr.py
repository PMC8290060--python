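"""1D NMR spectrum preprocessing and fixed-width spectral binning.

The preprocessing chain mirrors a standard processing-software recipe:
asymmetric-least-squares (Whittaker-penalised) baseline correction, Gaussian
line broadening, Savitzky-Golay smoothing, normalization by the largest peak,
and reduction to fixed-width chemical-shift buckets whose mean intensities
form the NMR variable block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .errors import DegenerateInputError, FormatError

DEFAULT_BIN_WIDTH = 0.04  # ppm
DEFAULT_SPECTROMETER_MHZ = 500.0  # 1H frequency of the acquisition instrument


@dataclass
class Spectrum:
    """A 1D NMR intensity trace on a strictly increasing ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if len(self.ppm) and np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")


@dataclass
class BinnedSpectrum:
    """Fixed-width bucket reduction of a spectrum.

    ``edges`` holds n_bins + 1 boundaries; bucket i covers the half-open
    interval [edges[i], edges[i+1]).
    """

    edges: np.ndarray
    values: np.ndarray
    sample_id: str = ""

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.values)


def load_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) text/CSV spectrum.

    Descending axes (the native NMR display order) are re-sorted ascending.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, header=None, comment="#",
                            names=["ppm", "intensity"], skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty spectrum file: {path}") from exc
    # Tolerate a textual header line.
    if table["ppm"].dtype == object:
        table = table[pd.to_numeric(table["ppm"], errors="coerce").notna()]
    table = table.apply(pd.to_numeric, errors="coerce")
    if table.empty or table.isna().any().any():
        raise FormatError(f"non-numeric content in spectrum file: {path}")
    ppm = table["ppm"].to_numpy()
    inten = table["intensity"].to_numpy()
    order = np.argsort(ppm, kind="stable")
    return Spectrum(ppm[order], inten[order],
                    sample_id=sample_id if sample_id is not None else path.stem)


def save_spectrum(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(
        path, index=False, header=False)


def baseline_correct(s: Spectrum, smoothness: float = 1e5,
                     asymmetry: float = 0.01, n_iter: int = 10) -> Spectrum:
    """Subtract an asymmetric-least-squares baseline (Whittaker smoother).

    The baseline z minimises sum_i w_i (y_i - z_i)^2 + smoothness * ||D2 z||^2
    with asymmetric weights (points above the baseline, i.e. peaks, get weight
    ``asymmetry``; points below get 1 - asymmetry), iterated to convergence.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    y = s.intensity
    m = len(y)
    if m < 3:
        return replace(s, intensity=np.zeros_like(y))
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m)).tocsc()
    penalty = smoothness * (d2.T @ d2)
    w = np.ones(m)
    z = y
    for _ in range(n_iter):
        weight_mat = sparse.diags(w, 0, format="csc")
        z = spsolve(weight_mat + penalty, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return replace(s, intensity=y - z)


def smooth(s: Spectrum, window_points: int = 11, poly_order: int = 3) -> Spectrum:
    """Savitzky-Golay polynomial smoothing; exact on polynomials up to the order."""
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if poly_order >= window_points:
        raise ValueError("poly_order must be smaller than window_points")
    return replace(s, intensity=savgol_filter(s.intensity, window_points, poly_order))


def gaussian_broaden(s: Spectrum, gb_hz: float = 1.0,
                     spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ) -> Spectrum:
    """Frequency-domain equivalent of Gaussian apodization.

    Convolves with a unit-area Gaussian whose standard deviation is gb_hz
    converted to ppm (gb_hz / spectrometer_mhz).  Requires an (approximately)
    uniform axis.
    """
    if gb_hz <= 0:
        raise ValueError("gb_hz must be positive")
    dppm = np.diff(s.ppm)
    step = float(np.median(dppm))
    sigma_ppm = gb_hz / spectrometer_mhz
    half = max(1, int(np.ceil(4 * sigma_ppm / step)))
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / sigma_ppm) ** 2)
    kernel /= kernel.sum()
    # Edge padding preserves the integral of flat regions at the boundaries.
    padded = np.pad(s.intensity, half, mode="edge")
    return replace(s, intensity=np.convolve(padded, kernel, mode="valid"))


def normalize_max(s: Spectrum) -> Spectrum:
    """Scale so the largest peak has intensity 1."""
    peak = float(np.max(np.abs(s.intensity))) if len(s.intensity) else 0.0
    if peak == 0.0:
        raise DegenerateInputError("cannot max-normalize an all-zero spectrum")
    return replace(s, intensity=s.intensity / peak)


def bin_spectrum(s: Spectrum, ppm_min: float = 0.0, ppm_max: float = 10.0,
                 width: float = DEFAULT_BIN_WIDTH, method: str = "mean") -> BinnedSpectrum:
    """Reduce a spectrum to fixed-width buckets.

    Buckets are half-open [low, low + width); the value is the arithmetic mean
    of the point intensities falling in each bucket (``method="sum"`` keeps
    the plain sum instead).  Empty buckets are zero.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if ppm_max <= ppm_min:
        raise ValueError("ppm_max must exceed ppm_min")
    if method not in ("mean", "sum"):
        raise ValueError("method must be 'mean' or 'sum'")
    n_bins = round((ppm_max - ppm_min) / width)
    edges = ppm_min + width * np.arange(n_bins + 1)
    idx = np.floor((s.ppm - ppm_min) / width).astype(int)
    in_range = (s.ppm >= ppm_min) & (idx < n_bins) & (idx >= 0)
    sums = np.bincount(idx[in_range], weights=s.intensity[in_range], minlength=n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    if method == "mean":
        values = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    else:
        values = sums
    return BinnedSpectrum(edges, values, sample_id=s.sample_id)


def preprocess(s: Spectrum, *, baseline: bool = True, smoothness: float = 1e5,
               asymmetry: float = 0.01, gb_hz: float = 1.0,
               spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ,
               window_points: int = 11, poly_order: int = 3,
               normalize: bool = True) -> Spectrum:
    """Default preprocessing chain: baseline -> broaden -> smooth -> normalize."""
    out = s
    if baseline:
        out = baseline_correct(out, smoothness=smoothness, asymmetry=asymmetry)
    out = gaussian_broaden(out, gb_hz=gb_hz, spectrometer_mhz=spectrometer_mhz)
    out = smooth(out, window_points=window_points, poly_order=poly_order)
    if normalize:
        out = normalize_max(out)
    return out


def bin_matrix(spectra: list[Spectrum], ppm_min: float = 0.0, ppm_max: float = 10.0,
               width: float = DEFAULT_BIN_WIDTH, method: str = "mean") -> pd.DataFrame:
    """Bin a collection of spectra onto identical edges; samples x bins.

    Columns are labelled by the bucket center chemical shift.
    """
    binned = [bin_spectrum(s, ppm_min, ppm_max, width, method) for s in spectra]
    if not binned:
        raise ValueError("no spectra supplied")
    centers = binned[0].centers
    for b in binned[1:]:
        if not np.allclose(b.edges, binned[0].edges):
            raise ValueError("spectra were binned on different edges")
    return pd.DataFrame([b.values for b in binned],
                        index=[b.sample_id for b in binned],
                        columns=[f"{c:.3f}" for c in centers])
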