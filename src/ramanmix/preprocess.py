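"""Spectral preprocessing: axis conversion, cropping, asymmetric-least-squares
baseline removal, Savitzky-Golay smoothing and min-max rescaling.

All matrix-level operations work per spectrum, independently, and preserve row
order and labels.  The canonical order is crop -> baseline -> smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .spectra import SpectraMatrix

__all__ = [
    "AslsParams",
    "SavgolParams",
    "nm_to_raman_shift",
    "raman_shift_to_nm",
    "crop_range",
    "asls_baseline",
    "savgol_smooth",
    "minmax_rescale",
    "preprocess_spectra",
]


@dataclass(frozen=True)
class AslsParams:
    """Asymmetric least squares baseline settings.

    ``lam`` is stored as printed; with ``lam_is_log10`` (the R ``baseline``
    package convention, and the default here) the effective smoothness
    penalty is ``10**lam``.
    """

    lam: float = 6.0
    p: float = 0.1
    n_iter: int = 10
    lam_is_log10: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("asymmetry weight p must lie in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    @property
    def lam_effective(self) -> float:
        return 10.0 ** self.lam if self.lam_is_log10 else self.lam


@dataclass(frozen=True)
class SavgolParams:
    window: int = 15
    polyorder: int = 1
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be smaller than window")
        if self.deriv < 0:
            raise ValueError("deriv must be >= 0")


def nm_to_raman_shift(wavelength_nm, excitation_nm: float):
    """Convert absolute wavelength (nm) to Raman shift (cm^-1).

    shift = 1e7 * (1/excitation - 1/wavelength); Stokes side only.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be positive")
    if np.any(wl < excitation_nm):
        raise ValueError("wavelength below excitation (anti-Stokes) not supported")
    return 1e7 * (1.0 / excitation_nm - 1.0 / wl)


def raman_shift_to_nm(shift_cm1, excitation_nm: float):
    """Inverse of :func:`nm_to_raman_shift`."""
    shift = np.asarray(shift_cm1, dtype=float)
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be positive")
    if np.any(shift < 0):
        raise ValueError("negative Raman shift (anti-Stokes) not supported")
    return 1.0 / (1.0 / excitation_nm - shift * 1e-7)


def crop_range(spectra: SpectraMatrix, lo: float, hi: float) -> SpectraMatrix:
    """Retain the columns with ``lo <= axis <= hi`` (inclusive)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    keep = (spectra.axis >= lo) & (spectra.axis <= hi)
    if not np.any(keep):
        raise ValueError(f"crop [{lo}, {hi}] leaves no spectral points")
    return replace(spectra, axis=spectra.axis[keep], values=spectra.values[:, keep])


def _second_difference(n: int) -> sparse.csc_matrix:
    # interior second differences only: (n-2) x n; edges unpenalized
    return sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)).tocsc()


def asls_baseline(y: np.ndarray, params: AslsParams | None = None):
    """Eilers-style asymmetric least squares baseline for one spectrum.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` with the
    weights re-set each iteration to ``p`` where ``y > z`` and ``1 - p``
    elsewhere.

    Returns
    -------
    (baseline, corrected)
        ``corrected = y - baseline``.
    """
    params = params or AslsParams()
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("spectrum must have at least 3 points")
    lam = params.lam_effective
    d2 = _second_difference(n)
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(params.n_iter):
        lhs = sparse.diags(w) + penalty
        z = spsolve(lhs.tocsc(), w * y)
        w = np.where(y > z, params.p, 1.0 - params.p)
    return z, y - z


def savgol_smooth(y: np.ndarray, params: SavgolParams | None = None) -> np.ndarray:
    """Savitzky-Golay filtering (derivative 0 = smoothing)."""
    params = params or SavgolParams()
    y = np.asarray(y, dtype=float)
    if params.window > y.shape[-1]:
        raise ValueError("window exceeds spectrum length")
    return savgol_filter(
        y, window_length=params.window, polyorder=params.polyorder,
        deriv=params.deriv, axis=-1,
    )


def minmax_rescale(y: np.ndarray) -> np.ndarray:
    """Map each spectrum linearly onto [0, 1]."""
    y = np.asarray(y, dtype=float)
    lo = y.min(axis=-1, keepdims=True)
    hi = y.max(axis=-1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise ValueError("constant spectrum has zero intensity range")
    return (y - lo) / (hi - lo)


def preprocess_spectra(
    spectra: SpectraMatrix,
    crop: tuple[float, float] | None = (1114.0, 1874.0),
    asls: AslsParams | None = AslsParams(),
    savgol: SavgolParams | None = SavgolParams(),
) -> SpectraMatrix:
    """Apply the standard chain crop -> AsLS baseline -> Savitzky-Golay.

    Defaults run the full chain with the standard settings; pass ``None``
    for a step to skip it.  Row order and labels are preserved.
    """
    out = spectra
    if crop is not None:
        out = crop_range(out, *crop)
    if asls is not None:
        corrected = np.empty_like(out.values)
        for i in range(out.n_samples):
            _, corrected[i] = asls_baseline(out.values[i], asls)
        out = out.with_values(corrected, stage="baseline_removed")
    if savgol is not None:
        out = out.with_values(savgol_smooth(out.values, savgol), stage="smoothed")
    return out
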