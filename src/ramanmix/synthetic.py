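"""Synthetic skin-Raman dataset generator with known ground truth.

Builds a small library of skin-like pure-component spectra (melanin,
proteins, water, NMF + lipids), draws class-dependent concentrations for the
five-class cohort, mixes them bilinearly, and layers on the acquisition
artifacts of a portable probe: a smooth fluorescence background, a sinusoidal
etalon ripple defined on the wavelength axis, and Gaussian noise calibrated
to a target signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .preprocess import raman_shift_to_nm
from .spectra import CLASS_LABELS, SpectraMatrix

__all__ = [
    "PeakSpec",
    "ComponentSpectrumSpec",
    "ClassProfile",
    "FluorescenceModel",
    "RippleModel",
    "AcquisitionModel",
    "SyntheticDataset",
    "default_grid",
    "raw_grid",
    "build_component_library",
    "default_component_specs",
    "cohort_profiles",
    "simulate_dataset",
    "add_fluorescence_baseline",
    "add_etalon_ripple",
    "add_noise_to_snr",
    "SNR_DEFINITION",
]

#: How the generator defines SNR (recorded in dataset metadata).
SNR_DEFINITION = "max clean Raman peak amplitude / Gaussian noise SD"

#: Cohort class sizes: NS, K, BCC, MM, PN.
COHORT_COUNTS = {"NS": 540, "K": 113, "BCC": 122, "MM": 67, "PN": 158}


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: center (cm^-1), FWHM (cm^-1), relative amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def render(self, grid: np.ndarray) -> np.ndarray:
        x = np.asarray(grid, dtype=float)
        if self.shape == "lorentzian":
            hw = self.fwhm / 2.0
            return self.amplitude * hw**2 / ((x - self.center) ** 2 + hw**2)
        s2 = self.fwhm**2 / (8.0 * np.log(2.0))
        return self.amplitude * np.exp(-((x - self.center) ** 2) / (2.0 * s2))


@dataclass(frozen=True)
class ComponentSpectrumSpec:
    """Named pure-component spectrum: a sum of peaks plus an optional flat pedestal."""

    name: str
    peaks: tuple[PeakSpec, ...]
    broadband: float = 0.0

    def __post_init__(self) -> None:
        if not self.peaks and self.broadband == 0.0:
            raise ValueError(f"component '{self.name}' has no peaks and no pedestal")
        if self.broadband < 0:
            raise ValueError("broadband pedestal must be >= 0")

    def render(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        for pk in self.peaks:
            if not grid[0] <= pk.center <= grid[-1]:
                raise ValueError(
                    f"grid [{grid[0]:.1f}, {grid[-1]:.1f}] does not cover the "
                    f"{pk.center:.0f} cm^-1 peak of component '{self.name}'"
                )
        y = np.full(grid.shape, float(self.broadband))
        for pk in self.peaks:
            y = y + pk.render(grid)
        # scale so the strongest point is 1 (shapes stay non-negative)
        return y / y.max()


@dataclass(frozen=True)
class ClassProfile:
    """Mean concentrations (per component name), CVs and sample count for one class."""

    class_label: str
    mean_concentration: dict
    cv: dict
    n_samples: int

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name, m in self.mean_concentration.items():
            if m < 0:
                raise ValueError(f"negative mean concentration for '{name}'")
        for name, c in self.cv.items():
            if c < 0:
                raise ValueError(f"negative cv for '{name}'")


@dataclass(frozen=True)
class FluorescenceModel:
    enabled: bool = True
    amplitude: float = 5.0
    decay_cm: float = 600.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("fluorescence amplitude must be >= 0")
        if self.decay_cm <= 0:
            raise ValueError("fluorescence decay scale must be positive")


@dataclass(frozen=True)
class RippleModel:
    enabled: bool = True
    amplitude: float = 0.05
    period_nm: float = 3.0
    phase: float = 0.0
    mode: str = "additive"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("ripple amplitude must be >= 0")
        if self.period_nm <= 0:
            raise ValueError("ripple period must be positive")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError("ripple mode must be 'additive' or 'multiplicative'")


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrument model: excitation line, artifact settings and target SNR.

    ``target_snr = None`` disables noise entirely.
    """

    excitation_nm: float = 785.0
    fluorescence: FluorescenceModel = field(default_factory=FluorescenceModel)
    ripple: RippleModel = field(default_factory=RippleModel)
    target_snr: float | None = 3.0

    def __post_init__(self) -> None:
        if self.excitation_nm <= 0:
            raise ValueError("excitation wavelength must be positive")
        if self.target_snr is not None and not self.target_snr > 0:
            raise ValueError("target_snr must be positive")


@dataclass
class SyntheticDataset:
    """Generated spectra plus the ground truth they were mixed from."""

    spectra: SpectraMatrix
    c_true: np.ndarray
    s_true: np.ndarray
    component_names: tuple
    seed: int
    acquisition: AcquisitionModel
    snr_definition: str = SNR_DEFINITION


def default_grid(lo: float = 1114.0, hi: float = 1874.0, step: float = 2.0) -> np.ndarray:
    """Working wavenumber grid (cm^-1), inclusive of both endpoints."""
    return np.arange(lo, hi + step / 2, step)


def raw_grid(step: float = 2.0) -> np.ndarray:
    """Uncropped instrument grid, 792-1874 cm^-1."""
    return default_grid(792.0, 1874.0, step)


def default_component_specs() -> tuple[ComponentSpectrumSpec, ...]:
    """Four skin-like components with the characteristic band positions.

    melanin: broad bands peaking near 1390 and 1520 cm^-1;
    proteins: 1150 / 1280 / 1450 / 1660 with 1450 the most intense;
    water: one broad band at 1650; nmf_lipids: 1174 / 1230 / 1750 plus a
    broad 1700-1850 lipid band.
    """
    return (
        ComponentSpectrumSpec(
            "melanin",
            peaks=(
                PeakSpec(1390.0, 60.0, 1.0),
                PeakSpec(1520.0, 60.0, 0.92),
            ),
            broadband=0.05,
        ),
        ComponentSpectrumSpec(
            "proteins",
            peaks=(
                PeakSpec(1150.0, 26.0, 0.35),
                PeakSpec(1280.0, 30.0, 0.45),
                PeakSpec(1450.0, 28.0, 1.0),
                PeakSpec(1660.0, 32.0, 0.75),
            ),
        ),
        ComponentSpectrumSpec(
            "water",
            peaks=(PeakSpec(1650.0, 130.0, 1.0, shape="gaussian"),),
        ),
        ComponentSpectrumSpec(
            "nmf_lipids",
            peaks=(
                PeakSpec(1174.0, 24.0, 0.8),
                PeakSpec(1230.0, 24.0, 0.7),
                PeakSpec(1750.0, 28.0, 0.9),
                PeakSpec(1790.0, 90.0, 0.4, shape="gaussian"),
            ),
        ),
    )


def build_component_library(
    grid: np.ndarray,
    specs: tuple[ComponentSpectrumSpec, ...] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Render the pure-component library on ``grid``.

    Returns ``(names, S)`` with ``S`` of shape (n_components, len(grid)),
    each row non-negative with unit maximum.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    specs = specs if specs is not None else default_component_specs()
    names = [sp.name for sp in specs]
    s = np.vstack([sp.render(grid) for sp in specs])
    return names, s


def cohort_profiles(
    cv: float = 0.25, counts: dict | None = None
) -> tuple[ClassProfile, ...]:
    """Five-class concentration profiles with melanin elevated in K, MM, PN.

    Class sizes default to the 540/113/122/67/158 cohort.
    """
    counts = counts or COHORT_COUNTS
    # melanin low in NS and BCC, high in the pigmented classes; each component
    # dominates at least one class, which gives SIMPLISMA near-pure rows
    means = {
        "NS": {"melanin": 0.02, "proteins": 0.30, "water": 1.20, "nmf_lipids": 0.05},
        "K": {"melanin": 0.90, "proteins": 0.30, "water": 0.15, "nmf_lipids": 1.10},
        "BCC": {"melanin": 0.05, "proteins": 1.20, "water": 0.40, "nmf_lipids": 0.10},
        "MM": {"melanin": 1.40, "proteins": 0.20, "water": 0.30, "nmf_lipids": 0.10},
        "PN": {"melanin": 1.00, "proteins": 0.60, "water": 0.50, "nmf_lipids": 0.60},
    }
    return tuple(
        ClassProfile(
            class_label=lab,
            mean_concentration=means[lab],
            cv={name: cv for name in means[lab]},
            n_samples=counts[lab],
        )
        for lab in CLASS_LABELS
        if lab in counts
    )


def _truncated_normal(mean: float, cv: float, size: int, rng: np.random.Generator):
    """Normal(mean, cv*mean) truncated at zero; degenerate when sd == 0."""
    sd = cv * mean
    if sd == 0.0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def add_fluorescence_baseline(
    values: np.ndarray, grid: np.ndarray, acquisition: AcquisitionModel
) -> np.ndarray:
    """Add the smooth, monotone-decaying fluorescence background.

    Closed form: ``amplitude * exp(-(nu - nu_min) / decay_cm)`` -- slowly
    varying (no structure narrower than the decay scale) and non-negative.
    """
    fl = acquisition.fluorescence
    if fl.amplitude == 0.0:
        return np.array(values, dtype=float, copy=True)
    grid = np.asarray(grid, dtype=float)
    background = fl.amplitude * np.exp(-(grid - grid[0]) / fl.decay_cm)
    return np.asarray(values, dtype=float) + background


def add_etalon_ripple(
    values: np.ndarray, grid: np.ndarray, acquisition: AcquisitionModel
) -> np.ndarray:
    """Apply the CCD-etalon sinusoid, defined on the wavelength axis.

    The ripple is ``amplitude * (1 + sin(2*pi*lambda/period + phase)) / 2``
    (always >= 0), added or, in multiplicative mode, applied as a gain
    ``1 + ripple``.
    """
    rp = acquisition.ripple
    values = np.array(values, dtype=float, copy=True)
    if rp.amplitude == 0.0:
        return values
    wl = raman_shift_to_nm(np.asarray(grid, dtype=float), acquisition.excitation_nm)
    ripple = rp.amplitude * 0.5 * (1.0 + np.sin(2.0 * np.pi * wl / rp.period_nm + rp.phase))
    if rp.mode == "additive":
        return values + ripple
    return values * (1.0 + ripple)


def add_noise_to_snr(
    values: np.ndarray, target_snr: float, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Add zero-mean Gaussian noise so that peak-signal / noise-SD == target_snr.

    The noise SD is set per spectrum from the maximum of the clean signal.
    Returns ``(noisy, noise_sd)``.
    """
    if not target_snr > 0:
        raise ValueError("target_snr must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    peak = values.max(axis=1)
    if np.any(peak <= 0):
        raise ValueError("clean signal has no positive peak; SNR undefined")
    sd = peak / target_snr
    noisy = values + rng.standard_normal(values.shape) * sd[:, None]
    return noisy, sd


def simulate_dataset(
    profiles: tuple[ClassProfile, ...] | None = None,
    grid: np.ndarray | None = None,
    specs: tuple[ComponentSpectrumSpec, ...] | None = None,
    acquisition: AcquisitionModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw the full synthetic cohort.

    Per sample the concentrations come from a zero-truncated normal with the
    profile's mean/cv; the clean spectrum is the concentration-weighted sum
    of library spectra; fluorescence, ripple and noise follow the
    acquisition model.  Identical seed => bit-identical output.
    """
    profiles = profiles if profiles is not None else cohort_profiles()
    grid = np.asarray(grid, dtype=float) if grid is not None else default_grid()
    acquisition = acquisition if acquisition is not None else AcquisitionModel()
    names, s_true = build_component_library(grid, specs)
    for prof in profiles:
        missing = set(prof.mean_concentration) - set(names)
        if missing:
            raise ValueError(
                f"profile '{prof.class_label}' references unknown components {sorted(missing)}"
            )

    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for prof in profiles:
        block = np.column_stack(
            [
                _truncated_normal(
                    prof.mean_concentration.get(name, 0.0),
                    prof.cv.get(name, 0.0),
                    prof.n_samples,
                    rng,
                )
                for name in names
            ]
        )
        rows.append(block)
        labels.extend([prof.class_label] * prof.n_samples)
    c_true = np.vstack(rows)
    clean = c_true @ s_true

    values = clean
    if acquisition.fluorescence.enabled:
        values = add_fluorescence_baseline(values, grid, acquisition)
    if acquisition.ripple.enabled:
        values = add_etalon_ripple(values, grid, acquisition)
    # artifacts keep every spectrum non-negative; noise (applied last) may not
    if acquisition.target_snr is not None and np.isfinite(acquisition.target_snr):
        values, _ = add_noise_to_snr_matrix(values, clean, acquisition.target_snr, rng)

    spectra = SpectraMatrix(
        axis=grid, values=values, labels=np.array(labels, dtype=object), stage="raw"
    )
    return SyntheticDataset(
        spectra=spectra,
        c_true=c_true,
        s_true=s_true,
        component_names=tuple(names),
        seed=seed,
        acquisition=acquisition,
    )


def add_noise_to_snr_matrix(
    values: np.ndarray,
    clean: np.ndarray,
    target_snr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise scaled against the *clean Raman* peaks, added to the artifacted data."""
    if not target_snr > 0:
        raise ValueError("target_snr must be positive")
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    peak = clean.max(axis=1)
    if np.any(peak <= 0):
        raise ValueError("clean signal has no positive peak; SNR undefined")
    sd = peak / target_snr
    noisy = np.atleast_2d(values) + rng.standard_normal(clean.shape) * sd[:, None]
    return noisy, sd
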