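"""Forward optical model for the flow-cell spectroscopy channel.

This module provides the synthetic dye absorption spectra, the Beer-Lambert
forward model (absorbance and normalized transmission through the Z-flow cell),
and a noisy detector readout emulating a compact CCD spectrometer.

The two default dyes are Erioglaucine disodium salt (EG, blue, absorption peak
631 nm, stock 25 ug/mL) and Tartrazine (TZ, yellow, absorption peak 424 nm,
stock 100 ug/mL), food-grade drug surrogates commonly used in infusion-line
studies.  Their true absorptivity spectra are not tabulated anywhere public, so
they are modelled as Gaussians with a small configurable secondary band giving
each dye a nonzero cross-absorption at the other dye's measurement wavelength;
this is what makes the two-wavelength unmixing problem non-trivial.

Units: wavelengths in nm, concentrations in ug/mL, path length in mm, specific
absorptivity in mL.ug^-1.mm^-1, so absorbance A = eps * C * L is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FlowSpecError, require

#: Spectrometer wavelength range (nm) and grid step (nm).
GRID_MIN_NM = 350.0
GRID_MAX_NM = 700.0
GRID_STEP_NM = 0.5

#: The two measurement wavelengths (nm): TZ and EG absorption peaks.
WAVELENGTH_TZ_NM = 424.0
WAVELENGTH_EG_NM = 631.0


def default_wavelength_grid(
    start: float = GRID_MIN_NM, stop: float = GRID_MAX_NM, step: float = GRID_STEP_NM
) -> np.ndarray:
    """Wavelength grid in nm covering the spectrometer range, endpoint included."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Per-dye specific absorptivity eps(lambda) on a wavelength grid.

    Attributes
    ----------
    dye_name : str
    wavelengths : ndarray
        Strictly increasing grid in nm.
    specific_absorptivity : ndarray
        Nonnegative eps values in mL.ug^-1.mm^-1 aligned to the grid.
    peak_wavelength : float
        Nominal absorption peak in nm; must coincide with the grid argmax
        within one grid step.
    """

    dye_name: str
    wavelengths: np.ndarray
    specific_absorptivity: np.ndarray
    peak_wavelength: float

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.specific_absorptivity, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "specific_absorptivity", eps)
        require(wl.ndim == 1 and wl.size >= 2, "invalid_grid")
        require(bool(np.all(np.diff(wl) > 0)), "invalid_grid", "grid must be strictly increasing")
        require(eps.shape == wl.shape, "invalid_grid", "absorptivity not aligned to grid")
        require(bool(np.all(eps >= 0)), "negative_absorptivity")
        step = float(np.max(np.diff(wl)))
        argmax_wl = float(wl[int(np.argmax(eps))])
        require(
            abs(argmax_wl - self.peak_wavelength) <= step + 1e-9,
            "peak_mismatch",
            f"spectrum argmax {argmax_wl} nm != declared peak {self.peak_wavelength} nm",
        )

    def absorptivity_at(self, wavelength: float, band_half_width: float = 0.0) -> float:
        """eps at a wavelength: nearest grid pixel, or the mean over a +/- band.

        ``band_half_width`` = 0 selects the single nearest pixel (the default
        measurement convention in this package).
        """
        wl = self.wavelengths
        require(
            wl[0] - 1e-9 <= wavelength <= wl[-1] + 1e-9,
            "wavelength_out_of_range",
            f"{wavelength} nm outside [{wl[0]}, {wl[-1]}] nm",
        )
        if band_half_width <= 0:
            return float(self.specific_absorptivity[int(np.argmin(np.abs(wl - wavelength)))])
        mask = np.abs(wl - wavelength) <= band_half_width + 1e-9
        return float(np.mean(self.specific_absorptivity[mask]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "absorptivity": self.specific_absorptivity}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dye_name: str) -> "AbsorptionSpectrum":
        df = pd.read_csv(path)
        wl = df["wavelength_nm"].to_numpy(float)
        eps = df["absorptivity"].to_numpy(float)
        peak = float(wl[int(np.argmax(eps))])
        return cls(dye_name, wl, eps, peak)


@dataclass(frozen=True)
class DyeDefinition:
    """A dye plus its syringe stock concentration C0 (ug/mL)."""

    name: str
    spectrum: AbsorptionSpectrum
    stock_concentration: float

    def __post_init__(self):
        require(self.stock_concentration > 0, "invalid_stock", "C0 must be > 0")


@dataclass(frozen=True)
class FlowCellGeometry:
    """Z-flow cell: 10 mm optical path, 26 uL internal volume by default."""

    path_length_mm: float = 10.0
    internal_volume_ul: float = 26.0

    def __post_init__(self):
        require(self.path_length_mm > 0, "invalid_geometry")
        require(self.internal_volume_ul > 0, "invalid_geometry")


@dataclass(frozen=True)
class DetectorConfig:
    """Spectrometer sampling contract.

    relative_noise_sd is the per-wavelength multiplicative Gaussian noise sd as
    a fraction of the signal (default 0.5%); measurement_interval is the
    sampling period in s (hardware minimum 0.2 s).
    """

    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)
    relative_noise_sd: float = 0.005
    measurement_interval: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        require(self.relative_noise_sd >= 0, "invalid_noise_sd")
        require(
            self.measurement_interval >= 0.2,
            "interval_too_short",
            "measurement interval below the 0.2 s hardware minimum",
        )


def make_dye_spectrum(
    peak_wavelength: float,
    width: float,
    peak_absorptivity: float,
    grid: np.ndarray | None = None,
    dye_name: str = "dye",
    secondary_bands: Iterable[tuple[float, float, float]] = (),
) -> AbsorptionSpectrum:
    """Build a Gaussian absorptivity profile on the grid.

    Parameters
    ----------
    peak_wavelength, width, peak_absorptivity
        Centre (nm), Gaussian sigma (nm) and amplitude (mL.ug^-1.mm^-1) of the
        main absorption band.
    secondary_bands
        Optional ``(peak_nm, width_nm, amplitude)`` tuples for weaker bands,
        used to give a dye a small cross-absorption at other wavelengths.
    """
    if grid is None:
        grid = default_wavelength_grid()
    grid = np.asarray(grid, dtype=float)
    require(width > 0, "invalid_width")
    require(peak_absorptivity > 0, "invalid_absorptivity")
    require(
        grid[0] <= peak_wavelength <= grid[-1],
        "peak_out_of_range",
        f"peak {peak_wavelength} nm outside grid [{grid[0]}, {grid[-1]}] nm",
    )
    eps = peak_absorptivity * np.exp(-((grid - peak_wavelength) ** 2) / (2.0 * width**2))
    for p, w, a in secondary_bands:
        require(w > 0 and a >= 0, "invalid_secondary_band")
        eps = eps + a * np.exp(-((grid - p) ** 2) / (2.0 * w**2))
    return AbsorptionSpectrum(dye_name, grid, eps, peak_wavelength)


def default_dyes(grid: np.ndarray | None = None) -> tuple[DyeDefinition, DyeDefinition]:
    """The (TZ, EG) dye pair with the package's default optical parameters.

    Peak absorptivities are set so that each syringe stock attenuates to
    I/I0 ~ 0.06 at its own peak through the 10 mm cell (a strongly attenuating
    but non-opaque calibration range), and each dye carries a few-percent
    secondary band at the other dye's peak so the unmixing cross terms are
    exercised.
    """
    tz = DyeDefinition(
        name="TZ",
        spectrum=make_dye_spectrum(
            WAVELENGTH_TZ_NM,
            width=30.0,
            peak_absorptivity=0.0012,
            grid=grid,
            dye_name="Tartrazine",
            secondary_bands=[(WAVELENGTH_EG_NM, 45.0, 0.0012 * 0.03)],
        ),
        stock_concentration=100.0,
    )
    eg = DyeDefinition(
        name="EG",
        spectrum=make_dye_spectrum(
            WAVELENGTH_EG_NM,
            width=30.0,
            peak_absorptivity=0.0048,
            grid=grid,
            dye_name="Erioglaucine",
            secondary_bands=[(WAVELENGTH_TZ_NM, 45.0, 0.0048 * 0.02)],
        ),
        stock_concentration=25.0,
    )
    return tz, eg


def absorbance(
    dyes: Sequence[DyeDefinition],
    concentrations: Sequence[float],
    geometry: FlowCellGeometry,
    wavelength: float,
    band_half_width: float = 0.0,
) -> float:
    """Beer-Lambert absorbance A(lambda) = sum_i eps_i(lambda) * c_i * L.

    Additive over dyes and linear in each concentration.
    """
    require(len(dyes) == len(concentrations), "misaligned_concentrations")
    conc = np.asarray(concentrations, dtype=float)
    require(bool(np.all(conc >= 0)), "negative_concentration")
    total = 0.0
    for dye, c in zip(dyes, conc):
        total += dye.spectrum.absorptivity_at(wavelength, band_half_width) * c
    return float(total * geometry.path_length_mm)


def transmission(absorbance_value):
    """Normalized transmission I/I0 = 10**(-A), in (0, 1] for A >= 0."""
    a = np.asarray(absorbance_value, dtype=float)
    require(bool(np.all(a >= 0)), "negative_absorbance")
    out = np.power(10.0, -a)
    return float(out) if out.ndim == 0 else out


def detector_readout(
    true_transmission_spectrum: np.ndarray,
    config: DetectorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy spectrometer readout of a normalized transmission spectrum.

    Applies independent multiplicative Gaussian noise (sd =
    ``config.relative_noise_sd`` of the signal) per wavelength and clips at 0.
    With the default ``rng=None`` the generator is seeded from
    ``config.rng_seed``, so repeated calls are bit-reproducible; pass an
    explicit generator to draw successive independent readouts.
    """
    spec = np.asarray(true_transmission_spectrum, dtype=float)
    require(
        spec.shape == config.wavelengths.shape,
        "grid_mismatch",
        f"spectrum shape {spec.shape} != detector grid {config.wavelengths.shape}",
    )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if config.relative_noise_sd == 0:
        return spec.copy()
    noisy = spec * (1.0 + config.relative_noise_sd * rng.standard_normal(spec.shape))
    return np.clip(noisy, 0.0, None)
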