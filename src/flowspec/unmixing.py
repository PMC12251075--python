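"""Multi-dye concentration recovery from normalized intensities.

The measurement scheme records normalized transmission at one wavelength per
dye (424 nm for Tartrazine, 631 nm for Erioglaucine).  In absorbance space the
Beer-Lambert model is linear, so with the cross-absorptivity matrix
K[w][d] = eps_d(lambda_w) * L the mixture satisfies

    A_w = -log10(I_w / I0_w) = sum_d K[w][d] * C_d,

an exact n x n linear system (n = 2 by default, generalizable to more dyes
given one wavelength per dye).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import FlowSpecError, require
from .spectra import DyeDefinition, FlowCellGeometry, WAVELENGTH_EG_NM, WAVELENGTH_TZ_NM

#: Condition-number threshold above which spectra are treated as degenerate.
CONDITION_LIMIT = 1e8

#: Negative-concentration tolerance as a fraction of stock concentration.
NEGATIVE_TOL_FRACTION = 0.005


@dataclass(frozen=True)
class CrossAbsorptivityMatrix:
    """Effective absorbance coefficients K[w][d] = eps_d(lambda_w) * L.

    Rows are wavelengths, columns are dyes; entries have units of absorbance
    per (ug/mL).  The matrix must be square and well conditioned for the
    absorbance-space solve to be meaningful.
    """

    wavelengths: tuple
    dye_names: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n_w, n_d = m.shape
        require(n_w == len(self.wavelengths) and n_d == len(self.dye_names), "shape_mismatch")
        require(n_w == n_d, "shape_mismatch", "need one wavelength per dye")
        require(bool(np.all(m >= 0)), "negative_coefficient")
        require(bool(np.all(np.diag(m) > 0)), "degenerate_spectra", "zero on-peak absorptivity")
        require(
            float(np.linalg.cond(m)) <= CONDITION_LIMIT,
            "degenerate_spectra",
            f"condition number {np.linalg.cond(m):.3g} exceeds {CONDITION_LIMIT:.0e}",
        )

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def build_cross_matrix(
    dyes: Sequence[DyeDefinition],
    geometry: FlowCellGeometry,
    wavelengths: Sequence[float] = (WAVELENGTH_TZ_NM, WAVELENGTH_EG_NM),
    band_half_width: float = 0.0,
) -> CrossAbsorptivityMatrix:
    """Evaluate K[w][d] = eps_d(lambda_w) * L from the dye spectra.

    The default wavelength order (424, 631) pairs with the (TZ, EG) dye order
    so the diagonal holds the on-peak coefficients.
    """
    require(len(dyes) == len(wavelengths), "shape_mismatch", "need one wavelength per dye")
    k = np.array(
        [
            [
                dye.spectrum.absorptivity_at(wl, band_half_width) * geometry.path_length_mm
                for dye in dyes
            ]
            for wl in wavelengths
        ]
    )
    return CrossAbsorptivityMatrix(
        wavelengths=tuple(float(w) for w in wavelengths),
        dye_names=tuple(d.name for d in dyes),
        matrix=k,
    )


def concentration_noise_sd(
    matrix: CrossAbsorptivityMatrix, relative_intensity_noise_sd: float
) -> np.ndarray:
    """Per-dye concentration noise sd propagated from relative intensity noise.

    Multiplicative intensity noise of relative sd s gives absorbance noise
    ~ s/ln(10) per wavelength (independent of the intensity level), which the
    linear solve maps through the rows of K^-1.
    """
    sd_absorbance = relative_intensity_noise_sd / np.log(10.0)
    k_inv = np.linalg.inv(matrix.matrix)
    return sd_absorbance * np.sqrt(np.sum(k_inv**2, axis=1))


def recover_concentrations(
    intensities,
    matrix: CrossAbsorptivityMatrix,
    stocks: Mapping[str, float] | Sequence[float] | None = None,
    negative_tol_fraction: float = NEGATIVE_TOL_FRACTION,
    noise_sd: float = 0.0,
):
    """Solve the absorbance-space linear system for dye concentrations.

    Parameters
    ----------
    intensities
        Normalized intensities (I/I0) per wavelength, in the matrix's
        wavelength order; either a length-n vector or an (n, T) array of time
        series.
    stocks
        Stock concentrations per dye (mapping by dye name, or sequence in dye
        order).  When given, the negative-solution tolerance is
        ``negative_tol_fraction`` of each stock; mild negatives from noise are
        clipped to 0, larger ones raise ``inconsistent_intensities``.  Without
        stocks the tolerance is effectively zero.
    noise_sd
        Relative intensity noise sd of the detector, if known.  Adds a
        5-sigma concentration-noise allowance (see
        :func:`concentration_noise_sd`) to the negative floor so routine
        measurement noise near the blank is not misread as a model violation.

    Returns
    -------
    ndarray of concentrations (ug/mL), shape (n,) or (n, T).
    """
    i_arr = np.asarray(intensities, dtype=float)
    scalar_input = i_arr.ndim == 1
    if scalar_input:
        i_arr = i_arr[:, None]
    n = matrix.matrix.shape[0]
    require(i_arr.shape[0] == n, "shape_mismatch")
    require(bool(np.all(i_arr > 0)), "opaque_sample", "nonpositive normalized intensity")

    absorb = -np.log10(i_arr)  # may be slightly negative for I > 1 under noise
    conc = np.linalg.solve(matrix.matrix, absorb)

    if stocks is None:
        thresholds = np.zeros(n)
    elif isinstance(stocks, Mapping):
        thresholds = np.array(
            [negative_tol_fraction * float(stocks[name]) for name in matrix.dye_names]
        )
    else:
        thresholds = negative_tol_fraction * np.asarray(stocks, dtype=float)
    if noise_sd > 0:
        thresholds = thresholds + 5.0 * concentration_noise_sd(matrix, noise_sd)
    floor = -(thresholds[:, None] + 1e-12)
    if np.any(conc < floor):
        worst = float(np.min(conc))
        raise FlowSpecError(
            "inconsistent_intensities",
            f"recovered concentration {worst:.4g} ug/mL below tolerance",
        )
    conc = np.clip(conc, 0.0, None)
    return conc[:, 0] if scalar_input else conc
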