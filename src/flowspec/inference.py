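"""Derived quantities: gravimetric total flow, saline fraction by mass
balance, per-stream flow back-calculation, and steady-state statistics.

With the two dye concentrations measured optically and the total flow known
from the balance (Q_tot ~ d(mass)/dt / rho), conservation of volume for the
incompressible mixture closes the system: the carrier (saline) fraction is

    (C/C0)_sal = 1 - (C/C0)_EG - (C/C0)_TZ,

and each stream's flow is its normalized concentration times Q_tot.  Accuracy
and repeatability follow the instrument-validation conventions: accuracy is
the maximum absolute difference between the expected steady-state
concentration and the cross-trial mean; repeatability is the standard error of
the mean (SEM) across independent trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FlowSpecError, require

#: Default window (s) for differentiating the balance mass.
FLOW_WINDOW_S = 30.0

#: Tolerance on normalized fractions before flagging a mass-balance violation.
FRACTION_TOL = 0.01


@dataclass
class FlowEstimate:
    """Total flow rate estimated from the balance over a finite-difference window."""

    time_s: np.ndarray
    q_tot_ml_h: np.ndarray
    window_s: float
    nonmonotone_flagged: bool = False

    def __post_init__(self):
        require(self.window_s > 0, "invalid_window")


def total_flow_from_balance(
    time_s: np.ndarray,
    mass_g: np.ndarray,
    density_g_ml: float = 1.0,
    window_s: float = FLOW_WINDOW_S,
    smooth: bool = True,
    noise_tolerance_g: float = 1e-4,
) -> FlowEstimate:
    """Q_tot(t) = d(mass)/dt / rho via a centered difference over ``window_s``.

    The balance quantizes at 1e-5 g, so at low flows a multi-sample window is
    required for a usable derivative; an optional moving average of the same
    width smooths residual quantization steps.  Mass decreasing by more than
    ``noise_tolerance_g`` anywhere sets ``nonmonotone_flagged`` (warning, not
    error) since evaporation/bumps are operational, not fatal.
    """
    t = np.asarray(time_s, dtype=float)
    m = np.asarray(mass_g, dtype=float)
    require(t.shape == m.shape and t.ndim == 1, "shape_mismatch")
    require(density_g_ml > 0, "invalid_density")
    dt = float(np.median(np.diff(t)))
    half = max(1, int(round(window_s / (2.0 * dt))))
    require(t.size >= 2 * half + 1, "window_too_long", "fewer than 2 samples per window")

    flagged = bool(np.min(np.diff(m)) < -noise_tolerance_g)
    if flagged:
        warnings.warn("balance mass decreases beyond noise tolerance", stacklevel=2)

    centre = np.arange(half, t.size - half)
    q_ml_s = (m[centre + half] - m[centre - half]) / (
        (t[centre + half] - t[centre - half]) * density_g_ml
    )
    q = q_ml_s * 3600.0
    if smooth and q.size >= 3:
        q = (
            pd.Series(q)
            .rolling(window=2 * half + 1, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    q = np.clip(q, 0.0, None)
    return FlowEstimate(t[centre], q, window_s, flagged)


def saline_fraction(eg_fraction, tz_fraction, tol: float = FRACTION_TOL):
    """Carrier-stream normalized concentration by mass balance: 1 - EG - TZ.

    Inputs are the dyes' normalized concentrations C/C0 in [0, 1 + tol].  A
    result below ``-tol`` means the measured dye fractions exceed unity — the
    transient/dead-volume regime where flow inference is invalid — and raises
    ``mass_balance_violation``.
    """
    a = np.asarray(eg_fraction, dtype=float)
    b = np.asarray(tz_fraction, dtype=float)
    require(
        bool(np.all((a >= -tol) & (a <= 1 + tol) & (b >= -tol) & (b <= 1 + tol))),
        "fraction_out_of_range",
    )
    out = 1.0 - a - b
    if np.any(out < -tol):
        raise FlowSpecError(
            "mass_balance_violation",
            f"dye fractions sum to {float(np.max(a + b)):.3f} > 1",
        )
    return float(out) if out.ndim == 0 else out


def stream_flows(
    dye_fractions: Mapping[str, float], q_tot_ml_h, tol: float = FRACTION_TOL
) -> dict:
    """Back-calculate per-stream flows: Q_i = (C/C0)_i * Q_tot; saline is the
    remainder, so the streams sum to Q_tot exactly by construction."""
    names = list(dye_fractions)
    require(len(names) >= 1, "no_dyes")
    fracs = [np.asarray(dye_fractions[n], dtype=float) for n in names]
    q_tot = np.asarray(q_tot_ml_h, dtype=float)
    require(bool(np.all(q_tot > 0)), "no_flow", "Q_tot must be positive")
    total_dye = sum(fracs)
    # Validates the fraction ranges and the <= 1 closure.
    if len(names) == 2:
        saline_fraction(fracs[0], fracs[1], tol)
    else:
        require(bool(np.all(total_dye <= 1 + tol)), "mass_balance_violation")
    flows = {n: f * q_tot for n, f in zip(names, fracs)}
    flows["saline"] = q_tot - sum(flows[n] for n in names)
    return {
        k: (float(v) if np.asarray(v).ndim == 0 else v) for k, v in flows.items()
    }


@dataclass
class SteadyStateReport:
    """Accuracy and repeatability of one solute over one steady-state window.

    ``accuracy`` is max_t |expected - cross-trial mean(t)| (ug/mL);
    ``sem_max`` (repeatability) is the largest per-time SEM = sd/sqrt(n) over
    the window.  ``*_norm`` values are divided by the stock concentration.
    """

    solute: str
    expected: float
    window_s: tuple
    n_trials: int
    trial_means: tuple
    grand_mean: float
    sem_max: float
    accuracy: float
    expected_norm: float | None = None
    accuracy_norm: float | None = None

    def __post_init__(self):
        require(self.n_trials >= 2, "insufficient_trials", "SEM needs >= 2 trials")
        require(self.sem_max >= 0 and self.accuracy >= 0, "invalid_report")

    def to_dict(self) -> dict:
        return {
            "solute": self.solute,
            "expected_ug_ml": self.expected,
            "window_s": list(self.window_s),
            "n_trials": self.n_trials,
            "trial_means_ug_ml": list(self.trial_means),
            "grand_mean_ug_ml": self.grand_mean,
            "repeatability_sem_ug_ml": self.sem_max,
            "accuracy_ug_ml": self.accuracy,
            "expected_norm": self.expected_norm,
            "accuracy_norm": self.accuracy_norm,
        }


def steady_state_stats(
    trials: Sequence[np.ndarray],
    time_s: np.ndarray,
    window: tuple,
    expected: float,
    solute: str = "solute",
    stock_concentration: float | None = None,
) -> SteadyStateReport:
    """Cross-trial steady-state statistics over a time window.

    ``trials`` are per-trial concentration series on the common ``time_s``
    grid.  Per time point the cross-trial mean and SEM (sample sd / sqrt(n))
    are formed; the report carries the maxima over the window.
    """
    require(len(trials) >= 2, "insufficient_trials")
    t = np.asarray(time_s, dtype=float)
    t0, t1 = window
    require(t[0] - 1e-9 <= t0 < t1 <= t[-1] + 1e-9, "window_outside_series")
    stacked = np.vstack([np.asarray(tr, dtype=float) for tr in trials])
    require(stacked.shape[1] == t.size, "shape_mismatch")
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    require(int(np.count_nonzero(mask)) >= 1, "window_outside_series")
    win = stacked[:, mask]
    n = win.shape[0]
    mean_t = win.mean(axis=0)
    sem_t = win.std(axis=0, ddof=1) / np.sqrt(n)
    accuracy = float(np.max(np.abs(expected - mean_t)))
    report = SteadyStateReport(
        solute=solute,
        expected=float(expected),
        window_s=(float(t0), float(t1)),
        n_trials=n,
        trial_means=tuple(float(v) for v in win.mean(axis=1)),
        grand_mean=float(mean_t.mean()),
        sem_max=float(np.max(sem_t)),
        accuracy=accuracy,
    )
    if stock_concentration is not None:
        report.expected_norm = float(expected / stock_concentration)
        report.accuracy_norm = float(accuracy / stock_concentration)
    return report
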