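"""Packaged validation experiments and the end-to-end pipeline.

Three preset pump programmes exercise the system the way a bench validation
would:

* ``exp_a`` — constant flows (saline/EG/TZ = 1.5/0.5/1 mL/h) for 60 min;
  steady-state check.
* ``exp_b`` — 7/3/3 mL/h for 15 min, then saline and EG pumps swap to 3/7/3
  for 20 min; step response of the EG channel.
* ``exp_c`` — 7/3/3 mL/h for 15 min, then saline and TZ swap to 3/3/7;
  the mirror-image step on the TZ channel.

At steady state each dye's normalized concentration C/C0 at the cell equals
its stream's flow fraction Q_dye/Q_tot, which is what the pipeline must
recover end-to-end (simulate -> detect -> unmix -> report).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FlowSpecError, require
from .fluidics import (
    LineConfig,
    LineTimeSeries,
    PumpSchedule,
    SALINE,
    simulate_line,
)
from .inference import SteadyStateReport, steady_state_stats
from .spectra import (
    DetectorConfig,
    DyeDefinition,
    FlowCellGeometry,
    WAVELENGTH_EG_NM,
    WAVELENGTH_TZ_NM,
    default_dyes,
)
from .unmixing import build_cross_matrix, recover_concentrations

PRESET_NAMES = ("exp_a", "exp_b", "exp_c")

#: Default steady-state averaging window: the last 5 min of each phase.
STEADY_WINDOW_S = 300.0


def display_round(fraction: float) -> float:
    """Round a steady-state fraction the way the validation tables print them:
    three decimals below 0.2 (e.g. 0.167), two decimals otherwise."""
    return round(fraction, 3) if fraction < 0.2 else round(fraction, 2)


@dataclass(frozen=True)
class ExperimentPreset:
    """A named pump programme plus its expected steady-state fractions.

    ``expected_fractions`` holds one ``{dye: C/C0}`` mapping per phase; at
    construction each stated value is checked against Q_dye/Q_tot computed
    from the schedule (display-rounded), so a preset cannot drift out of sync
    with its own schedule.
    """

    name: str
    schedule: PumpSchedule
    duration_s: float
    phase_bounds_s: tuple  # ((t0, t1), ...)
    expected_fractions: tuple  # ({dye: fraction}, ...) per phase

    def __post_init__(self):
        require(len(self.phase_bounds_s) == len(self.expected_fractions), "phase_mismatch")
        for i, expected in enumerate(self.expected_fractions):
            for dye, frac in expected.items():
                computed = expected_steady_fraction(self.schedule, i, dye)
                require(
                    abs(computed - frac) < 1e-12,
                    "inconsistent_preset",
                    f"{self.name} phase {i} {dye}: stated {frac} != computed {computed}",
                )

    def scaled(self, factor: float) -> "ExperimentPreset":
        """Time-scale the programme (rates unchanged, so fractions unchanged)."""
        rows = []
        bounds = self.schedule.breakpoints_s
        for t0, t1 in zip(bounds[:-1], bounds[1:]):
            t_mid = 0.5 * (t0 + t1)
            rates = {r: float(q[0]) for r, q in self.schedule.flows_at(t_mid).items()}
            rows.append((t0 * factor, t1 * factor, rates))
        return dataclasses.replace(
            self,
            schedule=PumpSchedule.from_rate_table(rows),
            duration_s=self.duration_s * factor,
            phase_bounds_s=tuple(
                (t0 * factor, t1 * factor) for t0, t1 in self.phase_bounds_s
            ),
        )


def _phases(schedule: PumpSchedule) -> list[tuple]:
    b = schedule.breakpoints_s
    return list(zip(b[:-1], b[1:]))


def expected_steady_fraction(schedule: PumpSchedule, phase: int, solute: str) -> float:
    """Analytic steady-state C/C0 of a solute in a phase: Q_solute / Q_tot,
    display-rounded."""
    phases = _phases(schedule)
    require(0 <= phase < len(phases), "invalid_phase")
    t0, t1 = phases[phase]
    flows = {r: float(q[0]) for r, q in schedule.flows_at(0.5 * (t0 + t1)).items()}
    q_tot = sum(flows.values())
    require(q_tot > 0, "no_flow", "zero total flow in phase")
    return display_round(flows.get(solute, 0.0) / q_tot)


def preset(name: str) -> ExperimentPreset:
    """Load one of the packaged presets (``exp_a``, ``exp_b``, ``exp_c``)."""
    require(name in PRESET_NAMES, "unknown_preset", f"unknown preset {name!r}")
    if name == "exp_a":
        rows = [(0.0, 3600.0, {SALINE: 1.5, "EG": 0.5, "TZ": 1.0})]
        bounds = ((0.0, 3600.0),)
        expected = ({"EG": 0.167, "TZ": 0.33},)
    elif name == "exp_b":
        rows = [
            (0.0, 900.0, {SALINE: 7.0, "EG": 3.0, "TZ": 3.0}),
            (900.0, 2100.0, {SALINE: 3.0, "EG": 7.0, "TZ": 3.0}),
        ]
        bounds = ((0.0, 900.0), (900.0, 2100.0))
        expected = ({"EG": 0.23, "TZ": 0.23}, {"EG": 0.54, "TZ": 0.23})
    else:
        rows = [
            (0.0, 900.0, {SALINE: 7.0, "EG": 3.0, "TZ": 3.0}),
            (900.0, 2100.0, {SALINE: 3.0, "EG": 3.0, "TZ": 7.0}),
        ]
        bounds = ((0.0, 900.0), (900.0, 2100.0))
        expected = ({"EG": 0.23, "TZ": 0.23}, {"EG": 0.23, "TZ": 0.54})
    schedule = PumpSchedule.from_rate_table(rows)
    return ExperimentPreset(name, schedule, rows[-1][1], bounds, expected)


@dataclass
class ExperimentResult:
    """Everything `run_experiment` produces for one preset."""

    preset: ExperimentPreset
    line_series: list  # LineTimeSeries per trial
    concentrations: list  # DataFrame per trial
    reports: dict  # (phase index, dye name) -> SteadyStateReport

    def report_dict(self) -> dict:
        return {
            f"phase{p}_{dye}": rep.to_dict() for (p, dye), rep in self.reports.items()
        }


def unmix_trial(
    series: LineTimeSeries,
    dyes: Sequence[DyeDefinition],
    geometry: FlowCellGeometry,
    wavelengths: Sequence[float] = (WAVELENGTH_TZ_NM, WAVELENGTH_EG_NM),
    band_half_width: float = 0.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Recover dye concentration time series from one trial's intensities.

    ``noise_sd`` is the detector's relative intensity noise, used to widen the
    negative-concentration floor by its 5-sigma propagated effect.
    """
    k = build_cross_matrix(dyes, geometry, wavelengths, band_half_width)
    i_stack = np.vstack([series.intensities[float(wl)] for wl in wavelengths])
    stocks = {d.name: d.stock_concentration for d in dyes}
    conc = recover_concentrations(i_stack, k, stocks=stocks, noise_sd=noise_sd)
    out = {"time_s": series.time_s}
    for j, dye in enumerate(dyes):
        out[f"C_{dye.name.lower()}_ug_ml"] = conc[j]
        out[f"C_{dye.name.lower()}_norm"] = conc[j] / dye.stock_concentration
    return pd.DataFrame(out)


def run_experiment(
    preset_or_name,
    dyes: Sequence[DyeDefinition] | None = None,
    geometry: FlowCellGeometry | None = None,
    line: LineConfig | None = None,
    detector: DetectorConfig | None = None,
    n_trials: int = 3,
    seed: int = 0,
    fast: bool = False,
    steady_window_s: float = STEADY_WINDOW_S,
    settling_margin_s: float = 0.0,
    out_dir=None,
    balance_noise_sd: float = 1e-5,
    balance_resolution: float = 1e-5,
) -> ExperimentResult:
    """Run the full pipeline for a preset: simulate -> unmix -> report.

    ``fast=True`` scales all times and the dead volume down 10x, preserving
    the dimensionless lag V/(Q * phase duration), so the programme completes
    in seconds of simulated time with the same convergence behaviour; the
    steady window scales with it.  Deterministic under a fixed ``seed``.
    """
    pre = preset(preset_or_name) if isinstance(preset_or_name, str) else preset_or_name
    if dyes is None:
        tz, eg = default_dyes()
        dyes = (tz, eg)
    geometry = geometry or FlowCellGeometry()
    line = line or LineConfig()
    detector = detector or DetectorConfig()
    if fast:
        pre = pre.scaled(0.1)
        line = dataclasses.replace(line, dead_volume_ml=line.dead_volume_ml * 0.1)
        steady_window_s *= 0.1
        settling_margin_s *= 0.1

    series = simulate_line(
        pre.schedule,
        line,
        dyes,
        geometry,
        detector,
        n_trials=n_trials,
        seed=seed,
        balance_noise_sd=balance_noise_sd,
        balance_resolution=balance_resolution,
    )
    conc_frames = [
        unmix_trial(tr, dyes, geometry, noise_sd=detector.relative_noise_sd)
        for tr in series
    ]

    # Cross-trial statistics need >= 2 trials; a single-trial run still
    # returns the simulated series and concentrations, just no reports.
    reports: dict = {}
    time_s = series[0].time_s
    for p, (t0, t1) in enumerate(pre.phase_bounds_s) if n_trials >= 2 else ():
        w0 = max(t0 + settling_margin_s, t1 - steady_window_s)
        require(w0 < t1, "window_outside_series", "steady window empty after settling margin")
        for dye in dyes:
            frac = pre.expected_fractions[p].get(dye.name)
            if frac is None:
                continue
            expected = frac * dye.stock_concentration
            trials = [df[f"C_{dye.name.lower()}_ug_ml"].to_numpy() for df in conc_frames]
            reports[(p, dye.name)] = steady_state_stats(
                trials,
                time_s,
                (w0, t1),
                expected,
                solute=dye.name,
                stock_concentration=dye.stock_concentration,
            )

    result = ExperimentResult(pre, series, conc_frames, reports)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (tr, conc) in enumerate(zip(series, conc_frames), start=1):
            tr.to_frame().to_csv(out / f"{pre.name}_trial{i}_line.csv", index=False)
            conc.to_csv(out / f"{pre.name}_trial{i}_concentration.csv", index=False)
        with open(out / f"{pre.name}_report.json", "w") as fh:
            json.dump(result.report_dict(), fh, indent=2)
    return result
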