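"""Digital twin of the infusion line.

Models the multi-pump assembly feeding a stopcock manifold, the dead volume
between the mixing junction and the Z-flow cell, and the analytical balance
collecting the outflow.

* Pump schedules are piecewise-constant flow rates per pump (mL/h).
* At the junction, solute concentrations mix instantaneously by flow fraction:
  C_i = Q_i * C0_i / Q_tot, so the steady-state normalized concentration
  C_i/C0_i equals the stream's flow fraction.
* Transport through the dead volume uses a tanks-in-series chain (n well-mixed
  compartments; n = 1 is a single mixing chamber, "plug" is the pure-delay
  limit), reproducing the lag with which concentration changes reach the cell.
* The balance integrates rho * Q_tot; its readout adds Gaussian noise and
  quantizes at the instrument resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FlowSpecError, require
from .spectra import (
    DetectorConfig,
    DyeDefinition,
    FlowCellGeometry,
    WAVELENGTH_EG_NM,
    WAVELENGTH_TZ_NM,
)
from .unmixing import build_cross_matrix

SALINE = "saline"

#: Analytical balance defaults: 0.01 mg resolution, noise of the same order.
BALANCE_RESOLUTION_G = 1e-5
BALANCE_NOISE_SD_G = 1e-5


@dataclass(frozen=True)
class PumpSegment:
    t_start_s: float
    t_end_s: float
    rate_ml_h: float

    def __post_init__(self):
        require(self.t_end_s > self.t_start_s, "invalid_segment")
        require(self.rate_ml_h >= 0, "negative_flow")


@dataclass(frozen=True)
class Pump:
    """One syringe pump: a role (``"saline"`` or a dye name) plus its segments.

    Segments must be contiguous and non-overlapping, starting at t = 0.
    """

    role: str
    segments: tuple

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        require(len(segs) >= 1, "invalid_segment")
        require(abs(segs[0].t_start_s) < 1e-9, "invalid_segment", "first segment must start at 0")
        for prev, nxt in zip(segs, segs[1:]):
            require(
                abs(nxt.t_start_s - prev.t_end_s) < 1e-9,
                "invalid_segment",
                "segments must be contiguous and non-overlapping",
            )

    @property
    def duration_s(self) -> float:
        return self.segments[-1].t_end_s

    def rates_at(self, times: np.ndarray) -> np.ndarray:
        """Piecewise-constant rate (mL/h), right-continuous at switch times."""
        t = np.asarray(times, dtype=float)
        starts = np.array([s.t_start_s for s in self.segments])
        rates = np.array([s.rate_ml_h for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(rates) - 1)
        out = rates[idx]
        out = np.where(t > self.duration_s + 1e-9, 0.0, out)
        return np.where(t < -1e-9, 0.0, out)


@dataclass(frozen=True)
class PumpSchedule:
    pumps: tuple

    def __post_init__(self):
        pumps = tuple(self.pumps)
        object.__setattr__(self, "pumps", pumps)
        roles = [p.role for p in pumps]
        require(len(set(roles)) == len(roles), "duplicate_role")

    @property
    def roles(self) -> tuple:
        return tuple(p.role for p in self.pumps)

    @property
    def duration_s(self) -> float:
        return max(p.duration_s for p in self.pumps)

    @property
    def breakpoints_s(self) -> np.ndarray:
        """Sorted times where any pump rate changes (phase boundaries incl. 0 and end)."""
        pts = {0.0, self.duration_s}
        for p in self.pumps:
            for s in p.segments:
                pts.update((s.t_start_s, s.t_end_s))
        return np.array(sorted(pts))

    def flows_at(self, times) -> dict:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        return {p.role: p.rates_at(t) for p in self.pumps}

    @classmethod
    def from_rate_table(cls, rows: Sequence[tuple]) -> "PumpSchedule":
        """Build from ``(t_start_s, t_end_s, {role: rate_ml_h})`` rows."""
        roles: dict[str, list[PumpSegment]] = {}
        for t0, t1, rates in rows:
            for role, rate in rates.items():
                roles.setdefault(role, []).append(PumpSegment(t0, t1, rate))
        return cls(tuple(Pump(role, tuple(segs)) for role, segs in roles.items()))


@dataclass(frozen=True)
class LineConfig:
    """Dead volume and transport model of the manifold-to-cell pathway.

    ``transport`` is ``"tanks"`` (tanks-in-series, ``n_tanks`` compartments) or
    ``"plug"`` (pure delay of one dead volume).  Density is fixed near 1 g/mL
    for dilute aqueous dye/saline.
    """

    dead_volume_ml: float = 1.0
    n_tanks: int = 5
    transport: str = "tanks"
    fluid_density_g_ml: float = 1.0

    def __post_init__(self):
        require(self.dead_volume_ml > 0, "invalid_dead_volume")
        require(self.n_tanks >= 1, "invalid_n_tanks")
        require(self.transport in ("tanks", "plug"), "unknown_transport")
        require(self.fluid_density_g_ml > 0, "invalid_density")


@dataclass
class LineTimeSeries:
    """One simulated trial: flows, concentrations at the cell, optics, balance."""

    time_s: np.ndarray
    flows_ml_h: dict  # role -> array
    q_tot_ml_h: np.ndarray
    conc_true: dict  # dye name -> array, ug/mL at the flow cell
    intensities: dict  # wavelength (float) -> measured I/I0 array
    mass_true_g: np.ndarray
    mass_g: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time_s}
        for role, q in self.flows_ml_h.items():
            short = "sal" if role == SALINE else role.lower()
            cols[f"Q_{short}"] = q
        for name, c in self.conc_true.items():
            cols[f"C_{name.lower()}_true"] = c
        for wl, i in sorted(self.intensities.items()):
            cols[f"I{int(round(wl))}"] = i
        cols["mass_g"] = self.mass_g
        return pd.DataFrame(cols)


def junction_concentration(
    flows: Mapping[str, float], stocks: Mapping[str, float]
) -> dict:
    """Instantaneous mixed concentration of each solute at the manifold.

    C_i = Q_i * C0_i / Q_tot.  ``flows`` maps every pump role to its rate;
    ``stocks`` maps solute roles to syringe concentrations (saline carries no
    solute and needs no entry).
    """
    q_tot = float(sum(flows.values()))
    require(q_tot > 0, "no_flow", "all pump flows are zero")
    for q in flows.values():
        require(q >= 0, "negative_flow")
    return {
        solute: flows.get(solute, 0.0) * c0 / q_tot for solute, c0 in stocks.items()
    }


def _advect_tanks(c_in: np.ndarray, q_ml_s: np.ndarray, dt: float, volume_ml: float, n_tanks: int):
    """Explicit update of an n-tank mixing chain, initially solute-free.

    c_in: (T, n_solutes) inlet concentrations; returns outlet of the last tank.
    Raises ``unstable_timestep`` if dt exceeds half the smallest tank residence
    time while flow is on.
    """
    tank_vol = volume_ml / n_tanks
    alpha = q_ml_s * dt / tank_vol  # fraction of a tank exchanged per step
    if np.any(alpha > 0.5 + 1e-12):
        raise FlowSpecError(
            "unstable_timestep",
            "sampling interval exceeds half the tank residence time; "
            "reduce the interval or coarsen n_tanks",
        )
    n_steps, n_sol = c_in.shape
    state = np.zeros((n_tanks, n_sol))
    out = np.zeros_like(c_in)
    for i in range(n_steps):
        out[i] = state[-1]
        a = alpha[i]
        upstream = np.vstack([c_in[i][None, :], state[:-1]])
        state = state + a * (upstream - state)
    return out


def _advect_plug(c_in: np.ndarray, cum_volume_ml: np.ndarray, dead_volume_ml: float):
    """Pure-delay transport: the cell sees the fluid that entered one dead
    volume of pumped throughput earlier; before that, saline (zero solute)."""
    target = cum_volume_ml - dead_volume_ml
    idx = np.searchsorted(cum_volume_ml, target, side="right") - 1
    out = np.zeros_like(c_in)
    filled = idx >= 0
    out[filled] = c_in[idx[filled]]
    return out


def balance_readout(
    mass_true_g: np.ndarray,
    balance_noise_sd: float = BALANCE_NOISE_SD_G,
    resolution: float = BALANCE_RESOLUTION_G,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Analytical-balance measurement: additive Gaussian noise, then
    quantization at the instrument resolution (round-half-even)."""
    m = np.asarray(mass_true_g, dtype=float)
    require(bool(np.all(np.diff(m) >= -1e-12)), "nonmonotone_mass")
    require(balance_noise_sd >= 0 and resolution > 0, "invalid_balance_config")
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = m + balance_noise_sd * rng.standard_normal(m.shape) if balance_noise_sd > 0 else m
    return np.round(noisy / resolution) * resolution


def simulate_line(
    schedule: PumpSchedule,
    line: LineConfig,
    dyes: Sequence[DyeDefinition],
    geometry: FlowCellGeometry,
    detector: DetectorConfig,
    n_trials: int = 1,
    seed: int = 0,
    wavelengths: Sequence[float] = (WAVELENGTH_TZ_NM, WAVELENGTH_EG_NM),
    balance_noise_sd: float = BALANCE_NOISE_SD_G,
    balance_resolution: float = BALANCE_RESOLUTION_G,
    band_half_width: float = 0.0,
) -> list[LineTimeSeries]:
    """Simulate the full line for ``n_trials`` independent trials.

    Per trial: junction mixing -> dead-volume transport -> Beer-Lambert
    transmission at the measurement wavelengths -> multiplicative detector
    noise -> balance readout.  The line starts filled with saline (zero dye)
    and pumps start at t = 0.  Trial seeds are spawned deterministically from
    ``seed``; trial-to-trial variation is measurement noise only.
    """
    require(n_trials >= 1, "invalid_n_trials")
    dt = detector.measurement_interval
    duration = schedule.duration_s
    n_steps = int(round(duration / dt)) + 1
    time_s = dt * np.arange(n_steps)

    flows = schedule.flows_at(time_s)
    q_tot_ml_h = np.sum(list(flows.values()), axis=0)
    q_tot_ml_s = q_tot_ml_h / 3600.0

    # Junction concentrations per solute (zero where no flow at all).
    stocks = {d.name: d.stock_concentration for d in dyes}
    c_in = np.zeros((n_steps, len(dyes)))
    on = q_tot_ml_h > 0
    for j, dye in enumerate(dyes):
        q_dye = flows.get(dye.name, np.zeros(n_steps))
        c_in[on, j] = q_dye[on] * dye.stock_concentration / q_tot_ml_h[on]

    # Exact cumulative pumped volume for a piecewise-constant, grid-aligned
    # rate (left-Riemann sum is exact here).
    cum_volume_ml = np.concatenate([[0.0], np.cumsum(q_tot_ml_s[:-1] * dt)])

    if line.transport == "plug":
        c_cell = _advect_plug(c_in, cum_volume_ml, line.dead_volume_ml)
    else:
        c_cell = _advect_tanks(c_in, q_tot_ml_s, dt, line.dead_volume_ml, line.n_tanks)

    # Beer-Lambert at the measurement wavelengths (linear in concentrations).
    k = build_cross_matrix(dyes, geometry, wavelengths, band_half_width).matrix
    absorb = c_cell @ k.T  # (T, n_wavelengths)
    i_true = np.power(10.0, -absorb)

    mass_true = line.fluid_density_g_ml * cum_volume_ml

    master = np.random.SeedSequence(seed)
    trials = []
    for child in master.spawn(n_trials):
        rng = np.random.default_rng(child)
        if detector.relative_noise_sd > 0:
            i_meas = i_true * (
                1.0 + detector.relative_noise_sd * rng.standard_normal(i_true.shape)
            )
            i_meas = np.clip(i_meas, np.finfo(float).tiny, None)
        else:
            i_meas = i_true.copy()
        mass_meas = balance_readout(
            mass_true, balance_noise_sd, balance_resolution, rng=rng
        )
        trials.append(
            LineTimeSeries(
                time_s=time_s,
                flows_ml_h={role: q.copy() for role, q in flows.items()},
                q_tot_ml_h=q_tot_ml_h.copy(),
                conc_true={d.name: c_cell[:, j].copy() for j, d in enumerate(dyes)},
                intensities={
                    float(wl): i_meas[:, w] for w, wl in enumerate(wavelengths)
                },
                mass_true_g=mass_true.copy(),
                mass_g=mass_meas,
            )
        )
    return trials
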