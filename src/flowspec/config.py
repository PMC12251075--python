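"""Experiment configuration files (JSON/YAML).

Schema::

    pumps:
      - role: saline            # or a dye name
        segments:
          - {t_start_s: 0, t_end_s: 900, rate_ml_h: 7.0}
    line: {dead_volume_ml: 1.0, n_tanks: 5, transport: tanks, fluid_density_g_ml: 1.0}
    geometry: {path_length_mm: 10.0, internal_volume_ul: 26.0}
    detector: {relative_noise_sd: 0.005, measurement_interval: 1.0, rng_seed: 0}
    dyes:
      - {name: TZ, stock_concentration_ug_ml: 100.0, peak_nm: 424.0,
         width_nm: 30.0, peak_absorptivity: 0.0012,
         secondary_bands: [[631.0, 45.0, 3.6e-05]]}

All sections are optional; omitted ones fall back to package defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .fluidics import LineConfig, Pump, PumpSchedule, PumpSegment
from .spectra import (
    DetectorConfig,
    DyeDefinition,
    FlowCellGeometry,
    default_dyes,
    default_wavelength_grid,
    make_dye_spectrum,
)


def _load_raw(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def load_experiment_config(path) -> dict:
    """Parse a config file into domain objects.

    Returns a dict with keys ``schedule`` (may be None), ``line``,
    ``geometry``, ``detector`` and ``dyes``.
    """
    raw = _load_raw(path) or {}
    schedule = None
    if "pumps" in raw:
        pumps = tuple(
            Pump(
                role=p["role"],
                segments=tuple(
                    PumpSegment(
                        float(s["t_start_s"]), float(s["t_end_s"]), float(s["rate_ml_h"])
                    )
                    for s in p["segments"]
                ),
            )
            for p in raw["pumps"]
        )
        schedule = PumpSchedule(pumps)
    line = LineConfig(**raw.get("line", {}))
    geometry = FlowCellGeometry(**raw.get("geometry", {}))
    det_raw = dict(raw.get("detector", {}))
    detector = DetectorConfig(wavelengths=default_wavelength_grid(), **det_raw)
    if "dyes" in raw:
        dyes = tuple(
            DyeDefinition(
                name=d["name"],
                spectrum=make_dye_spectrum(
                    float(d["peak_nm"]),
                    float(d["width_nm"]),
                    float(d["peak_absorptivity"]),
                    dye_name=d["name"],
                    secondary_bands=[tuple(map(float, b)) for b in d.get("secondary_bands", [])],
                ),
                stock_concentration=float(d["stock_concentration_ug_ml"]),
            )
            for d in raw["dyes"]
        )
    else:
        dyes = default_dyes()
    return {
        "schedule": schedule,
        "line": line,
        "geometry": geometry,
        "detector": detector,
        "dyes": dyes,
    }
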