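"""Recompute the model's headline tables from the packaged constants.

Each function rebuilds its inputs from scratch -- stems from the registry
geometry, discharge constants from the calibration oracle -- and returns
a DataFrame shaped like the corresponding published table, so computed
and published values can be compared column by column.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import registry
from .discharge import CalibratedDischargeConstants, calibrate_constants
from .energetics import (
    build_complex,
    calibrate_liana_resistances,
    heating,
    heating_density,
    max_power,
    strike_complex,
)
from .geometry import build_tapered_stem, stem_resistance, stem_volume

__all__ = ["default_constants", "species_table", "size_scan_table", "liana_protection_table"]


def default_constants() -> CalibratedDischargeConstants:
    """Discharge constants calibrated from the packaged reference table."""
    return calibrate_constants(registry.load_reference_energetics())


def species_table(constants: CalibratedDischargeConstants | None = None) -> pd.DataFrame:
    """Resistance, maximum power, and heating (D1-D3) per species, 20 m tree."""
    constants = constants or default_constants()
    stem = build_tapered_stem(
        registry.REFERENCE_HEIGHT_M,
        registry.REFERENCE_BASAL_DIAMETER_M,
        registry.TOP_DIAMETER_M,
        registry.SEGMENT_LENGTH_M,
    )
    rows = []
    for name, model in registry.species_models().items():
        r = stem_resistance(stem, model)
        rows.append(
            {
                "name": name,
                "region": model.region,
                "resistance_kohm": r / 1e3,
                "max_power_tw": max_power(r, constants.effective_peak) / 1e12,
                "heating_d1_gj": heating(r, constants.action_integral_d1) / 1e9,
                "heating_d2_gj": heating(r, constants.action_integral_d2) / 1e9,
                "heating_d3_gj": heating(r, constants.action_integral_d3) / 1e9,
            }
        )
    return pd.DataFrame(rows)


def size_scan_table(constants: CalibratedDischargeConstants | None = None) -> pd.DataFrame:
    """The intraspecific size scan: seven heights for two focal species."""
    constants = constants or default_constants()
    models = registry.species_models()
    rows = []
    for _, row in registry.load_size_scan_reference().iterrows():
        model = models[row["species"]]
        stem = build_tapered_stem(
            float(row["height_m"]),
            float(row["basal_diameter_cm"]) / 100.0,
            registry.TOP_DIAMETER_M,
            registry.SEGMENT_LENGTH_M,
        )
        r = stem_resistance(stem, model)
        v = stem_volume(stem)
        h = heating(r, constants.action_integral_d1)
        rows.append(
            {
                "species": row["species"],
                "height_m": float(row["height_m"]),
                "basal_diameter_cm": float(row["basal_diameter_cm"]),
                "resistance_kohm": r / 1e3,
                "volume_m3": v,
                "max_power_tw": max_power(r, constants.effective_peak) / 1e12,
                "heating_gj": h / 1e9,
                "heat_density_kj_cm3": heating_density(h, v) / 1e3,
            }
        )
    return pd.DataFrame(rows)


def liana_protection_table(
    constants: CalibratedDischargeConstants | None = None,
    liana_calibration: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Heating, power, and percent diverted with 0, 1, and 3 lianas."""
    constants = constants or default_constants()
    if liana_calibration is None:
        liana_calibration = calibrate_liana_resistances()
    rows = []
    for name, model in registry.species_models().items():
        row: dict = {"name": name, "region": model.region}
        for n in (0, 1, 3):
            rep = strike_complex(
                build_complex(model, n_lianas=n),
                constants,
                discharge="D1",
                liana_calibration=liana_calibration,
            )
            row[f"heating_{n}l_gj"] = rep.tree.heating / 1e9
            row[f"power_{n}l_tw"] = rep.tree.max_power / 1e12
            if n:
                row[f"diverted_{n}l_pct"] = rep.percent_diverted
        rows.append(row)
    return pd.DataFrame(rows)
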