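"""Packaged species constants and published model-output reference tables.

The package ships four small CSVs:

* ``species_registry.csv`` -- the eleven tree species' fitted
  ln-resistivity vs cube-root-diameter coefficients (slope m, intercept b)
  with region and growth form.
* ``reference_energetics.csv`` -- the published model outputs for the
  standard 20 m reference tree of each species (resistance, maximum power,
  and heating under the three canonical discharges).  These are used to
  calibrate the discharge constants and as cross-validation targets.
* ``liana_reference.csv`` -- published heating/power of each reference
  tree with 0, 1, or 3 lianas, used to calibrate the regional liana
  resistances.
* ``size_scan_reference.csv`` -- the published size scan (seven heights
  each for two species) with the height/basal-diameter pairs that serve
  as direct geometric inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import InvalidInputError
from .resistivity import SpeciesResistivityModel

# Reference geometry shared by every interspecific comparison: a 20 m
# stem tapering from 27.3 cm at the base to the fixed 1 cm top.
REFERENCE_HEIGHT_M = 20.0
REFERENCE_BASAL_DIAMETER_M = 0.273
TOP_DIAMETER_M = 0.01
SEGMENT_LENGTH_M = 0.01

__all__ = [
    "load_species_registry",
    "species_models",
    "get_species_model",
    "load_reference_energetics",
    "load_liana_reference",
    "load_size_scan_reference",
    "REFERENCE_HEIGHT_M",
    "REFERENCE_BASAL_DIAMETER_M",
    "TOP_DIAMETER_M",
    "SEGMENT_LENGTH_M",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("treestrike.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_species_registry() -> pd.DataFrame:
    """The packaged species table: name, region, growth_form, slope, intercept."""
    return _read("species_registry.csv")


def species_models() -> dict[str, SpeciesResistivityModel]:
    """All packaged species as :class:`SpeciesResistivityModel`, keyed by name."""
    frame = load_species_registry()
    return {
        row["name"]: SpeciesResistivityModel(
            name=row["name"],
            region=row["region"],
            growth_form=row["growth_form"],
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
        )
        for _, row in frame.iterrows()
    }


def get_species_model(name: str) -> SpeciesResistivityModel:
    models = species_models()
    try:
        return models[name]
    except KeyError:
        known = ", ".join(sorted(models))
        raise InvalidInputError(f"unknown species {name!r}; packaged species: {known}")


def load_reference_energetics() -> pd.DataFrame:
    """Published per-species resistance/power/heating for the 20 m reference tree."""
    return _read("reference_energetics.csv")


def load_liana_reference() -> pd.DataFrame:
    """Published 0/1/3-liana heating and power for the 20 m reference trees."""
    return _read("liana_reference.csv")


def load_size_scan_reference() -> pd.DataFrame:
    """Published size scan: heights, basal diameters, and model outputs."""
    return _read("size_scan_reference.csv")
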