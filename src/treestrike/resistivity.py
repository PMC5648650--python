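"""Plant electrical resistivity: measurements, species models, and fits.

Resistivity is the intrinsic opposition of stem tissue to longitudinal
current flow.  A field measurement of whole-stem resistance ``R`` (ohms)
over an electrode span ``L`` (m) on a stem of diameter ``d`` (m) converts
to resistivity via

    p = R * A / L,        A = pi * d**2 / 4   (ohm metres)

using the full circular cross-section: the conversion makes no assumption
about which tissues inside the stem carry the current.

Across species, resistivity rises with stem diameter.  The within-species
relationship is well described by a log-linear model on the cube root of
diameter,

    ln p = m * d**(1/3) + b

with ``d`` in metres and ``p`` in ohm metres.  ``SpeciesResistivityModel``
stores the fitted (m, b) pair; :func:`fit_resistivity_model` estimates it
from measurement tables by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, InvalidInputError

DEFAULT_ELECTRODE_SPAN_M = 0.30

__all__ = [
    "ResistivityMeasurement",
    "SpeciesResistivityModel",
    "ResistivityFit",
    "MoistureFit",
    "resistivity_from_measurement",
    "resistivity_at_diameter",
    "fit_resistivity_model",
    "fit_moisture_model",
    "measurements_from_frame",
    "measurements_to_frame",
]


@dataclass(frozen=True)
class ResistivityMeasurement:
    """One in situ resistance reading on a stem.

    Parameters
    ----------
    diameter : float
        Stem diameter at the electrode midpoint, metres.
    resistance : float
        Measured resistance, ohms.
    electrode_span : float
        Longitudinal separation of the two electrodes, metres.
    temperature : float, optional
        Air temperature at measurement time, deg C.  Carried as metadata
        only; it never enters any computation.
    moisture_fraction : float, optional
        Stem moisture content as a fraction of fresh mass, in [0, 1].
    """

    diameter: float
    resistance: float
    electrode_span: float = DEFAULT_ELECTRODE_SPAN_M
    temperature: float | None = None
    moisture_fraction: float | None = None

    def __post_init__(self) -> None:
        for name in ("diameter", "resistance", "electrode_span"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidInputError(f"{name} must be positive, got {value!r}")
        if self.moisture_fraction is not None and not (
            0.0 <= self.moisture_fraction <= 1.0
        ):
            raise InvalidInputError(
                f"moisture_fraction must lie in [0, 1], got {self.moisture_fraction!r}"
            )

    @property
    def cross_section(self) -> float:
        """Full circular cross-sectional area, m^2."""
        return np.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class SpeciesResistivityModel:
    """A species' fitted ln-resistivity vs cube-root-diameter line.

    ``slope`` (m) has units ln(ohm m) per m^(1/3); ``intercept`` (b) is in
    ln(ohm m).  Diameter is in metres throughout.
    """

    name: str
    region: str
    growth_form: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.region not in ("tropical", "temperate"):
            raise InvalidInputError(f"unknown region {self.region!r}")
        if self.growth_form not in ("tree", "liana"):
            raise InvalidInputError(f"unknown growth_form {self.growth_form!r}")

    def __call__(self, diameter) -> np.ndarray | float:
        return resistivity_at_diameter(self, diameter)


@dataclass(frozen=True)
class ResistivityFit:
    """A fitted model plus OLS diagnostics."""

    model: SpeciesResistivityModel
    r_squared: float
    residual_sd: float
    n: int
    slope_se: float
    intercept_se: float


@dataclass(frozen=True)
class MoistureFit:
    """Linear model of ln-resistivity on moisture fraction."""

    slope: float
    intercept: float
    r_squared: float
    r_squared_with_species: float | None
    n: int
    slope_se: float


def resistivity_from_measurement(meas: ResistivityMeasurement) -> float:
    """Convert a resistance measurement to resistivity, ohm metres."""
    return meas.resistance * meas.cross_section / meas.electrode_span


def resistivity_at_diameter(model: SpeciesResistivityModel, diameter):
    """Evaluate a species model at one or more diameters (metres) -> ohm m."""
    d = np.asarray(diameter, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise InvalidInputError(f"diameter must be positive, got {diameter!r}")
    out = np.exp(model.slope * np.cbrt(d) + model.intercept)
    return float(out) if np.isscalar(diameter) or out.ndim == 0 else out


def _check_fittable(x: np.ndarray, what: str) -> None:
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 measurements to fit, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise InsufficientDataError(f"all {what} values are identical; design is degenerate")


def fit_resistivity_model(
    measurements: Sequence[ResistivityMeasurement],
    name: str = "fitted",
    region: str = "tropical",
    growth_form: str = "tree",
) -> ResistivityFit:
    """OLS fit of ln(resistivity) on cube-root diameter.

    Returns the fitted :class:`SpeciesResistivityModel` together with the
    coefficient of determination, residual standard deviation, and
    coefficient standard errors.
    """
    d = np.array([m.diameter for m in measurements], dtype=float)
    _check_fittable(d, "diameter")
    y = np.log([resistivity_from_measurement(m) for m in measurements])
    X = sm.add_constant(np.cbrt(d))
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    model = SpeciesResistivityModel(name, region, growth_form, float(slope), float(intercept))
    resid_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return ResistivityFit(
        model=model,
        r_squared=float(res.rsquared),
        residual_sd=resid_sd,
        n=int(res.nobs),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
    )


def fit_moisture_model(
    measurements: Sequence[ResistivityMeasurement],
    species: Sequence[str] | None = None,
) -> MoistureFit:
    """OLS fit of ln(resistivity) on stem moisture fraction.

    When ``species`` labels are supplied (one per measurement), a second
    model with species indicator variables is fitted and its R-squared is
    reported alongside the species-free one, so the two can be compared to
    judge whether moisture predicts resistivity independently of identity.
    """
    kept = [m for m in measurements if m.moisture_fraction is not None]
    if species is not None:
        if len(species) != len(measurements):
            raise InvalidInputError("species labels must match measurements one-to-one")
        labels = [s for m, s in zip(measurements, species) if m.moisture_fraction is not None]
    else:
        labels = None
    w = np.array([m.moisture_fraction for m in kept], dtype=float)
    _check_fittable(w, "moisture_fraction")
    y = np.log([resistivity_from_measurement(m) for m in kept])
    X = sm.add_constant(w)
    res = sm.OLS(y, X).fit()
    r2_species = None
    if labels is not None and len(set(labels)) > 1:
        dummies = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
        X2 = sm.add_constant(np.column_stack([w, dummies.to_numpy()]))
        r2_species = float(sm.OLS(y, X2).fit().rsquared)
    return MoistureFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        r_squared_with_species=r2_species,
        n=int(res.nobs),
        slope_se=float(res.bse[1]),
    )


# -- measurement-table CSV dialect -------------------------------------------
#
# species,diameter_m,resistance_ohm,span_m,temperature_c,moisture_fraction
# (the last two columns are optional)

def measurements_from_frame(frame: pd.DataFrame) -> list[ResistivityMeasurement]:
    out = []
    for _, row in frame.iterrows():
        out.append(
            ResistivityMeasurement(
                diameter=float(row["diameter_m"]),
                resistance=float(row["resistance_ohm"]),
                electrode_span=float(row.get("span_m", DEFAULT_ELECTRODE_SPAN_M)),
                temperature=(
                    float(row["temperature_c"])
                    if "temperature_c" in row and pd.notna(row["temperature_c"])
                    else None
                ),
                moisture_fraction=(
                    float(row["moisture_fraction"])
                    if "moisture_fraction" in row and pd.notna(row["moisture_fraction"])
                    else None
                ),
            )
        )
    return out


def measurements_to_frame(
    measurements: Iterable[ResistivityMeasurement], species: str = ""
) -> pd.DataFrame:
    rows = [
        {
            "species": species,
            "diameter_m": m.diameter,
            "resistance_ohm": m.resistance,
            "span_m": m.electrode_span,
            "temperature_c": m.temperature,
            "moisture_fraction": m.moisture_fraction,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)
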