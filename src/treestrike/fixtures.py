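"""Synthetic measurement tables for exercising the fitting utilities.

Real field campaigns measure whole-stem resistance over a fixed electrode
span on stems spanning roughly 1-10 cm diameter, then regress
log resistivity on cube-root diameter.  The generators here emulate that
statistical structure -- uniform diameters over a range, Gaussian
residuals on the log scale -- so that parameter recovery by
:func:`treestrike.resistivity.fit_resistivity_model` and
:func:`treestrike.resistivity.fit_moisture_model` can be tested without
field data.  They do not emulate heteroscedasticity across size classes,
phylogenetic structure, or repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .resistivity import (
    DEFAULT_ELECTRODE_SPAN_M,
    ResistivityMeasurement,
    SpeciesResistivityModel,
)

__all__ = [
    "FixtureConfig",
    "generate_resistivity_measurements",
    "generate_moisture_measurements",
]

_DEFAULT_MODEL = SpeciesResistivityModel(
    "synthetic", "tropical", "tree", slope=8.29, intercept=2.07
)


@dataclass(frozen=True)
class FixtureConfig:
    """Design of one synthetic measurement campaign.

    Defaults emulate a typical field survey: 50 stems spanning 1-10 cm
    diameter, log-scale residual SD 0.4, electrode span 30 cm, and a
    moisture effect of -6 ln(ohm m) per unit moisture fraction over a
    0.30-0.60 moisture range.
    """

    model: SpeciesResistivityModel = _DEFAULT_MODEL
    diameter_range: tuple[float, float] = (0.01, 0.10)
    n: int = 50
    noise_sd: float = 0.4
    electrode_span: float = DEFAULT_ELECTRODE_SPAN_M
    moisture_intercept: float = 8.0
    moisture_slope: float = 6.0  # ln p drops by this per unit moisture fraction
    moisture_range: tuple[float, float] = (0.30, 0.60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InvalidInputError("n must be at least 3")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        lo, hi = self.diameter_range
        if not (0 < lo < hi):
            raise InvalidInputError("diameter_range must be increasing and positive")
        mlo, mhi = self.moisture_range
        if not (0 <= mlo < mhi <= 1):
            raise InvalidInputError("moisture_range must be increasing within [0, 1]")


def _to_measurement(
    diameter: np.ndarray, ln_p: np.ndarray, span: float, moisture=None
) -> list[ResistivityMeasurement]:
    # invert p = R A / L to recover the raw resistance the meter would read
    area = np.pi * diameter**2 / 4.0
    resistance = np.exp(ln_p) * span / area
    out = []
    for k in range(len(diameter)):
        out.append(
            ResistivityMeasurement(
                diameter=float(diameter[k]),
                resistance=float(resistance[k]),
                electrode_span=span,
                moisture_fraction=None if moisture is None else float(moisture[k]),
            )
        )
    return out


def generate_resistivity_measurements(config: FixtureConfig) -> list[ResistivityMeasurement]:
    """Draw a synthetic diameter-resistance table under a species model.

    ln p = m d^(1/3) + b + eps,  eps ~ N(0, noise_sd^2); diameters uniform
    on ``diameter_range``.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    d = rng.uniform(*config.diameter_range, size=config.n)
    ln_p = (
        config.model.slope * np.cbrt(d)
        + config.model.intercept
        + rng.normal(0.0, config.noise_sd, size=config.n)
    )
    return _to_measurement(d, ln_p, config.electrode_span)


def generate_moisture_measurements(config: FixtureConfig) -> list[ResistivityMeasurement]:
    """Draw a synthetic moisture-resistivity table.

    ln p = a - c * moisture + eps with moisture uniform on
    ``moisture_range``; diameters are drawn as in the resistivity
    generator so the records are complete measurements.
    """
    rng = np.random.default_rng(config.seed)
    d = rng.uniform(*config.diameter_range, size=config.n)
    w = rng.uniform(*config.moisture_range, size=config.n)
    ln_p = (
        config.moisture_intercept
        - config.moisture_slope * w
        + rng.normal(0.0, config.noise_sd, size=config.n)
    )
    return _to_measurement(d, ln_p, config.electrode_span, moisture=w)
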