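"""Strike energetics: heating, maximum power, and liana current division.

Resistive heating deposited in a conductor of resistance R by a discharge
with action integral AI is ``H = AI * R`` (joules); the peak heating rate
is ``P = Ipk^2 * R`` (watts).  Dividing H by conductor volume gives the
*heating density* (J/cm^3), the model's proxy for per-tissue damage.

When lianas climb a tree, the tree and liana stems form parallel
conductors under a common potential, so a strike's current divides
between them inversely to resistance.  With combined liana resistance
R_l, the tree carries the fraction

    f = R_l / (R_t + R_l)

of the total current; because heating and power both scale with current
squared, the tree's heating and maximum power are both reduced by the
factor f^2, and lianas divert an identical proportion 100*(1 - f^2) of
heat and of power.

No resistivity-diameter function is published for lianas, so the default
liana conductors are parameterised by a calibrated total resistance per
region (tropical / temperate), recovered by inverting the published
one-liana heating reductions (:func:`calibrate_liana_resistances`); the
calibrated value refers to the reference liana (25 m of stem on a 20 m
host) and scales linearly with stem length.  A ``resistance_override``
always wins when supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import registry
from .discharge import CalibratedDischargeConstants
from .errors import CalibrationError, InvalidInputError
from .geometry import TaperedStem, build_tapered_stem, stem_resistance, stem_volume
from .resistivity import SpeciesResistivityModel

REFERENCE_LIANA_LENGTH_M = 25.0  # 1.25 x the 20 m reference host
LIANA_LENGTH_FACTOR = 1.25
DEFAULT_LIANA_BASAL_DIAMETER_M = 0.06

__all__ = [
    "LianaSpec",
    "TreeLianaComplex",
    "ConductorResult",
    "StrikeReport",
    "ProtectionSummary",
    "heating",
    "max_power",
    "heating_density",
    "parallel_resistance",
    "tree_current_fraction",
    "calibrate_liana_resistances",
    "liana_resistance",
    "build_complex",
    "strike_complex",
    "protection_summary",
]


@dataclass(frozen=True)
class LianaSpec:
    """One liana conductor on a host tree.

    The stem is 25% longer than the host is tall (sinuous, scandent
    growth), tapering from a 6 cm basal diameter to the 1 cm top.
    """

    host_height: float
    region: str = "tropical"
    length: float | None = None
    d_base: float = DEFAULT_LIANA_BASAL_DIAMETER_M
    d_top: float = 0.01
    resistance_override: float | None = None

    def __post_init__(self) -> None:
        if self.host_height <= 0:
            raise InvalidInputError("host_height must be positive")
        if self.length is None:
            object.__setattr__(self, "length", LIANA_LENGTH_FACTOR * self.host_height)
        if self.length <= self.host_height:
            raise InvalidInputError("liana length must exceed host height")
        if self.resistance_override is not None and self.resistance_override <= 0:
            raise InvalidInputError("resistance_override must be positive")


@dataclass(frozen=True)
class TreeLianaComplex:
    """One tree conductor plus any number of parallel liana conductors."""

    stem: TaperedStem
    species: SpeciesResistivityModel
    lianas: tuple[LianaSpec, ...] = ()


@dataclass(frozen=True)
class ConductorResult:
    name: str
    resistance: float  # ohm
    current_fraction: float
    heating: float  # J
    max_power: float  # W


@dataclass(frozen=True)
class StrikeReport:
    """Energetic outcome of one discharge through a tree-liana complex."""

    discharge: str
    tree: ConductorResult
    lianas: tuple[ConductorResult, ...]
    tree_volume: float  # m^3
    tree_heating_density: float  # J/cm^3
    percent_diverted: float  # identical for heating and power

    @property
    def conductors(self) -> tuple[ConductorResult, ...]:
        return (self.tree, *self.lianas)


def heating(resistance: float, action_integral: float) -> float:
    """Deposited energy H = AI * R, joules."""
    if resistance < 0 or action_integral < 0:
        raise InvalidInputError("resistance and action integral must be non-negative")
    return action_integral * resistance


def max_power(resistance: float, peak_current: float) -> float:
    """Peak heating rate P = Ipk^2 * R, watts."""
    if resistance < 0 or peak_current < 0:
        raise InvalidInputError("resistance and peak current must be non-negative")
    return peak_current**2 * resistance


def heating_density(heating_j: float, volume_m3: float) -> float:
    """Heating per unit tissue volume, J/cm^3."""
    if volume_m3 <= 0:
        raise InvalidInputError("volume must be positive")
    if heating_j < 0:
        raise InvalidInputError("heating must be non-negative")
    return heating_j / (volume_m3 * 1e6)


def parallel_resistance(resistances: Sequence[float]) -> float:
    """Combined resistance of parallel conductors, 1 / sum(1/R_i)."""
    r = np.asarray(resistances, dtype=float)
    if r.size == 0:
        raise InvalidInputError("need at least one resistance")
    if np.any(r <= 0):
        raise InvalidInputError("resistances must be positive")
    return float(1.0 / np.sum(1.0 / r))


def tree_current_fraction(r_tree: float, r_lianas_combined: float) -> float:
    """Fraction of total current carried by the tree under a common potential."""
    if r_tree <= 0 or r_lianas_combined <= 0:
        raise InvalidInputError("resistances must be positive")
    return r_lianas_combined / (r_tree + r_lianas_combined)


def calibrate_liana_resistances(
    liana_reference: pd.DataFrame | None = None,
    tree_resistances: Mapping[str, float] | None = None,
    species: Sequence[str] | None = None,
) -> dict[str, float]:
    """Recover the regional liana resistances from published reductions.

    For each reference tree, the one-liana heating ratio gives the tree
    current fraction ``f = sqrt(H_1L / H_0L)``, hence the liana resistance
    ``R_l = R_t * f / (1 - f)``.  Values are averaged within each region.

    ``tree_resistances`` maps species name to the tree resistance in ohms;
    by default the packaged 20 m reference stems are rebuilt and their
    resistances computed with this package's own geometry.
    """
    ref = liana_reference if liana_reference is not None else registry.load_liana_reference()
    if species is not None:
        ref = ref[ref["name"].isin(species)]
    if len(ref) == 0:
        raise CalibrationError("liana reference selection is empty")
    if tree_resistances is None:
        models = registry.species_models()
        stem = build_tapered_stem(
            registry.REFERENCE_HEIGHT_M,
            registry.REFERENCE_BASAL_DIAMETER_M,
            registry.TOP_DIAMETER_M,
            registry.SEGMENT_LENGTH_M,
        )
        tree_resistances = {
            name: stem_resistance(stem, model) for name, model in models.items()
        }
    regions = registry.load_species_registry().set_index("name")["region"]
    out: dict[str, list[float]] = {}
    for _, row in ref.iterrows():
        name = row["name"]
        f = float(np.sqrt(row["heating_1l_gj"] / row["heating_0l_gj"]))
        r_l = tree_resistances[name] * f / (1.0 - f)
        out.setdefault(regions[name], []).append(r_l)
    return {region: float(np.mean(vals)) for region, vals in out.items()}


def liana_resistance(
    spec: LianaSpec, calibration: Mapping[str, float] | None = None
) -> float:
    """Total resistance of one liana conductor, ohms.

    An explicit ``resistance_override`` wins; otherwise the region's
    calibrated reference resistance (for a 25 m liana) is scaled linearly
    by stem length, as appropriate for a fixed-taper series conductor.
    """
    if spec.resistance_override is not None:
        return spec.resistance_override
    cal = calibration if calibration is not None else calibrate_liana_resistances()
    try:
        base = cal[spec.region]
    except KeyError:
        raise CalibrationError(
            f"no calibrated liana resistance for region {spec.region!r} "
            "and no resistance_override given"
        )
    return base * spec.length / REFERENCE_LIANA_LENGTH_M


def build_complex(
    species: SpeciesResistivityModel,
    height: float = registry.REFERENCE_HEIGHT_M,
    basal_diameter: float = registry.REFERENCE_BASAL_DIAMETER_M,
    n_lianas: int = 0,
    liana_region: str | None = None,
    liana_resistance_override: float | None = None,
) -> TreeLianaComplex:
    """Convenience constructor: tree stem plus N identical lianas."""
    stem = build_tapered_stem(
        height, basal_diameter, registry.TOP_DIAMETER_M, registry.SEGMENT_LENGTH_M
    )
    if n_lianas < 0:
        raise InvalidInputError("n_lianas must be non-negative")
    region = liana_region if liana_region is not None else species.region
    lianas = tuple(
        LianaSpec(
            host_height=height,
            region=region,
            resistance_override=liana_resistance_override,
        )
        for _ in range(n_lianas)
    )
    return TreeLianaComplex(stem=stem, species=species, lianas=lianas)


def strike_complex(
    complex_: TreeLianaComplex,
    constants: CalibratedDischargeConstants,
    discharge: str = "D1",
    liana_calibration: Mapping[str, float] | None = None,
) -> StrikeReport:
    """Distribute one discharge over a tree-liana complex.

    The liana-free tree would receive ``H0 = AI * R_t`` and
    ``P0 = Ipk^2 * R_t``; with lianas the tree receives ``H0 * f^2`` and
    ``P0 * f^2`` where f is its current fraction.  Each of the N identical
    lianas carries ``(1 - f) / N`` of the current.
    """
    ai = constants.action_integral(discharge)
    r_tree = stem_resistance(complex_.stem, complex_.species)
    volume = stem_volume(complex_.stem)
    if complex_.lianas:
        if liana_calibration is None and any(
            liana.resistance_override is None for liana in complex_.lianas
        ):
            liana_calibration = calibrate_liana_resistances()
        r_each = [liana_resistance(liana, liana_calibration) for liana in complex_.lianas]
        r_comb = parallel_resistance(r_each)
        f = tree_current_fraction(r_tree, r_comb)
    else:
        r_each = []
        f = 1.0
    h0 = heating(r_tree, ai)
    p0 = max_power(r_tree, constants.effective_peak)
    tree = ConductorResult(
        name=complex_.species.name,
        resistance=r_tree,
        current_fraction=f,
        heating=h0 * f**2,
        max_power=p0 * f**2,
    )
    liana_results = tuple(
        ConductorResult(
            name=f"liana_{k + 1}",
            resistance=r_k,
            current_fraction=(1.0 - f) / len(r_each),
            heating=ai * ((1.0 - f) / len(r_each)) ** 2 * r_k,
            max_power=constants.effective_peak**2 * ((1.0 - f) / len(r_each)) ** 2 * r_k,
        )
        for k, r_k in enumerate(r_each)
    )
    return StrikeReport(
        discharge=discharge,
        tree=tree,
        lianas=liana_results,
        tree_volume=volume,
        tree_heating_density=heating_density(tree.heating, volume),
        percent_diverted=100.0 * (1.0 - f**2),
    )


@dataclass(frozen=True)
class ProtectionSummary:
    """Mean +/- sample SD of percent heating/power diverted across species."""

    mean_percent: float
    sd_percent: float
    per_species: pd.DataFrame = field(repr=False)


def protection_summary(
    species: Sequence[SpeciesResistivityModel],
    constants: CalibratedDischargeConstants,
    n_lianas: int = 1,
    discharge: str = "D1",
    liana_calibration: Mapping[str, float] | None = None,
) -> ProtectionSummary:
    """Percent diverted for each species with region-matched lianas."""
    if len(species) == 0:
        raise InvalidInputError("species list must be non-empty")
    if liana_calibration is None:
        liana_calibration = calibrate_liana_resistances()
    rows = []
    for model in species:
        report = strike_complex(
            build_complex(model, n_lianas=n_lianas),
            constants,
            discharge=discharge,
            liana_calibration=liana_calibration,
        )
        rows.append(
            {
                "name": model.name,
                "region": model.region,
                "percent_diverted": report.percent_diverted,
                "tree_heating_gj": report.tree.heating / 1e9,
                "tree_max_power_tw": report.tree.max_power / 1e12,
            }
        )
    frame = pd.DataFrame(rows)
    pct = frame["percent_diverted"].to_numpy()
    sd = float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0
    return ProtectionSummary(
        mean_percent=float(np.mean(pct)), sd_percent=sd, per_species=frame
    )
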