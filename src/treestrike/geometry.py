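"""Model stems as conical stacks of short cylinders.

A tree (or liana) is idealised as a vertical conductor whose diameter
tapers linearly from a basal maximum to a fixed 1 cm top.  The conductor
is discretised into short cylinders (1 cm tall by default); each cylinder
contributes

    resistance :  p(d_i) * l_i / (pi d_i^2 / 4)     (series sum)
    volume     :  (pi d_i^2 / 4) * l_i

where p(.) is the species resistivity-diameter function.  The series sum
is dominated by the thin segments near the top, which is why trees of the
same species and height but different basal diameter have similar total
resistance.

Segment diameters follow the taper evaluated at each cylinder's *top*
face, so the topmost cylinder has exactly the fixed minimum diameter.
``convention="midpoint"`` (mid-face) and ``"bottom"`` are also available;
the three agree to well under 1% at 1 cm segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .resistivity import SpeciesResistivityModel

_CONVENTION_OFFSET = {"top": 1.0, "midpoint": 0.5, "bottom": 0.0}

__all__ = [
    "TaperedStem",
    "StemSummary",
    "build_tapered_stem",
    "stem_volume",
    "stem_resistance",
    "frustum_volume",
]


@dataclass(frozen=True)
class TaperedStem:
    """A conductor discretised as a base-to-top stack of cylinders."""

    length: float
    d_base: float
    d_top: float
    segment_length: float
    segment_diameters: np.ndarray  # metres, ordered base -> top
    segment_lengths: np.ndarray  # metres; equal except possibly the last

    @property
    def n_segments(self) -> int:
        return len(self.segment_diameters)


@dataclass(frozen=True)
class StemSummary:
    """Total series resistance (ohm) and volume (m^3) of a stem."""

    total_resistance: float
    total_volume: float


def build_tapered_stem(
    length: float,
    d_base: float,
    d_top: float = 0.01,
    segment_length: float = 0.01,
    convention: str = "top",
) -> TaperedStem:
    """Discretise a linearly tapering conductor into cylinders.

    ``n = round(length / segment_length)`` cylinders are used; when the
    division is not exact the remainder is folded into the final (top)
    segment's length.  The per-segment diameter decrement is
    ``(d_base - d_top) / n``.
    """
    if not (np.isfinite(length) and length > 0):
        raise InvalidInputError(f"length must be positive, got {length!r}")
    if not (np.isfinite(d_top) and d_top > 0):
        raise InvalidInputError(f"d_top must be positive, got {d_top!r}")
    if not (np.isfinite(d_base) and d_base > 0):
        raise InvalidInputError(f"d_base must be positive, got {d_base!r}")
    if d_top > d_base:
        raise InvalidInputError(
            f"taper is inverted: d_top={d_top!r} exceeds d_base={d_base!r}"
        )
    if segment_length <= 0:
        raise InvalidInputError(f"segment_length must be positive, got {segment_length!r}")
    if length < segment_length:
        raise InvalidInputError(
            f"length {length!r} is shorter than one segment ({segment_length!r})"
        )
    try:
        offset = _CONVENTION_OFFSET[convention]
    except KeyError:
        raise InvalidInputError(f"unknown diameter convention {convention!r}")

    n = round(length / segment_length)
    decrement = (d_base - d_top) / n
    diameters = d_base - (np.arange(n) + offset) * decrement
    # Guard the all-but-exact endpoints against floating-point drift.
    diameters = np.clip(diameters, d_top, d_base)
    lengths = np.full(n, segment_length)
    lengths[-1] = length - (n - 1) * segment_length
    return TaperedStem(
        length=float(length),
        d_base=float(d_base),
        d_top=float(d_top),
        segment_length=float(segment_length),
        segment_diameters=diameters,
        segment_lengths=lengths,
    )


def stem_volume(stem: TaperedStem) -> float:
    """Total volume of the cylinder stack, m^3."""
    d = stem.segment_diameters
    return float(np.sum(np.pi * d**2 / 4.0 * stem.segment_lengths))


def stem_resistance(stem: TaperedStem, model: SpeciesResistivityModel) -> float:
    """Total series resistance of the stack under a species model, ohms."""
    d = stem.segment_diameters
    p = model(d)
    return float(np.sum(p * stem.segment_lengths / (np.pi * d**2 / 4.0)))


def summarize_stem(stem: TaperedStem, model: SpeciesResistivityModel) -> StemSummary:
    return StemSummary(stem_resistance(stem, model), stem_volume(stem))


def frustum_volume(length: float, d_base: float, d_top: float) -> float:
    """Closed-form volume of the continuum truncated cone, m^3."""
    rb, rt = d_base / 2.0, d_top / 2.0
    return np.pi * length / 3.0 * (rb**2 + rb * rt + rt**2)
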