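"""Lightning current profiles and their energetic constants.

A cloud-to-ground flash is represented as a sequence of return strokes,
optionally followed by a continuing-current (CC) segment.  Each stroke is
a sum of Heidler terms,

    i(t) = (I0 / eta) * (t/tau1)^n / ((t/tau1)^n + 1) * exp(-t/tau2)

the standard analytic return-stroke waveform: a steep rise governed by
tau1, exponential decay governed by tau2, and amplitude-correction factor
eta so that the peak equals I0 up to the correction.

Two quantities of a profile matter for resistive heating in a struck
conductor: the *action integral* int i(t)^2 dt (A^2 s), which multiplied
by resistance gives deposited energy, and the *peak current* (A), whose
square times resistance gives maximum power.

Three canonical discharges are provided:

* ``D1`` -- a single return stroke with a 30 kA peak;
* ``D2`` -- that stroke followed by two smaller subsequent strokes;
* ``D3`` -- the first stroke truncated at 50 us, immediately followed by
  a continuing current of 200 A for 115 ms.

The published per-species heating and power values imply the action
integrals and effective peak current directly (heating / resistance and
sqrt(power / resistance) are species-independent), so
:func:`calibrate_constants` recovers them from the packaged reference
table.  Those calibrated constants are what the energetics layer uses;
the synthesized waveforms reproduce them to within a few percent and
exist so profiles can be inspected, plotted, and varied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidInputError

DEFAULT_DT_S = 1e-8  # fixed-step trapezoid resolution over stroke support

__all__ = [
    "HeidlerTerm",
    "ConstantCurrentSegment",
    "Stroke",
    "DischargeProfile",
    "CalibratedDischargeConstants",
    "heidler_current",
    "profile_current",
    "action_integral",
    "peak_current",
    "canonical_discharge",
    "load_default_params",
    "calibrate_constants",
]


@dataclass(frozen=True)
class HeidlerTerm:
    """One Heidler waveform term: amplitude I0 (A), correction factor eta,
    rise constant tau1 (s), decay constant tau2 (s), steepness exponent n."""

    amplitude: float
    eta: float
    tau1: float
    tau2: float
    exponent: float = 2.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "eta", "tau1", "tau2"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass(frozen=True)
class ConstantCurrentSegment:
    """A constant current of ``amplitude`` amperes lasting ``duration`` s."""

    amplitude: float
    duration: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 0:
            raise InvalidInputError("amplitude and duration must be positive")


@dataclass(frozen=True)
class Stroke:
    """Heidler terms active on [offset, offset + duration)."""

    offset: float
    terms: tuple[HeidlerTerm, ...]
    duration: float

    def current(self, t: np.ndarray) -> np.ndarray:
        tl = np.asarray(t, dtype=float) - self.offset
        active = (tl >= 0) & (tl < self.duration)
        out = np.zeros_like(tl)
        if np.any(active):
            s = np.zeros(np.count_nonzero(active))
            for term in self.terms:
                s += heidler_current(term, tl[active])
            out[active] = s
        return out


@dataclass(frozen=True)
class DischargeProfile:
    """A composite flash: non-overlapping strokes plus an optional CC tail."""

    strokes: tuple[Stroke, ...] = ()
    cc_segment: ConstantCurrentSegment | None = None

    def __post_init__(self) -> None:
        ends = 0.0
        last = -np.inf
        for s in self.strokes:
            if s.offset <= last:
                raise InvalidInputError("stroke offsets must be strictly increasing")
            if s.offset < ends:
                raise InvalidInputError("strokes must not overlap")
            last = s.offset
            ends = s.offset + s.duration

    @property
    def cc_start(self) -> float:
        """The CC segment begins when the final stroke ends."""
        if not self.strokes:
            return 0.0
        final = self.strokes[-1]
        return final.offset + final.duration


def heidler_current(term: HeidlerTerm, t) -> np.ndarray | float:
    """Evaluate one Heidler term at time(s) ``t`` (seconds) -> amperes."""
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0):
        raise InvalidInputError("time must be non-negative")
    x = (ta / term.tau1) ** term.exponent
    out = (term.amplitude / term.eta) * x / (x + 1.0) * np.exp(-ta / term.tau2)
    return float(out) if out.ndim == 0 else out


def profile_current(profile: DischargeProfile, t) -> np.ndarray | float:
    """Total current of the profile at time(s) ``t`` -> amperes."""
    ta = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ta < 0):
        raise InvalidInputError("time must be non-negative")
    out = np.zeros_like(ta)
    for stroke in profile.strokes:
        out += stroke.current(ta)
    if profile.cc_segment is not None:
        start = profile.cc_start
        inside = (ta >= start) & (ta < start + profile.cc_segment.duration)
        out[inside] += profile.cc_segment.amplitude
    return float(out[0]) if np.isscalar(t) else out


def _stroke_grid(stroke: Stroke, dt: float) -> np.ndarray:
    n = max(int(np.ceil(stroke.duration / dt)), 2)
    return np.linspace(0.0, stroke.duration, n + 1)


def action_integral(profile: DischargeProfile, dt: float = DEFAULT_DT_S) -> float:
    """Numerical integral of i(t)^2 over the profile support, A^2 s.

    Strokes are integrated by fixed-step trapezoid on their own support
    (they do not overlap, so per-stroke contributions add); the CC segment
    contributes its closed form I^2 * duration.
    """
    total = 0.0
    for stroke in profile.strokes:
        tl = _stroke_grid(stroke, dt)
        i = np.zeros_like(tl)
        for term in stroke.terms:
            i += heidler_current(term, tl)
        total += float(np.trapezoid(i * i, tl))
    if profile.cc_segment is not None:
        total += profile.cc_segment.amplitude**2 * profile.cc_segment.duration
    return total


def peak_current(profile: DischargeProfile, dt: float = DEFAULT_DT_S) -> float:
    """Global maximum of i(t) over the profile, amperes."""
    peak = 0.0
    for stroke in profile.strokes:
        tl = _stroke_grid(stroke, dt)
        i = np.zeros_like(tl)
        for term in stroke.terms:
            i += heidler_current(term, tl)
        peak = max(peak, float(i.max()))
    if profile.cc_segment is not None:
        peak = max(peak, profile.cc_segment.amplitude)
    return peak


def load_default_params() -> dict:
    """The packaged stroke/CC parameter configuration (JSON)."""
    with resources.files("treestrike.data").joinpath("discharge_params.json").open() as fh:
        return json.load(fh)


def _terms(cfg: Sequence[dict]) -> tuple[HeidlerTerm, ...]:
    return tuple(
        HeidlerTerm(
            amplitude=c["amplitude_a"],
            eta=c["eta"],
            tau1=c["tau1_s"],
            tau2=c["tau2_s"],
            exponent=c.get("exponent", 2),
        )
        for c in cfg
    )


def canonical_discharge(kind: str, params: dict | None = None) -> DischargeProfile:
    """Build one of the canonical discharges ``D1``, ``D2``, ``D3``."""
    p = params if params is not None else load_default_params()
    first = _terms(p["first_stroke"]["terms"])
    first_dur = p["first_stroke"]["duration_s"]
    if kind == "D1":
        return DischargeProfile(strokes=(Stroke(0.0, first, first_dur),))
    if kind == "D2":
        sub = _terms(p["subsequent_stroke"]["terms"])
        sub_dur = p["subsequent_stroke"]["duration_s"]
        off = p["interstroke_offset_s"]
        return DischargeProfile(
            strokes=(
                Stroke(0.0, first, first_dur),
                Stroke(off, sub, sub_dur),
                Stroke(2 * off, sub, sub_dur),
            )
        )
    if kind == "D3":
        trunc = p["d3_stroke_truncation_s"]
        return DischargeProfile(
            strokes=(Stroke(0.0, first, trunc),),
            cc_segment=ConstantCurrentSegment(
                amplitude=p["cc_amplitude_a"], duration=p["cc_duration_s"]
            ),
        )
    raise InvalidInputError(f"unknown discharge kind {kind!r}; expected D1, D2 or D3")


@dataclass(frozen=True)
class CalibratedDischargeConstants:
    """Discharge energetics implied by the published reference table.

    ``action_integral_d1/2/3`` are in A^2 s; ``effective_peak`` in A.  The
    difference between the D3 and D1 action integrals equals the CC
    contribution 200^2 * 0.115 = 4,600 A^2 s to within the table's
    rounding.
    """

    action_integral_d1: float
    action_integral_d2: float
    action_integral_d3: float
    effective_peak: float

    def action_integral(self, kind: str) -> float:
        try:
            return {
                "D1": self.action_integral_d1,
                "D2": self.action_integral_d2,
                "D3": self.action_integral_d3,
            }[kind]
        except KeyError:
            raise InvalidInputError(f"unknown discharge kind {kind!r}")


def calibrate_constants(
    reference: pd.DataFrame, species: Sequence[str] | None = None
) -> CalibratedDischargeConstants:
    """Invert heating = AI x R and power = Ipk^2 x R against a reference table.

    ``reference`` must carry columns ``name, resistance_kohm,
    max_power_tw, heating_d1_gj, heating_d2_gj, heating_d3_gj`` (the
    packaged table from :func:`treestrike.registry.load_reference_energetics`).
    Per species, heating / resistance yields the action integral of each
    discharge and sqrt(power / resistance) the effective peak current;
    values are averaged over the selected species (all by default).
    """
    frame = reference if species is None else reference[reference["name"].isin(species)]
    if len(frame) == 0:
        raise CalibrationError("reference table selection is empty")
    r = frame["resistance_kohm"].to_numpy(float) * 1e3
    ai = {
        k: float((frame[f"heating_{k}_gj"].to_numpy(float) * 1e9 / r).mean())
        for k in ("d1", "d2", "d3")
    }
    peak = float(np.sqrt(frame["max_power_tw"].to_numpy(float) * 1e12 / r).mean())
    return CalibratedDischargeConstants(
        action_integral_d1=ai["d1"],
        action_integral_d2=ai["d2"],
        action_integral_d3=ai["d3"],
        effective_peak=peak,
    )
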