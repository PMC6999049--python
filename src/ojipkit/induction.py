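"""OJIP landmark extraction, initial slope, and complementary-area quantities.

The polyphasic fluorescence rise is summarized by fixed-time landmarks —
F_O at 20 µs (minimal fluorescence, all PSII reaction centers open), F_L at
150 µs, F_K at 300 µs, F_J at 2 ms, F_I at 30 ms — plus the recorded
maximum F_M (= F_P) and its time t_FM.  From these come the approximated
initial slope M_0 = 4(F_270µs − F_O)/(F_M − F_O) in ms⁻¹ and the
complementary area above the curve: Area = ∫(F_M − F_t)dt from onset to
t_FM, normalized as S_m = Area/(F_M − F_O) (a multiple-turnover electron
capacity in ms) and the single-turnover analogue S_s = V_J/M_0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transients import FluorescenceTransient, value_at

__all__ = [
    "StepValues",
    "AreaValues",
    "DegenerateTransientError",
    "extract_steps",
    "compute_areas",
    "LANDMARK_TIMES_US",
]

#: landmark sampling times in µs from actinic-light onset
LANDMARK_TIMES_US = {
    "F_O": 20.0,
    "F_L": 150.0,
    "F_270": 270.0,
    "F_K": 300.0,
    "F_J": 2_000.0,
    "F_I": 30_000.0,
}


class DegenerateTransientError(ValueError):
    """Flat or inverted trace: F_M does not exceed F_O, so every normalized
    quantity downstream would divide by zero."""


@dataclass(frozen=True)
class StepValues:
    """Landmark fluorescence values of one OJIP transient.

    F_M is the maximum of the *recorded samples* (not of any interpolant),
    t_FM its time in ms (first occurrence on ties).  F_V = F_M − F_O is the
    maximal variable fluorescence.
    """

    F_O: float
    F_L: float
    F_K: float
    F_J: float
    F_I: float
    F_M: float
    t_FM: float
    F_270: float

    @property
    def F_V(self) -> float:
        return self.F_M - self.F_O


@dataclass(frozen=True)
class AreaValues:
    """Complementary-area and initial-slope quantities (times in ms)."""

    Area: float   # ∫(F_M − F_t)dt, onset → t_FM, instrument-units·ms
    S_m: float    # Area/(F_M − F_O), ms
    M_0: float    # 4(F_270 − F_O)/(F_M − F_O), ms⁻¹
    S_s: float    # V_J/M_0, ms


def extract_steps(transient: FluorescenceTransient, *, rule="linear") -> StepValues:
    """Read the OJIP landmarks off a transient.

    Fixed-time landmarks are interpolated with the module interpolation
    rule; F_M/t_FM come from the raw samples.  Raises
    DegenerateTransientError on a flat trace and warns if the peak falls
    at or before the 2 ms J-step (non-physiological).
    """
    i_max = int(np.argmax(transient.F))
    F_M = float(transient.F[i_max])
    t_FM_ms = float(transient.time[i_max]) / 1e3

    vals = {}
    for name, t_us in LANDMARK_TIMES_US.items():
        t_clip = min(max(t_us, transient.time[0]), transient.time[-1])
        vals[name] = value_at(transient, t_clip, rule=rule)

    if F_M <= vals["F_O"]:
        raise DegenerateTransientError(
            f"F_M={F_M:g} does not exceed F_O={vals['F_O']:g}"
        )
    if t_FM_ms <= 2.0:
        import warnings

        warnings.warn(
            f"t_FM={t_FM_ms:g} ms ≤ 2 ms: peak precedes the J-step, "
            "transient may not be physiological"
        )
    return StepValues(
        F_O=vals["F_O"], F_L=vals["F_L"], F_K=vals["F_K"], F_J=vals["F_J"],
        F_I=vals["F_I"], F_M=F_M, t_FM=t_FM_ms, F_270=vals["F_270"],
    )


def compute_areas(transient: FluorescenceTransient, steps: StepValues) -> AreaValues:
    """Complementary area and slope quantities from a transient + its steps.

    The area above the curve is trapezoidal on the raw sample grid from
    onset to t_FM, with F capped at F_M so noise excursions above the
    recorded maximum cannot contribute negatively.  Samples after t_FM are
    excluded.
    """
    if steps.F_V <= 0:
        raise DegenerateTransientError("F_M ≤ F_O")
    t_ms = transient.time / 1e3
    F = np.minimum(transient.F, steps.F_M)
    mask = t_ms <= steps.t_FM
    area = float(np.trapezoid(steps.F_M - F[mask], t_ms[mask]))
    S_m = area / steps.F_V
    M_0 = 4.0 * (steps.F_270 - steps.F_O) / steps.F_V
    V_J = (steps.F_J - steps.F_O) / steps.F_V
    S_s = V_J / M_0 if M_0 > 0 else float("nan")
    return AreaValues(Area=area, S_m=S_m, M_0=M_0, S_s=S_s)
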