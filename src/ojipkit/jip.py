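"""The JIP-test: energy-flux parameters derived from OJIP landmarks.

The JIP-test (Strasser's theory of energy fluxes in biomembranes) converts
the landmark values of a fast fluorescence rise into quantum yields, flux
ratios, phenomenological fluxes per excited cross-section (CS), reaction
center densities, and multiplicative performance indexes:

    φ_Po = 1 − F_O/F_M               maximum yield of primary photochemistry
    ψ_Eo = 1 − V_J                   electron moves beyond Q_A⁻
    φ_Eo = φ_Po·ψ_Eo                 yield of electron transport
    δ_Ro = (1 − V_I)/(1 − V_J)       intersystem carriers → PSI end acceptors
    φ_Ro = φ_Po·(1 − V_I)            yield of PSI end-acceptor reduction
    RC/ABS = φ_Po·(V_J/M_0)          γ_RC = RC/(ABS + RC)
    PI_ABS = [γ_RC/(1−γ_RC)]·[φ_Po/(1−φ_Po)]·[ψ_Eo/(1−ψ_Eo)]
    PI_total = PI_ABS·δ_Ro/(1−δ_Ro)

ABS/CS has no direct estimator; the standard proxy ABS/CS ≈ F_O is used by
default (F_M optionally), and the proxy choice is recorded in the result.

Group-level statistics compare a treated collection against a control:
R_J = [V_J(treated) − V_J(control)]/[1 − V_J(control)] estimates the
fraction of PSII reaction centers whose Q_B site is occupied by an
inhibitor, and the Q_A-reducing-center fraction is
(RC/CS)_t/(RC/CS)_c · (ABS/CS)_t/(ABS/CS)_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np

from .induction import AreaValues, DegenerateTransientError, StepValues

__all__ = [
    "JIPResult",
    "GroupComparison",
    "QuenchResult",
    "relative_variable_fluorescence",
    "compute_jip",
    "compare_groups",
    "compute_quench",
]

#: V_J at or above this is treated as a saturated J-step (DCMU-like limit):
#: the electron-transport denominators (1 − V_J) are within measurement
#: noise of zero, so ET-dependent indexes are reported as 0 / not-a-value
SATURATION_THRESHOLD = 0.95


def relative_variable_fluorescence(steps: StepValues, F_t: float) -> float:
    """V_t = (F_t − F_O)/(F_M − F_O), the relative variable fluorescence."""
    if steps.F_V <= 0:
        raise DegenerateTransientError("F_M ≤ F_O")
    return (F_t - steps.F_O) / steps.F_V


@dataclass(frozen=True)
class JIPResult:
    """The full derived parameter record for one sample.

    ``saturated_J`` flags the DCMU-like limit V_J → 1 where ψ_Eo = 0: the
    performance indexes are reported as 0 and δ_Ro/PI_total-specific terms
    as NaN (not-a-value) because the electron-transport denominators vanish.
    ``abs_cs_proxy`` records which landmark stood in for ABS/CS.
    """

    V_K: float
    V_J: float
    V_I: float
    F_K_over_F_J: float
    phi_Po: float
    psi_Eo: float
    phi_Eo: float
    phi_Do: float
    phi_Ro: float
    delta_Ro: float
    gamma_RC: float
    ABS_CS: float
    TR0_CS: float
    ET0_CS: float
    DI0_CS: float
    RC_CS: float
    Sm: float
    Ss: float
    M0: float
    t_FM: float
    Sm_over_tFM: float
    PI_ABS: float
    PI_total: float
    saturated_J: bool = False
    abs_cs_proxy: str = "F_O"

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def compute_jip(
    steps: StepValues,
    areas: AreaValues,
    *,
    abs_cs_proxy: str = "F_O",
    saturation_threshold: float = SATURATION_THRESHOLD,
) -> JIPResult:
    """Derive the full JIP-test record from landmarks and areas.

    ``abs_cs_proxy`` selects the absorption-flux stand-in: "F_O" (default)
    or "F_M".  When the J-step saturates (V_J ≥ ``saturation_threshold``,
    the DCMU-like full Q_A→Q_B block where the J level reaches the peak)
    the flux ratios through the electron-transport chain collapse: the
    performance indexes are reported as 0, δ_Ro as NaN, and
    ``saturated_J`` is set; ψ_Eo and φ_Eo keep their (near-zero) computed
    values.
    """
    if steps.F_V <= 0:
        raise DegenerateTransientError("F_M ≤ F_O")
    if abs_cs_proxy not in ("F_O", "F_M"):
        raise ValueError(f"unknown ABS/CS proxy {abs_cs_proxy!r}")

    V_K = relative_variable_fluorescence(steps, steps.F_K)
    V_J = relative_variable_fluorescence(steps, steps.F_J)
    V_I = relative_variable_fluorescence(steps, steps.F_I)

    phi_Po = 1.0 - steps.F_O / steps.F_M
    phi_Do = steps.F_O / steps.F_M
    psi_Eo = 1.0 - V_J
    phi_Eo = phi_Po * psi_Eo
    phi_Ro = phi_Po * (1.0 - V_I)

    saturated = V_J >= saturation_threshold
    delta_Ro = float("nan") if saturated else (1.0 - V_I) / (1.0 - V_J)

    rc_abs = phi_Po * (V_J / areas.M_0) if areas.M_0 > 0 else float("nan")
    gamma_RC = rc_abs / (1.0 + rc_abs) if math.isfinite(rc_abs) else float("nan")

    ABS_CS = steps.F_O if abs_cs_proxy == "F_O" else steps.F_M
    TR0_CS = phi_Po * ABS_CS
    ET0_CS = phi_Po * psi_Eo * ABS_CS
    DI0_CS = ABS_CS - TR0_CS
    RC_CS = rc_abs * ABS_CS if math.isfinite(rc_abs) else float("nan")

    def _odds(x):
        # odds-ratio term of the performance indexes; x → 1 (e.g. F_O = 0
        # giving φ_Po = 1) sends the index to infinity rather than erroring
        return x / (1.0 - x) if x < 1.0 else float("inf")

    if saturated:
        PI_ABS = 0.0
        PI_total = 0.0
    else:
        PI_ABS = _odds(gamma_RC) * _odds(phi_Po) * _odds(psi_Eo)
        if math.isfinite(delta_Ro) and delta_Ro < 1.0:
            PI_total = PI_ABS * delta_Ro / (1.0 - delta_Ro)
        else:
            PI_total = float("nan")

    return JIPResult(
        V_K=V_K, V_J=V_J, V_I=V_I,
        F_K_over_F_J=steps.F_K / steps.F_J,
        phi_Po=phi_Po, psi_Eo=psi_Eo, phi_Eo=phi_Eo, phi_Do=phi_Do,
        phi_Ro=phi_Ro, delta_Ro=delta_Ro, gamma_RC=gamma_RC,
        ABS_CS=ABS_CS, TR0_CS=TR0_CS, ET0_CS=ET0_CS, DI0_CS=DI0_CS,
        RC_CS=RC_CS,
        Sm=areas.S_m, Ss=areas.S_s, M0=areas.M_0, t_FM=steps.t_FM,
        Sm_over_tFM=areas.S_m / steps.t_FM,
        PI_ABS=PI_ABS, PI_total=PI_total,
        saturated_J=bool(saturated), abs_cs_proxy=abs_cs_proxy,
    )


_NUMERIC_FIELDS = [
    f.name for f in dc_fields(JIPResult) if f.type in ("float", float)
]


@dataclass(frozen=True)
class GroupComparison:
    """Treated-vs-control summary of two JIP result collections.

    R_J is computed from the group-mean V_J values (a single occupancy
    estimate per treatment, as reported per inhibitor concentration);
    the raw value is kept in ``R_J_raw`` and the headline ``R_J`` is
    clipped to [0, 1] since it estimates an occupancy fraction.
    ``R_J_per_sample`` holds each treated sample's R_J against the control
    mean, for dispersion.  ``relative_params`` is treated-mean /
    control-mean per numeric field (spider-plot values, control = 1).
    """

    R_J: float
    R_J_raw: float
    R_J_per_sample: tuple
    QA_reducing_fraction: float
    non_QA_reducing_fraction: float
    relative_params: dict


def _group_means(results: Sequence[JIPResult]) -> dict:
    out = {}
    for name in _NUMERIC_FIELDS:
        vals = np.asarray([getattr(r, name) for r in results], dtype=float)
        with np.errstate(invalid="ignore"):
            out[name] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
    return out


def compare_groups(
    treated: Sequence[JIPResult], control: Sequence[JIPResult]
) -> GroupComparison:
    """Q_B-site occupancy R_J and relative (spider-plot) parameters."""
    if not len(treated) or not len(control):
        raise ValueError("compare_groups: both groups must be non-empty")
    tm, cm = _group_means(treated), _group_means(control)
    if cm["V_J"] >= 1.0:
        raise ValueError("control group has a saturated mean V_J")

    denom = 1.0 - cm["V_J"]
    rj_raw = (tm["V_J"] - cm["V_J"]) / denom
    rj = float(np.clip(rj_raw, 0.0, 1.0))
    rj_each = tuple(
        float(np.clip((r.V_J - cm["V_J"]) / denom, 0.0, 1.0)) for r in treated
    )

    qa_frac = (tm["RC_CS"] / cm["RC_CS"]) * (tm["ABS_CS"] / cm["ABS_CS"])
    rel = {}
    for name in _NUMERIC_FIELDS:
        c = cm[name]
        rel[name] = tm[name] / c if c not in (0.0,) and math.isfinite(c) else float("nan")
    return GroupComparison(
        R_J=rj,
        R_J_raw=rj_raw,
        R_J_per_sample=rj_each,
        QA_reducing_fraction=qa_frac,
        non_QA_reducing_fraction=1.0 - qa_frac,
        relative_params=rel,
    )


@dataclass(frozen=True)
class QuenchResult:
    """Saturation-pulse quenching parameters from a PAM measurement."""

    Fv_over_Fm: float
    Yield: float
    qP: float
    ETR: float


def compute_quench(
    F_O: float,
    F_M: float,
    F_S: float,
    F_M_prime: float,
    *,
    par: float = 110.0,
    absorptance: float = 0.84,
    psii_fraction: float = 0.5,
    F_O_prime: float | None = None,
) -> QuenchResult:
    """Standard saturation-pulse definitions.

    Yield = (F_M′ − F_S)/F_M′; qP = (F_M′ − F_S)/(F_M′ − F_O′) with F_O′
    defaulting to the dark-adapted F_O (no F_O′ measurement assumed);
    ETR = Yield · PAR · absorptance · psii_fraction with the conventional
    leaf absorptance 0.84 and PSII share 0.5 unless overridden.
    """
    if not (F_M > F_O > 0):
        raise ValueError("requires F_M > F_O > 0")
    if F_M_prime < F_S:
        raise ValueError("F_M′ < F_S is not a valid saturation-pulse record")
    Fo_p = F_O if F_O_prime is None else F_O_prime
    y = (F_M_prime - F_S) / F_M_prime
    qp = (F_M_prime - F_S) / (F_M_prime - Fo_p) if F_M_prime > Fo_p else 0.0
    return QuenchResult(
        Fv_over_Fm=(F_M - F_O) / F_M,
        Yield=y,
        qP=qp,
        ETR=y * par * absorptance * psii_fraction,
    )
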