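"""Synthetic generators for OJIP transients, MR traces, and dose series.

No public repository of raw PEA transients accompanies the analyses this
package implements, so every pipeline stage is exercised against traces
generated here.  The OJIP generator is a deliberately minimal kinetic
model — it targets the phenomenology the JIP-test reads (an O-J-I-P
ordered rise whose J level grows with the fraction of Q_B-blocked
reaction centers and whose I→P amplitude tracks the PSI acceptor pool),
not photosynthetic realism.

Model (per reaction center, time in ms):

* a *blocked* subpopulation (fraction ``B``, Q_B site occupied by an
  inhibitor) accumulates Q_A⁻ with no reoxidation:
  dC_b/dt = k_L (1 − C_b);
* the *active* remainder is photoreduced at k_L and reoxidized at k_AB
  while oxidized plastoquinone remains:
  dC_a/dt = k_L (1 − C_a) − k_AB C_a g(P), with g a smooth availability
  factor on the oxidized-PQ pool P (initial size N_PQ);
* the pool is re-oxidized by a PSI-side drain that activates with rate
  k_FNR (ferredoxin-NADP⁺-reductase activation delays the I step) and
  stops once its acceptor capacity S_PSI is consumed — exhaustion of the
  drain releases the final I→P rise.

Fluorescence follows from the total closed fraction
C = B·C_b + (1−B)·C_a through the antenna-connectivity transform
F = F_O + (F_M − F_O)·C(1−p)/(1 − pC); both F levels are attenuated by
``antenna_loss`` (antenna damage scales the whole curve without touching
any normalized quantity).  Noise is multiplicative Gaussian, seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dose_response import DoseSeries, LesionRecord, classify_pathogenicity
from .transients import FluorescenceTransient, MRTrace

__all__ = [
    "SyntheticScenario",
    "default_time_grid_us",
    "simulate_ojip",
    "simulate_mr",
    "generate_dose_series",
    "generate_lesion_table",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one simulated OJIP measurement.

    Defaults give a control-like transient: V_J ≈ 0.45, a distinct I step
    near 30 ms, peak at a few hundred ms — the shape of a healthy
    dark-adapted sample under saturating red actinic light (the light
    intensity enters only through k_L).
    """

    B: float = 0.0            # fraction of RCs with the Q_B site blocked
    p: float = 0.25           # antenna connectivity
    k_L: float = 3.0          # ms⁻¹, light-driven Q_A reduction
    k_AB: float = 2.8         # ms⁻¹, Q_A⁻ → Q_B reoxidation
    N_PQ: float = 10.0        # oxidized PQ pool, e⁻ equivalents per RC
    S_PSI: float = 120.0      # PSI-side acceptor capacity, e⁻ equivalents
    k_FNR: float = 0.055      # ms⁻¹, activation/turnover of the PSI drain
    F_O_level: float = 500.0  # instrument units
    F_M_level: float = 2500.0
    antenna_loss: float = 0.0  # multiplicative attenuation of both levels
    noise_sd: float = 0.01     # relative (multiplicative) Gaussian noise
    seed: int = 0

    def __post_init__(self):
        for name in ("k_L", "k_AB", "N_PQ", "S_PSI", "k_FNR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("B", "p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.antenna_loss < 1.0:
            raise ValueError("antenna_loss must lie in [0, 1)")
        if self.F_M_level <= self.F_O_level or self.F_O_level <= 0:
            raise ValueError("need F_M_level > F_O_level > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")

    def with_(self, **kw):
        return replace(self, **kw)


def default_time_grid_us(t_end_us: float = 2e6) -> np.ndarray:
    """Instrument-like sampling: 10 µs steps to 300 µs, log-spaced after."""
    early = np.arange(10.0, 300.0, 10.0)
    late = np.logspace(np.log10(300.0), np.log10(t_end_us), 150)
    return np.unique(np.concatenate([early, late]))


def _integrate_active(scn: SyntheticScenario, t_grid_ms, substep_scale=1.0):
    """Closed fraction of the active subpopulation on t_grid_ms.

    Fixed-step explicit stepping with an exponential update for the fast
    Q_A state (P and the drain capacity move on slower scales and are
    stepped with Euler); the step grows proportionally to t, capped, and
    ``substep_scale`` < 1 refines every step for convergence checks.
    """
    eps_P = 0.02 * scn.N_PQ
    eps_R = 0.02 * scn.S_PSI
    C, P, R = 0.0, scn.N_PQ, scn.S_PSI
    out = np.empty(len(t_grid_ms))
    t = 0.0
    i = 0
    n = len(t_grid_ms)
    while i < n:
        t_next = t_grid_ms[i]
        while t < t_next:
            dt = min(max(2e-3, 5e-3 * t) * substep_scale, t_next - t, 0.5)
            g = P / (P + eps_P)
            lam = scn.k_L + scn.k_AB * g
            c_ss = scn.k_L / lam
            activation = 1.0 - math.exp(-scn.k_FNR * t)
            drain = scn.k_FNR * activation * (scn.N_PQ - P) * (R / (R + eps_R))
            flow_in = scn.k_AB * C * g
            C = c_ss + (C - c_ss) * math.exp(-lam * dt)
            P = min(scn.N_PQ, max(0.0, P + (drain - flow_in) * dt))
            R = max(0.0, R - drain * dt)
            t += dt
        out[i] = C
        i += 1
    return out


def simulate_ojip(
    scenario: SyntheticScenario,
    time_grid_us: np.ndarray | None = None,
    *,
    label: str = "",
    group: str = "",
    substep_scale: float = 1.0,
) -> FluorescenceTransient:
    """Simulate one OJIP transient for a scenario on a µs time grid.

    The grid should span ~10 µs to ≥ 1 s (log-spaced recommended; the
    default mimics PEA sampling).  Identical (scenario, grid) inputs give
    bit-identical output: all randomness flows from ``scenario.seed``.
    """
    if time_grid_us is None:
        time_grid_us = default_time_grid_us()
    t_ms = np.asarray(time_grid_us, float) / 1e3

    C_blocked = 1.0 - np.exp(-scenario.k_L * t_ms)
    if scenario.B < 1.0:
        C_active = _integrate_active(scenario, t_ms, substep_scale)
    else:
        C_active = np.zeros_like(t_ms)
    C = scenario.B * C_blocked + (1.0 - scenario.B) * C_active

    atten = 1.0 - scenario.antenna_loss
    F_O = scenario.F_O_level * atten
    F_M = scenario.F_M_level * atten
    p = scenario.p
    F = F_O + (F_M - F_O) * C * (1.0 - p) / (1.0 - p * C)

    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        F = F * (1.0 + scenario.noise_sd * rng.standard_normal(F.shape))
        F = np.maximum(F, 0.0)
    return FluorescenceTransient(np.asarray(time_grid_us, float), F,
                                 label=label, group=group)


def simulate_mr(
    fast_amp: float = 0.04,
    k_fast: float = 0.05,
    slow_amp: float = 0.06,
    k_slow: float = 0.02,
    t_onset_slow: float = 400.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    time_grid_ms: np.ndarray | None = None,
    mr_level: float = 1000.0,
    label: str = "",
    group: str = "",
) -> MRTrace:
    """Two-phase modulated-reflection trace.

    MR/MR_0(t) = 1 − fast_amp·(1 − e^(−k_fast·(t − t_ref)))
                   + slow_amp·σ(k_slow·(t − t_onset_slow)),

    a fast oxidation decay plus a sigmoidal re-reduction rise (σ is the
    logistic function; rates in ms⁻¹, times in ms).  The fast phase is
    referenced to t_ref = 0.7 ms, the first reliable sample at which MR_0
    is defined, so the programmed amplitudes are expressed on the same
    scale the extractor reads.  ``slow_amp = 0`` reproduces the
    methyl-viologen-like plateau at the fast-phase floor.  Defaults place
    the minimum near 140 ms and the slow-phase completion by 2 s, as in
    measured traces.
    """
    if fast_amp < 0 or slow_amp < 0:
        raise ValueError("amplitudes must be ≥ 0")
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rates must be > 0")
    if mr_level <= 0:
        raise ValueError("mr_level must be > 0")
    if time_grid_ms is None:
        time_grid_ms = np.logspace(np.log10(0.7), np.log10(2000.0), 240)
    t = np.asarray(time_grid_ms, float)
    te = np.maximum(t - 0.7, 0.0)
    ratio = (
        1.0
        - fast_amp * (1.0 - np.exp(-k_fast * te))
        + slow_amp / (1.0 + np.exp(-k_slow * (t - t_onset_slow)))
    )
    mr = mr_level * ratio
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mr = mr * (1.0 + noise_sd * rng.standard_normal(mr.shape))
    mr = np.maximum(mr, np.finfo(float).tiny)
    return MRTrace(t, mr, label=label, group=group)


def generate_dose_series(
    I50: float = 60.0,
    hill_slope: float = 1.2,
    doses=(0.0, 10.0, 30.0, 60.0, 100.0, 200.0),
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    control_level: float = 100.0,
) -> DoseSeries:
    """Log-logistic dose series: response = control/(1 + (d/I50)^slope).

    At d = I50 the noise-free response is exactly half the control level.
    Noise is relative Gaussian per replicate, seeded.
    """
    if I50 <= 0 or hill_slope <= 0 or control_level <= 0:
        raise ValueError("I50, hill_slope and control_level must be > 0")
    if 0.0 not in tuple(float(d) for d in doses):
        raise ValueError("doses must include the 0 control")
    rng = np.random.default_rng(seed)
    resp = []
    for d in doses:
        mean = control_level / (1.0 + (d / I50) ** hill_slope) if d > 0 else control_level
        reps = mean * (1.0 + noise_sd * rng.standard_normal(replicates))
        resp.append(tuple(float(x) for x in np.maximum(reps, 0.0)))
    return DoseSeries(tuple(float(d) for d in doses), tuple(resp))


#: fixed boundary-adjacent diameters every generated table contains
_BOUNDARY_DIAMETERS = (0.99, 1.0, 3.0, 3.01)


def generate_lesion_table(seed: int = 0, n_species: int = 6) -> list[LesionRecord]:
    """Synthetic lesion-survey table (species are fabricated).

    A species × {100, 500, 1000} µM grid with diameters drawn so all three
    pathogenicity classes occur, plus one species carrying the four
    boundary-adjacent diameters 0.99/1.0/3.0/3.01 mm.  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(seed)
    records = []
    ranges = [(0.3, 0.9), (1.2, 2.8), (3.2, 7.0)]  # one per class
    for i in range(n_species):
        lo, hi = ranges[i % 3]
        base = rng.uniform(lo, hi)
        for j, conc in enumerate((100.0, 500.0, 1000.0)):
            d = round(float(base * (1.0 + 0.25 * j) + 0.05 * rng.standard_normal()), 2)
            d = max(d, 0.05)
            records.append(
                LesionRecord(f"synthetic_sp_{i + 1:02d}", conc, d,
                             classify_pathogenicity(d))
            )
    for k, d in enumerate(_BOUNDARY_DIAMETERS):
        records.append(
            LesionRecord("synthetic_boundary", (100.0, 500.0, 1000.0)[k % 3] + k, d,
                         classify_pathogenicity(d))
        )
    return records
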