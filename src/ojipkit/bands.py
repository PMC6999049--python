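"""Double-normalized kinetics and treated-minus-control difference bands.

Normalizing the fluorescence rise between pairs of landmarks exposes
phases that the raw curve hides:

    V_t  = (F_t − F_O)/(F_M − F_O)     full rise
    W_OK = (F_t − F_O)/(F_K − F_O)     O-K phase; ΔW_OK is the L-band
                                       (~150 µs, antenna connectivity)
    W_OJ = (F_t − F_O)/(F_J − F_O)     O-J phase; ΔW_OJ is the K-band
                                       (~300 µs, OEC inactivation)
    W_OI = (F_t − F_O)/(F_I − F_O)     I-P amplitude read from the part ≥ 1
    W_IP = (F_t − F_I)/(F_P − F_I)     I-P rise on 30-530 ms; its half-time
                                       tracks the PSI end-acceptor
                                       re-reduction rate

Difference curves are treated minus control on a common (union) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .induction import StepValues
from .transients import FluorescenceTransient

__all__ = [
    "NormalizedCurves",
    "BandCurves",
    "normalize_curves",
    "difference_kinetics",
    "wip_half_time",
    "L_BAND_WINDOW_US",
    "K_BAND_WINDOW_US",
    "J_REGION_US",
    "WIP_RANGE_MS",
]

#: analysis windows (µs): the L and K bands bracket their defining steps
L_BAND_WINDOW_US = (100.0, 300.0)
K_BAND_WINDOW_US = (200.0, 500.0)
J_REGION_US = (1_000.0, 3_000.0)
#: W_IP analysis range (ms)
WIP_RANGE_MS = (30.0, 530.0)


@dataclass(frozen=True)
class NormalizedCurves:
    """Normalized kinetics of one transient on its own time grid (µs).

    Curves whose defining denominator vanished are all-NaN (flagged in
    ``invalid``); the others are still computed.
    """

    time: np.ndarray
    V_t: np.ndarray
    W_OK: np.ndarray
    W_OJ: np.ndarray
    W_OI: np.ndarray
    W_IP: np.ndarray
    steps: StepValues
    label: str = ""
    group: str = ""

    @property
    def invalid(self) -> tuple:
        out = []
        for name in ("V_t", "W_OK", "W_OJ", "W_OI", "W_IP"):
            if not np.any(np.isfinite(getattr(self, name))):
                out.append(name)
        return tuple(out)

    def woi_tail(self):
        """(time_ms, W_OI) restricted to W_OI ≥ 1 within 30-530 ms — the
        part whose span reflects the PSI end-acceptor pool size."""
        t_ms = self.time / 1e3
        m = (t_ms >= WIP_RANGE_MS[0]) & (t_ms <= WIP_RANGE_MS[1]) & (self.W_OI >= 1.0)
        return t_ms[m], self.W_OI[m]


def _safe_norm(F, lo, hi):
    denom = hi - lo
    if denom == 0:
        return np.full_like(F, np.nan, dtype=float)
    return (F - lo) / denom


def normalize_curves(
    transient: FluorescenceTransient, steps: StepValues
) -> NormalizedCurves:
    """All five normalized curves on the transient's own grid."""
    F = transient.F.astype(float)
    return NormalizedCurves(
        time=transient.time,
        V_t=_safe_norm(F, steps.F_O, steps.F_M),
        W_OK=_safe_norm(F, steps.F_O, steps.F_K),
        W_OJ=_safe_norm(F, steps.F_O, steps.F_J),
        W_OI=_safe_norm(F, steps.F_O, steps.F_I),
        W_IP=_safe_norm(F, steps.F_I, steps.F_M),
        steps=steps,
        label=transient.label,
        group=transient.group,
    )


def _window_extremum(time, curve, window):
    """(value, time) of the largest-magnitude finite value inside window."""
    m = (time >= window[0]) & (time <= window[1]) & np.isfinite(curve)
    if not np.any(m):
        return float("nan"), float("nan")
    idx = np.flatnonzero(m)
    k = idx[int(np.argmax(np.abs(curve[idx])))]
    return float(curve[k]), float(time[k])


@dataclass(frozen=True)
class BandCurves:
    """Treated-minus-control difference kinetics on the union grid (µs).

    Band summaries give the signed extremum (largest magnitude) and its
    time within the L-band window (ΔW_OK), the K-band window (ΔW_OJ), and
    the J-region of ΔV_t; ``dVt_at_J`` is ΔV_t exactly at 2 ms.
    """

    time: np.ndarray
    dV_t: np.ndarray
    dW_OK: np.ndarray
    dW_OJ: np.ndarray
    L_band: float
    L_band_time: float
    K_band: float
    K_band_time: float
    J_peak: float
    J_peak_time: float
    dVt_at_J: float


def _resample(time_src, curve, grid):
    finite = np.isfinite(curve)
    if finite.sum() < 2:
        return np.full(grid.shape, np.nan)
    return np.interp(grid, time_src[finite], curve[finite])


def difference_kinetics(
    treated: NormalizedCurves, control: NormalizedCurves
) -> BandCurves:
    """ΔV_t, ΔW_OK, ΔW_OJ and their band summaries.

    Both samples are resampled onto the union of their grids restricted to
    the overlapping time range; disjoint ranges are an error.
    """
    lo = max(treated.time[0], control.time[0])
    hi = min(treated.time[-1], control.time[-1])
    if lo >= hi:
        raise ValueError("difference_kinetics: time ranges do not overlap")
    grid = np.union1d(treated.time, control.time)
    grid = grid[(grid >= lo) & (grid <= hi)]

    dV = _resample(treated.time, treated.V_t, grid) - _resample(
        control.time, control.V_t, grid
    )
    dOK = _resample(treated.time, treated.W_OK, grid) - _resample(
        control.time, control.W_OK, grid
    )
    dOJ = _resample(treated.time, treated.W_OJ, grid) - _resample(
        control.time, control.W_OJ, grid
    )
    Lv, Lt = _window_extremum(grid, dOK, L_BAND_WINDOW_US)
    Kv, Kt = _window_extremum(grid, dOJ, K_BAND_WINDOW_US)
    Jv, Jt = _window_extremum(grid, dV, J_REGION_US)
    dVt_2ms = float(np.interp(2_000.0, grid, dV)) if lo <= 2_000.0 <= hi else float("nan")
    return BandCurves(
        time=grid, dV_t=dV, dW_OK=dOK, dW_OJ=dOJ,
        L_band=Lv, L_band_time=Lt, K_band=Kv, K_band_time=Kt,
        J_peak=Jv, J_peak_time=Jt, dVt_at_J=dVt_2ms,
    )


def wip_half_time(curves: NormalizedCurves) -> float:
    """Time (ms) of the first upward crossing of W_IP = 0.5 in 30-530 ms.

    Linear interpolation between the bracketing samples; NaN when the
    curve never crosses 0.5 in range (flagged not-a-value), since then no
    half-rise of the I-P phase exists to time.
    """
    t_ms = curves.time / 1e3
    m = (t_ms >= WIP_RANGE_MS[0]) & (t_ms <= WIP_RANGE_MS[1]) & np.isfinite(curves.W_IP)
    t, w = t_ms[m], curves.W_IP[m]
    if t.size < 2:
        return float("nan")
    for i in range(1, t.size):
        if w[i - 1] < 0.5 <= w[i]:
            frac = (0.5 - w[i - 1]) / (w[i] - w[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
        if w[i - 1] == 0.5 and w[i] > 0.5:
            return float(t[i - 1])
    return float("nan")
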