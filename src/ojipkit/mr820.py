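"""Feature extraction for modulated 820 nm reflection (MR) kinetics.

Under actinic light the MR signal, a proxy for the redox state of
plastocyanin and the PSI reaction center P700, shows two phases: a fast
decrease from MR_0 (the first reliable sample, 0.7 ms) to a minimum MR_min
(net oxidation of PC and P700, reached between ~10 and 200 ms), then a
slow rise to MR_max by 1-2 s (net re-reduction by electrons arriving from
PSII through the intersystem chain).  The features are amplitude ratios,
so they are invariant to the instrument's arbitrary signal scale:

    fast_amplitude = (MR_0 − MR_min)/MR_0
    slow_amplitude = (MR_max − MR_min)/MR_0

A vanishing slow amplitude means the two photosystems are disconnected
(DCMU-like full block, or a PSI-side acceptor like methyl viologen keeping
the signal at MR_min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .transients import MRTrace, value_at

__all__ = ["MRFeatures", "extract_mr_features"]

#: below this relative slow amplitude the re-reduction phase is flagged absent
SLOW_PHASE_EPS = 1e-3


@dataclass(frozen=True)
class MRFeatures:
    """Characteristic parameters of one MR trace (times in ms)."""

    MR_0: float
    MR_min: float
    t_min: float
    MR_max: float
    t_max: float
    fast_amplitude: float
    slow_amplitude: float
    slow_phase_absent: bool
    normalized_time: np.ndarray
    normalized_MR: np.ndarray  # MR/MR_0, as conventionally plotted


def extract_mr_features(
    trace: MRTrace,
    *,
    fast_window: tuple[float, float] = (0.7, 200.0),
    slow_end: float = 2000.0,
    smooth_window: int = 0,
) -> MRFeatures:
    """Extract MR_0, MR_min, MR_max and the two phase amplitudes.

    MR_0 is interpolated at 0.7 ms; MR_min is the global minimum within
    ``fast_window`` (default 0.7-200 ms, upper bound configurable since
    the balance point varies); MR_max the maximum after t_min up to
    ``slow_end``.  ``smooth_window`` > 1 applies a moving median before
    the extremum search (MR_min is an extremum statistic, so noise biases
    it low); default off.
    """
    t = trace.time
    if t[0] > fast_window[0] or t[-1] < slow_end:
        raise ValueError(
            f"trace range [{t[0]:g}, {t[-1]:g}] ms does not cover "
            f"[{fast_window[0]:g}, {slow_end:g}] ms"
        )
    mr = trace.MR.astype(float)
    if smooth_window and smooth_window > 1:
        mr = median_filter(mr, size=int(smooth_window), mode="nearest")

    mr0 = value_at(MRTrace(t, np.maximum(mr, np.finfo(float).tiny),
                           label=trace.label, group=trace.group), fast_window[0])

    in_fast = (t >= fast_window[0]) & (t <= fast_window[1])
    i_fast = np.flatnonzero(in_fast)
    k_min = i_fast[int(np.argmin(mr[i_fast]))]
    mr_min, t_min = float(mr[k_min]), float(t[k_min])

    after = np.flatnonzero((t > t_min) & (t <= slow_end))
    if after.size:
        k_max = after[int(np.argmax(mr[after]))]
        mr_max, t_max = float(mr[k_max]), float(t[k_max])
        mr_max = max(mr_max, mr_min)
    else:  # t_min at the very end: no slow phase observable
        mr_max, t_max = mr_min, t_min

    fast_amp = (mr0 - mr_min) / mr0
    slow_amp = (mr_max - mr_min) / mr0
    return MRFeatures(
        MR_0=float(mr0), MR_min=mr_min, t_min=t_min,
        MR_max=mr_max, t_max=t_max,
        fast_amplitude=float(fast_amp),
        slow_amplitude=float(slow_amp),
        slow_phase_absent=bool(slow_amp <= SLOW_PHASE_EPS),
        normalized_time=t.copy(),
        normalized_MR=trace.MR / mr0,
    )
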