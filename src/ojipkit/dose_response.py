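"""Percent inhibition, I_50 estimation, and lesion pathogenicity scoring.

I_50 is the inhibitor concentration halving a measured activity (oxygen
evolution rate, electron transport rate, or any derived parameter).  The
estimator fits a two-parameter log-logistic curve

    response(d) = U / (1 + (d / I50)^h)

with the upper asymptote U fixed at the control (dose 0) mean and the
lower at 0, by least squares over (I50, h).  A model-free linear
interpolation of mean inhibition vs log-dose across the 50% crossing is
always computed alongside as a cross-check.

Lesion phytotoxicity is scored from the necrotic/chlorotic lesion
diameter: "+" below 1.0 mm (low), "++" from 1.0 to 3.0 mm inclusive
(moderate), "+++" above 3.0 mm (high susceptibility).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseSeries",
    "LesionRecord",
    "I50Fit",
    "percent_inhibition",
    "fit_I50",
    "classify_pathogenicity",
    "load_lesion_survey",
]


@dataclass(frozen=True)
class DoseSeries:
    """Replicated responses at each inhibitor concentration (µM).

    ``responses[i]`` holds the replicate measurements at ``doses[i]``; a
    control (dose 0) with at least one replicate is required.
    """

    doses: tuple
    responses: tuple  # tuple of tuples, aligned with doses

    def __post_init__(self):
        doses = tuple(float(d) for d in self.doses)
        resp = tuple(tuple(float(x) for x in r) for r in self.responses)
        if len(doses) != len(resp):
            raise ValueError("doses and responses must align")
        if any(d < 0 for d in doses):
            raise ValueError("doses must be non-negative")
        if 0.0 not in doses:
            raise ValueError("a dose-0 control is required")
        if any(len(r) == 0 for r in resp):
            raise ValueError("every dose needs at least one replicate")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", resp)

    @property
    def control_mean(self) -> float:
        i = self.doses.index(0.0)
        return float(np.mean(self.responses[i]))

    @classmethod
    def from_long(cls, df: pd.DataFrame, dose_col="dose", response_col="response"):
        g = df.groupby(dose_col)[response_col].apply(list).sort_index()
        return cls(tuple(g.index), tuple(tuple(v) for v in g.values))


@dataclass(frozen=True)
class LesionRecord:
    """One (species, concentration) row of a leaf-lesion phytotoxicity assay."""

    species: str
    concentration: float  # µM
    diameter: float       # mm, mean lesion diameter
    level: str            # "+", "++", "+++"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("lesion diameter must be > 0")
        if self.level not in ("+", "++", "+++"):
            raise ValueError(f"unknown pathogenicity level {self.level!r}")


def percent_inhibition(series: DoseSeries) -> pd.DataFrame:
    """Mean inhibition % and SE per dose: 100·(1 − mean(dose)/mean(control))."""
    ctrl = series.control_mean
    if ctrl <= 0:
        raise ValueError("control mean must be > 0")
    rows = []
    for d, resp in zip(series.doses, series.responses):
        r = np.asarray(resp, float)
        mean_inh = 100.0 * (1.0 - r.mean() / ctrl)
        se = 100.0 * r.std(ddof=1) / ctrl / np.sqrt(r.size) if r.size > 1 else float("nan")
        rows.append({"dose": d, "inhibition_pct": mean_inh, "se_pct": se})
    return pd.DataFrame(rows).sort_values("dose", ignore_index=True)


@dataclass(frozen=True)
class I50Fit:
    """I_50 estimate with fit diagnostics and the interpolation cross-check.

    ``I50`` is NaN with ``flag`` set when no 50% crossing is estimable
    (e.g. no dose inhibits past 50%, or responses increase with dose).
    """

    I50: float
    hill_slope: float
    sse: float
    I50_interpolated: float
    flag: str = ""


def _interpolate_i50(inh: pd.DataFrame) -> float:
    """Model-free I_50: linear interpolation of mean inhibition vs log-dose
    across the first upward 50% crossing."""
    d = inh[inh["dose"] > 0].sort_values("dose")
    doses = d["dose"].to_numpy(float)
    y = d["inhibition_pct"].to_numpy(float)
    for i in range(y.size):
        if y[i] >= 50.0:
            if i == 0:
                return float(doses[0]) if y[0] == 50.0 else float("nan")
            x0, x1 = np.log(doses[i - 1]), np.log(doses[i])
            frac = (50.0 - y[i - 1]) / (y[i] - y[i - 1])
            return float(np.exp(x0 + frac * (x1 - x0)))
    return float("nan")


def fit_I50(series: DoseSeries) -> I50Fit:
    """Two-parameter log-logistic I_50 fit (upper asymptote = control mean).

    Requires nonzero doses with responses on both sides of half-control;
    otherwise the fit is flagged and only the (possibly NaN) interpolation
    estimate is meaningful.
    """
    ctrl = series.control_mean
    if ctrl <= 0:
        raise ValueError("control mean must be > 0")
    inh = percent_inhibition(series)
    i50_interp = _interpolate_i50(inh)

    doses, ys = [], []
    for d, resp in zip(series.doses, series.responses):
        if d > 0:
            for r in resp:
                doses.append(d)
                ys.append(r)
    doses = np.asarray(doses, float)
    ys = np.asarray(ys, float)

    means = inh[inh["dose"] > 0]["inhibition_pct"].to_numpy(float)
    if means.size == 0 or np.all(means < 50.0):
        return I50Fit(float("nan"), float("nan"), float("nan"), i50_interp,
                      flag="no inhibition beyond 50%")
    if np.all(means > 50.0):
        flag = "all doses beyond 50% inhibition; extrapolated"
    elif means.size < 3:
        flag = "fewer than 3 nonzero doses; fit poorly constrained"
    else:
        flag = ""

    def resid(p):
        log_i50, log_h = p
        return ctrl / (1.0 + (doses / np.exp(log_i50)) ** np.exp(log_h)) - ys

    x0 = np.array([np.log(i50_interp if np.isfinite(i50_interp) else np.median(doses)),
                   0.0])
    sol = least_squares(resid, x0, method="lm", max_nfev=10_000)
    i50 = float(np.exp(sol.x[0]))
    return I50Fit(
        I50=i50,
        hill_slope=float(np.exp(sol.x[1])),
        sse=float(np.sum(sol.fun**2)),
        I50_interpolated=i50_interp,
        flag=flag,
    )


def classify_pathogenicity(diameter: float) -> str:
    """Pathogenicity symbol from lesion diameter (mm).

    "+" for d < 1.0 (low susceptibility, chlorotic spots), "++" for
    1.0 ≤ d ≤ 3.0 (moderate), "+++" for d > 3.0 (highly susceptible,
    necrotic lesions).  Both cutoffs are strict on the outer classes.
    """
    d = float(diameter)
    if d <= 0:
        raise ValueError("lesion diameter must be > 0")
    if d < 1.0:
        return "+"
    if d <= 3.0:
        return "++"
    return "+++"


def load_lesion_survey() -> list[LesionRecord]:
    """The bundled 10-species × 3-concentration gliotoxin lesion survey
    (published mean diameters and printed pathogenicity levels)."""
    with resources.files("ojipkit.data").joinpath("lesion_survey.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        LesionRecord(r.species, float(r.concentration_uM), float(r.diameter_mm), r.level)
        for r in df.itertuples()
    ]
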