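"""Manifest-driven batch analysis: the full treated-vs-control workflow.

One delimited manifest lists every input trace with its treatment group
and kind; the pipeline derives a per-sample JIP record for each OJIP
trace, compares every treated group against the control (Q_B-occupancy
R_J, Q_A-reducing fraction, spider-plot ratios, band difference curves,
W_IP half-times), extracts MR features, and fits dose-response series.
Outputs are deterministic given inputs + config + seed; per-sample
failures are logged and skipped, and the run fails only when a whole
group is empty.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .bands import difference_kinetics, normalize_curves, wip_half_time
from .dose_response import DoseSeries, classify_pathogenicity, fit_I50, percent_inhibition
from .induction import compute_areas, extract_steps
from .jip import compare_groups, compute_jip
from .mr820 import extract_mr_features
from .transients import Dialect, read_mr_trace, read_transient

__all__ = ["RunConfig", "RunResult", "run_pipeline", "correlation_report"]

#: parameter pairs of the standard correlation report
CORRELATION_PAIRS = (
    ("V_J", "phi_Eo"),
    ("PI_ABS", "phi_Eo"),
    ("Sm_over_tFM", "phi_Eo"),
    ("Sm_over_tFM", "R_J"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run.

    ``manifest`` is a TSV with columns path, group, type (ojip | mr |
    dose | lesion); paths resolve relative to the manifest's directory.
    ``control_group`` names the group every other group is compared to.
    """

    manifest: str
    control_group: str = "mock"
    interpolation: str = "linear"
    abs_cs_proxy: str = "F_O"
    time_unit: str = "ms"
    mr_fast_window: tuple = (0.7, 200.0)
    mr_slow_end: float = 2000.0
    output_dir: str | None = None
    seed: int = 0
    average_curves: bool = False  # opt-in: JIP record of the group-mean curve

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    per_sample: pd.DataFrame
    groups: pd.DataFrame
    curves: pd.DataFrame
    mr_features: pd.DataFrame
    dose: pd.DataFrame
    lesions: pd.DataFrame
    log: list = field(default_factory=list)


def _jip_row(transient, cfg):
    steps = extract_steps(transient, rule=cfg.interpolation)
    areas = compute_areas(transient, steps)
    result = compute_jip(steps, areas, abs_cs_proxy=cfg.abs_cs_proxy)
    curves = normalize_curves(transient, steps)
    row = {"label": transient.label, "group": transient.group}
    row.update(
        F_O=steps.F_O, F_L=steps.F_L, F_K=steps.F_K, F_J=steps.F_J,
        F_I=steps.F_I, F_M=steps.F_M, t_FM=steps.t_FM, Area=areas.Area,
    )
    row.update(result.as_dict())
    row["W_IP_half_time"] = wip_half_time(curves)
    return row, result, curves


def _mean_curve(curve_list):
    """Pointwise mean of normalized curves on the union grid."""
    grid = curve_list[0].time
    for c in curve_list[1:]:
        grid = np.union1d(grid, c.time)
    lo = max(c.time[0] for c in curve_list)
    hi = min(c.time[-1] for c in curve_list)
    grid = grid[(grid >= lo) & (grid <= hi)]

    def avg(attr):
        return np.mean([np.interp(grid, c.time, getattr(c, attr)) for c in curve_list], axis=0)

    from .bands import NormalizedCurves

    return NormalizedCurves(
        time=grid, V_t=avg("V_t"), W_OK=avg("W_OK"), W_OJ=avg("W_OJ"),
        W_OI=avg("W_OI"), W_IP=avg("W_IP"), steps=curve_list[0].steps,
        label="group-mean", group=curve_list[0].group,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the batch analysis described by ``config``.

    Returns all result tables; additionally writes them as TSV under
    ``config.output_dir`` when set (per_sample.tsv, groups.tsv,
    curves.tsv, mr_features.tsv, dose.tsv, lesions.tsv, run_log.txt).
    """
    mpath = Path(config.manifest)
    manifest = pd.read_csv(mpath, sep="\t")
    for col in ("path", "group", "type"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    base = mpath.parent
    dialect = Dialect(time_unit=config.time_unit)
    log = [f"ojipkit {__version__} run, config {config.digest()}, seed {config.seed}"]

    sample_rows, jip_by_group, curves_by_group = [], {}, {}
    mr_rows, dose_rows, lesion_rows = [], [], []
    for rec in manifest.itertuples():
        path = base / rec.path
        try:
            if rec.type == "ojip":
                tr = read_transient(path, dialect, label=str(rec.path), group=rec.group)
                row, result, curves = _jip_row(tr, config)
                sample_rows.append(row)
                jip_by_group.setdefault(rec.group, []).append(result)
                curves_by_group.setdefault(rec.group, []).append(curves)
            elif rec.type == "mr":
                mtr = read_mr_trace(path, dialect, label=str(rec.path), group=rec.group)
                f = extract_mr_features(
                    mtr, fast_window=config.mr_fast_window, slow_end=config.mr_slow_end
                )
                mr_rows.append({
                    "label": mtr.label, "group": rec.group, "MR_0": f.MR_0,
                    "MR_min": f.MR_min, "t_min": f.t_min, "MR_max": f.MR_max,
                    "fast_amplitude": f.fast_amplitude,
                    "slow_amplitude": f.slow_amplitude,
                    "slow_phase_absent": f.slow_phase_absent,
                })
            elif rec.type == "dose":
                df = pd.read_csv(path, sep="\t")
                series = DoseSeries.from_long(df)
                fit = fit_I50(series)
                inh = percent_inhibition(series)
                for r in inh.itertuples():
                    dose_rows.append({
                        "label": str(rec.path), "group": rec.group,
                        "dose": r.dose, "inhibition_pct": r.inhibition_pct,
                        "se_pct": r.se_pct, "I50": fit.I50,
                        "I50_interpolated": fit.I50_interpolated,
                        "hill_slope": fit.hill_slope, "flag": fit.flag,
                    })
            elif rec.type == "lesion":
                df = pd.read_csv(path, sep="\t")
                for r in df.itertuples():
                    d = float(r.diameter_mm)
                    lesion_rows.append({
                        "species": r.species,
                        "concentration_uM": float(r.concentration_uM),
                        "diameter_mm": d,
                        "level": classify_pathogenicity(d),
                    })
            else:
                raise ValueError(f"unknown sample type {rec.type!r}")
        except Exception as exc:  # per-sample failures are logged, not fatal
            log.append(f"SKIP {rec.path} ({rec.type}): {exc}")

    if jip_by_group and config.control_group not in jip_by_group:
        raise ValueError(
            f"control group {config.control_group!r} has no valid OJIP samples"
        )

    group_rows, curve_frames = [], []
    if jip_by_group:
        ctrl_results = jip_by_group[config.control_group]
        ctrl_curves = _mean_curve(curves_by_group[config.control_group])
        for group, results in jip_by_group.items():
            if group == config.control_group:
                continue
            comp = compare_groups(results, ctrl_results)
            gcurves = _mean_curve(curves_by_group[group])
            bandc = difference_kinetics(gcurves, ctrl_curves)
            ht = [wip_half_time(c) for c in curves_by_group[group]]
            row = {
                "group": group, "control": config.control_group,
                "n_treated": len(results), "n_control": len(ctrl_results),
                "R_J": comp.R_J, "R_J_raw": comp.R_J_raw,
                "QA_reducing_fraction": comp.QA_reducing_fraction,
                "non_QA_reducing_fraction": comp.non_QA_reducing_fraction,
                "L_band": bandc.L_band, "L_band_time_us": bandc.L_band_time,
                "K_band": bandc.K_band, "K_band_time_us": bandc.K_band_time,
                "J_peak": bandc.J_peak, "dVt_at_2ms": bandc.dVt_at_J,
                "W_IP_half_time_mean": float(np.nanmean(ht)) if ht else float("nan"),
            }
            row.update({f"rel_{k}": v for k, v in comp.relative_params.items()})
            group_rows.append(row)
            curve_frames.append(pd.DataFrame({
                "sample": f"{group}-vs-{config.control_group}",
                "curve": "dV_t", "time_us": bandc.time, "value": bandc.dV_t,
            }))
        if not group_rows:
            log.append("WARNING: control group only; no comparisons computed")
        for group, clist in curves_by_group.items():
            for i, c in enumerate(clist):
                for name in ("V_t", "W_OK", "W_OJ", "W_OI", "W_IP"):
                    curve_frames.append(pd.DataFrame({
                        "sample": c.label or f"{group}_{i}", "curve": name,
                        "time_us": c.time, "value": getattr(c, name),
                    }))

    result = RunResult(
        per_sample=pd.DataFrame(sample_rows),
        groups=pd.DataFrame(group_rows),
        curves=(pd.concat(curve_frames, ignore_index=True)
                if curve_frames else pd.DataFrame()),
        mr_features=pd.DataFrame(mr_rows),
        dose=pd.DataFrame(dose_rows),
        lesions=pd.DataFrame(lesion_rows),
        log=log,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("per_sample", "groups", "curves", "mr_features", "dose", "lesions"):
            df = getattr(result, name)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.9g")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return result


def correlation_report(series_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise linear fits across a concentration series.

    ``series_table`` has one row per concentration level with columns
    V_J, PI_ABS, Sm_over_tFM, phi_Eo and R_J (e.g. group means assembled
    from per-sample tables plus the group R_J).  Returns slope, intercept
    and Pearson r for each standard pair; zero-variance input yields NaN
    r with a flag.  Requires at least 3 levels.
    """
    if len(series_table) < 3:
        raise ValueError("correlation_report needs ≥ 3 concentration levels")
    rows = []
    for x_name, y_name in CORRELATION_PAIRS:
        if x_name not in series_table.columns or y_name not in series_table.columns:
            continue
        x = series_table[x_name].to_numpy(float)
        y = series_table[y_name].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"x": x_name, "y": y_name, "slope": float("nan"),
                         "intercept": float("nan"), "pearson_r": float("nan"),
                         "n": int(x.size), "flag": "degenerate (zero variance or <3 points)"})
            continue
        fit = stats.linregress(x, y)
        rows.append({"x": x_name, "y": y_name, "slope": fit.slope,
                     "intercept": fit.intercept, "pearson_r": fit.rvalue,
                     "n": int(x.size), "flag": ""})
    return pd.DataFrame(rows)
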