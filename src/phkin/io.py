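"""Tidy CSV/JSON dialects for curves, estimates, tables and fit results.

One observation per row everywhere; plate-reader exports vary by vendor,
so a canonical long format with import adapters is the interface.  All
writers round-trip: ``read(write(x)) == x`` up to float representation.
Malformed rows are reported with their row number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import PHTrace
from .slope import ProgressionCurve, VmaxEstimate

CURVE_COLUMNS = ["enzyme", "ph", "dilution_factor", "replicate", "phase",
                 "time_s", "absorbance", "wavelength_nm", "direction"]


class ParseError(ValueError):
    """A file does not conform to its dialect."""


def write_curves(curves: list[ProgressionCurve], path: str | Path) -> None:
    """Long-format progression curve CSV (reaction + background phases)."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "enzyme": c.enzyme_id, "ph": c.ph,
            "dilution_factor": c.dilution_factor, "replicate": c.replicate,
            "phase": "reaction", "time_s": c.times * 60.0,
            "absorbance": c.absorbance, "wavelength_nm": c.wavelength,
            "direction": c.direction,
        }))
        if c.background is not None:
            bt, ba = c.background
            frames.append(pd.DataFrame({
                "enzyme": c.enzyme_id, "ph": c.ph,
                "dilution_factor": c.dilution_factor, "replicate": c.replicate,
                "phase": "background", "time_s": bt * 60.0,
                "absorbance": ba, "wavelength_nm": c.wavelength,
                "direction": c.direction,
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves(path: str | Path) -> list[ProgressionCurve]:
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    curves = []
    keys = ["enzyme", "ph", "dilution_factor", "replicate"]
    for (enzyme, ph, df_, rep), grp in df.groupby(keys, sort=True):
        rxn = grp[grp["phase"] == "reaction"]
        bg = grp[grp["phase"] == "background"]
        if rxn.empty:
            raise ParseError(
                f"{path}: no reaction phase for {enzyme} pH {ph} DF {df_} "
                f"rep {rep}"
            )
        t = rxn["time_s"].to_numpy() / 60.0
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = rxn.index[bad[0] + 1]
            raise ParseError(
                f"{path}: non-monotone time at row {row + 2} "
                f"({enzyme} pH {ph} DF {df_} rep {rep})"
            )
        background = None
        if not bg.empty:
            background = (bg["time_s"].to_numpy() / 60.0,
                          bg["absorbance"].to_numpy())
        curves.append(ProgressionCurve(
            enzyme_id=str(enzyme), ph=float(ph), dilution_factor=float(df_),
            replicate=int(rep), times=t,
            absorbance=rxn["absorbance"].to_numpy(), background=background,
            wavelength=float(rxn["wavelength_nm"].iloc[0]),
            direction=str(rxn["direction"].iloc[0]),
        ))
    return curves


def write_estimates(estimates: list[VmaxEstimate], path: str | Path) -> None:
    pd.DataFrame([{
        "enzyme": e.enzyme_id, "ph": e.ph, "method": e.method,
        "vmax": e.value, "spread": e.spread, "r_squared": e.r_squared,
        "dfs_used": ";".join(str(d) for d in e.dilution_factors_used),
        "flagged": e.flagged,
    } for e in estimates]).to_csv(path, index=False)


def read_estimates(path: str | Path) -> list[VmaxEstimate]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        dfs = ([float(x) for x in str(row["dfs_used"]).split(";")]
               if pd.notna(row["dfs_used"]) and str(row["dfs_used"]) else [])
        out.append(VmaxEstimate(
            enzyme_id=str(row["enzyme"]), ph=float(row["ph"]),
            method=str(row["method"]), value=float(row["vmax"]),
            spread=float(row["spread"]), r_squared=float(row["r_squared"]),
            dilution_factors_used=dfs, flagged=bool(row["flagged"]),
        ))
    return out


def write_titration(table: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(table, columns=["ratio", "ph"]).to_csv(path, index=False)


def read_titration(table_path: str | Path) -> np.ndarray:
    df = pd.read_csv(table_path)
    for col in ("ratio", "ph"):
        if col not in df.columns:
            raise ParseError(f"{table_path}: missing column {col!r}")
    return df[["ratio", "ph"]].to_numpy(dtype=float)


def write_trace(trace: PHTrace, path: str | Path) -> None:
    pd.DataFrame({"time_min": trace.times, "ph": trace.ph}).to_csv(
        path, index=False)


def read_trace(path: str | Path, label: str = "") -> PHTrace:
    df = pd.read_csv(path)
    for col in ("time_min", "ph"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return PHTrace(df["time_min"].to_numpy(dtype=float),
                   df["ph"].to_numpy(dtype=float), label=label)


def fit_result_to_dict(res) -> dict:
    """JSON-serializable record of a ProgressionFitResults."""
    return {
        "enzyme": res.model.scheme.enzyme_id,
        "layout": res.model.layout,
        "keq_mode": res.model.keq_mode,
        "lambda": res.model.lam,
        "vmax": {str(ph): v for ph, v in res.vmax.items()},
        "vmax_ci": {str(ph): v for ph, v in res.vmax_ci.items()},
        "km": dict(res.km),
        "km_ci": dict(res.km_ci),
        "sse": res.sse,
        "sse_by_ph": {str(ph): v for ph, v in res.sse_by_ph.items()},
        "regularization_penalty": res.regularization_penalty,
        "n_iterations": res.n_iterations,
        "converged": res.converged,
        "n_parameters": res.n_parameters,
        "n_residuals": res.n_residuals,
        "integration_failures": res.integration_failures,
    }


def write_fit_result(res, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(res), indent=2))


def read_fit_result(path: str | Path) -> dict:
    data = json.loads(Path(path).read_text())
    for key in ("vmax", "vmax_ci", "sse_by_ph"):
        data[key] = {float(k): v for k, v in data.get(key, {}).items()}
    return data


def write_fit_csv(res, path: str | Path) -> None:
    """Tidy per-pH Vmax table: enzyme, ph, vmax, ci_halfwidth, sse."""
    pd.DataFrame([{
        "enzyme": res.model.scheme.enzyme_id, "ph": ph, "vmax": v,
        "ci_halfwidth": res.vmax_ci.get(ph, float("nan")),
        "sse": res.sse_by_ph.get(ph, float("nan")),
    } for ph, v in sorted(res.vmax.items())]).to_csv(path, index=False)


def write_truth(study, path: str | Path) -> None:
    """Ground-truth sidecar JSON for a synthetic study."""
    Path(path).write_text(json.dumps({
        "seed": study.seed,
        "design": {
            "ph_grid": list(study.design.ph_grid),
            "dilution_factors": list(study.design.dilution_factors),
            "replicates": study.design.replicates,
            "sampling_interval_s": study.design.sampling_interval_s,
            "reaction_minutes": study.design.reaction_minutes,
            "background_minutes": study.design.background_minutes,
            "sigma_au": study.design.sigma_au,
            "drift_au_per_min": study.design.drift_au_per_min,
        },
        "vmax": {e: {str(ph): v for ph, v in d.items()}
                 for e, d in study.truth_vmax.items()},
        "km": study.truth_km,
    }, indent=2))


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return data
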