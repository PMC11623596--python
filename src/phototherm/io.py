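"""Plain-text I/O: trace/rate/melt CSV schemas and JSON result export.

Trace CSVs carry their metadata in a leading ``# key = value`` header block
followed by ``time_s,absorbance`` columns; rate and melt tables are flat
CSVs.  Result objects are exported as JSON with point estimates, standard
errors, CIs and provenance (n_boot, seed) but without the raw bootstrap
vectors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    AllosteryEnergetics,
    EyringFit,
    KineticTrace,
    MeltCurve,
    MeltFit,
    RateMeasurement,
)

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_rate_csv",
    "read_rate_csv",
    "write_melt_csv",
    "read_melt_csv",
    "result_to_dict",
    "write_results_json",
]

PathLike = Union[str, Path]


def write_trace_csv(trace: KineticTrace, path: PathLike) -> None:
    path = Path(path)
    meta = {
        "temp_C": trace.temperature,
        "condition": trace.condition,
        "enzyme_conc_M": trace.enzyme_conc,
        "epsilon_mM_cm": trace.epsilon,
        "pathlength_cm": trace.pathlength,
        "wavelength_nm": trace.wavelength_nm,
    }
    with path.open("w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        fh.write("time_s,absorbance\n")
        for t, a in zip(trace.time, trace.absorbance):
            fh.write(f"{float(t)!r},{float(a)!r}\n")


def read_trace_csv(path: PathLike) -> KineticTrace:
    path = Path(path)
    meta = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    frame = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    return KineticTrace(
        time=frame["time_s"].to_numpy(),
        absorbance=frame["absorbance"].to_numpy(),
        temperature=float(meta.get("temp_C", 25.0)),
        condition=meta.get("condition", "dark"),
        enzyme_conc=float(meta.get("enzyme_conc_M", 100e-9)),
        epsilon=float(meta.get("epsilon_mM_cm", 13.2)),
        pathlength=float(meta.get("pathlength_cm", 1.0)),
        wavelength_nm=float(meta.get("wavelength_nm", 340.0)),
    )


def write_rate_csv(measurements: Sequence[RateMeasurement], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "variant": [m.variant for m in measurements],
            "condition": [m.condition for m in measurements],
            "temp_C": [m.temperature for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "kcat_per_s": [m.kcat for m in measurements],
        }
    )
    frame.to_csv(path, index=False)


def read_rate_csv(path: PathLike) -> List[RateMeasurement]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return [
        RateMeasurement(
            temperature=float(row.temp_C),
            kcat=float(row.kcat_per_s),
            condition=str(row.condition),
            replicate=int(row.replicate),
            variant=str(row.variant),
        )
        for row in frame.itertuples()
    ]


def write_melt_csv(curve: MeltCurve, path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "variant": curve.variant,
            "condition": curve.condition,
            "temp_C": curve.temperature,
            "wavelength_nm": curve.wavelength,
            "cd_mdeg": curve.cd,
            "ht_v": curve.ht,
        }
    )
    frame.to_csv(path, index=False)


def read_melt_csv(path: PathLike) -> MeltCurve:
    frame = pd.read_csv(path, float_precision="round_trip")
    variants = frame["variant"].unique()
    conditions = frame["condition"].unique()
    if len(variants) != 1 or len(conditions) != 1:
        raise ValueError("melt CSV must contain a single variant and condition")
    return MeltCurve(
        temperature=frame["temp_C"].to_numpy(float),
        wavelength=frame["wavelength_nm"].to_numpy(float),
        cd=frame["cd_mdeg"].to_numpy(float),
        ht=frame["ht_v"].to_numpy(float),
        condition=str(conditions[0]),
        variant=str(variants[0]),
    )


def result_to_dict(result) -> dict:
    """JSON-safe summary of a fitted result object (no bootstrap vectors)."""
    if isinstance(result, EyringFit):
        return {
            "dh_act_cal_mol": result.dh_act,
            "ds_act_cal_mol_K": result.ds_act,
            "n_points": result.n_points,
            "n_excluded": result.n_excluded,
            "se_dh": result.se_dh,
            "se_ds": result.se_ds,
            "ci95_dh": _pair(result.ci95_dh),
            "ci95_ds": _pair(result.ci95_ds),
            "n_boot": result.n_boot,
            "n_redrawn": result.n_redrawn,
            "seed": result.seed,
        }
    if isinstance(result, AllosteryEnergetics):
        return {
            "ddh_cal_mol": result.ddh,
            "dds_cal_mol_K": result.dds,
            "t_dds_at_ref_cal_mol": result.t_dds_at_ref,
            "ddg_at_ref_cal_mol": result.ddg_at_ref,
            "t_ref_K": result.t_ref,
            "fold_change_at_ref": result.fold_change_at_ref,
            "ci95_ddh": _pair(result.ci95_ddh),
            "ci95_dds": _pair(result.ci95_dds),
            "ci95_t_dds": _pair(result.ci95_t_dds),
            "ci95_ddg": _pair(result.ci95_ddg),
            "ci95_fold": _pair(result.ci95_fold),
        }
    if isinstance(result, MeltFit):
        return {
            "tm_C": result.tm,
            "dh_fold_cal_mol": result.dh_fold,
            "baseline_folded": [result.f, result.cf],
            "baseline_unfolded": [result.u, result.cu],
            "fit_window_C": _pair(result.fit_window),
            "rms": result.rms,
            "converged": result.converged,
            "diagnostics": {
                k: v for k, v in result.diagnostics.items() if _json_safe(v)
            },
        }
    raise TypeError(f"unsupported result type: {type(result).__name__}")


def _pair(value):
    return None if value is None else [float(value[0]), float(value[1])]


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def write_results_json(results: dict, path: PathLike) -> None:
    """Write a {name: result-object-or-plain-value} mapping as JSON."""
    payload = {}
    for name, value in results.items():
        try:
            payload[name] = result_to_dict(value)
        except TypeError:
            payload[name] = value
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
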