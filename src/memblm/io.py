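"""Plain-text file formats: trace CSV, curve CSV, parameter/result JSON.

All curve and trace files are CSV with explicit SI headers; parameters and
results are JSON with unit-suffixed keys.  Data volumes are tiny, so no
binary formats.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .analytic import ResponseCurves
from .estimation import EstimationResult, FoldedResponse
from .model import DriveSpec, Trace
from .oracle import OracleSolution


def write_trace_csv(trace: Trace, path: str | Path, sidecar: bool = True) -> None:
    """Write ``time_s, voltage_V, current_A``; metadata to a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.t,
            "voltage_V": trace.u if trace.u is not None else np.nan,
            "current_A": trace.i,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = dict(trace.meta)
        meta["drive"] = trace.drive.to_dict()
        meta["fs_Hz"] = trace.fs
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_trace_csv(
    path: str | Path, drive: DriveSpec | None = None, fs: float | None = None
) -> Trace:
    """Read a trace CSV; drive/fs come from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if drive is None:
        if "drive" not in meta:
            raise ValueError(f"no drive specification for {path} (sidecar missing)")
        drive = DriveSpec.from_dict(meta["drive"])
    if fs is None:
        fs = meta.get("fs_Hz")
        if fs is None:
            dt = np.diff(df["time_s"].to_numpy())
            fs = 1.0 / float(np.median(dt))
    u = df["voltage_V"].to_numpy() if "voltage_V" in df else None
    if u is not None and np.all(np.isnan(u)):
        u = None
    return Trace(
        t=df["time_s"].to_numpy(),
        i=df["current_A"].to_numpy(),
        drive=drive,
        fs=float(fs),
        u=u,
        meta=meta,
    )


def write_response_curves_csv(curves: ResponseCurves, path: str | Path) -> None:
    pd.DataFrame(
        {
            "U_V": curves.U,
            "I_up_A": curves.I_up,
            "I_down_inv_A": curves.I_down_inv,
            "C_up_F": curves.C_up,
            "C_down_F": curves.C_down,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_response_curves_csv(path: str | Path) -> ResponseCurves:
    df = pd.read_csv(path, float_precision="round_trip")
    return ResponseCurves(
        U=df["U_V"].to_numpy(),
        I_up=df["I_up_A"].to_numpy(),
        I_down_inv=df["I_down_inv_A"].to_numpy(),
        C_up=df["C_up_F"].to_numpy(),
        C_down=df["C_down_F"].to_numpy(),
    )


def write_oracle_csv(sol: OracleSolution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": sol.t,
            "utilde_V": sol.utilde,
            "i1_A": sol.i1,
            "i2_A": sol.i2,
            "i3_A": sol.i3,
            "I0_A": sol.I0,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_folded_csv(folded: FoldedResponse, path: str | Path) -> None:
    pd.DataFrame(
        {
            "U_V": folded.U,
            "I_up_mean_A": folded.I_up_mean,
            "I_down_inv_mean_A": folded.I_down_inv_mean,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_estimation_json(result: EstimationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))
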