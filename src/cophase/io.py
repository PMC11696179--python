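"""Readers and writers for the plain formats the pipeline exchanges:
16-bit grayscale TIFF images, CSV tables for FRAP traces and sensorgrams
(time column first), and JSON parameter/report files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .condensate import NucleusImage
from .frap import FrapTrace
from .spr import BivalentParams, Sensorgram


def save_nucleus_tiff(path, image: NucleusImage) -> None:
    """Write intensities as 16-bit grayscale TIFF (values clipped/rounded)."""
    data = np.clip(np.round(image.intensities), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def load_nucleus_tiff(path, pixel_size: float = 0.1, channel: str = "") -> NucleusImage:
    data = tifffile.imread(str(path))
    if data.ndim == 3:  # multi-page stack: caller may max-project
        raise ValueError("stack TIFF: load pages individually or max-project first")
    return NucleusImage(data.astype(float), pixel_size=pixel_size, channel=channel)


def load_nucleus_stack(path, pixel_size: float = 0.1, channel: str = "") -> list[NucleusImage]:
    data = np.atleast_3d(tifffile.imread(str(path)))
    if data.ndim != 3:
        raise ValueError("expected a multi-page TIFF stack")
    return [NucleusImage(p.astype(float), pixel_size, channel) for p in data]


def frap_trace_to_csv(path, trace: FrapTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "bleach_roi": trace.bleach_roi,
            "reference_roi": trace.reference_roi,
            "prebleach": np.arange(trace.times.size) < trace.prebleach_frames,
        }
    ).to_csv(path, index=False)


def frap_trace_from_csv(path) -> FrapTrace:
    df = pd.read_csv(path)
    pre = int(df["prebleach"].sum()) if "prebleach" in df else 1
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        bleach_roi=df["bleach_roi"].to_numpy(),
        reference_roi=df["reference_roi"].to_numpy(),
        prebleach_frames=pre,
    )


def sensorgrams_to_csv(path, sensorgrams: list[Sensorgram]) -> None:
    frames = []
    for g in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": g.times,
                    "response_ru": g.response,
                    "concentration_m": g.analyte_concentration,
                    "phase": np.where(g.times <= g.phase_boundary, "association", "dissociation"),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def sensorgrams_from_csv(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("concentration_m", sort=False):
        boundary = grp.loc[grp["phase"] == "association", "time_s"].max()
        out.append(
            Sensorgram(
                grp["time_s"].to_numpy(),
                grp["response_ru"].to_numpy(),
                float(conc),
                phase_boundary=float(boundary),
            )
        )
    return out


def params_to_json(path, params: BivalentParams, extra: dict | None = None) -> None:
    payload = {
        "ka1_per_M_s": params.ka1,
        "kd1_per_s": params.kd1,
        "ka2_per_RU_s": params.ka2,
        "kd2_per_s": params.kd2,
        "rmax_RU": params.rmax,
        "first_order_kd_M": params.first_order_kd,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
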