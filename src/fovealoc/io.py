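"""Readers/writers for the package's CSV/JSON/TIFF artifacts.

All lengths are serialized in arcmin; densities in cones/deg^2 and
frequencies in cycles/deg, labeled in headers.  CSV files are
comma-separated UTF-8 with a mandatory header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .gaze import FixationTrace, SimilarityTransform
from .mosaic import ConeMosaic, DensityMap

__all__ = [
    "write_cone_csv", "read_cone_csv",
    "write_trace_csv", "read_trace_csv",
    "write_trial_csv", "read_trial_csv",
    "write_transforms_json", "read_transforms_json",
    "write_density_map", "write_json", "read_json",
    "validate_inputs",
]

TRIAL_COLUMNS = ["trial", "s_x", "s_y", "e_x", "e_y", "r_x", "r_y",
                 "response", "microsaccade_250ms"]


def write_cone_csv(mosaic: ConeMosaic, path) -> None:
    df = pd.DataFrame(mosaic.cones, columns=["x_arcmin", "y_arcmin"])
    df.to_csv(path, index=False)


def read_cone_csv(path, **kwargs) -> ConeMosaic:
    df = pd.read_csv(path)
    return ConeMosaic(cones=df[["x_arcmin", "y_arcmin"]].to_numpy(), **kwargs)


def write_trace_csv(trace: FixationTrace, path, schedule_path=None) -> None:
    trace.samples.to_csv(path, index=False)
    if schedule_path is not None:
        trace.schedule.to_csv(schedule_path, index=False)


def read_trace_csv(path, schedule_path=None) -> FixationTrace:
    samples = pd.read_csv(path)
    samples["valid"] = samples["valid"].astype(bool)
    if schedule_path is not None:
        schedule = pd.read_csv(schedule_path)
    else:  # reconstruct from epoch boundaries in the samples
        first = samples.groupby(["day", "run", "epoch"], as_index=False).first()
        schedule = first.rename(
            columns={"frame": "start_frame", "target_raster_x": "target_x",
                     "target_raster_y": "target_y"}
        )[["day", "run", "epoch", "start_frame", "target_x", "target_y"]]
    return FixationTrace(samples, schedule)


def write_trial_csv(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["microsaccade_250ms"] = df["microsaccade_250ms"].astype(bool)
    return df


def write_transforms_json(chain, path) -> None:
    data = [{"tx": t.tx, "ty": t.ty, "theta": t.theta, "scale": t.scale} for t in chain]
    Path(path).write_text(json.dumps(data, indent=2))


def read_transforms_json(path) -> list[SimilarityTransform]:
    data = json.loads(Path(path).read_text())
    return [SimilarityTransform(**d) for d in data]


def write_density_map(dmap: DensityMap, tiff_path, json_path) -> None:
    """Grayscale TIFF of the density field plus JSON metadata."""
    tifffile.imwrite(tiff_path, dmap.D.astype(np.float32))
    meta = {
        "peak_x_arcmin": float(dmap.peak[0]),
        "peak_y_arcmin": float(dmap.peak[1]),
        "peak_density_cones_per_deg2": dmap.peak_density,
        "window_arcmin": dmap.window,
        "pixel_scale_arcmin": dmap.pixel_scale,
        "origin_arcmin": dmap.origin.tolist(),
        "valid_margin_arcmin": dmap.valid_margin,
    }
    write_json(meta, json_path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())


def validate_inputs(cones: pd.DataFrame | None = None,
                    trace: pd.DataFrame | None = None,
                    trials: pd.DataFrame | None = None) -> list[dict]:
    """Schema/unit/invariant diagnostics for input tables.

    Returns machine-readable findings (empty list = all checks pass);
    never raises on data problems.
    """
    findings: list[dict] = []

    def add(file, row, message):
        findings.append({"file": file, "row": row, "message": message})

    if cones is not None:
        if len(cones) == 0:
            add("cones", None, "no rows")
        for col in ("x_arcmin", "y_arcmin"):
            if col not in cones.columns:
                add("cones", None, f"missing column {col}")

    if trace is not None:
        if len(trace) == 0:
            add("trace", None, "no rows")
        else:
            needed = {"day", "run", "frame", "epoch", "x_arcmin", "y_arcmin", "valid"}
            missing = needed - set(trace.columns)
            if missing:
                add("trace", None, f"missing columns {sorted(missing)}")
            else:
                for (day, run), g in trace.groupby(["day", "run"]):
                    f = g["frame"].to_numpy()
                    bad = np.flatnonzero(np.diff(f) <= 0)
                    for b in bad[:5]:
                        add("trace", int(g.index[b + 1]),
                            f"non-increasing frame index in day {day} run {run}")

    if trials is not None:
        if len(trials) == 0:
            add("trials", None, "no rows")
        else:
            missing = set(TRIAL_COLUMNS) - set(trials.columns)
            if missing:
                add("trials", None, f"missing columns {sorted(missing)}")
            else:
                r = trials[["r_x", "r_y"]].to_numpy()
                es = trials[["e_x", "e_y"]].to_numpy() + trials[["s_x", "s_y"]].to_numpy()
                bad = np.flatnonzero(np.linalg.norm(r - es, axis=1) > 1e-6)
                for b in bad[:10]:
                    add("trials", int(trials.index[b]),
                        "r != e + s (retinal-location identity violated)")
                bad_resp = ~trials["response"].isin(["yes", "maybe", "no"])
                for b in np.flatnonzero(bad_resp.to_numpy())[:10]:
                    add("trials", int(trials.index[b]),
                        f"unknown response {trials['response'].iloc[b]!r}")
    return findings
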