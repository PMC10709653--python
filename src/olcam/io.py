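"""File formats: multi-page TIFF movies, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import LocomotionBout, RestingPeriod, SpeedTrace
from .events import CaEvent
from .micromap import MicrodomainMap
from .preprocess import TwoChannelMovie
from .synthgen import GroundTruth

__all__ = [
    "save_movie",
    "load_movie",
    "save_speed",
    "load_speed",
    "save_events",
    "load_events",
    "save_bouts",
    "save_resting",
    "save_label_map",
    "load_label_map",
    "save_ground_truth",
    "save_traces",
    "load_traces",
]


def save_movie(movie: TwoChannelMovie, out_dir: str | Path, stem: str = "session") -> dict:
    """Write one TIFF per channel plus a metadata sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    green_path = out / f"{stem}_green.tif"
    red_path = out / f"{stem}_red.tif"
    tifffile.imwrite(green_path, movie.green.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(red_path, movie.red.astype(np.float32), photometric="minisblack")
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "n_frames": movie.n_frames,
        "green": green_path.name,
        "red": red_path.name,
    }
    (out / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))
    return meta


def load_movie(meta_path: str | Path) -> TwoChannelMovie:
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    base = meta_path.parent
    return TwoChannelMovie(
        green=tifffile.imread(base / meta["green"]),
        red=tifffile.imread(base / meta["red"]),
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta["pixel_size_um"],
    )


def save_speed(speed: SpeedTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": speed.time_s,
            "speed_mm_s": speed.speed_mm_s,
            "x_mm": speed.x_mm if speed.x_mm is not None else np.nan,
            "y_mm": speed.y_mm if speed.y_mm is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)


def load_speed(path: str | Path) -> SpeedTrace:
    df = pd.read_csv(path)
    x = df["x_mm"].to_numpy() if "x_mm" in df and df["x_mm"].notna().any() else None
    y = df["y_mm"].to_numpy() if "y_mm" in df and df["y_mm"].notna().any() else None
    return SpeedTrace(
        time_s=df["time_s"].to_numpy(),
        speed_mm_s=df["speed_mm_s"].to_numpy(),
        x_mm=x,
        y_mm=y,
    )


def save_events(events: list[CaEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "roi": e.roi_id,
                "onset_frame": e.onset_frame,
                "peak_frame": e.peak_frame,
                "offset_frame": e.offset_frame,
                "amplitude_z": e.amplitude_z,
                "duration_s": e.duration_s,
                "phase": e.phase,
            }
            for e in events
        ],
        columns=[
            "roi", "onset_frame", "peak_frame", "offset_frame",
            "amplitude_z", "duration_s", "phase",
        ],
    ).to_csv(path, index=False)


def load_events(path: str | Path, frame_rate_hz: float) -> list[CaEvent]:
    df = pd.read_csv(path)
    return [
        CaEvent(
            roi_id=int(r.roi),
            onset_frame=int(r.onset_frame),
            peak_frame=int(r.peak_frame),
            offset_frame=int(r.offset_frame),
            amplitude_z=float(r.amplitude_z),
            frame_rate_hz=frame_rate_hz,
            phase=str(r.phase),
        )
        for r in df.itertuples()
    ]


def save_bouts(bouts: list[LocomotionBout], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "start_s": b.start_s,
                "end_raw_s": b.end_raw_s,
                "end_extended_s": b.end_extended_s,
                "peak_speed_mm_s": b.peak_speed_mm_s,
            }
            for b in bouts
        ],
        columns=["start_s", "end_raw_s", "end_extended_s", "peak_speed_mm_s"],
    ).to_csv(path, index=False)


def save_resting(resting: list[RestingPeriod], path: str | Path) -> None:
    pd.DataFrame(
        [{"start_s": r.start_s, "end_s": r.end_s} for r in resting],
        columns=["start_s", "end_s"],
    ).to_csv(path, index=False)


def save_label_map(cam_map: MicrodomainMap, out_dir: str | Path, stem: str = "cam_map") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}.tif", cam_map.labels.astype(np.uint16))
    areas = cam_map.areas_um2
    pd.DataFrame(
        {"roi": list(areas), "area_um2": list(areas.values())}
    ).to_csv(out / f"{stem}_areas.csv", index=False)


def load_label_map(path: str | Path, pixel_size_um: float) -> MicrodomainMap:
    return MicrodomainMap(
        labels=tifffile.imread(path).astype(np.int32), pixel_size_um=pixel_size_um
    )


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_events": [
            {"roi": r, "onset_frame": o, "amplitude_z": a, "duration_frames": d}
            for r, o, a, d in truth.true_events
        ],
        "true_bouts": [{"start_s": s, "end_s": e} for s, e in truth.true_bouts],
        "true_motion": truth.true_motion.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def save_traces(traces: dict[int, np.ndarray], path: str | Path) -> None:
    """Trace CSV with one `roi_<k>` column per microdomain."""
    df = pd.DataFrame({f"roi_{k}": v for k, v in traces.items()})
    df.insert(0, "frame", np.arange(len(df)))
    df.to_csv(path, index=False)


def load_traces(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(col.removeprefix("roi_")): df[col].to_numpy()
        for col in df.columns
        if col.startswith("roi_")
    }
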