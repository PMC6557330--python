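"""File I/O: TIFF frame stacks, HDF5 time series, CSV tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .containers import (ActivityMatrix, BehaviorSession, FrameStack,
                         GroundTruthLog, PreyTracks, PreyTruth, TrialTable)


def write_frames(stack: FrameStack, path: str) -> None:
    tifffile.imwrite(path, stack.frames, photometric="minisblack",
                     metadata={"px_per_mm": stack.px_per_mm})


def read_frames(path: str, timestamps: np.ndarray | None = None,
                px_per_mm: float = 24.8) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if timestamps is None:
        timestamps = np.arange(len(frames), dtype=float)
    return FrameStack(frames=frames, timestamps=timestamps, px_per_mm=px_per_mm)


def write_session(session: BehaviorSession, prey: PreyTruth | None, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("session")
        for name in ("time", "body_centroid", "heading", "left_eye_angle",
                     "right_eye_angle", "tail_segment_angles"):
            g.create_dataset(name, data=getattr(session, name))
        g.attrs["sampling_rate"] = session.sampling_rate
        g.attrs["px_per_mm"] = session.px_per_mm
        if prey is not None:
            p = f.create_group("prey")
            p.create_dataset("time", data=prey.time)
            p.create_dataset("positions", data=prey.positions)
            p.attrs["rate"] = prey.rate


def read_session(path: str) -> tuple[BehaviorSession, PreyTruth | None]:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["session"]
        session = BehaviorSession(
            time=g["time"][:], body_centroid=g["body_centroid"][:],
            heading=g["heading"][:], left_eye_angle=g["left_eye_angle"][:],
            right_eye_angle=g["right_eye_angle"][:],
            tail_segment_angles=g["tail_segment_angles"][:],
            sampling_rate=float(g.attrs["sampling_rate"]),
            px_per_mm=float(g.attrs["px_per_mm"]))
        prey = None
        if "prey" in f:
            p = f["prey"]
            prey = PreyTruth(time=p["time"][:], positions=p["positions"][:],
                             rate=float(p.attrs["rate"]))
    return session, prey


def session_to_csv(session: BehaviorSession, path: str) -> None:
    df = pd.DataFrame({
        "time": session.time,
        "x_mm": session.body_centroid[:, 0], "y_mm": session.body_centroid[:, 1],
        "heading": session.heading,
        "left_eye_angle": session.left_eye_angle,
        "right_eye_angle": session.right_eye_angle,
        "vergence": session.vergence,
    })
    for i in range(session.tail_segment_angles.shape[1]):
        df[f"tail_angle_{i}"] = session.tail_segment_angles[:, i]
    df.to_csv(path, index=False)


def write_truth(log: GroundTruthLog, prefix: str) -> None:
    log.routines.to_csv(f"{prefix}_routines.csv", index=False)
    log.bouts.to_csv(f"{prefix}_bouts.csv", index=False)
    log.events.to_csv(f"{prefix}_events.csv", index=False)
    log.escapes.to_csv(f"{prefix}_escapes.csv", index=False)


def read_annotations(path: str) -> pd.DataFrame:
    """Annotation CSV: columns epoch_id, event in {ram, suction, ingestion}, time."""
    df = pd.read_csv(path)
    required = {"epoch_id", "event", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing column(s): {sorted(missing)}")
    bad = set(df["event"]) - {"ram", "suction", "ingestion"}
    if bad:
        raise ValueError(f"unknown event type(s): {sorted(bad)}")
    return df


def write_activity(activity: ActivityMatrix, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=activity.F)
        f.create_dataset("frame_times", data=activity.frame_times)
        g = f.create_group("rois")
        g.create_dataset("roi_id", data=activity.rois["roi_id"].to_numpy())
        for col in ("region", "side"):
            g.create_dataset(col, data=[str(v).encode()
                                        for v in activity.rois[col]])


def read_activity(path: str) -> ActivityMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        rois = pd.DataFrame({
            "roi_id": f["rois/roi_id"][:],
            "region": [s.decode() for s in f["rois/region"][:]],
            "side": [s.decode() for s in f["rois/side"][:]],
        })
        return ActivityMatrix(F=f["F"][:], frame_times=f["frame_times"][:], rois=rois)


def write_trials(trials: TrialTable, prefix: str) -> None:
    trials.stimuli.to_csv(f"{prefix}_stimuli.csv", index=False)
    trials.convergences.to_csv(f"{prefix}_convergences.csv", index=False)


def read_trials(prefix: str) -> TrialTable:
    return TrialTable(stimuli=pd.read_csv(f"{prefix}_stimuli.csv"),
                      convergences=pd.read_csv(f"{prefix}_convergences.csv"))


def write_tracks(tracks: PreyTracks, path: str) -> None:
    tracks.table.to_csv(path, index=False)


def read_tracks(path: str) -> PreyTracks:
    return PreyTracks(table=pd.read_csv(path))
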