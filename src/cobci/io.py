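"""On-disk interchange formats (see docs/FORMATS.md).

Recordings, trial sets, aligned sets and templates travel in a flat HDF5
container (one dataset per field); the event stream additionally gets a
plain-text TSV sidecar so it stays inspectable.  EDF recordings with a TSV
sidecar are accepted on input when ``mne`` is importable.
"""

from __future__ import annotations

import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp_align import AlignedTrialSet, ErpTemplate, SpatialFilter
from .events import VideoEvent
from .exceptions import DataError
from .preprocess import TrialSet
from .synthetic import RawRecording

_EVENT_COLS = ["onset", "video_id", "video_class", "duration", "target_onset"]


def events_to_frame(events: list[VideoEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset": e.onset,
                "video_id": e.video_id,
                "video_class": e.video_class,
                "duration": e.duration,
                "target_onset": math.nan if e.target_onset is None else e.target_onset,
            }
            for e in events
        ],
        columns=_EVENT_COLS,
    )


def frame_to_events(df: pd.DataFrame) -> list[VideoEvent]:
    return [
        VideoEvent(
            onset=float(r.onset),
            video_id=int(r.video_id),
            video_class=int(r.video_class),
            duration=float(r.duration),
            target_onset=None if pd.isna(r.target_onset) else float(r.target_onset),
        )
        for r in df.itertuples()
    ]


def write_events_tsv(events: list[VideoEvent], path) -> None:
    # %.17g keeps onset times bit round-trippable through text
    events_to_frame(events).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events_tsv(path) -> list[VideoEvent]:
    return frame_to_events(
        pd.read_csv(path, sep="\t", float_precision="round_trip")
    )


def write_recording(rec: RawRecording, path) -> None:
    """Recording + events into one HDF5 file; TSV sidecar alongside."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples, compression="gzip")
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["fs"] = rec.fs
        f.attrs["channels"] = list(rec.channels)
        ev = events_to_frame(rec.events)
        for col in _EVENT_COLS:
            f.create_dataset(f"events/{col}", data=ev[col].to_numpy())
    write_events_tsv(rec.events, path.with_suffix(".events.tsv"))


def read_recording(path) -> RawRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    with h5py.File(path, "r") as f:
        ev = pd.DataFrame({c: f[f"events/{c}"][()] for c in _EVENT_COLS})
        return RawRecording(
            subject_id=str(f.attrs["subject_id"]),
            samples=f["samples"][()],
            fs=float(f.attrs["fs"]),
            events=frame_to_events(ev),
            channels=tuple(str(c) for c in f.attrs["channels"]),
        )


def read_recording_edf(path) -> RawRecording:
    """EDF input path: signal from the EDF, events from the TSV sidecar."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise DataError("reading EDF requires the optional 'mne' dependency") from err
    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sidecar = path.with_suffix(".events.tsv")
    if not sidecar.exists():
        raise DataError(f"EDF recording needs an event sidecar at {sidecar}")
    return RawRecording(
        subject_id=path.stem,
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        events=read_events_tsv(sidecar),
        channels=tuple(raw.ch_names),
    )


def write_trialset(ts: TrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ts.trials, compression="gzip")
        f.create_dataset("labels", data=ts.labels)
        f.create_dataset("validity", data=ts.validity)
        f.create_dataset("trial_index", data=ts.trial_index)
        f.attrs["subject_id"] = ts.subject_id
        f.attrs["fs"] = ts.fs


def read_trialset(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        return TrialSet(
            subject_id=str(f.attrs["subject_id"]),
            trials=f["trials"][()],
            labels=f["labels"][()],
            validity=f["validity"][()],
            trial_index=f["trial_index"][()],
            fs=float(f.attrs["fs"]),
        )


def write_aligned(a: AlignedTrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=a.trials, compression="gzip")
        f.create_dataset("offsets", data=a.offsets)
        f.create_dataset("labels", data=a.labels)
        f.create_dataset("validity", data=a.validity)
        f.create_dataset("trial_index", data=a.trial_index)
        f.attrs["subject_id"] = a.subject_id


def read_aligned(path) -> AlignedTrialSet:
    with h5py.File(path, "r") as f:
        return AlignedTrialSet(
            subject_id=str(f.attrs["subject_id"]),
            trials=f["trials"][()],
            offsets=f["offsets"][()],
            labels=f["labels"][()],
            validity=f["validity"][()],
            trial_index=f["trial_index"][()],
        )


def write_template(t: ErpTemplate, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("series", data=t.series)
        f.create_dataset("weights", data=t.filter.weights)
        f.attrs["crop_start"] = t.crop_start


def read_template(path) -> ErpTemplate:
    with h5py.File(path, "r") as f:
        return ErpTemplate(
            series=f["series"][()],
            filter=SpatialFilter(weights=f["weights"][()]),
            crop_start=int(f.attrs["crop_start"]),
        )


def write_p3_maps_tsv(maps, path) -> None:
    from .montage import CHANNELS_16

    rows = []
    for m in maps:
        row = {"subject_id": m.subject_id, "peak_latency_ms": m.peak_latency_ms}
        row.update({ch: v for ch, v in zip(CHANNELS_16, m.topography)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
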