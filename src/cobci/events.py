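"""Stimulus-stream events and the trial segmentation rule.

A recording session is a sequence of video presentations.  Each video is
either a *target* video (contains exactly one vehicle, whose appearance time
is marked) or a *nontarget* video.  Epoching turns the stream into fixed
1500 ms trials:

* one trial per target video, starting at the marked target onset;
* nontarget videos tiled into non-overlapping 1500 ms trials from video
  onset, partial tails discarded.

The segmentation rule lives here because both the simulator (which injects
amplitude artifacts into specific future trials) and the preprocessing
module (which epochs recordings) must agree on it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DataError

TRIAL_SECONDS = 1.5

TARGET = 1
NONTARGET = 0


@dataclass(frozen=True)
class VideoEvent:
    """One video presentation within the stimulus stream.

    Times are in seconds from recording start.  ``target_onset`` is the
    absolute time the vehicle enters the frame; ``None`` for nontarget
    videos.
    """

    onset: float
    video_id: int
    video_class: int  # TARGET or NONTARGET
    duration: float
    target_onset: float | None = None

    def __post_init__(self) -> None:
        if self.video_class == TARGET and self.target_onset is None:
            raise DataError(f"target video {self.video_id} lacks a target onset marker")
        if self.video_class not in (TARGET, NONTARGET):
            raise DataError(f"unknown video class {self.video_class!r}")


def trial_windows(
    events: list[VideoEvent], trial_s: float = TRIAL_SECONDS
) -> list[tuple[float, int, int]]:
    """Segment an event stream into (start_time, label, video_id) trials.

    Trials are emitted in stimulus order, so their position in the returned
    list is the group-shared ``trial_index``.
    """
    windows: list[tuple[float, int, int]] = []
    last_onset = -math.inf
    for ev in events:
        if ev.onset <= last_onset:
            raise DataError("event onsets must be strictly increasing")
        last_onset = ev.onset
        if ev.video_class == TARGET:
            if ev.target_onset is None:
                raise DataError(f"target video {ev.video_id} lacks a target onset marker")
            windows.append((ev.target_onset, TARGET, ev.video_id))
        else:
            n_tiles = int(ev.duration / trial_s)
            for i in range(n_tiles):
                windows.append((ev.onset + i * trial_s, NONTARGET, ev.video_id))
    return windows
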