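"""Timestamped gait and music events, and the relative-phase computation.

The relative phase φ of a footfall is its position within the bracketing
beat interval, scaled to degrees:

    φ_360 = 360 · (t_footfall − t_prev_beat) / (t_next_beat − t_prev_beat)

φ = 0° means the footfall coincided with a beat (in-phase); φ = 180° means
it fell exactly between two beats (anti-phase). For display, phases are
mapped to (−180°, +180°]: a negative angle means the footfall preceded the
upcoming beat, a positive angle that it followed the previous beat. Left
and right steps are treated identically (per-step phase, not per gait
cycle). All times are absolute seconds on one clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FootfallEvent",
    "BeatEvent",
    "RelativePhaseSample",
    "InvalidIntervalError",
    "relative_phase",
    "to_display",
    "phase_series",
    "read_footfalls",
    "write_footfalls",
    "read_beats",
    "write_beats",
    "write_phases",
]


class InvalidIntervalError(ValueError):
    """Raised when a footfall/beat timestamp triple is mis-ordered."""


@dataclass(frozen=True)
class FootfallEvent:
    """A detected footfall: absolute time, validity flag, participant label."""

    time: float
    valid: bool = True
    participant_id: str = "p0"


@dataclass(frozen=True)
class BeatEvent:
    """A musical beat emitted by a playback: time, song, index within song."""

    time: float
    song_id: str = "song"
    beat_index: int = 0


@dataclass(frozen=True)
class RelativePhaseSample:
    """Relative phase of one footfall within its bracketing beat interval."""

    phi_360: float
    phi_display: float
    footfall_time: float
    prev_beat_time: float
    next_beat_time: float


def to_display(phi_360: float) -> float:
    """Map a phase in [0, 360) to the display scale (−180, +180].

    The anti-phase boundary 180° maps to +180° (half-open interval), giving
    a single canonical value for the offbeat.
    """
    phi = float(phi_360) % 360.0
    return phi if phi <= 180.0 else phi - 360.0


def relative_phase(
    footfall_time: float, prev_beat_time: float, next_beat_time: float
) -> RelativePhaseSample:
    """Relative phase of one footfall between two consecutive beats.

    Requires prev_beat_time ≤ footfall_time < next_beat_time: a footfall
    exactly on a beat belongs to that beat's interval, so φ = 0 is
    representable.
    """
    if not (prev_beat_time < next_beat_time):
        raise InvalidIntervalError(
            f"beat interval is empty or reversed: [{prev_beat_time}, {next_beat_time})"
        )
    if not (prev_beat_time <= footfall_time < next_beat_time):
        raise InvalidIntervalError(
            f"footfall at {footfall_time} not inside beat interval "
            f"[{prev_beat_time}, {next_beat_time})"
        )
    phi = 360.0 * (footfall_time - prev_beat_time) / (next_beat_time - prev_beat_time)
    return RelativePhaseSample(
        phi_360=phi,
        phi_display=to_display(phi),
        footfall_time=footfall_time,
        prev_beat_time=prev_beat_time,
        next_beat_time=next_beat_time,
    )


def phase_series(
    footfalls: Sequence[FootfallEvent], beats: Sequence[BeatEvent]
) -> list[RelativePhaseSample]:
    """Per-step relative phases of a footfall log against a beat log.

    One sample per valid footfall bracketed by two consecutive beats of the
    same playback (same song_id, consecutive beat_index). Invalid footfalls,
    and footfalls before the first or after the last beat — or inside a song
    change — yield no sample. An empty beat sequence yields an empty result.
    """
    if not beats:
        return []
    beat_times = np.array([b.time for b in beats])
    out: list[RelativePhaseSample] = []
    for f in footfalls:
        if not f.valid:
            continue
        # index of the last beat with time <= footfall time
        i = int(np.searchsorted(beat_times, f.time, side="right")) - 1
        if i < 0 or i + 1 >= len(beats):
            continue
        prev_b, next_b = beats[i], beats[i + 1]
        if prev_b.song_id != next_b.song_id or next_b.beat_index != prev_b.beat_index + 1:
            continue  # song change between the two beats
        out.append(relative_phase(f.time, prev_b.time, next_b.time))
    return out


# ---------------------------------------------------------------------------
# CSV dialects (documented once here, reused by the experiment runner):
#   footfalls: participant_id,time_s,valid      (valid as 0/1)
#   beats:     song_id,beat_index,time_s
#   phases:    participant_id,time_s,phi_display_deg,song_id
# ---------------------------------------------------------------------------


def write_footfalls(path, footfalls: Iterable[FootfallEvent]) -> None:
    df = pd.DataFrame(
        [(f.participant_id, f.time, int(f.valid)) for f in footfalls],
        columns=["participant_id", "time_s", "valid"],
    )
    df.to_csv(path, index=False)


def read_footfalls(path) -> list[FootfallEvent]:
    df = pd.read_csv(path)
    return [
        FootfallEvent(time=float(r.time_s), valid=bool(r.valid), participant_id=str(r.participant_id))
        for r in df.itertuples()
    ]


def write_beats(path, beats: Iterable[BeatEvent]) -> None:
    df = pd.DataFrame(
        [(b.song_id, b.beat_index, b.time) for b in beats],
        columns=["song_id", "beat_index", "time_s"],
    )
    df.to_csv(path, index=False)


def read_beats(path) -> list[BeatEvent]:
    df = pd.read_csv(path)
    return [
        BeatEvent(time=float(r.time_s), song_id=str(r.song_id), beat_index=int(r.beat_index))
        for r in df.itertuples()
    ]


def write_phases(path, samples: Sequence[RelativePhaseSample], participant_id: str = "p0",
                 song_ids: Sequence[str] | None = None) -> None:
    rows = []
    for k, s in enumerate(samples):
        sid = song_ids[k] if song_ids is not None else ""
        rows.append((participant_id, s.footfall_time, s.phi_display, sid))
    pd.DataFrame(
        rows, columns=["participant_id", "time_s", "phi_display_deg", "song_id"]
    ).to_csv(path, index=False)
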