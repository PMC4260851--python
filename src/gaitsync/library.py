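"""Annotated song metadata and the beat schedule of a playback.

A song is metadata only: an identifier, a nominal tempo in beats per minute
and (optionally) a beat-time grid at that nominal tempo. Playback is the
timing contract of a time stretcher: beats are emitted on a wall clock, with
the remaining nominal inter-beat intervals scaled by 1/tempo_modifier. The
modifier is clamped to ±10% around nominal — the stretch range found
acceptable for audio quality — and changing it never reschedules beats that
have already been emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Song",
    "Library",
    "PlaybackState",
    "LibraryFormatError",
    "SongSelectionError",
    "DEFAULT_CLAMP",
    "load_library",
    "save_library",
    "nearest_song",
    "start_song",
    "set_tempo_modifier",
    "next_beats",
    "advance",
]

DEFAULT_CLAMP = (0.9, 1.1)
DEFAULT_SONG_DURATION_S = 120.0


class LibraryFormatError(ValueError):
    """Malformed library file (duplicate ids, non-positive tempo, ...)."""


class SongSelectionError(LookupError):
    """No candidate song available for selection."""


@dataclass(frozen=True)
class Song:
    """Song metadata: id, nominal BPM, optional beat grid at nominal tempo.

    If ``beat_grid`` is absent an isochronous grid at 60/bpm over
    ``duration_s`` is implied (songs must end so that a player can move on).
    """

    song_id: str
    bpm: float
    beat_grid: tuple[float, ...] | None = None
    duration_s: float | None = None

    def __post_init__(self):
        if self.bpm <= 0:
            raise LibraryFormatError(f"song {self.song_id!r}: bpm must be positive, got {self.bpm}")
        if self.beat_grid is not None:
            g = np.asarray(self.beat_grid, dtype=float)
            if len(g) >= 2 and np.any(np.diff(g) <= 0):
                raise LibraryFormatError(f"song {self.song_id!r}: beat grid not strictly increasing")

    @property
    def grid(self) -> np.ndarray:
        """Nominal beat times in seconds, starting at the first beat."""
        if self.beat_grid is not None:
            return np.asarray(self.beat_grid, dtype=float)
        dur = self.duration_s if self.duration_s is not None else DEFAULT_SONG_DURATION_S
        period = 60.0 / self.bpm
        n = max(int(np.floor(dur / period)) + 1, 1)
        return np.arange(n) * period


@dataclass
class Library:
    songs: dict[str, Song] = field(default_factory=dict)

    def add(self, song: Song) -> None:
        if song.song_id in self.songs:
            raise LibraryFormatError(f"duplicate song_id {song.song_id!r}")
        self.songs[song.song_id] = song

    def __len__(self) -> int:
        return len(self.songs)

    def __iter__(self):
        return iter(self.songs.values())


def load_library(path) -> Library:
    """Load a library from CSV (``song_id,bpm[,duration_s[,grid_file]]``) or
    JSON (records with optional embedded ``beat_grid``).

    Sidecar grid files hold one nominal beat timestamp per line. Malformed
    rows are reported with their line number.
    """
    path = Path(path)
    lib = Library()
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        for i, rec in enumerate(records):
            try:
                lib.add(Song(
                    song_id=str(rec["song_id"]),
                    bpm=float(rec["bpm"]),
                    beat_grid=tuple(rec["beat_grid"]) if rec.get("beat_grid") else None,
                    duration_s=rec.get("duration_s"),
                ))
            except (KeyError, ValueError, LibraryFormatError) as e:
                raise LibraryFormatError(f"{path}: record {i}: {e}") from e
        return lib

    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return lib
    if len(df) == 0:
        return lib
    for row_no, r in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            grid = None
            grid_file = getattr(r, "grid_file", None)
            if isinstance(grid_file, str) and grid_file:
                grid_path = path.parent / grid_file
                grid = tuple(float(x) for x in grid_path.read_text().split())
            dur = getattr(r, "duration_s", None)
            dur = float(dur) if dur is not None and not pd.isna(dur) else None
            lib.add(Song(song_id=str(r.song_id), bpm=float(r.bpm), beat_grid=grid, duration_s=dur))
        except (ValueError, LibraryFormatError) as e:
            raise LibraryFormatError(f"{path}: line {row_no}: {e}") from e
    return lib


def save_library(path, library: Library) -> None:
    """Write a library back out; round-trips (song_id, bpm, beat_grid)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = []
        for s in library:
            rec: dict = {"song_id": s.song_id, "bpm": s.bpm}
            if s.beat_grid is not None:
                rec["beat_grid"] = list(s.beat_grid)
            if s.duration_s is not None:
                rec["duration_s"] = s.duration_s
            records.append(rec)
        path.write_text(json.dumps(records, indent=1))
        return
    rows = []
    for s in library:
        grid_file = ""
        if s.beat_grid is not None:
            grid_file = f"{s.song_id}.beats.txt"
            (path.parent / grid_file).write_text(
                "\n".join(repr(float(t)) for t in s.beat_grid) + "\n")
        rows.append((s.song_id, s.bpm, s.duration_s, grid_file))
    pd.DataFrame(rows, columns=["song_id", "bpm", "duration_s", "grid_file"]).to_csv(
        path, index=False)


def nearest_song(library: Library, target_spm: float,
                 exclude: Iterable[str] = ()) -> Song:
    """The song whose BPM is closest to the target cadence.

    Ties break to the lexicographically smallest song_id so that
    experiments replay deterministically.
    """
    exclude = set(exclude)
    candidates = [s for s in library if s.song_id not in exclude]
    if not candidates:
        raise SongSelectionError(
            f"no candidate songs for target {target_spm} SPM (library size "
            f"{len(library)}, {len(exclude)} excluded)")
    return min(candidates, key=lambda s: (abs(s.bpm - target_spm), s.song_id))


@dataclass
class PlaybackState:
    """One playback of one song: emitted beats plus the future schedule.

    ``position`` is the song-internal index of the next beat to emit;
    ``next_beat_time`` is its wall time under the current modifier. Past
    beats are never rescheduled.
    """

    song: Song
    start_wall_time: float
    tempo_modifier: float = 1.0
    emitted_beats: list = field(default_factory=list)
    position: int = 0
    next_beat_time: float | None = None
    clamp: tuple[float, float] = DEFAULT_CLAMP
    request_out_of_range: bool = False
    last_requested_modifier: float = 1.0

    @property
    def finished(self) -> bool:
        return self.next_beat_time is None

    @property
    def last_beat_time(self) -> float | None:
        return self.emitted_beats[-1].time if self.emitted_beats else None


def start_song(song: Song, wall_time: float, skip_to_first_beat: bool = True,
               clamp: tuple[float, float] = DEFAULT_CLAMP,
               tempo_modifier: float = 1.0) -> PlaybackState:
    """Begin a playback at ``wall_time``.

    With ``skip_to_first_beat`` the playback starts at the song's first
    annotated beat, so the first emitted beat lands exactly on ``wall_time``
    (used for phase-aligned song starts). Otherwise the song plays from 0
    and the first beat occurs at wall_time + grid[0].
    """
    grid = song.grid
    pb = PlaybackState(song=song, start_wall_time=wall_time, clamp=clamp)
    set_tempo_modifier(pb, tempo_modifier)
    first = wall_time if skip_to_first_beat else wall_time + grid[0]
    pb.next_beat_time = first if len(grid) else None
    return pb


def set_tempo_modifier(playback: PlaybackState, modifier: float) -> PlaybackState:
    """Request a tempo modifier; it is stored clamped to the stretch range.

    Records whether the raw request was out of range (the strategy layer
    uses that flag for the song-change debounce). The change takes effect
    at the next unemitted beat: its pending wall time is recomputed from
    the last emitted beat, never retroactively.
    """
    if modifier <= 0:
        raise ValueError(f"tempo modifier must be positive, got {modifier}")
    lo, hi = playback.clamp
    playback.last_requested_modifier = float(modifier)
    playback.request_out_of_range = not (lo <= modifier <= hi)
    clamped = min(max(float(modifier), lo), hi)
    if clamped != playback.tempo_modifier:
        playback.tempo_modifier = clamped
        grid = playback.song.grid
        if playback.position > 0 and playback.next_beat_time is not None:
            gap = (grid[playback.position] - grid[playback.position - 1]) / clamped
            playback.next_beat_time = playback.emitted_beats[-1].time + gap
    return playback


def advance(playback: PlaybackState, now: float) -> list:
    """Emit all beats due at or before ``now``; returns the newly emitted ones."""
    from .events import BeatEvent

    grid = playback.song.grid
    new = []
    while playback.next_beat_time is not None and playback.next_beat_time <= now:
        ev = BeatEvent(time=playback.next_beat_time, song_id=playback.song.song_id,
                       beat_index=playback.position)
        playback.emitted_beats.append(ev)
        new.append(ev)
        playback.position += 1
        if playback.position < len(grid):
            gap = (grid[playback.position] - grid[playback.position - 1]) / playback.tempo_modifier
            playback.next_beat_time = ev.time + gap
        else:
            playback.next_beat_time = None
    return new


def next_beats(playback: PlaybackState, horizon: float) -> list:
    """Future (not yet emitted) beats within ``horizon`` seconds.

    The horizon is counted from the last emitted beat, or from the playback
    start if nothing has been emitted yet. Does not mutate the playback.
    """
    from .events import BeatEvent

    if playback.next_beat_time is None:
        return []
    origin = playback.last_beat_time
    if origin is None:
        origin = playback.next_beat_time
    grid = playback.song.grid
    t, idx = playback.next_beat_time, playback.position
    out = []
    while t <= origin + horizon:
        out.append(BeatEvent(time=t, song_id=playback.song.song_id, beat_index=idx))
        idx += 1
        if idx >= len(grid):
            break
        t = t + (grid[idx] - grid[idx - 1]) / playback.tempo_modifier
    return out
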