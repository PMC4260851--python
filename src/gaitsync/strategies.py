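"""The four movement-music alignment controllers and the gait estimator.

All four strategies run the same per-step loop on footfall events:

1. period-adaptive, phase-random — the tempo modifier tracks the 5-step
   averaged cadence continuously; songs start at a random phase, and a
   persistently out-of-range tempo request (> debounce seconds) triggers an
   immediate song change.
2. period-fixed, phase-random — the tempo is set once per song from the
   most recent cadence and never touched mid-song; songs start at a random
   phase.
3. period-adaptive, phase-starting — like 1, but song changes are queued
   and the queued song starts, skipped to its first annotated beat, at the
   wall time where the walker's predicted phase equals the configured
   start phase (0° or 180°).
4. period-adaptive and phase-adaptive — like 3 (0° starts), plus a
   continuous phase correction: whenever the step's relative phase leaves
   the ±band (default ±30°), the modifier is nudged by 0.03 so the beat
   schedule converges back onto the footfalls. A step lagging the beat
   (φ > +band) slows the music so the next beats wait for the walker; a
   step leading the beat (φ < −band) speeds it up.

The gait estimator averages the last up-to-5 accepted inter-step
intervals. A new interval is accepted only if it matches the averaged
interval or one of its harmonics (×0.5, ×1, ×2) within a relative margin;
otherwise the step is flagged erroneous and ignored by the controllers,
which suppresses false positives from stumbles, stops and sensor knocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .events import BeatEvent, FootfallEvent, RelativePhaseSample, phase_series, to_display
from .library import (
    DEFAULT_CLAMP,
    Library,
    PlaybackState,
    Song,
    SongSelectionError,
    advance,
    nearest_song,
    next_beats,
    set_tempo_modifier,
    start_song,
)

__all__ = [
    "GaitEstimate",
    "StrategyConfig",
    "StrategyState",
    "TraceRow",
    "update_gait_estimate",
    "AdaptivePlayer",
    "step_strategy1",
    "step_strategy2",
    "step_strategy3",
    "step_strategy4",
    "run_controller",
]

HARMONICS = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class GaitEstimate:
    """Averaged cadence over the last up-to-5 accepted inter-step intervals."""

    spm: float = float("nan")
    valid: bool = False
    window: tuple[float, ...] = ()
    last_interval: float = float("nan")  # last accepted raw interval
    last_rejected: bool = False


def update_gait_estimate(
    estimate: GaitEstimate,
    new_step_time: float,
    prev_step_time: float,
    window_size: int = 5,
    harmonic_margin: float = 0.2,
) -> GaitEstimate:
    """Fold one inter-step interval into the estimate, with harmonic gating.

    The interval enters the averaging window only if it lies within
    ``harmonic_margin`` (relative) of the current averaged interval or of
    its ×0.5 / ×2 harmonics; otherwise the estimate is returned unchanged
    with ``last_rejected`` set.
    """
    if new_step_time <= prev_step_time:
        raise ValueError(
            f"step times must increase: {prev_step_time} -> {new_step_time}")
    interval = new_step_time - prev_step_time
    if estimate.window:
        avg = float(np.mean(estimate.window))
        ok = any(abs(interval - h * avg) <= harmonic_margin * h * avg for h in HARMONICS)
        if not ok:
            return replace(estimate, last_rejected=True)
    window = (estimate.window + (interval,))[-window_size:]
    return GaitEstimate(
        spm=60.0 / float(np.mean(window)),
        valid=True,
        window=window,
        last_interval=interval,
        last_rejected=False,
    )


@dataclass(frozen=True)
class StrategyConfig:
    """Controller parameters shared by all four strategies."""

    strategy: int = 1
    start_phase_deg: float = 0.0       # strategy 3/4 song-start phase (0 or 180)
    band_deg: float = 30.0             # allowed synchronisation half-range
    nudge: float = 0.03                # strategy-4 modifier increment
    clamp: tuple[float, float] = DEFAULT_CLAMP
    debounce_s: float = 5.0            # out-of-range persistence before song change
    avg_window_steps: int = 5
    harmonic_margin: float = 0.2
    exclude_played: bool = True
    discrete_modifiers: bool = False   # quantise to whole-% pre-rendered versions

    def __post_init__(self):
        if self.strategy not in (1, 2, 3, 4):
            raise ValueError(f"strategy must be 1-4, got {self.strategy}")
        if not (0 < self.band_deg < 180):
            raise ValueError("band_deg must be in (0, 180)")
        if self.nudge <= 0:
            raise ValueError("nudge must be positive")


@dataclass(frozen=True)
class TraceRow:
    step_index: int
    time_s: float
    spm: float
    base_modifier: float
    nudge: float
    final_modifier: float
    song_id: str
    event: str  # none | song_change | rejected_step | queued_start


@dataclass
class StrategyState:
    """Per-step bookkeeping of the active controller."""

    playback: PlaybackState | None = None
    estimate: GaitEstimate = field(default_factory=GaitEstimate)
    out_of_range_since: float | None = None
    queued_song: Song | None = None
    delta: float = float("nan")  # music tempo minus raw gait tempo, per minute
    played: set = field(default_factory=set)
    last_step_time: float | None = None


class AdaptivePlayer:
    """Event-driven closed-loop music player running one alignment strategy.

    Call :meth:`on_footfall` for every detected footfall; the player emits
    beats, updates its cadence estimate, adapts the playback, and returns
    the beat schedule the walker currently hears. Deterministic given its
    seed (used only for the random-phase song starts of strategies 1/2).
    """

    def __init__(self, library: Library, cfg: StrategyConfig, seed: int = 0):
        if len(library) == 0:
            raise SongSelectionError("cannot run a controller on an empty library")
        self.library = library
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.state = StrategyState()
        self.beats: list[BeatEvent] = []
        self.trace: list[TraceRow] = []
        self._step_index = 0
        self._trace_base = float("nan")
        self._trace_nudge = 0.0

    # -- song selection ----------------------------------------------------

    def _choose(self, target_spm: float) -> Song:
        st = self.state
        exclude = st.played if self.cfg.exclude_played else set()
        try:
            song = nearest_song(self.library, target_spm, exclude)
        except SongSelectionError:
            st.played.clear()  # library exhausted: allow re-plays
            song = nearest_song(self.library, target_spm)
        st.played.add(song.song_id)
        return song

    def _ratio(self, song: Song) -> float:
        return self.state.estimate.spm / song.bpm

    def _quantise_mod(self, modifier: float) -> float:
        if not self.cfg.discrete_modifiers:
            return modifier
        return float(np.clip(np.round(modifier * 100) / 100, 0.97, 1.03))

    def _start_random_phase(self, now: float) -> None:
        """Start the nearest song at an uncontrolled (random) phase."""
        st = self.state
        song = self._choose(st.estimate.spm)
        modifier = self._quantise_mod(self._ratio(song))
        period = 60.0 / (song.bpm * np.clip(modifier, *self.cfg.clamp))
        wall = now + float(self.rng.uniform(0.0, period))
        st.playback = start_song(song, wall, skip_to_first_beat=True,
                                 clamp=self.cfg.clamp, tempo_modifier=modifier)
        st.out_of_range_since = None

    def _start_phase_aligned(self, now: float) -> None:
        """Start the queued (or nearest) song at the predicted phase moment.

        The first beat is scheduled at last footfall + T_step for a 0°
        start, or half a beat period earlier (+T_step/2) for 180°, with
        T_step the last accepted inter-step interval.
        """
        st = self.state
        song = st.queued_song if st.queued_song is not None else self._choose(st.estimate.spm)
        st.queued_song = None
        t_step = st.estimate.last_interval
        frac = 1.0 - (self.cfg.start_phase_deg % 360.0) / 360.0
        wall = now + t_step * frac
        st.playback = start_song(song, wall, skip_to_first_beat=True,
                                 clamp=self.cfg.clamp,
                                 tempo_modifier=self._ratio(song))
        st.out_of_range_since = None

    # -- debounce ----------------------------------------------------------

    def _debounce(self, out_of_range: bool, now: float) -> bool:
        """Track out-of-range persistence; True when the debounce expires."""
        st = self.state
        if not out_of_range:
            st.out_of_range_since = None
            return False
        if st.out_of_range_since is None:
            st.out_of_range_since = now
            return False
        if now - st.out_of_range_since > self.cfg.debounce_s:
            st.out_of_range_since = None
            return True
        return False

    # -- per-step loop -----------------------------------------------------

    def on_footfall(self, footfall: FootfallEvent) -> np.ndarray:
        """Process one footfall; returns the heard beat schedule (times)."""
        now = footfall.time
        st = self.state
        if st.playback is not None:
            new = advance(st.playback, now)
            self.beats.extend(new)

        event = "none"
        if footfall.valid and st.last_step_time is not None:
            prev = st.estimate
            st.estimate = update_gait_estimate(
                prev, now, st.last_step_time,
                window_size=self.cfg.avg_window_steps,
                harmonic_margin=self.cfg.harmonic_margin)
            if st.estimate.last_rejected:
                event = "rejected_step"
        if footfall.valid:
            st.last_step_time = now

        phi_display = self._phase_display(now)
        step_fn = {1: step_strategy1, 2: step_strategy2,
                   3: step_strategy3, 4: step_strategy4}[self.cfg.strategy]
        if self.cfg.strategy == 4:
            event = step_fn(self, footfall, phi_display, now) or event
        else:
            event = step_fn(self, footfall, now) or event

        self._record(now, event, self._trace_base, self._trace_nudge)
        self._trace_base, self._trace_nudge = float("nan"), 0.0
        self._step_index += 1
        return self.heard_schedule(now)

    def _phase_display(self, now: float) -> float | None:
        """Display-convention phase of `now` within the current schedule."""
        st = self.state
        if st.playback is None or not self.beats:
            return None
        prev_b = self.beats[-1]
        nxt = st.playback.next_beat_time
        if nxt is None or prev_b.time > now or now >= nxt:
            return None
        if prev_b.song_id != st.playback.song.song_id:
            return None
        phi = 360.0 * (now - prev_b.time) / (nxt - prev_b.time)
        return to_display(phi)

    def heard_schedule(self, now: float, n_past: int = 4, n_future: int = 4
                       ) -> np.ndarray:
        """Beat times around `now`: recent emitted plus imminent future."""
        past = [b.time for b in self.beats[-n_past:]]
        st = self.state
        future: list[float] = []
        if st.playback is not None and not st.playback.finished:
            horizon = n_future * 60.0 / st.playback.song.bpm * 2.0
            future = [b.time for b in next_beats(st.playback, horizon)[:n_future]]
        sched = np.array(past + future, dtype=float)
        return sched

    def _record(self, now: float, event: str,
                base_modifier: float = float("nan"),
                nudge: float = 0.0) -> None:
        st = self.state
        pb = st.playback
        self.trace.append(TraceRow(
            step_index=self._step_index, time_s=now,
            spm=st.estimate.spm,
            base_modifier=base_modifier if np.isfinite(base_modifier)
            else (pb.tempo_modifier if pb else float("nan")),
            nudge=nudge,
            final_modifier=pb.tempo_modifier if pb else float("nan"),
            song_id=pb.song.song_id if pb else "",
            event=event,
        ))

    def finalize(self, until: float) -> None:
        """Emit remaining beats up to `until` (for log completeness)."""
        st = self.state
        if st.playback is not None:
            self.beats.extend(advance(st.playback, until))

    def _update_delta(self) -> None:
        st = self.state
        if st.playback is not None and np.isfinite(st.estimate.last_interval):
            music_tempo = st.playback.song.bpm * st.playback.tempo_modifier
            st.delta = music_tempo - 60.0 / st.estimate.last_interval


# ---------------------------------------------------------------------------
# Strategy step functions. Each acts on the player's StrategyState for one
# footfall and returns a trace event label (or None).
# ---------------------------------------------------------------------------


def step_strategy1(player: AdaptivePlayer, footfall: FootfallEvent, now: float
                   ) -> str | None:
    """Period-adaptive phase-random: modifier tracks spm/bpm every step."""
    st = player.state
    if not st.estimate.valid:
        return None
    if st.playback is None or st.playback.finished:
        player._start_random_phase(now)
        return "song_change"
    if footfall.valid and not st.estimate.last_rejected:
        set_tempo_modifier(st.playback, player._ratio(st.playback.song))
        player._update_delta()
        if player._debounce(st.playback.request_out_of_range, now):
            player._start_random_phase(now)
            return "song_change"
    return None


def step_strategy2(player: AdaptivePlayer, footfall: FootfallEvent, now: float
                   ) -> str | None:
    """Period-fixed phase-random: tempo chosen once per song, never touched."""
    st = player.state
    if not st.estimate.valid:
        return None
    if st.playback is None or st.playback.finished:
        player._start_random_phase(now)
        return "song_change"
    player._update_delta()
    return None


def _adapt_and_queue(player: AdaptivePlayer, footfall: FootfallEvent, now: float
                     ) -> tuple[float, str | None]:
    """Shared period adaptation of strategies 3/4: returns (base ratio, event)."""
    st = player.state
    base = player._ratio(st.playback.song)
    event = None
    if footfall.valid and not st.estimate.last_rejected:
        lo, hi = player.cfg.clamp
        if player._debounce(not (lo <= base <= hi), now) and st.queued_song is None:
            st.queued_song = player._choose(st.estimate.spm)
            event = "queued_start"
    return base, event


def step_strategy3(player: AdaptivePlayer, footfall: FootfallEvent, now: float
                   ) -> str | None:
    """Period-adaptive with phase-aligned song starts."""
    st = player.state
    if not st.estimate.valid:
        return None
    if st.playback is None or st.playback.finished:
        player._start_phase_aligned(now)
        return "song_change"
    base, event = _adapt_and_queue(player, footfall, now)
    if st.queued_song is not None:
        player._start_phase_aligned(now)
        return "song_change"
    if footfall.valid and not st.estimate.last_rejected:
        set_tempo_modifier(st.playback, base)
        player._update_delta()
    return event


def step_strategy4(player: AdaptivePlayer, footfall: FootfallEvent,
                   phi_display: float | None, now: float) -> str | None:
    """Period- and phase-adaptive: strategy 3 (0° starts) plus band nudges.

    When the step's phase leaves the allowed band the modifier is nudged
    once, after the base ratio and before the clamp: a step lagging the
    beat (φ > +band) slows the music by `nudge`, a leading step speeds it
    up, driving the relative phase back inside the band.
    """
    st = player.state
    if not st.estimate.valid:
        return None
    if st.playback is None or st.playback.finished:
        player._start_phase_aligned(now)
        return "song_change"
    base, event = _adapt_and_queue(player, footfall, now)
    if st.queued_song is not None:
        player._start_phase_aligned(now)
        return "song_change"
    if footfall.valid and not st.estimate.last_rejected:
        nudge = 0.0
        if phi_display is not None:
            if phi_display > player.cfg.band_deg:
                nudge = -player.cfg.nudge
            elif phi_display < -player.cfg.band_deg:
                nudge = player.cfg.nudge
        set_tempo_modifier(st.playback, base + nudge)
        player._update_delta()
        player._trace_base, player._trace_nudge = base, nudge
    return event


def run_controller(
    strategy_cfg: StrategyConfig,
    library: Library,
    footfall_stream: Sequence[FootfallEvent],
    seed: int = 0,
) -> tuple[list[BeatEvent], list[RelativePhaseSample], list[TraceRow]]:
    """Replay a footfall stream through a strategy (open loop).

    Returns the full emitted beat schedule, the per-step relative phases
    recomputed from the logs, and the controller trace.
    """
    player = AdaptivePlayer(library, strategy_cfg, seed=seed)
    last_t = 0.0
    for ev in footfall_stream:
        player.on_footfall(ev)
        last_t = ev.time
    if player.state.playback is not None:
        period = 60.0 / player.state.playback.song.bpm
        player.finalize(last_t + 2 * period)
    phases = phase_series(footfall_stream, player.beats)
    return player.beats, phases, player.trace
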