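"""Synthetic walker: stochastic cadence with attractor-based entrainment.

The walker is a discrete per-step phase-correction map in the spirit of
the HKB coupled-oscillator model. At footfall n with relative phase φ_n to
the heard beats (radians), the next inter-step interval is

    I_{n+1} = T_pref / detuning + ε_n − (a·sin φ_n + b·sin 2φ_n) · T_beat / 2π

where T_pref = 60/base_spm, ε_n is step-timing noise and T_beat the current
beat period. With a > 0 the in-phase fixed point (φ = 0) is stable and
anti-phase (φ = 180°) unstable; when 2b > a a locally stable anti-phase
fixed point appears whose basin (half-width arccos(−a/2b)) is smaller than
the in-phase basin — the asymmetry that makes offbeat synchronisation
fragile. With a = b = 0 the walker ignores the music entirely.

The sensor model reproduces a 100 Hz event logger: footfall times are
rounded up to the next sample tick, giving a mean detection error of half
a sample period (5 ms at 100 Hz) and a maximum below one period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .events import FootfallEvent

__all__ = [
    "WalkerParams",
    "SensorParams",
    "ScenarioEvent",
    "SimulationError",
    "simulate_walk",
    "quantise_events",
    "make_cohort",
    "DEFAULT_WALKER",
    "DEFAULT_COHORT_RANGES",
]


class SimulationError(RuntimeError):
    """The player callback returned an unusable (non-monotone) schedule."""


@dataclass(frozen=True)
class WalkerParams:
    """Intrinsic cadence, variability and music coupling of one walker.

    coupling_a / coupling_b are the in-phase and anti-phase attractor
    gains (dimensionless phase-correction per step); detuning is the ratio
    of intrinsic to nominal tempo (1 = none). noise_mode "white" draws
    independent Gaussian step perturbations; "pink" synthesises a 1/f-like
    long-memory series, matching the spectral character reported for
    healthy gait.
    """

    base_spm: float = 115.0
    noise_sd: float = 0.015
    coupling_a: float = 0.12
    coupling_b: float = 0.08
    detuning: float = 1.0
    seed: int = 0
    noise_mode: str = "white"

    def __post_init__(self):
        if self.base_spm <= 0:
            raise ValueError("base_spm must be positive")
        if self.noise_sd < 0 or self.coupling_a < 0 or self.coupling_b < 0:
            raise ValueError("noise_sd and coupling gains must be non-negative")


DEFAULT_WALKER = WalkerParams()

#: Cohort parameter ranges emulating a healthy adult group: cadence in the
#: natural 110–120 SPM walking band, step-time SD 12–18 ms, phase-correction
#: gains in the weakly-coupled regime, mild tempo preference spread.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "base_spm": (110.0, 120.0),
    "noise_sd": (0.012, 0.018),
    "coupling_a": (0.08, 0.16),
    "coupling_b": (0.05, 0.10),
    "detuning": (0.99, 1.01),
}


@dataclass(frozen=True)
class SensorParams:
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class ScenarioEvent:
    """A disturbance during a trial: a pause (magnitude = gap seconds), a
    cadence jump (magnitude = multiplicative factor on cadence) or a missed
    step (the next footfall is logged as invalid)."""

    time: float
    kind: str  # pause | cadence_jump | missed_step
    magnitude: float = 0.0

    def __post_init__(self):
        if self.kind not in ("pause", "cadence_jump", "missed_step"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-like noise via spectral synthesis (amplitude ∝ f^-1/2)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    x = (x - x.mean()) / max(x.std(), 1e-12)
    return sd * x


def _phase_at(t: float, schedule: np.ndarray) -> tuple[float, float] | None:
    """(φ in radians, beat period) of time t within the heard schedule."""
    if schedule is None or len(schedule) < 2:
        return None
    i = int(np.searchsorted(schedule, t, side="right")) - 1
    if i < 0 or i + 1 >= len(schedule):
        return None
    prev_b, next_b = schedule[i], schedule[i + 1]
    period = next_b - prev_b
    return 2 * np.pi * (t - prev_b) / period, period


def simulate_walk(
    walker: WalkerParams,
    player_callback: Callable[[FootfallEvent], Sequence[float]] | None,
    duration: float,
    scenario: Sequence[ScenarioEvent] = (),
    participant_id: str = "p0",
) -> list[FootfallEvent]:
    """Closed-loop walking simulation.

    After every emitted footfall the ``player_callback`` is invoked with the
    event and must return the beat schedule the walker currently hears
    (sorted times bracketing the present). The walker's next inter-step
    interval then applies the attractor correction to its phase within that
    schedule. A ``None`` callback (or an empty schedule) yields uncoupled
    walking.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(walker.seed)
    t_pref = 60.0 / walker.base_spm
    cadence_factor = 1.0

    max_steps = int(np.ceil(duration / (0.25 * t_pref))) + 2
    if walker.noise_mode == "pink":
        noise = _pink_noise(max_steps, walker.noise_sd, rng)
    elif walker.noise_mode == "white":
        noise = rng.normal(0.0, walker.noise_sd, size=max_steps)
    else:
        raise ValueError(f"unknown noise_mode {walker.noise_mode!r}")

    pending = sorted(scenario, key=lambda e: e.time)
    events: list[FootfallEvent] = []
    t = 0.0
    next_valid = True
    n = 0
    while t < duration and n < max_steps:
        ev = FootfallEvent(time=t, valid=next_valid, participant_id=participant_id)
        events.append(ev)
        next_valid = True

        schedule = None
        if player_callback is not None:
            schedule = np.asarray(player_callback(ev), dtype=float)
            if schedule.size and np.any(np.diff(schedule) <= 0):
                raise SimulationError("player callback returned a non-monotone beat schedule")

        correction = 0.0
        if walker.coupling_a > 0 or walker.coupling_b > 0:
            ph = _phase_at(t, schedule)
            if ph is not None:
                phi, period = ph
                correction = (
                    walker.coupling_a * np.sin(phi)
                    + walker.coupling_b * np.sin(2 * phi)
                ) * period / (2 * np.pi)

        interval = t_pref * cadence_factor / walker.detuning + noise[n] - correction
        interval = max(interval, 0.25 * t_pref)

        t_next = t + interval
        while pending and pending[0].time <= t_next:
            sev = pending.pop(0)
            if sev.kind == "pause":
                # gap plus a random phase reset within one step period
                t_next += sev.magnitude + rng.uniform(0.0, t_pref)
            elif sev.kind == "cadence_jump":
                cadence_factor *= sev.magnitude
            elif sev.kind == "missed_step":
                next_valid = False
        t = t_next
        n += 1
    return events


def quantise_events(events: Sequence[FootfallEvent], sensor: SensorParams
                    ) -> list[FootfallEvent]:
    """Snap each event time up to the next sensor sample tick.

    A sensor cannot report an event before it happens, so times are
    ceiled to the sampling grid; an event already on a tick is unchanged.
    The per-event displacement is < one sample period (mean half a period
    for uniformly-offset events). Never reorders events.
    """
    rate = sensor.sample_rate
    out = []
    for ev in events:
        tick = np.ceil(ev.time * rate - 1e-9) / rate
        out.append(replace(ev, time=float(tick)))
    return out


def make_cohort(
    n_participants: int,
    param_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    non_entrainer_fraction: float = 0.3,
) -> list[WalkerParams]:
    """Reproducible cohort of walkers spanning the given parameter ranges.

    A fixed fraction (rounded) of the cohort are non-entrainers with both
    coupling gains zero — there will always be people who do not
    synchronise. Each walker gets its own sub-seed, so extending the
    cohort never perturbs earlier participants.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)

    cohort = []
    for i in range(n_participants):
        rng = np.random.default_rng(children[i])
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        # deterministic striding: exact counts and stable under cohort extension
        flat = np.floor((i + 1) * non_entrainer_fraction) > np.floor(i * non_entrainer_fraction)
        if flat:
            draws["coupling_a"] = 0.0
            draws["coupling_b"] = 0.0
        cohort.append(WalkerParams(seed=sub_seed, **draws))
    return cohort
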