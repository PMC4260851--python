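"""Reproducible closed-loop trials and cohort experiments.

A trial wires one synthetic walker to one adaptive player for a fixed
duration, logs footfalls, beats, the controller trace and per-step phases,
and summarises the phase distribution. A cohort experiment runs a whole
group of walkers under one or more conditions (e.g. the 0° and 180°
starting-phase variants of the phase-starting strategy), pools the phases
per condition, classifies each participant with a per-participant Rayleigh
test, and compares paired conditions with Watson's two-sample U².

Everything is a pure function of (config, seed): the cohort's walker
parameters derive from the master seed, and each (participant, condition)
player gets its own counter-derived sub-seed, so runs are bit-reproducible
and cohorts extensible without perturbing earlier participants.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import circstats
from .circstats import CircTestResult, PhaseSummary, rayleigh_test, summarize
from .events import (
    FootfallEvent,
    phase_series,
    read_beats,
    read_footfalls,
    write_beats,
    write_footfalls,
    write_phases,
)
from .library import Library, Song, load_library
from .strategies import AdaptivePlayer, StrategyConfig, TraceRow
from .walker import SensorParams, WalkerParams, make_cohort, quantise_events, simulate_walk

__all__ = [
    "ExperimentConfig",
    "CohortSpec",
    "TrialResult",
    "SummaryReport",
    "default_library",
    "run_trial",
    "run_cohort",
    "analyze_logs",
    "report",
]

SUMMARY_FIELDS = ["n", "mean_angle_deg", "ci95_low_deg", "ci95_high_deg",
                  "R", "V", "s", "b", "k"]


def default_library(bpm_low: float = 80.0, bpm_high: float = 140.0,
                    bpm_step: float = 2.0, duration_s: float = 120.0) -> Library:
    """A synthetic pop-playlist stand-in: isochronous songs covering the
    walking-tempo range with several candidates per cadence."""
    lib = Library()
    for bpm in np.arange(bpm_low, bpm_high + 1e-9, bpm_step):
        lib.add(Song(song_id=f"s{int(round(bpm)):03d}", bpm=float(bpm),
                     duration_s=duration_s))
    return lib


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int = 10
    param_ranges: dict | None = None
    non_entrainer_fraction: float = 0.3


@dataclass
class ExperimentConfig:
    """One experiment: a strategy (or several named conditions), a walker
    cohort or an external footfall log, a library, a duration and a seed."""

    strategy_cfg: StrategyConfig = field(default_factory=StrategyConfig)
    conditions: dict[str, StrategyConfig] | None = None
    cohort: CohortSpec | None = field(default_factory=CohortSpec)
    footfall_log: str | None = None
    library: Library | str | None = None
    duration_s: float = 600.0
    seed: int = 0
    sensor: SensorParams | None = field(default_factory=SensorParams)
    output_dir: str | None = None

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if (self.cohort is None) == (self.footfall_log is None):
            raise ValueError("configure exactly one of cohort / footfall_log")

    def resolve_library(self) -> Library:
        if self.library is None:
            return default_library()
        if isinstance(self.library, Library):
            return self.library
        return load_library(self.library)

    def resolved_conditions(self) -> dict[str, StrategyConfig]:
        if self.conditions:
            return dict(self.conditions)
        scfg = self.strategy_cfg
        label = f"strategy{scfg.strategy}"
        if scfg.strategy in (3,):
            label += f"_{int(scfg.start_phase_deg)}deg"
        return {label: scfg}


@dataclass
class TrialResult:
    participant_id: str
    footfalls: list
    beats: list
    phases: list
    trace: list
    summary: PhaseSummary | None
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def phi_display(self) -> np.ndarray:
        return np.array([p.phi_display for p in self.phases])


def _player_seed(master_seed: int, participant_index: int, condition_index: int) -> int:
    ss = np.random.SeedSequence([master_seed, participant_index, condition_index, 7919])
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(
    cfg: ExperimentConfig,
    participant: WalkerParams,
    strategy_cfg: StrategyConfig | None = None,
    participant_id: str = "p0",
    condition_label: str = "",
    condition_index: int = 0,
    participant_index: int = 0,
) -> TrialResult:
    """One closed-loop trial: walker ↔ player for ``cfg.duration_s`` seconds.

    The player sees sensor-quantised footfall times (when a sensor model is
    configured); the walker hears the true beat schedule with zero latency.
    Logs are written under ``cfg.output_dir`` when set, and the per-step
    phases are recomputed from the logs alone, so any sample is
    reproducible from the CSVs.
    """
    scfg = strategy_cfg if strategy_cfg is not None else cfg.strategy_cfg
    library = cfg.resolve_library()
    player = AdaptivePlayer(
        library, scfg,
        seed=_player_seed(cfg.seed, participant_index, condition_index))
    sensor = cfg.sensor
    detected: list[FootfallEvent] = []

    def callback(ev: FootfallEvent) -> np.ndarray:
        if sensor is not None:
            ev_d = quantise_events([ev], sensor)[0]
        else:
            ev_d = ev
        detected.append(ev_d)
        player.on_footfall(ev_d)
        return player.heard_schedule(ev.time)

    simulate_walk(participant, callback, cfg.duration_s,
                  participant_id=participant_id)
    player.finalize(cfg.duration_s + 2.0)
    phases = phase_series(detected, player.beats)
    summary = summarize([p.phi_display for p in phases]) if phases else None

    files: dict[str, Path] = {}
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        if condition_label:
            out = out / condition_label
        out.mkdir(parents=True, exist_ok=True)
        tag = participant_id
        files["footfalls"] = out / f"{tag}_footfalls.csv"
        write_footfalls(files["footfalls"], detected)
        files["beats"] = out / f"{tag}_beats.csv"
        write_beats(files["beats"], player.beats)
        files["phases"] = out / f"{tag}_phases.csv"
        write_phases(files["phases"], phases, participant_id=participant_id)
        files["trace"] = out / f"{tag}_trace.csv"
        pd.DataFrame([asdict(t) for t in player.trace]).to_csv(files["trace"], index=False)
    return TrialResult(participant_id=participant_id, footfalls=detected,
                       beats=player.beats, phases=phases, trace=player.trace,
                       summary=summary, files=files)


@dataclass
class SummaryReport:
    """Cohort-level results: pooled summaries per condition, per-participant
    synchrony, uniformity tests and paired-condition comparisons."""

    pooled: dict[str, PhaseSummary]
    participant_R: dict[str, dict[str, float]]
    participant_rayleigh_p: dict[str, dict[str, float]]
    sync_fraction: dict[str, float]
    uniformity: dict[str, dict[str, CircTestResult]]
    watson: dict[tuple[str, str], CircTestResult]
    pooled_angles: dict[str, np.ndarray]


def run_cohort(cfg: ExperimentConfig, alpha: float = 0.05) -> SummaryReport:
    """Run every participant under every configured condition and analyse.

    Pools phases per condition for the Table-style summary, classifies each
    participant by a per-participant Rayleigh test (no multiplicity
    correction, α configurable), and — when several conditions are
    configured — compares each pair with Watson's two-sample U².
    """
    if cfg.cohort is None:
        raise ValueError("run_cohort needs a cohort spec")
    cohort = make_cohort(cfg.cohort.n_participants, cfg.cohort.param_ranges,
                         seed=cfg.seed,
                         non_entrainer_fraction=cfg.cohort.non_entrainer_fraction)
    conditions = cfg.resolved_conditions()
    pooled_angles: dict[str, np.ndarray] = {}
    pR: dict[str, dict[str, float]] = {}
    pP: dict[str, dict[str, float]] = {}
    for ci, (label, scfg) in enumerate(conditions.items()):
        angles_all = []
        pR[label], pP[label] = {}, {}
        for pi, walker in enumerate(cohort):
            pid = f"p{pi:03d}"
            res = run_trial(cfg, walker, strategy_cfg=scfg, participant_id=pid,
                            condition_label=label, condition_index=ci,
                            participant_index=pi)
            ang = res.phi_display
            angles_all.append(ang)
            if ang.size >= 3:
                _, R = circstats.mean_resultant(ang)
                pR[label][pid] = R
                pP[label][pid] = rayleigh_test(ang).p_value
        pooled_angles[label] = np.concatenate(angles_all) if angles_all else np.array([])

    pooled = {lab: summarize(a) for lab, a in pooled_angles.items() if a.size}
    sync = {lab: float(np.mean([p < alpha for p in pP[lab].values()]))
            for lab in conditions if pP[lab]}
    uniformity = {
        lab: {
            "rayleigh": circstats.rayleigh_test(a),
            "hodges_ajne": circstats.hodges_ajne_test(a),
        }
        for lab, a in pooled_angles.items() if a.size >= 9
    }
    watson = {}
    for a_lab, b_lab in itertools.combinations(conditions, 2):
        if pooled_angles[a_lab].size and pooled_angles[b_lab].size:
            watson[(a_lab, b_lab)] = circstats.watson_u2_two_sample(
                pooled_angles[a_lab], pooled_angles[b_lab])
    return SummaryReport(pooled=pooled, participant_R=pR,
                         participant_rayleigh_p=pP, sync_fraction=sync,
                         uniformity=uniformity, watson=watson,
                         pooled_angles=pooled_angles)


def analyze_logs(footfalls_path, beats_path) -> tuple[list, PhaseSummary | None]:
    """Recompute phases and their summary from footfall/beat CSV logs
    (usable on externally recorded gait logs, not only simulated ones)."""
    footfalls = read_footfalls(footfalls_path)
    beats = read_beats(beats_path)
    phases = phase_series(footfalls, beats)
    summary = summarize([p.phi_display for p in phases]) if phases else None
    return phases, summary


def _summary_frame(report_obj: SummaryReport) -> pd.DataFrame:
    cols = {}
    for lab, s in report_obj.pooled.items():
        cols[lab] = [getattr(s, f) for f in SUMMARY_FIELDS]
    return pd.DataFrame(cols, index=SUMMARY_FIELDS)


def report(summary: SummaryReport, fmt: str, out_dir) -> dict[str, Path]:
    """Emit the summary-table (rows: the eight distribution parameters,
    columns: conditions) plus the per-participant resultant lengths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _summary_frame(summary)
    pr = pd.DataFrame(summary.participant_R)
    files: dict[str, Path] = {}
    if fmt == "csv":
        files["summary"] = out / "summary.csv"
        df.to_csv(files["summary"])
        files["participants"] = out / "participant_R.csv"
        pr.to_csv(files["participants"])
    elif fmt == "json":
        files["summary"] = out / "summary.json"
        payload = {
            "schema_version": 1,
            "pooled": {lab: dict(zip(SUMMARY_FIELDS, map(float, df[lab])))
                       for lab in df.columns},
            "sync_fraction": summary.sync_fraction,
            "participant_R": summary.participant_R,
            "tests": {
                lab: {name: {"statistic": t.statistic, "p_value": t.p_value, "n": t.n}
                      for name, t in tests.items()}
                for lab, tests in summary.uniformity.items()
            },
            "watson_u2": {
                f"{a}|{b}": {"statistic": t.statistic, "p_value": t.p_value}
                for (a, b), t in summary.watson.items()
            },
        }
        files["summary"].write_text(json.dumps(payload, indent=1))
    elif fmt == "markdown":
        files["summary"] = out / "summary.md"
        files["summary"].write_text(df.to_markdown())
    else:
        raise ValueError(f"unknown report format {fmt!r} (csv|json|markdown)")
    return files
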