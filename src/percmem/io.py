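"""File formats and run configuration.

All tabular artifacts are plain CSV (comma, UTF-8, dot decimal).  Trial
logs serialize disambiguation strengths as *integer tenths* so the 0.1-step
grid survives round trips exactly; probe rows leave the segment columns
empty.  Malformed rows are reported with their line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observer import MISSING, ObserverParams, SessionData, TrialRecord, default_kernel
from .schedules import DisambiguationSchedule, DisambiguationSequence
from .triplets import ReverseCorrelationEstimate

__all__ = [
    "TrialLogError",
    "RunConfig",
    "write_trial_log",
    "read_trial_log",
    "write_estimates",
    "load_config",
]

_FIXED_COLUMNS = ["participant", "experiment", "trial_index", "trial_type", "report"]


class TrialLogError(ValueError):
    """A malformed trial log row; the message names the offending line."""


def _segment_columns(n_segments: int) -> list[str]:
    return [f"seg_{k:02d}" for k in range(1, n_segments + 1)]


def write_trial_log(sessions: dict[str, SessionData], path: str | Path) -> None:
    """Write sessions for all participants to one trial-log CSV."""
    schedules = {s.schedule.n_segments for s in sessions.values()}
    if len(schedules) != 1:
        raise ValueError("all sessions must share one schedule")
    n_seg = schedules.pop()
    seg_cols = _segment_columns(n_seg)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FIXED_COLUMNS + seg_cols)
        for participant, session in sessions.items():
            variant = session.schedule.variant
            for t in session.trials:
                segs = (
                    [""] * n_seg
                    if t.raw_sequence is None
                    else [str(int(v)) for v in t.raw_sequence.tenths]
                )
                writer.writerow(
                    [participant, variant, t.trial_index, t.trial_type, t.report]
                    + segs
                )


def read_trial_log(path: str | Path) -> dict[str, SessionData]:
    """Read a trial-log CSV back into per-participant sessions.

    Validates the header, the 21-level strength grid, probe/prime schema
    and (participant, trial_index) uniqueness; any violation raises
    TrialLogError naming the line.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrialLogError(f"{path}: empty file") from None
        if header[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
            raise TrialLogError(f"{path}: bad header {header[:5]}")
        seg_cols = header[len(_FIXED_COLUMNS) :]
        n_seg = len(seg_cols)
        if seg_cols != _segment_columns(n_seg) or n_seg == 0:
            raise TrialLogError(f"{path}: bad segment columns {seg_cols}")

        rows: dict[str, list[TrialRecord]] = {}
        variants: dict[str, str] = {}
        seen: set[tuple[str, int]] = set()
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise TrialLogError(f"{path}:{lineno}: expected {len(header)} fields")
            participant, variant, idx_s, trial_type, report = row[:5]
            try:
                idx = int(idx_s)
            except ValueError:
                raise TrialLogError(
                    f"{path}:{lineno}: bad trial_index {idx_s!r}"
                ) from None
            key = (participant, idx)
            if key in seen:
                raise TrialLogError(
                    f"{path}:{lineno}: duplicate (participant, trial_index) {key}"
                )
            seen.add(key)
            segs = row[5:]
            if trial_type == "probe":
                if any(s != "" for s in segs):
                    raise TrialLogError(
                        f"{path}:{lineno}: probe row carries segment strengths"
                    )
                seq = None
            elif trial_type == "prime":
                try:
                    tenths = np.array([int(s) for s in segs], dtype=np.int64)
                except ValueError:
                    raise TrialLogError(
                        f"{path}:{lineno}: strengths must be integer tenths"
                    ) from None
                if np.any(np.abs(tenths) > 10):
                    raise TrialLogError(
                        f"{path}:{lineno}: strength off the 0.1 grid in [-1, 1]"
                    )
                seq = DisambiguationSequence(tenths)
            else:
                raise TrialLogError(f"{path}:{lineno}: bad trial_type {trial_type!r}")
            if report not in ("left", "right", MISSING):
                raise TrialLogError(f"{path}:{lineno}: bad report {report!r}")
            try:
                record = TrialRecord(participant, idx, trial_type, seq, report)
            except ValueError as exc:
                raise TrialLogError(f"{path}:{lineno}: {exc}") from None
            rows.setdefault(participant, []).append(record)
            variants.setdefault(participant, variant)

        sessions = {}
        for participant, trials in rows.items():
            trials.sort(key=lambda t: t.trial_index)
            schedule = DisambiguationSchedule.from_variant(
                variants[participant], n_segments=n_seg
            )
            sessions[participant] = SessionData(schedule=schedule, trials=trials)
        return sessions


def estimates_frame(
    estimates: dict[str, ReverseCorrelationEstimate], onsets_ms: list[int]
) -> pd.DataFrame:
    """Long-format table of per-segment estimates, one block per participant."""
    rows = []
    for participant, est in estimates.items():
        for k in range(est.mean.size):
            rows.append(
                {
                    "participant": participant,
                    "selection": est.selection,
                    "segment_index": k + 1,
                    "onset_ms": onsets_ms[k],
                    "mean": est.mean[k],
                    "ci_lo": est.ci_lo[k],
                    "ci_hi": est.ci_hi[k],
                    "n_trials": est.n_trials,
                }
            )
    return pd.DataFrame(rows)


def write_estimates(
    estimates: dict[str, ReverseCorrelationEstimate],
    onsets_ms: list[int],
    path: str | Path,
) -> pd.DataFrame:
    """Write per-segment estimates (one block per participant or 'group')."""
    df = estimates_frame(estimates, onsets_ms)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate a full run from scratch."""

    schedule_variant: str = "onset_only"
    n_segments: int | None = None
    segment_ms: int | None = None
    n_participants: int = 4
    n_primes: int = 1000
    observer: ObserverParams = field(default_factory=ObserverParams)
    seed_simulation: int = 0
    seed_bootstrap: int = 0
    seed_mcmc: int = 0
    bootstrap_iterations: int = 2000
    interval_mass: float = 0.97
    mcmc_walkers: int | None = None
    mcmc_warmup: int = 10_000
    mcmc_steps: int = 40_000
    mcmc_thin: int = 80

    def schedule(self) -> DisambiguationSchedule:
        return DisambiguationSchedule.from_variant(
            self.schedule_variant,
            n_segments=self.n_segments,
            segment_ms=self.segment_ms,
        )


_TOP_KEYS = {"schedule", "observer", "simulation", "seeds", "bootstrap", "mcmc"}
_SECTION_KEYS = {
    "schedule": {"variant", "n_segments", "segment_ms"},
    "observer": {
        "kernel",
        "gain_perception",
        "gain_memory",
        "baseline_perception",
        "baseline_memory",
        "lapse",
        "p_miss",
    },
    "simulation": {"n_participants", "n_primes"},
    "seeds": {"simulation", "bootstrap", "mcmc"},
    "bootstrap": {"n_iterations", "interval_mass"},
    "mcmc": {"n_walkers", "n_warmup", "n_steps", "thin"},
}


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys and missing seeds are rejected."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        extra = set(raw.get(section, {}) or {}) - allowed
        if extra:
            raise ValueError(f"unknown keys in '{section}': {sorted(extra)}")
    seeds = raw.get("seeds") or {}
    missing = {"simulation", "bootstrap", "mcmc"} - set(seeds)
    if missing:
        raise ValueError(f"seeds must be explicit; missing: {sorted(missing)}")

    sched = raw.get("schedule") or {}
    sim = raw.get("simulation") or {}
    boot = raw.get("bootstrap") or {}
    mcmc = raw.get("mcmc") or {}
    obs_raw = dict(raw.get("observer") or {})
    n_segments = sched.get("n_segments")
    segment_ms = sched.get("segment_ms")
    if "kernel" in obs_raw:
        obs_raw["kernel"] = np.asarray(obs_raw["kernel"], dtype=float)
    else:
        obs_raw["kernel"] = default_kernel(n_segments or 10)
    observer = ObserverParams(**obs_raw)
    return RunConfig(
        schedule_variant=sched.get("variant", "onset_only"),
        n_segments=n_segments,
        segment_ms=segment_ms,
        n_participants=int(sim.get("n_participants", 4)),
        n_primes=int(sim.get("n_primes", 1000)),
        observer=observer,
        seed_simulation=int(seeds["simulation"]),
        seed_bootstrap=int(seeds["bootstrap"]),
        seed_mcmc=int(seeds["mcmc"]),
        bootstrap_iterations=int(boot.get("n_iterations", 2000)),
        interval_mass=float(boot.get("interval_mass", 0.97)),
        mcmc_walkers=mcmc.get("n_walkers"),
        mcmc_warmup=int(mcmc.get("n_warmup", 10_000)),
        mcmc_steps=int(mcmc.get("n_steps", 40_000)),
        mcmc_thin=int(mcmc.get("thin", 80)),
    )
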