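"""Probe-prime-probe triplets and reverse-correlation estimates.

Trials are grouped into triplets consisting of a leading probe, a prime and
a trailing probe, all with valid (non-missing) reports.  Outcomes are
classified against the leading probe's report in a 2x2:

* the *prime* changed iff the prime's report differs from the leading probe's;
* *memory* changed iff the trailing probe's report differs from the leading
  probe's.

The reverse-correlation estimate for a selection (``prime_changed`` =
classes {both_changed, prime_only}; ``memory_changed`` = classes
{both_changed, memory_only}) is the per-segment arithmetic mean of the
sign-aligned sequences over the selected triplets, with 97% percentile
bootstrap confidence intervals (2,000 iterations by default).  Group
intervals use a two-stage scheme: resample trials within each participant
per segment, average per participant, then average the participant means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .observer import MISSING, SessionData

__all__ = [
    "Triplet",
    "TripletClass",
    "BootstrapConfig",
    "ReverseCorrelationEstimate",
    "NoQualifyingTrialsError",
    "SELECTIONS",
    "build_triplets",
    "align_sign",
    "classify",
    "selection_matrix",
    "average_sequence",
    "bootstrap_individual",
    "bootstrap_group",
]


class TripletClass(Enum):
    """Four-way perceptual outcome of a triplet."""

    BOTH_CHANGED = "both_changed"
    PRIME_ONLY = "prime_only"
    MEMORY_ONLY = "memory_only"
    NO_CHANGE = "no_change"


#: Selection sets used for reverse-correlation averages.
SELECTIONS: dict[str, frozenset[TripletClass]] = {
    "prime_changed": frozenset({TripletClass.BOTH_CHANGED, TripletClass.PRIME_ONLY}),
    "memory_changed": frozenset({TripletClass.BOTH_CHANGED, TripletClass.MEMORY_ONLY}),
}


class NoQualifyingTrialsError(ValueError):
    """Raised when a selection contains no triplets (never a silent zero)."""


@dataclass(frozen=True)
class Triplet:
    participant: str
    leading_probe_report: str
    prime_report: str
    trailing_probe_report: str
    sequence_rel: np.ndarray = field(repr=False)  # positive = same as leading probe

    def __post_init__(self) -> None:
        for r in (
            self.leading_probe_report,
            self.prime_report,
            self.trailing_probe_report,
        ):
            if r not in ("left", "right"):
                raise ValueError(f"triplet reports must be valid, got {r!r}")
        object.__setattr__(
            self, "sequence_rel", np.asarray(self.sequence_rel, dtype=float)
        )


@dataclass(frozen=True)
class BootstrapConfig:
    n_iterations: int = 2000
    interval_mass: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 < self.interval_mass < 1.0:
            raise ValueError("interval_mass must lie in (0, 1)")


@dataclass(frozen=True)
class ReverseCorrelationEstimate:
    """Per-segment mean strength with bootstrap CI for one selection set."""

    selection: str
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_trials: int


def align_sign(raw_sequence: np.ndarray, leading_probe_report: str) -> np.ndarray:
    """Re-sign a sequence so positive = same direction as the leading probe.

    Raw sequences use the absolute convention (positive cues "right").
    Aligning twice with the same report is the identity.
    """
    if leading_probe_report == MISSING:
        raise ValueError("cannot align against a missing leading report")
    if leading_probe_report not in ("left", "right"):
        raise ValueError(f"bad report {leading_probe_report!r}")
    raw = np.asarray(raw_sequence, dtype=float)
    return raw if leading_probe_report == "right" else -raw


def classify(triplet: Triplet) -> TripletClass:
    """Label a triplet by which percepts changed relative to the leading probe."""
    prime_changed = triplet.prime_report != triplet.leading_probe_report
    memory_changed = triplet.trailing_probe_report != triplet.leading_probe_report
    if prime_changed and memory_changed:
        return TripletClass.BOTH_CHANGED
    if prime_changed:
        return TripletClass.PRIME_ONLY
    if memory_changed:
        return TripletClass.MEMORY_ONLY
    return TripletClass.NO_CHANGE


def build_triplets(session: SessionData, *, sliding: bool = True) -> list[Triplet]:
    """Extract probe-prime-probe triplets from a session.

    One triplet per prime whose own report and both flanking probe reports
    are valid.  With ``sliding=True`` (default) a probe may serve as the
    trailing probe of one triplet and the leading probe of the next; with
    ``sliding=False`` triplets are disjoint (a probe is consumed once).
    """
    trials = session.trials
    triplets: list[Triplet] = []
    last_used = -1  # index of the last probe consumed as a trailing probe
    for j in range(1, len(trials) - 1):
        t = trials[j]
        if t.trial_type != "prime" or t.report == MISSING:
            continue
        lead, trail = trials[j - 1], trials[j + 1]
        if lead.trial_type != "probe" or trail.trial_type != "probe":
            continue
        if lead.report == MISSING or trail.report == MISSING:
            continue
        if not sliding and j - 1 <= last_used:
            continue
        assert t.raw_sequence is not None
        triplets.append(
            Triplet(
                participant=t.participant,
                leading_probe_report=lead.report,
                prime_report=t.report,
                trailing_probe_report=trail.report,
                sequence_rel=align_sign(t.raw_sequence.values, lead.report),
            )
        )
        last_used = j + 1
    return triplets


def selection_matrix(triplets: list[Triplet], selection: str) -> np.ndarray:
    """Stack the aligned sequences of the selected triplets into (n, n_seg)."""
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}")
    classes = SELECTIONS[selection]
    rows = [t.sequence_rel for t in triplets if classify(t) in classes]
    if not rows:
        raise NoQualifyingTrialsError(
            f"no qualifying trials for selection {selection!r}"
        )
    return np.vstack(rows)


def average_sequence(triplets: list[Triplet], selection: str) -> np.ndarray:
    """Per-segment mean of the aligned sequences over a selection set."""
    return selection_matrix(triplets, selection).mean(axis=0)


def _percentile_interval(samples: np.ndarray, mass: float) -> tuple[np.ndarray, np.ndarray]:
    tail = (1.0 - mass) / 2.0
    lo = np.quantile(samples, tail, axis=0)
    hi = np.quantile(samples, 1.0 - tail, axis=0)
    return lo, hi


def bootstrap_individual(
    triplets: list[Triplet], selection: str, config: BootstrapConfig
) -> ReverseCorrelationEstimate:
    """Percentile bootstrap CI of the per-segment mean for one participant.

    Resampling is performed separately for each disambiguation segment.
    """
    values = selection_matrix(triplets, selection)  # raises if empty
    n, n_seg = values.shape
    rng = np.random.default_rng(config.seed)
    boot_means = np.empty((config.n_iterations, n_seg))
    for k in range(n_seg):
        idx = rng.integers(0, n, size=(config.n_iterations, n))
        boot_means[:, k] = values[idx, k].mean(axis=1)
    lo, hi = _percentile_interval(boot_means, config.interval_mass)
    return ReverseCorrelationEstimate(
        selection=selection,
        mean=values.mean(axis=0),
        ci_lo=lo,
        ci_hi=hi,
        n_trials=n,
    )


def bootstrap_group(
    per_participant_triplets: dict[str, list[Triplet]],
    selection: str,
    config: BootstrapConfig,
) -> ReverseCorrelationEstimate:
    """Two-stage group bootstrap.

    Each iteration resamples trials with replacement within every
    participant (separately per segment), computes participant means, then
    the unweighted mean across participants.  The CI is the percentile
    interval of those group means; the point estimate is the unweighted
    mean of the participant means.
    """
    if len(per_participant_triplets) < 2:
        raise ValueError("group bootstrap needs at least 2 participants")
    matrices = {
        p: selection_matrix(tr, selection)
        for p, tr in per_participant_triplets.items()
    }
    n_seg = next(iter(matrices.values())).shape[1]
    rng = np.random.default_rng(config.seed)
    group_means = np.zeros((config.n_iterations, n_seg))
    for values in matrices.values():
        n = values.shape[0]
        part_means = np.empty((config.n_iterations, n_seg))
        for k in range(n_seg):
            idx = rng.integers(0, n, size=(config.n_iterations, n))
            part_means[:, k] = values[idx, k].mean(axis=1)
        group_means += part_means
    group_means /= len(matrices)
    lo, hi = _percentile_interval(group_means, config.interval_mass)
    point = np.mean([v.mean(axis=0) for v in matrices.values()], axis=0)
    n_total = int(sum(v.shape[0] for v in matrices.values()))
    return ReverseCorrelationEstimate(
        selection=selection, mean=point, ci_lo=lo, ci_hi=hi, n_trials=n_total
    )
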