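"""Synthetic observer: a generative stand-in for human participants.

The analysis pipeline conditions only on categorical reports, so the
observer is a deliberately simple state machine rather than a cognitive
model.  Its state is the direction read out by the most recent probe.  A
prime's disambiguation sequence, sign-aligned to that state, is pooled
linearly through a temporal sensitivity kernel into a scalar drive

    d = sum_k kernel[k] * s_rel[k],

and both the prime's own percept and the *next* probe's percept (the
perceptual-memory readout) follow lapse-contaminated logistic rules

    P(same as previous probe) = lapse/2 + (1 - lapse) * logistic(theta + g * d).

Perception and memory share the kernel but differ in gain: with
``gain_memory > gain_perception`` the memory trace flips more easily, so the
sequences that flipped it are, on average, gentler — the qualitative
signature the pipeline is meant to recover.

The default kernel is a positive bell over the first five segments peaked
at segment 2 (zero afterwards).  Because switches are driven by evidence
*against* the current state, the expected reverse-correlation image of the
switch trials is the *negated* kernel: a moderate negative disambiguation,
strongest at the second segment, fading to fully ambiguous —
``switch_template`` returns that expected image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .schedules import (
    DisambiguationSchedule,
    DisambiguationSequence,
    generate_sequence,
)

__all__ = [
    "ObserverParams",
    "TrialRecord",
    "SessionData",
    "default_kernel",
    "switch_template",
    "drive",
    "response_probabilities",
    "simulate_session",
]

LEFT = "left"
RIGHT = "right"
MISSING = "missing"


def default_kernel(n_segments: int = 10) -> np.ndarray:
    """Temporal sensitivity profile: 0.6 * exp(-(k-2)^2 / 4) for k <= 5, else 0.

    Peaked at the second 30 ms segment and silent after 150 ms, echoing the
    empirical finding that only the early portion of the presentation
    influences perception and memory, with the second interval carrying the
    strongest weight.
    """
    k = np.arange(1, n_segments + 1, dtype=float)
    kernel = 0.6 * np.exp(-((k - 2.0) ** 2) / 4.0)
    kernel[k > 5] = 0.0
    return kernel


def switch_template(kernel: np.ndarray) -> np.ndarray:
    """Expected classification image of switch trials: the negated kernel."""
    return -np.asarray(kernel, dtype=float)


@dataclass(frozen=True)
class ObserverParams:
    """Ground-truth parameters of the synthetic observer.

    gain_memory defaults to twice gain_perception, the condition under which
    perceptual memory flips more easily than prime perception.
    """

    kernel: np.ndarray = field(default_factory=default_kernel)
    gain_perception: float = 12.0
    gain_memory: float = 24.0
    baseline_perception: float = 4.0
    baseline_memory: float = 4.0
    lapse: float = 0.02
    p_miss: float = 0.02

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", np.asarray(self.kernel, dtype=float))
        if self.gain_perception <= 0 or self.gain_memory <= 0:
            raise ValueError("gains must be positive")
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError("lapse must lie in [0, 0.2]")
        if not 0.0 <= self.p_miss <= 0.2:
            raise ValueError("p_miss must lie in [0, 0.2]")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: stimulus (primes only) and the participant's report."""

    participant: str
    trial_index: int
    trial_type: str  # "probe" | "prime"
    raw_sequence: DisambiguationSequence | None  # positive tenths cue "right"
    report: str  # "left" | "right" | "missing"

    def __post_init__(self) -> None:
        if self.trial_type not in ("probe", "prime"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.report not in (LEFT, RIGHT, MISSING):
            raise ValueError(f"bad report {self.report!r}")
        if self.trial_type == "probe" and self.raw_sequence is not None:
            raise ValueError("probes carry no disambiguation sequence")
        if self.trial_type == "prime" and self.raw_sequence is None:
            raise ValueError("primes must carry a disambiguation sequence")


@dataclass
class SessionData:
    """An ordered sequence of trials for one participant and schedule."""

    schedule: DisambiguationSchedule
    trials: list[TrialRecord]

    def validate(self) -> None:
        """Check session legality: probe first, no prime after a miss."""
        if self.trials and self.trials[0].trial_type != "probe":
            raise ValueError("first trial must be a probe")
        for prev, cur in zip(self.trials, self.trials[1:]):
            if cur.trial_type == "prime" and prev.report == MISSING:
                raise ValueError(
                    f"prime at trial {cur.trial_index} follows a missing report"
                )
            if cur.trial_type == "prime":
                seq = cur.raw_sequence
                if seq is None or len(seq) != self.schedule.n_segments:
                    raise ValueError(
                        f"prime at trial {cur.trial_index} has a malformed sequence"
                    )


def drive(sequence_rel: np.ndarray, kernel: np.ndarray) -> float:
    """Linear evidence pooling: dot product of aligned strengths and kernel."""
    s = np.asarray(sequence_rel, dtype=float)
    k = np.asarray(kernel, dtype=float)
    if s.shape != k.shape:
        raise ValueError(f"length mismatch: sequence {s.shape} vs kernel {k.shape}")
    return float(s @ k)


def response_probabilities(
    d: float, params: ObserverParams
) -> tuple[float, float]:
    """Probability that the prime / the next probe is seen in the *same*
    direction as the preceding probe's report, given pooled drive ``d``."""
    lam = params.lapse
    p_prime = lam / 2.0 + (1.0 - lam) * expit(
        params.baseline_perception + params.gain_perception * d
    )
    p_probe = lam / 2.0 + (1.0 - lam) * expit(
        params.baseline_memory + params.gain_memory * d
    )
    return float(p_prime), float(p_probe)


def _flip(direction: str) -> str:
    return LEFT if direction == RIGHT else RIGHT


def simulate_session(
    params: ObserverParams,
    schedule: DisambiguationSchedule,
    n_primes: int,
    rng: np.random.Generator,
    participant: str = "obs01",
) -> SessionData:
    """Simulate one alternating probe/prime session.

    The session starts with a probe (initial percept uniform).  After every
    valid response the next trial is a prime; after a missed response the
    next trial is always a probe.  Probe percepts following a prime are
    driven by that prime's sign-aligned sequence via the memory channel;
    probes not preceded by a prime persist (zero drive).  The internal
    percept always updates the memory state, even when the overt report is
    recorded as missing.
    """
    if n_primes < 1:
        raise ValueError("n_primes must be >= 1")
    if len(params.kernel) != schedule.n_segments:
        raise ValueError("kernel length must match the schedule")

    trials: list[TrialRecord] = []
    idx = 0

    def record(trial_type: str, seq: DisambiguationSequence | None, percept: str) -> str:
        nonlocal idx
        report = MISSING if rng.random() < params.p_miss else percept
        trials.append(TrialRecord(participant, idx, trial_type, seq, report))
        idx += 1
        return report

    # Leading probe: no memory yet, uniform percept.
    memory = RIGHT if rng.random() < 0.5 else LEFT
    last_report = record("probe", None, memory)

    primes_done = 0
    while primes_done < n_primes:
        if last_report == MISSING:
            # A miss suppresses the next prime; present a probe instead.
            # Zero drive: persistence with lapse.
            p_same = params.lapse / 2.0 + (1.0 - params.lapse) * expit(
                params.baseline_memory
            )
            percept = memory if rng.random() < p_same else _flip(memory)
            memory = percept
            last_report = record("probe", None, percept)
            continue

        # Prime trial.
        seq = generate_sequence(schedule, rng)
        # Align the absolute-signed sequence (positive cues "right") to the
        # current memory state so positive means "same direction as memory".
        rel = seq.values if memory == RIGHT else -seq.values
        d = drive(rel, params.kernel)
        p_prime_same, p_probe_same = response_probabilities(d, params)
        prime_percept = memory if rng.random() < p_prime_same else _flip(memory)
        last_report = record("prime", seq, prime_percept)
        primes_done += 1

        # Trailing probe reads out the memory trace laid down by the prime.
        probe_percept = memory if rng.random() < p_probe_same else _flip(memory)
        memory = probe_percept
        last_report = record("probe", None, probe_percept)

    return SessionData(schedule=schedule, trials=trials)
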