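"""Triplet construction, outcome classification and bootstrap estimates."""

import itertools

import numpy as np
import pytest

from percmem import (
    BootstrapConfig,
    NoQualifyingTrialsError,
    ObserverParams,
    Triplet,
    TripletClass,
    align_sign,
    average_sequence,
    bootstrap_group,
    bootstrap_individual,
    build_triplets,
    classify,
    simulate_session,
)
from percmem.observer import SessionData, TrialRecord
from percmem.schedules import DisambiguationSequence
from percmem.triplets import selection_matrix


def _triplet(lead, prime, trail, seq=None):
    return Triplet(
        participant="p",
        leading_probe_report=lead,
        prime_report=prime,
        trailing_probe_report=trail,
        sequence_rel=np.zeros(10) if seq is None else np.asarray(seq, float),
    )


def test_classification_exhaustive_and_exclusive():
    """All 8 report triples get exactly the label the 2x2 definition gives."""
    for lead, prime, trail in itertools.product(["left", "right"], repeat=3):
        label = classify(_triplet(lead, prime, trail))
        expected = {
            (True, True): TripletClass.BOTH_CHANGED,
            (True, False): TripletClass.PRIME_ONLY,
            (False, True): TripletClass.MEMORY_ONLY,
            (False, False): TripletClass.NO_CHANGE,
        }[(prime != lead, trail != lead)]
        assert label is expected


def test_classification_examples():
    assert classify(_triplet("left", "right", "right")) is TripletClass.BOTH_CHANGED
    assert classify(_triplet("left", "right", "left")) is TripletClass.PRIME_ONLY
    assert classify(_triplet("left", "left", "right")) is TripletClass.MEMORY_ONLY
    assert classify(_triplet("left", "left", "left")) is TripletClass.NO_CHANGE


def test_align_sign_convention_and_involution(rng):
    raw = np.array([0.5, -0.3, 0.0])
    np.testing.assert_allclose(align_sign(raw, "right"), raw)
    np.testing.assert_allclose(align_sign(raw, "left"), -raw)
    random = rng.choice(np.arange(-10, 11) / 10, size=10)
    for report in ("left", "right"):
        np.testing.assert_array_equal(
            align_sign(align_sign(random, report), report), random
        )
    with pytest.raises(ValueError):
        align_sign(raw, "missing")


def _session_from_rows(rows, schedule):
    trials = []
    for i, (kind, report) in enumerate(rows):
        seq = (
            DisambiguationSequence(np.arange(-5, 5))
            if kind == "prime"
            else None
        )
        trials.append(TrialRecord("p", i, kind, seq, report))
    return SessionData(schedule=schedule, trials=trials)


def test_clean_session_yields_one_triplet_per_prime(onset_schedule):
    params = ObserverParams(p_miss=0.0)
    session = simulate_session(params, onset_schedule, 100, np.random.default_rng(2))
    assert len(build_triplets(session)) == 100


def test_missing_prime_report_drops_only_that_triplet(onset_schedule):
    rows = [
        ("probe", "left"),
        ("prime", "missing"),
        ("probe", "left"),
        ("prime", "right"),
        ("probe", "right"),
    ]
    triplets = build_triplets(_session_from_rows(rows, onset_schedule))
    assert len(triplets) == 1
    assert triplets[0].prime_report == "right"


def test_probe_only_session_yields_no_triplets(onset_schedule):
    rows = [("probe", "left")] * 5
    assert build_triplets(_session_from_rows(rows, onset_schedule)) == []


def test_disjoint_mode_halves_sliding_triplets(onset_schedule):
    params = ObserverParams(p_miss=0.0)
    session = simulate_session(params, onset_schedule, 10, np.random.default_rng(2))
    sliding = build_triplets(session, sliding=True)
    disjoint = build_triplets(session, sliding=False)
    assert len(sliding) == 10
    assert len(disjoint) == 5  # every second trailing probe is reused


def test_sign_alignment_applied_to_triplet_sequences(onset_schedule):
    rows = [("probe", "left"), ("prime", "right"), ("probe", "left")]
    (t,) = build_triplets(_session_from_rows(rows, onset_schedule))
    np.testing.assert_allclose(t.sequence_rel, -np.arange(-5, 5) / 10)


def test_average_sequence_two_point_mean():
    triplets = [
        _triplet("left", "right", "left", seq=[0.4] + [0.0] * 9),
        _triplet("left", "right", "right", seq=[-0.2] + [0.0] * 9),
    ]
    avg = average_sequence(triplets, "prime_changed")
    assert avg[0] == pytest.approx(0.1)


def test_average_sequence_matches_brute_force_oracle(rng):
    triplets = []
    for _ in range(50):
        reports = rng.choice(["left", "right"], size=3)
        seq = rng.choice(np.arange(-10, 11) / 10, size=10)
        triplets.append(_triplet(*reports, seq=seq))
    for selection, classes in [
        ("prime_changed", {TripletClass.BOTH_CHANGED, TripletClass.PRIME_ONLY}),
        ("memory_changed", {TripletClass.BOTH_CHANGED, TripletClass.MEMORY_ONLY}),
    ]:
        selected = [t for t in triplets if classify(t) in classes]
        if not selected:
            continue
        # independent per-segment sum/count re-summation
        sums, count = np.zeros(10), 0
        for t in selected:
            for k in range(10):
                sums[k] += t.sequence_rel[k]
            count += 1
        np.testing.assert_allclose(
            average_sequence(triplets, selection), sums / count
        )


def test_empty_selection_is_explicit():
    triplets = [_triplet("left", "left", "left")]
    with pytest.raises(NoQualifyingTrialsError):
        average_sequence(triplets, "prime_changed")
    with pytest.raises(NoQualifyingTrialsError):
        bootstrap_individual(triplets, "prime_changed", BootstrapConfig())
    with pytest.raises(ValueError):
        selection_matrix(triplets, "nonsense")


def test_bootstrap_constant_data_gives_zero_width_ci():
    triplets = [
        _triplet("left", "right", "left", seq=[0.3] * 10) for _ in range(20)
    ]
    est = bootstrap_individual(triplets, "prime_changed", BootstrapConfig(seed=1))
    np.testing.assert_allclose(est.mean, 0.3)
    np.testing.assert_allclose(est.ci_lo, 0.3)
    np.testing.assert_allclose(est.ci_hi, 0.3)
    assert est.n_trials == 20


def test_bootstrap_determinism(small_triplets):
    cfg = BootstrapConfig(n_iterations=300, seed=42)
    a = bootstrap_individual(small_triplets, "memory_changed", cfg)
    b = bootstrap_individual(small_triplets, "memory_changed", cfg)
    np.testing.assert_array_equal(a.ci_lo, b.ci_lo)
    np.testing.assert_array_equal(a.ci_hi, b.ci_hi)
    assert np.all(a.ci_lo <= a.mean) and np.all(a.mean <= a.ci_hi)


def test_group_bootstrap_constant_participants():
    make = lambda c: [
        _triplet("left", "right", "left", seq=[c] * 10) for _ in range(15)
    ]
    per_part = {"a": make(0.2), "b": make(0.6)}
    est = bootstrap_group(per_part, "prime_changed", BootstrapConfig(seed=3))
    np.testing.assert_allclose(est.mean, 0.4)
    np.testing.assert_allclose(est.ci_lo, 0.4)
    np.testing.assert_allclose(est.ci_hi, 0.4)


def test_group_mean_is_unweighted_mean_of_participant_means(rng):
    per_part = {}
    for p, n in [("a", 30), ("b", 60), ("c", 45)]:
        per_part[p] = [
            _triplet(
                "left", "right", "left", seq=rng.normal(size=10) / 4
            )
            for _ in range(n)
        ]
    est = bootstrap_group(per_part, "prime_changed", BootstrapConfig(seed=5))
    # two-pass oracle: participant means first, then their plain average
    oracle = np.mean(
        [
            np.mean([t.sequence_rel for t in trs], axis=0)
            for trs in per_part.values()
        ],
        axis=0,
    )
    np.testing.assert_allclose(est.mean, oracle)


def test_group_bootstrap_requires_two_participants():
    per_part = {"a": [_triplet("left", "right", "left")]}
    with pytest.raises(ValueError):
        bootstrap_group(per_part, "prime_changed", BootstrapConfig())
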