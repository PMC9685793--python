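import datetime as dt
import itertools
import random

import pytest

from rxregimen.coexposure import (
    build_events,
    compute_J_and_stage,
    compute_N,
    detect_episodes,
    find_episodes,
    stage_boundaries,
)

from conftest import INDEX, make_member, rx


def day(offset):
    return INDEX + dt.timedelta(days=offset)


# ---------------------------------------------------------------------------
# brute-force day-set oracle


def oracle_episodes(prescriptions, member):
    """Materialize exposed-day sets per drug and intersect them exhaustively.

    Independent of the interval implementation: events are maximal runs of
    the day set, episodes are maximal runs of pairwise run intersections,
    and the potential co-exposure time is counted day by day.
    """
    start0 = member.index_date
    horizon = (member.followup_end - start0).days
    days_by_atc = {}
    for p in prescriptions:
        off = (p.redeem_date - start0).days
        if not 0 <= off < horizon:
            continue
        days_by_atc.setdefault(p.atc, set()).update(
            d for d in range(off, off + p.duration_days) if d < horizon
        )
    def runs(dayset):
        out, cur = [], []
        for d in sorted(dayset):
            if cur and d == cur[-1] + 1:
                cur.append(d)
            else:
                if cur:
                    out.append(cur)
                cur = [d]
        if cur:
            out.append(cur)
        return out

    last_treated = max((max(s) for s in days_by_atc.values() if s), default=None)
    episodes = []
    for a, b in itertools.combinations(sorted(days_by_atc), 2):
        for run_a in runs(days_by_atc[a]):
            for run_b in runs(days_by_atc[b]):
                inter = sorted(set(run_a) & set(run_b))
                if not inter:
                    continue
                j = inter[0]
                potential = min(last_treated + 1, horizon) - j
                episodes.append(
                    {
                        "pair": frozenset((a, b)),
                        "overlap_start": j,
                        "coexposure_days": len(inter),
                        "N": len(inter) / potential,
                    }
                )
    return sorted(
        episodes, key=lambda e: (e["overlap_start"], sorted(e["pair"]))
    )


def implementation_episodes(prescriptions, member):
    _, eps = detect_episodes(prescriptions, member)
    return sorted(
        (
            {
                "pair": frozenset((e.drug_first, e.drug_second)),
                "overlap_start": e.J,
                "coexposure_days": e.coexposure_days,
                "N": e.N,
            }
            for e in eps
        ),
        key=lambda e: (e["overlap_start"], sorted(e["pair"])),
    )


def random_instance(rng, n_drugs=3, followup=250):
    member = make_member(followup_days=followup)
    prescriptions = []
    for i in range(rng.randint(2, n_drugs)):
        atc = f"N03AX{i:02d}"
        for _ in range(rng.randint(1, 4)):
            prescriptions.append(
                rx(atc, rng.randint(0, followup - 10), rng.randint(5, 60))
            )
    return prescriptions, member


@pytest.mark.parametrize("seed", range(30))
def test_interval_algebra_matches_day_set_oracle(seed):
    rng = random.Random(seed)
    for _ in range(10):
        prescriptions, member = random_instance(rng)
        # N is the same integer ratio on both routes, so equality is exact
        assert implementation_episodes(prescriptions, member) == oracle_episodes(
            prescriptions, member
        )


# ---------------------------------------------------------------------------
# events


def test_overlapping_supplies_merge_into_one_event(member):
    events = build_events([rx("A", 0, 30), rx("A", 20, 30)], member)
    assert len(events) == 1
    assert (events[0].start, events[0].end) == (day(0), day(50))
    assert events[0].source_prescription_count == 2


def test_separated_supplies_stay_two_events(member):
    events = build_events([rx("A", 0, 30), rx("A", 200, 30)], member)
    assert [(e.start, e.end) for e in events] == [(day(0), day(30)), (day(200), day(230))]


def test_event_clipped_at_followup_end(member):
    events = build_events([rx("A", 710, 30)], member)
    assert (events[0].start, events[0].end) == (day(710), day(730))


def test_abutting_supplies_merge_and_grace_gap(member):
    assert len(build_events([rx("A", 0, 30), rx("A", 30, 30)], member)) == 1
    assert len(build_events([rx("A", 0, 30), rx("A", 32, 30)], member)) == 2
    assert len(build_events([rx("A", 0, 30), rx("A", 32, 30)], member, grace_gap_days=2)) == 1


def test_same_person_same_atc_events_disjoint(member):
    rng = random.Random(4)
    prescriptions = [rx("A", rng.randint(0, 700), rng.randint(5, 90)) for _ in range(20)]
    events = build_events(prescriptions, member)
    for e1, e2 in itertools.combinations(events, 2):
        assert e1.end <= e2.start or e2.end <= e1.start


# ---------------------------------------------------------------------------
# episodes, N, J, stage


def test_simple_overlap_episode(member):
    events = build_events([rx("A", 0, 100), rx("B", 90, 60)], member)
    eps = find_episodes(events, member)
    assert len(eps) == 1
    ep = eps[0]
    assert ep.drug_first == "A" and ep.drug_second == "B"
    assert ep.coexposure_days == 10
    assert ep.sequence_index == 1


def test_disjoint_events_give_no_episode(member):
    events = build_events([rx("A", 0, 50), rx("B", 60, 40)], member)
    assert find_episodes(events, member) == []


def test_three_drugs_three_pairwise_episodes(member):
    events = build_events(
        [rx("A", 0, 100), rx("B", 50, 100), rx("C", 80, 100)], member
    )
    eps = find_episodes(events, member)
    assert {frozenset((e.drug_first, e.drug_second)) for e in eps} == {
        frozenset("AB"),
        frozenset("AC"),
        frozenset("BC"),
    }
    assert [e.sequence_index for e in eps] == [1, 2, 3]


def test_N_denominator_last_treatment_day(member):
    """Overlap [90,100), last drug event ends day 150: N = 10/60."""
    events = build_events([rx("A", 0, 100), rx("B", 90, 60)], member)
    ep = find_episodes(events, member)[0]
    n = compute_N(ep, events, member)
    assert ep.potential_days == 60
    assert n == pytest.approx(10 / 60)


def test_N_full_coexposure_is_one(member):
    events = build_events([rx("A", 0, 100), rx("B", 60, 40)], member)
    ep = find_episodes(events, member)[0]
    assert compute_N(ep, events, member) == pytest.approx(1.0)


def test_N_denominator_clipped_at_followup_end():
    member = make_member(followup_days=100)
    events = build_events([rx("A", 0, 300), rx("B", 50, 300)], member)
    ep = find_episodes(events, member)[0]
    compute_N(ep, events, member)
    assert ep.potential_days == 50  # window end, not treatment end
    assert ep.N == pytest.approx(1.0)


def test_N_denominator_scope_pair_only(member):
    # a third drug C treated until day 200 extends the any_asm denominator
    events = build_events(
        [rx("A", 0, 100), rx("B", 90, 20), rx("C", 150, 50)], member
    )
    ep = [e for e in find_episodes(events, member)][0]
    assert compute_N(ep, events, member, "any_asm") == pytest.approx(10 / 110)
    assert compute_N(ep, events, member, "pair_only") == pytest.approx(10 / 20)


@pytest.mark.parametrize(
    "j,expected",
    [(0, "early"), (100, "early"), (182, "early"), (183, "middle"), (300, "middle"),
     (547, "middle"), (548, "late"), (600, "late"), (700, "late")],
)
def test_stage_assignment(member, j, expected):
    events = build_events([rx("A", max(0, j - 5), 20), rx("B", j, 20)], member)
    ep = find_episodes(events, member)[0]
    jj, stage = compute_J_and_stage(ep, member)
    assert jj == j
    assert stage == expected


def test_stage_boundaries_730():
    assert stage_boundaries(730) == (182.5, 547.5, 548)


def test_episode_order_invariance(member):
    rng = random.Random(9)
    prescriptions = [
        rx(atc, rng.randint(0, 600), rng.randint(10, 90))
        for atc in "ABC"
        for _ in range(4)
    ]
    _, eps1 = detect_episodes(prescriptions, member)
    shuffled = prescriptions[:]
    rng.shuffle(shuffled)
    _, eps2 = detect_episodes(shuffled, member)
    assert eps1 == eps2
    assert sum(e.coexposure_days for e in eps1) == sum(e.coexposure_days for e in eps2)
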