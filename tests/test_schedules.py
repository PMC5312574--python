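"""FR/VR/PR state machines, RFID schedule selection, and the session controller."""

from __future__ import annotations

import numpy as np
import pytest

from licklab import (
    DomainError,
    Event,
    EventKind,
    OrderingError,
    ProtocolError,
    RfidScheduleMap,
    ScheduleFamily,
    ScheduleSpec,
    ValidationError,
    fr_on_lick,
    initial_state,
    on_lick,
    pr_requirement,
    resolve_schedule,
    run_session,
    vr_draw_requirement,
    vr_on_lick,
)

from _oracles import replay_reward_times
from conftest import TAG, random_lick_stream, regular_licks


def reward_times(record):
    return [e.time for e in record.events if e.kind is EventKind.REWARD]


class TestFixedRatio:
    def test_fr1_first_lick_rewards(self):
        spec = ScheduleSpec(ScheduleFamily.FR, ratio=1, timeout_s=0)
        state = initial_state(spec)
        _, rewarded = fr_on_lick(state, 0.0, spec)
        assert rewarded

    def test_fr10_rewards_only_on_tenth_lick(self, fr10):
        state = initial_state(fr10)
        flags = [fr_on_lick(state, i * 0.15, fr10)[1] for i in range(10)]
        assert flags == [False] * 9 + [True]
        assert state.licks_toward_requirement == 0  # counter reset after reward

    def test_timeout_licks_do_not_count(self, fr10):
        """Licks every 0.15 s for 60 s: reward times equal the replay oracle's."""
        stream = regular_licks(400, ili=0.15)  # 60 s of steady licking
        rec = run_session(stream, fr10)
        assert reward_times(rec) == replay_reward_times(stream, fr10)
        # first reward after 10 licks, then one per timeout expiry + 10 licks
        assert reward_times(rec)[0] == pytest.approx(9 * 0.15)

    def test_counter_never_reaches_requirement(self, fr10):
        state = initial_state(fr10)
        for i in range(100):
            on_lick(state, i * 1000.0, fr10)  # spaced beyond any timeout
            assert state.licks_toward_requirement < state.current_requirement

    def test_non_monotone_lick_is_ordering_error(self, fr10):
        state = initial_state(fr10)
        fr_on_lick(state, 5.0, fr10)
        with pytest.raises(OrderingError):
            fr_on_lick(state, 4.0, fr10)

    def test_family_mismatch_rejected(self, vr10):
        with pytest.raises(DomainError):
            fr_on_lick(initial_state(vr10, np.random.default_rng(0)), 0.0, vr10)


class TestVariableRatio:
    def test_mean_one_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(vr_draw_requirement(rng, 1) == 1 for _ in range(100))

    def test_draws_bounded_and_positive(self, rng):
        draws = [vr_draw_requirement(rng, 10) for _ in range(5000)]
        assert min(draws) >= 1 and max(draws) <= 19

    def test_sample_mean_matches_nominal(self, rng):
        n = 20_000
        draws = np.array([vr_draw_requirement(rng, 10) for _ in range(n)])
        se = np.sqrt((19**2 - 1) / 12 / n)  # SE of uniform{1..19}
        assert abs(draws.mean() - 10.0) < 3 * se

    def test_bad_mean_rejected(self, rng):
        with pytest.raises(DomainError):
            vr_draw_requirement(rng, 0)

    def test_vr_mean_one_equals_fr1(self):
        spec_vr = ScheduleSpec(ScheduleFamily.VR, ratio=1)
        spec_fr = ScheduleSpec(ScheduleFamily.FR, ratio=1)
        stream = regular_licks(200, ili=0.3)
        rec_vr = run_session(stream, spec_vr, rng=0)
        rec_fr = run_session(stream, spec_fr)
        assert reward_times(rec_vr) == reward_times(rec_fr)

    def test_fixed_seed_reproduces_reward_times(self, vr10, rng):
        stream = random_lick_stream(rng, 2000)
        a = run_session(stream, vr10, rng=7)
        b = run_session(stream, vr10, rng=7)
        assert reward_times(a) == reward_times(b)

    def test_counted_licks_per_reward_converge_to_mean(self, vr10):
        """With no timeout, total licks / rewards estimates the VR mean."""
        spec = ScheduleSpec(ScheduleFamily.VR, ratio=10, timeout_s=0)
        state = initial_state(spec, np.random.default_rng(11))
        n = 100_000
        rewards = sum(vr_on_lick(state, i * 0.1, spec)[1] for i in range(n))
        ratio = n / rewards
        # sd of uniform{1..19} is ~5.48; rewards ~ n/10 draws
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_degenerate_vr_equals_fr_on_identical_stream(self, rng):
        stream = random_lick_stream(rng, 3000)
        for m in (3, 10):
            fr = ScheduleSpec(ScheduleFamily.FR, ratio=m)
            vr = ScheduleSpec(ScheduleFamily.VR, ratio=m, vr_values=(m,))
            assert reward_times(run_session(stream, vr)) == reward_times(run_session(stream, fr))


class TestProgressiveRatio:
    def test_base_case(self, pr_spec):
        assert pr_requirement(1, pr_spec) == 10

    def test_arithmetic_progression(self, pr_spec):
        assert pr_requirement(3, pr_spec) == 20  # 10 + 2*5

    def test_strictly_increasing(self, pr_spec):
        reqs = [pr_requirement(k, pr_spec) for k in range(1, 101)]
        assert all(b > a for a, b in zip(reqs, reqs[1:]))

    def test_bad_index_rejected(self, pr_spec):
        with pytest.raises(DomainError):
            pr_requirement(0, pr_spec)

    def test_pr_session_ends_after_idle_window(self, pr_spec):
        stream = regular_licks(30, ili=0.2)  # last active lick at t=100-ish? no: 29*0.2
        stream.append(Event(100.0, EventKind.LICK_ACTIVE))
        rec = run_session(stream, pr_spec)
        assert rec.events[-1].time == 100.0 + 600.0
        assert (rec.end_time - rec.start_time).total_seconds() == 700.0


class TestResolveSchedule:
    def setup_method(self):
        self.pr = ScheduleSpec(ScheduleFamily.PR, ratio=10)
        self.fr = ScheduleSpec(ScheduleFamily.FR, ratio=10)
        self.map = RfidScheduleMap(
            entries={
                "AAAAAAAAAAA1": self.pr,
                "BBBBBBBBBBB1": self.fr,
                "BBBBBBBBBBB2": self.fr,  # two alternative tags per schedule
            }
        )

    def test_mapped_tag_selects_schedule(self):
        assert resolve_schedule("AAAAAAAAAAA1", self.map) is self.pr

    def test_unmapped_tag_falls_back_to_vr10(self):
        spec = resolve_schedule(TAG, self.map)
        assert spec.family is ScheduleFamily.VR and spec.ratio == 10

    def test_alternative_tags_resolve_to_same_schedule(self):
        assert resolve_schedule("BBBBBBBBBBB1", self.map) is resolve_schedule(
            "bbbbbbbbbbb2".upper(), self.map
        )

    def test_lookup_is_case_insensitive(self):
        assert resolve_schedule("aaaaaaaaaaa1", self.map) is self.pr

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValidationError):
            resolve_schedule("xyz", self.map)
        with pytest.raises(ValidationError):
            RfidScheduleMap(entries={"tooshort": self.fr})


class TestRunSession:
    def test_empty_session_spans_full_duration(self, fr10):
        rec = run_session([Event(0.0, EventKind.RFID_SCAN, TAG)], fr10)
        assert rec.rewards == 0
        assert rec.events[-1].time == fr10.session_s
        assert [e.kind for e in rec.events] == [
            EventKind.SESSION_START,
            EventKind.RFID_SCAN,
            EventKind.SESSION_END,
        ]

    def test_missing_leading_scan_is_protocol_error(self, fr10):
        with pytest.raises(ProtocolError):
            run_session([Event(0.0, EventKind.LICK_ACTIVE)], fr10)
        with pytest.raises(ProtocolError):
            run_session([], fr10)

    def test_disordered_input_rejected(self, fr10):
        stream = [
            Event(0.0, EventKind.RFID_SCAN, TAG),
            Event(5.0, EventKind.LICK_ACTIVE),
            Event(4.0, EventKind.LICK_ACTIVE),
        ]
        with pytest.raises(OrderingError):
            run_session(stream, fr10)

    def test_input_beyond_fixed_session_end_is_dropped(self, fr10):
        stream = regular_licks(5, ili=0.2)
        stream.append(Event(fr10.session_s + 1.0, EventKind.LICK_ACTIVE))
        rec = run_session(stream, fr10)
        assert sum(1 for e in rec.events if e.kind is EventKind.LICK_ACTIVE) == 5
        assert rec.events[-1].time == fr10.session_s

    def test_inactive_licks_never_advance_schedule(self, fr10):
        stream = [Event(0.0, EventKind.RFID_SCAN, TAG)]
        stream += [Event(0.1 * (i + 1), EventKind.LICK_INACTIVE) for i in range(100)]
        rec = run_session(stream, fr10)
        assert rec.rewards == 0

    def test_cue_pairs_span_cue_duration(self, fr10, rng):
        stream = random_lick_stream(rng, 1500, active_frac=1.0)
        rec = run_session(stream, fr10)
        ons = [e.time for e in rec.events if e.kind is EventKind.CUE_ON]
        offs = [e.time for e in rec.events if e.kind is EventKind.CUE_OFF]
        assert len(ons) == len(offs) == rec.rewards > 0
        end = rec.events[-1].time
        for on, off in zip(ons, offs):
            assert off == pytest.approx(min(on + fr10.cue_s, end))

    def test_rebases_times_to_scan(self, fr10):
        stream = [Event(50.0, EventKind.RFID_SCAN, TAG), Event(51.0, EventKind.LICK_ACTIVE)]
        rec = run_session(stream, fr10)
        assert rec.events[0].time == 0.0
        assert rec.lick_times("active")[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["FR", "VR", "PR"])
    def test_reward_times_match_replay_oracle(self, family, rng):
        """Engine vs independently coded single-pass replay, all families."""
        for trial in range(25):
            spec = ScheduleSpec(
                ScheduleFamily(family),
                ratio=int(rng.integers(1, 20)),
                pr_step=int(rng.integers(1, 10)),
                timeout_s=float(rng.choice([0.0, 5.0, 20.0])),
            )
            n = int(rng.integers(10, 3000))
            stream = random_lick_stream(rng, n)
            seed = int(rng.integers(2**31))
            rec = run_session(stream, spec, rng=seed)
            assert reward_times(rec) == replay_reward_times(stream, spec, seed=seed)

    def test_successive_rewards_separated_by_more_than_timeout(self, rng, fr10, pr_spec):
        for spec in (fr10, pr_spec):
            rec = run_session(random_lick_stream(rng, 4000), spec, rng=1)
            rt = reward_times(rec)
            assert len(rt) > 1
            assert all(b - a > spec.timeout_s for a, b in zip(rt, rt[1:]))
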