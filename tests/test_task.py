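"""Titration engine: halving schedule, rounding, indifference extraction."""

import itertools

import numpy as np
import pytest

from tdmed.agents import AgentSpec
from tdmed.task import (
    BisectionState,
    TaskConfig,
    TrialRecord,
    advance,
    extract_indifference,
    frame_to_trials,
    init_block,
    round_display,
    run_task,
    score_catch,
    trials_to_frame,
)


def _unrounded_endpoint(history, cfg):
    state = BisectionState(current_unrounded_amount=cfg.later_amount * 0.5)
    for choice in history:
        state = advance(state, cfg, choice)
    return state.current_unrounded_amount


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"later_amount": 0.0},
            {"trials_per_block": 0},
            {"rounding_step": 0.0},
            {"block_delays": (90, 21, 730)},
            {"block_delays": (2, 90, 730)},  # not above the sooner delay
            {"catch_trials": ((1.0, 3, 30.0, 730),)},  # no dominating option
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TaskConfig(**kwargs)

    def test_default_task_has_20_trials(self, task_cfg):
        assert task_cfg.n_trials_total == 20

    def test_roundtrip_dict(self, task_cfg):
        assert TaskConfig.from_dict(task_cfg.to_dict()) == task_cfg


class TestInitBlock:
    def test_first_offer_is_half_the_later_amount(self, task_cfg):
        state = init_block(task_cfg, 0)
        assert state.current_unrounded_amount == 35.0
        assert state.next_trial_index == 1

    def test_scales_with_later_amount(self):
        cfg = TaskConfig(later_amount=10.0)
        assert init_block(cfg, 2).current_unrounded_amount == 5.0

    def test_invalid_block_rejected(self, task_cfg):
        with pytest.raises(ValueError):
            init_block(task_cfg, 3)


class TestAdvance:
    def test_later_choice_steps_up_by_quarter_of_maximum(self, task_cfg):
        state = advance(init_block(task_cfg, 0), task_cfg, "later")
        assert state.current_unrounded_amount == pytest.approx(52.5)
        assert state.next_trial_index == 2

    def test_sooner_choice_steps_down(self, task_cfg):
        state = advance(init_block(task_cfg, 0), task_cfg, "sooner")
        assert state.current_unrounded_amount == pytest.approx(17.5)

    def test_all_later_trajectory_matches_partial_sums(self, task_cfg):
        # closed form: after m patient choices the amount is 70 * (1 - 2^-(m+1))
        state = init_block(task_cfg, 0)
        seen = [state.current_unrounded_amount]
        for _ in range(6):
            state = advance(state, task_cfg, "later")
            seen.append(state.current_unrounded_amount)
        expected = [70.0 * (1.0 - 2.0 ** -(m + 1)) for m in range(7)]
        assert seen == pytest.approx(expected)
        assert seen[:6] == pytest.approx([35.0, 52.5, 61.25, 65.625, 67.8125, 68.90625])

    def test_cannot_advance_past_block_end(self, task_cfg):
        state = init_block(task_cfg, 0)
        for _ in range(6):
            state = advance(state, task_cfg, "later")
        with pytest.raises(ValueError):
            advance(state, task_cfg, "later")


class TestRoundDisplay:
    @pytest.mark.parametrize(
        "amount,expected",
        [(8.75, 9.0), (35.0, 35.0), (68.90625, 69.0), (0.546875, 0.5), (69.453125, 69.5)],
    )
    def test_nearest_half_pound_half_steps_away_from_zero(self, task_cfg, amount, expected):
        assert round_display(amount, task_cfg) == pytest.approx(expected)

    def test_nonpositive_amount_rejected(self, task_cfg):
        with pytest.raises(ValueError):
            round_display(0.0, task_cfg)


class TestExtractIndifference:
    @pytest.mark.parametrize(
        "history,expected",
        [
            (["later"] * 6, 69.5),
            (["sooner"] * 6, 0.5),
            # alternating choices: 35 + 17.5 - 8.75 + 4.375 - 2.1875
            #   + 1.09375 - 0.546875 = 46.484375 -> 46.5
            (["later", "sooner", "later", "sooner", "later", "sooner"], 46.5),
            (["sooner", "later", "sooner", "later", "sooner", "later"], 23.5),
        ],
    )
    def test_examples(self, task_cfg, history, expected):
        assert extract_indifference(history, task_cfg) == pytest.approx(expected)

    def test_incomplete_history_rejected(self, task_cfg):
        with pytest.raises(ValueError):
            extract_indifference(["later"] * 5, task_cfg)

    def test_bisection_oracle_all_64_histories_monotone(self, task_cfg):
        """Brute force: ordering histories as binary numbers (later=1, first
        trial most significant) strictly orders the unrounded endpoints."""
        endpoints = []
        for bits in itertools.product([0, 1], repeat=6):
            history = ["later" if b else "sooner" for b in bits]
            value = int("".join(map(str, bits)), 2)
            endpoints.append((value, _unrounded_endpoint(history, task_cfg),
                              extract_indifference(history, task_cfg)))
        endpoints.sort()
        unrounded = [e[1] for e in endpoints]
        rounded = [e[2] for e in endpoints]
        assert all(u2 > u1 for u1, u2 in zip(unrounded, unrounded[1:]))
        assert all(r2 >= r1 for r1, r2 in zip(rounded, rounded[1:]))
        assert len({e[0] for e in endpoints}) == 64

    def test_threshold_responder_recovered_within_final_step(self, task_cfg):
        """A deterministic responder with true indifference y* (preferring
        the sooner amount whenever it exceeds y*) ends within 70 * 2^-7."""
        tol = 70.0 * 2.0**-7
        for y_star in np.linspace(0.6, 69.4, 173):
            state = init_block(task_cfg, 0)
            for _ in range(6):
                choice = "sooner" if state.current_unrounded_amount > y_star else "later"
                state = advance(state, task_cfg, choice)
            assert abs(state.current_unrounded_amount - y_star) <= tol + 1e-12


class TestRunTask:
    def test_emits_20_records_with_catches_last(self, task_cfg):
        records, _ = run_task(task_cfg, AgentSpec(model="hyperbolic", k=0.01), 5)
        assert len(records) == 20
        assert [t.is_catch for t in records] == [False] * 18 + [True, True]

    def test_always_later_agent_hits_the_ceiling(self, task_cfg):
        _, points = run_task(task_cfg, AgentSpec(model="always_later"), 3)
        assert points.points == {21: 69.5, 90: 69.5, 730: 69.5}

    def test_same_seed_reproduces_the_log_bitwise(self, task_cfg):
        agent = AgentSpec(model="hyperbolic", k=0.02, beta=1.0)
        r1, p1 = run_task(task_cfg, agent, 42)
        r2, p2 = run_task(task_cfg, agent, 42)
        assert p1.points == p2.points
        assert [vars(a) for a in r1] == [vars(b) for b in r2]

    def test_displayed_amounts_on_the_50p_grid_below_the_maximum(self, task_cfg):
        records, _ = run_task(task_cfg, AgentSpec(model="hyperbolic", k=0.005), 9)
        for t in records:
            if not t.is_catch:
                assert 0.0 < t.sooner_amount < 70.0
                assert (t.sooner_amount / 0.5) == pytest.approx(
                    round(t.sooner_amount / 0.5))

    def test_trial_frame_roundtrip(self, task_cfg):
        records, _ = run_task(task_cfg, AgentSpec(model="hyperbolic", k=0.01), 8)
        frame = trials_to_frame(records, "p1")
        back = frame_to_trials(frame)
        assert [vars(a) for a in back] == [vars(b) for b in records]


class TestScoreCatch:
    def _catch(self, choice):
        return TrialRecord(block_index=-1, trial_index=1, sooner_amount=30.0,
                           sooner_delay=3, later_amount=1.0, later_delay=730,
                           is_catch=True, choice=choice)

    def test_dominating_choice_passes(self):
        assert score_catch([self._catch("sooner")]) == 0

    def test_dominated_choice_fails(self):
        assert score_catch([self._catch("later")]) == 1

    def test_mixed_catches_count(self):
        assert score_catch([self._catch("sooner"), self._catch("later")]) == 1

    def test_no_catch_trials_is_an_error(self):
        titration = TrialRecord(block_index=0, trial_index=1, sooner_amount=35.0,
                                sooner_delay=3, later_amount=70.0, later_delay=21)
        with pytest.raises(ValueError):
            score_catch([titration])
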