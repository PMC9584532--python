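"""Update schemes, perturbation protocols and trajectory reproducibility."""

import math
import random

import numpy as np
import pytest

from pewbool.dynamics import (
    Perturbation,
    UpdateScheme,
    apply_perturbations,
    compile_model,
    index_to_state,
    make_state,
    simulate,
    state_to_index,
    step_general_async,
    step_random_order_sweep,
    step_synchronous,
    validate_perturbations,
)
from pewbool.grammar import parse_model
from pewbool.models import generate_random_model
from pewbool.noise import eval_expression

TOGGLE = parse_model("A* = B\nB* = not A")


class TestStateIndexing:
    def test_index_round_trip(self):
        model = parse_model("A* = B\nB* = C\nC* = A")
        for idx in range(8):
            assert state_to_index(model, index_to_state(model, idx)) == idx

    def test_bit_zero_is_first_node(self):
        model = parse_model("A* = B\nB* = A")
        assert state_to_index(model, {"A": 1, "B": 0}) == 1


class TestSynchronous:
    def test_noise_free_step_is_deterministic_across_seeds(self):
        state = make_state(TOGGLE, ["A"])
        results = {
            tuple(step_synchronous(TOGGLE, state, random.Random(s)).items())
            for s in range(5)
        }
        assert len(results) == 1

    def test_single_self_input_is_identity(self):
        model = parse_model("A* = A")
        for a in (0, 1):
            assert step_synchronous(model, {"A": a}, random.Random(0)) == {"A": a}

    def test_symmetric_coin_from_off_state(self):
        model = parse_model("A* = [0.5,0.5] A")
        rng = random.Random(11)
        n = 10_000
        ones = sum(
            step_synchronous(model, {"A": 0}, rng)["A"] for _ in range(n)
        )
        se = math.sqrt(0.25 / n)
        assert abs(ones / n - 0.5) <= 4 * se


class TestGeneralAsync:
    def test_single_node_model_equals_synchronous(self):
        model = parse_model("A* = not A")
        for a in (0, 1):
            assert step_general_async(model, {"A": a}, random.Random(3)) == {
                "A": 1 - a
            }

    def test_two_node_successor_distribution_is_uniform_node_mixture(self):
        # from (A=1, B=0): updating A gives (0,0); updating B leaves (1,0)
        counts = {(0, 0): 0, (1, 0): 0}
        rng = random.Random(5)
        n = 4000
        for _ in range(n):
            s = step_general_async(TOGGLE, {"A": 1, "B": 0}, rng)
            counts[(s["A"], s["B"])] += 1
        for key in counts:
            assert abs(counts[key] / n - 0.5) <= 4 * math.sqrt(0.25 / n)

    def test_fixed_point_is_absorbing(self):
        model = parse_model("A* = A and B\nB* = A and B")
        for scheme_step in (step_synchronous, step_general_async, step_random_order_sweep):
            assert scheme_step(model, {"A": 1, "B": 1}, random.Random(0)) == {
                "A": 1,
                "B": 1,
            }


class TestRandomOrderSweep:
    def test_sweep_sees_in_sweep_updates(self):
        # A* = B; B* = A from (1,0): order (A,B) -> (0,0); order (B,A) -> (1,1)
        model = parse_model("A* = B\nB* = A")
        seen = set()
        rng = random.Random(2)
        for _ in range(200):
            s = step_random_order_sweep(model, {"A": 1, "B": 0}, rng)
            seen.add((s["A"], s["B"]))
        assert seen == {(0, 0), (1, 1)}

    def test_sweep_distribution_matches_permutation_enumeration(self):
        # both orders are equally likely
        model = parse_model("A* = B\nB* = A")
        rng = random.Random(9)
        n = 4000
        hits = sum(
            step_random_order_sweep(model, {"A": 1, "B": 0}, rng) == {"A": 0, "B": 0}
            for _ in range(n)
        )
        assert abs(hits / n - 0.5) <= 4 * math.sqrt(0.25 / n)

    def test_one_sweep_is_n_node_updates(self):
        # count rule evaluations through a coin-per-evaluation model
        model = parse_model("A* = [0.5,0.5] A\nB* = [0.5,0.5] B\nC* = [0.5,0.5] C")

        class CountingRandom(random.Random):
            calls = 0

            def random(self):
                CountingRandom.calls += 1
                return super().random()

        rng = CountingRandom(0)
        step_random_order_sweep(model, make_state(model), rng)
        # shuffle of 3 items draws 2 variates; each of the N=3 rule
        # evaluations draws exactly one PEW coin
        assert CountingRandom.calls == 2 + 3


class TestPerturbations:
    def test_saturating_pulse_holds_node_then_washes_out(self):
        model = parse_model("SMAD* = TGFB")
        pulse = Perturbation("TGFB", 1, prob=1.0, t_start=0, t_end=10, after_value=0)
        traj = simulate(model, [], UpdateScheme.SYNCHRONOUS, steps=15, perturbations=[pulse], seed=0)
        tgfb = traj.node_series("TGFB")
        assert tgfb[:10].tolist() == [1] * 10
        assert tgfb[10:].tolist() == [0] * 6

    def test_partial_pulse_time_average_matches_probability(self):
        model = parse_model("SMAD* = TGFB")
        pulse = Perturbation("TGFB", 1, prob=0.3, t_start=0, t_end=5000)
        traj = simulate(model, [], UpdateScheme.SYNCHRONOUS, steps=4999, perturbations=[pulse], seed=4)
        mean = traj.node_series("TGFB").mean()
        assert abs(mean - 0.3) <= 4 * math.sqrt(0.3 * 0.7 / 5000)

    def test_input_keeps_last_value_without_after_value(self):
        model = parse_model("SMAD* = TGFB")
        pulse = Perturbation("TGFB", 1, prob=1.0, t_start=0, t_end=3)
        traj = simulate(model, [], UpdateScheme.SYNCHRONOUS, steps=8, perturbations=[pulse], seed=0)
        assert traj.node_series("TGFB").tolist() == [1] * 9

    def test_ruled_node_reverts_to_rule_outside_window(self):
        model = parse_model("A* = False")
        clamp = Perturbation("A", 1, prob=1.0, t_start=0, t_end=3)
        traj = simulate(model, [], UpdateScheme.SYNCHRONOUS, steps=6, perturbations=[clamp], seed=0)
        assert traj.node_series("A").tolist() == [1, 1, 1, 0, 0, 0, 0]

    def test_overlapping_windows_rejected(self):
        model = parse_model("SMAD* = TGFB")
        ps = [
            Perturbation("TGFB", 1, 1.0, 0, 10),
            Perturbation("TGFB", 0, 1.0, 5, 15),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            validate_perturbations(model, ps)

    def test_apply_perturbations_is_pure(self):
        state = {"A": 0}
        out = apply_perturbations([Perturbation("A", 1, 1.0, 0, 5)], state, 1, random.Random(0))
        assert out == {"A": 1} and state == {"A": 0}


class TestSimulate:
    def test_seeded_trajectories_are_identical(self):
        model = generate_random_model(5, 2, pew_fraction=0.6, seed=3)
        a = simulate(model, ["n0"], UpdateScheme.RANDOM_ORDER_ASYNC, steps=50, seed=17)
        b = simulate(model, ["n0"], UpdateScheme.RANDOM_ORDER_ASYNC, steps=50, seed=17)
        assert np.array_equal(a.states, b.states)

    def test_noise_free_synchronous_is_seed_independent(self):
        model = generate_random_model(5, 2, pew_fraction=0.0, seed=3)
        a = simulate(model, ["n0", "n2"], UpdateScheme.SYNCHRONOUS, steps=40, seed=1)
        b = simulate(model, ["n0", "n2"], UpdateScheme.SYNCHRONOUS, steps=40, seed=999)
        assert np.array_equal(a.states, b.states)

    def test_noise_free_sync_becomes_periodic_within_state_space(self):
        model = generate_random_model(4, 2, pew_fraction=0.0, seed=8)
        traj = simulate(model, ["n1"], UpdateScheme.SYNCHRONOUS, steps=2**4 + 4, seed=0)
        seen = [tuple(row) for row in traj.states]
        assert any(seen.count(s) > 1 for s in set(seen))

    def test_trajectory_length_and_frame(self):
        traj = simulate(TOGGLE, ["A"], UpdateScheme.SYNCHRONOUS, steps=7, seed=0)
        assert len(traj) == 8
        df = traj.to_dataframe()
        assert list(df.columns) == ["step", "A", "B"]

    def test_normalized_gasync_single_node_matches_synchronous(self):
        model = parse_model("A* = not A")
        traj = simulate(
            model, [], UpdateScheme.GENERAL_ASYNC, steps=6, seed=0, normalize_gasync=True
        )
        assert traj.node_series("A").tolist() == [0, 1, 0, 1, 0, 1, 0]


class TestCompiledClosures:
    def test_compiled_rules_replay_reference_evaluator(self):
        # identical seeds -> identical draw sequences -> identical values
        for model_seed in range(6):
            model = generate_random_model(5, 3, pew_fraction=0.7, seed=model_seed)
            fns = compile_model(model)
            for state_idx in (0, 9, 21, 31):
                state = index_to_state(model, state_idx)
                values = [state[n] for n in model.nodes]
                for draw_seed in range(4):
                    for i, name in enumerate(model.nodes):
                        ref = eval_expression(
                            model.expression_for(name), state, random.Random(draw_seed)
                        )
                        fast = fns[i](values, random.Random(draw_seed))
                        assert ref == fast
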