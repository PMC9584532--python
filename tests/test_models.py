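"""EMT reconstruction, PEW edits, BNp emulation, loaders, fixtures."""

import numpy as np
import pytest

from pewbool.dynamics import Perturbation, UpdateScheme, simulate, state_to_index
from pewbool.grammar import NoiseSpec, parse_model, render_model
from pewbool.markov import ergodic_subsets, find_attractors, transition_matrix
from pewbool.models import (
    MESENCHYMAL_PATTERN,
    EmtConfig,
    PewEdit,
    apply_pew_edits,
    bnp_wrap,
    build_emt_model,
    builtin_model_names,
    cyclin_cdk1_edits,
    emt_mutant,
    emt_wild_type,
    generate_random_model,
    load_booleannet_file,
    load_builtin_model,
)
from pewbool.grammar import iter_pew_nodes
from pewbool.noise import expression_probability


def iter_pew_specs(model, target):
    return [p.noise for p in iter_pew_nodes(model.rules_by_target[target].expression)]


def noise_free_emt(**kw):
    identity = NoiseSpec(1.0, 0.0)
    return build_emt_model(
        EmtConfig(zeb_mir200_weight=identity, snai1_loop_weight=identity, **kw)
    )


class TestEmtModel:
    def test_structure_and_weight_placement(self):
        model = build_emt_model()
        # 6 named nodes (incl. the TGFB input) + n + m dummies
        assert model.n == 6 + 6 + 3
        assert model.input_nodes == ("TGFB",)
        assert iter_pew_specs(model, "miR200") == [NoiseSpec(0.95, 0.0)]
        assert iter_pew_specs(model, "SNAI1") == [NoiseSpec(0.95, 0.0)]

    def test_mutant_changes_only_the_zeb_mir200_edge(self):
        mut = emt_mutant()
        assert iter_pew_specs(mut, "miR200") == [NoiseSpec(0.05, 0.0)]
        assert iter_pew_specs(mut, "SNAI1") == [NoiseSpec(0.95, 0.0)]

    def test_epithelial_state_is_a_fixed_point_without_tgfb(self):
        model = noise_free_emt()
        epi = state_to_index(model, {**{n: 0 for n in model.nodes}, "Ecad": 1, "miR200": 1})
        atts = find_attractors(model)
        assert any(a.kind == "fixed_point" and a.states == (epi,) for a in atts)

    def test_chain_length_validation(self):
        with pytest.raises(ValueError, match="m < n"):
            EmtConfig(n=3, m=3)

    def test_noise_free_pulse_locks_mesenchymal_state(self):
        # with identity weights the mesenchymal stable motif is irreversible
        model = noise_free_emt()
        pulse = Perturbation("TGFB", 1, 1.0, 0, 30, after_value=0)
        traj = simulate(
            model, ["Ecad", "miR200"], UpdateScheme.SYNCHRONOUS, steps=120,
            perturbations=[pulse], seed=0,
        )
        cols = [model.index[n] for n in MESENCHYMAL_PATTERN]
        want = np.array(list(MESENCHYMAL_PATTERN.values()), dtype=np.uint8)
        locked = (traj.states[60:, cols] == want).all(axis=1)
        assert locked.all()

    def test_bundled_rule_files_match_builders(self):
        assert load_builtin_model("emt_wild_type") == emt_wild_type()
        assert load_builtin_model("emt_mutant") == emt_mutant()


class TestPewEdits:
    def test_edit_wraps_selected_conjunction(self):
        model = parse_model("X* = A or (Cdk1 and CyclinB)\nCdk1* = Cdk1\nCyclinB* = CyclinB\nA* = A")
        edited = apply_pew_edits(model, [PewEdit("X", "Cdk1 and CyclinB", NoiseSpec(0.5, 0))])
        specs = iter_pew_specs(edited, "X")
        assert specs == [NoiseSpec(0.5, 0.0)]
        # original untouched
        assert iter_pew_specs(model, "X") == []

    def test_identity_edit_is_distributionally_transparent(self):
        model = parse_model("X* = A and B\nA* = B\nB* = not X")
        edited = apply_pew_edits(model, [PewEdit("X", "A and B", NoiseSpec(1, 0))])
        P0 = transition_matrix(model, UpdateScheme.SYNCHRONOUS).dense()
        P1 = transition_matrix(edited, UpdateScheme.SYNCHRONOUS).dense()
        assert np.array_equal(P0, P1)

    def test_ambiguous_selector_rejected(self):
        model = parse_model("X* = (A and B) or (A and B)\nA* = A\nB* = B")
        with pytest.raises(ValueError, match="ambiguous"):
            apply_pew_edits(model, [PewEdit("X", "A and B", NoiseSpec(0.5, 0))])

    def test_unmatched_selector_rejected(self):
        model = parse_model("X* = A or B\nA* = A\nB* = B")
        with pytest.raises(ValueError, match="matches no clause"):
            apply_pew_edits(model, [PewEdit("X", "A and B", NoiseSpec(0.5, 0))])

    def test_cyclin_cdk1_recipe_targets_three_antiapoptotic_rules(self):
        toy = load_builtin_model("apoptosis_toy_synthetic")
        edited = apply_pew_edits(toy, cyclin_cdk1_edits(0.6))
        for target in ("MCL1", "BCLXL", "BCL2"):
            assert iter_pew_specs(edited, target) == [NoiseSpec(0.6, 0.0)]


def bnp_oracle_matrix(model, p):
    """Independent BNp construction: deterministic update then flip w.p. p."""
    size = 1 << model.n
    P = np.zeros((size, size))
    for s in range(size):
        state = {name: (s >> i) & 1 for i, name in enumerate(model.nodes)}
        det = [
            int(expression_probability(model.expression_for(name), state))
            for name in model.nodes
        ]
        for t in range(size):
            prob = 1.0
            for i in range(model.n):
                ti = (t >> i) & 1
                prob *= (1.0 - p) if ti == det[i] else p
            P[s, t] = prob
    return P


class TestBnpWrap:
    def test_zero_flip_probability_preserves_dynamics(self):
        model = generate_random_model(3, 2, seed=4)
        P0 = transition_matrix(model, UpdateScheme.SYNCHRONOUS).dense()
        P1 = transition_matrix(bnp_wrap(model, 0.0), UpdateScheme.SYNCHRONOUS).dense()
        assert np.array_equal(P0, P1)

    def test_half_flip_probability_is_a_fair_coin_per_node(self):
        model = parse_model("A* = B\nB* = not A")
        P = transition_matrix(bnp_wrap(model, 0.5), UpdateScheme.SYNCHRONOUS).dense()
        assert np.allclose(P, 0.25)

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("p", [0.1, 0.35])
    def test_matches_independent_bnp_oracle(self, seed, p):
        # agreement to one ulp: the chain builder forms the stay-probability
        # as 1-(1-p), the oracle writes p directly; equal in real arithmetic
        model = generate_random_model(3, 2, seed=seed)
        ours = transition_matrix(bnp_wrap(model, p), UpdateScheme.SYNCHRONOUS).dense()
        assert np.abs(ours - bnp_oracle_matrix(model, p)).max() <= 1e-14

    def test_positive_flip_noise_makes_the_chain_irreducible(self):
        model = generate_random_model(4, 2, seed=7)
        tm = transition_matrix(bnp_wrap(model, 0.1), UpdateScheme.SYNCHRONOUS)
        assert ergodic_subsets(tm) == [tuple(range(16))]

    def test_noisy_input_rejected(self):
        model = parse_model("A* = [0.3,0] A")
        with pytest.raises(ValueError, match="noise-free"):
            bnp_wrap(model, 0.1)


class TestLoaders:
    def test_file_round_trip(self, tmp_path):
        model = emt_wild_type()
        path = tmp_path / "emt.txt"
        path.write_text(render_model(model))
        assert load_booleannet_file(path) == model

    def test_pew_free_file_is_noise_free(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("A* = B and C\nB* = not A\n")
        assert load_booleannet_file(path).is_noise_free

    def test_builtin_listing(self):
        names = builtin_model_names()
        assert {"emt_wild_type", "emt_mutant", "worked_example"} <= set(names)
        with pytest.raises(KeyError, match="no builtin model"):
            load_builtin_model("nope")


class TestRandomModels:
    def test_seed_reproducibility(self):
        a = generate_random_model(6, 3, pew_fraction=0.5, seed=42)
        b = generate_random_model(6, 3, pew_fraction=0.5, seed=42)
        assert a == b

    def test_zero_pew_fraction_is_noise_free(self):
        assert generate_random_model(5, 2, pew_fraction=0.0, seed=1).is_noise_free

    @pytest.mark.parametrize("seed", range(4))
    def test_all_engines_accept_generated_models(self, seed):
        model = generate_random_model(4, 2, pew_fraction=0.6, seed=seed)
        for scheme in UpdateScheme:
            simulate(model, ["n0"], scheme, steps=10, seed=seed)
            tm = transition_matrix(model, scheme)
            assert np.allclose(tm.dense().sum(axis=1), 1.0, atol=1e-12)
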