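import itertools

import numpy as np
import pytest

from oligoscore import metrics
from oligoscore.pipelines import (
    METRIC_PROFILES, _build_mapping, aggregate_weighted, evaluate_aa,
    evaluate_rbm, evaluate_standard, map_chains,
)
from oligoscore.interfaces import extract_interfaces, find_contacts
from oligoscore.structures import Assembly, Chain
from oligoscore.synthetic import (
    ComplexSpec, PerturbationSpec, make_complex, perturb_model,
)


def relabel_swap(asm: Assembly) -> Assembly:
    """Exchange the chain ids of a two-chain assembly (pure relabelling)."""
    a, b = asm.chains
    return Assembly(asm.id, [Chain(b.id, a.residues, a.molecule_class),
                             Chain(a.id, b.residues, b.molecule_class)])


class TestMapChains:
    def test_distinct_sequences_identity_mapping(self, dimer):
        mapping = map_chains(dimer, dimer)
        assert mapping.chain_map == {"A": "A", "B": "B"}

    def test_extra_copy_left_unmapped(self, homodimer):
        extra = perturb_model(homodimer, PerturbationSpec(
            "chain_duplicate", chain="A", offset=80.0, seed=2))
        mapping = map_chains(homodimer, extra)
        assert len(mapping.chain_map) == 2
        assert len(set(mapping.chain_map.values())) == 2

    def test_relabelled_homodimer_absorbed(self, homodimer):
        relabelled = relabel_swap(homodimer)
        mapping = map_chains(homodimer, relabelled)
        # the crossed permutation restores the identity geometry exactly
        assert mapping.chain_map == {"A": "B", "B": "A"}

    @pytest.mark.parametrize("copies", [2, 3, 4])
    def test_agrees_with_exhaustive_permutation_search(self, copies):
        spec = ComplexSpec(entities={"A": 14}, copies={"A": copies},
                           interfaces=tuple(
                               (chr(65 + i), chr(65 + i + 1), 4)
                               for i in range(copies - 1)),
                           seed=31)
        target = make_complex(spec)
        model = perturb_model(target, PerturbationSpec(
            "rigid_shift", magnitude=3.0, chain="B", seed=5))
        mapping = map_chains(target, model)

        def objective(perm):
            cm = dict(zip(target.chain_ids, perm))
            m = _build_mapping(target, model, cm)
            value = metrics.lddt(target, model, m.chain_map, m.residue_maps)
            return value if value is not None else 0.0

        best = max(itertools.permutations(model.chain_ids), key=objective)
        chosen = tuple(mapping.chain_map[c] for c in target.chain_ids)
        assert objective(chosen) == pytest.approx(objective(best), abs=1e-9)

    def test_unrelated_chains_give_empty_mapping(self, dimer):
        other = make_complex(ComplexSpec(entities={"Q": 25, "R": 25},
                                         interfaces=(("A", "B", 6),), seed=99))
        assert map_chains(dimer, other).chain_map == {}


class TestAggregateWeighted:
    def test_equal_weights_is_mean(self):
        assert aggregate_weighted([0.2, 0.4, 0.9], [1, 1, 1]) == pytest.approx(0.5)

    def test_weighted_example(self):
        assert aggregate_weighted([0.3, 0.9], [1, 2]) == pytest.approx(0.7)

    def test_single_interface_is_its_own_score(self):
        assert aggregate_weighted([0.42], [3.7]) == pytest.approx(0.42)

    def test_empty_is_missing(self):
        assert aggregate_weighted([], []) is None

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            s = rng.uniform(0, 1, size=5)
            w = rng.uniform(0.1, 3, size=5)
            agg = aggregate_weighted(s, w)
            assert s.min() - 1e-12 <= agg <= s.max() + 1e-12


class TestEvaluateStandard:
    def test_identity_scores_one_everywhere(self, dimer):
        result = evaluate_standard(dimer, dimer)
        for metric, value in result.aggregates.items():
            assert value == pytest.approx(1.0, abs=1e-6), metric

    def test_homodimer_label_swap_scores_identical(self, homodimer):
        swapped = relabel_swap(homodimer)
        base = evaluate_standard(homodimer, homodimer)
        swap = evaluate_standard(homodimer, swapped)
        for metric in base.aggregates:
            assert swap.aggregates[metric] == pytest.approx(
                base.aggregates[metric], abs=1e-6)

    def test_extra_far_chain_pair_ignored(self, dimer):
        spurious = make_complex(ComplexSpec(
            entities={"A": 30, "B": 24, "C": 20, "D": 20},
            interfaces=(("A", "B", 8), ("C", "D", 8)), seed=11, id="dimer"))
        base = evaluate_standard(dimer, dimer, METRIC_PROFILES["aa"])
        extra = evaluate_standard(dimer, spurious, METRIC_PROFILES["aa"])
        assert extra.aggregates == pytest.approx(base.aggregates)

    def test_shifted_chain_lowers_interface_scores(self, dimer):
        model = perturb_model(dimer, PerturbationSpec(
            "rigid_shift", magnitude=12.0, chain="B", seed=4))
        result = evaluate_standard(dimer, model)
        assert result.aggregates["ics"] < 0.5
        assert result.aggregates["dockq"] < 0.8


class TestEvaluateRbm:
    def test_identity_equals_standard(self, dimer, two_iface_complex):
        for asm in (dimer, two_iface_complex):
            std = evaluate_standard(asm, asm)
            rbm = evaluate_rbm(asm, asm)
            for metric in std.aggregates:
                assert rbm.aggregates[metric] == pytest.approx(
                    std.aggregates[metric], abs=1e-6), metric

    def test_spurious_interface_halves_score(self, dimer):
        model = make_complex(ComplexSpec(
            entities={"A": 30, "B": 24, "C": 20, "D": 20},
            interfaces=(("A", "B", 8), ("C", "D", 8)), seed=11, id="dimer"))
        rbm = evaluate_rbm(dimer, model, ("ics", "ips", "qs"))
        for metric, (d1, d2) in rbm.directions.items():
            assert d1 == pytest.approx(1.0, abs=1e-6)
            assert d2 == pytest.approx(0.5, abs=1e-6)
            assert rbm.aggregates[metric] == pytest.approx(0.5, abs=1e-6)

    def test_missing_interface_halves_score(self, two_iface_complex):
        model = make_complex(ComplexSpec(
            entities={"A": 20, "B": 20}, interfaces=(("A", "B", 8),),
            seed=17, id="twoiface"))
        rbm = evaluate_rbm(two_iface_complex, model, ("ics", "ips", "qs"))
        for metric, (d1, d2) in rbm.directions.items():
            assert d1 == pytest.approx(0.5, abs=1e-6)
            assert d2 == pytest.approx(1.0, abs=1e-6)
        assert rbm.aggregates["ics"] == pytest.approx(0.5, abs=1e-6)

    def test_penalises_spurious_but_standard_does_not(self, dimer):
        model = make_complex(ComplexSpec(
            entities={"A": 30, "B": 24, "C": 20, "D": 20},
            interfaces=(("A", "B", 8), ("C", "D", 8)), seed=11, id="dimer"))
        profile = ("ics", "ips", "qs")
        std_base = evaluate_standard(dimer, dimer, profile).aggregates
        std_spur = evaluate_standard(dimer, model, profile).aggregates
        rbm_base = evaluate_rbm(dimer, dimer, profile).aggregates
        rbm_spur = evaluate_rbm(dimer, model, profile).aggregates
        for metric in profile:
            assert std_spur[metric] == pytest.approx(std_base[metric], abs=1e-9)
            assert rbm_spur[metric] < rbm_base[metric] - 0.1


@pytest.fixture(scope="module")
def aa_complex():
    """Antibody heavy/light chains (A, B) bound to an antigen (C)."""
    spec = ComplexSpec(
        entities={"H": 20, "L": 20, "G": 30},
        interfaces=(("A", "B", 6), ("A", "C", 6), ("B", "C", 6)),
        seed=41, id="aa_target")
    return make_complex(spec)


AA_CLASSMAP = {"A": "antibody", "B": "antibody", "C": "antigen"}


class TestEvaluateAA:
    def test_antibody_antibody_interface_excluded(self, aa_complex):
        result = evaluate_aa(aa_complex, aa_complex, AA_CLASSMAP)
        assert set(result.per_interface) == {("A", "C"), ("B", "C")}

    def test_identity_scores_one(self, aa_complex):
        result = evaluate_aa(aa_complex, aa_complex, AA_CLASSMAP)
        for metric, value in result.aggregates.items():
            assert value == pytest.approx(1.0, abs=1e-6), metric

    def test_profile_excludes_global_metrics(self, aa_complex):
        result = evaluate_aa(aa_complex, aa_complex, AA_CLASSMAP)
        assert set(result.aggregates) <= {"ics", "ips", "qs", "dockq"}

    def test_concatenated_mode_single_interface(self, aa_complex):
        result = evaluate_aa(aa_complex, aa_complex, AA_CLASSMAP,
                             mode="concatenated")
        assert len(result.per_interface) == 1
        ((pair, panel),) = result.per_interface.items()
        assert panel.ics == pytest.approx(1.0)
        # merged interface carries the union of the two cross-class contact sets
        hg = extract_interfaces(find_contacts(aa_complex))
        cross = {i.chains: i.n_contacts for i in hg}
        merged_iface = extract_interfaces(find_contacts(
            __import__("oligoscore.pipelines", fromlist=["_concatenate_by_class"])
            ._concatenate_by_class(aa_complex, AA_CLASSMAP)))
        assert merged_iface[0].n_contacts == cross[("A", "C")] + cross[("B", "C")]

    def test_rbm_base_identity(self, aa_complex):
        result = evaluate_aa(aa_complex, aa_complex, AA_CLASSMAP, base="rbm")
        for metric, value in result.aggregates.items():
            assert value == pytest.approx(1.0, abs=1e-6), metric

    def test_no_cross_class_interface_warns_and_is_missing(self):
        spec = ComplexSpec(entities={"H": 20, "L": 20},
                           interfaces=(("A", "B", 6),), seed=43)
        asm = make_complex(spec)
        with pytest.warns(UserWarning):
            result = evaluate_aa(asm, asm, {"A": "antibody", "B": "antibody"})
        assert all(v is None for v in result.aggregates.values())

    def test_uncovered_chain_rejected(self, aa_complex):
        with pytest.raises(ValueError):
            evaluate_aa(aa_complex, aa_complex, {"A": "antibody"})
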