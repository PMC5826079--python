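import pytest

from magtrace.errors import BoundedSearchError, InputError
from magtrace.reconcile import (
    EventCosts,
    dollo_gains,
    min_event_reconciliation,
    min_vertical_losses,
    scenario_narrative,
)
from magtrace.simulate import add_sister_leaf, plant_transfers, simulate_yule_tree
from magtrace.tree_ops import leaf_labels, parse_newick, serialize
from tests._oracles import (
    dollo_gains_by_search,
    reconcile_min_cost_by_enumeration,
    vertical_losses_by_search,
)


class TestDolloGains:
    def test_two_isolated_gains(self):
        t = parse_newick("((A,B),(C,D));")
        n, branches = dollo_gains(t, {"A": 1, "B": 0, "C": 0, "D": 1})
        assert n == 2
        assert branches == ["A", "D"]

    def test_all_zero_no_gain(self):
        t = parse_newick("((A,B),(C,D));")
        assert dollo_gains(t, {l: 0 for l in "ABCD"})[0] == 0

    def test_all_one_single_root_gain(self):
        t = parse_newick("((A,B),(C,D));")
        assert dollo_gains(t, {l: 1 for l in "ABCD"})[0] == 1

    def test_fused_clade_single_gain(self, bundle):
        for variant in ("a", "b"):
            n, branches = dollo_gains(bundle.rc_tree(variant), bundle.fusion_states)
            assert n == 1
            assert branches == ["CP2_42A+Kouleothrix+Roseiflexus"]

    def test_matches_exhaustive_assignment_search(self):
        import itertools

        for seed in range(4):
            t = simulate_yule_tree(6, seed)
            labels = leaf_labels(t)
            for bits in itertools.product((0, 1), repeat=len(labels)):
                states = dict(zip(labels, bits))
                assert dollo_gains(t, states)[0] == dollo_gains_by_search(t, states)

    def test_missing_state_rejected(self):
        with pytest.raises(InputError):
            dollo_gains(parse_newick("((A,B),C);"), {"A": 1, "B": 0})


class TestVerticalLosses:
    def test_all_present_zero_losses(self):
        t = parse_newick("(((A,B),C),D);")
        assert min_vertical_losses(t, {"A", "B", "C", "D"})[0] == 0

    def test_two_losses_from_root_origin(self):
        t = parse_newick("(((A,B),C),D);")
        n, lost = min_vertical_losses(t, {"A", "D"})
        assert n == 2
        assert lost == ["B", "C"]

    def test_matches_exhaustive_search(self):
        import itertools

        for seed in range(4):
            t = simulate_yule_tree(6, seed + 10)
            labels = leaf_labels(t)
            for size in (1, 2, 3):
                for combo in itertools.combinations(labels, size):
                    assert (
                        min_vertical_losses(t, set(combo))[0]
                        == vertical_losses_by_search(t, set(combo))
                    )

    def test_fixture_losses_exceed_transfers(self, bundle):
        n_losses, _ = min_vertical_losses(
            bundle.organismal_tree(), set(bundle.phototrophs)
        )
        rec = min_event_reconciliation(
            bundle.organismal_tree(), bundle.rc_tree("a"),
            fusion_states=bundle.fusion_states,
        )
        assert n_losses >= 3
        assert n_losses > rec.min_transfers

    def test_empty_present_rejected(self):
        with pytest.raises(InputError):
            min_vertical_losses(parse_newick("((A,B),C);"), set())


class TestReconciliationBasics:
    def test_congruent_case_no_events(self):
        s = parse_newick("((A,B),C);")
        g = parse_newick("((A,B),C);")
        rec = min_event_reconciliation(s, g)
        assert rec.min_cost == 0
        assert rec.min_transfers == 0
        assert rec.min_losses == 0
        assert rec.scenarios[0].origin_branch == "A+B+C"

    def test_distant_pair_needs_one_transfer(self):
        s = parse_newick("(((A,B),C),D);")
        g = parse_newick("(A,D);")
        rec = min_event_reconciliation(s, g)
        assert rec.min_transfers == 1
        assert rec.min_cost == 1

    def test_identity_for_random_trees(self):
        for seed in range(6):
            t = simulate_yule_tree(8, seed)
            rec = min_event_reconciliation(t, t)
            assert rec.min_cost == 0
            assert rec.min_transfers == 0

    def test_relabeling_equivariance(self):
        s = parse_newick("(((A,B),C),(D,E));")
        g = parse_newick("(((A,D),C),(B,E));")
        rec1 = min_event_reconciliation(s, g)
        sub = {"A": "W", "B": "X", "C": "Y", "D": "Z", "E": "V"}
        relabel = lambda t: parse_newick("".join(sub.get(c, c) for c in serialize(t)))
        rec2 = min_event_reconciliation(relabel(s), relabel(g))
        assert rec1.min_cost == rec2.min_cost
        assert rec1.min_transfers == rec2.min_transfers

    def test_gene_leaf_missing_rejected(self):
        with pytest.raises(InputError, match="missing"):
            min_event_reconciliation(
                parse_newick("((A,B),C);"), parse_newick("(A,Z);")
            )

    def test_present_must_equal_gene_leaves(self):
        with pytest.raises(InputError):
            min_event_reconciliation(
                parse_newick("((A,B),C);"),
                parse_newick("(A,B);"),
                present={"A", "B", "C"},
            )

    def test_nonbinary_gene_tree_rejected(self):
        with pytest.raises(InputError, match="binary"):
            min_event_reconciliation(
                parse_newick("((A,B),C);"), parse_newick("(A,B,C);")
            )

    def test_event_bound_enforced(self):
        s = parse_newick("(((A,B),C),D);")
        g = parse_newick("(A,D);")
        with pytest.raises(BoundedSearchError):
            min_event_reconciliation(s, g, max_events=0)

    def test_invalid_costs_rejected(self):
        with pytest.raises(InputError):
            EventCosts(transfer=0.0)


class TestReconciliationFixture:
    @pytest.mark.parametrize("variant", ["a", "b"])
    def test_two_transfers_one_fusion(self, bundle, variant):
        rec = min_event_reconciliation(
            bundle.organismal_tree(),
            bundle.rc_tree(variant),
            present=set(bundle.phototrophs),
            fusion_states=bundle.fusion_states,
        )
        assert rec.min_transfers == 2
        assert rec.min_fusions == 1
        assert rec.min_losses == 0

    def test_origin_on_chloroflexales_stem(self, bundle):
        rec = min_event_reconciliation(
            bundle.organismal_tree(), bundle.rc_tree("a"),
            fusion_states=bundle.fusion_states,
        )
        assert rec.scenarios[0].origin_branch == "Chloroflexus+Kouleothrix+Roseiflexus"

    def test_donors_within_classical_phototroph_clade(self, bundle):
        chloroflexia = {"Chloroflexus", "Kouleothrix", "Roseiflexus"}
        rec = min_event_reconciliation(
            bundle.organismal_tree(), bundle.rc_tree("a"),
            fusion_states=bundle.fusion_states,
        )
        s = rec.scenarios[0]
        for donor, recipient in s.transfers:
            assert set(donor.split("+")) <= chloroflexia
            assert recipient in {"JP3_7", "CP2_42A"}

    def test_narrative_mentions_transfers(self, bundle):
        rec = min_event_reconciliation(
            bundle.organismal_tree(), bundle.rc_tree("a"),
            fusion_states=bundle.fusion_states,
        )
        text = scenario_narrative(rec)
        assert "transfer from" in text
        assert "fusion gained" in text
        assert text.count("transfer from") >= 2

    def test_narrative_rejects_empty(self):
        from magtrace.reconcile import Reconciliation

        with pytest.raises(InputError):
            scenario_narrative(
                Reconciliation((), 0.0, 0, 0, 0)
            )

    def test_congruent_narrative(self):
        rec = min_event_reconciliation(
            parse_newick("((A,B),C);"), parse_newick("((A,B),C);")
        )
        assert "no transfers" in scenario_narrative(rec)


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration_small_random(self):
        """DP equals naive enumeration over all valid event placements."""
        for seed in range(12):
            n = 4 + seed % 4  # species trees of 4..7 leaves
            species = simulate_yule_tree(n, seed)
            history = plant_transfers(
                species, k=seed % 2, seed=seed, well_separated=False
            )
            got = min_event_reconciliation(history.species_tree, history.gene_tree)
            want = reconcile_min_cost_by_enumeration(
                history.species_tree, history.gene_tree
            )
            assert got.min_cost == pytest.approx(want)

    def test_matches_enumeration_on_restricted_gene_trees(self):
        for seed in range(8):
            species = simulate_yule_tree(7, 100 + seed)
            labels = leaf_labels(species)
            from magtrace.tree_ops import restrict_to_leaves

            keep = set(labels[:4])
            gene = restrict_to_leaves(
                plant_transfers(species, 1, seed=seed, well_separated=False).gene_tree,
                keep,
            )
            sub = {l for l in leaf_labels(gene)}
            got = min_event_reconciliation(species, gene, present=sub)
            want = reconcile_min_cost_by_enumeration(species, gene)
            assert got.min_cost == pytest.approx(want)

    def test_fixture_verified_by_enumeration(self, bundle):
        for variant in ("a", "b"):
            got = min_event_reconciliation(
                bundle.organismal_tree(), bundle.rc_tree(variant)
            )
            want = reconcile_min_cost_by_enumeration(
                bundle.organismal_tree(), bundle.rc_tree(variant)
            )
            assert got.min_cost == pytest.approx(want) == 2.0


class TestMonotonicity:
    def test_adding_adjacent_present_leaf_never_increases_transfers(self):
        for seed in range(6):
            species = simulate_yule_tree(8, seed)
            history = plant_transfers(species, 1, seed=seed)
            base = min_event_reconciliation(history.species_tree, history.gene_tree)
            anchor = leaf_labels(history.species_tree)[0]
            s2 = add_sister_leaf(history.species_tree, anchor, "NEW")
            g2 = add_sister_leaf(history.gene_tree, anchor, "NEW")
            grown = min_event_reconciliation(s2, g2)
            assert grown.min_transfers <= base.min_transfers
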