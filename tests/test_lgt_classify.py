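"""LGT classification: sister groups, bacterial-clade rule, direction, tiers."""

import pytest

from lgtscreen.lgt_classify import (
    A_TO_B,
    B_TO_A,
    E_TO_A,
    LGT_BACTERIAL,
    LGT_EUKARYOTE,
    LGT_NESTED,
    NON_LGT,
    NOT_APPLICABLE,
    ScreenConfig,
    UNKNOWN,
    classify_tree,
    closest_neighbor_group,
    is_bacterial_clade,
    support_tier,
)

from conftest import FOCAL, MSMITHII, annotated_tree, taxon


class TestSupportTier:
    @pytest.mark.parametrize(
        "support,tier",
        [(71, "high"), (70, "moderate"), (51, "moderate"), (50, "low"),
         (0, "low"), (100, "high"), (None, "absent")],
    )
    def test_tier_boundaries(self, support, tier):
        assert support_tier(support) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            support_tier(101)
        with pytest.raises(ValueError):
            support_tier(-1)

    def test_boundary_is_configurable(self):
        cfg = ScreenConfig(tier_moderate_low=50)
        assert support_tier(50, cfg) == "moderate"


class TestBacterialCladeRule:
    def test_three_phyla_qualify(self):
        members = [taxon("a", "Bacteria", "Firmicutes"),
                   taxon("b", "Bacteria", "Bacteroidetes"),
                   taxon("c", "Bacteria", "Proteobacteria")]
        assert is_bacterial_clade(members)

    def test_two_phyla_insufficient(self):
        members = [taxon("a", "Bacteria", "Firmicutes"),
                   taxon("b", "Bacteria", "Firmicutes"),
                   taxon("c", "Bacteria", "Bacteroidetes")]
        assert not is_bacterial_clade(members)

    def test_any_non_bacterium_disqualifies(self):
        members = [taxon("a", "Bacteria", "Firmicutes"), taxon("x", "Archaea")]
        assert not is_bacterial_clade(members)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            is_bacterial_clade([])

    def test_threshold_configurable(self):
        members = [taxon("a", "Bacteria", "Firmicutes")]
        assert is_bacterial_clade(members, ScreenConfig(min_bacterial_phyla=1))


class TestClosestNeighborGroup:
    def test_single_leaf_sister(self, config_as_provided):
        gtree = annotated_tree(
            "((Focal:1,BacA:1):1,ArchX:1);",
            [FOCAL, taxon("BacA", "Bacteria"), taxon("ArchX", "Archaea")],
        )
        assert closest_neighbor_group(gtree, config_as_provided) == {"BacA"}

    def test_clade_sister(self, config_as_provided):
        gtree = annotated_tree(
            "((Focal:1,(BacA:1,BacB:1):1):1,ArchX:1);",
            [FOCAL, taxon("BacA", "Bacteria"), taxon("BacB", "Bacteria"),
             taxon("ArchX", "Archaea")],
        )
        assert closest_neighbor_group(gtree, config_as_provided) == {"BacA", "BacB"}

    def test_innermost_caterpillar_position(self, config_as_provided):
        leaves = [taxon(f"L{i}", "Bacteria") for i in range(7)]
        nwk = "((((((Focal:1,L0:1):1,L1:1):1,L2:1):1,L3:1):1,L4:1):1,(L5:1,L6:1):1);"
        gtree = annotated_tree(nwk, [FOCAL] + leaves)
        assert closest_neighbor_group(gtree, config_as_provided) == {"L0"}

    def test_focal_absent_errors(self, config_as_provided):
        gtree = annotated_tree(
            "((A:1,B:1):1,C:1);",
            [taxon(x, "Bacteria") for x in "ABC"],
        )
        with pytest.raises(ValueError, match="focal"):
            closest_neighbor_group(gtree, config_as_provided)


class TestClassifyTree:
    def test_bacterial_neighbor_with_support_and_donor(self, config_as_provided):
        gtree = annotated_tree(
            "((Focal:1,BacF:1)85:1,(ArchA:1,(BacX:1,BacY:1):1):1);",
            [FOCAL, taxon("BacF", "Bacteria", "Firmicutes"),
             taxon("ArchA", "Archaea"),
             taxon("BacX", "Bacteria", "Bacteroidetes"),
             taxon("BacY", "Bacteria", "Proteobacteria")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_BACTERIAL
        assert cls.inspected_branch_support == 85
        assert cls.support_tier == "high"
        assert cls.donor_phylum == "Firmicutes"
        # a mixed group above the enclosure leaves the direction open
        assert cls.direction == UNKNOWN

    def test_nested_pair_with_archaeal_outgroup_direction_unknown(self, config_as_provided):
        gtree = annotated_tree(
            "(((Focal:1,Msmithii:1)60:1,(BacF:1,(BacB:1,BacP:1):1):1)55:1,ArchOut:1);",
            [FOCAL, MSMITHII,
             taxon("BacF", "Bacteria", "Firmicutes"),
             taxon("BacB", "Bacteria", "Bacteroidetes"),
             taxon("BacP", "Bacteria", "Proteobacteria"),
             taxon("ArchOut", "Archaea")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_NESTED
        assert cls.companion_present == "smithii"
        assert cls.direction == UNKNOWN
        assert cls.inspected_branch_support == 60
        assert cls.support_tier == "moderate"
        assert not cls.only_archaea_rescue  # ArchOut is a third archaeon

    def test_deeply_nested_pair_gives_bacterial_direction(self, config_as_provided):
        gtree = annotated_tree(
            "((((Focal:1,Msmithii:1)60:1,(BacF:1,(BacB:1,BacP:1):1):1):1,"
            "(BacA:1,BacV:1):1):1,ArchOut:1);",
            [FOCAL, MSMITHII,
             taxon("BacF", "Bacteria", "Firmicutes"),
             taxon("BacB", "Bacteria", "Bacteroidetes"),
             taxon("BacP", "Bacteria", "Proteobacteria"),
             taxon("BacA", "Bacteria", "Actinobacteria"),
             taxon("BacV", "Bacteria", "Verrucomicrobia"),
             taxon("ArchOut", "Archaea")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_NESTED
        assert cls.direction == B_TO_A

    def test_archaeal_sister_is_vertical(self, config_as_provided):
        gtree = annotated_tree(
            "((Focal:1,ArchA:1):1,(BacX:1,BacY:1):1);",
            [FOCAL, taxon("ArchA", "Archaea"),
             taxon("BacX", "Bacteria"), taxon("BacY", "Bacteria")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == NON_LGT
        assert cls.direction == NOT_APPLICABLE
        assert cls.inspected_branch_support is None

    def test_mixed_domain_sister_is_conservative_non_lgt(self, config_as_provided):
        gtree = annotated_tree(
            "((Focal:1,(BacA:1,ArchB:1):1):1,ArchC:1);",
            [FOCAL, taxon("BacA", "Bacteria"), taxon("ArchB", "Archaea"),
             taxon("ArchC", "Archaea")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == NON_LGT
        assert any("mixed-domain" in note for note in cls.review_notes)

    def test_eukaryote_neighbor(self, config_as_provided):
        gtree = annotated_tree(
            "(((Focal:1,Euk1:1)75:1,(Euk2:1,Euk3:1):1):1,ArchOut:1);",
            [FOCAL, taxon("Euk1", "Eukaryota", "Ascomycota"),
             taxon("Euk2", "Eukaryota", "Chordata"),
             taxon("Euk3", "Eukaryota", "Amoebozoa"),
             taxon("ArchOut", "Archaea")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_EUKARYOTE
        assert cls.direction == E_TO_A
        assert cls.donor_phylum == "Ascomycota"

    def test_only_archaea_rescue_flagged(self, config_as_provided):
        # focal + companion sister to a (single-phylum) bacterial clade at
        # the root: no direction, but a likely bacterial origin
        gtree = annotated_tree(
            "((Focal:1,Msmithii:1)65:1,((BacA:1,BacB:1):1,(BacC:1,BacD:1):1):1);",
            [FOCAL, MSMITHII,
             taxon("BacA", "Bacteria", "Firmicutes"),
             taxon("BacB", "Bacteria", "Bacteroidetes"),
             taxon("BacC", "Bacteria", "Proteobacteria"),
             taxon("BacD", "Bacteria", "Firmicutes")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_NESTED
        assert cls.direction == UNKNOWN
        assert cls.only_archaea
        assert cls.only_archaea_rescue

    def test_archaea_export_direction(self, config_as_provided):
        gtree = annotated_tree(
            "((((Focal:1,BacX:1)70:1,ArchA:1):1,ArchB:1):1,(ArchC:1,ArchD:1):1);",
            [FOCAL, taxon("BacX", "Bacteria", "Proteobacteria"),
             taxon("ArchA", "Archaea", genus="Methanosarcina"),
             taxon("ArchB", "Archaea", genus="Methanococcus"),
             taxon("ArchC", "Archaea", genus="Haloferax"),
             taxon("ArchD", "Archaea", genus="Sulfolobus")],
        )
        cls = classify_tree(gtree, config_as_provided)
        assert cls.status == LGT_BACTERIAL
        assert cls.direction == A_TO_B
        assert cls.donor_phylum == "Proteobacteria"

    def test_unannotated_leaf_errors(self, config_as_provided):
        from lgtscreen.trees import parse_newick

        gtree = annotated_tree(
            "((Focal:1,BacA:1):1,ArchX:1);",
            [FOCAL, taxon("BacA", "Bacteria"), taxon("ArchX", "Archaea")],
        )
        del gtree.annotations["BacA"]
        with pytest.raises(KeyError):
            classify_tree(gtree, config_as_provided)


class TestInvariants:
    def test_classification_invariant_under_leaf_order(self, config_default):
        from lgtscreen.synth import SCENARIOS, ScenarioSpec, make_gene_tree
        from lgtscreen.trees import parse_newick, write_newick

        for scenario in SCENARIOS:
            gtree, _ = make_gene_tree(ScenarioSpec(scenario=scenario, seed=4))
            a = classify_tree(gtree, config_default)
            # re-serialize with reversed child order everywhere
            mirrored, _ = make_gene_tree(ScenarioSpec(scenario=scenario, seed=4))
            for node in mirrored.tree.preorder_internal_node_iter():
                node.set_child_nodes(list(reversed(node.child_nodes())))
            b = classify_tree(mirrored, config_default)
            for f in ("status", "direction", "companion_present",
                      "inspected_branch_support", "donor_phylum"):
                assert getattr(a, f) == getattr(b, f), scenario

    def test_tightening_phylum_threshold_never_creates_lgt(self, config_default):
        from lgtscreen.synth import make_scenario_batch

        batch = make_scenario_batch(25, seed=60)
        lgt_sets = []
        for min_phyla in (1, 2, 3, 4, 5):
            cfg = ScreenConfig(min_bacterial_phyla=min_phyla)
            hits = set()
            for gtree, _ in batch:
                fresh = classify_tree(gtree, cfg)
                if fresh.is_lgt:
                    hits.add(gtree.gene_id)
            lgt_sets.append(hits)
        for looser, tighter in zip(lgt_sets, lgt_sets[1:]):
            assert tighter <= looser

    def test_planted_scenarios_recovered_exactly(self, config_default):
        from lgtscreen.synth import make_scenario_batch

        for gtree, expected in make_scenario_batch(50, seed=123):
            got = classify_tree(gtree, config_default)
            for f in ("status", "direction", "companion_present",
                      "inspected_branch_support", "support_tier", "donor_phylum"):
                assert getattr(got, f) == getattr(expected, f), gtree.gene_id
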