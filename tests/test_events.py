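import numpy as np
import pytest

from caspevo.core import SpeciesTree
from caspevo.events import count_total_events, date_duplication, dollo_reconstruct
from oracles import dollo_min_losses_oracle


def random_tree(n_leaves: int, seed: int) -> SpeciesTree:
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n_leaves)]
    nodes = [f"{l}:0.1" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):0.1")
    return SpeciesTree.from_newick(nodes[0][: nodes[0].rfind(":")] + ";")


class TestDollo:
    def test_intact_everywhere_zero_losses(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        rec = dollo_reconstruct({s: True for s in "ABCD"}, tree, "g")
        assert rec.loss_count == 0

    def test_single_leaf_loss(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        rec = dollo_reconstruct({"A": True, "B": False, "C": True, "D": True}, tree, "g")
        assert rec.loss_branches == [["B"]]

    def test_clade_loss_counts_once_with_forced_origin(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        rec = dollo_reconstruct(
            {"A": True, "B": True, "C": False, "D": False},
            tree,
            "g",
            forced_origin=["A", "B", "C", "D"],
        )
        assert rec.loss_count == 1
        assert rec.loss_branches == [["C", "D"]]

    def test_origin_defaults_to_lca_of_intact_species(self):
        # without a forced deeper origin the gene never existed outside the
        # intact clade, so there is nothing to lose
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        rec = dollo_reconstruct({"A": True, "B": True, "C": False, "D": False}, tree, "g")
        assert rec.origin_leaves == ["A", "B"]
        assert rec.loss_count == 0

    def test_absent_everywhere_without_origin_is_error(self):
        tree = SpeciesTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            dollo_reconstruct({s: False for s in "ABC"}, tree, "g")

    def test_matches_brute_force_exhaustively_8_leaves(self):
        tree = random_tree(8, seed=0)
        labels = tree.leaf_labels
        for pattern in range(1, 2**8):
            presence = {l: bool(pattern >> i & 1) for i, l in enumerate(labels)}
            rec = dollo_reconstruct(presence, tree, "g")
            origin = tree.mrca(sorted(l for l, v in presence.items() if v))
            assert rec.loss_count == dollo_min_losses_oracle(tree, presence, origin)

    @pytest.mark.parametrize("n_leaves,seed", [(10, 1), (12, 2)])
    def test_matches_brute_force_sampled_patterns(self, n_leaves, seed):
        tree = random_tree(n_leaves, seed=seed)
        labels = tree.leaf_labels
        rng = np.random.default_rng(seed)
        for _ in range(150):
            presence = {l: bool(rng.integers(2)) for l in labels}
            if not any(presence.values()):
                continue
            rec = dollo_reconstruct(presence, tree, "g")
            origin = tree.mrca(sorted(l for l, v in presence.items() if v))
            assert rec.loss_count == dollo_min_losses_oracle(tree, presence, origin)

    def test_adding_intact_species_inside_lost_clade_never_decreases_losses(self):
        # sampling an extra intact species inside a lost clade splits it
        before = dollo_reconstruct(
            {"A": True, "B": True, "C": False, "D": False},
            SpeciesTree.from_newick("((A,B),(C,D));"),
            "g",
        ).loss_count
        after = dollo_reconstruct(
            {"A": True, "B": True, "C": False, "D": False, "E": True},
            SpeciesTree.from_newick("((A,B),((C,E),D));"),
            "g",
        ).loss_count
        assert after >= before
        assert after == 2

    def test_pseudogene_and_absent_equivalent_as_non_intact(self):
        # the presence matrix abstracts the non-intact route entirely: the
        # same booleans give the same reconstruction whether a homolog was
        # pseudogenized or deleted outright
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        from_pseudo = {"A": True, "B": False, "C": False, "D": True}
        from_absent = dict(from_pseudo)
        rec1 = dollo_reconstruct(from_pseudo, tree, "g")
        rec2 = dollo_reconstruct(from_absent, tree, "g")
        assert rec1.loss_branches == rec2.loss_branches
        assert rec1.loss_count == 2


class TestDateDuplication:
    def _aged_tree(self):
        tree = SpeciesTree.from_newick("(((Hum,Mac),Tarsier),Lemur);")
        tree.attach_ages_from_pairs(
            [("Hum", "Mac", 43.0), ("Hum", "Tarsier", 69.0), ("Hum", "Lemur", 74.0)]
        )
        return tree

    def test_simian_stem_interval(self):
        tree = self._aged_tree()
        presence = {"Hum": True, "Mac": True, "Tarsier": False, "Lemur": False}
        assert date_duplication(presence, tree) == (69.0, 43.0)

    def test_all_leaves_open_ended_above_root(self):
        tree = self._aged_tree()
        presence = {s: True for s in ("Hum", "Mac", "Tarsier", "Lemur")}
        old, young = date_duplication(presence, tree)
        assert old is None
        assert young == 74.0

    def test_missing_ages_is_error(self):
        tree = SpeciesTree.from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            date_duplication({"A": True, "B": True, "C": False}, tree)

    def test_simulated_duplication_bracketed(self):
        # a duplicate carried by the great-ape clade dates to its stem branch
        tree = SpeciesTree.from_newick("(((Hum,Gor),Mac),Marm);")
        tree.attach_ages_from_pairs(
            [("Hum", "Gor", 9.0), ("Hum", "Mac", 29.0), ("Hum", "Marm", 43.0)]
        )
        presence = {"Hum": True, "Gor": True, "Mac": False, "Marm": False}
        old, young = date_duplication(presence, tree)
        assert old == 29.0 and young == 9.0


class TestCountTable:
    def test_rows_and_columns(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        recs = [
            dollo_reconstruct({"A": True, "B": False, "C": True, "D": True}, tree, "g1"),
            dollo_reconstruct({"A": False, "B": True, "C": True, "D": True}, tree, "g2"),
        ]
        df = count_total_events(recs, clade_of={"g1": "primates", "g2": "rodents"})
        assert list(df["gene"]) == ["g1", "g2"]
        assert list(df["loss_count"]) == [1, 1]
        assert set(df.columns) >= {"gene", "clade", "loss_count", "loss_branches"}


class TestFixtures:
    def test_primate_casp12_at_least_four_losses(self):
        from importlib import resources

        base = resources.files("caspevo.tables")
        tree = SpeciesTree.from_newick((base / "primate_tree_synthetic.nwk").read_text())
        rows = [
            ln.split("\t")
            for ln in (base / "primate_casp12_status_synthetic.tsv").read_text().splitlines()
            if ln and not ln.startswith("#") and not ln.startswith("species")
        ]
        presence = {sp: code == "1" for sp, code in rows}
        rec = dollo_reconstruct(presence, tree, "CASP12")
        assert rec.loss_count >= 4

    def test_rodent_casp12_at_most_six_losses(self):
        from importlib import resources

        base = resources.files("caspevo.tables")
        tree = SpeciesTree.from_newick((base / "rodent_tree_synthetic.nwk").read_text())
        rows = [
            ln.split("\t")
            for ln in (base / "rodent_casp12_status_synthetic.tsv").read_text().splitlines()
            if ln and not ln.startswith("#") and not ln.startswith("species")
        ]
        presence = {sp: code == "1" for sp, code in rows}
        rec = dollo_reconstruct(presence, tree, "Casp12")
        assert 1 <= rec.loss_count <= 6
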