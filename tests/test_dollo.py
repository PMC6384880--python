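"""Dollo parsimony: trivial cases, brute-force oracle, timelines."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from endosym import (
    AncestorSpec,
    EvolutionParams,
    PresenceAbsenceMatrix,
    dollo_reconstruct,
    evolve_tree,
    generate_ancestor,
    load_dated_tree,
    loss_timeline,
    retained_fraction,
    shared_family_counts,
)
from endosym.simulate import _label


def _matrix(d, taxa):
    return PresenceAbsenceMatrix(pd.DataFrame(d, index=taxa).T)


SIX_LEAF_TREE = "(((A:1,B:1)ab:1,(C:1,D:1)cd:1)abcd:1,(E:1,F:1)ef:2)R;"


def brute_force_min_losses(tree, bearing_leaves):
    """Exhaustive minimal-loss count over all single-gain connected-subtree
    labelings whose subtree contains every bearing leaf."""
    nodes = list(tree.preorder_node_iter())
    labels = [_label(n) for n in nodes]
    children = {
        _label(n): [_label(c) for c in n.child_nodes()] for n in nodes
    }
    parent = {
        _label(n): _label(n.parent_node) if n.parent_node else None for n in nodes
    }
    best = None
    for gain in labels:
        # subtree below `gain` must contain all bearing leaves
        for present_mask in itertools.product(
            [0, 1], repeat=len(labels)
        ):
            present = {
                lab for lab, m in zip(labels, present_mask) if m
            }
            if gain not in present:
                continue
            if not bearing_leaves <= present:
                continue
            # present leaves must be exactly the bearing leaves
            leaf_set = {lab for lab in labels if not children[lab]}
            if (present & leaf_set) != bearing_leaves:
                continue
            # connectivity: every present node reaches gain through presents
            ok = True
            for lab in present:
                cur = lab
                while cur != gain:
                    cur = parent[cur]
                    if cur is None or cur not in present:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            losses = sum(
                1
                for lab in present
                for c in children[lab]
                if c not in present
            )
            if best is None or losses < best:
                best = losses
    return best


class TestDolloTrivial:
    def test_family_in_all_leaves_gained_at_root(self):
        m = _matrix({"f": [1, 1, 1]}, ["A", "B", "C"])
        r = dollo_reconstruct(m, "((A:1,B:1)ab:1,C:2)R;")
        assert "f" in r.node_families["R"]
        assert r.gains["R"] == ["f"]
        assert r.total_losses() == 0

    def test_single_leaf_family_terminal_gain(self):
        m = _matrix({"f": [0, 1, 0], "g": [1, 1, 1]}, ["A", "B", "C"])
        r = dollo_reconstruct(m, "((A:1,B:1)ab:1,C:2)R;")
        assert r.gains["B"] == ["f"]
        assert "f" not in r.node_families["ab"]
        assert r.total_losses() == 0

    def test_conservation_and_reorder_invariance(self):
        rng = np.random.default_rng(4)
        fams = {f"f{i}": rng.integers(0, 2, 6).tolist() for i in range(40)}
        fams = {k: v for k, v in fams.items() if sum(v)}
        taxa = ["A", "B", "C", "D", "E", "F"]
        m = _matrix(fams, taxa)
        r = dollo_reconstruct(m, SIX_LEAF_TREE)
        tree = r.tree
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            lab = _label(nd)
            plab = _label(nd.parent_node)
            assert len(r.node_families[lab]) == (
                len(r.node_families[plab])
                + len(r.gains[lab])
                - len(r.losses[lab])
            )
        # invariance under family and taxon-column reordering
        m2 = PresenceAbsenceMatrix(
            m.data.iloc[::-1][["F", "A", "C", "B", "E", "D"]]
        )
        r2 = dollo_reconstruct(m2, SIX_LEAF_TREE)
        assert r2.total_losses() == r.total_losses()
        assert {k: len(v) for k, v in r2.node_families.items()} == {
            k: len(v) for k, v in r.node_families.items()
        }

    def test_errors(self):
        m = _matrix({"f": [1, 1]}, ["A", "B"])
        with pytest.raises(ValueError, match="taxa"):
            dollo_reconstruct(m, "((X:1,Y:1)xy:1,Z:2)R;")
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(pd.DataFrame({"A": [0], "B": [0]}, index=["f"]))
        with pytest.raises(ValueError):
            PresenceAbsenceMatrix(pd.DataFrame({"A": [2]}, index=["f"]))


class TestDolloOracle:
    def test_matches_exhaustive_minimal_loss_search(self):
        """Per-family loss counts equal the brute-force minimum over all
        single-gain connected-subtree labelings (6-leaf tree, 50 families)."""
        tree = load_dated_tree(SIX_LEAF_TREE)
        taxa = ["A", "B", "C", "D", "E", "F"]
        rng = np.random.default_rng(11)
        fams = {}
        for i in range(50):
            row = rng.integers(0, 2, 6)
            if row.sum() == 0:
                row[rng.integers(6)] = 1
            fams[f"f{i}"] = row.tolist()
        m = _matrix(fams, taxa)
        r = dollo_reconstruct(m, SIX_LEAF_TREE)
        for fam, row in fams.items():
            bearing = {t for t, v in zip(taxa, row) if v}
            expected = brute_force_min_losses(tree, bearing)
            observed = sum(fam in v for v in r.losses.values())
            assert observed == expected, fam


class TestRetainedFraction:
    def test_chromatophore_scale_arithmetic(self):
        # 882 retained of 882+1620 ancestral families
        assert round(retained_fraction(882, 1620)) == 35

    def test_extremes_and_errors(self):
        assert retained_fraction(0, 10) == 0.0
        assert retained_fraction(10, 0) == 100.0
        with pytest.raises(ValueError):
            retained_fraction(0, 0)


class TestLossTimeline:
    def test_rate_arithmetic_on_printed_scale(self):
        """1,620 losses over the 124→60 Mya interval is 25.3 OGF/My."""
        # two outgroup leaves witness the ancestral inventory; the stem
        # branch S spans 124→60 Mya and loses 1,620 families
        fams = {f"f{i}": [0, 0, 1, 1] for i in range(1620)}
        fams.update({f"k{i}": [1, 1, 1, 1] for i in range(882)})
        m = _matrix(fams, ["L1", "L2", "A1", "A2"])
        tree = load_dated_tree("((L1:60,L2:60)S:64,A1:0.0,A2:0.0)R;")
        r = dollo_reconstruct(m, tree)
        assert len(r.losses["S"]) == 1620
        ages = {"R": 124.0, "S": 60.0, "L1": 0.0, "L2": 0.0,
                "A1": 124.0, "A2": 124.0}
        tl = loss_timeline(r, ages=ages, leaf="L1")
        (a0, a1, lost, rate) = tl.intervals[0]
        assert (a0, a1, lost) == (124.0, 60.0, 1620)
        assert round(rate, 1) == 25.3

    def test_zero_loss_interval(self):
        m = _matrix({"f": [1, 1]}, ["A", "B"])
        r = dollo_reconstruct(m, "(A:1,B:1)R;")
        tl = loss_timeline(r, leaf="A")
        assert tl.intervals[0][2] == 0 and tl.intervals[0][3] == 0.0

    def test_undated_node_errors(self):
        m = _matrix({"f": [1, 1]}, ["A", "B"])
        r = dollo_reconstruct(m, "(A:1,B:1)R;")
        with pytest.raises(ValueError, match="undated"):
            loss_timeline(r, ages={"R": 1.0, "A": 0.0}, leaf="B")


class TestSharedFamilies:
    def test_identical_and_disjoint(self):
        m = _matrix(
            {"f1": [1, 1, 0], "f2": [1, 1, 0], "f3": [0, 0, 1]},
            ["A", "B", "C"],
        )
        t = shared_family_counts(m, [("A", "B"), ("A", "C")])
        assert t.loc[0, "shared"] == 2 and t.loc[0, "jaccard"] == 1.0
        assert t.loc[1, "shared"] == 0

    def test_random_matrix_matches_set_oracle(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(
            rng.integers(0, 2, (80, 4)),
            index=[f"f{i}" for i in range(80)],
            columns=list("ABCD"),
        )
        data = data[data.sum(axis=1) > 0]
        m = PresenceAbsenceMatrix(data)
        t = shared_family_counts(m, [("A", "C"), ("B", "D")])
        for _, row in t.iterrows():
            sa = set(data.index[data[row.taxon_a] == 1])
            sb = set(data.index[data[row.taxon_b] == 1])
            assert row.shared == len(sa & sb)
            assert row.union == len(sa | sb)

    def test_unknown_taxon_errors(self):
        m = _matrix({"f": [1, 1]}, ["A", "B"])
        with pytest.raises(KeyError):
            shared_family_counts(m, [("A", "Z")])


class TestSimulatedRecovery:
    def test_per_branch_losses_recovered_exactly(self):
        """With the ancestor anchored as a zero-length root leaf, Dollo
        recovers the simulator's per-branch losses exactly for every family
        surviving in at least one leaf."""
        anc = generate_ancestor(
            AncestorSpec(
                genome_length=40_000, n_genes=60, mean_cds_length=500,
                n_duplicated_genes=0, rng_seed=21,
            )
        )
        params = EvolutionParams(
            tree="(((A:20,B:20)ab:20,C:40)abc:40,D:80)R;",
            seed=5, sub_rate=1e-4, indel_rate=0, inversion_rate=0,
            gene_loss_rate_per_phase=((80.0, 0.0, 0.004),),
        )
        leaves, log = evolve_tree(anc, params)
        assert len(log.losses()) > 5
        presence = {
            gid: {f.family for f in g.features if f.kind != "pseudogene"}
            for gid, g in leaves.items()
        }
        presence["ANC"] = {f.family for f in anc.features}
        m = PresenceAbsenceMatrix.from_presence(presence, sorted(presence))
        r = dollo_reconstruct(
            m, "((((A:20,B:20)ab:20,C:40)abc:40,D:80)stem:0.0,ANC:0.0)R;"
        )
        surviving = set().union(*(presence[l] for l in leaves))
        for branch in ("A", "B", "C", "D", "ab", "abc"):
            true = {e.family for e in log.losses(branch) if e.family in surviving}
            assert set(r.losses[branch]) == true
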