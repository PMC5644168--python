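"""NJ engine, bootstrap, consensus, rogue removal, rooting, assignment."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from ssu_census.phylogeny import (
    assign_phyla,
    bootstrap_trees,
    build_nj_tree,
    find_and_drop_rogues,
    flag_long_branches,
    jc_distance,
    majority_consensus,
    nj_tree,
    root_with_outgroup,
    tree_splits,
)
from ssu_census.qc import InternalWindow

from conftest import aseq


# --- helpers ---------------------------------------------------------------

def random_binary_tree(names, rng, lo=0.1, hi=1.0):
    nodes = [TreeNode(name=n) for n in names]
    for nd in nodes:
        nd.length = rng.uniform(lo, hi)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = TreeNode()
        p.length = rng.uniform(lo, hi)
        p.extend([nodes[j], nodes[i]])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = TreeNode()
    root.extend(nodes)
    return root


def path_distances(tree, names):
    tips = {t.name: t for t in tree.tips()}
    n = len(names)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = tips[names[a]].distance(tips[names[b]])
    return d


def splits_from_distances(d, names):
    """Independent oracle: splits supported by the four-point condition.

    A bipartition {A|B} is additive-supported iff for every quartet
    (a1,a2,b1,b2), d(a1,a2)+d(b1,b2) < min of the two cross pairings.
    """
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    anchor = min(names)
    supported = set()
    for r in range(2, n - 1):
        for side in itertools.combinations([nm for nm in names if nm != anchor], r):
            A = set(side)
            B = set(names) - A
            ok = True
            for a1, a2 in itertools.combinations(sorted(A), 2):
                for b1, b2 in itertools.combinations(sorted(B), 2):
                    s0 = d[idx[a1], idx[a2]] + d[idx[b1], idx[b2]]
                    s1 = d[idx[a1], idx[b1]] + d[idx[a2], idx[b2]]
                    s2 = d[idx[a1], idx[b2]] + d[idx[a2], idx[b1]]
                    if not (s0 < s1 - 1e-9 and s0 < s2 - 1e-9):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                supported.add(frozenset(A))
    return supported


# --- NJ --------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(np.zeros((2, 2)), ["A", "B"])

    def test_zero_distance_pair(self):
        assert jc_distance(0.0) == 0.0

    def test_saturated_proportion_capped_with_warning(self):
        with pytest.warns(UserWarning, match="saturated"):
            d = jc_distance(0.8)
        assert d == jc_distance(0.71)  # both capped at 0.70

    def test_recovers_topology_from_additive_distances(self):
        """NJ is consistent on tree-additive distances (4-8 leaves)."""
        rng = np.random.default_rng(2)
        for trial in range(50):
            n = int(rng.integers(4, 9))
            names = [f"L{i}" for i in range(n)]
            true = random_binary_tree(names, rng)
            d = path_distances(true, names)
            est = nj_tree(d, names)
            assert tree_splits(est) == tree_splits(true)

    def test_splits_match_four_point_oracle_for_small_trees(self):
        """For 4-6 leaves, compare against exhaustive bipartition checking."""
        rng = np.random.default_rng(3)
        for trial in range(15):
            n = int(rng.integers(4, 7))
            names = [f"L{i}" for i in range(n)]
            true = random_binary_tree(names, rng)
            d = path_distances(true, names)
            assert tree_splits(nj_tree(d, names)) == splits_from_distances(d, names)

    def test_agrees_with_skbio_nj_on_noisy_distances(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = int(rng.integers(4, 10))
            names = [f"L{i}" for i in range(n)]
            d = path_distances(random_binary_tree(names, rng), names)
            d += rng.uniform(0, 0.02, d.shape)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            mine = nj_tree(d, names)
            ref = skbio_nj(DistanceMatrix(d, names))
            assert tree_splits(mine) == tree_splits(ref)

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = 7
            names = [f"L{i}" for i in range(n)]
            d = rng.uniform(0.1, 1.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            tree = nj_tree(d, names)
            assert all(
                nd.length >= 0 for nd in tree.traverse(include_self=False)
            )

    def test_newick_roundtrip(self):
        rng = np.random.default_rng(6)
        names = [f"L{i}" for i in range(6)]
        d = path_distances(random_binary_tree(names, rng), names)
        tree = nj_tree(d, names)
        back = TreeNode.read([str(tree)])
        assert str(back) == str(tree)


class TestBuildFromSequences:
    def test_identical_pair_distance_zero(self):
        w = InternalWindow(0, 20)
        seqs = [
            aseq("a", "ACGTACGTACGTACGTACGT"),
            aseq("b", "ACGTACGTACGTACGTACGT"),
            aseq("c", "TTTTACGTACGTACGTCCCC"),
        ]
        tree = build_nj_tree(seqs, w)
        tips = {t.name: t for t in tree.tips()}
        assert tips["a"].distance(tips["b"]) == pytest.approx(0.0)

    def test_requires_three_sequences(self):
        w = InternalWindow(0, 4)
        with pytest.raises(ValueError):
            build_nj_tree([aseq("a", "ACGT"), aseq("b", "ACGT")], w)


class TestBootstrap:
    def test_zero_replicates(self, window900, small_dataset):
        _, seqs, truth, _ = small_dataset
        reps = [s for s in seqs if s.seq_id in truth.clean_ids()][:5]
        assert bootstrap_trees(reps, window900, n=0) == []

    def test_deterministic_under_seed(self, window900, small_dataset):
        _, seqs, truth, _ = small_dataset
        reps = [s for s in seqs if s.seq_id in truth.clean_ids()][:8]
        a = bootstrap_trees(reps, window900, n=5, seed=7)
        b = bootstrap_trees(reps, window900, n=5, seed=7)
        assert [str(t) for t in a] == [str(t) for t in b]

    def test_deep_splits_supported_on_clean_data(self, window900, small_dataset):
        """Phylum-level bipartitions appear in nearly every replicate."""
        _, seqs, truth, _ = small_dataset
        by_otu = {}
        for s in seqs:
            if s.seq_id in truth.clean_ids():
                by_otu.setdefault(truth.true_otu[s.seq_id], s)
        reps = sorted(by_otu.values(), key=lambda s: s.seq_id)
        trees = bootstrap_trees(reps, window900, n=40, seed=1)
        leaves = frozenset(s.seq_id for s in reps)
        anchor = min(leaves)
        for phylum in sorted({truth.true_phylum[s.seq_id] for s in reps}):
            side = frozenset(
                s.seq_id for s in reps if truth.true_phylum[s.seq_id] == phylum
            )
            if anchor in side:
                side = leaves - side
            support = sum(1 for t in trees if side in tree_splits(t)) / len(trees)
            assert support >= 0.95


class TestConsensus:
    def test_identical_trees_reproduce_with_full_support(self):
        t = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,E:1);"])
        cons = majority_consensus([t.copy() for _ in range(6)])
        assert tree_splits(cons) == tree_splits(t)
        assert all(n.support == 100.0 for n in cons.non_tips())

    def test_even_conflict_collapses_to_polytomy(self):
        t1 = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,E:1);"])
        t2 = TreeNode.read(["((A:1,C:1):1,(B:1,D:1):1,E:1);"])
        cons = majority_consensus([t1, t2])
        assert tree_splits(cons) == set()

    def test_supports_match_bruteforce_bipartition_tally(self):
        rng = np.random.default_rng(9)
        names = list("ABCDE")
        trees = [random_binary_tree(names, rng) for _ in range(9)]
        cons = majority_consensus(trees)
        leaves = frozenset(names)
        for node in cons.non_tips():
            clade = frozenset(t.name for t in node.tips())
            side = leaves - clade if "A" in clade else clade
            count = sum(1 for t in trees if side in tree_splits(t))
            assert node.support == pytest.approx(100.0 * count / len(trees))
            assert 50.0 < node.support <= 100.0

    def test_mismatched_leaf_sets_rejected(self):
        t1 = TreeNode.read(["((A,B),(C,D),E);"])
        t2 = TreeNode.read(["((A,B),(C,D),F);"])
        with pytest.raises(ValueError, match="leaf set"):
            majority_consensus([t1, t2])


def plant_rogue(base, rng, name="rogue"):
    """Attach a rogue leaf on a uniformly random edge of a copy of base."""
    t = base.copy()
    nodes = list(t.traverse(include_self=False))
    target = nodes[rng.integers(len(nodes))]
    parent = target.parent
    holder = TreeNode()
    parent.remove(target)
    holder.extend([target, TreeNode(name=name)])
    parent.append(holder)
    return t


class TestRogueRemoval:
    def test_identical_replicates_have_no_rogues(self):
        rng = np.random.default_rng(1)
        base = random_binary_tree([f"x{i}" for i in range(8)], rng)
        surv, log = find_and_drop_rogues([base.copy() for _ in range(10)])
        assert log[0]["rogues"] == []
        assert log[0]["stopped"] == "fewer_rogues_than_threshold"
        assert surv == frozenset(f"x{i}" for i in range(8))

    def test_planted_rogue_identified_in_round_one(self):
        found = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = random_binary_tree([f"t{i:02d}" for i in range(11)], rng)
            reps = [plant_rogue(base, rng) for _ in range(50)]
            surv, log = find_and_drop_rogues(reps, stop_when_fewer_than=1, max_rounds=1)
            found += "rogue" in log[0]["rogues"]
        assert found >= 18

    def test_resolution_never_drops_when_rogues_pruned(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            base = random_binary_tree([f"t{i:02d}" for i in range(11)], rng)
            reps = [plant_rogue(base, rng) for _ in range(50)]
            _, log = find_and_drop_rogues(reps, stop_when_fewer_than=1)
            for entry in log:
                if "resolved_after" in entry:
                    assert entry["resolved_after"] >= entry["resolved_before_on_pruned_set"]

    def test_requires_five_leaves(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        with pytest.raises(ValueError, match="5 leaves"):
            find_and_drop_rogues([t, t.copy()])


class TestRooting:
    def test_single_outgroup_roots_on_pendant_edge(self):
        t = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,O:2);"])
        r = root_with_outgroup(t, ["O"])
        sides = [sorted(x.name for x in c.tips(include_self=True)) for c in r.children]
        assert ["O"] in sides

    def test_monophyletic_outgroup_roots_on_stem(self):
        t = TreeNode.read(
            ["(((A:1,B:1):1,(C:1,D:1):1):1,((X:1,Y:1):1,Z:1):1,E:1);"]
        )
        r = root_with_outgroup(t, ["X", "Y", "Z"])
        sides = [frozenset(x.name for x in c.tips(include_self=True)) for c in r.children]
        assert frozenset({"X", "Y", "Z"}) in sides

    def test_nonmonophyletic_outgroup_warns(self):
        t = TreeNode.read(["((A:1,X:1):1,(C:1,Y:1):1,E:1);"])
        with pytest.warns(UserWarning, match="not monophyletic"):
            root_with_outgroup(t, ["X", "Y"])

    def test_outgroup_covering_all_leaves_rejected(self):
        t = TreeNode.read(["((A,B),(C,D),E);"])
        with pytest.raises(ValueError, match="every leaf"):
            root_with_outgroup(t, list("ABCDE"))

    def test_missing_outgroup_id_rejected(self):
        t = TreeNode.read(["((A,B),(C,D),E);"])
        with pytest.raises(ValueError, match="absent"):
            root_with_outgroup(t, ["Q"])


class TestLongBranches:
    def test_equal_pendants_give_no_flags(self):
        t = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1,E:1);"])
        assert flag_long_branches(t) == []

    def test_single_outlier_flagged(self):
        t = TreeNode.read(
            ["((A:0.1,B:0.1):0.1,(C:0.1,D:2.0):0.1,(E:0.1,F:0.1):0.1);"]
        )
        assert flag_long_branches(t, multiplier=10) == ["D"]

    def test_infinite_multiplier_flags_nothing(self):
        t = TreeNode.read(["((A:0.1,B:9.9):0.1,(C:0.1,D:2.0):0.1,E:0.1);"])
        assert flag_long_branches(t, multiplier=float("inf")) == []


class TestAssignPhyla:
    def test_sister_to_labeled_leaf_with_high_support(self):
        t = TreeNode.read(["((q:1,ref:1)100:1,(o1:1,o2:1)100:1)root;"])
        out = assign_phyla(t, {"ref": "PhylumA"})
        assert out["q"] == "PhylumA"

    def test_mixed_labels_in_smallest_clade_stay_unassigned(self):
        t = TreeNode.read(["((q:1,(a:1,b:1)100:1)100:1,(c:1,d:1)100:1)root;"])
        out = assign_phyla(t, {"a": "A", "b": "B"})
        assert out["q"] is None

    def test_low_support_blocks_assignment(self):
        t = TreeNode.read(["((q:1,ref:1)30:1,(o1:1,o2:1)100:1)root;"])
        out = assign_phyla(t, {"ref": "PhylumA"})
        assert out["q"] is None

    def test_no_labels_warns_and_unassigns_everything(self):
        t = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1)root;"])
        with pytest.warns(UserWarning, match="no labeled"):
            out = assign_phyla(t, {})
        assert set(out.values()) == {None}

    def test_recovery_on_synthetic_data_with_half_labels(self, small_dataset, window900):
        """Most unlabeled OTU representatives recover their true phylum
        when half the representatives per phylum carry labels."""
        _, seqs, truth, _ = small_dataset
        by_otu = {}
        for s in seqs:
            if s.seq_id in truth.clean_ids():
                by_otu.setdefault(truth.true_otu[s.seq_id], s)
        reps = sorted(by_otu.values(), key=lambda s: s.seq_id)
        labels = {}
        for phylum in sorted({truth.true_phylum[s.seq_id] for s in reps}):
            members = [s for s in reps if truth.true_phylum[s.seq_id] == phylum]
            for s in members[: len(members) // 2]:
                labels[s.seq_id] = phylum
        from ssu_census.phylogeny import annotate_support

        trees = bootstrap_trees(reps, window900, n=30, seed=0)
        tree = build_nj_tree(reps, window900).root_at_midpoint(reset=True)
        annotate_support(tree, trees)
        out = assign_phyla(tree, labels)
        unlabeled = [s.seq_id for s in reps if s.seq_id not in labels]
        correct = sum(
            1 for sid in unlabeled if out[sid] == truth.true_phylum[sid]
        )
        assert correct / len(unlabeled) >= 0.95
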