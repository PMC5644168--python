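"""Tree building and tree-based screening for the census pipeline.

The internal inference engine is distance-based: Jukes–Cantor–corrected
distances over the internal window feed a neighbor-joining (NJ)
construction. Column-resampling bootstrap replicates provide support
values, a majority-rule consensus summarises them, and "rogue" leaves —
taxa whose position is unstable across replicates, degrading consensus
resolution — are detected and removed iteratively. An optional adapter
slot lets a driver substitute an external maximum-likelihood engine; all
downstream stages only require Newick trees with branch lengths.

Trees are :class:`skbio.TreeNode` objects throughout, so Newick IO, LCA
queries and re-rooting come from scikit-bio.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .qc import InternalWindow
from .seqio import GAP_CODE, AlignedSequence, encode

#: observed-difference proportions are capped here before JC correction
P_CAP = 0.70
#: proportions at or beyond this are formally saturated under JC
P_SATURATION = 0.75


def jc_distance(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p) for proportion p.

    Proportions above :data:`P_CAP` are capped (with a warning at or above
    the formal saturation point 0.75, where the correction diverges).
    """
    if p < 0:
        raise ValueError("difference proportion must be >= 0")
    if p >= P_SATURATION:
        warnings.warn(
            f"observed difference proportion {p:.3f} is saturated; capping at {P_CAP}",
            stacklevel=2,
        )
    p = min(p, P_CAP)
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _pair_indicators(
    seqs: Sequence[AlignedSequence], window: InternalWindow
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Per-pair per-column (match, scored) boolean matrices over the window."""
    enc = encode(seqs)[:, window.slice()]
    gaps = enc == GAP_CODE
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    M = np.empty((len(pairs), window.width), dtype=bool)
    S = np.empty((len(pairs), window.width), dtype=bool)
    for k, (i, j) in enumerate(pairs):
        both_gap = gaps[i] & gaps[j]
        S[k] = ~both_gap
        M[k] = (enc[i] == enc[j]) & S[k]
    return pairs, M, S


def _distance_matrix_from_counts(
    n: int,
    pairs: list[tuple[int, int]],
    matches: np.ndarray,
    scored: np.ndarray,
) -> np.ndarray:
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        # saturation warnings are raised once per build, not per pair
        warnings.simplefilter("ignore")
        for k, (i, j) in enumerate(pairs):
            p = 1.0 - matches[k] / scored[k] if scored[k] else P_CAP
            d[i, j] = d[j, i] = jc_distance(p)
    return d


def jc_distance_matrix(
    seqs: Sequence[AlignedSequence], window: InternalWindow
) -> np.ndarray:
    """Pairwise JC-corrected distance matrix over the window."""
    pairs, M, S = _pair_indicators(seqs, window)
    return _distance_matrix_from_counts(
        len(seqs), pairs, M.sum(axis=1).astype(float), S.sum(axis=1).astype(float)
    )


def nj_tree(distances: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix.

    Negative branch lengths produced by the NJ formulas are clamped to
    zero and the deficit moved to the sibling branch (the co-joined
    node's branch), preserving the path length between the joined pair.
    Returns an unrooted tree (trifurcating root).
    """
    d = np.asarray(distances, dtype=float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or len(names) != n:
        raise ValueError("distance matrix and name list are inconsistent")
    nodes = [TreeNode(name=str(nm)) for nm in names]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first minimum: deterministic
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li  # move deficit to the sibling
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        ai, aj = active[i], active[j]
        parent = TreeNode()
        nodes[ai].length = li
        nodes[aj].length = lj
        parent.extend([nodes[ai], nodes[aj]])
        # distances from the new node to the remaining taxa
        new = np.zeros(d.shape[0] + 1)
        for t, at in enumerate(active):
            if at in (ai, aj):
                continue
            new[at] = 0.5 * (d[ai, at] + d[aj, at] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new) - 1] = new[:-1]
        d[: len(new) - 1, -1] = new[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = np.array([la, lb, lc])
    if (lens < 0).any():
        deficit = lens[lens < 0].sum()
        lens = np.clip(lens, 0.0, None)
        lens[np.argmax(lens)] += deficit
        lens = np.clip(lens, 0.0, None)
    root = TreeNode()
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), lens):
        node.length = float(ln)
        root.append(node)
    return root


def build_nj_tree(
    seqs: Sequence[AlignedSequence], window: InternalWindow
) -> TreeNode:
    """JC-corrected NJ tree of the given sequences over the window."""
    if len(seqs) < 3:
        raise ValueError("tree building needs at least 3 sequences")
    d = jc_distance_matrix(seqs, window)
    return nj_tree(d, [s.seq_id for s in seqs])


def bootstrap_trees(
    seqs: Sequence[AlignedSequence],
    window: InternalWindow,
    n: int = 100,
    seed: int = 0,
) -> list[TreeNode]:
    """Column-resampling bootstrap: n replicate NJ trees.

    Each replicate resamples the window's columns with replacement,
    recomputes JC distances on the resampled columns, and rebuilds the
    tree. Deterministic under ``seed``.
    """
    if n == 0:
        return []
    if len(seqs) < 3:
        raise ValueError("tree building needs at least 3 sequences")
    rng = np.random.default_rng(seed)
    pairs, M, S = _pair_indicators(seqs, window)
    names = [s.seq_id for s in seqs]
    out = []
    for _ in range(n):
        idx = rng.integers(0, window.width, size=window.width)
        matches = M[:, idx].sum(axis=1).astype(float)
        scored = S[:, idx].sum(axis=1).astype(float)
        d = _distance_matrix_from_counts(len(seqs), pairs, matches, scored)
        out.append(nj_tree(d, names))
    return out


# ---------------------------------------------------------------------------
# bipartitions and consensus

def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, in canonical form.

    Each split is stored as the frozenset of leaf names on the side NOT
    containing the lexicographically smallest leaf.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def _restricted_split_sets(
    split_sets: Sequence[set[frozenset]],
    leaves: frozenset,
    exclude: frozenset = frozenset(),
) -> list[set[frozenset]]:
    """Restrict each tree's splits to ``leaves - exclude``, re-canonicalised."""
    remaining = leaves - exclude
    anchor = min(remaining)
    out = []
    for splits in split_sets:
        restricted: set[frozenset] = set()
        for side in splits:
            side = side & remaining
            if anchor in side:
                side = remaining - side
            if 2 <= len(side) <= len(remaining) - 2:
                restricted.add(side)
        out.append(restricted)
    return out


def _majority_splits(
    split_sets: Sequence[set[frozenset]],
) -> dict[frozenset, int]:
    """Splits occurring in a strict majority of the trees, with counts."""
    counts = Counter(s for splits in split_sets for s in splits)
    nt = len(split_sets)
    return {s: c for s, c in counts.items() if 2 * c > nt}


def count_resolved_splits(
    split_sets: Sequence[set[frozenset]],
    leaves: frozenset,
    exclude: frozenset = frozenset(),
) -> int:
    """Number of internal bipartitions with >50% support after pruning."""
    return len(_majority_splits(_restricted_split_sets(split_sets, leaves, exclude)))


def consensus_score(
    split_sets: Sequence[set[frozenset]],
    leaves: frozenset,
    exclude: frozenset = frozenset(),
) -> tuple[int, float]:
    """(resolved-split count, total support) of the majority consensus.

    Total support sums, over the strict-majority bipartitions, the
    fraction of replicates containing each — the quantity rogue removal
    tries to increase. A leaf that merely wanders among replicates may
    depress every support without dissolving any single majority split,
    so the support sum detects instability the count alone cannot.
    """
    maj = _majority_splits(_restricted_split_sets(split_sets, leaves, exclude))
    nt = len(split_sets)
    return len(maj), float(sum(maj.values())) / nt


def _restrict_majority(
    maj: Mapping[frozenset, int], remaining: frozenset
) -> dict[frozenset, int]:
    """Project majority splits onto a leaf subset, merging duplicates.

    Splits that become identical after restriction keep the highest
    count; trivial splits drop. This is the like-for-like baseline when
    judging what pruning a leaf changes: a split that existed only as a
    leaf-shifted variant of another should not count as lost resolution.
    """
    anchor = min(remaining)
    out: dict[frozenset, int] = {}
    for side, count in maj.items():
        side = side & remaining
        if anchor in side:
            side = remaining - side
        if 2 <= len(side) <= len(remaining) - 2:
            out[side] = max(out.get(side, 0), count)
    return out


def majority_consensus(trees: Sequence[TreeNode]) -> TreeNode:
    """Majority-rule (>50%) consensus with percent supports on internal nodes.

    All trees must share one leaf set. Retained bipartitions are those in
    a strict majority of replicates (so supports lie in (50, 100]); all
    other resolutions collapse to polytomies.
    """
    if not trees:
        raise ValueError("no trees given")
    leafsets = [frozenset(t.name for t in tr.tips()) for tr in trees]
    leaves = leafsets[0]
    if any(ls != leaves for ls in leafsets):
        raise ValueError("trees are not on the same leaf set")
    split_sets = [tree_splits(t) for t in trees]
    maj = _majority_splits(split_sets)

    # strict-majority splits are pairwise compatible; build the tree by
    # nesting the canonical sides (none contains the anchor leaf)
    root = TreeNode()
    nodes: list[tuple[frozenset, TreeNode]] = []
    for side in sorted(maj, key=len, reverse=True):
        parent = root
        for other, onode in nodes:
            if side < other:
                parent = onode  # nodes are processed largest-first: smallest container wins
        node = TreeNode()
        node.support = 100.0 * maj[side] / len(trees)
        node.name = f"{node.support:g}"
        parent.append(node)
        nodes.append((side, node))
    for leaf in sorted(leaves):
        parent = root
        best: frozenset | None = None
        for side, onode in nodes:
            if leaf in side and (best is None or side < best):
                parent, best = onode, side
        parent.append(TreeNode(name=leaf))
    return root


def annotate_support(
    tree: TreeNode, replicates: Sequence[TreeNode]
) -> TreeNode:
    """Attach bootstrap supports (percent) to a tree's internal nodes."""
    leaves = frozenset(t.name for t in tree.tips())
    counts = Counter(s for t in replicates for s in tree_splits(t))
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        side = leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(leaves) - 2:
            node.support = 100.0 * counts.get(side, 0) / max(len(replicates), 1)
            node.name = f"{node.support:g}"
    return tree


# ---------------------------------------------------------------------------
# rogue taxa

def find_and_drop_rogues(
    trees: Sequence[TreeNode],
    max_rounds: int = 10,
    stop_when_fewer_than: int = 5,
    min_support_gain: float = 0.5,
) -> tuple[frozenset, list[dict]]:
    """Iterative leaf-stability screening over bootstrap replicates.

    Per round, each remaining leaf ``t`` gets an improvement score from
    the consensus of the replicates with ``t`` pruned, relative to the
    unpruned consensus: primarily the change in the number of
    majority-supported bipartitions, and — when the count is unchanged —
    the change in their total support (a wandering leaf depresses
    supports without necessarily dissolving any single majority split;
    the support change must exceed ``min_support_gain``, measured in
    summed replicate fractions, to count — bootstrap noise on stable
    data sits well below half a bipartition's worth of support).
    All leaves with positive improvement are that round's rogues; they
    are pruned and the procedure repeats. It stops when a round
    identifies fewer than ``stop_when_fewer_than`` rogues (those are
    left in place), when pruning would leave fewer than 4 leaves, or
    after ``max_rounds``.

    Returns the surviving leaf set and a per-round log.
    """
    if len(trees) < 2:
        raise ValueError("rogue detection needs at least 2 replicate trees")
    leaves = frozenset(t.name for t in trees[0].tips())
    if len(leaves) < 5:
        raise ValueError("rogue detection needs at least 5 leaves")
    split_sets = [tree_splits(t) for t in trees]
    removed: frozenset = frozenset()
    log: list[dict] = []
    eps = max(min_support_gain, 1e-9)
    nt = len(split_sets)
    for rnd in range(1, max_rounds + 1):
        current = leaves - removed
        base_maj = _majority_splits(_restricted_split_sets(split_sets, leaves, removed))
        improvements = {}
        for t in sorted(current):
            cnt, sup = consensus_score(split_sets, leaves, removed | {t})
            # baseline on the same (pruned) leaf set, duplicates merged
            ref = _restrict_majority(base_maj, current - {t})
            dc = cnt - len(ref)
            ds = sup - sum(ref.values()) / nt
            improvements[t] = (dc, ds)
        rogues = sorted(
            t
            for t, (dc, ds) in improvements.items()
            if dc > 0 or (dc == 0 and ds >= eps)
        )
        entry = {
            "round": rnd,
            "resolved_before": len(base_maj),
            "support_before": float(sum(base_maj.values())) / nt,
            "improvements": improvements,
            "rogues": rogues,
        }
        if len(rogues) < stop_when_fewer_than:
            entry["stopped"] = "fewer_rogues_than_threshold"
            log.append(entry)
            break
        if len(current) - len(rogues) < 4:
            warnings.warn("pruning all rogues would leave fewer than 4 leaves; stopping")
            entry["stopped"] = "too_few_leaves"
            log.append(entry)
            break
        removed = removed | frozenset(rogues)
        entry["resolved_before_on_pruned_set"] = len(
            _restrict_majority(base_maj, leaves - removed)
        )
        entry["resolved_after"] = count_resolved_splits(split_sets, leaves, removed)
        log.append(entry)
    return leaves - removed, log


# ---------------------------------------------------------------------------
# rooting, long branches, phylum assignment

def root_with_outgroup(tree: TreeNode, outgroup_ids: Iterable[str]) -> TreeNode:
    """Root on the stem of the smallest clade containing the outgroup.

    If the outgroup is not monophyletic, the root goes on the edge whose
    leaf-side maximises Jaccard similarity with the outgroup set, with a
    warning.
    """
    outgroup = frozenset(outgroup_ids)
    if not outgroup:
        raise ValueError("outgroup_ids is empty")
    leaves = frozenset(t.name for t in tree.tips())
    missing = outgroup - leaves
    if missing:
        raise ValueError(f"outgroup ids absent from tree: {sorted(missing)[:3]}")
    ingroup = leaves - outgroup
    if not ingroup:
        raise ValueError("outgroup covers every leaf; nothing to root")

    # anchor the traversal outside the outgroup so its clade is well defined
    anchor_name = min(ingroup)
    anchor = next(t for t in tree.tips() if t.name == anchor_name)
    work = tree.root_at(anchor.parent, reset=True)

    lca = work.lca(sorted(outgroup)) if len(outgroup) > 1 else next(
        t for t in work.tips() if t.name in outgroup
    )
    clade = frozenset(t.name for t in lca.tips(include_self=True))
    if clade != outgroup:
        best, best_side, best_score = None, frozenset(), -1.0
        for node in work.postorder(include_self=False):
            side = frozenset(t.name for t in node.tips(include_self=True))
            score = len(side & outgroup) / len(side | outgroup)
            if score > best_score or (score == best_score and len(side) < len(best_side)):
                best, best_side, best_score = node, side, score
        warnings.warn(
            "outgroup is not monophyletic; rooting on the edge with highest "
            f"outgroup purity (Jaccard {best_score:.2f})"
        )
        lca = best
    return work.root_at(lca, above=True, reset=True)


def flag_long_branches(tree: TreeNode, multiplier: float = 10.0) -> list[str]:
    """Leaves whose pendant branch exceeds ``multiplier`` x median pendant length.

    Advisory flags only — likely contaminants or artifacts; removal is the
    caller's decision.
    """
    tips = list(tree.tips())
    lengths = np.array([t.length if t.length is not None else 0.0 for t in tips])
    med = float(np.median(lengths))
    return [t.name for t, ln in zip(tips, lengths) if ln > multiplier * med]


def node_support(node: TreeNode) -> float | None:
    """Support of an internal node, from the attribute or a numeric name."""
    s = getattr(node, "support", None)
    if s is not None:
        return float(s)
    if node.name:
        try:
            return float(node.name)
        except ValueError:
            return None
    return None


def assign_phyla(
    rooted_tree: TreeNode,
    leaf_labels: Mapping[str, str],
    support_min: float = 50.0,
) -> dict[str, str | None]:
    """Monophyly-based phylum assignment of unlabeled leaves.

    Internal edges with support below ``support_min`` (absent support
    fails) are treated as unresolved, i.e. collapsed into their parent.
    Each unlabeled leaf then walks toward the root to the smallest
    trustworthy (supported) clade containing at least one labeled leaf;
    it receives that phylum iff every labeled leaf in the clade carries
    the same phylum. A mixed clade, or reaching the root without a
    supported labeled clade, leaves it unassigned (``None``).
    """
    tips = list(rooted_tree.tips())
    if not any(t.name in leaf_labels for t in tips):
        warnings.warn("no labeled leaves; every leaf is unassigned")
        return {t.name: None for t in tips}

    label_sets: dict[int, set[str]] = {}
    for node in rooted_tree.postorder(include_self=True):
        if node.is_tip():
            lbl = leaf_labels.get(node.name)
            label_sets[id(node)] = {lbl} if lbl is not None else set()
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= label_sets[id(child)]
            label_sets[id(node)] = acc

    out: dict[str, str | None] = {}
    for tip in tips:
        if tip.name in leaf_labels:
            out[tip.name] = leaf_labels[tip.name]
            continue
        assigned: str | None = None
        node = tip.parent
        while node is not None and node.parent is not None:
            sup = node_support(node)
            if sup is None or sup < support_min:  # unresolved: collapse upward
                node = node.parent
                continue
            labels = label_sets[id(node)]
            if labels:
                if len(labels) == 1:
                    assigned = next(iter(labels))
                break
            node = node.parent
        out[tip.name] = assigned
    return out


def run_external_ml(*args, **kwargs):  # pragma: no cover - untested glue
    """Adapter slot for an external maximum-likelihood tree engine.

    Downstream stages only need Newick trees with branch lengths, so a
    driver may substitute trees from a GTR+GAMMA ML program here; nothing
    in this package shells out by itself.
    """
    raise NotImplementedError("external ML inference is not bundled")
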