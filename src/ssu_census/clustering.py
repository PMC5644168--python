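"""Greedy centroid clustering at two identity levels and novelty calls.

The clustering scheme mirrors length-sorted greedy centroid clustering:
sequences are visited in order of decreasing ungapped length (ties broken
by ascending id), and each either joins the first existing centroid — in
centroid-creation order — within the identity threshold, or founds a new
cluster. Identity is computed over the internal window only:

    identity = 100 * (matching columns) / (columns where at least one
               sequence has a residue)

Dual-gap columns are excluded entirely; a residue opposite a gap counts as
a mismatch. Clustering is run first at 97% (species-like OTUs), then the
97% centroids are clustered at 85% (order-level clusters); every OTU is
thereby linked to exactly one 85% cluster. 85% clusters backed by a single
underlying sequence are removed and their OTUs flagged unplaced.

Novelty of each OTU against an amplicon reference database is decided by a
joint re-clustering of pipeline plus reference sequences at 97%: an OTU
whose representative co-clusters with a reference sequence is categorised
``mg_and_silva``; OTUs containing a genome-derived member are
``genome_backed`` regardless (precedence genome_backed > mg_and_silva >
mg_only); the rest are ``mg_only``. Joint clusters made up purely of
reference sequences are discarded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qc import InternalWindow
from .seqio import GAP_CODE, AlignedSequence, encode

NOVELTY_CATEGORIES = ("mg_only", "mg_and_silva", "genome_backed")

# identity comparisons use an epsilon so that e.g. 29/30 columns compared
# against a rational threshold does not flip on float rounding
_EPS = 1e-9


@dataclass
class Otu97:
    """A 97%-identity operational taxonomic unit."""

    otu_id: str
    centroid_id: str
    member_ids: list[str]
    contains_genome: bool = False
    novelty: str | None = None
    unplaced: bool = False  # true when its 85% cluster was removed as a singleton


@dataclass
class Cluster85:
    """An 85%-identity (order-level) cluster of 97% OTU centroids."""

    cluster_id: str
    centroid_otu_id: str
    member_otu_ids: list[str]
    silva_only: bool = False


def pairwise_identity(
    a: AlignedSequence, b: AlignedSequence, window: InternalWindow
) -> float:
    """Percent identity of two aligned sequences over ``window``.

    Raises if either sequence is entirely gaps within the window, in which
    case identity is undefined.
    """
    sa = a.residues[window.slice()]
    sb = b.residues[window.slice()]
    matches = scored = 0
    a_has = b_has = False
    for ca, cb in zip(sa, sb):
        ga, gb = ca == "-", cb == "-"
        a_has |= not ga
        b_has |= not gb
        if ga and gb:
            continue
        scored += 1
        if ca == cb:
            matches += 1
    if not a_has:
        raise ValueError(f"sequence {a.seq_id!r} is all-gap in the window")
    if not b_has:
        raise ValueError(f"sequence {b.seq_id!r} is all-gap in the window")
    return 100.0 * matches / scored


def _sort_order(seqs: list[AlignedSequence]) -> list[int]:
    """Length-descending, id-ascending visit order (index list)."""
    return sorted(
        range(len(seqs)), key=lambda i: (-seqs[i].ungapped_length, seqs[i].seq_id)
    )


def greedy_cluster(
    seqs: list[AlignedSequence],
    threshold_percent: float,
    window: InternalWindow,
) -> list[list[str]]:
    """Greedy centroid clustering; returns member-id lists, centroid first.

    Deterministic: visit order is ungapped length descending (ties by id
    ascending); each sequence joins the first centroid, in creation order,
    with window identity >= ``threshold_percent``, else founds a cluster.
    """
    if not 0 < threshold_percent <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold_percent}")
    if not seqs:
        return []
    order = _sort_order(seqs)
    win = encode(seqs)[:, window.slice()]
    if (win == GAP_CODE).all(axis=1).any():
        bad = next(i for i in range(len(seqs)) if (win[i] == GAP_CODE).all())
        raise ValueError(f"sequence {seqs[bad].seq_id!r} is all-gap in the window")

    centroid_rows: list[int] = []
    clusters: list[list[str]] = []
    cmat = np.empty((0, win.shape[1]), dtype=np.uint8)
    cgap = np.empty((0, win.shape[1]), dtype=bool)
    for i in order:
        row = win[i]
        row_gap = row == GAP_CODE
        if centroid_rows:
            both_gap = cgap & row_gap
            scored = (~both_gap).sum(axis=1)
            matches = ((cmat == row) & ~both_gap).sum(axis=1)
            ident = 100.0 * matches / scored
            hits = np.flatnonzero(ident >= threshold_percent - _EPS)
            if hits.size:
                clusters[int(hits[0])].append(seqs[i].seq_id)
                continue
        centroid_rows.append(i)
        clusters.append([seqs[i].seq_id])
        cmat = np.vstack([cmat, row[None, :]])
        cgap = np.vstack([cgap, row_gap[None, :]])
    return clusters


def greedy_cluster_reference(
    seqs: list[AlignedSequence],
    threshold_percent: float,
    window: InternalWindow,
) -> list[list[str]]:
    """Naive re-statement of the greedy scan rule, for cross-checking.

    Implements the definition directly with scalar pairwise identities and
    no vectorisation; used as an independent oracle in tests.
    """
    order = _sort_order(list(seqs))
    centroids: list[AlignedSequence] = []
    clusters: list[list[str]] = []
    for i in order:
        s = seqs[i]
        placed = False
        for k, c in enumerate(centroids):
            if pairwise_identity(s, c, window) >= threshold_percent - _EPS:
                clusters[k].append(s.seq_id)
                placed = True
                break
        if not placed:
            centroids.append(s)
            clusters.append([s.seq_id])
    return clusters


def two_level_cluster(
    seqs: list[AlignedSequence],
    window: InternalWindow,
    t1: float = 97.0,
    t2: float = 85.0,
    singleton_unit: str = "sequence",
) -> tuple[list[Otu97], list[Cluster85], dict[str, str]]:
    """97% then 85% clustering with linkage and singleton removal.

    Returns ``(otus, clusters85, linkage)`` where ``linkage`` maps each
    placed OTU id to its 85% cluster id. 85% clusters whose total
    underlying count is 1 (``singleton_unit='sequence'``: one sequence;
    ``'otu'``: one OTU) are removed and their OTUs flagged unplaced.
    """
    if singleton_unit not in ("sequence", "otu"):
        raise ValueError("singleton_unit must be 'sequence' or 'otu'")
    by_id = {s.seq_id: s for s in seqs}
    raw97 = greedy_cluster(seqs, t1, window)
    otus = [
        Otu97(
            otu_id=f"otu97_{k:05d}",
            centroid_id=members[0],
            member_ids=list(members),
            contains_genome=any(by_id[m].source == "genome" for m in members),
        )
        for k, members in enumerate(raw97)
    ]
    otu_by_centroid = {o.centroid_id: o for o in otus}
    centroid_seqs = [by_id[o.centroid_id] for o in otus]
    raw85 = greedy_cluster(centroid_seqs, t2, window)

    clusters: list[Cluster85] = []
    linkage: dict[str, str] = {}
    k = 0
    for members in raw85:
        member_otus = [otu_by_centroid[cid] for cid in members]
        n_under = (
            sum(len(o.member_ids) for o in member_otus)
            if singleton_unit == "sequence"
            else len(member_otus)
        )
        if n_under <= 1:
            for o in member_otus:
                o.unplaced = True
            continue
        cl = Cluster85(
            cluster_id=f"cl85_{k:04d}",
            centroid_otu_id=member_otus[0].otu_id,
            member_otu_ids=[o.otu_id for o in member_otus],
        )
        clusters.append(cl)
        for o in member_otus:
            linkage[o.otu_id] = cl.cluster_id
        k += 1
    return otus, clusters, linkage


def categorize_novelty(
    otus: list[Otu97],
    seqs: list[AlignedSequence],
    reference_seqs: list[AlignedSequence],
    window: InternalWindow,
    t1: float = 97.0,
    match_by: str = "representative",
) -> dict:
    """Assign a novelty category to every OTU via joint re-clustering.

    ``match_by='representative'`` matches an OTU to a joint cluster through
    its centroid sequence (the default); ``'any_member'`` matches through
    any member. Returns a summary dict with per-category counts and the
    number of reference-only joint clusters discarded.
    """
    if match_by not in ("representative", "any_member"):
        raise ValueError("match_by must be 'representative' or 'any_member'")
    if reference_seqs and seqs and len(reference_seqs[0]) != len(seqs[0]):
        raise ValueError("reference sequences are not in the pipeline's coordinates")
    ref_ids = {s.seq_id for s in reference_seqs}
    overlap = ref_ids & {s.seq_id for s in seqs}
    if overlap:
        raise ValueError(f"reference ids collide with pipeline ids: {sorted(overlap)[:3]}")

    joint = greedy_cluster(list(seqs) + list(reference_seqs), t1, window)
    joint_of: dict[str, int] = {}
    for k, members in enumerate(joint):
        for m in members:
            joint_of[m] = k
    has_ref = [any(m in ref_ids for m in members) for members in joint]
    ref_only = sum(1 for members in joint if all(m in ref_ids for m in members))

    for otu in otus:
        if otu.contains_genome:
            otu.novelty = "genome_backed"
            continue
        if match_by == "representative":
            matched = has_ref[joint_of[otu.centroid_id]]
        else:
            matched = any(has_ref[joint_of[m]] for m in otu.member_ids)
        otu.novelty = "mg_and_silva" if matched else "mg_only"

    counts = {c: sum(1 for o in otus if o.novelty == c) for c in NOVELTY_CATEGORIES}
    counts["reference_only_joint_clusters"] = ref_only
    return counts
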