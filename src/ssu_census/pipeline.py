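"""End-to-end census pipeline.

Chains every stage on in-memory sequences: quality control, two-level
clustering, novelty categorisation against the reference-database split,
chimera screening of 85%-cluster representatives against genome-derived
sequences, bootstrap NJ phylogeny with rogue-taxon removal, monophyly
phylum assignment, and the census tables. Each stage is also available
separately; this module only wires them together and collects results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from skbio import TreeNode

from . import census, chimera, clustering, phylogeny, qc
from .clustering import Cluster85, Otu97
from .qc import InternalWindow
from .seqio import AlignedSequence


@dataclass
class PipelineParams:
    min_bases: int = 1200
    window_width: int = 900
    window_start: int | None = None
    max_gaps: int = 40
    t1: float = 97.0
    t2: float = 85.0
    singleton_unit: str = "sequence"
    chimera_d_min: float = 2.0
    chimera_s_min: float = 90.0
    chimera_stride: int = 10
    n_bootstrap: int = 50
    bootstrap_seed: int = 0
    rogue_stop: int = 5
    rogue_max_rounds: int = 10
    rogue_min_support_gain: float = 0.5
    support_min: float = 50.0
    #: which representatives become tree leaves: one per 85% cluster
    #: (coarse, order-level) or one per 97% OTU (fine; needed for
    #: per-OTU phylum assignment when there are few clusters)
    tree_leaves: str = "cluster85"
    min_known_otus_for_pd: int = 5
    drop_environments: tuple = ()
    primers: tuple = census.EMP_PRIMERS


@dataclass
class CensusResult:
    """Everything the pipeline computed, stage by stage."""

    window: InternalWindow
    qc_log: dict
    otus: list[Otu97]
    clusters: list[Cluster85]
    linkage: dict[str, str]
    novelty_counts: dict
    chimera_verdicts: list
    chimeric_ids: set[str]
    tree: TreeNode | None
    rogue_log: list[dict]
    dropped_rogues: set[str]
    phylum_of_leaf: dict[str, str | None]
    phylum_of_otu: dict[str, str | None]
    richness: pd.DataFrame
    environment: pd.DataFrame
    primer_report: pd.DataFrame
    pd_table: pd.DataFrame

    def write_tables(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.richness.to_csv(directory / "richness.tsv", sep="\t", index=False)
        self.environment.to_csv(directory / "environment_tally.tsv", sep="\t")
        self.primer_report.to_csv(directory / "primer_report.tsv", sep="\t", index=False)
        self.pd_table.to_csv(directory / "pd_increase.tsv", sep="\t", index=False)
        membership = pd.DataFrame(
            [
                {
                    "seq_id": m,
                    "otu_id": o.otu_id,
                    "is_centroid": m == o.centroid_id,
                    "cluster_id": self.linkage.get(o.otu_id, ""),
                    "novelty": o.novelty or "",
                }
                for o in self.otus
                for m in o.member_ids
            ]
        )
        membership.to_csv(directory / "otu_membership.tsv", sep="\t", index=False)
        if self.tree is not None:
            self.tree.write(str(directory / "tree.nwk"))


def run_pipeline(
    seqs: Sequence[AlignedSequence],
    params: PipelineParams | None = None,
    phylum_labels: Mapping[str, str] | None = None,
    outgroup: Sequence[AlignedSequence] = (),
) -> CensusResult:
    """Run the full census on aligned sequences.

    ``seqs`` carry their source category; sequences with source
    ``reference_db`` act as the amplicon reference database (used for
    novelty calls, excluded from OTU counts), and genome-derived
    sequences double as the chimera-training set. ``phylum_labels`` maps
    known sequence ids (typically genome-derived) to phylum names for the
    monophyly assignment; ``outgroup`` sequences root the tree.
    """
    params = params or PipelineParams()
    phylum_labels = dict(phylum_labels or {})

    # --- QC ---------------------------------------------------------------
    kept, window, qc_log = qc.apply_qc(
        list(seqs) + list(outgroup),
        min_bases=params.min_bases,
        width=params.window_width,
        max_gaps=params.max_gaps,
        window_start=params.window_start,
    )
    outgroup_ids = {s.seq_id for s in outgroup}
    reference = [s for s in kept if s.source == "reference_db"]
    pipeline_seqs = [
        s for s in kept if s.source != "reference_db" and s.seq_id not in outgroup_ids
    ]
    kept_outgroup = [s for s in kept if s.seq_id in outgroup_ids]

    # --- clustering and novelty ------------------------------------------
    otus, clusters, linkage = clustering.two_level_cluster(
        pipeline_seqs, window, t1=params.t1, t2=params.t2,
        singleton_unit=params.singleton_unit,
    )
    novelty_counts = clustering.categorize_novelty(
        otus, pipeline_seqs, reference, window, t1=params.t1
    )

    # --- chimera screening of the tree-leaf representatives ---------------
    by_id = {s.seq_id: s for s in pipeline_seqs}
    otus_by_id = {o.otu_id: o for o in otus}
    if params.tree_leaves == "cluster85":
        candidates = [
            by_id[otus_by_id[c.centroid_otu_id].centroid_id] for c in clusters
        ]
    elif params.tree_leaves == "otu97":
        candidates = [by_id[o.centroid_id] for o in otus if o.otu_id in linkage]
    else:
        raise ValueError("tree_leaves must be 'cluster85' or 'otu97'")
    training = [s for s in pipeline_seqs if s.source == "genome"]
    verdicts = chimera.screen_chimeras(
        candidates, training, window,
        stride=params.chimera_stride,
        d_min=params.chimera_d_min, s_min=params.chimera_s_min,
    )
    chimeric_ids = {v.query_id for v in verdicts if v.verdict == "chimeric"}

    # --- phylogeny on surviving representatives ---------------------------
    leaves = [s for s in candidates if s.seq_id not in chimeric_ids] + kept_outgroup
    tree = None
    rogue_log: list[dict] = []
    dropped: set[str] = set()
    phylum_of_leaf: dict[str, str | None] = {}
    if len(leaves) >= 5 and params.n_bootstrap >= 2:
        replicates = phylogeny.bootstrap_trees(
            leaves, window, n=params.n_bootstrap, seed=params.bootstrap_seed
        )
        survivors, rogue_log = phylogeny.find_and_drop_rogues(
            replicates,
            max_rounds=params.rogue_max_rounds,
            stop_when_fewer_than=params.rogue_stop,
            min_support_gain=params.rogue_min_support_gain,
        )
        dropped = {s.seq_id for s in leaves} - set(survivors)
        final_leaves = [s for s in leaves if s.seq_id in survivors]
        if len(final_leaves) >= 3:
            tree = phylogeny.build_nj_tree(final_leaves, window)
            og_in_tree = [s.seq_id for s in kept_outgroup if s.seq_id in survivors]
            if og_in_tree:
                tree = phylogeny.root_with_outgroup(tree, og_in_tree)
            else:  # no outgroup survived: midpoint root so phyla form clades
                tree = tree.root_at_midpoint(reset=True)
            phylogeny.annotate_support(tree, replicates)
            # a leaf inherits the phylum of its represented sequences:
            # any member of the OTU (or cluster) with a known taxonomy
            # labels the representative, if the labels agree
            rep_members: dict[str, list[str]] = {}
            if params.tree_leaves == "otu97":
                for o in otus:
                    rep_members[o.centroid_id] = o.member_ids
            else:
                for c in clusters:
                    rep = otus_by_id[c.centroid_otu_id].centroid_id
                    rep_members[rep] = [
                        m for oid in c.member_otu_ids
                        for m in otus_by_id[oid].member_ids
                    ]
            labels_on_leaves = {}
            for s in final_leaves:
                found = {
                    phylum_labels[m]
                    for m in rep_members.get(s.seq_id, [s.seq_id])
                    if m in phylum_labels
                }
                if s.seq_id in phylum_labels:
                    found.add(phylum_labels[s.seq_id])
                if len(found) == 1:
                    labels_on_leaves[s.seq_id] = next(iter(found))
            phylum_of_leaf = phylogeny.assign_phyla(
                tree, labels_on_leaves, support_min=params.support_min
            )

    # propagate leaf phyla to OTUs
    phylum_of_otu: dict[str, str | None] = {}
    if params.tree_leaves == "otu97":
        for otu in otus:
            phylum_of_otu[otu.otu_id] = phylum_of_leaf.get(otu.centroid_id)
    else:
        rep_of_cluster = {
            c.cluster_id: otus_by_id[c.centroid_otu_id].centroid_id for c in clusters
        }
        for otu in otus:
            cl = linkage.get(otu.otu_id)
            rep = rep_of_cluster.get(cl) if cl else None
            phylum_of_otu[otu.otu_id] = phylum_of_leaf.get(rep) if rep else None

    # --- census tables ----------------------------------------------------
    richness = census.richness_table(otus, clusters, phylum_of_otu)
    environment = census.environment_tally(
        otus, by_id, drop_environments=params.drop_environments
    )
    primer_report = census.primer_report_table(
        clusters, otus_by_id, by_id, primers=params.primers
    )
    pd_table = census.pd_increase_table(
        otus, phylum_of_otu, by_id, window,
        min_known_otus=params.min_known_otus_for_pd,
    )

    return CensusResult(
        window=window,
        qc_log=qc_log,
        otus=otus,
        clusters=clusters,
        linkage=linkage,
        novelty_counts=novelty_counts,
        chimera_verdicts=verdicts,
        chimeric_ids=chimeric_ids,
        tree=tree,
        rogue_log=rogue_log,
        dropped_rogues=dropped,
        phylum_of_leaf=phylum_of_leaf,
        phylum_of_otu=phylum_of_otu,
        richness=richness,
        environment=environment,
        primer_report=primer_report,
        pd_table=pd_table,
    )
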