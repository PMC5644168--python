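"""Census statistics: diversity, richness, environments, primer coverage.

Four reporting stages close the pipeline:

* **Phylogenetic diversity (PD)** — Faith-style: the sum of all branch
  lengths of a tree. Per phylum, PD of the tree built from previously
  known OTU representatives is compared with PD of the tree from all
  representatives; the increase is ``100 * (pd_all - pd_known) / pd_known``.
* **Taxonomic richness** — per-phylum counts of 97% OTUs (total and by
  novelty category) and of 85% clusters.
* **Environment tally** — each OTU contributes at most one count to every
  environment in which at least one of its members was observed,
  preventing deeply sampled habitats from inflating the tally.
* **Primer mismatch prediction** — an in-silico PCR check of each 85%
  cluster against a primer pair (e.g. the Earth Microbiome Project
  515f/806r set). Each member sequence is scored with a 3'-weighted
  mismatch score at the primer's best binding site; a cluster whose mean
  score exceeds 1 for either primer is predicted to be missed by amplicon
  surveys using that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .clustering import NOVELTY_CATEGORIES, Cluster85, Otu97
from .phylogeny import build_nj_tree
from .qc import InternalWindow
from .seqio import AlignedSequence

# ---------------------------------------------------------------------------
# phylogenetic diversity

def phylogenetic_diversity(tree: TreeNode) -> float:
    """Sum of all branch lengths (pendant and internal) of a tree."""
    total = 0.0
    for node in tree.postorder(include_self=False):
        if node.length is None:
            raise ValueError(f"node {node.name!r} has no branch length")
        total += node.length
    return total


@dataclass(frozen=True)
class PDResult:
    phylum: str
    pd_known: float
    pd_all: float

    @property
    def pd_increase_percent(self) -> float:
        return 100.0 * (self.pd_all - self.pd_known) / self.pd_known


def pd_increase(
    seqs_known: Sequence[AlignedSequence],
    seqs_all: Sequence[AlignedSequence],
    window: InternalWindow,
    phylum: str = "",
) -> PDResult:
    """PD of the known-only tree vs the all-representatives tree.

    Both trees are built independently with the NJ engine. Requires at
    least 3 sequences on each side and a strictly positive known PD.
    """
    pd_known = phylogenetic_diversity(build_nj_tree(seqs_known, window))
    pd_all = phylogenetic_diversity(build_nj_tree(seqs_all, window))
    if pd_known <= 0:
        raise ValueError(f"PD of the known tree is 0 for phylum {phylum!r}; increase undefined")
    return PDResult(phylum=phylum, pd_known=pd_known, pd_all=pd_all)


def pd_increase_table(
    otus: Sequence[Otu97],
    phylum_of_otu: Mapping[str, str | None],
    seqs_by_id: Mapping[str, AlignedSequence],
    window: InternalWindow,
    min_known_otus: int = 5,
) -> pd.DataFrame:
    """Per-phylum PD increase from novel (mg_only) OTU representatives.

    Phyla with fewer than ``min_known_otus`` OTUs that are not mg_only are
    skipped: with too few previously known lineages the baseline PD is not
    meaningful.
    """
    rows = []
    phyla = sorted({p for p in phylum_of_otu.values() if p is not None})
    for phylum in phyla:
        members = [o for o in otus if phylum_of_otu.get(o.otu_id) == phylum]
        known = [o for o in members if o.novelty != "mg_only"]
        if len(known) < min_known_otus or len(members) < 3 or len(known) < 3:
            continue
        res = pd_increase(
            [seqs_by_id[o.centroid_id] for o in known],
            [seqs_by_id[o.centroid_id] for o in members],
            window,
            phylum=phylum,
        )
        rows.append(
            {
                "phylum": phylum,
                "n_otus_known": len(known),
                "n_otus_all": len(members),
                "pd_known": res.pd_known,
                "pd_all": res.pd_all,
                "pd_increase_percent": res.pd_increase_percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phylum", "n_otus_known", "n_otus_all",
            "pd_known", "pd_all", "pd_increase_percent",
        ],
    )


# ---------------------------------------------------------------------------
# richness and environments

def richness_table(
    otus: Sequence[Otu97],
    clusters: Sequence[Cluster85],
    phylum_of_otu: Mapping[str, str | None],
) -> pd.DataFrame:
    """Per-phylum 97% OTU counts (total and by novelty) and 85% cluster counts.

    An 85% cluster is counted toward the phylum of its centroid OTU.
    Unassigned OTUs are grouped under ``unassigned``.
    """
    def key(otu_id: str) -> str:
        p = phylum_of_otu.get(otu_id)
        return p if p is not None else "unassigned"

    phyla = sorted({key(o.otu_id) for o in otus})
    rows = []
    for phylum in phyla:
        members = [o for o in otus if key(o.otu_id) == phylum]
        row = {"phylum": phylum, "n_otus_97": len(members)}
        for cat in NOVELTY_CATEGORIES:
            row[f"n_{cat}"] = sum(1 for o in members if o.novelty == cat)
        row["n_clusters_85"] = sum(
            1 for c in clusters if key(c.centroid_otu_id) == phylum
        )
        rows.append(row)
    cols = ["phylum", "n_otus_97", *(f"n_{c}" for c in NOVELTY_CATEGORIES), "n_clusters_85"]
    return pd.DataFrame(rows, columns=cols)


def environment_tally(
    otus: Sequence[Otu97],
    seqs_by_id: Mapping[str, AlignedSequence],
    drop_environments: Iterable[str] = (),
) -> pd.DataFrame:
    """Environment x novelty-category OTU counts, max one per environment.

    An OTU whose members span several environments contributes one count
    to each; repeated observations in one environment still count once.
    Empty labels tally as ``unknown``. Environments in
    ``drop_environments`` (e.g. ``engineered``) are excluded.
    """
    drop = set(drop_environments)
    counts: dict[tuple[str, str], int] = {}
    envs: set[str] = set()
    for otu in otus:
        cat = otu.novelty or "uncategorized"
        otu_envs = {
            seqs_by_id[m].environment or "unknown" for m in otu.member_ids
        } - drop
        for env in otu_envs:
            envs.add(env)
            counts[(env, cat)] = counts.get((env, cat), 0) + 1
    cats = list(NOVELTY_CATEGORIES) + (
        ["uncategorized"] if any(k[1] == "uncategorized" for k in counts) else []
    )
    table = pd.DataFrame(
        [[counts.get((env, cat), 0) for cat in cats] for env in sorted(envs)],
        index=sorted(envs),
        columns=cats,
    )
    table.index.name = "environment"
    return table


# ---------------------------------------------------------------------------
# primer mismatch scoring

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class PrimerWeights:
    """Per-event weights of the 3'-weighted mismatch score."""

    non3_mismatch: float = 0.4
    three_prime_mismatch: float = 1.0
    non3_gap: float = 1.0
    three_prime_gap: float = 3.0


@dataclass(frozen=True)
class PrimerSpec:
    """An IUPAC primer with its 3'-weighting configuration.

    The 3' window covers the last ``three_prime_window`` primer bases in
    the primer's own 5'->3' orientation; mismatches and gaps there carry
    heavier weights because they disrupt polymerase extension.
    """

    name: str
    direction: str  # forward | reverse
    iupac_sequence: str
    three_prime_window: int = 5
    weights: PrimerWeights = field(default_factory=PrimerWeights)

    def __post_init__(self) -> None:
        seq = self.iupac_sequence.upper()
        object.__setattr__(self, "iupac_sequence", seq)
        if not seq or any(c not in IUPAC for c in seq):
            raise ValueError(f"invalid IUPAC primer sequence {seq!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")

    def pattern(self) -> str:
        """Pattern matched against the plus strand of the gene."""
        if self.direction == "forward":
            return self.iupac_sequence
        return reverse_complement(self.iupac_sequence)

    def three_prime_positions(self) -> frozenset[int]:
        """1-based pattern positions belonging to the 3' window."""
        m = len(self.iupac_sequence)
        w = min(self.three_prime_window, m)
        if self.direction == "forward":
            return frozenset(range(m - w + 1, m + 1))
        # after reverse complementation the primer's 3' end is the
        # pattern's first bases
        return frozenset(range(1, w + 1))


@dataclass(frozen=True)
class PrimerHit:
    """Best binding site of a primer in one sequence."""

    primer_name: str
    score: float
    edit_distance: int
    end: int | None  # 0-based exclusive end of the site in the sequence
    mismatches_3p: int = 0
    mismatches_non3: int = 0
    gaps_3p: int = 0
    gaps_non3: int = 0


#: edit-count steps dominate weighted-score steps in the combined DP cost
_BIG = 1e7


def primer_weighted_score(sequence: str, primer: PrimerSpec) -> PrimerHit:
    """Score the primer's best binding site in an ungapped sequence.

    The site is the semi-global alignment of the primer pattern (free ends
    in the sequence) minimising unit-cost edits; among unit-cost ties the
    alignment with the smallest weighted score is taken. The weighted
    score sums, per event class, the configured weights: mismatches and
    gaps inside the 3' window count more than elsewhere. Degenerate primer
    positions match any base of their IUPAC set at zero cost.

    A sequence shorter than the primer has no valid site: infinite score.
    """
    pattern = primer.pattern()
    m, n = len(pattern), len(sequence)
    if n < m:
        return PrimerHit(primer.name, float("inf"), m, None)
    seq = sequence.upper()
    w = primer.weights
    three = primer.three_prime_positions()  # already in pattern coordinates
    is3 = [(i + 1 in three) for i in range(m)]
    sub_w = np.array([w.three_prime_mismatch if f else w.non3_mismatch for f in is3])
    gap_w = np.array([w.three_prime_gap if f else w.non3_gap for f in is3])

    seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    D = np.empty((m + 1, n + 1))
    D[0, :] = 0.0
    for i in range(1, m + 1):
        allowed = IUPAC[pattern[i - 1]]
        match = np.isin(seq_arr, np.frombuffer(allowed.encode("ascii"), dtype=np.uint8))
        sub_cost = np.where(match, 0.0, _BIG + sub_w[i - 1])
        diag = D[i - 1, :-1] + sub_cost
        up = D[i - 1, 1:] + (_BIG + gap_w[i - 1])
        row = np.minimum(diag, up)
        # within-row insertions (extra sequence bases inside the primer span)
        ins = _BIG + gap_w[i - 1]
        idx = np.arange(n + 1)
        first = D[i - 1, 0] + (_BIG + gap_w[i - 1])  # D[i,0]: pattern prefix over gaps
        row_full = np.concatenate([[first], row])
        shifted = np.minimum.accumulate(row_full - ins * idx) + ins * idx
        D[i] = np.minimum(row_full, shifted)

    j_end = int(np.argmin(D[m]))
    combined = float(D[m, j_end])
    edits = int(combined // _BIG)
    score = combined - edits * _BIG

    # traceback for the per-class event counts
    mm3 = mmn = g3 = gn = 0
    i, j = m, j_end
    while i > 0:
        allowed = IUPAC[pattern[i - 1]]
        here = D[i, j]
        if j > 0 and abs(
            here
            - (D[i - 1, j - 1] + (0.0 if seq[j - 1] in allowed else _BIG + sub_w[i - 1]))
        ) < 1e-4:
            if seq[j - 1] not in allowed:
                if is3[i - 1]:
                    mm3 += 1
                else:
                    mmn += 1
            i, j = i - 1, j - 1
        elif abs(here - (D[i - 1, j] + _BIG + gap_w[i - 1])) < 1e-4:
            if is3[i - 1]:
                g3 += 1
            else:
                gn += 1
            i -= 1
        else:  # insertion
            if is3[i - 1]:
                g3 += 1
            else:
                gn += 1
            j -= 1
    return PrimerHit(
        primer_name=primer.name,
        score=float(round(score, 6)),
        edit_distance=edits,
        end=j_end,
        mismatches_3p=mm3,
        mismatches_non3=mmn,
        gaps_3p=g3,
        gaps_non3=gn,
    )


@dataclass(frozen=True)
class ClusterPrimerReport:
    cluster_id: str
    means: dict[str, float]  # primer name -> mean score over members
    sds: dict[str, float]

    @property
    def predicted_missed(self) -> bool:
        return any(mean > 1.0 for mean in self.means.values())

    @property
    def mismatch_score(self) -> float:
        return max(self.means.values())


def cluster_primer_report(
    cluster_id: str,
    member_seqs: Sequence[str],
    primers: Sequence[PrimerSpec],
    sd: str = "population",
) -> ClusterPrimerReport:
    """Per-primer mean and SD of member scores; flags clusters missed by PCR.

    ``member_seqs`` are ungapped gene sequences of every sequence in the
    85% cluster. A cluster is predicted missed when either primer's mean
    weighted mismatch score is strictly greater than 1.
    """
    if not member_seqs:
        raise ValueError(f"cluster {cluster_id!r} has no member sequences")
    if sd not in ("population", "sample"):
        raise ValueError("sd must be 'population' or 'sample'")
    ddof = 0 if sd == "population" else 1
    means, sds = {}, {}
    for primer in primers:
        scores = np.array([primer_weighted_score(s, primer).score for s in member_seqs])
        means[primer.name] = float(scores.mean())
        sds[primer.name] = float(scores.std(ddof=ddof)) if len(scores) > ddof else 0.0
    return ClusterPrimerReport(cluster_id=cluster_id, means=means, sds=sds)


#: the Earth Microbiome Project V4 primer pair, shipped as a convenience
#: default; any primer set can be supplied via configuration
EMP_PRIMERS = (
    PrimerSpec(name="515f", direction="forward", iupac_sequence="GTGYCAGCMGCCGCGGTAA"),
    PrimerSpec(name="806r", direction="reverse", iupac_sequence="GGACTACNVGGGTWTCTAAT"),
)


def primer_report_table(
    clusters: Sequence[Cluster85],
    otus_by_id: Mapping[str, Otu97],
    seqs_by_id: Mapping[str, AlignedSequence],
    primers: Sequence[PrimerSpec] = EMP_PRIMERS,
    sd: str = "population",
) -> pd.DataFrame:
    """Primer mismatch report over all 85% clusters."""
    rows = []
    for cl in clusters:
        members = [
            seqs_by_id[m].residues.replace("-", "")
            for oid in cl.member_otu_ids
            for m in otus_by_id[oid].member_ids
        ]
        rep = cluster_primer_report(cl.cluster_id, members, primers, sd=sd)
        row = {"cluster_id": cl.cluster_id}
        for p in primers:
            row[f"{p.name}_mean"] = rep.means[p.name]
            row[f"{p.name}_sd"] = rep.sds[p.name]
        row["mismatch_score"] = rep.mismatch_score
        row["predicted_missed"] = rep.predicted_missed
        rows.append(row)
    cols = ["cluster_id"]
    for p in primers:
        cols += [f"{p.name}_mean", f"{p.name}_sd"]
    cols += ["mismatch_score", "predicted_missed"]
    return pd.DataFrame(rows, columns=cols)
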