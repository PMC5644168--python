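"""Synthetic SSU rRNA communities with known truth.

Real census inputs (thousands of metagenome-derived genes plus reference
databases) are emulated here by phylum-structured sequence families
evolved along simulated guide trees, so that every downstream stage can
be tested against planted truth:

* A global ancestor sequence is drawn uniformly over {A,C,G,T}; each
  phylum's root diverges from it by ``between_phylum_divergence``
  substitutions/site.
* Within a phylum, OTU ancestors sit at the leaves of a random
  bifurcating, ultrametric-ish guide tree whose heights are scaled so the
  mean leaf-to-leaf path equals ``2 x between_otu_divergence`` (each
  lineage diverges ``between_otu_divergence`` from the within-phylum
  MRCA on average, with a deliberately narrow spread so all pairs stay
  within the identity band the thresholds assume).
* Each OTU's member sequences diverge ``within_otu_divergence`` from the
  OTU ancestor under a Jukes–Cantor kernel (independent sites, uniform
  rates, no indels — alignment coordinates are exact by construction).

Artifacts are planted on top: chimeras (two clean parents from distinct
phyla joined at a breakpoint in the middle third of the alignment),
truncated sequences (ungapped length pushed below 1200 bases by masking
leading columns), gap-riddled sequences (45 gaps forced into the columns
shared by every 900-column window), and optionally rogue lineages evolved
straight from the global ancestor so their tree position is unstable.
Source categories and environment labels are assigned per configuration,
and a :class:`SyntheticTruth` table records everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .seqio import SOURCES, AlignedSequence

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community.

    Divergences are in substitutions/site and denote per-lineage depths:
    the expected leaf-to-leaf divergence is twice the value. They must be
    strictly ordered ``within_otu < between_otu < between_phylum``.
    Artifact fractions are proportions of the total emitted sequences.
    """

    n_phyla: int = 3
    otus_per_phylum: int = 5
    seqs_per_otu: int = 4
    match_length: int = 1534
    within_otu_divergence: float = 0.0025
    between_otu_divergence: float = 0.05
    between_phylum_divergence: float = 0.20
    chimera_fraction: float = 0.05
    truncated_fraction: float = 0.05
    gappy_fraction: float = 0.05
    source_mix: dict = field(
        default_factory=lambda: {"metagenome": 0.6, "genome": 0.2, "reference_db": 0.2}
    )
    #: fraction of OTUs whose members are all metagenome-derived —
    #: database representation is structured by lineage, not by
    #: individual sequence, and full-length gene censuses find a large
    #: share of lineages only in metagenomes
    mg_only_otu_fraction: float = 1 / 3
    environments: list = field(
        default_factory=lambda: ["soil", "freshwater", "seawater", "groundwater", "host"]
    )
    multi_environment_prob: float = 0.2
    rogue_count: int = 0
    #: relative spread of guide-tree node heights; small values keep all
    #: between-OTU distances close to the target
    height_spread: float = 0.3
    #: column range for planted chimera breakpoints; None means the middle
    #: third of a 900-column internal window anchored at the alignment
    #: start, so both parent segments are visible to the downstream screen
    chimera_breakpoint_range: tuple | None = None
    #: embed conserved primer-binding sites (the V4 515f/806r pair) into
    #: every sequence, as in real SSU genes where primer regions are
    #: conserved; a fraction of phyla get 3'-mutated forward sites so
    #: primer-miss prediction has planted truth
    embed_primer_sites: bool = True
    primer_missed_phyla_fraction: float = 1 / 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_phyla, self.otus_per_phylum, self.seqs_per_otu) < 1:
            raise ValueError("counts must be >= 1")
        fracs = (self.chimera_fraction, self.truncated_fraction, self.gappy_fraction)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("artifact fractions must lie in [0,1] and sum to <= 1")
        if not (
            0 <= self.within_otu_divergence
            < self.between_otu_divergence
            < self.between_phylum_divergence
        ):
            raise ValueError(
                "divergences must satisfy within_otu < between_otu < between_phylum"
            )
        if set(self.source_mix) - set(SOURCES) or not self.source_mix:
            raise ValueError(f"source_mix keys must be among {SOURCES}")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix proportions must sum to 1")
        if self.match_length < 900:
            raise ValueError("match_length must cover the internal window (>= 900)")


@dataclass
class SyntheticTruth:
    """Truth tables for every emitted sequence.

    ``true_otu`` is ``None`` for chimeras (they belong to no real OTU).
    Artifact flags (chimera / truncated / gappy) are mutually exclusive.
    """

    true_otu: dict[str, str | None] = field(default_factory=dict)
    true_phylum: dict[str, str | None] = field(default_factory=dict)
    chimera_info: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    truncated_ids: set[str] = field(default_factory=set)
    gappy_ids: set[str] = field(default_factory=set)
    source: dict[str, str] = field(default_factory=dict)
    environment: dict[str, str] = field(default_factory=dict)
    planted_rogue_ids: set[str] = field(default_factory=set)
    #: phyla whose forward primer site carries 3' mutations, so their
    #: clusters should be predicted missed by the primer pair
    primer_missed_phyla: set[str] = field(default_factory=set)

    @property
    def chimera_ids(self) -> set[str]:
        return set(self.chimera_info)

    def clean_ids(self) -> set[str]:
        """Sequences with no planted artifact."""
        return (
            set(self.true_otu)
            - self.chimera_ids
            - self.truncated_ids
            - self.gappy_ids
        )

    def validate(self) -> None:
        ids = set(self.true_otu)
        for name, mapping in (
            ("true_phylum", self.true_phylum),
            ("source", self.source),
            ("environment", self.environment),
        ):
            if set(mapping) != ids:
                raise AssertionError(f"truth map {name} does not cover every sequence")
        flags = [self.chimera_ids, self.truncated_ids, self.gappy_ids]
        for a in range(len(flags)):
            for b in range(a + 1, len(flags)):
                if flags[a] & flags[b]:
                    raise AssertionError("artifact flags are not mutually exclusive")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for sid in sorted(self.true_otu):
            ca, cb, bp = self.chimera_info.get(sid, ("", "", ""))
            rows.append(
                {
                    "seq_id": sid,
                    "true_otu": self.true_otu[sid] or "",
                    "true_phylum": self.true_phylum[sid] or "",
                    "source": self.source[sid],
                    "environment": self.environment[sid],
                    "is_chimera": sid in self.chimera_info,
                    "chimera_parent_a": ca,
                    "chimera_parent_b": cb,
                    "chimera_breakpoint": bp,
                    "is_truncated": sid in self.truncated_ids,
                    "is_gappy": sid in self.gappy_ids,
                    "is_rogue": sid in self.planted_rogue_ids,
                }
            )
        pd.DataFrame(rows).to_csv(directory / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# guide trees

def _random_join_tree(leaf_names: list[str], rng: np.random.Generator, spread: float):
    """Random bifurcating topology with increasing join heights in [1, 1+spread]."""
    clades = [(TreeNode(name=nm), 0.0, 1) for nm in leaf_names]  # (node, height, size)
    n_joins = len(leaf_names) - 1
    incr = rng.exponential(size=n_joins) if n_joins else np.array([])
    heights = 1.0 + spread * np.cumsum(incr) / incr.sum() if n_joins else []
    pair_height_sum = 0.0  # sum over leaf pairs of their MRCA height
    for h in heights:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        (na, ha, sa), (nb, hb, sb) = clades[i], clades[j]
        parent = TreeNode()
        na.length = h - ha
        nb.length = h - hb
        parent.extend([na, nb])
        pair_height_sum += h * sa * sb
        clades = [c for k, c in enumerate(clades) if k not in (i, j)]
        clades.append((parent, h, sa + sb))
    root, _, size = clades[0]
    n_pairs = size * (size - 1) / 2
    mean_path = 2.0 * pair_height_sum / n_pairs if n_pairs else 0.0
    return root, mean_path


def simulate_guide_trees(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, TreeNode]:
    """One random guide tree per phylum, leaves named by OTU.

    Branch lengths are scaled so the mean leaf-to-leaf path length equals
    ``2 x between_otu_divergence`` (single-leaf trees have no branches).
    """
    if config.otus_per_phylum < 1:
        raise ValueError("otus_per_phylum must be >= 1")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    trees = {}
    for p in range(config.n_phyla):
        phylum = f"phylum_{p:02d}"
        leaves = [f"{phylum}_otu_{k:03d}" for k in range(config.otus_per_phylum)]
        tree, mean_path = _random_join_tree(leaves, rng, config.height_spread)
        if mean_path > 0:
            factor = 2.0 * config.between_otu_divergence / mean_path
            for node in tree.traverse(include_self=False):
                node.length *= factor
        trees[phylum] = tree
    return trees


# ---------------------------------------------------------------------------
# sequence evolution

def _random_root(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _evolve_branch(
    seq: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes–Cantor substitution along one branch of length t subs/site."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    p_change = 0.75 * -np.expm1(-4.0 * t / 3.0)
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p_change)
    # add 1..3 mod 4: uniform over the three other bases
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size, dtype=np.uint8)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def evolve_alignment(
    root_sequence: str,
    tree: TreeNode,
    rate_per_site: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve one sequence per leaf along a guide tree (JC, no indels).

    ``rate_per_site`` multiplies branch lengths; with rate 0 every leaf
    equals the root. Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    root = np.array([codes[c] for c in root_sequence.upper()], dtype=np.uint8)
    out: dict[str, str] = {}

    def recurse(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = (child.length or 0.0) * rate_per_site
            child_seq = _evolve_branch(seq, t, rng)
            if child.is_tip():
                out[child.name] = _decode(child_seq)
            else:
                recurse(child, child_seq)

    if tree.is_tip():
        out[tree.name] = _decode(root)
    else:
        recurse(tree, root)
    return out


def make_chimera(
    parent_a: AlignedSequence, parent_b: AlignedSequence, breakpoint: int
) -> str:
    """Join parent residues: columns [0, breakpoint) from A, the rest from B."""
    if len(parent_a) != len(parent_b):
        raise ValueError("chimera parents must share alignment coordinates")
    if not 0 <= breakpoint <= len(parent_a):
        raise ValueError(f"breakpoint {breakpoint} outside [0, {len(parent_a)}]")
    return parent_a.residues[:breakpoint] + parent_b.residues[breakpoint:]


# ---------------------------------------------------------------------------
# full dataset

def _truncate(residues: str, target_bases: int) -> str:
    """Mask leading columns so only ``target_bases`` residues remain."""
    keep_from = len(residues) - target_bases
    return "-" * keep_from + residues[keep_from:]


def _gappify(residues: str, columns: np.ndarray) -> str:
    arr = list(residues)
    for c in columns:
        arr[c] = "-"
    return "".join(arr)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[AlignedSequence], SyntheticTruth, dict[str, TreeNode]]:
    """Generate the full synthetic community.

    Returns ``(sequences, truth, guide_trees)``. The base community has
    ``n_phyla x otus_per_phylum x seqs_per_otu`` clean sequences; extra
    chimeric / truncated / gappy sequences are appended so each artifact
    class makes up its configured fraction of the total, and ``rogue_count``
    isolated lineages are added. Bit-identical for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = config.match_length
    truth = SyntheticTruth()
    trees = simulate_guide_trees(config, rng)

    ancestor = _random_root(L, rng)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    seqs: list[AlignedSequence] = []
    otu_ancestors: dict[str, np.ndarray] = {}
    otu_phylum: dict[str, str] = {}
    members_of: dict[str, list[str]] = {}

    for phylum, tree in trees.items():
        phylum_root = _evolve_branch(ancestor, config.between_phylum_divergence, rng)
        leaf_seqs = evolve_alignment(_decode(phylum_root), tree, 1.0, rng)
        for otu_name, anc in leaf_seqs.items():
            otu_ancestors[otu_name] = np.array([codes[c] for c in anc], dtype=np.uint8)
            otu_phylum[otu_name] = phylum
            members_of[otu_name] = []

    env_of_otu = {
        otu: config.environments[rng.integers(len(config.environments))]
        for otu in otu_ancestors
    }

    # conserved primer-binding sites, optionally 3'-mutated per phylum
    splice = lambda residues, phylum: residues
    if config.embed_primer_sites and L >= 810:
        from .census import EMP_PRIMERS, IUPAC

        fwd_pat = EMP_PRIMERS[0].pattern()
        rev_pat = EMP_PRIMERS[1].pattern()
        concrete = lambda pat: "".join(IUPAC[c][0] for c in pat)
        fwd_base, rev_site = concrete(fwd_pat), concrete(rev_pat)
        F0, R0 = 515, 787  # approximate V4 coordinates, inside the window
        phyla = sorted(trees)
        n_missed = int(round(config.primer_missed_phyla_fraction * len(phyla)))
        missed = (
            {phyla[i] for i in rng.choice(len(phyla), size=n_missed, replace=False)}
            if n_missed
            else set()
        )
        truth.primer_missed_phyla = set(missed)
        fwd_by_phylum = {}
        for ph in phyla:
            site = list(fwd_base)
            if ph in missed:
                # three 3'-window mismatches: every member scores well
                # above the miss threshold regardless of alignment slack
                m = len(site)
                for idx in (m - 1, m - 3, m - 5):
                    bad = next(b for b in "ACGT" if b not in IUPAC[fwd_pat[idx]])
                    site[idx] = bad
            fwd_by_phylum[ph] = "".join(site)

        def splice(residues: str, phylum: str | None) -> str:
            f = fwd_by_phylum.get(phylum, fwd_base)
            return (
                residues[: F0]
                + f
                + residues[F0 + len(f) : R0]
                + rev_site
                + residues[R0 + len(rev_site) :]
            )

    all_otus = sorted(otu_ancestors)
    n_mg_only = int(round(config.mg_only_otu_fraction * len(all_otus)))
    mg_only_otus = (
        {all_otus[i] for i in rng.choice(len(all_otus), size=n_mg_only, replace=False)}
        if n_mg_only
        else set()
    )

    def draw_source(otu: str) -> str:
        if otu in mg_only_otus:
            return "metagenome"
        names = sorted(config.source_mix)
        probs = np.array([config.source_mix[n] for n in names])
        return names[rng.choice(len(names), p=probs / probs.sum())]

    def draw_environment(otu: str) -> str:
        if len(config.environments) > 1 and rng.random() < config.multi_environment_prob:
            others = [e for e in config.environments if e != env_of_otu[otu]]
            return others[rng.integers(len(others))]
        return env_of_otu[otu]

    def add_member(otu: str, sid: str) -> AlignedSequence:
        codes_arr = _evolve_branch(otu_ancestors[otu], config.within_otu_divergence, rng)
        seq = AlignedSequence(
            sid,
            splice(_decode(codes_arr), otu_phylum[otu]),
            draw_source(otu),
            draw_environment(otu),
        )
        seqs.append(seq)
        truth.true_otu[sid] = otu
        truth.true_phylum[sid] = otu_phylum[otu]
        truth.source[sid] = seq.source
        truth.environment[sid] = seq.environment
        members_of[otu].append(sid)
        return seq

    for otu in sorted(otu_ancestors):
        for s in range(config.seqs_per_otu):
            add_member(otu, f"{otu}_seq_{s:03d}")

    n_base = len(seqs)
    art_frac = config.chimera_fraction + config.truncated_fraction + config.gappy_fraction
    total = n_base / (1.0 - art_frac) if art_frac < 1 else n_base
    n_chim = int(round(config.chimera_fraction * total))
    n_trunc = int(round(config.truncated_fraction * total))
    n_gappy = int(round(config.gappy_fraction * total))

    # chimera parents are drawn from genome-source sequences when possible:
    # reference-based screening presumes the parents' lineages are present
    # in the clean training database
    genome_pool = [s for s in seqs if s.source == "genome"]
    pool_phyla = {truth.true_phylum[s.seq_id] for s in genome_pool}
    need = 2 if config.n_phyla > 1 else 1
    clean_pool = genome_pool if len(pool_phyla) >= need and len(genome_pool) >= 2 else list(seqs)

    # chimeras: parents from distinct phyla, breakpoint in the middle third
    # of the internal window
    if config.chimera_breakpoint_range is not None:
        bp_lo, bp_hi = config.chimera_breakpoint_range
    else:
        w = min(900, L)
        bp_lo, bp_hi = w // 3, 2 * w // 3
    for c in range(n_chim):
        while True:
            pa, pb = rng.choice(len(clean_pool), size=2, replace=False)
            a, b = clean_pool[pa], clean_pool[pb]
            if config.n_phyla > 1:
                if truth.true_phylum[a.seq_id] != truth.true_phylum[b.seq_id]:
                    break
            elif truth.true_otu[a.seq_id] != truth.true_otu[b.seq_id]:
                break
        bp = int(rng.integers(bp_lo, bp_hi))
        sid = f"chimera_{c:03d}"
        env = truth.environment[a.seq_id]
        seq = AlignedSequence(sid, make_chimera(a, b, bp), "metagenome", env)
        seqs.append(seq)
        truth.true_otu[sid] = None
        truth.true_phylum[sid] = None
        truth.chimera_info[sid] = (a.seq_id, b.seq_id, bp)
        truth.source[sid] = "metagenome"
        truth.environment[sid] = env

    # truncated: extra OTU members with ungapped length pushed below 1200
    otu_list = sorted(otu_ancestors)
    for t in range(n_trunc):
        otu = otu_list[int(rng.integers(len(otu_list)))]
        sid = f"truncated_{t:03d}"
        seq = add_member(otu, sid)
        target = int(rng.integers(800, 1200))
        seq.residues = _truncate(seq.residues, target)
        truth.truncated_ids.add(sid)

    # gappy: 45 gaps planted in the columns every 900-wide window contains
    lo, hi = max(0, L - 900), min(L, 900)
    common = np.arange(lo, hi)
    if common.size < 45:  # very short alignments: use the center instead
        center = L // 2
        common = np.arange(max(0, center - 30), min(L, center + 30))
    for g in range(n_gappy):
        otu = otu_list[int(rng.integers(len(otu_list)))]
        sid = f"gappy_{g:03d}"
        seq = add_member(otu, sid)
        cols = rng.choice(common, size=45, replace=False)
        seq.residues = _gappify(seq.residues, cols)
        truth.gappy_ids.add(sid)

    # rogues: isolated lineages straight from the global ancestor
    for r in range(config.rogue_count):
        sid = f"rogue_{r:02d}"
        codes_arr = _evolve_branch(ancestor, config.between_phylum_divergence, rng)
        env = config.environments[rng.integers(len(config.environments))]
        seq = AlignedSequence(sid, splice(_decode(codes_arr), None), "metagenome", env)
        seqs.append(seq)
        truth.true_otu[sid] = sid
        truth.true_phylum[sid] = None
        truth.source[sid] = "metagenome"
        truth.environment[sid] = env
        truth.planted_rogue_ids.add(sid)

    truth.validate()
    return seqs, truth, trees
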