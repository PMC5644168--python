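"""Scoring pipeline output against synthetic-community truth tables.

Used by the test-suite and the reproduction script to measure parameter
recovery: OTU-partition agreement (adjusted Rand index), chimera-screen
recall and false-positive rate, and novelty-category fractions. All
comparisons restrict themselves to sequences both sides can see — planted
artifacts removed by QC, reference-only OTUs discarded during novelty
assessment, and chimera-founded OTUs are excluded where the truth has no
corresponding unit.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from sklearn.metrics import adjusted_rand_score

from .chimera import ChimeraVerdict
from .clustering import NOVELTY_CATEGORIES, Otu97
from .synthetic import SyntheticTruth


def otu_recovery_ari(truth: SyntheticTruth, otus: Sequence[Otu97]) -> float:
    """Adjusted Rand index between recovered and true OTU partitions.

    Scored over artifact-free sequences present in the recovered
    partition.
    """
    memb = {m: o.otu_id for o in otus for m in o.member_ids}
    ids = sorted(truth.clean_ids() & set(memb))
    if not ids:
        raise ValueError("no clean sequences in the recovered partition")
    return float(
        adjusted_rand_score([truth.true_otu[i] for i in ids], [memb[i] for i in ids])
    )


def cluster85_vs_phylum_ari(
    truth: SyntheticTruth, otus: Sequence[Otu97], linkage: Mapping[str, str]
) -> float:
    """ARI between 85%-cluster membership and the planted phylum grouping."""
    memb = {m: o.otu_id for o in otus for m in o.member_ids}
    ids = sorted(
        i for i in truth.clean_ids() if i in memb and memb[i] in linkage
    )
    if not ids:
        raise ValueError("no clean sequences placed in 85% clusters")
    return float(
        adjusted_rand_score(
            [truth.true_phylum[i] for i in ids], [linkage[memb[i]] for i in ids]
        )
    )


def chimera_screen_metrics(
    truth: SyntheticTruth, verdicts: Iterable[ChimeraVerdict]
) -> dict[str, float]:
    """Recall on planted chimeras and false-positive rate on clean queries."""
    flagged = {v.query_id for v in verdicts if v.verdict == "chimeric"}
    screened = {v.query_id for v in verdicts}
    planted = truth.chimera_ids & screened
    clean = screened - truth.chimera_ids
    out = {}
    out["recall"] = len(flagged & planted) / len(planted) if planted else float("nan")
    out["fpr"] = len(flagged & clean) / len(clean) if clean else 0.0
    return out


def true_novelty_by_otu(truth: SyntheticTruth) -> dict[str, str]:
    """Expected novelty category of each true OTU from planted sources.

    Only OTUs observable by the pipeline count: at least one artifact-free
    member with source metagenome or genome (reference-only OTUs are
    discarded during novelty assessment, mirroring the exclusion of
    database-only clusters).
    """
    cats: dict[str, str] = {}
    observable: set[str] = set()
    for sid in truth.clean_ids():
        otu = truth.true_otu[sid]
        src = truth.source[sid]
        if src in ("metagenome", "genome"):
            observable.add(otu)
        cur = cats.get(otu)
        if src == "genome":
            cats[otu] = "genome_backed"
        elif src == "reference_db":
            if cur != "genome_backed":
                cats[otu] = "mg_and_silva"
        elif cur is None:
            cats[otu] = "mg_only"
    return {otu: cats[otu] for otu in observable}


def novelty_fractions(
    truth: SyntheticTruth, result
) -> tuple[dict[str, float], dict[str, float]]:
    """(true, recovered) per-category OTU fractions, on comparable units.

    Recovered fractions are computed over OTUs containing at least one
    artifact-free sequence, so chimera-founded OTUs (which have no true
    counterpart) do not dilute the comparison.
    """
    true_cat = true_novelty_by_otu(truth)
    n_true = len(true_cat)
    clean = truth.clean_ids()
    real_otus = [o for o in result.otus if any(m in clean for m in o.member_ids)]
    n_rec = len(real_otus)
    t_frac, r_frac = {}, {}
    for cat in NOVELTY_CATEGORIES:
        t_frac[cat] = sum(1 for v in true_cat.values() if v == cat) / n_true
        r_frac[cat] = sum(1 for o in real_otus if o.novelty == cat) / n_rec
    return t_frac, r_frac
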