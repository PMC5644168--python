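"""Reference-based two-parent chimera screening.

A chimeric SSU rRNA sequence is an assembly artifact joining fragments of
two distinct parent organisms. The screen here asks, for each query,
whether some two-parent model explains it markedly better than any single
reference does: candidate parents are pre-selected by shared k-mer counts,
then every breakpoint position in the internal window is scanned, scoring
the identity of a model that follows parent A left of the breakpoint and
parent B right of it. Let

    divergence = id(query, best two-parent model) - id(query, best single parent)

The verdict is ``chimeric`` when divergence >= ``d_min`` (default 2.0
percentage points) and the query matches each parent at >= ``s_min``
(default 90%) on that parent's side of the breakpoint. Identities follow
the clustering module's window rule (dual-gap columns excluded, residue
vs gap is a mismatch).

Genome-derived sequences serve as the clean training set: they cannot be
chimeric by construction of the reference-genome assembly process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qc import InternalWindow
from .seqio import GAP_CODE, AlignedSequence, encode


@dataclass
class ChimeraVerdict:
    query_id: str
    verdict: str  # chimeric | clean | no_parents
    best_parents: tuple[str, str] | None = None
    breakpoint: int | None = None
    id_to_model: float | None = None
    id_to_best_single: float | None = None

    @property
    def divergence(self) -> float | None:
        if self.id_to_model is None or self.id_to_best_single is None:
            return None
        return self.id_to_model - self.id_to_best_single


def _ungapped_window(seq: AlignedSequence, window: InternalWindow) -> str:
    return seq.residues[window.slice()].replace("-", "")


def candidate_parents(
    query: AlignedSequence,
    reference_db: list[AlignedSequence],
    window: InternalWindow,
    k: int = 8,
    top: int = 4,
) -> list[str]:
    """Rank references by shared k-mer count with the query; return top ids.

    Counts distinct shared k-mers of the ungapped window sequences; ties
    are broken by ascending reference id.
    """
    if not reference_db:
        return []
    q = _ungapped_window(query, window)
    qmers = {q[i : i + k] for i in range(len(q) - k + 1)}
    scored = []
    for ref in reference_db:
        r = _ungapped_window(ref, window)
        rmers = {r[i : i + k] for i in range(len(r) - k + 1)}
        scored.append((-len(qmers & rmers), ref.seq_id))
    scored.sort()
    return [sid for _, sid in scored[:top]]


def _match_scored(q: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (match, scored) indicators under the window identity rule."""
    both_gap = (q == GAP_CODE) & (p == GAP_CODE)
    scored = ~both_gap
    match = (q == p) & scored
    return match, scored


def chimera_score(
    query: AlignedSequence,
    parent_a: AlignedSequence,
    parent_b: AlignedSequence,
    window: InternalWindow,
    stride: int = 10,
    d_min: float = 2.0,
    s_min: float = 90.0,
) -> ChimeraVerdict:
    """Score a two-parent chimera model for one ordered candidate pair.

    Scans breakpoints ``b`` across the window (every ``stride`` columns,
    both parent orders); the model takes parent A on columns < b and
    parent B on columns >= b. Returns the best model found and the verdict
    for this pair.
    """
    if parent_a.seq_id == parent_b.seq_id:
        raise ValueError("chimera parents must be distinct")
    enc = encode([query, parent_a, parent_b])[:, window.slice()]
    q, pa, pb = enc
    ma, sa = _match_scored(q, pa)
    mb, sb = _match_scored(q, pb)
    # prefix sums: left-of-b counts are cum[:b], right-of-b are total - cum[:b]
    cma, csa = np.cumsum(ma), np.cumsum(sa)
    cmb, csb = np.cumsum(mb), np.cumsum(sb)
    W = window.width
    tot_ma, tot_sa, tot_mb, tot_sb = cma[-1], csa[-1], cmb[-1], csb[-1]
    if tot_sa == 0 or tot_sb == 0:
        return ChimeraVerdict(query.seq_id, "no_parents")
    id_a = 100.0 * tot_ma / tot_sa
    id_b = 100.0 * tot_mb / tot_sb
    best_single = max(id_a, id_b)

    interior = list(range(stride, W, stride))
    if not interior:
        return ChimeraVerdict(query.seq_id, "no_parents")
    # 0 and W are the degenerate pure-parent models; including them
    # guarantees id_to_model >= id_to_best_single (divergence >= 0)
    breakpoints = [0] + interior + [W]

    best = None  # (id_model, side_left, side_right, b, first_parent_is_a)
    for first_a in (True, False):
        mleft, sleft = (cma, csa) if first_a else (cmb, csb)
        mright_tot, sright_tot = (tot_mb, tot_sb) if first_a else (tot_ma, tot_sa)
        mright_cum, sright_cum = (cmb, csb) if first_a else (cma, csa)
        for b in breakpoints:
            ml = mleft[b - 1] if b > 0 else 0
            sl = sleft[b - 1] if b > 0 else 0
            mr = mright_tot - (mright_cum[b - 1] if b > 0 else 0)
            sr = sright_tot - (sright_cum[b - 1] if b > 0 else 0)
            if sl + sr == 0:
                continue
            id_model = 100.0 * (ml + mr) / (sl + sr)
            # a side with no scored columns imposes no constraint; report
            # the model identity itself for it
            side_l = 100.0 * ml / sl if sl else id_model
            side_r = 100.0 * mr / sr if sr else id_model
            key = (id_model, side_l, side_r, b, first_a)
            if best is None or key[0] > best[0]:
                best = key
    if best is None:
        return ChimeraVerdict(query.seq_id, "no_parents")
    id_model, side_l, side_r, b, first_a = best
    parents = (
        (parent_a.seq_id, parent_b.seq_id) if first_a else (parent_b.seq_id, parent_a.seq_id)
    )
    divergence = id_model - best_single
    chimeric = divergence >= d_min and side_l >= s_min and side_r >= s_min
    return ChimeraVerdict(
        query_id=query.seq_id,
        verdict="chimeric" if chimeric else "clean",
        best_parents=parents,
        breakpoint=window.start + b,
        id_to_model=id_model,
        id_to_best_single=best_single,
    )


def screen_chimeras(
    queries: list[AlignedSequence],
    reference_db: list[AlignedSequence],
    window: InternalWindow,
    k: int = 8,
    top: int = 4,
    stride: int = 10,
    d_min: float = 2.0,
    s_min: float = 90.0,
) -> list[ChimeraVerdict]:
    """Screen every query against two-parent models from the reference set.

    For each query, the ``top`` k-mer-ranked references are considered
    pairwise; the pair whose best model has the highest identity decides
    the verdict. Queries present in the reference set are matched against
    themselves as a single parent (divergence 0 -> clean), so a self-screen
    of the reference set yields no flags.
    """
    by_id = {r.seq_id: r for r in reference_db}
    # a chimera matches its two parents on opposite sides of the window, so
    # global k-mer ranking can be dominated by one side; also ranking each
    # half guarantees both segments are represented among the candidates
    half = window.width // 2
    left = InternalWindow(window.start, half)
    right = InternalWindow(window.start + half, window.width - half)
    out = []
    for q in queries:
        full = candidate_parents(q, reference_db, window, k=k, top=top)
        seen = set(full)
        cand = list(full)
        for sub in (left, right):
            for sid in candidate_parents(q, reference_db, sub, k=k, top=max(2, top // 2)):
                if sid not in seen:
                    seen.add(sid)
                    cand.append(sid)
        if len(cand) < 2:
            out.append(ChimeraVerdict(q.seq_id, "no_parents"))
            continue
        best: ChimeraVerdict | None = None
        for i in range(len(cand)):
            for j in range(i + 1, len(cand)):
                v = chimera_score(
                    q, by_id[cand[i]], by_id[cand[j]], window,
                    stride=stride, d_min=d_min, s_min=s_min,
                )
                if v.id_to_model is None:
                    continue
                if best is None or v.id_to_model > best.id_to_model:
                    best = v
        out.append(best if best is not None else ChimeraVerdict(q.seq_id, "no_parents"))
    return out


def summarize_verdicts(verdicts: list[ChimeraVerdict]) -> dict[str, int]:
    counts = {"chimeric": 0, "clean": 0, "no_parents": 0}
    for v in verdicts:
        counts[v.verdict] += 1
    return counts
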