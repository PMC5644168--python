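"""Quality filters for aligned SSU rRNA genes.

Two filters, both with strict, hand-checkable boundaries:

* a length filter keeping sequences of at least ``min_bases`` ungapped
  bases (default 1200), and
* a gap filter keeping sequences with at most ``max_gaps`` gap characters
  (default 40) inside an internal window of the alignment.

The internal window (default 900 columns) is the contiguous stretch that is
well covered by every sequence; restricting clustering to it avoids
artifacts from ragged terminal gaps. "Well covered by all sequences" is
operationalised as the window maximising the minimum per-sequence non-gap
count, with ties broken toward the smallest start column; a fixed start may
be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import GAP_CODE, AlignedSequence, encode


@dataclass(frozen=True)
class InternalWindow:
    """A contiguous column window ``[start, start + width)``, 0-based."""

    start: int
    width: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.width <= 0:
            raise ValueError(f"invalid window [{self.start}, +{self.width})")

    @property
    def stop(self) -> int:
        return self.start + self.width

    def slice(self) -> slice:
        return slice(self.start, self.stop)


def filter_by_length(
    seqs: Sequence[AlignedSequence], min_bases: int = 1200
) -> tuple[list[AlignedSequence], list[AlignedSequence]]:
    """Split into (kept, discarded) by ungapped length >= ``min_bases``.

    The threshold is on gene length in bases, not alignment columns; a
    1199-base sequence is discarded, a 1200-base sequence kept.
    """
    kept = [s for s in seqs if s.ungapped_length >= min_bases]
    discarded = [s for s in seqs if s.ungapped_length < min_bases]
    return kept, discarded


def select_internal_window(
    seqs: Sequence[AlignedSequence],
    width: int = 900,
    start: int | None = None,
) -> InternalWindow:
    """Choose the internal clustering window.

    With ``start`` given, returns exactly ``[start, start + width)``.
    Otherwise scans all contiguous windows of ``width`` columns and returns
    the one maximising the minimum per-sequence non-gap count (smallest
    start wins ties).
    """
    if not seqs:
        raise ValueError("cannot select a window from an empty alignment")
    length = len(seqs[0])
    if length < width:
        raise ValueError(f"alignment length {length} shorter than window width {width}")
    if start is not None:
        if start + width > length:
            raise ValueError(f"window [{start}, +{width}) exceeds alignment length {length}")
        return InternalWindow(start, width)

    nongap = (encode(seqs) != GAP_CODE).astype(np.int64)
    # cumulative sums -> non-gap count in every candidate window, per sequence
    csum = np.concatenate(
        [np.zeros((len(seqs), 1), dtype=np.int64), np.cumsum(nongap, axis=1)], axis=1
    )
    starts = np.arange(length - width + 1)
    counts = csum[:, starts + width] - csum[:, starts]  # (n, n_windows)
    min_cov = counts.min(axis=0)
    best = int(np.argmax(min_cov))  # argmax returns the first (smallest) start on ties
    return InternalWindow(best, width)


def filter_by_gaps(
    seqs: Sequence[AlignedSequence],
    window: InternalWindow,
    max_gaps: int = 40,
) -> tuple[list[AlignedSequence], list[AlignedSequence]]:
    """Split into (kept, discarded) by gap count within ``window``.

    Strict rule: more than ``max_gaps`` gaps inside the window discards
    the sequence; exactly ``max_gaps`` is kept. All gap characters falling
    in the window are counted.
    """
    if seqs and window.stop > len(seqs[0]):
        raise ValueError("window exceeds alignment length")
    kept, discarded = [], []
    for s in seqs:
        n_gaps = s.residues.count("-", window.start, window.stop)
        (kept if n_gaps <= max_gaps else discarded).append(s)
    return kept, discarded


def apply_qc(
    seqs: Sequence[AlignedSequence],
    min_bases: int = 1200,
    width: int = 900,
    max_gaps: int = 40,
    window_start: int | None = None,
) -> tuple[list[AlignedSequence], InternalWindow, dict]:
    """Run both filters and window selection; returns (kept, window, log).

    The window is selected after the length filter so truncated sequences
    do not drag it toward the alignment interior they happen to retain.
    """
    long_enough, too_short = filter_by_length(seqs, min_bases)
    if not long_enough:
        raise ValueError("no sequences pass the length filter")
    window = select_internal_window(long_enough, width=width, start=window_start)
    kept, gappy = filter_by_gaps(long_enough, window, max_gaps)
    log = {
        "n_input": len(seqs),
        "n_too_short": len(too_short),
        "n_too_gappy": len(gappy),
        "n_kept": len(kept),
        "too_short_ids": [(s.seq_id, s.ungapped_length) for s in too_short],
        "too_gappy_ids": [s.seq_id for s in gappy],
        "window_start": window.start,
        "window_width": window.width,
    }
    return kept, window, log
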