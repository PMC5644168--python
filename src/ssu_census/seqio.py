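"""Aligned-sequence records and file IO.

Sequences live in fixed alignment coordinates: every record in a dataset has
the same residue-string length, over the alphabet ``{A, C, G, T, -}``.
Lower-case residues and ``.`` gap characters are normalised on read, so a
write/read round trip is the identity on normalised records.

Metadata (source category and environment label) is carried per sequence and
merged from a tab-separated table with columns ``seq_id``, ``source``,
``environment``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SOURCES = ("metagenome", "genome", "reference_db")

GAP = "-"
_ALPHABET = frozenset("ACGT-")

#: byte codes used in the packed residue matrix
_CODE = {c: i for i, c in enumerate("ACGT-")}
GAP_CODE = _CODE[GAP]


class AlignmentFormatError(ValueError):
    """Raised for malformed alignments (ragged records, duplicate ids)."""


@dataclass
class AlignedSequence:
    """One SSU rRNA gene sequence in fixed alignment coordinates.

    Parameters
    ----------
    seq_id : str
        Unique identifier.
    residues : str
        Aligned residues over ``{A, C, G, T, -}``; normalised on
        construction (upper-cased, ``.`` mapped to ``-``).
    source : str
        One of ``metagenome``, ``genome``, ``reference_db``.
    environment : str
        Free-text environment label; empty string when unknown.
    """

    seq_id: str
    residues: str
    source: str = "metagenome"
    environment: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace(".", GAP)
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise AlignmentFormatError(
                f"sequence {self.seq_id!r} contains non-ACGT- characters: {sorted(bad)}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r} for {self.seq_id!r}")

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap residues (gene length in bases)."""
        return len(self.residues) - self.residues.count(GAP)

    def __len__(self) -> int:
        return len(self.residues)


def encode(seqs: Sequence[AlignedSequence]) -> np.ndarray:
    """Pack sequences into a ``(n, L)`` uint8 matrix (A,C,G,T,- -> 0..4)."""
    if not seqs:
        return np.zeros((0, 0), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    mat = np.empty((len(seqs), len(seqs[0])), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i] = lut[np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8)]
    return mat


def _check_rectangular(seqs: Iterable[AlignedSequence]) -> None:
    length = None
    for s in seqs:
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise AlignmentFormatError(
                f"record {s.seq_id!r} has length {len(s)}, expected {length}"
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a seq_id/source/environment TSV into a DataFrame indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"seq_id", "source", "environment"}
    missing = required - set(df.columns)
    if missing:
        raise AlignmentFormatError(f"metadata missing columns: {sorted(missing)}")
    if df["seq_id"].duplicated().any():
        dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise AlignmentFormatError(f"duplicate seq_id in metadata: {dup!r}")
    return df.set_index("seq_id")


def read_alignment(
    path: str | Path, metadata_path: str | Path | None = None
) -> list[AlignedSequence]:
    """Read an aligned FASTA (plus optional metadata TSV) into records.

    Records missing from the metadata default to ``source='metagenome'``
    and an empty environment, with a logged warning.
    """
    meta = read_metadata(metadata_path) if metadata_path is not None else None
    seqs: list[AlignedSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AlignmentFormatError(f"duplicate seq_id in alignment: {rec.id!r}")
        seen.add(rec.id)
        source, environment = "metagenome", ""
        if meta is not None:
            if rec.id in meta.index:
                source = meta.at[rec.id, "source"]
                environment = meta.at[rec.id, "environment"]
            else:
                logger.warning(
                    "no metadata for %s; defaulting to source=metagenome", rec.id
                )
        seqs.append(AlignedSequence(rec.id, str(rec.seq), source, environment))
    _check_rectangular(seqs)
    return seqs


def write_alignment(seqs: Sequence[AlignedSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.seq_id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def write_metadata(seqs: Sequence[AlignedSequence], path: str | Path) -> None:
    pd.DataFrame(
        {
            "seq_id": [s.seq_id for s in seqs],
            "source": [s.source for s in seqs],
            "environment": [s.environment for s in seqs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_stockholm(path: str | Path) -> tuple[list[AlignedSequence], np.ndarray]:
    """Read a Stockholm alignment and derive the match-column mask.

    The mask marks consensus (match) columns of the covariance model,
    taken from the ``#=GC RF`` reference-annotation line: columns where
    the annotation is not ``.`` (or ``~``) are match columns.
    """
    aln = AlignIO.read(str(path), "stockholm")
    rf = aln.column_annotations.get("reference_annotation")
    if rf is None:
        raise AlignmentFormatError("Stockholm file lacks a #=GC RF line")
    mask = np.array([c not in ".~" for c in rf], dtype=bool)
    seqs = [AlignedSequence(rec.id, str(rec.seq)) for rec in aln]
    _check_rectangular(seqs)
    return seqs, mask


def drop_insert_columns(
    seqs: Sequence[AlignedSequence], match_mask: np.ndarray
) -> list[AlignedSequence]:
    """Project an alignment onto its match columns.

    Emulates the match-only projection of a covariance-model alignment:
    only columns with ``match_mask`` true are retained, order preserved.
    """
    match_mask = np.asarray(match_mask, dtype=bool)
    if seqs and match_mask.shape[0] != len(seqs[0]):
        raise ValueError(
            f"mask length {match_mask.shape[0]} != alignment length {len(seqs[0])}"
        )
    keep = np.flatnonzero(match_mask)
    out = []
    for s in seqs:
        arr = np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8)
        out.append(
            AlignedSequence(
                s.seq_id, arr[keep].tobytes().decode("ascii"), s.source, s.environment
            )
        )
    return out


def run_cmalign(*args, **kwargs):  # pragma: no cover - untested glue
    """Adapter slot for an external covariance-model aligner.

    Building the covariance-model alignment itself is delegated to external
    tooling (Infernal's cmsearch/cmalign); this package consumes the aligned
    result. The hook exists so a pipeline driver can shell out if such a
    tool is installed; it is deliberately logic-free.
    """
    raise NotImplementedError(
        "external covariance-model alignment is not bundled; "
        "provide a pre-aligned FASTA or Stockholm file"
    )
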