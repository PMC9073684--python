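"""In-frame codon alignments of TE copies and their metadata.

The unit of analysis is a multiple sequence alignment of the coding
sequence of all intact copies of one TE family from a single genome,
aligned at the amino-acid level so that every gap is a whole number of
codons and the reading frame is preserved in every column.

`CodonAlignment` stores the alignment as a compact (n_sequences,
n_codon_columns) uint8 matrix of packed codon codes, which keeps scans of
large simulated families cheap, while exposing sequences as codon strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codes import (
    CODE_TO_CODON,
    GAP_CODE,
    GAP_CODON,
    codon_to_code,
    decode_codon_row,
)

__all__ = [
    "CodonAlignment",
    "AlignmentError",
    "FrameError",
    "read_codon_alignment",
    "write_codon_alignment",
    "make_table1_fixture",
    "read_metadata",
    "write_metadata",
]

GENE_LABELS = (
    "gag",
    "protease",
    "integrase",
    "reverse_transcriptase",
    "ribonuclease",
    "combined",
)


class AlignmentError(ValueError):
    """Malformed alignment (lengths, alphabet, duplicate ids...)."""


class FrameError(AlignmentError):
    """Records whose gap runs break the codon reading frame."""

    def __init__(self, offending_ids):
        self.offending_ids = list(offending_ids)
        super().__init__(
            "frame-breaking gap runs (length not a multiple of 3) in: "
            + ", ".join(self.offending_ids)
        )


class CodonAlignment:
    """An in-frame codon MSA of TE copies.

    Parameters
    ----------
    sequences : iterable of (id, codons)
        ``codons`` is a list of 3-mer strings over {A,C,G,T,-}; a gap codon
        is exactly ``"---"``.
    family, gene : str, optional
        Labels carried through to curves and result tables.
    strict : bool
        With the default True, a codon containing a gap character but not
        equal to ``"---"`` marks the record as frame-breaking and the whole
        construction fails with `FrameError` naming the offenders. With
        False such codons are treated as a gap at that column only.

    Notes
    -----
    Internally 0-based column indices are used; every reported position is a
    1-based codon-column index.
    """

    def __init__(self, sequences: Iterable[tuple[str, list[str]]],
                 family: str = "", gene: str = "combined",
                 strict: bool = True):
        ids, rows = [], []
        bad_frame = []
        for seq_id, codons in sequences:
            row = np.empty(len(codons), dtype=np.uint8)
            for j, codon in enumerate(codons):
                if codon == GAP_CODON:
                    row[j] = GAP_CODE
                elif "-" in codon:
                    bad_frame.append(seq_id)
                    row[j] = GAP_CODE
                else:
                    row[j] = codon_to_code(codon)
            ids.append(seq_id)
            rows.append(row)
        if bad_frame and strict:
            raise FrameError(sorted(set(bad_frame)))
        if len(rows) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            offenders = [i for i, r in zip(ids, rows)
                         if len(r) != len(rows[0])]
            raise AlignmentError(
                f"unequal codon-column counts; offending ids: {offenders}"
            )
        self._finish_init(ids, np.vstack(rows), family, gene)

    def _finish_init(self, ids, codes, family, gene):
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        self.ids: list[str] = list(ids)
        self.codes: np.ndarray = codes
        self.family = family
        self.gene = gene

    @classmethod
    def from_codes(cls, ids: list[str], codes: np.ndarray,
                   family: str = "", gene: str = "combined") -> "CodonAlignment":
        """Build directly from a packed (n, L) uint8 codon-code matrix."""
        codes = np.ascontiguousarray(codes, dtype=np.uint8)
        if codes.ndim != 2 or codes.shape[0] < 2:
            raise AlignmentError("codes must be a 2-D matrix with >= 2 rows")
        obj = cls.__new__(cls)
        obj._finish_init(list(ids), codes, family, gene)
        return obj

    # -- container protocol ------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_codon_columns(self) -> int:
        return self.codes.shape[1]

    @property
    def sequences(self) -> list[tuple[str, list[str]]]:
        """Sequences as (id, list of codon strings); materialized on demand."""
        return [(i, decode_codon_row(row)) for i, row in zip(self.ids, self.codes)]

    def column(self, index: int) -> list[str]:
        """Codon strings of one column (0-based index)."""
        return [CODE_TO_CODON[c] for c in self.codes[:, index]]

    def iter_columns(self) -> Iterator[list[str]]:
        for j in range(self.n_codon_columns):
            yield self.column(j)

    def __eq__(self, other):
        return (
            isinstance(other, CodonAlignment)
            and self.ids == other.ids
            and self.codes.shape == other.codes.shape
            and bool(np.all(self.codes == other.codes))
        )

    def __repr__(self):
        return (f"CodonAlignment(n_sequences={self.n_sequences}, "
                f"n_codon_columns={self.n_codon_columns}, "
                f"family={self.family!r}, gene={self.gene!r})")


def read_codon_alignment(path, frame_offset: int = 0,
                         family: str = "", gene: str = "combined") -> CodonAlignment:
    """Read an in-frame codon alignment from aligned FASTA.

    Parameters
    ----------
    path : path-like
        FASTA of equal-length aligned nucleotide records.
    frame_offset : int
        Number of leading nucleotide columns to drop before cutting codons;
        the remaining length must be divisible by 3.

    Raises
    ------
    AlignmentError
        On unequal record lengths, non-ACGT- characters, fewer than two
        records, or a length not compatible with the frame.
    FrameError
        If any record contains a gap run that is not a multiple of 3,
        i.e. a frameshifted copy; ids are reported.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: fewer than 2 records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        ref = len(records[0].seq)
        offenders = [r.id for r in records if len(r.seq) != ref]
        raise AlignmentError(f"{path}: unequal lengths; offending ids: {offenders}")
    length = lengths.pop()
    if (length - frame_offset) % 3 != 0:
        raise AlignmentError(
            f"{path}: length {length} minus frame offset {frame_offset} "
            "is not divisible by 3"
        )
    seqs = []
    for r in records:
        s = str(r.seq).upper()[frame_offset:]
        bad = set(s) - set("ACGT-")
        if bad:
            raise AlignmentError(
                f"{path}: record {r.id} contains non-ACGT- characters {sorted(bad)}"
            )
        seqs.append((r.id, [s[i:i + 3] for i in range(0, len(s), 3)]))
    return CodonAlignment(seqs, family=family, gene=gene)


def write_codon_alignment(aln: CodonAlignment, path, description: str = "") -> None:
    """Write the alignment as FASTA wrapped at 60 characters.

    ``description`` (e.g. a simulation seed) is stamped on every header.
    """
    records = [
        SeqRecord(Seq("".join(codons)), id=seq_id, description=description)
        for seq_id, codons in aln.sequences
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# -- Element metadata ------------------------------------------------------

@dataclass(frozen=True)
class ElementMetadata:
    element_id: str
    family: str
    species: str
    gene: str = "combined"


def read_metadata(path) -> pd.DataFrame:
    """Read the element metadata table (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"element_id", "family", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["element_id"].duplicated().any():
        dupes = df.loc[df["element_id"].duplicated(), "element_id"].tolist()
        raise ValueError(f"{path}: duplicate element ids {dupes}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- Worked toy alignment --------------------------------------------------

_TOY_EXPLICIT = {
    1: ["TTT", "TTT", "TTT", "TTT", "TTT"],
    2: ["TTT", "TTT", "TTC", "TTC", "TTC"],
    3: ["TTC", "CTT", "CTT", "AGA", "CTT"],
    10: ["TTC", "CTT", "CTT", "AGG", "CTT"],
    11: ["TTC", "CTT", "CTT", "GCT", "AAA"],
    12: ["TTC", "CTT", "CTT", "ACT", "AAA"],
    20: ["TTC", "CTT", "CTT", "TTT", "AAG"],
}


def make_table1_fixture() -> CodonAlignment:
    """The 20-sequence, 5-codon worked example alignment.

    Rows 4-9 repeat row 3 and rows 13-19 repeat row 12 (the elided rows are
    filled with the nearest explicit row above). Column compositions are
    then
    col 1 {TTT×2, TTC×18}, col 2 {TTT×2, CTT×18},
    col 3 {TTT×1, TTC×1, CTT×18},
    col 4 {TTT×2, TTC×1, AGA×7, AGG×1, GCT×1, ACT×8} (no set reaches 10),
    col 5 {TTT×1, TTC×1, CTT×8, AAA×9, AAG×1} (two sets score).
    """
    rows = []
    last = None
    for i in range(1, 21):
        last = _TOY_EXPLICIT.get(i, last)
        rows.append((f"seq{i}", list(last)))
    return CodonAlignment(rows, family="toy", gene="combined")
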