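"""Relative element ages from divergence between the two LTRs.

The two long terminal repeats of an LTR retrotransposon are identical when
the element inserts, so the divergence between them measures the element's
relative age (no absolute dating is attempted; LTRs may be under
functional constraint and evolve below the neutral rate). Divergence is
(point mutations + indel events) per aligned site: mismatched columns
count as point mutations, each maximal gap run counts as one indel event
(a per-column convention is available via ``indel_mode="per_column"``),
and columns containing N are excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "LtrPair",
    "AgeEstimate",
    "make_aligner",
    "align_ltr_pair",
    "ltr_divergence",
    "ltr_ages",
    "read_ltr_pairs",
]


@dataclass(frozen=True)
class LtrPair:
    """The 5' and 3' LTR sequences of one element."""

    element_id: str
    ltr5: str
    ltr3: str

    def __post_init__(self):
        for name, seq in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if not seq:
                raise ValueError(f"{self.element_id}: empty {name}")
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"{self.element_id}: invalid characters {sorted(bad)} in {name}"
                )


@dataclass(frozen=True)
class AgeEstimate:
    """Per-element relative age: (mismatches + indel events) / aligned length."""

    element_id: str
    n_mismatches: int
    n_indel_events: int
    aligned_length: int

    @property
    def divergence(self) -> float:
        if self.aligned_length == 0:
            raise ValueError(f"{self.element_id}: zero aligned length")
        return (self.n_mismatches + self.n_indel_events) / self.aligned_length


def make_aligner(match: float = 2.0, mismatch: float = -1.0,
                 gap_open: float = -8.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    """Global affine-gap aligner with deterministic alignment ordering."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_ltr_pair(pair: LtrPair, match: float = 2.0, mismatch: float = -1.0,
                   gap_open: float = -8.0, gap_extend: float = -1.0):
    """Optimal global alignment of the two LTRs under affine gap scoring.

    Returns a ``Bio.Align.Alignment``; ties between co-optimal alignments
    are broken by taking the first alignment in the aligner's deterministic
    enumeration order. N matches nothing but scores as a mismatch here;
    N-containing columns are excluded later by `ltr_divergence`.
    """
    if len(pair.ltr5) < 20 or len(pair.ltr3) < 20:
        raise ValueError(f"{pair.element_id}: LTR sequences must be >= 20 nt")
    aligner = make_aligner(match, mismatch, gap_open, gap_extend)
    return aligner.align(pair.ltr5.upper(), pair.ltr3.upper())[0]


def _gapped_strings(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def ltr_divergence(alignment, element_id: str = "",
                   indel_mode: str = "per_event") -> AgeEstimate:
    """Summarize an LTR-pair alignment into an `AgeEstimate`.

    ``indel_mode="per_event"`` counts each maximal gap run once (a single
    mutational event regardless of its length); ``"per_column"`` counts
    every gap column.
    """
    a, b = _gapped_strings(alignment)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("invalid alignment")
    keep = [i for i in range(len(a)) if a[i] != "N" and b[i] != "N"]
    mismatches = 0
    indel_events = 0
    in_gap_a = in_gap_b = False
    for i in keep:
        ca, cb = a[i], b[i]
        if ca == "-" or cb == "-":
            if ca == "-" and not in_gap_a:
                indel_events += 1
            if cb == "-" and not in_gap_b:
                indel_events += 1
        else:
            mismatches += ca != cb
        in_gap_a, in_gap_b = ca == "-", cb == "-"
    if indel_mode == "per_column":
        indel_events = sum(
            1 for i in keep if (a[i] == "-") != (b[i] == "-")
        )
    elif indel_mode != "per_event":
        raise ValueError(f"unknown indel_mode {indel_mode!r}")
    aligned_length = len(keep)
    if aligned_length == 0:
        raise ValueError("zero aligned length after N-masking")
    return AgeEstimate(element_id=element_id, n_mismatches=mismatches,
                       n_indel_events=indel_events,
                       aligned_length=aligned_length)


def ltr_ages(pairs: list[LtrPair], indel_mode: str = "per_event",
             **aligner_kwargs) -> pd.DataFrame:
    """Align every pair and tabulate divergences.

    Returns a DataFrame with element_id, divergence, mismatches,
    indel_events and aligned_length, one row per element.
    """
    rows = []
    for pair in pairs:
        est = ltr_divergence(align_ltr_pair(pair, **aligner_kwargs),
                             element_id=pair.element_id,
                             indel_mode=indel_mode)
        rows.append({
            "element_id": est.element_id,
            "divergence": est.divergence,
            "mismatches": est.n_mismatches,
            "indel_events": est.n_indel_events,
            "aligned_length": est.aligned_length,
        })
    return pd.DataFrame(rows)


def read_ltr_pairs(path) -> list[LtrPair]:
    """Read LTR pairs from FASTA with records named ``<element_id>/5`` and
    ``<element_id>/3``."""
    five, three = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("/5"):
            five[rec.id[:-2]] = str(rec.seq)
        elif rec.id.endswith("/3"):
            three[rec.id[:-2]] = str(rec.seq)
        else:
            raise ValueError(f"{path}: record {rec.id} lacks a /5 or /3 suffix")
    missing = set(five) ^ set(three)
    if missing:
        raise ValueError(f"{path}: unpaired elements {sorted(missing)}")
    return [LtrPair(eid, five[eid], three[eid]) for eid in sorted(five)]
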