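"""Scan codon columns for segregating rate-matched variants.

At every codon column, each codon set with at least ``min_instances``
member codons present contributes one variant record per segregating
nucleotide position among those instances. The position's role in the set
determines whether the variant is synonymous or nonsynonymous. A variant's
frequency is that of the minor allele, with the *whole-alignment* sequence
count in the denominator (not just the set instances); sequences that carry
a gap or a non-member codon at the column still count toward the
denominator.

Positions with three or more alleles (possible only in the 16-codon NCN
set) are scored once, at the frequency of the rarest allele, by default;
``multiallelic="split"`` instead scores every non-major allele separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codes import GAP_CODON, N_CODES, BASE_INDEX, codon_to_code
from .alignment import CodonAlignment
from .codon_sets import CodonSet, builtin_codon_sets

__all__ = [
    "VariantRecord",
    "variant_frequency",
    "scan_column",
    "scan_alignment",
    "records_to_frame",
]


@dataclass(frozen=True)
class VariantRecord:
    """One segregating synonymous or nonsynonymous variant.

    ``column`` is a 1-based codon-column index; ``total_sequences`` is the
    whole-alignment sequence count, so ``frequency`` is the minor-allele
    frequency across the alignment.
    """

    column: int
    set_name: str
    position_in_codon: int
    variant_class: str  # "synonymous" | "nonsynonymous"
    minor_count: int
    total_sequences: int

    def __post_init__(self):
        if not 1 <= self.minor_count <= self.total_sequences / 2:
            raise ValueError(
                f"minor_count {self.minor_count} is not a minor allele "
                f"count for {self.total_sequences} sequences"
            )

    @property
    def frequency(self) -> float:
        return self.minor_count / self.total_sequences

    def sort_key(self):
        return (self.column, self.set_name, self.position_in_codon,
                self.variant_class, self.minor_count)


def variant_frequency(minor_count: int, n_sequences: int) -> float:
    """Minor-allele frequency of a variant across the whole alignment.

    A variant seen in 1 of 100 sequences has frequency 0.01. The caller
    must pass the *minor* allele count; anything above n/2 is rejected.
    """
    if minor_count <= 0:
        raise ValueError("minor_count must be positive")
    if minor_count > n_sequences / 2:
        raise ValueError(
            f"minor_count {minor_count} exceeds half of {n_sequences}; "
            "flip to the minor allele first"
        )
    return minor_count / n_sequences


def _records_for_alleles(counts: Counter, column_index: int, set_: CodonSet,
                         position: int, total: int,
                         multiallelic: str) -> list[VariantRecord]:
    """Turn an allele spectrum at one (column, set, position) into records."""
    if len(counts) < 2:
        return []
    vclass = set_.classify_position(position)
    ordered = counts.most_common()
    if len(ordered) == 2 or multiallelic == "rarest":
        minor = min(c for _, c in ordered)
        return [VariantRecord(column_index, set_.name, position, vclass,
                              minor, total)]
    if multiallelic == "split":
        return [VariantRecord(column_index, set_.name, position, vclass,
                              count, total)
                for _, count in ordered[1:]]
    raise ValueError(f"unknown multiallelic policy {multiallelic!r}")


def scan_column(column: list[str], sets: list[CodonSet] | None = None,
                min_instances: int = 10, column_index: int = 1,
                multiallelic: str = "rarest") -> list[VariantRecord]:
    """Scan one codon column for variants within each eligible codon set.

    Parameters
    ----------
    column : list of codon strings
        One column of a validated alignment; gap codons allowed.
    sets : list of CodonSet, optional
        Defaults to `builtin_codon_sets()`.
    min_instances : int
        Minimum member codons of a set that must be present in the column
        for the set to be scored there (default 10).
    column_index : int
        1-based column label stamped on the records.
    multiallelic : {"rarest", "split"}
        Scoring policy for positions with >= 3 alleles.
    """
    if min_instances < 2:
        raise ValueError("min_instances must be at least 2")
    if sets is None:
        sets = builtin_codon_sets()
    total = len(column)
    records: list[VariantRecord] = []
    for set_ in sets:
        instances = [c for c in column if c in set_.codons and c != GAP_CODON]
        if len(instances) < min_instances:
            continue
        for position in sorted(set_.syn_positions | set_.nonsyn_positions):
            alleles = Counter(c[position - 1] for c in instances)
            records.extend(
                _records_for_alleles(alleles, column_index, set_, position,
                                     total, multiallelic)
            )
        # positions outside the declared roles cannot segregate within a
        # well-formed set; assert rather than silently skip
        other = {1, 2, 3} - (set_.syn_positions | set_.nonsyn_positions)
        for position in other:
            assert len({c[position - 1] for c in instances}) == 1, (
                f"set {set_.name}: position {position} segregates but has "
                "no syn/nonsyn role"
            )
    return records


def _scan_codes(codes: np.ndarray, sets: list[CodonSet], min_instances: int,
                multiallelic: str) -> list[VariantRecord]:
    """Vectorized whole-alignment scan on the packed code matrix."""
    n, n_cols = codes.shape
    # per-column codon spectrum: (n_cols, 65)
    flat = codes.astype(np.int64) + N_CODES * np.arange(n_cols, dtype=np.int64)
    spectra = np.bincount(flat.ravel(), minlength=N_CODES * n_cols)
    spectra = spectra.reshape(n_cols, N_CODES)

    records: list[VariantRecord] = []
    for set_ in sets:
        member_codes = sorted(codon_to_code(c) for c in set_.codons)
        instance_counts = spectra[:, member_codes].sum(axis=1)
        eligible = instance_counts >= min_instances
        if not eligible.any():
            continue
        elig_idx = np.nonzero(eligible)[0]
        for position in sorted(set_.syn_positions | set_.nonsyn_positions):
            groups: dict[str, list[int]] = {}
            for code in member_codes:
                base = "ACGT"[(code >> (2 * (3 - position))) & 3]
                groups.setdefault(base, []).append(code)
            allele_counts = np.stack(
                [spectra[elig_idx][:, g].sum(axis=1) for g in groups.values()],
                axis=1,
            )
            n_alleles = (allele_counts > 0).sum(axis=1)
            seg = np.nonzero(n_alleles >= 2)[0]
            for k in seg:
                col = int(elig_idx[k])
                counts = Counter({
                    base: int(c)
                    for base, c in zip(groups.keys(), allele_counts[k])
                    if c > 0
                })
                records.extend(
                    _records_for_alleles(counts, col + 1, set_, position,
                                         n, multiallelic)
                )
    records.sort(key=lambda r: r.sort_key())
    return records


def scan_alignment(aln: CodonAlignment, sets: list[CodonSet] | None = None,
                   min_instances: int = 10,
                   multiallelic: str = "rarest") -> list[VariantRecord]:
    """Scan every column of an alignment.

    Returns the concatenation of per-column records in deterministic
    (column, set, position) order. Uses a vectorized path over the packed
    code matrix; results are identical to looping `scan_column` over
    columns (tested property).
    """
    if min_instances < 2:
        raise ValueError("min_instances must be at least 2")
    if aln.n_sequences == 0 or aln.n_codon_columns == 0:
        raise ValueError("empty alignment")
    if sets is None:
        sets = builtin_codon_sets()
    return _scan_codes(aln.codes, sets, min_instances, multiallelic)


def records_to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    """Variant records as a tidy DataFrame (one row per variant)."""
    return pd.DataFrame(
        [
            {
                "column": r.column,
                "set": r.set_name,
                "position": r.position_in_codon,
                "class": r.variant_class,
                "minor_count": r.minor_count,
                "n_sequences": r.total_sequences,
                "frequency": r.frequency,
            }
            for r in records
        ],
        columns=["column", "set", "position", "class", "minor_count",
                 "n_sequences", "frequency"],
    )
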