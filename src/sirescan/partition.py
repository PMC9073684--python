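"""Partition pol polyproteins into their four genes by motif/domain anchors.

Copia-lineage pol encodes protease, integrase, reverse transcriptase and
ribonuclease H in that order. Junctions are set from two Pfam domain hits
supplied as input (GAG-pre-integrase PF13976 and reverse transcriptase
PF07727) plus two sequence motifs: ADIFTK, a Copia-conserved anchor lying
a short distance upstream of the 3' end of pol and used to confirm 3'
completeness, and the ribonuclease-H catalytic D10-E48-D70 motif whose
first aspartate marks the start of the ribonuclease region. The ILGD
motif near the integrase 3' end is detected and reported but not used for
coordinates. All coordinates are 1-based inclusive amino-acid positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DomainHits",
    "GenePartition",
    "PartitionError",
    "check_pol_anchor",
    "find_ilgd",
    "find_rnase_motif",
    "partition_pol",
    "read_domain_hits",
    "partition_to_frame",
]

GAG_PRE_INTEGRASE = "GAG-pre-integrase"
RT_DOMAIN = "PF07727-RT"
POL_ANCHOR_MOTIF = "ADIFTK"
GENE_ORDER = ("protease", "integrase", "reverse_transcriptase", "ribonuclease")


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHits:
    """Pfam-style domain coordinates for one pol protein (1-based, inclusive)."""

    element_id: str
    hits: tuple  # of (domain_name, start, end)

    def get(self, name: str):
        for domain, start, end in self.hits:
            if domain == name:
                if not 1 <= start <= end:
                    raise PartitionError(
                        f"{self.element_id}: malformed hit {domain} "
                        f"[{start}, {end}]"
                    )
                return start, end
        return None


@dataclass(frozen=True)
class GenePartition:
    """Ordered, contiguous gene segments over a pol protein."""

    element_id: str
    segments: tuple  # of (gene_name, start, end), 1-based inclusive
    complete: bool = True
    warnings: tuple = ()


def check_pol_anchor(protein: str) -> tuple[bool, int | None]:
    """Is the ADIFTK 3'-completeness anchor present?

    Returns (found, 1-based position of the LAST occurrence); the motif
    sits a short distance upstream of the pol 3' end, so the last match is
    the anchor.
    """
    if not protein:
        raise ValueError("empty protein")
    pos = protein.rfind(POL_ANCHOR_MOTIF)
    if pos < 0:
        return False, None
    return True, pos + 1


def find_ilgd(protein: str) -> int | None:
    """1-based position of the last ILGD motif (integrase 3'-end marker)."""
    pos = protein.rfind("ILGD")
    return None if pos < 0 else pos + 1


def find_rnase_motif(protein: str, search_start: int, window: int = 120,
                     tolerance: int = 3) -> int | None:
    """Locate the ribonuclease D10-E48-D70 motif's first aspartate.

    Scans D positions in ``[search_start, search_start + window)``
    (1-based) for a D with an E at +48 and a D at +70, each within
    ``tolerance`` residues of the canonical spacing. Returns the 1-based
    position of the first such D, or None.
    """
    n = len(protein)
    for p in range(search_start - 1, min(n, search_start - 1 + window)):
        if protein[p] != "D":
            continue
        e_ok = any(
            0 <= p + 48 + d < n and protein[p + 48 + d] == "E"
            for d in range(-tolerance, tolerance + 1)
        )
        d_ok = any(
            0 <= p + 70 + d < n and protein[p + 70 + d] == "D"
            for d in range(-tolerance, tolerance + 1)
        )
        if e_ok and d_ok:
            return p + 1
    return None


def partition_pol(protein: str, hits: DomainHits, rt_offset: int = 30,
                  rnase_offset: int = 15, rnase_window: int = 120,
                  rnase_tolerance: int = 3) -> GenePartition:
    """Split a pol protein into its four genes.

    protease spans from the start of pol to the GAG-pre-integrase domain;
    integrase from there to ``rt_offset`` residues upstream of the PF07727
    reverse transcriptase domain; reverse transcriptase continues to
    ``rnase_offset`` residues upstream of the ribonuclease D10-E48-D70
    motif's first aspartate (sought ~85 aa downstream of PF07727);
    ribonuclease runs to the protein end.

    Raises `PartitionError` on missing or disordered domain hits. A
    missing ribonuclease motif yields a partial three-segment partition
    with ``complete=False`` and a warning.
    """
    if not protein:
        raise PartitionError("empty protein")
    n = len(protein)
    gag = hits.get(GAG_PRE_INTEGRASE)
    rt = hits.get(RT_DOMAIN)
    if gag is None or rt is None:
        missing = [name for name, h in
                   ((GAG_PRE_INTEGRASE, gag), (RT_DOMAIN, rt)) if h is None]
        raise PartitionError(f"{hits.element_id}: missing domain hits {missing}")
    gag_start, _ = gag
    rt_start, rt_end = rt
    if not gag_start < rt_start:
        raise PartitionError(
            f"{hits.element_id}: GAG-pre-integrase must precede PF07727"
        )
    if rt_end > n:
        raise PartitionError(f"{hits.element_id}: PF07727 hit beyond protein end")

    notes = []
    protease_end = gag_start - 1
    if protease_end < 1:
        notes.append("empty protease segment (GAG-pre-integrase at position 1)")
    int_rt_junction = rt_start - rt_offset  # first residue of RT
    if int_rt_junction <= gag_start:
        raise PartitionError(
            f"{hits.element_id}: integrase/reverse-transcriptase junction "
            "falls before the integrase start"
        )

    d_pos = find_rnase_motif(protein, search_start=rt_end + 1,
                             window=rnase_window, tolerance=rnase_tolerance)
    if d_pos is None:
        notes.append("ribonuclease D10E48D70 motif not found; "
                     "rt/ribonuclease junction unresolved")
        segments = tuple(
            seg for seg in (
                ("protease", 1, protease_end),
                ("integrase", gag_start, int_rt_junction - 1),
                ("reverse_transcriptase", int_rt_junction, n),
            ) if seg[1] <= seg[2]
        )
        part = GenePartition(hits.element_id, segments, complete=False,
                             warnings=tuple(notes))
        warnings.warn(f"{hits.element_id}: {notes[-1]}")
        return part

    rnase_start = d_pos - rnase_offset
    if rnase_start <= int_rt_junction:
        raise PartitionError(
            f"{hits.element_id}: ribonuclease junction before reverse "
            "transcriptase start"
        )
    segments = tuple(
        seg for seg in (
            ("protease", 1, protease_end),
            ("integrase", gag_start, int_rt_junction - 1),
            ("reverse_transcriptase", int_rt_junction, rnase_start - 1),
            ("ribonuclease", rnase_start, n),
        ) if seg[1] <= seg[2]
    )
    if notes:
        warnings.warn(f"{hits.element_id}: " + "; ".join(notes))
    return GenePartition(hits.element_id, segments, complete=True,
                         warnings=tuple(notes))


def read_domain_hits(path) -> dict[str, DomainHits]:
    """Read a TSV of domain hits (element_id, domain, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"element_id": str, "domain": str})
    out: dict[str, DomainHits] = {}
    for eid, grp in df.groupby("element_id", sort=False):
        out[eid] = DomainHits(
            element_id=eid,
            hits=tuple(
                (r.domain, int(r.start), int(r.end))
                for r in grp.itertuples()
            ),
        )
    return out


def partition_to_frame(parts: list[GenePartition]) -> pd.DataFrame:
    rows = [
        {"element_id": p.element_id, "gene": g, "start": a, "end": b,
         "complete": p.complete}
        for p in parts
        for g, a, b in p.segments
    ]
    return pd.DataFrame(rows, columns=["element_id", "gene", "start", "end",
                                       "complete"])
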