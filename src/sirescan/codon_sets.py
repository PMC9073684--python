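"""Rate-matched codon sets.

vN/vS counting only compares synonymous and nonsynonymous changes that are
expected to arise at the same rate. That holds inside special groups of
codons: quartets {XY, XY', ZY, ZY'} in which the exchange at one position is
always synonymous and the exchange at the other is always nonsynonymous, with
the two underlying nucleotide exchanges either identical (e.g. C<>T and C<>T)
or complementary (T<>C and A<>G, i.e. the same exchange on the opposite
strand); and the sixteen NCN codons (Pro, Thr, Ala and 4-fold Ser), where any
third-position change is synonymous and any first-position change is
nonsynonymous. Assuming context effects on the mutation rate are negligible,
raw variant counts within a set are directly comparable.

The default list holds 5 same-exchange quartets, 3 complement quartets and
the NCN set; all 9 are pairwise codon-disjoint so counts are independent.
Custom lists can be supplied to the scanner or loaded from a config file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._codes import BASES, GENETIC_CODE

__all__ = [
    "CodonSet",
    "builtin_codon_sets",
    "enumerate_candidate_quartets",
]

#: unordered base exchanges that are complementary (opposite strand).
_COMPLEMENT_EXCHANGE = {
    frozenset("TC"): frozenset("AG"),
    frozenset("AG"): frozenset("TC"),
    frozenset("AC"): frozenset("TG"),
    frozenset("TG"): frozenset("AC"),
    frozenset("AT"): frozenset("AT"),
    frozenset("CG"): frozenset("CG"),
}


@dataclass(frozen=True)
class CodonSet:
    """A group of codons with rate-matched syn/nonsyn single-base changes.

    Parameters
    ----------
    name : str
        Label used in variant records (e.g. ``"Phe/Leu"``).
    codons : frozenset of str
        Member codons. Quartets have 4, the NCN set 16.
    syn_positions, nonsyn_positions : frozenset of int
        Codon positions (1-3) at which within-set changes are synonymous
        respectively nonsynonymous.
    kind : str
        One of ``same_mutation_quartet``, ``complement_quartet``,
        ``ncn_sixteen``.
    """

    name: str
    codons: frozenset
    syn_positions: frozenset
    nonsyn_positions: frozenset
    kind: str

    def __post_init__(self):
        if self.kind in ("same_mutation_quartet", "complement_quartet"):
            if len(self.codons) != 4:
                raise ValueError(f"{self.name}: quartet must have 4 codons")
        elif self.kind == "ncn_sixteen":
            if len(self.codons) != 16 or any(c[1] != "C" for c in self.codons):
                raise ValueError(f"{self.name}: NCN set must be the 16 NCN codons")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.syn_positions & self.nonsyn_positions:
            raise ValueError(f"{self.name}: syn/nonsyn positions overlap")

    def classify_position(self, position: int) -> str:
        if position in self.syn_positions:
            return "synonymous"
        if position in self.nonsyn_positions:
            return "nonsynonymous"
        raise AssertionError(
            f"position {position} segregates in set {self.name} but has no "
            "syn/nonsyn role; the set definition is inconsistent"
        )


def _quartet(name, codons, syn_pos, nonsyn_pos, kind):
    return CodonSet(
        name=name,
        codons=frozenset(codons),
        syn_positions=frozenset([syn_pos]),
        nonsyn_positions=frozenset([nonsyn_pos]),
        kind=kind,
    )


def builtin_codon_sets() -> list[CodonSet]:
    """The default codon sets.

    Returns the 5 same-exchange quartets, 3 complement quartets and the
    16-codon NCN set, in a fixed order. The sets are pairwise disjoint.
    """
    ncn = frozenset(a + "C" + b for a in BASES for b in BASES)
    return [
        _quartet("Phe/Leu", ["TTT", "TTC", "CTT", "CTC"], 3, 1, "same_mutation_quartet"),
        _quartet("Tyr/His", ["TAT", "TAC", "CAT", "CAC"], 3, 1, "same_mutation_quartet"),
        _quartet("Cys/Arg", ["TGT", "TGC", "CGT", "CGC"], 3, 1, "same_mutation_quartet"),
        _quartet("Lys/Arg", ["AAA", "AAG", "AGA", "AGG"], 3, 2, "same_mutation_quartet"),
        _quartet("Glu/Gly", ["GAA", "GAG", "GGA", "GGG"], 3, 2, "same_mutation_quartet"),
        _quartet("Ile/Val", ["ATT", "ATC", "GTT", "GTC"], 3, 1, "complement_quartet"),
        _quartet("Asn/Asp", ["AAT", "AAC", "GAT", "GAC"], 3, 1, "complement_quartet"),
        _quartet("Ser/Gly", ["AGT", "AGC", "GGT", "GGC"], 3, 1, "complement_quartet"),
        CodonSet(
            name="NCN",
            codons=ncn,
            syn_positions=frozenset([3]),
            nonsyn_positions=frozenset([1]),
            kind="ncn_sixteen",
        ),
    ]


def enumerate_candidate_quartets(
    genetic_code: dict[str, str] | None = None,
) -> list[CodonSet]:
    """Brute-force all rate-matched quartets under a genetic code.

    A candidate is a set of 4 codons {XY, XY', ZY, ZY'} differing at two
    codon positions, where the exchange at one position is synonymous in both
    contexts, the exchange at the other is nonsynonymous in both contexts,
    no member is a stop codon, and the two nucleotide exchanges are identical
    or complementary. Useful for auditing the builtin list; note that not all
    candidates are mutually codon-disjoint.
    """
    code = genetic_code if genetic_code is not None else GENETIC_CODE
    out = []
    seen = set()
    for pos_a, pos_b in itertools.combinations(range(3), 2):
        ctx_pos = ({0, 1, 2} - {pos_a, pos_b}).pop()
        for ctx in BASES:
            for xa, za in itertools.combinations(BASES, 2):
                for yb, wb in itertools.combinations(BASES, 2):
                    quartet = {}
                    for a, b in itertools.product((xa, za), (yb, wb)):
                        codon = [None, None, None]
                        codon[pos_a], codon[pos_b], codon[ctx_pos] = a, b, ctx
                        quartet[(a, b)] = "".join(codon)
                    codons = list(quartet.values())
                    if any(code.get(c, "*") == "*" for c in codons):
                        continue
                    aa = {k: code[v] for k, v in quartet.items()}
                    # exchange at pos_a (xa<>za) within each pos_b context
                    a_syn = all(aa[(xa, b)] == aa[(za, b)] for b in (yb, wb))
                    a_non = all(aa[(xa, b)] != aa[(za, b)] for b in (yb, wb))
                    b_syn = all(aa[(a, yb)] == aa[(a, wb)] for a in (xa, za))
                    b_non = all(aa[(a, yb)] != aa[(a, wb)] for a in (xa, za))
                    if a_syn and b_non:
                        syn_pos, nonsyn_pos = pos_a, pos_b
                    elif b_syn and a_non:
                        syn_pos, nonsyn_pos = pos_b, pos_a
                    else:
                        continue
                    ex_a, ex_b = frozenset((xa, za)), frozenset((yb, wb))
                    if ex_a == ex_b:
                        kind = "same_mutation_quartet"
                    elif _COMPLEMENT_EXCHANGE[ex_a] == ex_b:
                        kind = "complement_quartet"
                    else:
                        continue
                    key = frozenset(codons)
                    if key in seen:
                        continue
                    seen.add(key)
                    aas = sorted(set(aa.values()))
                    out.append(
                        _quartet(
                            "/".join(aas) + f"@{syn_pos + 1}s{nonsyn_pos + 1}n",
                            codons,
                            syn_pos + 1,
                            nonsyn_pos + 1,
                            kind,
                        )
                    )
    return out


def sets_from_config(entries: list[dict]) -> list[CodonSet]:
    """Build codon sets from parsed config entries.

    Each entry needs ``name``, ``codons`` (list), ``syn_positions``,
    ``nonsyn_positions`` (lists of 1-based positions) and ``kind``.
    """
    return [
        CodonSet(
            name=e["name"],
            codons=frozenset(e["codons"]),
            syn_positions=frozenset(e["syn_positions"]),
            nonsyn_positions=frozenset(e["nonsyn_positions"]),
            kind=e["kind"],
        )
        for e in entries
    ]
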