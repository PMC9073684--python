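"""Frequency binning of variants and the vN/vS curve.

Variant frequencies are folded (minor allele), so they live in (0, 1/2].
The default binning halves the axis in powers of two: (0, 2^-6],
(2^-6, 2^-5], ..., (2^-2, 2^-1]; a bin is labelled "P<upper>" after its
inclusive upper bound, e.g. "P0.015625" for (0, 2^-6]. Powers of two are
exact in binary floating point, so boundary assignment is bit-exact.

The ratio vN/vS per bin falls with frequency under negative selection on
the element's own transposition, and its high-frequency asymptote
estimates f, the fraction of nonsynonymous mutations that are neutral for
transposition; 1 - f is the deleterious fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scan import VariantRecord

__all__ = [
    "FrequencyBin",
    "VnVsCurve",
    "default_bins",
    "bins_from_edges",
    "bin_variants",
    "vnvs_curve",
    "pool_bins",
    "curve_to_frame",
]


@dataclass(frozen=True)
class FrequencyBin:
    """One frequency category: lower exclusive, upper inclusive."""

    lower: float
    upper: float
    label: str
    vN: int = 0
    vS: int = 0

    @property
    def ratio(self) -> float | None:
        """vN/vS, or None when vS = 0 (undefined, never coerced)."""
        if self.vS == 0:
            return None
        return self.vN / self.vS


def _label(upper: float) -> str:
    return f"P{upper:g}"


def default_bins() -> list[FrequencyBin]:
    """The six power-of-two bins (0, 2^-6] ... (2^-2, 2^-1]."""
    edges = [0.0] + [2.0 ** -k for k in range(6, 0, -1)]
    return bins_from_edges(edges)


def bins_from_edges(edges: list[float]) -> list[FrequencyBin]:
    """Bins from strictly increasing edges; bin i is (edges[i], edges[i+1]]."""
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    return [
        FrequencyBin(lower=lo, upper=hi, label=_label(hi))
        for lo, hi in zip(edges, edges[1:])
    ]


def bin_variants(records: list[VariantRecord],
                 bins: list[FrequencyBin] | None = None) -> list[FrequencyBin]:
    """Assign each variant to its frequency bin and tally vN/vS counts.

    Every record's frequency must fall in some bin (lower < f <= upper);
    counts are conserved.
    """
    if bins is None:
        bins = default_bins()
    uppers = np.array([b.upper for b in bins])
    lowers = np.array([b.lower for b in bins])
    vN = [0] * len(bins)
    vS = [0] * len(bins)
    for r in records:
        f = r.frequency
        # first bin whose (lower, upper] contains f; searchsorted on the
        # inclusive-upper convention
        i = int(np.searchsorted(uppers, f, side="left"))
        if i >= len(bins) or not (lowers[i] < f <= uppers[i]):
            raise ValueError(
                f"variant frequency {f} outside the binning range "
                f"({lowers[0]}, {uppers[-1]}]"
            )
        if r.variant_class == "nonsynonymous":
            vN[i] += 1
        else:
            vS[i] += 1
    return [replace(b, vN=n, vS=s) for b, n, s in zip(bins, vN, vS)]


@dataclass(frozen=True)
class VnVsCurve:
    """Binned vN/vS counts with the tail asymptote.

    ``asymptote`` is the mean ratio over the last ``tail_bins`` bins with a
    defined ratio (vS > 0); interpreted as ``f_hat``, the estimated neutral
    fraction of nonsynonymous mutations.
    """

    bins: tuple
    family: str = ""
    gene: str = "combined"
    tail_bins: int = 3

    @property
    def ratios(self) -> list[float | None]:
        return [b.ratio for b in self.bins]

    @property
    def asymptote(self) -> float | None:
        defined = [b.ratio for b in self.bins if b.ratio is not None]
        if not defined:
            return None
        tail = defined[-self.tail_bins:]
        return float(np.mean(tail))

    @property
    def f_hat(self) -> float | None:
        return self.asymptote

    @property
    def deleterious_fraction(self) -> float | None:
        a = self.asymptote
        return None if a is None else 1.0 - a

    @property
    def total_vN(self) -> int:
        return sum(b.vN for b in self.bins)

    @property
    def total_vS(self) -> int:
        return sum(b.vS for b in self.bins)


def vnvs_curve(bins: list[FrequencyBin], tail_bins: int = 3,
               family: str = "", gene: str = "combined") -> VnVsCurve:
    """Wrap binned counts into a `VnVsCurve` with a ``tail_bins`` asymptote."""
    if tail_bins < 1:
        raise ValueError("tail_bins must be >= 1")
    curve = VnVsCurve(bins=tuple(bins), family=family, gene=gene,
                      tail_bins=tail_bins)
    return curve


def pool_bins(curves: list[VnVsCurve], family: str = "",
              gene: str = "combined", tail_bins: int | None = None) -> VnVsCurve:
    """Pool variant counts across curves with identical binning.

    Summing counts before taking ratios is how per-gene curves combine
    families (counts pooled, not family ratios averaged).
    """
    if not curves:
        raise ValueError("no curves to pool")
    ref = curves[0]
    for c in curves[1:]:
        if [(b.lower, b.upper) for b in c.bins] != [
            (b.lower, b.upper) for b in ref.bins
        ]:
            raise ValueError("curves have different binnings")
    pooled = [
        replace(
            ref.bins[i],
            vN=sum(c.bins[i].vN for c in curves),
            vS=sum(c.bins[i].vS for c in curves),
        )
        for i in range(len(ref.bins))
    ]
    return VnVsCurve(bins=tuple(pooled), family=family, gene=gene,
                     tail_bins=tail_bins if tail_bins is not None else ref.tail_bins)


def curve_to_frame(curve: VnVsCurve) -> pd.DataFrame:
    """Curve as a table: label, bounds, counts, ratio (NaN where undefined)."""
    return pd.DataFrame(
        {
            "bin": [b.label for b in curve.bins],
            "lower": [b.lower for b in curve.bins],
            "upper": [b.upper for b in curve.bins],
            "vN": [b.vN for b in curve.bins],
            "vS": [b.vS for b in curve.bins],
            "ratio": [math.nan if b.ratio is None else b.ratio
                      for b in curve.bins],
        }
    )
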