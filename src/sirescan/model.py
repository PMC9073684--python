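"""Model/Results front end for the vN/vS selection scan.

`VnVsModel` wraps a codon alignment plus the scan settings; `fit()`
performs the scan, bins the variants, and runs the trend test, returning
a `VnVsResults` with the curve, the neutral-fraction estimate and a
``summary()`` table. Several fitted groups combine through
`combined_trend_pvalue` and `heterogeneity_between`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, read_codon_alignment
from .codon_sets import CodonSet, builtin_codon_sets
from .scan import VariantRecord, records_to_frame, scan_alignment
from .spectrum import (FrequencyBin, VnVsCurve, bin_variants, curve_to_frame,
                       default_bins, vnvs_curve)
from . import stats as _stats

__all__ = ["VnVsModel", "VnVsResults", "combined_trend_pvalue",
           "heterogeneity_between"]


class VnVsModel:
    """Selection scan of a TE family alignment.

    Parameters
    ----------
    alignment : CodonAlignment
        In-frame codon MSA of the family's intact copies.
    sets : list of CodonSet, optional
        Rate-matched codon sets (default: the builtin nine).
    min_instances : int
        Minimum set instances for a column/set to be scored (default 10).
    bins : list of FrequencyBin, optional
        Frequency categories (default: the six power-of-two bins).
    multiallelic : {"rarest", "split"}
        Scoring of >2-allele positions in the NCN set.

    Examples
    --------
    >>> from sirescan import make_table1_fixture, VnVsModel
    >>> res = VnVsModel(make_table1_fixture()).fit()
    >>> (res.total_vS, res.total_vN)
    (4, 3)
    """

    def __init__(self, alignment: CodonAlignment,
                 sets: list[CodonSet] | None = None,
                 min_instances: int = 10,
                 bins: list[FrequencyBin] | None = None,
                 multiallelic: str = "rarest"):
        self.alignment = alignment
        self.sets = sets if sets is not None else builtin_codon_sets()
        self.min_instances = min_instances
        self.bins = bins if bins is not None else default_bins()
        self.multiallelic = multiallelic

    @classmethod
    def from_fasta(cls, path, frame_offset: int = 0, family: str = "",
                   gene: str = "combined", **kwargs) -> "VnVsModel":
        aln = read_codon_alignment(path, frame_offset=frame_offset,
                                   family=family, gene=gene)
        return cls(aln, **kwargs)

    def scan(self) -> list[VariantRecord]:
        return scan_alignment(self.alignment, self.sets,
                              self.min_instances, self.multiallelic)

    def fit(self, tail_bins: int = 3) -> "VnVsResults":
        """Run the scan and assemble binned counts, trend and estimates."""
        records = self.scan()
        binned = bin_variants(records, self.bins)
        curve = vnvs_curve(binned, tail_bins=tail_bins,
                           family=self.alignment.family,
                           gene=self.alignment.gene)
        try:
            trend = _stats.spearman_trend(curve)
        except ValueError:
            trend = None
        return VnVsResults(model=self, records=records, curve=curve,
                           trend=trend)


@dataclass
class VnVsResults:
    """Fitted selection scan: variants, curve, trend test and estimates."""

    model: VnVsModel
    records: list
    curve: VnVsCurve
    trend: _stats.TrendResult | None

    @property
    def variants(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    @property
    def f_hat(self) -> float | None:
        """Tail-asymptote vN/vS: the estimated neutral fraction of
        nonsynonymous mutations."""
        return self.curve.f_hat

    @property
    def deleterious_fraction(self) -> float | None:
        return self.curve.deleterious_fraction

    @property
    def total_vN(self) -> int:
        return self.curve.total_vN

    @property
    def total_vS(self) -> int:
        return self.curve.total_vS

    def curve_frame(self) -> pd.DataFrame:
        return curve_to_frame(self.curve)

    def summary(self) -> str:
        """Human-readable report of the fitted scan."""
        aln = self.model.alignment
        lines = [
            "vN/vS selection scan",
            "=" * 58,
            f"family: {aln.family or '-':<20} gene: {aln.gene}",
            f"sequences: {aln.n_sequences:<14} codon columns: {aln.n_codon_columns}",
            f"variants: {self.total_vN} nonsynonymous, "
            f"{self.total_vS} synonymous",
            "-" * 58,
            f"{'bin':>10} {'(lower, upper]':>22} {'vN':>6} {'vS':>6} {'vN/vS':>8}",
        ]
        for b in self.curve.bins:
            ratio = "undef" if b.ratio is None else f"{b.ratio:.3f}"
            interval = f"({b.lower:.6g}, {b.upper:.6g}]"
            lines.append(
                f"{b.label:>10} {interval:>22} {b.vN:>6} {b.vS:>6} {ratio:>8}"
            )
        lines.append("-" * 58)
        if self.f_hat is not None:
            lines.append(
                f"tail asymptote (last {self.curve.tail_bins} defined bins): "
                f"f_hat = {self.f_hat:.3f}"
            )
            lines.append(
                f"estimated deleterious fraction of nonsynonymous mutations: "
                f"{self.deleterious_fraction:.3f}"
            )
        else:
            lines.append("tail asymptote undefined (no bins with vS > 0)")
        if self.trend is not None:
            kind = "exact" if self.trend.exact else "asymptotic"
            lines.append(
                f"Spearman trend: rho = {self.trend.rho:.3f}, "
                f"two-sided {kind} p = {self.trend.p_value:.4g} "
                f"(n = {self.trend.n_bins_used} bins)"
            )
        else:
            lines.append("Spearman trend: not computed (fewer than 3 usable bins)")
        return "\n".join(lines)

    def plot(self, ax=None, label: str | None = None):
        """Plot vN/vS against frequency category (log2 x-axis of bin uppers)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = [b.upper for b in self.curve.bins if b.ratio is not None]
        ys = [b.ratio for b in self.curve.bins if b.ratio is not None]
        ax.plot(xs, ys, "o-", label=label or self.curve.family or None)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("variant frequency (bin upper bound)")
        ax.set_ylabel("vN/vS")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        if label or self.curve.family:
            ax.legend()
        return ax


def combined_trend_pvalue(results: list[VnVsResults],
                          method: str = "fisher") -> float:
    """Fisher-combined p across the trend tests of several groups."""
    ps = [r.trend.p_value for r in results if r.trend is not None]
    return _stats.combine_pvalues(ps, method=method)


def heterogeneity_between(results: dict[str, VnVsResults]) -> pd.DataFrame:
    """Per-frequency-category chi-square of vN/vS between fitted groups.

    Returns a table with one row per frequency category plus a Total row
    summing statistics and degrees of freedom. Groups without variants in
    a category are dropped from that category's test.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 groups")
    ref = next(iter(results.values())).curve
    rows = []
    per_cat = []
    for i, b in enumerate(ref.bins):
        counts = {
            g: (r.curve.bins[i].vN, r.curve.bins[i].vS)
            for g, r in results.items()
        }
        try:
            h = _stats.heterogeneity_test(counts, category=b.label)
        except ValueError:
            continue
        per_cat.append(h)
        rows.append({"category": h.frequency_category,
                     "chi_square": h.chi_square, "df": h.df,
                     "p_value": h.p_value})
    if per_cat:
        tot = _stats.heterogeneity_total(per_cat)
        rows.append({"category": "Total", "chi_square": tot.chi_square,
                     "df": tot.df, "p_value": tot.p_value})
    return pd.DataFrame(rows, columns=["category", "chi_square", "df",
                                       "p_value"])
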