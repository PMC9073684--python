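"""Statistical tests on vN/vS curves and element-age distributions.

Three questions are addressed. Does vN/vS decline with variant frequency
within a group (Spearman rank correlation across frequency categories,
with an exhaustive-permutation two-sided p-value at the small bin counts
involved)? Do several groups share a single declining trend (Fisher
combination of their p-values)? And does the vN/vS level differ between
groups within a frequency category (Pearson chi-square on the 2 x k table
of (vN, vS) counts by group)? A fourth utility compares relative-age
(LTR divergence) distributions between families with Kruskal-Wallis and
pairwise Mann-Whitney tests.

No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats

from .spectrum import VnVsCurve

__all__ = [
    "TrendResult",
    "HeterogeneityResult",
    "spearman_trend",
    "combine_pvalues",
    "heterogeneity_test",
    "heterogeneity_total",
    "compare_age_distributions",
]

EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class TrendResult:
    """Spearman trend of vN/vS across frequency categories."""

    group: str
    rho: float
    p_value: float
    n_bins_used: int
    exact: bool


@dataclass(frozen=True)
class HeterogeneityResult:
    """Chi-square for vN/vS differences between groups in one category."""

    frequency_category: str
    chi_square: float
    df: int
    p_value: float


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.int64,
    )
    return perms.reshape(-1, n)


def _exact_spearman_p(x_ranks: np.ndarray, y_ranks: np.ndarray,
                      rho_obs: float) -> float:
    """Two-sided exhaustive permutation p for Spearman's rho.

    Permutes the observed (possibly mid-ranked) y ranks over all n!
    orderings and counts |rho_perm| >= |rho_obs|. For strictly monotone
    data this gives 2/n!.
    """
    n = len(x_ranks)
    perms = _permutation_matrix(n)
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 1.0
    rho_perm = (yc[perms] @ xc) / denom
    hits = np.count_nonzero(np.abs(rho_perm) >= abs(rho_obs) - 1e-12)
    return hits / len(perms)


def spearman_trend(curve: VnVsCurve, group: str | None = None) -> TrendResult:
    """Spearman correlation of per-bin vN/vS against frequency-bin order.

    Bins with undefined ratio (vS = 0) are excluded. The two-sided p-value
    is exhaustive-permutation exact for up to 10 usable bins (tied ratios
    mid-ranked), asymptotic beyond that. A strictly decreasing 6-bin curve
    gives rho = -1 and p = 2/720.

    Raises
    ------
    ValueError
        If fewer than 3 bins have a defined ratio.
    """
    pairs = [(i, b.ratio) for i, b in enumerate(curve.bins)
             if b.ratio is not None]
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 bins with defined vN/vS, got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    n = len(x)
    label = group if group is not None else (curve.family or curve.gene)
    if np.ptp(y) == 0:
        # no trend is definable on constant ratios
        return TrendResult(group=label, rho=0.0, p_value=1.0,
                           n_bins_used=n, exact=True)
    rho, p_asym = scipy.stats.spearmanr(x, y)
    if n <= EXACT_PERMUTATION_MAX_N:
        xr = scipy.stats.rankdata(x)
        yr = scipy.stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, float(rho))
        return TrendResult(group=label, rho=float(rho), p_value=p,
                           n_bins_used=n, exact=True)
    return TrendResult(group=label, rho=float(rho), p_value=float(p_asym),
                       n_bins_used=n, exact=False)


def combine_pvalues(p_values: list[float], method: str = "fisher") -> float:
    """Combine independent p-values (Fisher's method by default).

    Fisher: -2 sum(ln p) against chi-square with 2k df. ``method`` may also
    be ``"stouffer"``. A single p-value is returned unchanged (up to
    floating point, since the chi-square(2) tail inverts the transform).
    """
    ps = list(p_values)
    if not ps:
        raise ValueError("no p-values to combine")
    if any(not (0 < p <= 1) for p in ps):
        raise ValueError("p-values must be in (0, 1]")
    res = scipy.stats.combine_pvalues(ps, method=method)
    return float(res.pvalue)


def heterogeneity_test(counts: dict[str, tuple[int, int]],
                       category: str = "Total") -> HeterogeneityResult:
    """Pearson chi-square for (vN, vS) differences between groups.

    Parameters
    ----------
    counts : dict group -> (vN, vS)
        Groups with vN + vS = 0 are dropped and the degrees of freedom
        reduced accordingly (df = number of groups with data - 1).
    category : str
        Label for the frequency category tested.
    """
    kept = {g: c for g, c in counts.items() if c[0] + c[1] > 0}
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with nonzero variant counts")
    table = np.array([[c[0] for c in kept.values()],
                      [c[1] for c in kept.values()]], dtype=float)
    df = len(kept) - 1
    if (table.sum(axis=1) == 0).any():
        # one variant class absent everywhere: no heterogeneity measurable
        return HeterogeneityResult(category, 0.0, df,
                                   float(scipy.stats.chi2.sf(0.0, df)))
    chi2, _, dof, _ = scipy.stats.chi2_contingency(table, correction=False)
    assert dof == df
    p = float(scipy.stats.chi2.sf(chi2, df))
    return HeterogeneityResult(category, float(chi2), df, p)


def heterogeneity_total(results: list[HeterogeneityResult]) -> HeterogeneityResult:
    """Sum chi-square statistics and df across frequency categories."""
    if not results:
        raise ValueError("no per-category results")
    chi2 = sum(r.chi_square for r in results)
    df = sum(r.df for r in results)
    return HeterogeneityResult("Total", chi2, df,
                               float(scipy.stats.chi2.sf(chi2, df)))


def compare_age_distributions(ages: dict[str, list[float]]) -> dict:
    """Kruskal-Wallis across families plus pairwise Mann-Whitney tests.

    Parameters
    ----------
    ages : dict family -> list of per-element LTR divergences (>= 2 each).

    Returns
    -------
    dict with keys ``kruskal`` (statistic, p_value), ``pairwise`` (DataFrame
    of U and p per family pair) and ``medians``.
    """
    if len(ages) < 2 or any(len(v) < 2 for v in ages.values()):
        raise ValueError("need >= 2 families with >= 2 elements each")
    groups = {k: np.asarray(v, dtype=float) for k, v in ages.items()}
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        import warnings

        warnings.warn("all age values identical; tests are degenerate")
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*groups.values())
    rows = []
    for a, b in itertools.combinations(groups, 2):
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            u, pu = len(groups[a]) * len(groups[b]) / 2, 1.0
        else:
            u, pu = scipy.stats.mannwhitneyu(groups[a], groups[b],
                                             alternative="two-sided",
                                             method="auto")
        rows.append({"family_a": a, "family_b": b, "U": float(u),
                     "p_value": float(pu)})
    return {
        "kruskal": {"statistic": float(h), "p_value": float(p)},
        "pairwise": pd.DataFrame(rows),
        "medians": {k: float(np.median(v)) for k, v in groups.items()},
    }
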