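"""Independent brute-force oracles the implementation is checked against.

Everything here is written from the definitions, deliberately avoiding the
package's own code paths (no Counter-based spectra, no dynamic-programming
shortcuts, no scipy test functions), so agreement is meaningful.
"""

from __future__ import annotations

import itertools


# -- variant scanning ------------------------------------------------------

def oracle_scan_column(column, sets, min_instances=10, multiallelic="rarest"):
    """Naive allele enumeration per (set, position).

    Returns a sorted list of tuples
    (set_name, position, variant_class, minor_count, total_sequences).
    """
    total = len(column)
    out = []
    for cs in sets:
        members = []
        for codon in column:
            if codon in cs.codons and codon != "---":
                members.append(codon)
        if len(members) < min_instances:
            continue
        for pos in (1, 2, 3):
            if pos in cs.syn_positions:
                vclass = "synonymous"
            elif pos in cs.nonsyn_positions:
                vclass = "nonsynonymous"
            else:
                continue
            counts = {}
            for codon in members:
                base = codon[pos - 1]
                counts[base] = counts.get(base, 0) + 1
            if len(counts) < 2:
                continue
            ordered = sorted(counts.values())
            if len(counts) == 2 or multiallelic == "rarest":
                out.append((cs.name, pos, vclass, ordered[0], total))
            else:
                for c in ordered[:-1]:
                    out.append((cs.name, pos, vclass, c, total))
    return sorted(out)


# -- global affine-gap alignment score ------------------------------------

def oracle_affine_score(a, b, match=2.0, mismatch=-1.0, gap_open=-8.0,
                        gap_extend=-1.0):
    """Optimal global alignment score by exhaustive recursion.

    gap_open is the score of the first gap column of a run, gap_extend of
    each further column (biopython's open/extend convention). Memoized on
    (i, j, state) where state marks the previous column type.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = diagonal/start, 1 = gap in a, 2 = gap in b
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1, 0))
        if j < len(b):  # consume b, gap in a
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i, j + 1, 1))
        if i < len(a):  # consume a, gap in b
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i + 1, j, 2))
        return max(options)

    return best(0, 0, 0)


# -- chi-square and rank statistics ----------------------------------------

def oracle_chi_square(table):
    """Direct sum of (O-E)^2/E over a 2 x k table given as [row1, row2]."""
    col_totals = [table[0][j] + table[1][j] for j in range(len(table[0]))]
    row_totals = [sum(table[0]), sum(table[1])]
    grand = sum(col_totals)
    chi2 = 0.0
    for i in (0, 1):
        for j in range(len(table[0])):
            expected = row_totals[i] * col_totals[j] / grand
            chi2 += (table[i][j] - expected) ** 2 / expected
    return chi2


def oracle_spearman_exact_p(y):
    """Two-sided exhaustive-permutation p for Spearman rho of y against
    its index order, using scipy's rho on every permutation."""
    import scipy.stats

    x = list(range(len(y)))
    rho_obs = abs(scipy.stats.spearmanr(x, y).statistic)
    hits = 0
    n_perm = 0
    for perm in itertools.permutations(y):
        n_perm += 1
        r = scipy.stats.spearmanr(x, perm).statistic
        if abs(r) >= rho_obs - 1e-12:
            hits += 1
    return hits / n_perm


def oracle_mannwhitney_exact_p(xs, ys):
    """Two-sided exact Mann-Whitney p by enumerating all group splits."""
    pooled = list(xs) + list(ys)
    n, m = len(xs), len(ys)

    def u_stat(group_a, group_b):
        u = 0.0
        for a in group_a:
            for b in group_b:
                if a > b:
                    u += 1
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_stat(xs, ys)
    dev_obs = abs(u_obs - n * m / 2)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        total += 1
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(n + m) if i not in idx]
        if abs(u_stat(grp_a, grp_b) - n * m / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total
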