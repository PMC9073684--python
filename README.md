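# sirescan

Selection scans on transposable-element (TE) codon alignments.

All the copies of a TE family inside one genome descend from each other by
transposition, so the variation segregating among them records how natural
selection acts on the element's own genes. `sirescan` implements a
phylogeny-free method for measuring that selection: it counts synonymous
(vS) and nonsynonymous (vN) variants in *rate-matched codon sets* across an
in-frame alignment of intact TE copies, bins the variants by minor-allele
frequency, and tests whether vN/vS declines with frequency — the signature
expected when an element's gene products act in *cis* (mobilizing the copy
that encoded them), because copies that accumulate transposition-reducing
nonsynonymous mutations leave fewer descendants. If products act in
*trans*, degenerate copies ride along and vN/vS stays near 1 at all
frequencies.

It is written for molecular-evolution researchers working on LTR
retrotransposons (the conventions follow plant Sireviruses: intact
*gag*/*pol* copies, pol partitioned into protease, integrase, reverse
transcriptase and ribonuclease), but nothing restricts it to that lineage.

## The statistic

Raw vN/vS counts are only comparable when both kinds of change arise at the
same mutation rate. The scanner therefore counts variants only inside codon
sets built so that this holds:

- **5 same-exchange quartets** such as {TTT, TTC, CTT, CTC} (Phe/Leu): the
  synonymous change (position 3) and the nonsynonymous change (position 1)
  are both C&lt;&gt;T;
- **3 complement quartets** such as {ATT, ATC, GTT, GTC} (Ile/Val):
  synonymous T&lt;&gt;C versus nonsynonymous A&lt;&gt;G, the same exchange
  on the opposite strand;
- the **16 NCN codons** (Pro, Thr, Ala, 4-fold Ser): any third-position
  change is synonymous, any first-position change is nonsynonymous.

A codon column is scored for a set only if it contains at least 10 member
codons (one column may score through several sets). Each segregating
position yields one variant whose frequency is the minor-allele count over
*all* sequences in the alignment; a variant seen in 1 of 100 sequences has
frequency 0.01. Variants are pooled into frequency categories
(0, 2⁻⁶], (2⁻⁶, 2⁻⁵], …, (2⁻², 2⁻¹], written P0.015625 … P0.5.

Under the cis model the per-bin ratio vN/vS falls with frequency and its
high-frequency asymptote estimates **f, the fraction of nonsynonymous
mutations that are neutral for transposition** (so 1 − f is the deleterious
fraction). The decline is tested with Spearman's rank correlation across
bins, with an exhaustive-permutation exact p-value at these small bin
counts; groups combine via Fisher's method, and between-group differences
per frequency category use a 2×k chi-square.

## Worked example

Simulate one TE family under cis selection (130 copies, 500 codons, 15% of
nonsynonymous mutations neutral) and fit the scan:

```python
import sirescan as ss

sim = ss.simulate_family(ss.SimParams(seed=42))     # mode="cis", f=0.15
fit = ss.VnVsModel(sim.alignment).fit()
print(fit.summary())
```

```
vN/vS selection scan
==========================================================
family: sim-seed42           gene: combined
sequences: 130            codon columns: 500
variants: 25 nonsynonymous, 36 synonymous
----------------------------------------------------------
       bin         (lower, upper]     vN     vS    vN/vS
 P0.015625          (0, 0.015625]     24     24    1.000
  P0.03125    (0.015625, 0.03125]      0      0    undef
   P0.0625      (0.03125, 0.0625]      0      6    0.000
    P0.125        (0.0625, 0.125]      0      3    0.000
     P0.25          (0.125, 0.25]      1      2    0.500
      P0.5            (0.25, 0.5]      0      1    0.000
----------------------------------------------------------
tail asymptote (last 3 defined bins): f_hat = 0.167
estimated deleterious fraction of nonsynonymous mutations: 0.833
Spearman trend: rho = -0.447, two-sided exact p = 0.5 (n = 5 bins)
```

Reading the output: rare variants (bin P0.015625) show vN/vS ≈ 1 — recent
mutations that selection has not yet sorted — while common variants are
depleted of nonsynonymous changes; the tail average `f_hat = 0.167` is the
estimate of the neutral fraction (true value here 0.15), i.e. ~83% of
nonsynonymous mutations reduce transposition. One family of 130 copies has
too few variants for the trend to reach significance (p = 0.5); pooling
variant counts over 200 replicate families, as a multi-family dataset
would, gives

```python
from sirescan.spectrum import bin_variants, pool_bins, vnvs_curve

fams = ss.simulate_families(ss.SimParams(mode="cis", seed=0), 200)
curve = pool_bins([vnvs_curve(bin_variants(ss.scan_alignment(r.alignment)))
                   for r in fams])
trend = ss.spearman_trend(curve, group="cis pooled")
# f_hat = 0.173, rho = -0.943, exact p = 0.0167
```

whereas the same experiment with `mode="trans"` stays flat at vN/vS ≈ 1.

The same analyses are scriptable from the shell: `sirescan scan`, `curve`,
`trend`, `heterogeneity` (per-category chi-square between families or
genes), `ages` (relative element ages from 5'/3' LTR divergence),
`partition` (motif/domain-anchored pol gene junctions) and `simulate`.
`sirescan sets` prints the active codon sets; all defaults can be
overridden by a YAML config (`--config`).

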