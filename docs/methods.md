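# Methods

## The counting model

The unit of analysis is an in-frame codon alignment of the intact copies of
one TE family from a single genome, aligned at the amino-acid level so
every gap is a whole codon. Because the copies form a star-poor, poorly
resolved genealogy, no tree is estimated; instead each segregating
difference ("variant" — neither a fixed substitution nor a host-population
polymorphism) is placed on the unobserved genealogy by its frequency: a
variant on k copies arose on a branch with k extant descendants.

Synonymous and nonsynonymous variants are counted only inside codon sets in
which the two kinds of single-base change have matched mutation rates
(same or strand-complementary base exchanges; context effects on the
mutation rate are ignored by construction). The builtin list holds five
same-exchange quartets, three complement quartets and the sixteen NCN
codons; the nine sets are pairwise codon-disjoint so their counts are
independent. An exhaustive enumeration routine
(`enumerate_candidate_quartets`) audits this list against the genetic code;
it also reports a further candidate quartet ({CAA, CAG, CGA, CGG}, Gln/Arg)
that the default list deliberately omits, and the active list can be
replaced through configuration, so any alternative choice is isolated to
one table.

Scanning rules, in order:

1. a column is scored for a set only if ≥ `min_instances` (default 10)
   member codons are present; gap codons never count as instances but do
   count in frequency denominators;
2. each segregating position among the instances yields one variant,
   classified by the position's role in the set; positions with three or
   more alleles (possible only in the NCN set) are scored once at the
   frequency of the rarest allele (`multiallelic="split"` scores each
   non-major allele instead);
3. the variant's frequency is the minor-allele count divided by the number
   of sequences in the *whole alignment*. The 20-sequence reference example
   annotates one of its variants as "1 in 10" (the
   within-set count); under the whole-alignment rule implemented here the
   same variant is 1/20. The whole-alignment rule is the general
   definition the method states, and it is what the 1-in-100 example
   encodes; the inconsistency is noted here rather than resolved.

Frequencies are folded (minor allele), so they lie in (0, ½] and are binned
into (0, 2⁻⁶], (2⁻⁶, 2⁻⁵], …, (2⁻², 2⁻¹]. Power-of-two edges are exact in
binary floating point, making boundary assignment bit-exact. Bins with
vS = 0 have an undefined ratio; they are excluded from trend tests and
asymptotes, never coerced to 0 or ∞.

The tail asymptote (mean of the last `tail_bins` = 3 defined ratios)
estimates f, the neutral fraction of nonsynonymous mutations: synonymous
variants accumulate ∝ u, nonsynonymous ∝ u·f once selection has removed
transposition-reducing variants from the upper frequency classes, so
vN/vS → f. When curves are combined (families within a gene, replicate
simulations), variant *counts* are pooled before ratios are taken; ratios
are never averaged across groups.

## Statistical tests

- **Trend**: Spearman's rho between bin order and per-bin ratio. With
  n ≤ 10 usable bins the two-sided p is computed by exhaustive permutation
  of the (mid-ranked) ratios — a strictly monotone 6-bin curve gives
  p = 2/720 ≈ 0.003 — and asymptotically otherwise. Constant ratios return
  rho = 0, p = 1 by convention.
- **Combination**: Fisher's method (−2Σln p against χ² with 2k df);
  Stouffer available. A single p passes through unchanged.
- **Heterogeneity**: Pearson χ² on the 2×k table of (vN, vS) by group
  within one frequency category, without continuity correction. Groups
  with no variants in the category are dropped and df reduced accordingly
  (so a small family empty in the rarest bin lowers that category's df by
  one); a Total row sums statistics and df across categories.
- **Ages**: Kruskal–Wallis across families and pairwise Mann–Whitney on
  per-element LTR divergences, with medians reported.
- No multiple-testing correction is applied anywhere, matching the
  analysis convention this method defines.

## LTR relative ages

The two LTRs of a copy are identical at insertion, so their divergence
orders copies by age (no absolute dating — LTRs may be constrained).
Each pair is globally aligned with affine gap scores (defaults: match +2,
mismatch −1, gap open −8, gap extend −1; ties broken by the aligner's
deterministic enumeration order). Divergence = (mismatch columns + indel
events)/aligned columns, where a maximal gap run counts as one event —
"indels per site" weighted per mutational event, not per column; a
per-column convention is a switch. Columns containing N are excluded from
numerator and denominator.

## pol gene partitioning

Protease runs from the start of pol to the GAG-pre-integrase domain
(PF13976); integrase to 30 aa upstream of the reverse-transcriptase domain
(PF07727); reverse transcriptase to 15 aa upstream of the first aspartate
of the ribonuclease-H D₁₀E₄₈D₇₀ motif, sought within ~120 aa downstream of
PF07727 with ±3 aa spacing tolerance; ribonuclease to the protein end.
Domain coordinates are consumed from a table (any HMM scanner's output);
the ADIFTK motif checks pol 3′ completeness and ILGD is reported
descriptively. All offsets, window and tolerance are flags because the
canonical values are approximate.

## The simulator

`simulate_family` produces alignments with known ground truth. Each
transposition copies the parent's current sequence and adds Poisson(u·L)
point mutations (uniform over codon positions and target bases);
a synonymous change is neutral, a nonsynonymous change is neutral with
probability f, otherwise deleterious, multiplying the element's
transposition rate by (1 − s) per mutation carried. Under `cis` an
element's own load sets its offspring number; under `trans` every element
reproduces at the population-mean rate, so load is invisible to selection.
Mutations creating or destroying stop codons are classified as
nonsynonymous and follow the same neutral-with-probability-f rule; no
separate lethal class is modelled (s = 1 provides one).

Demography has two epochs:

1. **Expansion** from a single founder to `max_elements` copies — either a
   free branching process (Poisson offspring per element per generation)
   or, by default, the same process conditioned on its deterministic growth
   trajectory, with parents drawn multinomially ∝ (1−s)^load. Conditioning
   removes demographic noise without altering relative transposition
   success, which is what selection acts on.
2. **Turnover** for `turnover_generations` generations at constant copy
   number: a fraction `loss_rate` of elements is deleted at random
   (fitness-independent — loss models excision/silencing, not
   transposition) and replaced by fitness-weighted transpositions from the
   survivors. This equilibrium between transposition and element loss is
   what gives old families their deep shared ancestry, and it is the only
   regime in which selection against a lineage compounds over generations;
   without it (set `turnover_generations=0` for the pure expansion model)
   almost no variants reach the upper frequency bins and a deleterious
   lineage suffers only a one-shot reproductive deficit, so the vN/vS
   curve floors near (1−s) rather than f.

Every element ever born stays in the genealogy (parents, birth
generations); the emitted alignment holds the copies alive at the end. All
randomness flows from one seeded numpy generator; replicate families in
`simulate_families` get child seeds spawned from a master seed, and the
CLI stamps the seed into the FASTA headers.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `u` | 2×10⁻³ /codon/copy | with L=500 gives ~1 mutation per transposition, the scale of an error-prone reverse transcriptase plus host replication over an element generation; keeps per-site multiple hits rare (~0.1/codon over the tree depth) |
| `f` | 0.15 | the neutral fraction the method is designed to recover |
| `s` | 0.7 | population-scaled selection N·s ≫ 1 but per-mutation cost moderate, so deleterious variants are purged *gradually* across frequency bins (see below) |
| `max_elements` | 130 | the sampling depth typical for large maize Sirevirus families, and the smallest n whose singletons (1/130) still fall in the lowest bin |
| `loss_rate`, `turnover_generations` | 0.8, 80 | pairwise coalescence ≈ 27 generations, so 80 generations ≈ 3 coalescent times: lineages mostly share ancestry within the simulated window at a simulation cost of ~8,000 births per family |
| `base_rate` | 0.5 | ×1.5 growth per generation during the burst epoch |
| `L` | 500 | one gene-sized region; validation experiments pool many families instead of inflating L |

The selection strength trades off two observable features. Very strong
selection (s → 1) confines deleterious variants to singletons: the curve
tail sits exactly at f but is *flat*, so the rank correlation across bins
degenerates into coin-flip tie-breaking. Weak selection spreads the decline
but inflates the tail above f. s = 0.7 under the default demography gives
both a graded decline and a tail asymptote within ~0.02 of f; this regime
was chosen by scanning s on the generator's own output before the
validation experiments were frozen.

### What the generator does and does not emulate

It emulates: descent of all copies from one ancestor, rate-matched
accumulation of synonymous and nonsynonymous variants, cis versus trans
selection on transposition, element turnover, and (via
`simulate_duplication_noise`) segmental duplication that promotes
singletons to doubletons. It does not emulate: alignment error, indels and
frameshifts (alignments are emitted gap-free), context-dependent mutation
rates (CpG), gene conversion between copies, host-population dynamics of
insertions, or horizontal transfer. Passing validation therefore shows the
*inference chain* is correct under the stated model; it does not certify
robustness to misalignment or non-uniform mutation, which the scanning
rules only partially buffer.

## Validation experiments (tests/test_acceptance.py)

- **Worked example**: the 20×5 toy alignment reproduces its annotated
  per-column counts exactly; its elided rows are filled by repeating the
  nearest explicit row above, the minimal fill consistent with the
  explicit rows and count annotations.
- **Neutral null**: with f = 1, pooled counts from 20 seeded datasets
  (16 families × 130 copies each) stay inside the 95% exact-binomial band
  around vN/vS = 1 in every bin with ≥ 50 variants.
- **Signature contrast**: with f = 0.15, s = 0.7, 200 families × 130
  copies (26,000 elements) per seed, cis datasets show a significantly
  negative exact Spearman trend (p < 0.05) in ≥ 18 of 20 seeds and a
  pooled tail asymptote within ±0.05 of 0.15; trans datasets show no such
  decline and a tail near 1. Problem sizes here are the package's chosen
  validation scale: large enough that tail bins hold hundreds of
  synonymous variants, the scale on which rank inversions between
  near-asymptotic bins become rare.
- **Oracle equivalence**: the vectorized column scanner against a naive
  allele-enumeration oracle on 1,000 random columns; pairwise alignment
  scores against an exhaustive recursion on ≤ 12-nt pairs; the
  heterogeneity statistic against direct Σ(O−E)²/E.

Numerical conventions worth knowing: exact permutation p-values compare
|rho| with a 10⁻¹² slack to absorb rank-arithmetic rounding; fitness
weights are recentred on the least-loaded class before exponentiation so
(1−s)^load never underflows; codons are packed into base-4 integers
(gap = 64) and alignments stored as uint8 matrices, which is what makes
scanning 26,000×500 alignments cheap.

## Known limitations

- The builtin codon-set list satisfies every rate-matching and
  independence constraint, but other compliant choices exist (and at least
  one further candidate quartet is deliberately excluded); it is
  configurable for exactly this reason.
- The frequency-denominator inconsistency in the worked example (above) is
  documented, not resolved.
- Frameshifted copies are rejected at parse time rather than retained as
  alignment noise; analyses of families with genuine frameshifts must
  pre-filter those copies.
- The trend test treats bins as independent observations; with very few
  variants per bin the exact p is honest but weak, which is why grouped
  analyses pool counts before testing.
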