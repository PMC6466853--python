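# Methods

## Coordinate and counting conventions

All internal coordinates are 0-based half-open; BED is read natively and
GTF converted on ingest (1-based inclusive → 0-based half-open). Each gene
is reduced to one TSS: for multi-feature GTF input the 5′-most TSS on the
gene's strand is kept, since the analysis is gene-level and transcript
resolution adds nothing to a promoter-window statistic. A read contributes
to all counting at exactly one position, its midpoint `⌊(start+end)/2⌋`, so
reads are counted once per non-overlapping window and every counting kernel
is trivially checkable against an O(reads × regions) brute-force scan (the
test suite does exactly that).

## Promoter enrichment

Per gene and mark, enrichment is computed by direct counting in the
symmetric window `[tss − 2000, tss + 2000)` — strand-free because the
window is symmetric — as

    E = log2( (RPM_IP + ε) / (RPM_input + ε) ),   ε = 0.5 RPM.

The pseudocount is added symmetrically to both terms: it bounds log-ratios
on empty windows and fixes genes with no coverage in either library at
exactly E = 0, keeping them in the universe for downstream set arithmetic.
The sliding 2000-bp / 200-bp binned RPM track is computed by the same
midpoint rule and serves profile/export purposes; window enrichment
deliberately does not take a maximum over sliding bins (the simplest
whole-window reading; a bin-max variant would be a one-line change in
`window_enrichment` if ever wanted).

A promoter is called marked when E strictly exceeds `min_log2_enrichment`.
The default is 1.0, i.e. a >2-fold ratio over input: "2-fold enrichment on
the log2 scale" is genuinely ambiguous between ratio > 2 and ratio > 4, so
the threshold is an explicit parameter everywhere and only its default
encodes the ratio-greater-than-2 reading. Strict inequality means a gene
sitting exactly at the cutoff is unmarked.

## Metagene profiles

Profiles aggregate read midpoints by strand-oriented offset from the TSS
(upstream negative for both strands) in 100-bp bins over ±2 kb; the value
per bin is `(mean IP RPM + ε)/(mean input RPM + ε)` with the mean across
the supplied gene set. `profile_level` estimates the local profile value at
an offset by averaging the bins within ±200 bp, because a single 100-bp bin
of input coverage carries ~20% counting noise at realistic depths;
`profile_fwhm` reports the span of bins at or above the midpoint between
the profile's minimum and maximum, a definition that behaves sensibly for
both the unimodal H3K4me3 and the centrally dipped H3K27me3 shape.

## Expression integration

Correlation uses `log2(signal + 1)` by default (the flag is exposed and
recorded); undetected genes are retained for correlation but excluded from
differential calls, where the detection policy defaults to "detected in at
least one of the two conditions" — a gene silent in the stem state but
induced after differentiation is exactly the interesting case and must not
be filtered away. Fold change is `(signal_diff + c)/(signal_stem + c)` with
c = 1.0 signal unit, guarding division by zero on array-scale signals;
up/down calls use strict inequalities against the 2-fold threshold, so a
gene at exactly 2.0 is "unchanged". Per-state expression quartiles use
linear interpolation between order statistics (the numpy default), on the
linear signal scale. Derepressed bivalent genes are the intersection of the
bivalent state with the up-calls, per lineage; the common set is the
intersection over lineages and is order-invariant by construction.

## Category enrichment

The 2×2 table for a category with K members in an N-gene universe and k in
the n-gene query is tested with the hypergeometric upper tail
P(X ≥ k) (one-sided "greater", the default, since the question is
over-representation; a two-sided mode via the exact-test convention is
provided). Bonferroni multiplies by the number of categories with at least
one member in the universe — empty-after-intersection categories are
dropped before m is counted so untestable hypotheses do not inflate the
correction — and caps at 1.

## The synthetic generator

The generator emulates the statistical structure of the study system, not
its sequences:

- **Genes**: `n_genes` = 2000 evenly spaced on one 25-Mb chromosome
  (spacing ≥ 10 kb keeps promoter windows disjoint), random strand.
- **States**: multinomial with defaults K4-only 0.43, K27-only 0.03,
  bivalent 0.03, none 0.51 — the marked fractions of a ~20k-gene
  annotation implied by roughly 9.7k K4-marked, 1.2k K27-marked and ~0.6k
  bivalent genes.
- **Reads**: marked promoters receive Poisson(50) IP reads per mark whose
  midpoint offsets are drawn Normal(+200, 300) bp for H3K4me3 and from the
  equal mixture Normal(−1000, 800) / Normal(+1000, 800) for H3K27me3 — the
  two-component mixture is the simplest mechanism that yields the broad,
  centrally depressed profile. IP off-target background is uniform at
  1e−4 reads/bp; the input libraries are uniform at 2e−3 reads/bp, i.e.
  sequenced to a depth comparable to the IP libraries (~50k reads), which
  is what makes the input denominator informative at the single-promoter
  scale. Reads are 50 bp around the sampled midpoint; only midpoints matter
  downstream.
- **Expression**: `log2(signal + 1)` per gene is Normal(loc_state, 1.5)
  with locations 7 (K4-only), 4 (none), 3 (bivalent and K27-only),
  clamped at 0 — active promoters high, repressed low, unmarked
  intermediate.
- **Derepression**: of the realized bivalent genes, 13% form the common
  core, topped up to 23% (hepatocyte) and 20% (cholangiocyte) with
  disjoint lineage-specific extras — the fractions implied by
  128/115/72-per-562-style proportions. The fold (default 4) is applied on
  the pseudocount-shifted signal, `diff + c = fold · (stem + c) · 2^η`, so
  the designated fold is exactly what the downstream fold-change measure
  sees even for near-zero stem signals; between-condition noise η is
  Normal(0, 0.2) in log2, which keeps spurious 2-fold calls at the
  5-sigma level. The detection flag is `signal > 1.0`.

What the generator does **not** emulate: broad lineage-specific expression
programs (thousands of differentiation-responsive genes unrelated to
bivalency), replicate structure, mappability/GC structure, chromosome
heterogeneity, and peak-width variation between genes. Passing recovery
tests therefore demonstrates the correctness of the measurement and set
logic under the modeled noise, not robustness to every artefact of real
libraries.

### Model-implied correlations

The generator's "population" mark/expression correlation is estimated by
`population_correlations()`: a direct parametric Monte Carlo (default
n = 50,000 genes) of the same model — Poisson signal/background counts in
the ±2-kb window using analytic in-window mass fractions, Poisson input
counts, expected library sizes, per-state expression — without touching the
BED/coverage code path. Pipeline-recovered correlations on emitted datasets
agree with this independent estimate to well within ±0.1 at n = 2000
(sampling error ≈ 0.02); the defaults imply r ≈ +0.59 for H3K4me3 and
≈ −0.14 for H3K27me3. The K27 magnitude is small because only 6% of genes
carry the mark and unmarked-promoter enrichment is dominated by sparse-count
noise — the same reason the real measurement's negative correlation is much
weaker than the positive H3K4me3 one.

## Problem sizes

All tests and the acceptance script run on the default 2,000-gene, ~160k-read
configuration (seconds per simulation); the exhaustive hypergeometric check
enumerates every 2×2 table with N ≤ 50 (~390k tables) against exact
big-integer tail sums. These sizes give sampling errors an order of
magnitude below every tolerance asserted.
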