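# bivseq

Bivalent-promoter analysis from ChIP-seq TSS-window enrichment, integrated
with gene expression across differentiation.

## The problem

In stem and progenitor cells, many developmental genes carry a *bivalent
domain* at their promoter: the activating H3K4me3 and the repressive
H3K27me3 histone marks at the same time. These genes sit poised — lowly
expressed, but ready to switch on when differentiation resolves the domain
by losing the H3K27me3 half (*derepression*). `bivseq` implements the
promoter-centric analysis used to find such genes in a bipotent hepatic
stem/progenitor system differentiating into hepatocyte and cholangiocyte
lineages, as a tested, reusable library:

1. **TSS-window enrichment.** For each gene and mark, reads-per-million
   (RPM) of IP-library read midpoints in the window ±2 kb around the
   transcription start site, divided by the matched input:
   `E = log2((RPM_IP + ε) / (RPM_input + ε))`, ε = 0.5 RPM.
2. **Mark-state classification.** A promoter is marked when `E` strictly
   exceeds `min_log2_enrichment` (default 1.0, a >2-fold ratio over input);
   both marks ⇒ bivalent. The four states (K4-only / K27-only / bivalent /
   none) partition the gene universe.
3. **Expression integration.** Pearson correlation of each mark's
   enrichment with `log2(signal + 1)`; expression quartiles per state;
   differential calls at a strict 2-fold cutoff between the stem state and
   each lineage; derepressed bivalent genes = bivalent ∩ upregulated, per
   lineage and in common.
4. **Category enrichment.** One-sided Fisher's exact test of the bivalent
   set against functional categories, Bonferroni-adjusted.
5. **Shape diagnostics.** Strand-oriented metagene profiles around the TSS
   (sliding 2000/200-bp RPM bins for track export), which show the
   characteristic sharp H3K4me3 peak versus the broad, centrally depressed
   H3K27me3 signal.

Because the analysis is defined on standard formats (BED6/GTF annotations,
BED3/SAM reads, TSV expression tables), it runs unchanged on real data. A
ground-truth synthetic generator (`bivseq.synthetic_data`) emulates the
statistical structure of such a study so every stage is testable end to end
without downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data, writing their tables under `results/`:

```bash
python analysis/01_simulate.py            # dataset + ground truth
python analysis/02_promoter_enrichment.py # enrichment, states, Venn, overlaps
python analysis/03_metagene_profiles.py   # TSS profiles for both marks
python analysis/04_expression_integration.py
python analysis/05_category_enrichment.py
```

Output of the default run (2,000 genes, seed 1):

```
marked genes at log2 > 1.0: 939 H3K4me3, 179 H3K27me3, 81 bivalent
state recovery vs ground truth: 1933/2000 (96.7%)
H3K4me3: 938 promoters, FWHM 800 bp, TSS level 23.94 vs +-1kb 0.82
H3K27me3: 113 promoters, FWHM 1600 bp, TSS level 32.61 vs +-1kb 38.82
Pearson r, H3K4me3 enrichment vs log2(signal+1): +0.581 (n=2000)
Pearson r, H3K27me3 enrichment vs log2(signal+1): -0.164 (n=2000)
hepatocyte: 13 up, 0 down (26 undetected skipped)
cholangiocyte: 11 up, 0 down (27 undetected skipped)
commonly derepressed in both lineages: 7
ground-truth common set recovered: 7/7
  development: k=30/137, p_raw=4.12e-16, p_adj=3.71e-15
```

Reading this: the classifier recovers 96.7% of the generator's true
promoter states; H3K4me3 enrichment correlates positively with expression
and H3K27me3 negatively; the H3K27me3 profile is twice as wide as H3K4me3
and dips at the TSS itself (32.6 at the TSS vs 38.8 at ±1 kb); all 7
truly-derepressed-in-both-lineages bivalent genes are recovered with no
false positives; and the deliberately bivalent-biased "development"
category is the only significant one after Bonferroni.

## Layout

- `src/bivseq/` — the library: `genome_model` (annotation/read parsing,
  coordinate conventions), `coverage` (binned RPM, window enrichment,
  metagene), `bivalent` (states, Venn, list overlap), `integrate`
  (correlation, quartiles, differential and derepression calls), `stats`
  (Fisher/Bonferroni), `synthetic_data` (generator + ground truth),
  `pipeline` (files → classification glue).
- `analysis/` — the numbered drivers above.
- `tests/` — unit and property tests per module plus end-to-end recovery
  checks against brute-force oracles and the generator's truth.
- `docs/methods.md` — the model, generator design, and numerical choices.
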