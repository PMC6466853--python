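"""Classify promoters from TSS-window enrichment and overlap the bivalent set
with external (here synthetic) bivalent-gene lists.

Reads results/simulation/, computes per-gene log2(IP/input) RPM in the
+-2 kb TSS window for both marks, classifies each promoter at the >2-fold
(log2 > 1) cutoff, and reports the Venn counts, the recovery against ground
truth, and the overlap with stand-in "ES" and "HSC" bivalent lists.
"""

import argparse
from pathlib import Path

import pandas as pd

from bivseq.bivalent import (
    MarkState,
    overlap_with_lists,
    state_counts,
    write_classification_tsv,
    write_venn_json,
)
from bivseq.coverage import write_enrichment_tsv
from bivseq.pipeline import classify_promoters
from bivseq.synthetic_data import synthetic_external_lists


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", default="results/simulation")
    parser.add_argument("--outdir", default="results/classification")
    parser.add_argument("--min-log2-enrichment", type=float, default=1.0)
    args = parser.parse_args()

    sim = Path(args.simdir)
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pipe = classify_promoters(
        sim / "genes.bed",
        sim / "k4_ip.bed",
        sim / "k27_ip.bed",
        sim / "k4_input.bed",
        sim / "k27_input.bed",
        min_log2_enrichment=args.min_log2_enrichment,
    )
    write_enrichment_tsv(pipe.k4_records + pipe.k27_records, out / "enrichment.tsv")
    write_classification_tsv(pipe.classified, out / "states.tsv")
    counts, venn = state_counts(pipe.classified)
    write_venn_json(counts, venn, out / "venn.json")
    print(
        f"marked genes at log2 > {args.min_log2_enrichment}: "
        f"{venn.k4_total_marked} H3K4me3, {venn.k27_total_marked} H3K27me3, "
        f"{venn.bivalent} bivalent"
    )

    truth = pd.read_csv(sim / "truth.tsv", sep="\t").set_index("gene_id")
    predicted = {c.gene_id: c.state.value for c in pipe.classified}
    agree = sum(predicted[g] == truth.loc[g, "state"] for g in truth.index)
    print(f"state recovery vs ground truth: {agree}/{len(truth)} "
          f"({100 * agree / len(truth):.1f}%)")

    bivalent = [c.gene_id for c in pipe.classified if c.state is MarkState.BIVALENT]
    lists = synthetic_external_lists(truth.reset_index(), seed=0)
    overlap = overlap_with_lists(bivalent, lists)
    for name, size in overlap.sizes.items():
        print(f"overlap with synthetic {name} bivalent list: {size}")
    print(f"bivalent in all lists: {len(overlap.intersection)}")
    pd.Series(
        {**overlap.sizes, "all_lists": len(overlap.intersection)}
    ).to_json(out / "overlap.json", indent=2)


if __name__ == "__main__":
    main()
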