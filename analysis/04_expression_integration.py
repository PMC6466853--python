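"""Integrate promoter states with expression across differentiation.

Computes mark/expression Pearson correlations in the stem state, per-state
expression quartiles, 2-fold differential calls for each lineage, and the
derepressed-bivalent gene sets, then checks them against the ground truth.
Writes tables under results/integration/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bivseq.bivalent import MarkState
from bivseq.coverage import read_enrichment_tsv
from bivseq.integrate import (
    derepressed_bivalent,
    differential_calls,
    expression_for_condition,
    mark_expression_correlation,
    expression_by_state,
    read_expression_tsv,
    write_derepression_json,
)
from bivseq.bivalent import ClassifiedGene


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", default="results/simulation")
    parser.add_argument("--classdir", default="results/classification")
    parser.add_argument("--outdir", default="results/integration")
    args = parser.parse_args()

    sim, cls, out = Path(args.simdir), Path(args.classdir), Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    expression = read_expression_tsv(sim / "expression.tsv")
    stem = expression_for_condition(expression, "stem")
    records = read_enrichment_tsv(cls / "enrichment.tsv")
    by_mark = {
        mark: [r for r in records if r.mark == mark]
        for mark in ("H3K4me3", "H3K27me3")
    }
    correlations = {}
    for mark, recs in by_mark.items():
        res = mark_expression_correlation(recs, stem)
        correlations[mark] = {"r": round(res.r, 4), "n": res.n}
        print(f"Pearson r, {mark} enrichment vs log2(signal+1): "
              f"{res.r:+.3f} (n={res.n})")
    (out / "correlations.json").write_text(json.dumps(correlations, indent=2) + "\n")

    states = pd.read_csv(cls / "states.tsv", sep="\t")
    classified = [
        ClassifiedGene(r.gene_id, r.k4_log2, r.k27_log2, MarkState(r.state))
        for r in states.itertuples()
    ]
    quartiles = expression_by_state(classified, stem)
    quartiles.to_csv(out / "expression_by_state.tsv", sep="\t", index=False,
                     float_format="%.6g")
    print("expression quartiles per state:")
    print(quartiles.to_string(index=False))

    lineages = ["hepatocyte", "cholangiocyte"]
    calls = {}
    for lineage in lineages:
        res = differential_calls(
            stem, expression_for_condition(expression, lineage), lineage
        )
        calls[lineage] = res
        res.to_frame().to_csv(out / f"calls_{lineage}.tsv", sep="\t", index=False,
                              float_format="%.6g")
        print(f"{lineage}: {len(res.up)} up, {len(res.down)} down "
              f"({res.n_skipped_undetected} undetected skipped)")

    derep = derepressed_bivalent(classified, calls)
    write_derepression_json(derep, out / "derepression.json")
    for lineage in lineages:
        print(f"derepressed bivalent, {lineage}: {len(derep.per_lineage[lineage])}")
    print(f"commonly derepressed in both lineages: {len(derep.common)}")

    truth = pd.read_csv(sim / "truth.tsv", sep="\t").set_index("gene_id")
    true_common = set(
        truth.index[
            (truth["derepressed_hepatocyte"] == 1)
            & (truth["derepressed_cholangiocyte"] == 1)
        ]
    )
    recovered = len(set(derep.common) & true_common)
    print(f"ground-truth common set recovered: {recovered}/{len(true_common)}")


if __name__ == "__main__":
    main()
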