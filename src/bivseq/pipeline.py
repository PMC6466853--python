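"""Convenience driver: files on disk -> per-mark enrichment -> mark states.

Thin glue over :mod:`genome_model`, :mod:`coverage` and :mod:`bivalent` used
by the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import bivalent, coverage, genome_model

__all__ = ["PromoterClassification", "classify_promoters"]


@dataclass
class PromoterClassification:
    genes: list[genome_model.GeneModel]
    k4_records: list[coverage.EnrichmentRecord]
    k27_records: list[coverage.EnrichmentRecord]
    classified: list[bivalent.ClassifiedGene]

    @property
    def state_of(self) -> dict[str, bivalent.MarkState]:
        return {c.gene_id: c.state for c in self.classified}


def classify_promoters(
    genes_path: str | Path,
    k4_ip_path: str | Path,
    k27_ip_path: str | Path,
    k4_input_path: str | Path,
    k27_input_path: str | Path,
    annotation_format: str = "bed6",
    reads_format: str = "bed",
    flank: int = coverage.DEFAULT_FLANK,
    pseudocount: float = coverage.DEFAULT_PSEUDOCOUNT,
    min_log2_enrichment: float = bivalent.DEFAULT_MIN_LOG2_ENRICHMENT,
) -> PromoterClassification:
    """Run annotation + four read libraries through enrichment and classification."""
    genes = genome_model.read_gene_annotation(genes_path, format=annotation_format)
    k4_ip = genome_model.read_alignments(k4_ip_path, format=reads_format)
    k27_ip = genome_model.read_alignments(k27_ip_path, format=reads_format)
    k4_input = genome_model.read_alignments(k4_input_path, format=reads_format)
    k27_input = genome_model.read_alignments(k27_input_path, format=reads_format)
    k4_records = coverage.window_enrichment(
        k4_ip, k4_input, genes, mark=bivalent.H3K4ME3, flank=flank, pseudocount=pseudocount
    )
    k27_records = coverage.window_enrichment(
        k27_ip, k27_input, genes, mark=bivalent.H3K27ME3, flank=flank, pseudocount=pseudocount
    )
    classified = bivalent.classify(
        [*k4_records, *k27_records], threshold=min_log2_enrichment
    )
    return PromoterClassification(
        genes=genes,
        k4_records=k4_records,
        k27_records=k27_records,
        classified=classified,
    )
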