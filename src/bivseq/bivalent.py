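"""Promoter mark-state classification and gene-set overlap arithmetic.

A promoter is called marked by H3K4me3 or H3K27me3 when its log2 IP/input
window enrichment strictly exceeds ``min_log2_enrichment`` (default 1.0,
i.e. a >2-fold ratio over input); carrying both marks makes it bivalent.
The four states partition the gene universe.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .coverage import EnrichmentRecord

__all__ = [
    "H3K4ME3",
    "H3K27ME3",
    "DEFAULT_MIN_LOG2_ENRICHMENT",
    "MarkState",
    "ClassifiedGene",
    "VennCounts",
    "OverlapResult",
    "classify",
    "state_counts",
    "overlap_with_lists",
    "read_symbol_list",
    "classification_to_frame",
    "write_classification_tsv",
    "write_venn_json",
]

H3K4ME3 = "H3K4me3"
H3K27ME3 = "H3K27me3"
DEFAULT_MIN_LOG2_ENRICHMENT = 1.0


class MarkState(str, Enum):
    """Four-way promoter state from the two histone marks."""

    K4_ONLY = "K4_ONLY"
    K27_ONLY = "K27_ONLY"
    BIVALENT = "BIVALENT"
    NONE = "NONE"

    def __str__(self) -> str:  # plain value in tables/JSON
        return self.value


@dataclass(frozen=True)
class ClassifiedGene:
    gene_id: str
    k4_log2: float
    k27_log2: float
    state: MarkState


class VennCounts(NamedTuple):
    """Venn-diagram totals: all K4-marked, all K27-marked, and the overlap."""

    k4_total_marked: int
    k27_total_marked: int
    bivalent: int


def classify(
    records: Iterable[EnrichmentRecord],
    threshold: float = DEFAULT_MIN_LOG2_ENRICHMENT,
) -> list[ClassifiedGene]:
    """Classify each gene from its two per-mark enrichment records.

    BIVALENT iff both log2 enrichments strictly exceed ``threshold``;
    K4_ONLY / K27_ONLY iff exactly one does; NONE otherwise. Every gene must
    appear exactly once per mark.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    k4: dict[str, float] = {}
    k27: dict[str, float] = {}
    for r in records:
        table = {H3K4ME3: k4, H3K27ME3: k27}.get(r.mark)
        if table is None:
            raise ValueError(f"unknown mark {r.mark!r} for gene {r.gene_id}")
        if r.gene_id in table:
            raise ValueError(f"duplicate {r.mark} record for gene {r.gene_id}")
        table[r.gene_id] = r.log2_enrichment
    missing = sorted(set(k4) ^ set(k27))
    if missing:
        raise ValueError(
            f"genes present for one mark only: {missing[:20]}"
            + (" ..." if len(missing) > 20 else "")
        )
    out = []
    for gene_id in k4:
        a, b = k4[gene_id], k27[gene_id]
        if a > threshold and b > threshold:
            state = MarkState.BIVALENT
        elif a > threshold:
            state = MarkState.K4_ONLY
        elif b > threshold:
            state = MarkState.K27_ONLY
        else:
            state = MarkState.NONE
        out.append(ClassifiedGene(gene_id=gene_id, k4_log2=a, k27_log2=b, state=state))
    return out


def state_counts(
    classified: Iterable[ClassifiedGene],
) -> tuple[dict[MarkState, int], VennCounts]:
    """Counts per state plus the Venn triple (the counts partition the universe)."""
    counter = Counter(c.state for c in classified)
    counts = {state: counter.get(state, 0) for state in MarkState}
    venn = VennCounts(
        k4_total_marked=counts[MarkState.K4_ONLY] + counts[MarkState.BIVALENT],
        k27_total_marked=counts[MarkState.K27_ONLY] + counts[MarkState.BIVALENT],
        bivalent=counts[MarkState.BIVALENT],
    )
    return counts, venn


@dataclass
class OverlapResult:
    """Overlap of a query gene set with named external symbol lists.

    Symbols are matched case-insensitively after trimming whitespace; the
    returned sets carry the query's original spelling.
    """

    per_list: dict[str, frozenset[str]]
    sizes: dict[str, int]
    intersection: frozenset[str]


def _norm(symbol: str) -> str:
    return symbol.strip().lower()


def overlap_with_lists(
    bivalent_ids: Iterable[str], external_lists: Mapping[str, Iterable[str]]
) -> OverlapResult:
    """Per-list overlaps and the intersection across the query and all lists."""
    query = {}
    for s in bivalent_ids:
        if not s or not s.strip():
            raise ValueError("gene symbols must be non-empty")
        query.setdefault(_norm(s), s)
    per_list: dict[str, frozenset[str]] = {}
    common_keys = set(query)
    for name, symbols in external_lists.items():
        keys = {_norm(s) for s in symbols if s and s.strip()}
        if not keys:
            warnings.warn(f"external list {name!r} is empty", stacklevel=2)
        hit = set(query) & keys
        per_list[name] = frozenset(query[k] for k in hit)
        common_keys &= keys
    return OverlapResult(
        per_list=per_list,
        sizes={name: len(s) for name, s in per_list.items()},
        intersection=frozenset(query[k] for k in common_keys),
    )


def read_symbol_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list (blank lines and '#' skipped)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out


def classification_to_frame(classified: Iterable[ClassifiedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.k4_log2, c.k27_log2, c.state.value) for c in classified],
        columns=["gene_id", "k4_log2", "k27_log2", "state"],
    )


def write_classification_tsv(
    classified: Iterable[ClassifiedGene], path: str | Path
) -> None:
    classification_to_frame(classified).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_venn_json(
    counts: Mapping[MarkState, int], venn: VennCounts, path: str | Path
) -> None:
    payload = {
        "states": {state.value: counts[state] for state in MarkState},
        "venn": {
            "k4_total_marked": venn.k4_total_marked,
            "k27_total_marked": venn.k27_total_marked,
            "bivalent": venn.bivalent,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
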