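"""Chromatin-state / expression integration across differentiation.

Joins promoter mark states and enrichment with expression tables to compute
mark-expression Pearson correlations, per-state expression quartiles,
2-fold differential calls between the stem state and each differentiated
lineage, and the derepressed-bivalent gene sets (bivalent promoters whose
expression rises more than the fold threshold after differentiation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bivalent import ClassifiedGene, MarkState
from .coverage import EnrichmentRecord

__all__ = [
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_EXPRESSION_PSEUDO",
    "CorrelationResult",
    "DifferentialCall",
    "DifferentialResult",
    "DerepressionResult",
    "read_expression_tsv",
    "expression_for_condition",
    "mark_expression_correlation",
    "expression_by_state",
    "differential_calls",
    "derepressed_bivalent",
    "write_derepression_json",
]

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_EXPRESSION_PSEUDO = 1.0

_EXPR_COLUMNS = ["gene_id", "condition", "signal", "detected"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read an expression table (gene_id, condition, signal, detected 0/1).

    ``signal`` must be finite and non-negative; (gene_id, condition) must be
    unique. The detection flag is consumed as given — it is the upstream
    platform's above-background call, not recomputed here.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing column(s) {missing}")
    df = df[_EXPR_COLUMNS].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    df["signal"] = df["signal"].astype(float)
    df["detected"] = df["detected"].astype(int).astype(bool)
    if not np.isfinite(df["signal"]).all() or (df["signal"] < 0).any():
        raise ValueError("expression signal must be finite and >= 0")
    if df.duplicated(["gene_id", "condition"]).any():
        raise ValueError("duplicate (gene_id, condition) rows in expression table")
    return df


def expression_for_condition(expression: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Rows of one condition, indexed by gene_id."""
    sub = expression[expression["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no expression rows for condition {condition!r}")
    return sub.set_index("gene_id")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def mark_expression_correlation(
    records: Iterable[EnrichmentRecord],
    expression: pd.DataFrame,
    log_transform: bool = True,
) -> CorrelationResult:
    """Pearson correlation of one mark's log2 enrichment with expression.

    ``expression`` holds a single condition (index gene_id). Expression is
    taken as ``log2(signal + 1)`` unless ``log_transform`` is False. The
    correlation runs over the inner join on gene_id; undetected genes are
    retained.
    """
    enr = {r.gene_id: r.log2_enrichment for r in records}
    marks = {r.mark for r in records} if enr else set()
    if len(marks) > 1:
        raise ValueError(f"records mix marks {sorted(marks)}")
    shared = [g for g in enr if g in expression.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 genes shared between enrichment and expression")
    x = np.array([enr[g] for g in shared])
    signal = expression.loc[shared, "signal"].to_numpy(dtype=float)
    y = np.log2(signal + 1.0) if log_transform else signal
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r = sps.pearsonr(x, y).statistic
    return CorrelationResult(r=float(r), n=len(shared))


def expression_by_state(
    classified: Iterable[ClassifiedGene], expression: pd.DataFrame
) -> pd.DataFrame:
    """25th/50th/75th percentile of linear expression signal per mark state.

    Percentiles use linear interpolation between order statistics. States
    with no expressed genes in the table are omitted with a warning.
    """
    state_of = {c.gene_id: c.state for c in classified}
    rows = []
    for state in MarkState:
        genes = [g for g, s in state_of.items() if s is state and g in expression.index]
        if not genes:
            warnings.warn(f"no expression data for state {state.value}", stacklevel=2)
            continue
        signal = expression.loc[genes, "signal"].to_numpy(dtype=float)
        q25, q50, q75 = np.percentile(signal, [25, 50, 75])
        rows.append((state.value, len(genes), q25, q50, q75))
    return pd.DataFrame(rows, columns=["state", "n", "q25", "q50", "q75"])


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    lineage: str
    fold_change: float
    direction: str  # up / down / unchanged


@dataclass
class DifferentialResult:
    calls: list[DifferentialCall]
    n_skipped_missing: int  # genes present in only one condition
    n_skipped_undetected: int  # genes failing the detection policy

    @property
    def up(self) -> frozenset[str]:
        return frozenset(c.gene_id for c in self.calls if c.direction == "up")

    @property
    def down(self) -> frozenset[str]:
        return frozenset(c.gene_id for c in self.calls if c.direction == "down")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.gene_id, c.lineage, c.fold_change, c.direction) for c in self.calls],
            columns=["gene_id", "lineage", "fold_change", "direction"],
        )


def differential_calls(
    stem: pd.DataFrame,
    differentiated: pd.DataFrame,
    lineage: str,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudo: float = DEFAULT_EXPRESSION_PSEUDO,
    detection: str = "either",
) -> DifferentialResult:
    """Fold-change calls between the stem state and one differentiated lineage.

    ``fold_change = (signal_diff + pseudo) / (signal_stem + pseudo)``; a gene
    is up iff fold_change strictly exceeds ``fc_threshold`` and down iff it is
    strictly below ``1/fc_threshold``. ``detection`` controls which genes are
    eligible: 'either' (detected in at least one condition, default), 'both',
    or 'ignore'. Genes present in only one condition are skipped and counted.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    if detection not in ("either", "both", "ignore"):
        raise ValueError(f"unknown detection policy {detection!r}")
    shared = stem.index.intersection(differentiated.index)
    n_missing = (len(stem.index) - len(shared)) + (len(differentiated.index) - len(shared))
    if len(shared) == 0:
        raise ValueError("no genes shared between stem and differentiated tables")
    s = stem.loc[shared]
    d = differentiated.loc[shared]
    s_det = s["detected"].to_numpy(dtype=bool)
    d_det = d["detected"].to_numpy(dtype=bool)
    if detection == "either":
        keep = s_det | d_det
    elif detection == "both":
        keep = s_det & d_det
    else:
        keep = np.ones(len(shared), dtype=bool)
    n_undetected = int((~keep).sum())
    fc = (d["signal"].to_numpy(dtype=float) + pseudo) / (
        s["signal"].to_numpy(dtype=float) + pseudo
    )
    calls = []
    for gene_id, f, k in zip(shared, fc, keep):
        if not k:
            continue
        if f > fc_threshold:
            direction = "up"
        elif f < 1.0 / fc_threshold:
            direction = "down"
        else:
            direction = "unchanged"
        calls.append(
            DifferentialCall(
                gene_id=str(gene_id), lineage=lineage, fold_change=float(f), direction=direction
            )
        )
    return DifferentialResult(
        calls=calls, n_skipped_missing=n_missing, n_skipped_undetected=n_undetected
    )


@dataclass
class DerepressionResult:
    """Bivalent genes upregulated per lineage, and their intersection."""

    per_lineage: dict[str, frozenset[str]]
    common: frozenset[str]


def derepressed_bivalent(
    classified: Iterable[ClassifiedGene],
    calls_by_lineage: Mapping[str, DifferentialResult | Iterable[DifferentialCall]],
) -> DerepressionResult:
    """Per lineage, the bivalent genes called up; ``common`` intersects all lineages."""
    if not calls_by_lineage:
        raise ValueError("at least one lineage is required")
    bivalent = {c.gene_id for c in classified if c.state is MarkState.BIVALENT}
    per_lineage: dict[str, frozenset[str]] = {}
    for lineage, calls in calls_by_lineage.items():
        if isinstance(calls, DifferentialResult):
            up = calls.up
        else:
            up = {c.gene_id for c in calls if c.direction == "up"}
        per_lineage[lineage] = frozenset(bivalent & set(up))
    common = frozenset.intersection(*per_lineage.values())
    return DerepressionResult(per_lineage=per_lineage, common=common)


def write_derepression_json(result: DerepressionResult, path: str | Path) -> None:
    payload = {
        "per_lineage": {k: sorted(v) for k, v in result.per_lineage.items()},
        "common": sorted(result.common),
        "sizes": {
            **{k: len(v) for k, v in result.per_lineage.items()},
            "common": len(result.common),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
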