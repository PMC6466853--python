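"""Synthetic ChIP-seq / expression data with known ground truth.

Emulates the statistical structure of a promoter bivalency study on a
bipotent stem-cell system: a sharp, slightly downstream-shifted H3K4me3
signal at active promoters; a broad, centrally depressed H3K27me3 signal
(a two-component mixture flanking the TSS) at repressed promoters; uniform
input background; expression coupled to the promoter state; and a
designated subset of bivalent genes derepressed (>2-fold up) after
"differentiation" into each of two lineages, with a configured common core.

Everything is driven by one seeded generator, so a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .bivalent import MarkState
from .coverage import DEFAULT_FLANK, DEFAULT_PSEUDOCOUNT
from .genome_model import GeneModel, ReadInterval, ReadSet

__all__ = [
    "MIN_PROMOTER_SPACING",
    "SimConfig",
    "SimResult",
    "simulate",
    "population_correlations",
    "PopulationCorrelations",
    "synthetic_categories",
    "synthetic_external_lists",
]

#: Minimum TSS-to-TSS spacing so that 2-kb promoter windows never overlap.
MIN_PROMOTER_SPACING = 10_000

_STATE_ORDER = [MarkState.K4_ONLY, MarkState.K27_ONLY, MarkState.BIVALENT, MarkState.NONE]


def _default_state_proportions() -> dict[MarkState, float]:
    # roughly the study system's marked fractions on a ~20k-gene universe
    return {
        MarkState.K4_ONLY: 0.43,
        MarkState.K27_ONLY: 0.03,
        MarkState.BIVALENT: 0.03,
        MarkState.NONE: 0.51,
    }


def _default_expression_loc() -> dict[MarkState, float]:
    # log2(signal + 1) location per state: active high, repressed/bivalent low
    return {
        MarkState.K4_ONLY: 7.0,
        MarkState.K27_ONLY: 3.0,
        MarkState.BIVALENT: 3.0,
        MarkState.NONE: 4.0,
    }


def _default_expression_scale() -> dict[MarkState, float]:
    return {s: 1.5 for s in _STATE_ORDER}


def _default_derepression_fraction() -> dict[str, float]:
    return {"hepatocyte": 0.23, "cholangiocyte": 0.20}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study-like conditions.

    Promoter shapes: H3K4me3 midpoint offsets are Normal(+200, 300) bp
    relative to the (strand-oriented) TSS; H3K27me3 offsets come from an
    equal mixture of Normal(-1000, 800) and Normal(+1000, 800), which
    produces the broad, centrally depressed profile. IP off-target
    background and the input libraries are uniform; the inputs are
    sequenced to a depth comparable to the IP libraries
    (``input_rate`` reads/bp).
    """

    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: int = 25_000_000
    state_proportions: dict[MarkState, float] = field(
        default_factory=_default_state_proportions
    )
    reads_per_marked_promoter: float = 50.0
    background_rate: float = 1e-4  # IP off-target reads per bp
    input_rate: float = 2e-3  # input library reads per bp
    read_length: int = 50
    k4_offset_mean: float = 200.0
    k4_offset_sd: float = 300.0
    k27_offset: float = 1000.0
    k27_offset_sd: float = 800.0
    expression_log2_loc: dict[MarkState, float] = field(
        default_factory=_default_expression_loc
    )
    expression_log2_scale: dict[MarkState, float] = field(
        default_factory=_default_expression_scale
    )
    lineages: tuple[str, ...] = ("hepatocyte", "cholangiocyte")
    derepression_fraction: dict[str, float] = field(
        default_factory=_default_derepression_fraction
    )
    common_fraction: float = 0.13
    derepression_fold: float = 4.0
    condition_noise_sd: float = 0.2  # log2 units between conditions
    expression_pseudo: float = 1.0
    detection_threshold: float = 1.0  # signal units
    seed: int = 1

    def validate(self) -> None:
        fracs = [self.state_proportions.get(s, 0.0) for s in _STATE_ORDER]
        if any(f < 0 or f > 1 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("state_proportions must lie in [0,1] and sum to 1")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if self.n_genes * MIN_PROMOTER_SPACING > self.chrom_length:
            raise ValueError(
                f"infeasible spacing: {self.n_genes} genes x {MIN_PROMOTER_SPACING} bp "
                f"> chrom_length {self.chrom_length}"
            )
        for name, value in [
            ("reads_per_marked_promoter", self.reads_per_marked_promoter),
            ("k4_offset_sd", self.k4_offset_sd),
            ("k27_offset_sd", self.k27_offset_sd),
            ("condition_noise_sd", self.condition_noise_sd),
            ("expression_pseudo", self.expression_pseudo),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.background_rate < 0 or self.input_rate <= 0:
            raise ValueError("background_rate must be >= 0 and input_rate > 0")
        if self.derepression_fold <= 1:
            raise ValueError("derepression_fold must be > 1")
        for lineage in self.lineages:
            f = self.derepression_fraction.get(lineage, 0.0)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"derepression_fraction[{lineage}] out of [0,1]")
            if self.common_fraction > f + 1e-12:
                raise ValueError("common_fraction cannot exceed any lineage fraction")
        if not 0.0 <= self.common_fraction <= 1.0:
            raise ValueError("common_fraction out of [0,1]")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_proportions"] = {s.value: f for s, f in self.state_proportions.items()}
        d["expression_log2_loc"] = {s.value: v for s, v in self.expression_log2_loc.items()}
        d["expression_log2_scale"] = {
            s.value: v for s, v in self.expression_log2_scale.items()
        }
        d["lineages"] = list(self.lineages)
        return d


@dataclass
class SimResult:
    """Outputs of one simulation: file paths plus in-memory objects."""

    config: SimConfig
    paths: dict[str, Path]
    genes: list[GeneModel]
    readsets: dict[str, ReadSet]  # k4_ip, k27_ip, k4_input, k27_input
    truth: pd.DataFrame  # gene_id, state, derepressed_<lineage>..., read counts
    expression: pd.DataFrame  # gene_id, condition, signal, detected


def _signal_midpoints(
    rng: np.random.Generator,
    counts: np.ndarray,
    tss: np.ndarray,
    strand_sign: np.ndarray,
    config: SimConfig,
    mark: str,
) -> np.ndarray:
    """Strand-oriented midpoint positions for all signal reads of one library."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    if mark == "k4":
        offsets = rng.normal(config.k4_offset_mean, config.k4_offset_sd, total)
    else:
        component = rng.choice((-1.0, 1.0), size=total)
        offsets = rng.normal(component * config.k27_offset, config.k27_offset_sd, total)
    gene_tss = np.repeat(tss, counts)
    gene_sign = np.repeat(strand_sign, counts)
    return gene_tss + (gene_sign * np.round(offsets)).astype(np.int64)


def _uniform_midpoints(rng: np.random.Generator, rate: float, length: int) -> np.ndarray:
    n = int(rng.poisson(rate * length))
    return rng.integers(0, length, size=n, dtype=np.int64)


def _make_readset(midpoints: np.ndarray, config: SimConfig) -> ReadSet:
    half = config.read_length // 2
    mids = np.clip(midpoints, half, config.chrom_length - half)
    mids = np.sort(mids)
    reads = [
        ReadInterval(config.chrom, int(m) - half, int(m) + config.read_length - half)
        for m in mids
    ]
    return ReadSet(reads)


def simulate(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate the full synthetic dataset and write it under ``outdir``.

    Emits a BED6 gene annotation, four BED3 read libraries (H3K4me3 IP,
    H3K27me3 IP and their inputs), a long-format expression TSV for the stem
    state plus each lineage, a ground-truth TSV, and a JSON copy of the
    resolved configuration.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # --- gene placement, evenly spaced so promoter windows never overlap ---
    spacing = config.chrom_length // n
    tss = (np.arange(n, dtype=np.int64) * spacing) + spacing // 2
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    strand_sign = np.where(strands == "+", 1, -1).astype(np.int64)
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])
    genes = [
        GeneModel(gene_id=str(g), chrom=config.chrom, tss=int(t), strand=str(s))
        for g, t, s in zip(gene_ids, tss, strands)
    ]

    # --- true states ---
    probs = [config.state_proportions[s] for s in _STATE_ORDER]
    state_idx = rng.choice(len(_STATE_ORDER), size=n, p=probs)
    states = np.array([_STATE_ORDER[i].value for i in state_idx])
    k4_marked = np.isin(states, [MarkState.K4_ONLY.value, MarkState.BIVALENT.value])
    k27_marked = np.isin(states, [MarkState.K27_ONLY.value, MarkState.BIVALENT.value])

    # --- reads ---
    k4_counts = np.where(k4_marked, rng.poisson(config.reads_per_marked_promoter, n), 0)
    k27_counts = np.where(k27_marked, rng.poisson(config.reads_per_marked_promoter, n), 0)
    k4_sig = _signal_midpoints(rng, k4_counts, tss, strand_sign, config, "k4")
    k27_sig = _signal_midpoints(rng, k27_counts, tss, strand_sign, config, "k27")
    k4_bg = _uniform_midpoints(rng, config.background_rate, config.chrom_length)
    k27_bg = _uniform_midpoints(rng, config.background_rate, config.chrom_length)
    k4_input = _uniform_midpoints(rng, config.input_rate, config.chrom_length)
    k27_input = _uniform_midpoints(rng, config.input_rate, config.chrom_length)
    readsets = {
        "k4_ip": _make_readset(np.concatenate([k4_sig, k4_bg]), config),
        "k27_ip": _make_readset(np.concatenate([k27_sig, k27_bg]), config),
        "k4_input": _make_readset(k4_input, config),
        "k27_input": _make_readset(k27_input, config),
    }

    # --- derepression assignment among bivalent genes ---
    biv_idx = np.flatnonzero(states == MarkState.BIVALENT.value)
    perm = rng.permutation(biv_idx)
    n_biv = len(biv_idx)
    n_common = int(round(config.common_fraction * n_biv))
    derep = {lineage: np.zeros(n, dtype=bool) for lineage in config.lineages}
    cursor = n_common
    common_idx = perm[:n_common]
    for lineage in config.lineages:
        n_lin = int(round(config.derepression_fraction[lineage] * n_biv))
        extra = max(0, n_lin - n_common)
        idx = np.concatenate([common_idx, perm[cursor : cursor + extra]])
        cursor += extra
        derep[lineage][idx.astype(np.int64)] = True

    # --- expression ---
    loc = np.array([config.expression_log2_loc[_STATE_ORDER[i]] for i in state_idx])
    scale = np.array([config.expression_log2_scale[_STATE_ORDER[i]] for i in state_idx])
    y_stem = loc + scale * rng.standard_normal(n)
    stem_signal = np.maximum(0.0, np.exp2(y_stem) - 1.0)
    pseudo = config.expression_pseudo
    signals = {"stem": stem_signal}
    for lineage in config.lineages:
        eta = rng.normal(0.0, config.condition_noise_sd, n)
        log2fc = np.where(derep[lineage], np.log2(config.derepression_fold), 0.0)
        y_lin = np.log2(stem_signal + pseudo) + log2fc + eta
        signals[lineage] = np.maximum(0.0, np.exp2(y_lin) - pseudo)

    expr_rows = []
    for condition in ["stem", *config.lineages]:
        s = signals[condition]
        detected = (s > config.detection_threshold).astype(int)
        for g, v, d in zip(gene_ids, s, detected):
            expr_rows.append((str(g), condition, float(v), int(d)))
    expression = pd.DataFrame(
        expr_rows, columns=["gene_id", "condition", "signal", "detected"]
    )

    truth = pd.DataFrame({"gene_id": gene_ids, "state": states})
    for lineage in config.lineages:
        truth[f"derepressed_{lineage}"] = derep[lineage].astype(int)
    truth["k4_signal_reads"] = k4_counts
    truth["k27_signal_reads"] = k27_counts

    # --- write everything ---
    paths = {
        "genes": outdir / "genes.bed",
        "k4_ip": outdir / "k4_ip.bed",
        "k27_ip": outdir / "k27_ip.bed",
        "k4_input": outdir / "k4_input.bed",
        "k27_input": outdir / "k27_input.bed",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.json",
    }
    gene_length = 2000  # cosmetic body length for the BED6 record
    with open(paths["genes"], "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, min(g.tss + gene_length, config.chrom_length)
            else:
                start, end = max(0, g.tss + 1 - gene_length), g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")
    for key in ("k4_ip", "k27_ip", "k4_input", "k27_input"):
        with open(paths[key], "w") as fh:
            for r in readsets[key]:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    expression.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6g")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(config.to_json_dict(), fh, indent=2)
        fh.write("\n")

    return SimResult(
        config=config,
        paths=paths,
        genes=genes,
        readsets=readsets,
        truth=truth,
        expression=expression,
    )


@dataclass(frozen=True)
class PopulationCorrelations:
    """Model-implied Pearson correlations between enrichment and expression."""

    r_k4: float
    r_k27: float
    n: int


def _window_fraction_k4(config: SimConfig, flank: int) -> float:
    d = norm(config.k4_offset_mean, config.k4_offset_sd)
    return float(d.cdf(flank) - d.cdf(-flank))


def _window_fraction_k27(config: SimConfig, flank: int) -> float:
    d1 = norm(config.k27_offset, config.k27_offset_sd)
    d2 = norm(-config.k27_offset, config.k27_offset_sd)
    return float(0.5 * (d1.cdf(flank) - d1.cdf(-flank)) + 0.5 * (d2.cdf(flank) - d2.cdf(-flank)))


def expected_library_sizes(config: SimConfig) -> dict[str, float]:
    """Expected total reads per library under the generator model."""
    p = config.state_proportions
    n, rpp = config.n_genes, config.reads_per_marked_promoter
    bg = config.background_rate * config.chrom_length
    return {
        "k4_ip": n * (p[MarkState.K4_ONLY] + p[MarkState.BIVALENT]) * rpp + bg,
        "k27_ip": n * (p[MarkState.K27_ONLY] + p[MarkState.BIVALENT]) * rpp + bg,
        "k4_input": config.input_rate * config.chrom_length,
        "k27_input": config.input_rate * config.chrom_length,
    }


def population_correlations(
    config: SimConfig,
    n: int = 50_000,
    seed: int | None = None,
    flank: int = DEFAULT_FLANK,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PopulationCorrelations:
    """The generator model's implied mark/expression correlations.

    Estimated by drawing (state, promoter-window counts, expression)
    directly from the parametric model — Poisson signal and background
    counts in the 2*flank window, Poisson input counts, per-state
    expression — without touching the BED/coverage code path. This is the
    reference value that pipeline-recovered correlations on emitted
    datasets are compared against.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    probs = [config.state_proportions[s] for s in _STATE_ORDER]
    state_idx = rng.choice(len(_STATE_ORDER), size=n, p=probs)
    states = np.array([_STATE_ORDER[i].value for i in state_idx])
    k4_marked = np.isin(states, [MarkState.K4_ONLY.value, MarkState.BIVALENT.value])
    k27_marked = np.isin(states, [MarkState.K27_ONLY.value, MarkState.BIVALENT.value])
    libs = expected_library_sizes(config)
    rpp = config.reads_per_marked_promoter
    w4 = _window_fraction_k4(config, flank)
    w27 = _window_fraction_k27(config, flank)
    bg_window = config.background_rate * 2 * flank
    input_window = config.input_rate * 2 * flank

    k4_ip = rng.poisson(rpp * w4, n) * k4_marked + rng.poisson(bg_window, n)
    k27_ip = rng.poisson(rpp * w27, n) * k27_marked + rng.poisson(bg_window, n)
    k4_in = rng.poisson(input_window, n)
    k27_in = rng.poisson(input_window, n)
    e4 = np.log2(
        (k4_ip / libs["k4_ip"] * 1e6 + pseudocount)
        / (k4_in / libs["k4_input"] * 1e6 + pseudocount)
    )
    e27 = np.log2(
        (k27_ip / libs["k27_ip"] * 1e6 + pseudocount)
        / (k27_in / libs["k27_input"] * 1e6 + pseudocount)
    )
    loc = np.array([config.expression_log2_loc[_STATE_ORDER[i]] for i in state_idx])
    scale = np.array([config.expression_log2_scale[_STATE_ORDER[i]] for i in state_idx])
    y = np.maximum(0.0, loc + scale * rng.standard_normal(n))  # log2(signal + 1)
    return PopulationCorrelations(
        r_k4=float(pearsonr(e4, y).statistic),
        r_k27=float(pearsonr(e27, y).statistic),
        n=n,
    )


def synthetic_categories(
    truth: pd.DataFrame,
    seed: int = 0,
    enriched_category: str = "development",
    p_in_bivalent: float = 0.5,
    p_background: float = 0.05,
    n_random_categories: int = 8,
    p_random: float = 0.1,
) -> dict[str, set[str]]:
    """Functional-category labels with one category enriched in bivalent genes.

    Gives the category-enrichment test something with known structure: the
    ``enriched_category`` covers bivalent genes at ``p_in_bivalent`` and all
    others at ``p_background``; the random categories are state-blind.
    """
    rng = np.random.default_rng(seed)
    gene_ids = truth["gene_id"].to_numpy()
    is_biv = (truth["state"] == MarkState.BIVALENT.value).to_numpy()
    p = np.where(is_biv, p_in_bivalent, p_background)
    categories = {
        enriched_category: set(gene_ids[rng.random(len(gene_ids)) < p])
    }
    for j in range(n_random_categories):
        mask = rng.random(len(gene_ids)) < p_random
        categories[f"random_{j:02d}"] = set(gene_ids[mask])
    return {name: members for name, members in categories.items() if members}


def synthetic_external_lists(
    truth: pd.DataFrame,
    seed: int = 0,
    recall: Mapping[str, float] | None = None,
    n_foreign: int = 200,
) -> dict[str, set[str]]:
    """Stand-ins for published bivalent-gene lists from other stem-cell systems.

    Synthetic: each list captures a fraction (``recall``) of this dataset's
    true bivalent genes plus ``n_foreign`` symbols absent from the dataset,
    mimicking lists derived from a different genome annotation.
    """
    if recall is None:
        recall = {"ES": 0.30, "HSC": 0.15}
    rng = np.random.default_rng(seed)
    biv = truth.loc[truth["state"] == MarkState.BIVALENT.value, "gene_id"].to_numpy()
    lists = {}
    for name, frac in recall.items():
        n_hit = int(round(frac * len(biv)))
        hits = set(rng.choice(biv, size=n_hit, replace=False)) if n_hit else set()
        foreign = {f"{name.lower()}_only_{i:04d}" for i in range(n_foreign)}
        lists[name] = {str(s) for s in hits} | foreign
    return lists
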