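"""Mark/expression correlation, per-state quartiles, differential and derepression calls."""

import numpy as np
import pandas as pd
import pytest

from bivseq.bivalent import ClassifiedGene, MarkState
from bivseq.coverage import EnrichmentRecord
from bivseq.integrate import (
    DifferentialCall,
    derepressed_bivalent,
    differential_calls,
    expression_by_state,
    mark_expression_correlation,
    read_expression_tsv,
)


def enr(values, mark="H3K4me3"):
    return [EnrichmentRecord(f"g{i}", mark, 0, 0, v) for i, v in enumerate(values)]


def expr_frame(signals, detected=None, condition="stem"):
    detected = detected if detected is not None else [1] * len(signals)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(signals))],
            "condition": condition,
            "signal": signals,
            "detected": detected,
        }
    ).set_index("gene_id")


def test_correlation_perfect_linearity():
    # log2(signal + 1) = [2, 4, 6] -> r = 1 against enrichment [1, 2, 3]
    expr = expr_frame([3.0, 15.0, 63.0])
    assert mark_expression_correlation(enr([1, 2, 3]), expr).r == pytest.approx(1.0)
    assert mark_expression_correlation(enr([3, 2, 1]), expr).r == pytest.approx(-1.0)


def test_correlation_product_moment_example():
    # x = [1,2,3,4], y = [1,3,2,4] -> r = 0.8 by direct evaluation
    expr = expr_frame([1.0, 3.0, 2.0, 4.0])
    res = mark_expression_correlation(enr([1, 2, 3, 4]), expr, log_transform=False)
    assert res.r == pytest.approx(0.8)
    assert res.n == 4


def test_correlation_errors():
    with pytest.raises(ValueError, match="zero variance"):
        mark_expression_correlation(enr([1, 1, 1]), expr_frame([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match=">= 3 genes"):
        mark_expression_correlation(enr([1, 2]), expr_frame([1.0, 2.0]))
    mixed = enr([1, 2]) + [EnrichmentRecord("g2", "H3K27me3", 0, 0, 3)]
    with pytest.raises(ValueError, match="mix marks"):
        mark_expression_correlation(mixed, expr_frame([1.0, 2.0, 4.0]))


def classified_uniform(n, state):
    return [ClassifiedGene(f"g{i}", 0, 0, state) for i in range(n)]


def test_expression_by_state_quartiles():
    table = expression_by_state(
        classified_uniform(5, MarkState.K4_ONLY), expr_frame([1.0, 2.0, 3.0, 4.0, 5.0])
    )
    row = table.set_index("state").loc["K4_ONLY"]
    assert (row.q25, row.q50, row.q75) == (2.0, 3.0, 4.0)


def test_expression_by_state_single_gene_group_warns_on_missing_states():
    with pytest.warns(UserWarning, match="no expression data"):
        table = expression_by_state(
            classified_uniform(1, MarkState.BIVALENT), expr_frame([7.0])
        )
    row = table.set_index("state").loc["BIVALENT"]
    assert (row.q25, row.q50, row.q75) == (7.0, 7.0, 7.0)


@pytest.mark.parametrize("seed", range(3))
def test_expression_by_state_matches_sorted_interpolation(seed):
    """Quartiles agree with a hand-rolled sort-and-interpolate computation."""
    rng = np.random.default_rng(seed)
    signals = rng.gamma(2.0, 10.0, size=17).round(3)
    table = expression_by_state(
        classified_uniform(len(signals), MarkState.NONE), expr_frame(list(signals))
    )

    def brute_quantile(values, q):
        v = sorted(values)
        pos = q * (len(v) - 1)
        lo = int(pos)
        frac = pos - lo
        return v[lo] if lo + 1 == len(v) else v[lo] * (1 - frac) + v[lo + 1] * frac

    row = table.iloc[0]
    for col, q in [("q25", 0.25), ("q50", 0.5), ("q75", 0.75)]:
        assert row[col] == pytest.approx(brute_quantile(signals, q))


def test_differential_calls_directions_and_boundary():
    stem = expr_frame([10.0, 10.0, 20.0], condition="stem")
    diff = expr_frame([25.0, 20.0, 5.0], condition="hep")
    res = differential_calls(stem, diff, "hep", pseudo=1e-9)
    by_gene = {c.gene_id: c for c in res.calls}
    assert by_gene["g0"].direction == "up"  # FC 2.5
    assert by_gene["g1"].direction == "unchanged"  # FC exactly 2.0, strict >
    assert by_gene["g2"].direction == "down"  # FC 0.25


def test_differential_calls_swap_symmetry():
    rng = np.random.default_rng(0)
    a = expr_frame(list(rng.gamma(2, 10, size=30)))
    b = expr_frame(list(rng.gamma(2, 10, size=30)))
    fwd = {c.gene_id: c.direction for c in differential_calls(a, b, "l").calls}
    rev = {c.gene_id: c.direction for c in differential_calls(b, a, "l").calls}
    flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
    assert rev == {g: flip[d] for g, d in fwd.items()}


def test_differential_calls_skips_and_detection_policy():
    stem = expr_frame([10.0, 10.0, 1000.0], detected=[1, 0, 1])
    diff = expr_frame([50.0, 50.0], detected=[1, 1], condition="hep")
    res = differential_calls(stem, diff, "hep")
    assert res.n_skipped_missing == 1  # g2 present in stem only
    assert res.n_skipped_undetected == 0  # 'either' keeps g1, detected after differentiation
    res_both = differential_calls(stem, diff, "hep", detection="both")
    assert res_both.n_skipped_undetected == 1
    with pytest.raises(ValueError, match="no genes shared"):
        differential_calls(stem, expr_frame([1.0], condition="x").rename(index={"g0": "zz"}), "x")


def test_derepressed_bivalent_set_arithmetic():
    classified = [
        ClassifiedGene(g, 0, 0, MarkState.BIVALENT) for g in "abc"
    ] + [ClassifiedGene("x", 0, 0, MarkState.K4_ONLY)]

    def up_calls(genes, lineage):
        return [DifferentialCall(g, lineage, 3.0, "up") for g in genes]

    calls = {"hep": up_calls("abx", "hep"), "chol": up_calls("bc", "chol")}
    res = derepressed_bivalent(classified, calls)
    assert res.per_lineage["hep"] == {"a", "b"}
    assert res.per_lineage["chol"] == {"b", "c"}
    assert res.common == {"b"}

    # lineage-order invariance
    res_rev = derepressed_bivalent(classified, dict(reversed(list(calls.items()))))
    assert res_rev.common == res.common and res_rev.per_lineage == res.per_lineage

    # single lineage: common is that lineage's set
    single = derepressed_bivalent(classified, {"hep": calls["hep"]})
    assert single.common == single.per_lineage["hep"] == {"a", "b"}

    # no bivalent genes -> everything empty
    empty = derepressed_bivalent([ClassifiedGene("x", 0, 0, MarkState.NONE)], calls)
    assert empty.common == frozenset() and all(
        v == frozenset() for v in empty.per_lineage.values()
    )


def test_read_expression_tsv_validation(tmp_path):
    path = tmp_path / "expr.tsv"
    pd.DataFrame(
        {
            "gene_id": ["a", "a"],
            "condition": ["stem", "stem"],
            "signal": [1.0, 2.0],
            "detected": [1, 1],
        }
    ).to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_expression_tsv(path)
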