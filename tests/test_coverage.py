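"""Binned RPM, TSS-window enrichment and metagene profiles vs brute force."""

import math

import numpy as np
import pytest

from bivseq.coverage import (
    bin_rpm,
    metagene_profile,
    window_enrichment,
)
from bivseq.genome_model import GeneModel, ReadInterval, ReadSet


def make_reads(midpoints, chrom="chr1", library_size=None, length=50):
    half = length // 2
    reads = [ReadInterval(chrom, max(0, m - half), max(0, m - half) + length) for m in midpoints]
    return ReadSet(reads, library_size=library_size)


def brute_bin_counts(readset, chrom, chrom_length, bin_width, step):
    """O(reads x bins) per-read scan: a read is in a bin iff its midpoint is."""
    n_bins = math.ceil(chrom_length / step)
    counts = [0] * n_bins
    for r in readset:
        if r.chrom != chrom:
            continue
        m = (r.start + r.end) // 2
        for i in range(n_bins):
            if i * step <= m < i * step + bin_width:
                counts[i] += 1
    return counts


def brute_window_count(readset, gene, flank):
    return sum(
        1
        for r in readset
        if r.chrom == gene.chrom
        and gene.tss - flank <= (r.start + r.end) // 2 < gene.tss + flank
    )


def test_bin_rpm_arithmetic_example():
    rs = make_reads([100, 250, 2100])
    track = bin_rpm(rs, "chr1", chrom_length=4000, bin_width=2000, step=2000)
    assert track.values[0] == pytest.approx(2 / 3 * 1e6)
    assert track.values[1] == pytest.approx(1 / 3 * 1e6)


def test_bin_rpm_absent_chromosome_is_all_zero():
    rs = make_reads([100, 250])
    track = bin_rpm(rs, "chrZ", chrom_length=10_000)
    assert track.values.shape == (50,) and not track.values.any()


@pytest.mark.parametrize("bad", [dict(bin_width=0), dict(step=0), dict(step=3000)])
def test_bin_rpm_parameter_validation(bad):
    rs = make_reads([100])
    with pytest.raises(ValueError):
        bin_rpm(rs, "chr1", chrom_length=10_000, **{**dict(bin_width=2000, step=200), **bad})


@pytest.mark.parametrize("seed", range(4))
def test_bin_rpm_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    mids = rng.integers(25, 9975, size=100)
    rs = make_reads(mids.tolist())
    track = bin_rpm(rs, "chr1", chrom_length=10_000, bin_width=2000, step=200)
    expected = brute_bin_counts(rs, "chr1", 10_000, 2000, 200)
    assert np.array_equal(track.values * rs.library_size / 1e6, expected)


def test_window_enrichment_arithmetic_example():
    genes = [GeneModel("g", "chr1", 5000, "+")]
    ip = make_reads(list(range(4000, 6000, 50)), library_size=10**6)  # 40 in window
    inp = make_reads(list(range(4500, 5500, 100)), library_size=10**6)  # 10 in window
    (rec,) = window_enrichment(ip, inp, genes, mark="H3K4me3", pseudocount=1e-9)
    assert rec.ip_rpm == pytest.approx(40.0)
    assert rec.input_rpm == pytest.approx(10.0)
    assert rec.log2_enrichment == pytest.approx(2.0, abs=1e-6)


def test_window_enrichment_identity_and_absent_chrom():
    genes = [GeneModel("g", "chr1", 5000, "+"), GeneModel("h", "chrZ", 5000, "+")]
    ip = make_reads([4900, 5100], library_size=1000)
    inp = make_reads([4800, 5200], library_size=1000)
    recs = {r.gene_id: r for r in window_enrichment(ip, inp, genes, mark="H3K4me3")}
    assert recs["g"].log2_enrichment == 0.0  # ip_rpm == input_rpm
    assert recs["h"].ip_rpm == recs["h"].input_rpm == 0.0
    assert recs["h"].log2_enrichment == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_window_enrichment_matches_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    genes = [
        GeneModel(f"g{i}", "chr1", int(t), "+" if i % 2 else "-")
        for i, t in enumerate(rng.integers(2000, 98_000, size=50))
    ]
    ip = make_reads(rng.integers(25, 99_975, size=500).tolist())
    inp = make_reads(rng.integers(25, 99_975, size=500).tolist())
    recs = window_enrichment(ip, inp, genes, mark="H3K4me3")
    for rec, gene in zip(recs, genes):
        assert rec.ip_rpm * ip.library_size / 1e6 == pytest.approx(
            brute_window_count(ip, gene, 2000)
        )
        assert rec.input_rpm * inp.library_size / 1e6 == pytest.approx(
            brute_window_count(inp, gene, 2000)
        )


def test_scale_invariance_of_enrichment():
    """Multiplying both libraries' read multiplicities leaves log2 enrichment alone."""
    rng = np.random.default_rng(0)
    genes = [GeneModel("g", "chr1", 5000, "+")]
    ip_mids = rng.integers(3000, 7000, size=60).tolist()
    inp_mids = rng.integers(3000, 7000, size=30).tolist()
    (r1,) = window_enrichment(make_reads(ip_mids), make_reads(inp_mids), genes, mark="m")
    (r3,) = window_enrichment(
        make_reads(ip_mids * 3), make_reads(inp_mids * 3), genes, mark="m"
    )
    # RPM is scale-free, so even the pseudocount sees identical values
    assert r3.log2_enrichment == pytest.approx(r1.log2_enrichment)


def test_midpoint_conservation_over_disjoint_windows():
    rng = np.random.default_rng(1)
    rs = make_reads(rng.integers(25, 99_975, size=400).tolist())
    genes = [GeneModel(f"g{i}", "chr1", 2000 + 4000 * i, "+") for i in range(20)]
    recs = window_enrichment(rs, make_reads([50]), genes, mark="m")
    total = sum(r.ip_rpm for r in recs) * rs.library_size / 1e6
    assert total <= rs.library_size


def test_metagene_symmetry_and_identity():
    genes = [GeneModel(f"g{i}", "chr1", 10_000 + 20_000 * i, s) for i, s in enumerate("++--")]
    # offsets at bin centres so the half-open binning keeps mirror pairs together
    sym_offsets = [-1450, -450, -50, 50, 450, 1450]
    ip_mids = [g.tss + o for g in genes for o in sym_offsets]
    inp_mids = [g.tss + o for g in genes for o in range(-1950, 2000, 100)]
    ip, inp = make_reads(ip_mids), make_reads(inp_mids)
    prof = metagene_profile(ip, inp, genes, profile_bin=100)
    assert np.allclose(prof.ip_over_input, prof.ip_over_input[::-1], rtol=0.01)
    ident = metagene_profile(ip, ip, genes, profile_bin=100)
    assert np.allclose(ident.ip_over_input, 1.0)


def test_metagene_strand_orientation():
    """A downstream-shifted signal peaks at positive offsets on both strands."""
    plus = GeneModel("p", "chr1", 50_000, "+")
    minus = GeneModel("m", "chr1", 150_000, "-")
    # +500 downstream: right of the + TSS, left of the - TSS
    ip = make_reads([plus.tss + 500] * 20 + [minus.tss - 500] * 20)
    inp = make_reads(
        [t + o for t in (plus.tss, minus.tss) for o in range(-1950, 2000, 100)]
    )
    prof = metagene_profile(ip, inp, [plus, minus], profile_bin=100)
    assert prof.offsets[np.argmax(prof.ip_over_input)] == 500


def test_metagene_requires_genes_and_divisible_flank():
    rs = make_reads([100])
    with pytest.raises(ValueError, match="non-empty"):
        metagene_profile(rs, rs, [])
    with pytest.raises(ValueError, match="divisible"):
        metagene_profile(rs, rs, [GeneModel("g", "chr1", 500, "+")], profile_bin=300)
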