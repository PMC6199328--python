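import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_junction_counts
from tedeff.annotation import GeneModel
from tedeff.junctions import (
    JunctionCounts,
    count_junctions,
    median_split,
    retention_score,
    score_samples,
)

HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"
SEQ = "A" * 50

# one gene, exons [1000,2000) [3000,4000) [4600,5800): junctions
# (2000,3000) with 1000 bp intron and (4000,4600) with 600 bp intron
GENE = GeneModel(
    "g1", "chr1", "+", 1000, 5799, [(1000, 2000), (3000, 4000), (4600, 5800)]
)


def sam_line(qname, pos0, mapq, cigar, flag=0):
    return f"{qname}\t{flag}\tchr1\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{SEQ}\t*\n"


def spliced(qname, donor, gap, left, mapq=60):
    # `left` bases on the upstream exon, the rest downstream
    return sam_line(qname, donor - left, mapq, f"{left}M{gap}N{50 - left}M")


def unspliced(qname, boundary, left, mapq=60):
    return sam_line(qname, boundary - left, mapq, "50M")


def run_both(sam_text, tmp_path, models=None):
    p = tmp_path / "toy.sam"
    p.write_text(sam_text)
    models = models or {"g1": GENE}
    got = count_junctions(str(p), models)
    juncs = [(c.donor, c.acceptor) for c in got]
    expect = brute_force_junction_counts(sam_text, juncs)
    return got, expect


def assert_match(got, expect):
    for c in got:
        e = expect[(c.donor, c.acceptor)]
        assert (c.ee_reads, c.ei_reads, c.ie_reads) == (e["ee"], e["ei"], e["ie"]), (
            c.donor,
            c.acceptor,
        )


def test_toy_sam_counts_match_stated_values(tmp_path):
    text = HEADER
    for i in range(10):
        text += spliced(f"ee{i}", 2000, 1000, 25)  # 25/25 anchors
    text += unspliced("ei1", 2000, 20)  # 20 exon / 30 intron bases
    text += unspliced("ei2", 2000, 30)
    got, expect = run_both(text, tmp_path)
    j = {(c.donor, c.acceptor): c for c in got}[(2000, 3000)]
    assert (j.ee_reads, j.ei_reads, j.ie_reads) == (10, 2, 0)
    assert_match(got, expect)


@pytest.mark.parametrize("left", [7, 8, 9])
def test_anchor_boundary_on_spliced_reads(tmp_path, left):
    text = HEADER + spliced("r", 2000, 1000, left)
    got, expect = run_both(text, tmp_path)
    j = {(c.donor, c.acceptor): c for c in got}[(2000, 3000)]
    assert j.ee_reads == (1 if left >= 8 else 0)
    assert_match(got, expect)


@pytest.mark.parametrize("right", [7, 8, 9])
def test_anchor_boundary_on_far_exon(tmp_path, right):
    text = HEADER + spliced("r", 2000, 1000, 50 - right)
    got, expect = run_both(text, tmp_path)
    j = {(c.donor, c.acceptor): c for c in got}[(2000, 3000)]
    assert j.ee_reads == (1 if right >= 8 else 0)
    assert_match(got, expect)


@pytest.mark.parametrize("mapq", [19, 20, 21])
def test_mapq_boundary_is_strict(tmp_path, mapq):
    text = HEADER + spliced("r", 2000, 1000, 25, mapq=mapq) + unspliced(
        "u", 3000, 25, mapq=mapq
    )
    got, expect = run_both(text, tmp_path)
    j = {(c.donor, c.acceptor): c for c in got}[(2000, 3000)]
    assert j.ee_reads == (1 if mapq > 20 else 0)
    assert j.ie_reads == (1 if mapq > 20 else 0)
    assert_match(got, expect)


@pytest.mark.parametrize("anchor_side", [7, 8])
def test_unspliced_boundary_anchor(tmp_path, anchor_side):
    # `anchor_side` bases on the intron side of the donor
    text = HEADER + unspliced("u", 2000, 50 - anchor_side)
    got, expect = run_both(text, tmp_path)
    j = {(c.donor, c.acceptor): c for c in got}[(2000, 3000)]
    assert j.ei_reads == (1 if anchor_side >= 8 else 0)
    assert_match(got, expect)


def test_window_limit_on_boundary_reads(tmp_path):
    # ungapped read covering the donor but starting >150 bp away cannot
    # exist with 50 bp reads; instead check a read near vs far in window
    near = unspliced("n", 2000, 40)
    text = HEADER + near
    got, expect = run_both(text, tmp_path)
    assert_match(got, expect)


def test_randomized_toy_sams_match_oracle(tmp_path):
    rng = np.random.default_rng(123)
    genes = {
        "g1": GENE,
        "g2": GeneModel(
            "g2", "chr1", "-", 69_999, 50_000, [(56_000, 58_000), (50_000, 52_000), (60_000, 70_000)][::-1]
        ),
    }
    boundaries = []
    for g in genes.values():
        ex = g.exons_genomic()
        for (_, e1), (s2, _) in zip(ex, ex[1:]):
            boundaries.append((e1, s2))
    text = HEADER
    for i in range(400):
        donor, acceptor = boundaries[rng.integers(len(boundaries))]
        mapq = int(rng.choice([0, 19, 20, 21, 60]))
        a = int(rng.integers(1, 50))
        kind = rng.random()
        if kind < 0.5:
            text += spliced(f"r{i}", donor, acceptor - donor, a, mapq=mapq)
        elif kind < 0.75:
            text += unspliced(f"r{i}", donor, a, mapq=mapq)
        else:
            text += unspliced(f"r{i}", acceptor, a, mapq=mapq)
    got, expect = run_both(text, tmp_path, genes)
    assert_match(got, expect)
    assert sum(c.ee_reads + c.ei_reads + c.ie_reads for c in got) > 100


def test_unsupported_cigar_skipped_with_warning(tmp_path):
    text = HEADER + f"h\t0\tchr1\t1501\t60\t10H40M\t*\t0\t0\t{'A' * 40}\t*\n"
    p = tmp_path / "h.sam"
    p.write_text(text)
    with pytest.warns(UserWarning, match="unsupported CIGAR"):
        counts = count_junctions(str(p), {"g1": GENE})
    assert all(c.ee_reads == 0 for c in counts)


def test_retention_ratio_arithmetic_and_eligibility():
    eligible = JunctionCounts("g", 1000, 2000, ee_reads=10, ei_reads=1, ie_reads=1)
    assert retention_score([eligible]).ratio == pytest.approx(0.2)

    # < 5 EE reads: excluded entirely even with massive EI signal
    weak = JunctionCounts("g", 1000, 2000, ee_reads=4, ei_reads=100)
    assert retention_score([eligible, weak]).ratio == pytest.approx(0.2)

    # short intron: excluded
    short = JunctionCounts("g", 1000, 1400, ee_reads=50, ei_reads=50)
    assert retention_score([eligible, short]).ratio == pytest.approx(0.2)

    spliced_only = JunctionCounts("g", 1000, 2000, ee_reads=20)
    assert retention_score([spliced_only]).ratio == 0.0

    with pytest.warns(UserWarning, match="no eligible"):
        assert np.isnan(retention_score([weak]).ratio)


def test_adding_unspliced_read_never_decreases_score():
    base = [JunctionCounts("g", 1000, 2000, ee_reads=10, ei_reads=2)]
    s0 = retention_score(base).ratio
    more = [JunctionCounts("g", 1000, 2000, ee_reads=10, ei_reads=3)]
    assert retention_score(more).ratio >= s0


def test_median_split_rules():
    s42 = pd.Series(np.arange(42.0) + 0.5, index=[f"v{i}" for i in range(42)])
    high, low = median_split(s42)
    assert (len(high), len(low)) == (21, 21)

    high, low = median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}))
    assert set(high) == {"c", "d"}

    high, low = median_split(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 2.0}))
    assert set(high) == {"d"} and set(low) == {"a", "b", "c"}

    with pytest.raises(ValueError, match="degenerate"):
        median_split(pd.Series({"a": 1.0, "b": 1.0}))


def test_planted_retention_separates_groups(small_cohort):
    b = small_cohort
    class1 = {g for g, c in b.truth["gene_classes"].items() if c == "I"}
    scores = score_samples(b.sam_paths, b.genes, class1)
    deff = scores[[s for s, l in b.truth["samples"].items() if l == "TEdeff"]]
    prof = scores[[s for s, l in b.truth["samples"].items() if l == "TEprof"]]
    assert deff.median() > prof.median()
    assert deff.min() > prof.max()  # rates 0.12 vs 0.02 separate cleanly
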