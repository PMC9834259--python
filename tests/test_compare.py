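import numpy as np
import pandas as pd
import pytest

from medipdmr import (
    associate_genes,
    dmr_pca,
    extended_overlap,
    rpkm_matrix,
    venn_overlap,
)
from medipdmr.compare import (
    CompareError,
    GeneModel,
    dmr_windows,
    interval_gap,
    read_genes_gff3,
)
from medipdmr.dmr import DMR, call_dmrs

from conftest import make_results


def _dmr(chrom="chr1", start=0, end=1000):
    return DMR(chrom, start, end, 1, 1e-6, 1e-4, 1.0)


def _gene(chrom="chr1", start=0, end=1000, gid="g1"):
    return GeneModel(gid, gid.upper(), chrom, start, end, "+")


# --------------------------------------------------------- gene association


@pytest.mark.parametrize(
    "gene_start,expected_distance,associated",
    [
        (6000, 5000, True),     # gap 5000 <= 10 kb
        (11_000, 10_000, True),  # boundary inclusive
        (16_000, None, False),   # gap 15000
        (500, 0, True),          # overlapping
    ],
)
def test_association_distance_rules(gene_start, expected_distance, associated):
    dmr = _dmr(end=1000)
    gene = _gene(start=gene_start, end=gene_start + 2000)
    assocs = associate_genes([dmr], [gene])
    if associated:
        assert len(assocs) == 1
        assert assocs[0].distance_bp == expected_distance
    else:
        assert assocs == []


def test_association_many_to_many():
    dmrs = [_dmr(end=1000), _dmr(start=3000, end=4000)]
    genes = [_gene(start=1500, end=2500, gid="g1"), _gene(start=5000, end=6000, gid="g2")]
    assocs = associate_genes(dmrs, genes)
    assert len(assocs) == 4  # every pair within 10 kb


def test_association_agrees_with_brute_force():
    rng = np.random.default_rng(77)
    dmrs = [
        _dmr(start=int(s), end=int(s) + 1000)
        for s in rng.integers(0, 200_000, size=30)
    ]
    genes = [
        _gene(start=int(s), end=int(s) + int(l), gid=f"g{i}")
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 200_000, size=30), rng.integers(500, 5000, size=30))
        )
    ]
    got = {(a.dmr_name, a.gene_id, a.distance_bp) for a in associate_genes(dmrs, genes)}
    want = set()
    for d in dmrs:
        for g in genes:
            gap = interval_gap(d.start, d.end, g.start, g.end)
            if gap <= 10_000:
                want.add((d.name, g.gene_id, gap))
    assert got == want


def test_gff3_reader_converts_to_zero_based(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene1;Name=ABC\n"
        "chr1\tsrc\texon\t101\t150\t.\t+\t.\tID=exon1;Parent=gene1\n"
        "chr2\tsrc\tgene\t1\t50\t.\t-\t.\tID=gene2\n"
    )
    genes = read_genes_gff3(gff)
    assert len(genes) == 2  # exon features ignored
    g1 = next(g for g in genes if g.gene_id == "gene1")
    assert (g1.start, g1.end, g1.symbol, g1.strand) == (100, 200, "ABC", "+")
    g2 = next(g for g in genes if g.gene_id == "gene2")
    assert (g2.start, g2.end, g2.strand) == (0, 50, "-")


# -------------------------------------------------------------------- Venn


def test_identical_sets_fully_intersect():
    a = [_dmr(end=1000), _dmr(start=5000, end=6000)]
    report = venn_overlap({"A": a, "B": list(a)})
    assert report.membership["A"] == {("A", "B"): 2}
    assert report.pairwise[("A", "B")] == 2


def test_disjoint_sets_have_no_intersections():
    report = venn_overlap(
        {"A": [_dmr(end=1000)], "B": [_dmr(start=9000, end=10_000)]}
    )
    assert report.membership["A"] == {("A",): 1}
    assert report.pairwise[("A", "B")] == 0


def test_three_set_interval_arithmetic():
    a = [_dmr(start=0, end=1000)]
    b = [_dmr(start=999, end=2000)]
    c = [_dmr(start=5000, end=6000)]
    report = venn_overlap({"A": a, "B": b, "C": c})
    assert report.pairwise[("A", "B")] == 1
    assert report.pairwise[("A", "C")] == 0
    assert report.pairwise[("B", "C")] == 0
    assert report.membership["A"] == {("A", "B"): 1}
    assert report.membership["C"] == {("C",): 1}


def test_venn_set_count_bounds():
    sets = {k: [_dmr()] for k in "ABCDE"}
    with pytest.raises(CompareError):
        venn_overlap(sets)
    with pytest.raises(CompareError):
        venn_overlap({"A": [_dmr()]})


def test_membership_counts_sum_to_set_sizes():
    rng = np.random.default_rng(8)
    sets = {
        name: [
            _dmr(start=int(s) * 1000, end=int(s) * 1000 + 1000)
            for s in rng.integers(0, 50, size=20)
        ]
        for name in "AB"
    }
    report = venn_overlap(sets)
    for name in sets:
        assert sum(report.membership[name].values()) == report.set_sizes[name]


# -------------------------------------------------------- extended overlap


def test_extended_overlap_of_set_with_its_own_relaxed_results():
    res = make_results([0.9, 1e-6, 0.04, 0.9, 0.9, 1e-7, 0.9])
    strict = call_dmrs(res)
    count, pct = extended_overlap(strict, res)
    assert count == len(strict)
    assert pct == 100.0


def test_extended_overlap_zero_when_nothing_relaxed():
    strict = [_dmr()]
    res = make_results([0.9, 0.8, 0.7])
    count, pct = extended_overlap(strict, res)
    assert (count, pct) == (0, 0.0)


def test_extended_overlap_empty_strict_warns():
    with pytest.warns(UserWarning):
        count, pct = extended_overlap([], make_results([0.01]))
    assert (count, pct) == (0, 0.0)


def test_extension_is_monotone_in_threshold():
    # relaxing the seed can only add overlapping regions
    rng = np.random.default_rng(12)
    p = 10.0 ** rng.uniform(-8, 0, size=200)
    res = make_results([float(x) for x in p])
    strict = call_dmrs(res)
    c_strict, _ = extended_overlap(strict, res, p_relaxed=1e-5)
    c_relaxed, _ = extended_overlap(strict, res, p_relaxed=0.05)
    assert c_relaxed >= c_strict


# ------------------------------------------------------------------- RPKM


def _count_matrix(counts, libs, window_lengths=None):
    from medipdmr.windows import CountMatrix, GenomicWindow

    counts = np.asarray(counts)
    if window_lengths is None:
        window_lengths = [1000] * counts.shape[0]
    windows, pos = [], 0
    for i, l in enumerate(window_lengths):
        windows.append(GenomicWindow("chr1", pos, pos + l, i))
        pos += l
    samples = [f"s{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        windows, samples, counts, np.asarray(libs), {s: "g" for s in samples}
    )


def test_rpkm_definitional_values():
    m = _count_matrix([[10], [10]], [1_000_000], window_lengths=[1000, 500])
    rpkm = rpkm_matrix(m)
    assert rpkm.iloc[0, 0] == pytest.approx(10.0)
    assert rpkm.iloc[1, 0] == pytest.approx(20.0)  # 500 bp partial window


def test_rpkm_invariant_to_proportional_depth():
    m1 = _count_matrix([[10], [30]], [1_000_000])
    m2 = _count_matrix([[20], [60]], [2_000_000])
    assert np.allclose(rpkm_matrix(m1).to_numpy(), rpkm_matrix(m2).to_numpy())


def test_rpkm_conservation_identity():
    # sum_w RPKM(w,s) * length_kb(w) == 1e6 exactly when counts sum to library
    rng = np.random.default_rng(3)
    counts = rng.poisson(25, size=(40, 3))
    m = _count_matrix(counts, counts.sum(axis=0), window_lengths=[1000] * 39 + [400])
    rpkm = rpkm_matrix(m)
    lengths_kb = np.array([w.length for w in m.windows]) / 1000
    totals = (rpkm.to_numpy() * lengths_kb[:, None]).sum(axis=0)
    assert totals == pytest.approx(np.full(3, 1e6), rel=1e-12)


def test_rpkm_zero_library_rejected():
    m = _count_matrix([[0], [0]], [0])
    with pytest.raises(CompareError):
        rpkm_matrix(m)


def test_rpkm_unknown_window_rejected(small_sim):
    _, matrix, _ = small_sim
    from medipdmr.windows import GenomicWindow

    with pytest.raises(CompareError):
        rpkm_matrix(matrix, [GenomicWindow("chrZ", 0, 1000, 0)])


# -------------------------------------------------------------------- PCA


def test_identical_samples_give_zero_scores():
    rpkm = pd.DataFrame(
        np.tile(np.arange(5, dtype=float)[:, None], (1, 4)),
        columns=list("abcd"),
    )
    scores, evr = dmr_pca(rpkm)
    assert np.allclose(scores.to_numpy(), 0)
    assert np.allclose(evr, 0)


def test_explained_variance_fractions_ordered():
    rng = np.random.default_rng(10)
    rpkm = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"s{i}" for i in range(6)])
    _, evr = dmr_pca(rpkm)
    assert evr[0] >= evr[1] >= 0
    assert evr.sum() <= 1 + 1e-12


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(11)
    rpkm = pd.DataFrame(rng.normal(size=(15, 5)), columns=list("abcde"))
    s1, _ = dmr_pca(rpkm)
    s2, _ = dmr_pca(rpkm.copy())
    assert np.allclose(s1.to_numpy(), s2.to_numpy())


def test_pca_needs_three_samples():
    with pytest.raises(CompareError):
        dmr_pca(pd.DataFrame(np.ones((5, 2)), columns=["a", "b"]))


def test_groups_separate_on_spiked_windows(small_sim):
    genome, matrix, truth = small_sim
    dmrs = [DMR(c, s, e, 1, 1e-9, 1e-6, lfc) for c, s, e, lfc in truth.regions]
    windows = dmr_windows(matrix, dmrs)
    rpkm = rpkm_matrix(matrix, windows)
    scores, _ = dmr_pca(rpkm)
    from sklearn.linear_model import Perceptron

    labels = [matrix.design[s] for s in scores.index]
    clf = Perceptron(max_iter=2000, tol=None, random_state=0)
    clf.fit(scores.to_numpy(), labels)
    assert clf.score(scores.to_numpy(), labels) == 1.0
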