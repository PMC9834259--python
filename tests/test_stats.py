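import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats as sps

from medipdmr import (
    bh_fdr,
    estimate_common_dispersion,
    exact_test,
    generate_genome,
    simulate_counts,
    tmm_factors,
    filter_windows,
    SimulationConfig,
)
from medipdmr.stats import (
    NormalizationError,
    PValueError,
    nb_conditional_pvalue,
    resolve_groups,
)
from medipdmr.windows import CountMatrix, GenomicWindow


def matrix_from(counts, groups=None, libs=None):
    counts = np.asarray(counts)
    n_w, n_s = counts.shape
    windows = [GenomicWindow("chr1", i * 1000, (i + 1) * 1000, i) for i in range(n_w)]
    samples = [f"s{j}" for j in range(n_s)]
    if groups is None:
        groups = ["case"] * (n_s // 2) + ["control"] * (n_s - n_s // 2)
    libs = counts.sum(axis=0) if libs is None else np.asarray(libs)
    return CountMatrix(windows, samples, counts, libs, dict(zip(samples, groups)))


# ------------------------------------------------------------------- TMM


def test_identical_columns_give_unit_factors():
    rng = np.random.default_rng(1)
    col = rng.poisson(30, size=100)
    m = matrix_from(np.tile(col[:, None], (1, 4)))
    assert tmm_factors(m).factors == pytest.approx(np.ones(4), abs=1e-12)


def test_pure_library_scaling_is_fully_compensated():
    rng = np.random.default_rng(2)
    col = rng.poisson(50, size=500)
    counts = np.tile(col[:, None], (1, 4))
    counts[:, 0] *= 2  # no composition change, only depth
    m = matrix_from(counts)
    f = tmm_factors(m)
    eff = f.effective_library_sizes(m.library_sizes)
    # the doubled sample's effective library size doubles, so normalized
    # means line up with the other samples again
    norm_means = (m.counts / eff).mean(axis=0)
    assert norm_means == pytest.approx(np.full(4, norm_means[1]), rel=1e-6)
    assert eff[0] == pytest.approx(2 * eff[1], rel=1e-6)


def test_factors_scale_invariant():
    rng = np.random.default_rng(3)
    counts = rng.negative_binomial(5, 0.3, size=(300, 5))
    f1 = tmm_factors(matrix_from(counts))
    f2 = tmm_factors(matrix_from(counts * 10))
    assert f1.factors == pytest.approx(f2.factors, rel=1e-9)


def test_factors_have_unit_geometric_mean():
    rng = np.random.default_rng(4)
    counts = rng.negative_binomial(8, 0.4, size=(400, 6))
    counts[:, 1] = (counts[:, 1] * 1.7).astype(int)
    f = tmm_factors(matrix_from(counts))
    assert np.exp(np.mean(np.log(f.factors))) == pytest.approx(1.0, abs=1e-9)


def test_tmm_needs_two_samples():
    with pytest.raises(NormalizationError):
        tmm_factors(matrix_from(np.ones((10, 1), dtype=int), groups=["g"]))


# ------------------------------------------------- brute-force oracles


def brute_force_p(y1, y2, n1, n2, phi, mu=3.7):
    """Enumerate the conditional distribution from unconditional NB pmfs.

    Any positive mu gives the same conditional law; the arbitrary value
    checks that independence explicitly.
    """
    s = y1 + y2
    o = np.arange(s + 1)
    if phi == 0:
        f1 = sps.poisson.pmf(o, n1 * mu)
        f2 = sps.poisson.pmf(s - o, n2 * mu)
    else:
        r1, r2 = n1 / phi, n2 / phi
        f1 = sps.nbinom.pmf(o, r1, r1 / (r1 + n1 * mu))
        f2 = sps.nbinom.pmf(s - o, r2, r2 / (r2 + n2 * mu))
    joint = f1 * f2
    joint /= joint.sum()
    return float(joint[joint <= joint[y1] * (1 + 1e-10)].sum())


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
def test_exact_p_matches_enumeration_oracle(phi):
    for s in range(0, 26):
        for y1 in range(s + 1):
            got = nb_conditional_pvalue(y1, s - y1, 2, 2, phi)
            want = brute_force_p(y1, s - y1, 2, 2, phi)
            assert got == pytest.approx(want, abs=1e-12)


def test_unequal_group_sizes_against_oracle():
    for y1, y2 in [(0, 9), (5, 5), (12, 3), (20, 40)]:
        got = nb_conditional_pvalue(y1, y2, 3, 5, 0.2)
        want = brute_force_p(y1, y2, 3, 5, 0.2)
        assert got == pytest.approx(want, abs=1e-12)


def test_phi_zero_limit_equals_conditional_binomial():
    for y1, y2 in [(3, 17), (10, 10), (0, 5)]:
        tiny = nb_conditional_pvalue(y1, y2, 4, 4, 1e-8)
        binom = nb_conditional_pvalue(y1, y2, 4, 4, 0.0)
        assert tiny == pytest.approx(binom, abs=1e-6)


def test_balanced_equal_totals_give_p_one():
    assert nb_conditional_pvalue(7, 7, 2, 2, 0.1) == pytest.approx(1.0)
    assert nb_conditional_pvalue(0, 0, 2, 2, 0.1) == 1.0


def test_p_monotone_in_imbalance():
    s = 30
    ps = [nb_conditional_pvalue(y1, s - y1, 2, 2, 0.1) for y1 in range(15, 31)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_exact_test_symmetry_under_label_swap(filtered_small):
    m = filtered_small
    f = tmm_factors(m)
    res1 = exact_test(m, f, 0.1, "case", "control")
    res2 = exact_test(m, f, 0.1, "control", "case")
    assert res1["p_value"].to_numpy() == pytest.approx(
        res2["p_value"].to_numpy(), rel=1e-12
    )
    assert res1["log2fc"].to_numpy() == pytest.approx(
        -res2["log2fc"].to_numpy(), abs=1e-12
    )


def test_zero_total_window_gets_p_one_and_zero_lfc():
    counts = np.array([[0, 0, 0, 0], [30, 30, 30, 30]])
    m = matrix_from(counts)
    res = exact_test(m, phi=0.1)
    assert res.loc[0, "p_value"] == 1.0
    assert res.loc[0, "log2fc"] == 0.0


def test_fdr_column_dominates_p(filtered_small):
    res = exact_test(filtered_small, phi=0.1)
    assert (res["fdr"] >= res["p_value"] - 1e-15).all()


def test_resolve_groups_prefers_control_label(filtered_small):
    assert resolve_groups(filtered_small) == ("case", "control")


# -------------------------------------------------------------- edgeR


def test_exact_p_and_tmm_match_edger(tmp_path):
    """Independent cross-check against the Bioconductor implementation."""
    rng = np.random.default_rng(9)
    counts = rng.negative_binomial(10, 0.25, size=(120, 4))
    counts[:3] = [[10, 12, 30, 28], [5, 7, 6, 8], [0, 1, 2, 3]]
    np.savetxt(tmp_path / "c.tsv", counts, fmt="%d", delimiter="\t")
    script = tmp_path / "check.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            counts <- as.matrix(read.table("c.tsv"))
            group <- factor(c("case","case","control","control"),
                            levels=c("control","case"))
            d <- DGEList(counts=counts, group=group, lib.size=rep(1e5, 4))
            d$samples$norm.factors <- 1
            et <- exactTest(d, dispersion=0.1, rejection.region="smallp")
            cat(sprintf("%.15g\\n", et$table$PValue))
            cat("FACTORS\\n")
            cat(sprintf("%.12g\\n", calcNormFactors(counts, method="TMM")))
            """
        )
    )
    out = subprocess.run(
        ["Rscript", str(script)], cwd=tmp_path, capture_output=True, text=True
    )
    assert out.returncode == 0, out.stderr
    lines = out.stdout.split()
    split = lines.index("FACTORS")
    edger_p = np.array([float(x) for x in lines[:split]])
    edger_f = np.array([float(x) for x in lines[split + 1 :]])

    ours = np.array(
        [
            nb_conditional_pvalue(int(r[0] + r[1]), int(r[2] + r[3]), 2, 2, 0.1)
            for r in counts
        ]
    )
    assert ours == pytest.approx(edger_p, rel=1e-9, abs=1e-12)

    m = matrix_from(counts)
    assert tmm_factors(m).factors == pytest.approx(edger_f, rel=1e-9)


# -------------------------------------------------------- dispersion


def test_dispersion_recovery_small():
    cfg = SimulationConfig(
        n_chromosomes=1,
        chromosome_length=2_000_000,
        n_case_samples=10,
        n_control_samples=10,
        n_spiked_regions=0,
        dispersion=0.1,
        rng_seed=21,
    )
    g = generate_genome(cfg)
    m, _ = simulate_counts(g, cfg)
    m = filter_windows(m)
    est = estimate_common_dispersion(m, tmm_factors(m))
    assert 0.05 <= est.phi <= 0.2


def test_poisson_data_yield_near_zero_dispersion():
    cfg = SimulationConfig(
        n_chromosomes=1,
        chromosome_length=1_000_000,
        n_case_samples=10,
        n_control_samples=10,
        n_spiked_regions=0,
        dispersion=0.0,
        rng_seed=22,
    )
    g = generate_genome(cfg)
    m, _ = simulate_counts(g, cfg)
    m = filter_windows(m)
    est = estimate_common_dispersion(m, tmm_factors(m))
    assert est.phi <= 0.02


def test_all_zero_group_still_estimates_finite_phi():
    from medipdmr.stats import NormalizationFactors

    counts = np.zeros((50, 4), dtype=int)
    counts[:, 2:] = np.random.default_rng(5).poisson(20, size=(50, 2))
    m = matrix_from(counts, libs=[1000, 1000, 1000, 1000])
    unit = NormalizationFactors(tuple(m.samples), np.ones(4))
    est = estimate_common_dispersion(m, unit)
    assert np.isfinite(est.phi) and est.phi >= 0


# --------------------------------------------------------------- BH FDR


def test_bh_hand_example():
    adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_constant():
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])


def test_bh_dominates_raw_and_is_permutation_consistent():
    rng = np.random.default_rng(6)
    p = rng.uniform(0.001, 1, size=50)
    adj = bh_fdr(p)
    assert (adj >= p - 1e-15).all() and (adj <= 1).all()
    perm = rng.permutation(50)
    assert bh_fdr(p[perm]) == pytest.approx(adj[perm])


@pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan]])
def test_bh_rejects_out_of_range(bad):
    with pytest.raises(PValueError):
        bh_fdr(bad)
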