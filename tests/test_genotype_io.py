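"""VCF round-trips, SNP/genotype filtering, MAF, pruning and assignment."""

import numpy as np
import pandas as pd
import pytest

from deltapop.core import LOCUS_COLUMNS, GenotypeMatrix
from deltapop.genotype_io import (
    FilterThresholds,
    assign_subpopulations,
    filter_by_maf,
    filter_snps,
    ld_prune,
    minor_allele_frequency,
    read_vcf,
    regroup_q_matrix,
    write_vcf,
)


def make_matrix(genotypes, gq=None, dp=None, qual=500.0, mq=55.0, sb=0.5, edb=0.5):
    """Small helper: wrap a genotype array with clean locus metadata."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    loci = pd.DataFrame(
        {
            "chrom": ["Chr01"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "qual": np.broadcast_to(qual, m).astype(float),
            "mq": np.broadcast_to(mq, m).astype(float),
            "strand_bias_p": np.broadcast_to(sb, m).astype(float),
            "end_dist_bias_p": np.broadcast_to(edb, m).astype(float),
            "gene_id": [f"g{j}" for j in range(m)],
            "region_class": ["genic"] * m,
        },
        columns=LOCUS_COLUMNS,
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        loci=loci,
        genotypes=g,
        gq=None if gq is None else np.asarray(gq, dtype=np.int16),
        dp=None if dp is None else np.asarray(dp, dtype=np.int16),
    )


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------


def test_vcf_round_trip_small_fixture(tmp_path):
    m = make_matrix([[0, 2], [1, -1], [2, 0]], gq=[[99, 50], [40, 30], [60, 70]], dp=[[20, 9], [15, 30], [8, 40]])
    path = tmp_path / "toy.vcf"
    write_vcf(m, str(path))
    back = read_vcf(str(path))
    assert back.samples == m.samples
    np.testing.assert_array_equal(back.genotypes, m.genotypes)
    np.testing.assert_array_equal(back.gq, m.gq)
    np.testing.assert_array_equal(back.dp, m.dp)
    assert list(back.loci["pos"]) == list(m.loci["pos"])
    assert list(back.loci["gene_id"]) == list(m.loci["gene_id"])


def test_missing_genotype_round_trip(tmp_path):
    m = make_matrix([[-1], [1], [0]])
    path = tmp_path / "miss.vcf"
    write_vcf(m, str(path))
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert body[0].split("\t")[9].startswith("./.")
    back = read_vcf(str(path))
    assert back.genotypes[0, 0] == -1


def test_synthetic_cohort_round_trip(tmp_path, small_cohort):
    _cfg, (matrix, _r, _e, _t) = small_cohort
    p1 = tmp_path / "cohort.vcf"
    p2 = tmp_path / "cohort2.vcf"
    write_vcf(matrix, str(p1))
    back = read_vcf(str(p1))
    np.testing.assert_array_equal(back.genotypes, matrix.genotypes)
    # write -> read -> write is byte-stable
    write_vcf(back, str(p2))
    assert p1.read_text() == p2.read_text()


def test_multiallelic_records_dropped_or_rejected(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
        "Chr01\t100\t.\tA\tG\t99\tPASS\tGENE=g1\tGT\t0/1\n"
        "Chr01\t200\t.\tA\tG,T\t99\tPASS\tGENE=g1\tGT\t1/2\n"
    )
    path = tmp_path / "multi.vcf"
    path.write_text(text)
    m = read_vcf(str(path))
    assert m.n_loci == 1
    with pytest.raises(ValueError, match="multi-allelic"):
        read_vcf(str(path), multiallelic="error")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def test_genotype_masking_boundaries():
    # GQ = 20 and DP = 8 is retained; DP = 7 is set missing
    m = make_matrix(
        [[1], [1]],
        gq=[[20], [20]],
        dp=[[8], [7]],
    )
    out, _rep = filter_snps(m, FilterThresholds(max_missing=1.0))
    assert out.genotypes[0, 0] == 1
    assert out.genotypes[1, 0] == -1


def test_missingness_boundary_25_percent():
    # 100 samples: 25 missing kept (<= 25%), 26 missing dropped (> 25%)
    g = np.ones((100, 2), dtype=np.int8)
    g[:25, 0] = -1
    g[:26, 1] = -1
    m = make_matrix(g)
    out, rep = filter_snps(m)
    assert out.n_loci == 1
    assert rep.removed["missingness"] == 1


def test_crafted_fixture_one_violation_per_rule():
    """10 loci, one violating each rule in turn -> exactly 6 dropped and the
    report names the rule that fired for each."""
    n = 20
    g = np.ones((n, 10), dtype=np.int8)
    gq = np.full((n, 10), 99, dtype=np.int16)
    dp = np.full((n, 10), 30, dtype=np.int16)
    qual = np.full(10, 500.0)
    mq = np.full(10, 55.0)
    sb = np.full(10, 0.5)
    edb = np.full(10, 0.5)
    qual[0] = 49.0  # site quality
    mq[1] = 29.0  # mapping quality
    sb[2] = 1e-6  # strand bias
    edb[3] = 1e-6  # end-distance bias
    g[:6, 4] = -1  # direct missingness 30%
    gq[:6, 5] = 10  # masking pushes locus 5 over the missingness limit
    m = make_matrix(g, gq=gq, dp=dp, qual=qual, mq=mq, sb=sb, edb=edb)
    out, rep = filter_snps(m)
    assert out.n_loci == 4
    assert rep.removed == {
        "site_quality": 1,
        "mapping_quality": 1,
        "strand_bias": 1,
        "end_distance_bias": 1,
        "missingness": 2,
    }
    fired = dict(zip(rep.fired["locus"], rep.fired["rule"]))
    assert fired["Chr01:100"] == "site_quality"
    assert fired["Chr01:200"] == "mapping_quality"
    assert fired["Chr01:300"] == "strand_bias"
    assert fired["Chr01:400"] == "end_distance_bias"
    assert fired["Chr01:500"] == "missingness"
    assert fired["Chr01:600"] == "missingness"


def test_masking_before_missingness_order_is_observable():
    """Locus 5 of the crafted fixture survives if masking is skipped:
    swapping the order changes the surviving locus count."""
    n = 20
    g = np.ones((n, 1), dtype=np.int8)
    gq = np.full((n, 1), 99, dtype=np.int16)
    gq[:6, 0] = 10  # 30% of genotypes fail GQ
    m = make_matrix(g, gq=gq, dp=np.full((n, 1), 30, dtype=np.int16))
    out, _ = filter_snps(m)
    assert out.n_loci == 0  # masked first -> 30% missing -> dropped
    # without masking the locus has no missing calls at all
    out2, _ = filter_snps(
        make_matrix(g), FilterThresholds()
    )
    assert out2.n_loci == 1


def test_filter_idempotence(small_cohort):
    _cfg, (matrix, _r, _e, _t) = small_cohort
    once, _ = filter_snps(matrix)
    twice, rep = filter_snps(once)
    assert twice.n_loci == once.n_loci
    np.testing.assert_array_equal(twice.genotypes, once.genotypes)
    assert sum(rep.removed.values()) == 0


def test_and_mask_rule_differs():
    m = make_matrix([[1], [1]], gq=[[10], [99]], dp=[[30], [5]])
    out_or, _ = filter_snps(m, FilterThresholds(max_missing=1.0, mask_rule="or"))
    out_and, _ = filter_snps(m, FilterThresholds(max_missing=1.0, mask_rule="and"))
    assert (out_or.genotypes == -1).sum() == 2
    assert (out_and.genotypes == -1).sum() == 0


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def test_maf_direct_count():
    m = make_matrix([[0], [0], [1], [2]])
    assert minor_allele_frequency(m)[0] == pytest.approx(3 / 8)


def test_monomorphic_removed_at_any_positive_cutoff():
    m = make_matrix([[0], [0], [0]])
    assert minor_allele_frequency(m)[0] == 0.0
    assert filter_by_maf(m, 0.001).n_loci == 0


def test_maf_against_brute_force(rng):
    g = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
    g[rng.random(g.shape) < 0.15] = -1
    m = make_matrix(g)
    maf = minor_allele_frequency(m)
    for j in range(30):
        col = g[:, j][g[:, j] >= 0]
        p = col.sum() / (2 * len(col))
        assert maf[j] == pytest.approx(min(p, 1 - p), abs=1e-12)


def test_maf_strictness_convention():
    # 4 samples, one het -> MAF exactly 0.125
    m = make_matrix([[0], [0], [0], [1]])
    assert filter_by_maf(m, 0.125, keep="greater").n_loci == 0
    assert filter_by_maf(m, 0.125, keep="geq").n_loci == 1


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def test_prune_keeps_first_of_perfect_pair(rng):
    a = rng.integers(0, 3, size=100).astype(np.int8)
    m = make_matrix(np.column_stack([a, a]))
    kept = ld_prune(m, r2_threshold=0.8)
    assert list(kept) == [0]


def test_prune_keeps_independent_loci(rng):
    g = np.column_stack(
        [(rng.random(400) < 0.5).astype(np.int8) + (rng.random(400) < 0.5) for _ in range(4)]
    ).astype(np.int8)
    m = make_matrix(g)
    kept = ld_prune(m, r2_threshold=0.8)
    assert list(kept) == [0, 1, 2, 3]


def test_prune_matches_hand_run_greedy(rng):
    """5 loci with a known correlation layout: the greedy scan keeps
    0 (first), drops 1 (copy of 0), keeps 2, drops 3 (copy of 2), keeps 4."""
    a = (rng.random(600) < 0.5).astype(np.int8)
    b = (rng.random(600) < 0.5).astype(np.int8)
    c = (rng.random(600) < 0.5).astype(np.int8)
    hap = np.column_stack([a, a, b, b, c])
    g = (hap[0::2] + hap[1::2]).astype(np.int8)
    m = make_matrix(g)
    kept = ld_prune(m, r2_threshold=0.8)
    assert list(kept) == [0, 2, 4]


# ---------------------------------------------------------------------------
# subpopulation assignment
# ---------------------------------------------------------------------------


def test_assignment_examples():
    q = pd.DataFrame(
        {"pop1": [0.85, 0.5, 0.80], "pop2": [0.15, 0.5, 0.20]},
        index=["a", "b", "c"],
    )
    asg = assign_subpopulations(q, cutoff=0.8, strict=True)
    assert asg.labels["a"] == "pop1"
    assert asg.labels["b"] == "admixed"
    # "above 80%" read strictly: exactly 0.80 is admixed
    assert asg.labels["c"] == "admixed"
    lax = assign_subpopulations(q, cutoff=0.8, strict=False)
    assert lax.labels["c"] == "pop1"


def test_assignment_rejects_malformed_q():
    bad_sum = pd.DataFrame({"pop1": [0.7], "pop2": [0.2]}, index=["a"])
    with pytest.raises(ValueError, match="sum to 1"):
        assign_subpopulations(bad_sum)
    negative = pd.DataFrame({"pop1": [1.2], "pop2": [-0.2]}, index=["a"])
    with pytest.raises(ValueError, match="non-negative"):
        assign_subpopulations(negative)


def test_hierarchical_regrouping_excludes_unlisted_pop():
    q = pd.DataFrame(
        {
            "west": [0.5, 0.1, 0.05],
            "west_mr": [0.4, 0.1, 0.05],
            "center": [0.05, 0.7, 0.0],
            "east": [0.05, 0.1, 0.9],
        },
        index=["w", "c", "e"],
    )
    merged = regroup_q_matrix(q, {"west_k2": ["west", "west_mr"], "east_k2": ["east"]})
    asg = assign_subpopulations(merged, cutoff=0.8)
    assert asg.labels["w"] == "west_k2"  # 0.9 merged coefficient
    assert asg.labels["e"] == "east_k2"
    assert asg.labels["c"] == "admixed"  # center-dominated sample drops out
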