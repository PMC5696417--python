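"""Environmental association: variable selection, latent-factor scan,
deme grouping, Bayes factors and the top-quantile intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from deltapop.differentiation import OmegaMatrix
from deltapop.eaa import (
    bayes_factor_scan,
    bayes_factor_single,
    bonferroni_threshold,
    group_demes,
    lfmm_scan,
    select_env_variables,
    top_intersection,
)
from deltapop.simulate import SimulationConfig, simulate_cohort


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------


def test_orthogonal_variables_all_selected():
    # four exactly orthogonal variables (Fourier basis): no redundancy to
    # remove, so the four PCs select four distinct variables
    n = 256
    t = np.arange(n)
    env = pd.DataFrame(
        {f"v{k + 1}": np.sin(2 * np.pi * (k + 1) * t / n) for k in range(4)}
    )
    selected, prov = select_env_variables(env, {"g": ["v1", "v2", "v3", "v4"]})
    assert sorted(selected) == ["v1", "v2", "v3", "v4"]
    assert set(prov["pc"]) == {1, 2, 3, 4}


def test_duplicate_variable_collapses_to_first():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(100, 4))
    env = pd.DataFrame(base, columns=["a", "b", "c", "d"])
    env["a_copy"] = env["a"]  # exact duplicate
    selected, _ = select_env_variables(env, {"g": ["a", "a_copy", "b", "c", "d"]})
    assert "a_copy" not in selected
    assert "a" in selected


def test_constant_variable_dropped():
    rng = np.random.default_rng(1)
    env = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    env["flat"] = 3.0
    selected, _ = select_env_variables(env, {"g": ["flat", "a", "b", "c", "d"]})
    assert "flat" not in selected


def test_selection_matches_eigen_oracle(small_cohort):
    from deltapop.simulate import env_variable_groups

    _cfg, (_m, _r, env, _t) = small_cohort
    groups = env_variable_groups()
    selected, prov = select_env_variables(env, groups)
    # oracle: eigen-decomposition of the correlation matrix per group
    for group, cols in groups.items():
        block = env[cols].to_numpy()
        z = (block - block.mean(0)) / block.std(0)
        vals, vecs = np.linalg.eigh(np.corrcoef(z.T))
        order = np.argsort(vals)[::-1]
        for pc in range(4):
            contrib = vecs[:, order[pc]] ** 2
            expected = cols[int(np.argmax(contrib))]
            got = prov[(prov["group"] == group) & (prov["pc"] == pc + 1)]
            assert got["variable"].iloc[0] == expected
        var4 = vals[order][:4].sum() / vals.sum()
        assert prov[prov["group"] == group]["var_explained_npcs"].iloc[0] == pytest.approx(
            var4, abs=1e-6
        )
        assert var4 > 0.9  # redundancy built into the generator


# ---------------------------------------------------------------------------
# latent-factor scan
# ---------------------------------------------------------------------------


def _no_structure_matrix(rng, n=120, m=300):
    from deltapop.core import LOCUS_COLUMNS, GenotypeMatrix

    p = rng.uniform(0.1, 0.9, size=m)
    g = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    loci = pd.DataFrame(
        {
            "chrom": "Chr01",
            "pos": np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
            "qual": 500.0,
            "mq": 55.0,
            "strand_bias_p": 0.5,
            "end_dist_bias_p": 0.5,
            "gene_id": [f"g{j}" for j in range(m)],
            "region_class": "genic",
        },
        columns=LOCUS_COLUMNS,
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], loci=loci, genotypes=g)


def test_k_zero_equals_ols_t_statistic(rng):
    m = _no_structure_matrix(rng)
    env = rng.normal(size=m.n_samples)
    res = lfmm_scan(m, env, k=0, n_runs=1, seed=1)
    # oracle: per-locus OLS t statistic for the env slope
    x = np.column_stack([np.ones(m.n_samples), (env - env.mean()) / env.std()])
    xtx_inv = np.linalg.inv(x.T @ x)
    g = m.genotypes.astype(float)
    g = g - g.mean(0)
    beta = xtx_inv @ x.T @ g
    resid = g - x @ beta
    sigma2 = (resid**2).sum(0) / (m.n_samples - 2)
    t = beta[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
    np.testing.assert_allclose(res.table["z"].to_numpy(), t, atol=1e-8)


def test_null_scan_calibrated(rng):
    m = _no_structure_matrix(rng, n=150, m=500)
    env = rng.normal(size=m.n_samples)
    res = lfmm_scan(m, env, k=2, n_runs=5, seed=2)
    assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01
    assert res.table["significant"].sum() == 0


def test_scan_is_deterministic(small_cohort):
    _cfg, (matrix, _r, env, truth) = small_cohort
    z1 = lfmm_scan(matrix, env["tmin_coldest"].to_numpy(), seed=11).table["z"]
    z2 = lfmm_scan(matrix, env["tmin_coldest"].to_numpy(), seed=11).table["z"]
    np.testing.assert_array_equal(z1.to_numpy(), z2.to_numpy())


def test_scan_input_validation(rng):
    m = _no_structure_matrix(rng, n=30, m=40)
    with pytest.raises(ValueError, match="K must be smaller"):
        lfmm_scan(m, rng.normal(size=30), k=30)
    env = rng.normal(size=30)
    env[3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        lfmm_scan(m, env)


def test_bonferroni_threshold_exact():
    assert bonferroni_threshold(0.01, 114_261) == 0.01 / 114_261
    with pytest.raises(ValueError):
        bonferroni_threshold(0.01, 0)


# ---------------------------------------------------------------------------
# demes
# ---------------------------------------------------------------------------


def _coords_frame(rng, n):
    return pd.DataFrame(
        {
            "lat": rng.uniform(28, 36, n),
            "lon": rng.uniform(-96, -78, n),
            "altitude": rng.uniform(0, 300, n),
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_singleton_demes_reproduce_sample_env(rng):
    coords = _coords_frame(rng, 12)
    env = pd.DataFrame({"v": rng.normal(size=12)}, index=coords.index)
    demes = group_demes(coords, env, ["v"], k=12, seed=0)
    assert demes.n_demes == 12
    # per-deme standardized env equals the standardized sample values
    sample_z = (env["v"] - env["v"].mean()) / env["v"].std(ddof=0)
    deme_of = demes.deme_of_sample
    got = demes.env.loc[deme_of.to_numpy(), "v"].to_numpy()
    np.testing.assert_allclose(got, sample_z.to_numpy(), atol=1e-9)


def test_single_deme_rejected(rng):
    coords = _coords_frame(rng, 10)
    env = pd.DataFrame({"v": rng.normal(size=10)}, index=coords.index)
    with pytest.raises(ValueError, match="at least 2"):
        group_demes(coords, env, ["v"], k=1)
    with pytest.raises(ValueError, match="exceeds"):
        group_demes(coords, env, ["v"], k=11)


def test_two_separated_clusters_recovered(rng):
    a = _coords_frame(rng, 10)
    b = _coords_frame(rng, 10)
    b["lon"] += 60  # far away
    coords = pd.concat([a, b])
    coords.index = [f"s{i}" for i in range(20)]
    env = pd.DataFrame({"v": rng.normal(size=20)}, index=coords.index)
    demes = group_demes(coords, env, ["v"], k=2, seed=0)
    labels = demes.deme_of_sample.to_numpy()
    assert len(set(labels[:10])) == 1
    assert len(set(labels[10:])) == 1
    assert labels[0] != labels[10]


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------


def test_bayes_factor_matches_quadrature_oracle():
    """Closed form equals numerical integration over the slope prior."""
    y = np.array([0.8, -0.3])
    e = np.array([1.0, -1.0])
    tau = 1.3

    def like(beta):
        r = y - beta * e
        return np.exp(-0.5 * r @ r) * stats.norm.pdf(beta, 0, tau)

    num, _ = integrate.quad(like, -15, 15)
    den = np.exp(-0.5 * y @ y)
    oracle = num / den
    got = bayes_factor_single(y, e, prior_sd=tau)
    assert got == pytest.approx(oracle, abs=1e-6)


def test_monotone_frequencies_give_unit_rho():
    P = 12
    freqs = np.linspace(0.2, 0.8, P)[None, :]
    n_chrom = np.full((1, P), 40)
    om = OmegaMatrix(labels=[str(i) for i in range(P)], values=np.eye(P), n_loci=100)
    env = np.linspace(-2, 2, P) ** 3  # strictly increasing, nonlinear
    tab = bayes_factor_scan(freqs, n_chrom, om, env, top_q=0.5)
    assert tab["rho"].iloc[0] == pytest.approx(1.0)


def test_constant_env_rejected():
    om = OmegaMatrix(labels=["a", "b"], values=np.eye(2), n_loci=10)
    with pytest.raises(ValueError, match="constant"):
        bayes_factor_scan(
            np.array([[0.4, 0.6]]), np.array([[20, 20]]), om, np.array([1.0, 1.0])
        )


def test_permuted_env_top_lists_are_exactly_one_percent(rng):
    """Under a permuted environment each top list has exactly ceil(q*L) loci
    by the quantile rule."""
    P, L = 40, 500
    freqs = rng.uniform(0.2, 0.8, size=(L, P))
    n_chrom = np.full((L, P), 20)
    om = OmegaMatrix(labels=[str(i) for i in range(P)], values=np.eye(P), n_loci=100)
    env = rng.permutation(np.linspace(-2, 2, P))
    tab = bayes_factor_scan(freqs, n_chrom, om, env, top_q=0.01)
    picked = top_intersection(tab, q=0.01)
    n_top = int(np.ceil(0.01 * L))
    assert len(picked) <= n_top
    assert (np.abs(tab["rho"]) < 0.6).all()
    # under the null the conjugate Bayes factor centers at its Occam
    # penalty -0.5 log(1 + tau^2 |e|^2), i.e. below 1
    log_bf = np.log(tab["bayes_factor"])
    assert np.median(log_bf) < 0
    assert np.median(log_bf) > -0.5 * np.log1p(1.0 * P) - 0.5
    # and each single-variable top list holds exactly ceil(q L) loci
    bf_top = (tab["bayes_factor"] >= np.sort(tab["bayes_factor"])[-n_top]).sum()
    assert bf_top == n_top


# ---------------------------------------------------------------------------
# top intersection
# ---------------------------------------------------------------------------


def test_identical_ranks_intersection_size():
    L = 500
    bf = np.linspace(1, 2, L)
    tab = pd.DataFrame({"bayes_factor": bf, "rho": bf / 10.0})
    picked = top_intersection(tab, q=0.01)
    assert len(picked) == int(np.ceil(0.01 * L))


def test_planted_leaders_always_in_intersection(rng):
    L = 300
    bf = rng.uniform(0, 1, L)
    rho = rng.uniform(-0.2, 0.2, L)
    bf[:3] = 100.0
    rho[:3] = 0.99
    tab = pd.DataFrame({"bayes_factor": bf, "rho": rho})
    picked = top_intersection(tab, q=0.01)
    assert {0, 1, 2} <= set(picked)


def test_independent_ranks_intersection_scales_as_q_squared(rng):
    L, q, reps = 2000, 0.05, 200
    sizes = [
        len(
            top_intersection(
                pd.DataFrame(
                    {"bayes_factor": rng.permutation(L).astype(float),
                     "rho": rng.permutation(L).astype(float)}
                ),
                q=q,
            )
        )
        for _ in range(reps)
    ]
    expected = q * q * L  # = 5
    assert np.mean(sizes) == pytest.approx(expected, rel=0.25)
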