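"""Environmental association analysis, two ways.

1. A latent-factor regression scan at the individual level: per locus,
   genotype ~ intercept + env + K latent factors, with the factors estimated
   by alternating truncated SVD and regression.  Z-scores from several
   independently initialized runs are Stouffer-combined, recalibrated by the
   genomic inflation factor (median chi-square method), and flagged at a
   Bonferroni-corrected level.

2. A deme-level Bayes-factor scan: samples are grouped into small demes by
   geography, deme allele frequencies are standardized and whitened by the
   neutral covariance Omega, and each locus gets a closed-form Bayes factor
   for a linear environment effect (conjugate normal prior on the slope)
   plus a nonparametric Spearman rank correlation.  Strong candidates are
   loci in the top quantile of BOTH the Bayes-factor and |rho| rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix
from .differentiation import OmegaMatrix, standardized_freqs
from ._stats import standardize

# ---------------------------------------------------------------------------
# Environmental variable selection by PCA contribution
# ---------------------------------------------------------------------------


def select_env_variables(
    env: pd.DataFrame,
    groups: dict[str, list[str]],
    n_pcs: int = 4,
    per_pc: int = 1,
) -> tuple[list[str], pd.DataFrame]:
    """Select representative variables per group by PCA contribution.

    For each variable group (e.g. temperature, precipitation) a PCA is run on
    the standardized variables; for each of the first ``n_pcs`` components
    the ``per_pc`` variables with the largest squared loading are taken.
    Returns the selected union (column order preserved) and a provenance
    table (group, pc, variable, contribution, variance explained by the
    first ``n_pcs`` PCs of that group).  Constant and duplicate variables
    are dropped before the PCA.
    """
    selected: list[str] = []
    prov_rows = []
    for group, cols in groups.items():
        cols = [c for c in cols if c in env.columns]
        block = env[cols].to_numpy(dtype=float)
        keep = []
        seen: list[np.ndarray] = []
        for i, c in enumerate(cols):
            col = block[:, i]
            if col.std() == 0:
                continue  # constant variable: no information
            z = (col - col.mean()) / col.std()
            if any(np.allclose(z, s) or np.allclose(z, -s) for s in seen):
                continue  # duplicate collapses to its first occurrence
            seen.append(z)
            keep.append(i)
        if len(keep) < n_pcs:
            raise ValueError(
                f"group {group!r} has {len(keep)} usable variables, "
                f"fewer than n_pcs={n_pcs}"
            )
        names = [cols[i] for i in keep]
        z = np.column_stack(seen)
        # PCA via SVD of the standardized block
        u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
        var = s**2 / np.sum(s**2)
        var_explained = float(var[:n_pcs].sum())
        for pc in range(n_pcs):
            contrib = vt[pc] ** 2
            top = np.argsort(-contrib, kind="mergesort")[:per_pc]
            for t in top:
                prov_rows.append(
                    (group, pc + 1, names[t], float(contrib[t]), var_explained)
                )
                if names[t] not in selected:
                    selected.append(names[t])
    prov = pd.DataFrame(
        prov_rows,
        columns=["group", "pc", "variable", "contribution", "var_explained_npcs"],
    )
    return selected, prov


# ---------------------------------------------------------------------------
# Latent-factor association scan
# ---------------------------------------------------------------------------

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def _impute_center(genotypes: np.ndarray) -> np.ndarray:
    """Mean-impute missing genotypes per locus and center columns."""
    g = genotypes.astype(float)
    miss = genotypes == MISSING
    with np.errstate(invalid="ignore"):
        means = np.where(
            miss.all(axis=0),
            0.0,
            np.nansum(np.where(miss, np.nan, g), axis=0) / (~miss).sum(axis=0),
        )
    g = np.where(miss, means[None, :], g)
    return g - g.mean(axis=0)


def _factor_regression(
    g: np.ndarray, env_z: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 15
) -> np.ndarray:
    """One latent-factor run: returns per-locus z-scores for the env slope."""
    n, m = g.shape
    if k >= min(n, m):
        raise ValueError("K must be smaller than both sample and locus counts")
    x_fixed = np.column_stack([np.ones(n), env_z])
    if k == 0:
        u = np.empty((n, 0))
    else:
        u = rng.normal(0.0, 0.1, size=(n, k))
        for _ in range(n_iter):
            x = np.column_stack([x_fixed, u])
            beta, *_ = np.linalg.lstsq(x, g, rcond=None)
            resid_fixed = g - x_fixed @ beta[:2]
            uu, ss, _vt = np.linalg.svd(resid_fixed, full_matrices=False)
            u = uu[:, :k] * ss[:k]
    x = np.column_stack([x_fixed, u])
    q = x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ g
    resid = g - x @ beta
    dof = max(n - q, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return beta[1] / se


@dataclass
class LfmmResult:
    """Combined latent-factor scan result for one environmental variable."""

    table: pd.DataFrame  # locus, gene_id, z, p, significant
    variable: str
    inflation: float
    bonferroni_p: float
    k: int
    n_runs: int


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests (exact arithmetic)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def lfmm_scan(
    matrix: GenotypeMatrix,
    env_values: np.ndarray,
    variable: str = "env",
    k: int = 2,
    n_runs: int = 5,
    alpha: float = 0.01,
    seed: int = 0,
) -> LfmmResult:
    """Latent-factor association scan for one environmental variable.

    Genotypes are mean-imputed and centered; each of ``n_runs`` runs
    estimates K latent factors from a different random initialization and
    produces per-locus z-scores; the combined z is the Stouffer mean
    (sum z / sqrt(n_runs)).  P-values come from the standard normal after
    dividing the squared z by the genomic inflation factor
    lambda = median(z^2) / median(chi^2_1).  The ``significant`` flag applies
    the Bonferroni level alpha / n_loci.
    """
    env_values = np.asarray(env_values, dtype=float)
    if not np.all(np.isfinite(env_values)):
        raise ValueError("environmental variable contains non-finite values")
    if env_values.size != matrix.n_samples:
        raise ValueError("environment vector length must match sample count")
    env_z = standardize(env_values)
    g = _impute_center(matrix.genotypes)
    seeds = np.random.SeedSequence(seed).spawn(max(n_runs, 1))
    zs = [
        _factor_regression(g, env_z, k, np.random.default_rng(s))
        for s in seeds[:n_runs]
    ]
    z = np.sum(zs, axis=0) / np.sqrt(len(zs))
    lam = float(np.median(z**2) / _CHI2_MEDIAN)
    lam = max(lam, 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(z) / np.sqrt(lam))
    thresh = bonferroni_threshold(alpha, matrix.n_loci)
    table = pd.DataFrame(
        {
            "locus": matrix.loci["chrom"].astype(str)
            + ":"
            + matrix.loci["pos"].astype(str),
            "gene_id": matrix.loci["gene_id"],
            "variable": variable,
            "z": z,
            "p": p,
            "significant": p < thresh,
        }
    )
    return LfmmResult(
        table=table,
        variable=variable,
        inflation=lam,
        bonferroni_p=thresh,
        k=k,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# Deme grouping
# ---------------------------------------------------------------------------


@dataclass
class DemeTable:
    """Geographic demes: membership, mean environment, allele frequencies."""

    deme_of_sample: pd.Series  # sample id -> deme id (int)
    env: pd.DataFrame  # per-deme mean environment, standardized columns
    coords: pd.DataFrame  # per-deme mean lat/lon/altitude

    @property
    def n_demes(self) -> int:
        return int(self.env.shape[0])


def group_demes(
    coords: pd.DataFrame,
    env: pd.DataFrame,
    variables: list[str],
    k: int = 50,
    seed: int = 0,
) -> DemeTable:
    """Group samples into k demes by k-means on standardized latitude,
    longitude and altitude (10 restarts, seeded, deterministic).

    Per-deme mean environmental values are computed and then standardized
    across demes.  k = 1 is rejected (the across-deme standardization is
    degenerate); k greater than the sample count is rejected.
    """
    from sklearn.cluster import KMeans

    n = len(coords)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k < 2:
        raise ValueError("need at least 2 demes (standardization is degenerate)")
    feats = np.column_stack(
        [
            standardize(coords["lat"].to_numpy()),
            standardize(coords["lon"].to_numpy()),
            standardize(coords["altitude"].to_numpy()),
        ]
    )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    deme_of_sample = pd.Series(labels, index=coords.index, name="deme")
    env_means = env[variables].groupby(labels).mean()
    env_std = (env_means - env_means.mean()) / env_means.std(ddof=0)
    coord_means = coords[["lat", "lon", "altitude"]].groupby(labels).mean()
    return DemeTable(deme_of_sample=deme_of_sample, env=env_std, coords=coord_means)


def deme_frequencies(
    matrix: GenotypeMatrix, demes: DemeTable
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Per-deme allele frequencies and chromosome counts (loci x demes)."""
    from .differentiation import population_frequencies

    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    pop_indices = {}
    for d in demes.env.index:
        members = demes.deme_of_sample.index[demes.deme_of_sample == d]
        idx = np.asarray([sample_pos[s] for s in members if s in sample_pos])
        if idx.size == 0:
            raise ValueError(f"deme {d} has no members present in the matrix")
        pop_indices[str(d)] = idx
    freqs, n_chrom = population_frequencies(matrix, pop_indices)
    return freqs, n_chrom, pop_indices


# ---------------------------------------------------------------------------
# Bayes-factor scan
# ---------------------------------------------------------------------------


def _whitener(omega: OmegaMatrix, rcond: float = 1e-3) -> np.ndarray:
    """Symmetric inverse square root of Omega on its informative eigenspace.

    Centering deme frequencies by the pooled mean leaves one near-null
    eigendirection carrying only weighting noise; naively inverting it
    amplifies that noise past the signal, so eigenvalues below ``rcond``
    times the largest are zeroed out instead of inverted.
    """
    vals, vecs = np.linalg.eigh(omega.values)
    if np.any(vals <= 0):
        raise ValueError("Omega is not positive definite")
    keep = vals > rcond * vals.max()
    inv_sqrt = np.where(keep, 1.0 / np.sqrt(np.where(keep, vals, 1.0)), 0.0)
    return vecs @ np.diag(inv_sqrt) @ vecs.T


def bayes_factor_single(
    y: np.ndarray, e: np.ndarray, prior_sd: float = 1.0
) -> float:
    """Closed-form Bayes factor for y = beta * e + N(0, I) with
    beta ~ N(0, prior_sd^2), against beta = 0.

    log BF = -0.5 log(1 + tau^2 |e|^2)
             + 0.5 tau^2 (e'y)^2 / (1 + tau^2 |e|^2).
    """
    t2 = prior_sd**2
    ee = float(e @ e)
    ey = float(e @ y)
    log_bf = -0.5 * np.log1p(t2 * ee) + 0.5 * t2 * ey * ey / (1.0 + t2 * ee)
    return float(np.exp(log_bf))


def bayes_factor_scan(
    freqs: np.ndarray,
    n_chrom: np.ndarray,
    omega: OmegaMatrix,
    env_values: np.ndarray,
    locus_ids: pd.Series | np.ndarray | None = None,
    gene_ids: pd.Series | np.ndarray | None = None,
    variable: str = "env",
    prior_sd: float = 1.0,
    top_q: float = 0.01,
) -> pd.DataFrame:
    """Bayes factor + Spearman rho per locus against a deme-level variable.

    ``freqs``/``n_chrom`` are loci x demes; ``env_values`` is the
    standardized per-deme variable (must match Omega's deme order).  Both the
    standardized frequencies and the environment are whitened by
    Omega^{-1/2} before the conjugate linear model and the rank correlation.
    Loci with a fixed pooled frequency get NaN statistics.

    The returned table carries ``strong_candidate``: membership in the top
    ``top_q`` quantile of both the BF and |rho| rankings.
    """
    env_values = np.asarray(env_values, dtype=float)
    if env_values.std() == 0:
        raise ValueError("environmental variable is constant across demes")
    if env_values.size != omega.values.shape[0]:
        raise ValueError("environment length must equal the number of demes")
    w = _whitener(omega)
    e = w @ standardize(env_values)
    # demes with no called genotype at a locus sit at the pooled mean
    # (x = 0): conservative, and keeps loci usable when a small deme is
    # entirely missing.  Loci fixed in the pooled sample stay NaN.
    from .differentiation import standardized_freqs_filled

    x, usable = standardized_freqs_filled(freqs, n_chrom)
    n_loci = x.shape[0]
    bf = np.full(n_loci, np.nan)
    rho = np.full(n_loci, np.nan)
    t2 = prior_sd**2
    ee = float(e @ e)
    shrink = 0.5 * t2 / (1.0 + t2 * ee)
    const = -0.5 * np.log1p(t2 * ee)
    ys = x[usable] @ w.T  # whitened standardized freqs per usable locus
    ey = ys @ e
    bf[usable] = np.exp(const + shrink * ey * ey)
    rho_vals = np.array(
        [stats.spearmanr(y, e).statistic for y in ys]
    )
    rho[usable] = rho_vals
    out = pd.DataFrame(
        {
            "locus": locus_ids if locus_ids is not None else np.arange(n_loci),
            "gene_id": gene_ids if gene_ids is not None else "",
            "variable": variable,
            "bayes_factor": bf,
            "rho": rho,
        }
    )
    strong = top_intersection(out, q=top_q)
    out["strong_candidate"] = out.index.isin(strong)
    return out


def top_intersection(results: pd.DataFrame, q: float = 0.01) -> np.ndarray:
    """Indices of loci in the top-q fraction of BOTH the Bayes-factor and
    the |rho| rankings (ties broken by input order; NaNs rank last).

    The size of each top list is ceil(q * L) over loci with defined
    statistics.
    """
    bf = results["bayes_factor"].to_numpy(dtype=float)
    rho = np.abs(results["rho"].to_numpy(dtype=float))
    ok = np.isfinite(bf) & np.isfinite(rho)
    n_top = int(np.ceil(q * ok.sum()))
    if n_top == 0:
        return np.array([], dtype=int)
    idx = np.flatnonzero(ok)
    top_bf = idx[np.argsort(-bf[ok], kind="mergesort")[:n_top]]
    top_rho = idx[np.argsort(-rho[ok], kind="mergesort")[:n_top]]
    return np.intersect1d(top_bf, top_rho)
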