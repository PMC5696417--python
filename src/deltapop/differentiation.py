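"""Covariance-corrected population-differentiation scan.

Per locus, subpopulation (or deme) allele frequencies are centered by the
pooled mean and scaled by sqrt(p_bar (1 - p_bar)); the differentiation
statistic is the Mahalanobis form x' Omega^{-1} x, where Omega is the
covariance matrix of those standardized frequencies across putatively
neutral (intergenic) loci.  Correcting by Omega discounts allele-frequency
differences explained by shared evolutionary history.

Significance comes from an empirical null: the same statistic computed on
the intergenic loci themselves, with add-one empirical p-values and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SubpopAssignment
from ._stats import benjamini_hochberg, empirical_pvalues


@dataclass
class OmegaMatrix:
    """P x P covariance of standardized subpopulation allele frequencies."""

    labels: list[str]
    values: np.ndarray
    n_loci: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("Omega dimension must match the population labels")
        if not np.allclose(v, v.T):
            raise ValueError("Omega must be symmetric")
        self.values = v

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.values)

    def pseudo_inverse(self, rcond: float = 1e-3) -> np.ndarray:
        """Inverse restricted to the informative eigenspace.

        Centering the per-population frequencies by their pooled mean leaves
        the standardized vectors in a (P-1)-dimensional subspace, so Omega
        always has one near-null eigendirection that carries only weighting
        noise; directions with eigenvalue below ``rcond`` times the largest
        are discarded before inverting.
        """
        vals, vecs = np.linalg.eigh(self.values)
        keep = vals > rcond * vals.max()
        inv_vals = np.where(keep, 1.0 / np.where(keep, vals, 1.0), 0.0)
        return vecs @ np.diag(inv_vals) @ vecs.T


def population_frequencies(
    matrix: GenotypeMatrix, pop_indices: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-population allele frequencies and chromosome counts.

    Returns (freqs, n_chrom), both shaped (n_loci, P) in the label order of
    ``pop_indices``.
    """
    n_loci = matrix.n_loci
    P = len(pop_indices)
    freqs = np.full((n_loci, P), np.nan)
    n_chrom = np.zeros((n_loci, P))
    for k, idx in enumerate(pop_indices.values()):
        g = matrix.genotypes[idx]
        called = g != MISSING
        n = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, k] = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / n, np.nan)
        n_chrom[:, k] = n
    return freqs, n_chrom


def standardized_freqs(
    freqs: np.ndarray, n_chrom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize per-population frequencies locus by locus.

    x_j = (p_j - p_bar) / sqrt(p_bar (1 - p_bar)) with p_bar the
    chromosome-count-weighted pooled mean.  Returns (x, usable) where
    ``usable`` flags loci with a polymorphic pooled frequency and data in
    every population.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n_chrom = np.atleast_2d(np.asarray(n_chrom, dtype=float))
    total = n_chrom.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.nansum(freqs * n_chrom, axis=1) / total
        scale = np.sqrt(p_bar * (1.0 - p_bar))
        x = (freqs - p_bar[:, None]) / scale[:, None]
    usable = (
        np.isfinite(freqs).all(axis=1)
        & (n_chrom >= 2).all(axis=1)
        & (p_bar > 0)
        & (p_bar < 1)
    )
    return x, usable


def standardized_freqs_filled(
    freqs: np.ndarray, n_chrom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`standardized_freqs`, but populations with no called
    genotype at a locus sit at the pooled mean (x = 0) instead of making the
    locus unusable — conservative, and necessary when many small demes are
    scored.  Loci fixed in the pooled sample remain unusable.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n_chrom = np.atleast_2d(np.asarray(n_chrom, dtype=float))
    have = np.isfinite(freqs) & (n_chrom > 0)
    total = np.where(have, n_chrom, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.nansum(np.where(have, freqs * n_chrom, 0.0), axis=1) / total
    filled = np.where(have, freqs, p_bar[:, None])
    return standardized_freqs(filled, np.maximum(n_chrom, 2.0))


def select_neutral_loci(
    matrix: GenotypeMatrix,
    min_spacing_bp: int = 15_000,
    min_maf: float = 0.01,
    min_call_rate: float = 0.8,
    max_loci: int = 1800,
) -> np.ndarray:
    """Indices of intergenic loci for the neutral parametrization of Omega:
    at least ``min_spacing_bp`` apart, MAF above ``min_maf`` and call rate
    above ``min_call_rate``; the first ``max_loci`` passing, scanning each
    chromosome in position order."""
    from .genotype_io import minor_allele_frequency

    loci = matrix.loci
    maf = minor_allele_frequency(matrix)
    call = 1.0 - matrix.missing_fraction()
    with np.errstate(invalid="ignore"):
        ok = (
            (loci["region_class"].to_numpy() == "intergenic")
            & np.nan_to_num(maf > min_maf)
            & (call > min_call_rate)
        )
    picked: list[int] = []
    pos = loci["pos"].to_numpy()
    chrom = loci["chrom"].to_numpy()
    for c in pd.unique(chrom[ok]):
        idx = np.flatnonzero(ok & (chrom == c))
        idx = idx[np.argsort(pos[idx], kind="mergesort")]
        last = -np.inf
        for j in idx:
            if pos[j] - last >= min_spacing_bp:
                picked.append(j)
                last = pos[j]
    picked = sorted(picked)
    return np.asarray(picked[:max_loci], dtype=int)


def estimate_omega(
    matrix: GenotypeMatrix,
    assignment: SubpopAssignment | None = None,
    pop_indices: dict[str, np.ndarray] | None = None,
    loci: np.ndarray | None = None,
    method: str = "moment",
    ridge: float = 1e-6,
    n_runs: int = 5,
    fill_missing: bool = False,
    seed: int = 0,
) -> OmegaMatrix:
    """Estimate Omega from putatively neutral loci.

    ``method="moment"`` (default): the empirical second-moment matrix of the
    standardized frequency vectors, ridge-regularized by
    ``ridge * trace/P * I`` so it stays invertible even for P = 2.

    ``method="mcmc"``: Bayesian refinement under the conjugate
    inverse-Wishart model x_l ~ N(0, Omega); the estimate is the average of
    the last posterior draw from ``n_runs`` independent chains, mirroring the
    multi-run averaging protocol of MCMC-based tools at desk scale.  The two
    methods agree within sampling error.
    """
    if pop_indices is None:
        if assignment is None:
            raise ValueError("provide assignment or pop_indices")
        pop_indices = assignment.indices_by_population(matrix.samples)
    labels = list(pop_indices)
    P = len(labels)
    sub = matrix if loci is None else matrix.take_loci(loci)
    freqs, n_chrom = population_frequencies(sub, pop_indices)
    standardizer = standardized_freqs_filled if fill_missing else standardized_freqs
    x, usable = standardizer(freqs, n_chrom)
    x = x[usable]
    if x.shape[0] < P + 1:
        raise ValueError(
            f"need at least {P + 1} usable neutral loci, got {x.shape[0]}"
        )
    omega = x.T @ x / x.shape[0]
    if method == "mcmc":
        rng = np.random.default_rng(seed)
        L = x.shape[0]
        psi = x.T @ x + np.eye(P)  # prior IW(P+2, I)
        nu = L + P + 2
        draws = []
        for _ in range(n_runs):
            # draw Omega ~ IW(nu, psi) via the inverse of a Wishart draw
            chol = np.linalg.cholesky(np.linalg.inv(psi))
            a = np.zeros((P, P))
            for i in range(P):
                a[i, i] = np.sqrt(rng.chisquare(nu - i))
                for j in range(i):
                    a[i, j] = rng.normal()
            w = chol @ a
            draws.append(np.linalg.inv(w @ w.T))
        omega = np.mean(draws, axis=0)
    elif method != "moment":
        raise ValueError("method must be 'moment' or 'mcmc'")
    omega = omega + ridge * (np.trace(omega) / P) * np.eye(P)
    # enforce positive definiteness
    np.linalg.cholesky(omega)
    return OmegaMatrix(labels=labels, values=omega, n_loci=int(x.shape[0]))


def xtx_statistic(
    matrix: GenotypeMatrix,
    pop_indices: dict[str, np.ndarray],
    omega: OmegaMatrix,
    loci: np.ndarray | None = None,
    rcond: float = 1e-3,
) -> pd.DataFrame:
    """x' Omega^{+} x per locus (pseudo-inverse on the informative
    eigenspace; see :meth:`OmegaMatrix.pseudo_inverse`).

    Returns a table with locus id, gene_id, xtx, and a ``skipped`` reason
    column (empty when computed) for loci with a fixed pooled frequency or
    missing populations.
    """
    if list(pop_indices) != omega.labels:
        raise ValueError("population labels do not match Omega")
    sub = matrix if loci is None else matrix.take_loci(loci)
    freqs, n_chrom = population_frequencies(sub, pop_indices)
    x, usable = standardized_freqs(freqs, n_chrom)
    inv = omega.pseudo_inverse(rcond=rcond)
    xtx = np.full(sub.n_loci, np.nan)
    xs = x[usable]
    xtx[usable] = np.einsum("ij,jk,ik->i", xs, inv, xs)
    out = pd.DataFrame(
        {
            "locus": sub.loci["chrom"].astype(str) + ":" + sub.loci["pos"].astype(str),
            "gene_id": sub.loci["gene_id"],
            "region_class": sub.loci["region_class"],
            "xtx": xtx,
            "skipped": np.where(usable, "", "fixed_or_missing"),
        }
    )
    return out


def xtx_scan(
    matrix: GenotypeMatrix,
    assignment: SubpopAssignment | None = None,
    pop_indices: dict[str, np.ndarray] | None = None,
    omega: OmegaMatrix | None = None,
    genic_maf: float = 0.1,
    null_maf: float | None = None,
    fdr: float = 0.05,
    omega_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, OmegaMatrix]:
    """Full differentiation scan with an intergenic empirical null.

    1. Omega from spaced intergenic loci (unless supplied).
    2. The statistic on intergenic loci -> null distribution.
    3. The statistic on genic loci with MAF >= ``genic_maf`` -> observed.
    4. Add-one empirical p-values, BH q-values, outliers at q <= ``fdr``.

    ``null_maf`` defaults to ``genic_maf``: the null loci are ascertained at
    the same frequency cutoff as the scanned loci, because the sampling noise
    of the statistic is frequency-dependent and an unmatched null miscalibrates
    the empirical p-values.

    Returns (per-SNP table, per-gene table, Omega).  A gene is an outlier
    when any of its SNPs is.
    """
    if null_maf is None:
        null_maf = genic_maf
    from .genotype_io import minor_allele_frequency

    if pop_indices is None:
        if assignment is None:
            raise ValueError("provide assignment or pop_indices")
        pop_indices = assignment.indices_by_population(matrix.samples)
    if omega is None:
        neutral = select_neutral_loci(matrix, **(omega_kwargs or {}))
        omega = estimate_omega(matrix, pop_indices=pop_indices, loci=neutral)

    region = matrix.loci["region_class"].to_numpy()
    maf = minor_allele_frequency(matrix)
    with np.errstate(invalid="ignore"):
        genic_idx = np.flatnonzero(
            (region == "genic") & np.nan_to_num(maf >= genic_maf)
        )
    intergenic_idx = np.flatnonzero(
        (region == "intergenic") & np.nan_to_num(maf >= null_maf)
    )

    null_tab = xtx_statistic(matrix, pop_indices, omega, loci=intergenic_idx)
    null = null_tab["xtx"].to_numpy()
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise ValueError("no usable intergenic loci for the null distribution")

    snp = xtx_statistic(matrix, pop_indices, omega, loci=genic_idx)
    ok = np.isfinite(snp["xtx"].to_numpy())
    p = np.full(len(snp), np.nan)
    q = np.full(len(snp), np.nan)
    p[ok] = empirical_pvalues(snp["xtx"].to_numpy()[ok], null)
    q[ok] = benjamini_hochberg(p[ok])
    snp["empirical_p"] = p
    snp["q_value"] = q
    snp["outlier"] = (q <= fdr) & ok

    gene = (
        snp[ok]
        .groupby("gene_id")
        .agg(
            n_snps=("locus", "size"),
            max_xtx=("xtx", "max"),
            min_p=("empirical_p", "min"),
            min_q=("q_value", "min"),
            outlier=("outlier", "any"),
        )
        .reset_index()
    )
    return snp, gene, omega
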