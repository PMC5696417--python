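"""Linkage disequilibrium: pairwise r^2 within genes, the drift-recombination
expectation E(r^2 | C, n), nonlinear least-squares estimation of the
per-bp recombination intensity, and the distance at which the fitted curve
drops below a threshold.

For unphased genotypes, two-locus haplotype frequencies are estimated by EM
(the double-heterozygote phase is the only ambiguity for biallelic loci);
phased haplotypes are counted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Two-locus r^2
# ---------------------------------------------------------------------------


def haplotype_r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """r^2 from phased haplotypes by direct counting (missing excluded)."""
    ok = (hap_a != MISSING) & (hap_b != MISSING)
    a, b = hap_a[ok].astype(float), hap_b[ok].astype(float)
    if a.size < 2:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def em_haplotype_freqs(
    g_a: np.ndarray,
    g_b: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, int]:
    """EM estimate of the four two-locus haplotype frequencies (AB, Ab, aB,
    ab) from unphased biallelic genotypes, where "A"/"B" denote the
    alternate alleles.  Returns (freqs, n_individuals used).
    """
    ok = (g_a != MISSING) & (g_b != MISSING)
    a = g_a[ok].astype(int)
    b = g_b[ok].astype(int)
    n = a.size
    if n < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    # genotype table counts
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    # initialize at linkage equilibrium
    f = np.array(
        [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    )  # AB, Ab, aB, ab
    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    # expected haplotype counts from unambiguous genotype cells
    base = np.zeros(4)
    #            AB                          Ab
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        if denom <= 0:
            frac_cis = 0.5
        else:
            frac_cis = f[0] * f[3] / denom  # P(AB/ab | double het)
        newc = base.copy()
        newc[0] += n_dh * frac_cis
        newc[3] += n_dh * frac_cis
        newc[1] += n_dh * (1 - frac_cis)
        newc[2] += n_dh * (1 - frac_cis)
        new = newc / (2.0 * n)
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    else:
        raise RuntimeError("EM for haplotype frequencies did not converge")
    return f, n


def genotype_r2(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """r^2 between two loci from unphased genotypes via EM haplotype
    frequencies: r^2 = D^2 / (p_A p_a p_B p_b)."""
    try:
        f, _n = em_haplotype_freqs(g_a, g_b)
    except (ValueError, RuntimeError):
        return float("nan")
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return float("nan")
    d = f[0] - pa * pb
    return float(d * d / denom)


def pairwise_r2(
    matrix: GenotypeMatrix,
    maf_cutoff: float = 0.0,
    use_haplotypes: bool = False,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """All within-gene locus pairs with their distance and r^2.

    Only genic loci whose MAF exceeds ``maf_cutoff`` enter; pairs where the
    r^2 estimate fails (EM non-convergence, monomorphic after subsetting) are
    skipped with a warning counter.  Columns: gene_id, locus_a, locus_b,
    distance, r2, n.
    """
    from .genotype_io import minor_allele_frequency

    loci = matrix.loci
    maf = minor_allele_frequency(matrix)
    genic = (loci["region_class"].to_numpy() == "genic") & (maf > maf_cutoff)
    rows = []
    skipped = 0
    pos = loci["pos"].to_numpy()
    gene_col = loci["gene_id"].to_numpy()
    for gene in pd.unique(gene_col[genic]):
        if genes is not None and gene not in genes:
            continue
        cols = np.flatnonzero(genic & (gene_col == gene))
        cols = cols[np.argsort(pos[cols], kind="mergesort")]
        if cols.size < 2:
            continue
        for ia in range(cols.size - 1):
            for ib in range(ia + 1, cols.size):
                ja, jb = cols[ia], cols[ib]
                if use_haplotypes and matrix.haplotypes is not None:
                    r2 = haplotype_r2(
                        matrix.haplotypes[:, ja], matrix.haplotypes[:, jb]
                    )
                    n = matrix.n_samples
                else:
                    r2 = genotype_r2(
                        matrix.genotypes[:, ja], matrix.genotypes[:, jb]
                    )
                    n = int(
                        (
                            (matrix.genotypes[:, ja] != MISSING)
                            & (matrix.genotypes[:, jb] != MISSING)
                        ).sum()
                    )
                if not np.isfinite(r2):
                    skipped += 1
                    continue
                rows.append(
                    (
                        gene,
                        f"{loci['chrom'].iat[ja]}:{pos[ja]}",
                        f"{loci['chrom'].iat[jb]}:{pos[jb]}",
                        int(pos[jb] - pos[ja]),
                        r2,
                        n,
                    )
                )
    if skipped:
        warnings.warn(f"{skipped} locus pairs skipped (r2 undefined)", stacklevel=2)
    return pd.DataFrame(
        rows, columns=["gene_id", "locus_a", "locus_b", "distance", "r2", "n"]
    )


# ---------------------------------------------------------------------------
# Expected r^2 and curve fitting
# ---------------------------------------------------------------------------


def expected_r2(c: np.ndarray | float, n: int) -> np.ndarray | float:
    """Drift-recombination expectation of r^2 at scaled recombination
    C = rho * distance for a sample of n individuals:

        E(r^2) = [(10+C) / ((2+C)(11+C))]
                 * [1 + ((3+C)(12+12C+C^2)) / (n (2+C)(11+C))]

    Strictly decreasing in C; tends to 0 as C grows.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("C must be non-negative")
    if n < 2:
        raise ValueError("n must be >= 2")
    denom = (2.0 + c) * (11.0 + c)
    first = (10.0 + c) / denom
    second = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c * c)) / (n * denom)
    out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class LdFit:
    """Result of fitting the expected-r^2 curve to a pair cloud."""

    c_per_bp: float  # rho = 4 N_e r per base pair
    n: int
    rss: float
    n_pairs: int
    converged: bool
    decay_distance: int | None = None  # filled by decay_distance()


_START_GRID = (1e-4, 1e-3, 1e-2)  # fixed multi-start for determinism


def fit_c(
    pairs: pd.DataFrame,
    n: int,
    bounds: tuple[float, float] = (0.0, 1.0),
    min_pairs: int = 10,
) -> LdFit:
    """Nonlinear least squares for the per-bp recombination intensity.

    Minimizes sum_i (r2_i - E(r^2 | C_per_bp * d_i, n))^2 over C_per_bp in
    ``bounds``, from a fixed 3-point start grid to dodge local minima.
    """
    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if d.size < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs, got {d.size}")
    if np.all(d == d[0]):
        raise ValueError("degenerate distances: all pairs at the same distance")

    def resid(theta):
        return expected_r2(theta[0] * d, n) - r2

    best = None
    for start in _START_GRID:
        start = min(max(start, bounds[0] + 1e-12), bounds[1])
        sol = least_squares(resid, x0=[start], bounds=([bounds[0]], [bounds[1]]))
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (float(sol.x[0]), rss, bool(sol.success))
    c_hat, rss, ok = best
    if not ok:
        raise RuntimeError(f"curve fit did not converge (last C = {c_hat:g})")
    return LdFit(c_per_bp=c_hat, n=n, rss=rss, n_pairs=int(d.size), converged=ok)


def bin_pairs(pairs: pd.DataFrame, bin_width: int = 100) -> pd.DataFrame:
    """Optional distance-binned means of the pair cloud (same columns)."""
    df = pairs.copy()
    df["bin"] = (df["distance"] // bin_width).astype(int)
    out = (
        df.groupby("bin")
        .agg(distance=("distance", "mean"), r2=("r2", "mean"), n=("n", "median"))
        .reset_index(drop=True)
    )
    out["gene_id"] = "binned"
    return out


def decay_distance(
    fit: LdFit, threshold: float = 0.2, max_distance: int = 10_000_000
) -> tuple[int, bool]:
    """Smallest integer distance d with E(r^2 | C_per_bp * d, n) < threshold.

    Returns (distance, reached); when the curve never exceeds the threshold
    (already below it at d = 1) the result is (0, False).
    """
    if expected_r2(fit.c_per_bp * 1.0, fit.n) < threshold:
        return 0, False
    lo, hi = 1, 2
    while expected_r2(fit.c_per_bp * hi, fit.n) >= threshold:
        hi *= 2
        if hi > max_distance:
            return max_distance, False
    # invariant: E(lo) >= threshold > E(hi); bisect on the monotone curve
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_r2(fit.c_per_bp * mid, fit.n) < threshold:
            hi = mid
        else:
            lo = mid
    return hi, True


def fit_population_ld(
    matrix: GenotypeMatrix,
    maf_cutoff: float = 0.0,
    threshold: float = 0.2,
    use_haplotypes: bool = False,
) -> tuple[LdFit, pd.DataFrame]:
    """Convenience: pair cloud -> fitted curve -> decay distance for one
    population slice of the data."""
    pairs = pairwise_r2(matrix, maf_cutoff=maf_cutoff, use_haplotypes=use_haplotypes)
    n = int(pairs["n"].median()) if len(pairs) else matrix.n_samples
    fit = fit_c(pairs, n)
    dist, reached = decay_distance(fit, threshold=threshold)
    fit.decay_distance = dist if reached else 0
    return fit, pairs
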