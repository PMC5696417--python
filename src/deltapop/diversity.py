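"""Per-gene and per-population diversity and neutrality statistics.

Implements Watterson's theta, nucleotide diversity pi, Tajima's D, Wall's B,
expected/observed heterozygosity, the Weir–Cockerham (1984) F_ST estimator,
and the effective-population-size identity N_e = theta_W / (4 mu).

Per-site statistics are scaled by the *surveyed* (captured) length of each
region, not its genomic span: in exome-capture data only the probe footprint
is assayed, so the probe footprint is the correct denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GeneRegion, GenotypeMatrix, SubpopAssignment


# ---------------------------------------------------------------------------
# Single-population estimators
# ---------------------------------------------------------------------------


def harmonic_number(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i^power."""
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sum(1.0 / i**power))


def watterson_theta(s: int, n_chrom: int, length: float) -> float:
    """Watterson's per-site diversity estimator theta_W = S / (a_{n-1} L)."""
    if n_chrom < 2:
        return float("nan")
    if length < 1:
        raise ValueError("length must be >= 1")
    if s == 0:
        return 0.0
    return s / (harmonic_number(n_chrom - 1) * length)


def nucleotide_pi(
    genotypes: np.ndarray | None = None,
    length: float = 1.0,
    freqs: np.ndarray | None = None,
    n_chrom: np.ndarray | None = None,
) -> float:
    """Per-site nucleotide diversity.

    pi = sum over loci of [n/(n-1)] * 2 p (1-p) / L, with n the non-missing
    chromosome count at each locus.  Either a genotype slice
    (samples x loci, -1 missing) or precomputed ``freqs``/``n_chrom`` arrays
    may be given.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if freqs is None:
        if genotypes is None:
            raise ValueError("provide genotypes or freqs")
        called = genotypes != MISSING
        n_chrom = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(
                n_chrom > 0,
                np.where(called, genotypes, 0).sum(axis=0) / n_chrom,
                np.nan,
            )
    freqs = np.asarray(freqs, dtype=float)
    n_chrom = np.asarray(n_chrom, dtype=float)
    ok = np.isfinite(freqs) & (n_chrom >= 2)
    n = n_chrom[ok]
    p = freqs[ok]
    per_locus = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
    return float(per_locus.sum() / length)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard normalization constants for Tajima's D at sample size n
    (number of sequences)."""
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(s: int, pi_total: float, n_chrom: int) -> float:
    """Tajima's D from the segregating-site count S, the *summed* (not
    per-site) pairwise diversity pi_total, and the sequence count.

    Undefined (NaN) when S = 0.
    """
    if s == 0:
        return float("nan")
    c = tajima_constants(n_chrom)
    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
    return float((pi_total - s / c["a1"]) / np.sqrt(var))


def walls_b(haplotypes: np.ndarray, positions: np.ndarray | None = None) -> float:
    """Wall's B: the fraction of adjacent segregating-site pairs that are
    congruent, i.e. show at most two distinct gametes (no fourth gamete).

    ``haplotypes`` is a (n_haplotypes x n_sites) 0/1 array (missing = -1
    entries are excluded pairwise).  Sites are taken in ``positions`` order
    (or input order).  Undefined (NaN) when fewer than 2 segregating sites.
    """
    hap = np.asarray(haplotypes)
    if positions is not None:
        order = np.argsort(np.asarray(positions), kind="mergesort")
        hap = hap[:, order]
    seg = []
    for j in range(hap.shape[1]):
        col = hap[:, j]
        vals = np.unique(col[col != MISSING])
        if len(vals) > 1:
            seg.append(j)
    s = len(seg)
    if s < 2:
        return float("nan")
    congruent = 0
    for a, b in zip(seg[:-1], seg[1:]):
        ok = (hap[:, a] != MISSING) & (hap[:, b] != MISSING)
        gametes = {(int(x), int(y)) for x, y in zip(hap[ok, a], hap[ok, b])}
        if len(gametes) <= 2:
            congruent += 1
    return congruent / (s - 1.0)


def heterozygosities(
    genotypes: np.ndarray, unbiased: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus expected and observed heterozygosity.

    H_E = 2 p (1-p) (times n/(n-1) when ``unbiased``); H_O = fraction of
    heterozygous calls among non-missing genotypes.  All-missing loci are NaN.
    """
    called = genotypes != MISSING
    n_ind = called.sum(axis=0).astype(float)
    n_chrom = 2.0 * n_ind
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, np.where(called, genotypes, 0).sum(axis=0) / n_chrom, np.nan)
        h_exp = 2.0 * p * (1.0 - p)
        if unbiased:
            h_exp = np.where(n_chrom > 1, h_exp * n_chrom / (n_chrom - 1.0), np.nan)
        h_obs = np.where(
            n_ind > 0, ((genotypes == 1) & called).sum(axis=0) / n_ind, np.nan
        )
    return h_exp, h_obs


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def _wc_components(
    genotypes: np.ndarray, pop_indices: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components a, b, c for an
    arbitrary number of populations, from unphased diploid genotypes."""
    r = len(pop_indices)
    n_loci = genotypes.shape[1]
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for k, idx in enumerate(pop_indices):
        g = genotypes[idx]
        called = g != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called, g, 0).sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = ((g == 1) & called).sum(axis=0) / n_i[k]
    valid = (n_i >= 2).all(axis=0)
    n_bar = n_i.mean(axis=0)
    n_total = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


@dataclass
class FstResult:
    per_locus: np.ndarray  # per-locus theta-hat (NaN where undefined)
    multilocus: float  # ratio of summed variance components


def pairwise_fst(
    matrix: GenotypeMatrix,
    assignment: SubpopAssignment,
    pop_a: str,
    pop_b: str,
    include_monomorphic: bool = False,
) -> FstResult:
    """Weir–Cockerham F_ST between two labeled subpopulations.

    The multilocus estimate is the ratio of summed variance components (never
    a mean of per-locus ratios).  Loci monomorphic in both populations are
    excluded by default; per-locus values may be negative.
    """
    idx = assignment.indices_by_population(matrix.samples)
    for p in (pop_a, pop_b):
        if p not in idx or idx[p].size < 2:
            raise ValueError(f"population {p} needs at least 2 samples")
    return fst_from_genotypes(
        matrix.genotypes, [idx[pop_a], idx[pop_b]], include_monomorphic
    )


def fst_from_genotypes(
    genotypes: np.ndarray,
    pop_indices: list[np.ndarray],
    include_monomorphic: bool = False,
) -> FstResult:
    a, b, c = _wc_components(genotypes, pop_indices)
    total = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = a / total
    informative = np.isfinite(total) & (
        include_monomorphic | (np.abs(total) > 1e-300)
    )
    # monomorphic-in-both loci have a = b = c = 0 -> excluded from the sums
    poly = informative & (total != 0)
    multilocus = float(a[poly].sum() / total[poly].sum()) if poly.any() else float("nan")
    per_locus = np.where(poly, per_locus, np.nan)
    return FstResult(per_locus=per_locus, multilocus=multilocus)


# ---------------------------------------------------------------------------
# Effective population size
# ---------------------------------------------------------------------------


def mutation_rate_per_generation(rate_per_year: float, generation_years: float) -> float:
    """Per-generation mutation rate from a per-year rate and generation time."""
    return rate_per_year * generation_years


def ne_from_theta(theta_w: float, mu: float, round_hundreds: bool = False) -> float:
    """Effective population size N_e = theta_W / (4 mu) for a diploid.

    ``round_hundreds`` rounds to the nearest hundred, the reporting
    convention for approximate N_e values.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    ne = theta_w / (4.0 * mu)
    if round_hundreds:
        ne = round(ne / 100.0) * 100.0
    return float(ne)


# ---------------------------------------------------------------------------
# Per-gene summary over populations
# ---------------------------------------------------------------------------


def _pseudo_haplotypes(genotypes: np.ndarray) -> np.ndarray:
    """Major-phase pseudo-haplotypes for unphased genotypes: hom calls yield
    two identical copies, het calls put the reference allele on the first
    copy.  Exact only for phased input; callers warn."""
    n, m = genotypes.shape
    hap = np.empty((2 * n, m), dtype=np.int8)
    g = genotypes
    hap[0::2] = np.where(g == MISSING, MISSING, (g == 2).astype(np.int8))
    hap[1::2] = np.where(g == MISSING, MISSING, (g >= 1).astype(np.int8))
    return hap


def gene_diversity(
    matrix: GenotypeMatrix,
    regions: list[GeneRegion],
    assignment: SubpopAssignment | None = None,
    populations: dict[str, np.ndarray] | None = None,
    include_total: bool = True,
    unbiased_h: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-population diversity table.

    Columns: population, gene_id, region_class, n_chrom (gene-median
    non-missing chromosome count), S, theta_w, pi (both per surveyed site),
    tajima_d, wall_b, h_exp, h_obs.

    Wall's B uses the phased haplotypes when the matrix carries them;
    otherwise major-phase pseudo-haplotypes with a warning.
    """
    if populations is None:
        if assignment is None:
            populations = {}
        else:
            populations = assignment.indices_by_population(matrix.samples)
    pops = dict(populations)
    if include_total:
        pops = {"total": np.arange(matrix.n_samples), **pops}

    phased = matrix.haplotypes is not None
    if not phased:
        warnings.warn(
            "no phased haplotypes available; Wall's B computed on "
            "major-phase pseudo-haplotypes",
            stacklevel=2,
        )

    gene_col = matrix.loci["gene_id"].to_numpy()
    pos_col = matrix.loci["pos"].to_numpy()
    loc_by_gene: dict[str, np.ndarray] = {}
    for j, g in enumerate(gene_col):
        loc_by_gene.setdefault(g, []).append(j)  # type: ignore[arg-type]

    rows = []
    for region in regions:
        cols = np.asarray(loc_by_gene.get(region.gene_id, []), dtype=int)
        if cols.size:
            cols = cols[np.argsort(pos_col[cols], kind="mergesort")]
        for pop, sidx in pops.items():
            g = matrix.genotypes[np.ix_(sidx, cols)] if cols.size else np.empty((len(sidx), 0), dtype=np.int8)
            called = g != MISSING
            n_chrom_per_locus = 2 * called.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freqs = np.where(
                    n_chrom_per_locus > 0,
                    np.where(called, g, 0).sum(axis=0) / n_chrom_per_locus,
                    np.nan,
                )
            segregating = (
                np.isfinite(freqs) & (freqs > 0) & (freqs < 1) & (n_chrom_per_locus >= 2)
            )
            s = int(segregating.sum())
            n_med = (
                int(np.median(n_chrom_per_locus[n_chrom_per_locus > 0]))
                if (n_chrom_per_locus > 0).any()
                else 0
            )
            L = float(region.surveyed_length)
            theta = watterson_theta(s, n_med, L) if n_med >= 2 else float("nan")
            pi = (
                nucleotide_pi(freqs=freqs, n_chrom=n_chrom_per_locus, length=L)
                if cols.size
                else 0.0
            )
            d = (
                tajimas_d(s, pi * L, n_med)
                if (s >= 1 and n_med >= 4)
                else float("nan")
            )
            if cols.size and s >= 2:
                if phased:
                    hidx = np.stack([2 * sidx, 2 * sidx + 1], axis=1).ravel()
                    hap = matrix.haplotypes[np.ix_(hidx, cols)]
                else:
                    hap = _pseudo_haplotypes(g)
                wb = walls_b(hap)
            else:
                wb = float("nan")
            he, ho = heterozygosities(g, unbiased=unbiased_h) if cols.size else (np.array([]), np.array([]))
            rows.append(
                (
                    pop,
                    region.gene_id,
                    region.region_class,
                    n_med,
                    s,
                    theta,
                    pi,
                    d,
                    wb,
                    float(np.nanmean(he)) if he.size and np.isfinite(he).any() else float("nan"),
                    float(np.nanmean(ho)) if ho.size and np.isfinite(ho).any() else float("nan"),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "gene_id",
            "region_class",
            "n_chrom",
            "S",
            "theta_w",
            "pi",
            "tajima_d",
            "wall_b",
            "h_exp",
            "h_obs",
        ],
    )


def population_summary(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Mean diversity statistics per population and region class."""
    return (
        per_gene.groupby(["population", "region_class"], sort=True)
        .agg(
            n_genes=("gene_id", "size"),
            mean_S=("S", "mean"),
            mean_theta_w=("theta_w", "mean"),
            mean_pi=("pi", "mean"),
            mean_tajima_d=("tajima_d", "mean"),
            mean_wall_b=("wall_b", "mean"),
            mean_h_exp=("h_exp", "mean"),
            mean_h_obs=("h_obs", "mean"),
        )
        .reset_index()
    )
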