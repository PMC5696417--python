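"""Synthetic cohort generator.

Emulates the statistical structure of a range-wide hardwood-tree exome
capture cohort: a handful of weakly differentiated subpopulations
(island-model F_ST of a few percent), a site-frequency spectrum enriched in
rare alleles, within-gene linkage disequilibrium that decays with physical
distance, climate gradients correlated with geography, planted clinal
(locally adaptive) loci, and the missingness / quality annotations a variant
caller would emit.  Every downstream stage of the pipeline can therefore be
exercised and power-tested without any external data.

Model sketch
------------
* Ancestral allele frequencies are Beta-distributed (default Beta(0.5, 2.5),
  a rare-allele-heavy spectrum).
* Subpopulation frequencies follow the Balding–Nichols island model:
  Beta(p(1-F)/F, (1-p)(1-F)/F), so E = p and Var = F p (1-p).
* Within a gene, haplotypes are mosaics over a finite founder pool.  Founder
  k carries the alternate allele at a locus iff k falls inside that locus's
  carrier block (a prefix or suffix of the pool whose size is the rounded
  pool count K*q).  Sampled haplotypes copy one founder and re-pick a founder
  between adjacent loci with probability 1 - exp(-switch_rate * distance),
  which makes r^2 decay geometrically with distance while leaving each
  locus's marginal frequency pinned to its Balding–Nichols draw.
* Intergenic loci are mutually independent (no founder pool).
* Adaptive loci receive a per-sample logit shift proportional to a
  standardized climate signal; strongly divergent loci (for differentiation
  power tests) get subpopulation frequencies forced apart by a fixed delta.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneRegion, GenotypeMatrix, LOCUS_COLUMNS
from ._stats import standardize

N_CHROMOSOMES = 19

# environment variable definitions: name -> (group, loadings on the
# standardized latitude / longitude / altitude signals)
ENV_VARIABLES: dict[str, tuple[str, tuple[float, float, float]]] = {
    "tmean_annual": ("temperature", (0.90, 0.30, -0.20)),
    "tmin_coldest": ("temperature", (0.95, 0.20, -0.15)),
    "tmax_warmest": ("temperature", (0.80, 0.35, -0.10)),
    "tmean_wettest": ("temperature", (0.70, 0.50, -0.10)),
    "t_seasonality": ("temperature", (0.50, 0.70, 0.00)),
    "t_diurnal_range": ("temperature", (0.30, 0.80, 0.10)),
    "p_annual": ("precipitation", (0.40, 0.85, 0.00)),
    "p_wettest": ("precipitation", (0.30, 0.90, 0.05)),
    "p_driest": ("precipitation", (0.60, 0.60, -0.10)),
    "p_seasonality": ("precipitation", (0.20, 0.90, 0.10)),
    "p_coldest": ("precipitation", (0.85, 0.30, 0.00)),
}

#: climate signal that drives planted clines (latitude-dominated, so the
#: cline is not collinear with the longitudinal population structure)
CLINE_VARIABLE = "tmin_coldest"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a two-subpopulation cohort of 100 + 100 trees at
    F_ST = 0.07 (the hierarchical west/east split scale), 150 captured genes
    of 3 kb with 8 SNPs each, and 4,000 independent intergenic SNPs.
    """

    n_subpops: int = 2
    samples_per_subpop: tuple[int, ...] = (100, 100)
    fst_per_subpop: tuple[float, ...] = (0.07, 0.07)
    n_genes: int = 300
    loci_per_gene: int = 12
    gene_length_bp: int = 3000
    n_intergenic: int = 4000
    intergenic_region_length: int = 150
    founder_haplotypes_per_gene: int = 256
    switch_rate_per_bp: float = 8e-4
    ancestral_beta: tuple[float, float] = (0.05, 1.2)
    env_gradient_slope: float = 5.0
    env_noise_sd: float = 2.0
    n_adaptive_loci: int = 20
    cline_strength: float = 1.5
    n_divergent_loci: int = 0
    divergent_delta: float = 0.75
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop length must equal n_subpops")
        if len(self.fst_per_subpop) != self.n_subpops:
            raise ValueError("fst_per_subpop length must equal n_subpops")
        if any(n < 1 for n in self.samples_per_subpop):
            raise ValueError("each subpopulation needs at least one sample")
        for f in self.fst_per_subpop:
            if not (0.0 <= f < 1.0):
                raise ValueError(
                    "fst must lie in [0, 1); F = 1 gives a degenerate "
                    "Balding-Nichols Beta"
                )
        if self.loci_per_gene > self.gene_length_bp:
            raise ValueError("loci_per_gene exceeds gene_length_bp")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be a probability")
        if self.founder_haplotypes_per_gene < 2:
            raise ValueError("need at least 2 founder haplotypes")
        for name in ("n_genes", "loci_per_gene", "n_intergenic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_subpop))

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, for power / FDR evaluation."""

    adaptive_locus_ids: list[str]
    cline_coefficients: dict[str, float]  # locus id -> logit units per env sd
    cline_variable: str
    divergent_locus_ids: list[str]
    subpop_freqs: pd.DataFrame  # loci x subpop realized frequencies
    true_fst: tuple[float, ...]
    subpop_of_sample: pd.Series  # sample id -> subpop label
    coords: pd.DataFrame  # sample id, lat, lon, altitude

    def truth_frame(self) -> pd.DataFrame:
        """Flat per-locus table (adaptive / divergent flags + coefficients)."""
        df = self.subpop_freqs.copy()
        df["adaptive"] = df.index.isin(self.adaptive_locus_ids)
        df["divergent"] = df.index.isin(self.divergent_locus_ids)
        df["cline_coefficient"] = [
            self.cline_coefficients.get(l, 0.0) for l in df.index
        ]
        return df


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fixed-order independent substreams derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    """Subpopulation frequencies with E = p, Var = F p(1-p)."""
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _sample_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted offsets in [0, length)."""
    return np.sort(rng.choice(length, size=n, replace=False))


def simulate_coordinates(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Sample coordinates: subpopulations strung along a longitude gradient,
    latitude and altitude varying independently within subpopulations."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    centers = np.linspace(-96.0, -78.0, config.n_subpops)
    rows = []
    i = 0
    for s, n in enumerate(config.samples_per_subpop):
        lon = centers[s] + rng.normal(0.0, 1.2, size=n)
        lat = 32.0 + rng.normal(0.0, 1.5, size=n)
        alt = np.abs(rng.normal(80.0, 40.0, size=n))
        for j in range(n):
            rows.append((f"s{i:04d}", lat[j], lon[j], alt[j], f"pop{s + 1}"))
            i += 1
    return pd.DataFrame(rows, columns=["sample", "lat", "lon", "altitude", "subpop"])


def env_target_correlation(config: SimulationConfig) -> pd.DataFrame:
    """Correlation matrix implied by the variable loadings and noise level.

    The three geographic signals are standardized and mutually independent,
    so for loading vectors l_i the model correlation is
    ``s^2 l_i.l_j / sqrt((s^2|l_i|^2 + sd^2)(s^2|l_j|^2 + sd^2))``.
    """
    names = list(ENV_VARIABLES)
    load = np.array([ENV_VARIABLES[n][1] for n in names])
    s2 = config.env_gradient_slope**2
    cov = s2 * load @ load.T + np.eye(len(names)) * config.env_noise_sd**2
    d = np.sqrt(np.diag(cov))
    return pd.DataFrame(cov / np.outer(d, d), index=names, columns=names)


def simulate_env_gradient(
    coords: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Generate >= 11 correlated climate variables as linear functions of
    standardized latitude / longitude / altitude plus Gaussian noise.

    Returns a table with one row per unit (sample or deme): identifier,
    coordinates, and one column per variable.
    """
    if {"lat", "lon", "altitude"} - set(coords.columns):
        raise ValueError("coords must have lat, lon and altitude columns")
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    signals = np.column_stack(
        [
            standardize(coords["lat"].to_numpy()),
            standardize(coords["lon"].to_numpy()),
            standardize(coords["altitude"].to_numpy()),
        ]
    )
    out = coords[[c for c in ("sample", "deme") if c in coords.columns]].copy()
    out[["lat", "lon", "altitude"]] = coords[["lat", "lon", "altitude"]]
    n = len(coords)
    for name, (_group, load) in ENV_VARIABLES.items():
        base = config.env_gradient_slope * signals @ np.asarray(load)
        noise = (
            rng.normal(0.0, config.env_noise_sd, size=n)
            if config.env_noise_sd > 0
            else 0.0
        )
        out[name] = base + noise
    return out


def env_variable_groups() -> dict[str, list[str]]:
    """Variable names by group (temperature / precipitation)."""
    groups: dict[str, list[str]] = {}
    for name, (group, _l) in ENV_VARIABLES.items():
        groups.setdefault(group, []).append(name)
    return groups


def cline_signal(coords: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    """Noise-free standardized climate signal that drives planted clines."""
    signals = np.column_stack(
        [
            standardize(coords["lat"].to_numpy()),
            standardize(coords["lon"].to_numpy()),
            standardize(coords["altitude"].to_numpy()),
        ]
    )
    load = np.asarray(ENV_VARIABLES[CLINE_VARIABLE][1])
    return standardize(signals @ load)


def _carrier_counts(
    rng: np.random.Generator, q: np.ndarray, pool: int
) -> np.ndarray:
    """Stochastically rounded carrier counts so E[count/pool] = q."""
    return np.floor(pool * q + rng.random(q.shape)).astype(int).clip(0, pool)


def _gene_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    positions: np.ndarray,
    counts: np.ndarray,
    orient: np.ndarray,
    pool: int,
    switch_rate: float,
) -> np.ndarray:
    """Mosaic haplotypes over the founder pool for one gene, one subpop.

    ``counts[l]`` founders carry the alternate allele at locus l; the carrier
    block is a prefix of the pool or (orient) a suffix, which gives adjacent
    loci strongly overlapping carrier sets and hence high short-range r^2.
    """
    n_loci = len(positions)
    founders = np.empty((n_hap, n_loci), dtype=np.int64)
    founders[:, 0] = rng.integers(pool, size=n_hap)
    if n_loci > 1:
        gaps = np.diff(positions).astype(float)
        p_switch = 1.0 - np.exp(-switch_rate * gaps)
        switch = rng.random((n_hap, n_loci - 1)) < p_switch[None, :]
        fresh = rng.integers(pool, size=(n_hap, n_loci - 1))
        for j in range(1, n_loci):
            founders[:, j] = np.where(
                switch[:, j - 1], fresh[:, j - 1], founders[:, j - 1]
            )
    # founder f carries alt at locus l iff f < counts[l] (prefix) or
    # f >= pool - counts[l] (suffix)
    hap = np.where(
        orient[None, :],
        founders >= (pool - counts)[None, :],
        founders < counts[None, :],
    )
    return hap.astype(np.int8)


def _quality_annotations(
    rng: np.random.Generator, n_loci: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Site-level QUAL / MQ / strand-bias-p / end-distance-bias-p fields,
    with small planted fractions failing the standard filter thresholds."""
    qual = rng.gamma(4.0, 100.0, size=n_loci)  # a few % below 50
    mq = 60.0 - rng.exponential(6.0, size=n_loci)  # rarely below 30
    sb = np.where(
        rng.random(n_loci) < 0.005,
        10.0 ** rng.uniform(-9, -4, size=n_loci),
        rng.uniform(1e-4, 1.0, size=n_loci),
    )
    edb = np.where(
        rng.random(n_loci) < 0.005,
        10.0 ** rng.uniform(-9, -4, size=n_loci),
        rng.uniform(1e-4, 1.0, size=n_loci),
    )
    return qual, np.round(mq, 2), sb, edb


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[GeneRegion], pd.DataFrame, SyntheticTruth]:
    """Simulate a full cohort.

    Returns the genotype matrix (with phased haplotypes attached), the gene
    and intergenic region table, the per-sample environment table, and the
    ground-truth record.  Identical configs (including seed) produce
    bit-identical outputs.
    """
    (
        rng_freq,
        rng_hap,
        rng_coord,
        rng_env,
        rng_plant,
        rng_qc,
        rng_miss,
    ) = _rngs(config.seed, 7)

    coords = simulate_coordinates(config, rng_coord)
    env = simulate_env_gradient(coords, config, rng_env)
    env_z = cline_signal(coords, config)

    n_genic = config.n_genes * config.loci_per_gene
    n_loci = n_genic + config.n_intergenic
    P = config.n_subpops
    pool = config.founder_haplotypes_per_gene

    # --- locus layout -----------------------------------------------------
    regions: list[GeneRegion] = []
    chrom_arr = np.empty(n_loci, dtype=object)
    pos_arr = np.zeros(n_loci, dtype=np.int64)
    gene_arr = np.empty(n_loci, dtype=object)
    class_arr = np.empty(n_loci, dtype=object)
    gene_slices: list[slice] = []
    for g in range(config.n_genes):
        chrom = f"Chr{g % N_CHROMOSOMES + 1:02d}"
        start = 50_000 + (g // N_CHROMOSOMES) * (config.gene_length_bp + 10_000)
        offs = _sample_positions(rng_freq, config.loci_per_gene, config.gene_length_bp)
        sl = slice(g * config.loci_per_gene, (g + 1) * config.loci_per_gene)
        gene_slices.append(sl)
        gid = f"gene{g:05d}"
        chrom_arr[sl] = chrom
        pos_arr[sl] = start + offs + 1  # 1-based VCF coordinates
        gene_arr[sl] = gid
        class_arr[sl] = "genic"
        regions.append(
            GeneRegion(
                gene_id=gid,
                chrom=chrom,
                start=start,
                end=start + config.gene_length_bp,
                surveyed_length=config.gene_length_bp,
                region_class="genic",
            )
        )
    for i in range(config.n_intergenic):
        chrom = f"Chr{i % N_CHROMOSOMES + 1:02d}"
        start = 5_000_000 + (i // N_CHROMOSOMES) * 20_000
        j = n_genic + i
        rid = f"ig{i:05d}"
        chrom_arr[j] = chrom
        pos_arr[j] = start + config.intergenic_region_length // 2 + 1
        gene_arr[j] = rid
        class_arr[j] = "intergenic"
        regions.append(
            GeneRegion(
                gene_id=rid,
                chrom=chrom,
                start=start,
                end=start + config.intergenic_region_length,
                surveyed_length=config.intergenic_region_length,
                region_class="intergenic",
            )
        )
    locus_ids = np.array(
        [f"{c}:{p}" for c, p in zip(chrom_arr, pos_arr)], dtype=object
    )

    # --- allele frequencies -----------------------------------------------
    a, b = config.ancestral_beta
    ancestral = rng_freq.beta(a, b, size=n_loci).clip(0.005, 0.995)
    subpop_freqs = np.column_stack(
        [
            _balding_nichols(rng_freq, ancestral, config.fst_per_subpop[s])
            for s in range(P)
        ]
    )

    # planted loci: adaptive clines and strongly divergent loci, at most one
    # per gene, away from the founder-pool LD machinery's extremes
    genic_ids = np.arange(n_genic)
    genes_of = genic_ids // config.loci_per_gene
    n_plant = config.n_adaptive_loci + config.n_divergent_loci
    if n_plant > config.n_genes:
        raise ValueError("more planted loci than genes (need one gene each)")
    planted_genes = rng_plant.choice(config.n_genes, size=n_plant, replace=False)
    planted_loci = np.array(
        [
            g * config.loci_per_gene + rng_plant.integers(config.loci_per_gene)
            for g in planted_genes
        ],
        dtype=int,
    )
    adaptive_idx = planted_loci[: config.n_adaptive_loci]
    divergent_idx = planted_loci[config.n_adaptive_loci :]

    # adaptive loci: keep subpop frequencies away from the boundary so the
    # logit shift has room to act
    cline_coef = np.zeros(n_loci)
    for l in adaptive_idx:
        subpop_freqs[l] = rng_plant.uniform(0.25, 0.75)
        sign = 1.0 if rng_plant.random() < 0.5 else -1.0
        cline_coef[l] = sign * config.cline_strength * rng_plant.uniform(0.5, 1.5)
    # divergent loci: force |delta p| between a random pair of subpops
    for l in divergent_idx:
        lo = rng_plant.uniform(0.05, 0.2)
        hi = min(lo + config.divergent_delta, 0.95)
        hi_pop = rng_plant.integers(P)
        for s in range(P):
            subpop_freqs[l, s] = hi if s == hi_pop else lo

    # --- haplotypes ---------------------------------------------------------
    n_samples = config.n_samples
    haplotypes = np.zeros((2 * n_samples, n_loci), dtype=np.int8)
    sample_subpop = np.repeat(np.arange(P), config.samples_per_subpop)
    hap_subpop = np.repeat(sample_subpop, 2)
    orient = rng_hap.random(n_genic) < 0.5  # per-locus carrier-block side

    for s in range(P):
        rows = np.flatnonzero(hap_subpop == s)
        n_hap = rows.size
        for g in range(config.n_genes):
            sl = gene_slices[g]
            counts = _carrier_counts(rng_hap, subpop_freqs[sl, s], pool)
            haplotypes[np.ix_(rows, np.arange(sl.start, sl.stop))] = _gene_haplotypes(
                rng_hap,
                n_hap,
                pos_arr[sl],
                counts,
                orient[sl],
                pool,
                config.switch_rate_per_bp,
            )
        # intergenic: independent Bernoulli draws per chromosome copy
        ig = slice(n_genic, n_loci)
        haplotypes[rows, ig] = (
            rng_hap.random((n_hap, config.n_intergenic))
            < subpop_freqs[ig, s][None, :]
        ).astype(np.int8)

    # adaptive loci: per-haplotype Bernoulli with an environment-dependent
    # logit shift (overrides the founder mosaic at that column only)
    env_z_hap = np.repeat(env_z, 2)
    for l in adaptive_idx:
        base = np.log(subpop_freqs[l] / (1.0 - subpop_freqs[l]))
        logit = base[hap_subpop] + cline_coef[l] * env_z_hap
        prob = 1.0 / (1.0 + np.exp(-logit))
        haplotypes[:, l] = (rng_hap.random(2 * n_samples) < prob).astype(np.int8)

    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)

    # --- quality fields and missingness -------------------------------------
    qual, mq, sb, edb = _quality_annotations(rng_qc, n_loci)
    lam = rng_qc.gamma(4.0, 7.5, size=(n_samples, n_loci))
    dp = rng_qc.poisson(lam).astype(np.int16)
    gq = np.minimum(99, rng_qc.gamma(6.0, 12.0, size=(n_samples, n_loci))).astype(
        np.int16
    )
    mask = rng_miss.random((n_samples, n_loci)) < config.missing_rate
    genotypes[mask] = -1

    ref = np.full(n_loci, "A", dtype=object)
    alt = np.full(n_loci, "G", dtype=object)
    loci = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "ref": ref,
            "alt": alt,
            "qual": np.round(qual, 2),
            "mq": mq,
            "strand_bias_p": sb,
            "end_dist_bias_p": edb,
            "gene_id": gene_arr,
            "region_class": class_arr,
        },
        columns=LOCUS_COLUMNS,
    )

    samples = list(coords["sample"])
    matrix = GenotypeMatrix(
        samples=samples,
        loci=loci,
        genotypes=genotypes,
        gq=gq,
        dp=dp,
        haplotypes=haplotypes,
    )

    truth = SyntheticTruth(
        adaptive_locus_ids=[locus_ids[l] for l in adaptive_idx],
        cline_coefficients={
            locus_ids[l]: float(cline_coef[l]) for l in adaptive_idx
        },
        cline_variable=CLINE_VARIABLE,
        divergent_locus_ids=[locus_ids[l] for l in divergent_idx],
        subpop_freqs=pd.DataFrame(
            subpop_freqs,
            index=pd.Index(locus_ids, name="locus"),
            columns=[f"pop{s + 1}" for s in range(P)],
        ),
        true_fst=config.fst_per_subpop,
        subpop_of_sample=pd.Series(
            [f"pop{s + 1}" for s in sample_subpop], index=samples, name="subpop"
        ),
        coords=coords.set_index("sample")[["lat", "lon", "altitude"]],
    )
    return matrix, regions, env, truth


def truth_q_matrix(truth: SyntheticTruth) -> pd.DataFrame:
    """Idealized ancestry-coefficient matrix from the true subpop labels.

    True members get coefficient 1 for their subpopulation; useful when the
    pipeline needs a Q-matrix input and no admixture model was simulated.
    """
    labels = sorted(truth.subpop_of_sample.unique())
    q = pd.DataFrame(
        0.0, index=truth.subpop_of_sample.index, columns=labels
    )
    for s, lab in truth.subpop_of_sample.items():
        q.loc[s, lab] = 1.0
    return q
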