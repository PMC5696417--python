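"""Pipeline orchestration: simulate -> filter -> diversity -> LD -> X^T^X ->
environmental association (both engines) -> set integration -> enrichment.

Every stage writes plain-text artifacts into the output directory and
registers them in a manifest (JSON) that records the configuration, the
master seed, per-stage row counts and a SHA-256 hash of every output file.
Reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import eaa, differentiation, integration, ld
from . import genotype_io as gio
from .core import GenotypeMatrix, SubpopAssignment, regions_to_frame
from .simulate import (
    SimulationConfig,
    env_variable_groups,
    simulate_cohort,
    truth_q_matrix,
)

log = logging.getLogger("deltapop")

STAGES = [
    "simulate",
    "filter",
    "diversity",
    "ld",
    "xtx",
    "eaa_lfmm",
    "eaa_bayenv",
    "integrate",
    "enrich",
]


@dataclass
class PipelineConfig:
    """All stage parameters with field defaults matching the analysis
    protocol (filter thresholds, MAF cutoffs, K = 2 latent factors, 5 runs,
    Bonferroni alpha 0.01, 50 demes, top-1% intersection, FDR 0.05)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: gio.FilterThresholds = field(default_factory=gio.FilterThresholds)
    regroup: dict[str, list[str]] | None = None
    ancestry_cutoff: float = 0.8
    ld_maf_cutoffs: tuple[float, ...] = (0.01, 0.05, 0.10)
    ld_threshold: float = 0.2
    xtx_genic_maf: float = 0.1
    xtx_fdr: float = 0.05
    omega_spacing_bp: int = 15_000
    omega_max_loci: int = 1800
    lfmm_k: int = 2
    lfmm_runs: int = 5
    lfmm_alpha: float = 0.01
    lfmm_maf: float = 0.05
    lfmm_prune_r2: float = 0.8
    n_demes: int = 50
    bayenv_top_q: float = 0.01
    bayenv_prior_sd: float = 1.0
    tajima_q: float = 0.01
    enrichment_fdr: float = 0.05
    mu_per_year: float = 2.5e-9
    generation_years: float = 15.0
    n_annotation_terms: int = 30
    annotation_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            sim = dict(self.simulation)
            for key in ("samples_per_subpop", "fst_per_subpop", "ancestral_beta"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            self.simulation = SimulationConfig(**sim)
        if isinstance(self.thresholds, dict):
            self.thresholds = gio.FilterThresholds(**self.thresholds)
        if isinstance(self.ld_maf_cutoffs, list):
            self.ld_maf_cutoffs = tuple(self.ld_maf_cutoffs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, simulation=self.simulation.replace(seed=seed)
        )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def synthetic_annotation(
    genes: list[str], n_terms: int, seed: int
) -> pd.DataFrame:
    """Deterministic synthetic gene -> term table (1-3 terms per gene).

    A stand-in for a user-supplied functional annotation, used when the
    pipeline runs on simulated cohorts.
    """
    rng = np.random.default_rng(seed + 104729)
    rows = []
    for g in genes:
        k = rng.integers(1, 4)
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append((g, f"term{t:03d}"))
    return pd.DataFrame(rows, columns=["gene", "term"])


class PipelineRun:
    """Executes the stages in order, collecting artifacts and a manifest."""

    def __init__(self, config: PipelineConfig, out_dir: str):
        self.config = config
        self.out = out_dir
        os.makedirs(out_dir, exist_ok=True)
        self.manifest: dict = {
            "config": config.to_dict(),
            "seed": config.seed,
            "stages": {},
        }
        # in-memory state shared between stages
        self.matrix: GenotypeMatrix | None = None
        self.filtered: GenotypeMatrix | None = None
        self.regions = None
        self.env: pd.DataFrame | None = None
        self.truth = None
        self.assignment: SubpopAssignment | None = None
        self.per_gene: pd.DataFrame | None = None
        self.selected_vars: list[str] | None = None
        self.candidates: dict[str, integration.CandidateSet] = {}
        self.lfmm_genes: set[str] = set()
        self.xtx_gene_tab: pd.DataFrame | None = None

    # -- helpers ------------------------------------------------------------

    def _path(self, name: str) -> str:
        return os.path.join(self.out, name)

    def _register(self, stage: str, rows: int, files: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "rows": int(rows),
            "files": {os.path.basename(f): _sha256(f) for f in sorted(files)},
        }
        log.info("stage %s: %d rows, %d files", stage, rows, len(files))

    def _assign(self, q: pd.DataFrame) -> SubpopAssignment:
        cfg = self.config
        if cfg.regroup:
            q = gio.regroup_q_matrix(q, cfg.regroup)
        return gio.assign_subpopulations(q, cutoff=cfg.ancestry_cutoff)

    def _load_upstream(self) -> None:
        """Reload the filter-stage artifacts from disk (for stage subsets)."""
        self.filtered = gio.read_vcf(self._path("filtered.vcf"))
        self.regions = gio.read_regions_bed(self._path("regions.bed"))
        self.env = gio.read_table(self._path("environment.tsv"))
        q = gio.read_q_matrix(self._path("q_matrix.tsv"))
        self.assignment = self._assign(q)

    # -- stages --------------------------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        self.matrix, self.regions, self.env, self.truth = simulate_cohort(
            cfg.simulation
        )
        q = truth_q_matrix(self.truth)
        self.assignment = self._assign(q)
        vcf = self._path("cohort.vcf")
        bed = self._path("regions.bed")
        envp = self._path("environment.tsv")
        qp = self._path("q_matrix.tsv")
        tp = self._path("truth.tsv")
        gio.write_vcf(self.matrix, vcf)
        gio.write_regions_bed(self.regions, bed)
        gio.write_table(self.env, envp)
        gio.write_q_matrix(q, qp)
        gio.write_table(self.truth.truth_frame().reset_index(), tp)
        self._register("simulate", self.matrix.n_loci, [vcf, bed, envp, qp, tp])

    def stage_filter(self) -> None:
        if self.matrix is None:
            self.matrix = gio.read_vcf(self._path("cohort.vcf"))
        self.filtered, report = gio.filter_snps(self.matrix, self.config.thresholds)
        fvcf = self._path("filtered.vcf")
        frep = self._path("filter_report.tsv")
        gio.write_vcf(self.filtered, fvcf)
        gio.write_table(report.to_frame(), frep)
        self._register("filter", self.filtered.n_loci, [fvcf, frep])

    def stage_diversity(self) -> None:
        cfg = self.config
        mat, regions, assignment = self.filtered, self.regions, self.assignment
        self.per_gene = dv.gene_diversity(mat, regions, assignment)
        summary = dv.population_summary(self.per_gene)
        mu = dv.mutation_rate_per_generation(cfg.mu_per_year, cfg.generation_years)
        ne_rows = []
        for row in summary.itertuples(index=False):
            theta = row.mean_theta_w
            if np.isfinite(theta):
                ne_rows.append(
                    (
                        row.population,
                        row.region_class,
                        theta,
                        mu,
                        dv.ne_from_theta(theta, mu, round_hundreds=True),
                    )
                )
        ne = pd.DataFrame(
            ne_rows, columns=["population", "region_class", "theta_w", "mu", "ne"]
        )
        p1 = self._path("diversity_per_gene.tsv")
        p2 = self._path("diversity_summary.tsv")
        p3 = self._path("effective_size.tsv")
        gio.write_table(self.per_gene, p1)
        gio.write_table(summary, p2)
        gio.write_table(ne, p3)
        self._register("diversity", len(self.per_gene), [p1, p2, p3])

    def stage_ld(self) -> None:
        cfg = self.config
        rows = []
        for maf in cfg.ld_maf_cutoffs:
            fit, pairs = ld.fit_population_ld(
                self.filtered, maf_cutoff=maf, threshold=cfg.ld_threshold
            )
            rows.append(
                (
                    "total",
                    maf,
                    fit.c_per_bp,
                    fit.n,
                    fit.n_pairs,
                    fit.rss,
                    fit.decay_distance,
                )
            )
        fits = pd.DataFrame(
            rows,
            columns=[
                "population",
                "maf_cutoff",
                "c_per_bp",
                "n",
                "n_pairs",
                "rss",
                "decay_distance_bp",
            ],
        )
        p = self._path("ld_fits.tsv")
        gio.write_table(fits, p)
        self._register("ld", len(fits), [p])

    def stage_xtx(self) -> None:
        cfg = self.config
        snp, gene, omega = differentiation.xtx_scan(
            self.filtered,
            assignment=self.assignment,
            genic_maf=cfg.xtx_genic_maf,
            fdr=cfg.xtx_fdr,
            omega_kwargs={
                "min_spacing_bp": cfg.omega_spacing_bp,
                "max_loci": cfg.omega_max_loci,
            },
        )
        self.xtx_gene_tab = gene
        self.candidates["xtx"] = integration.CandidateSet(
            method="xtx", genes=list(gene.loc[gene["outlier"], "gene_id"])
        )
        p1 = self._path("xtx_snps.tsv")
        p2 = self._path("xtx_genes.tsv")
        p3 = self._path("omega_subpop.tsv")
        gio.write_table(snp, p1)
        gio.write_table(gene, p2)
        gio.write_table(
            pd.DataFrame(omega.values, index=omega.labels, columns=omega.labels),
            p3,
            index=True,
        )
        self._register("xtx", len(snp), [p1, p2, p3])

    def _common_genic(self) -> GenotypeMatrix:
        cfg = self.config
        genic = np.flatnonzero(
            self.filtered.loci["region_class"].to_numpy() == "genic"
        )
        common = gio.filter_by_maf(
            self.filtered.take_loci(genic), cfg.lfmm_maf, keep="greater"
        )
        keep = gio.ld_prune(common, r2_threshold=cfg.lfmm_prune_r2, window_bp=5000)
        return common.take_loci(keep)

    def stage_eaa_lfmm(self) -> None:
        cfg = self.config
        groups = env_variable_groups()
        self.selected_vars, prov = eaa.select_env_variables(self.env, groups)
        common = self._common_genic()
        tables = []
        for i, var in enumerate(self.selected_vars):
            res = eaa.lfmm_scan(
                common,
                self.env[var].to_numpy(),
                variable=var,
                k=cfg.lfmm_k,
                n_runs=cfg.lfmm_runs,
                alpha=cfg.lfmm_alpha,
                seed=cfg.seed * 1000 + i,
            )
            t = res.table
            t["inflation"] = res.inflation
            tables.append(t)
        assoc = pd.concat(tables, ignore_index=True)
        sig = assoc[assoc["significant"]]
        self.lfmm_genes = set(sig["gene_id"])
        self.candidates["lfmm"] = integration.CandidateSet(
            method="lfmm",
            genes=sorted(self.lfmm_genes),
            provenance=sig[["gene_id", "locus", "variable"]].reset_index(drop=True),
        )
        p1 = self._path("lfmm_associations.tsv")
        p2 = self._path("env_selected_variables.tsv")
        gio.write_table(assoc, p1)
        gio.write_table(prov, p2)
        self._register("eaa_lfmm", len(assoc), [p1, p2])

    def stage_eaa_bayenv(self) -> None:
        cfg = self.config
        coords = self.env.set_index("sample")[["lat", "lon", "altitude"]]
        env_idx = self.env.set_index("sample")
        if self.selected_vars is None:
            self.selected_vars, _ = eaa.select_env_variables(
                self.env, env_variable_groups()
            )
        demes = eaa.group_demes(
            coords, env_idx, self.selected_vars, k=cfg.n_demes, seed=cfg.seed
        )
        # Omega over demes from LD-pruned complete genic loci, excluding loci
        # already flagged by the differentiation or latent-factor scans
        genic = np.flatnonzero(
            self.filtered.loci["region_class"].to_numpy() == "genic"
        )
        genic_mat = self.filtered.take_loci(genic)
        # near-complete common loci stand in for the "no missing data" rule:
        # under scattered missingness a literally complete locus is
        # vanishingly rare, and rare loci carry no frequency signal per deme
        from .genotype_io import minor_allele_frequency

        with np.errstate(invalid="ignore"):
            low_miss = np.flatnonzero(
                (genic_mat.missing_fraction() <= 0.1)
                & np.nan_to_num(minor_allele_frequency(genic_mat) > 0.05)
            )
        genic_mat_omega = genic_mat.take_loci(low_miss)
        keep = low_miss[
            gio.ld_prune(genic_mat_omega, r2_threshold=0.2, window_bp=5000)
        ]
        locus_ids = (
            genic_mat.loci["chrom"].astype(str)
            + ":"
            + genic_mat.loci["pos"].astype(str)
        ).to_numpy()
        flagged: set[str] = set()
        if "xtx" in self.candidates and self.xtx_gene_tab is not None:
            flagged |= set(
                self.xtx_gene_tab.loc[self.xtx_gene_tab["outlier"], "gene_id"]
            )
        gene_ids = genic_mat.loci["gene_id"].to_numpy()
        keep = np.asarray(
            [j for j in keep if gene_ids[j] not in flagged], dtype=int
        )
        _freqs_n, _chrom_n, pop_indices = eaa.deme_frequencies(genic_mat, demes)
        omega = differentiation.estimate_omega(
            genic_mat, pop_indices=pop_indices, loci=keep, fill_missing=True
        )
        # scan the common SNPs with tolerable missingness
        common = self._common_genic()
        ok_miss = common.missing_fraction() <= 0.25
        common = common.take_loci(np.flatnonzero(ok_miss))
        freqs, n_chrom, _ = eaa.deme_frequencies(common, demes)
        lids = (
            common.loci["chrom"].astype(str) + ":" + common.loci["pos"].astype(str)
        )
        tables = []
        for var in self.selected_vars:
            tab = eaa.bayes_factor_scan(
                freqs,
                n_chrom,
                omega,
                demes.env[var].to_numpy(),
                locus_ids=lids,
                gene_ids=common.loci["gene_id"],
                variable=var,
                prior_sd=cfg.bayenv_prior_sd,
                top_q=cfg.bayenv_top_q,
            )
            tables.append(tab)
        assoc = pd.concat(tables, ignore_index=True)
        strong = assoc[assoc["strong_candidate"]]
        self.candidates["bayenv"] = integration.CandidateSet(
            method="bayenv",
            genes=sorted(set(strong["gene_id"])),
            provenance=strong[["gene_id", "locus", "variable"]].reset_index(drop=True),
        )
        p1 = self._path("bayenv_associations.tsv")
        p2 = self._path("omega_demes.tsv")
        gio.write_table(assoc, p1)
        gio.write_table(
            pd.DataFrame(omega.values, index=omega.labels, columns=omega.labels),
            p2,
            index=True,
        )
        self._register("eaa_bayenv", len(assoc), [p1, p2])

    def stage_integrate(self) -> None:
        cfg = self.config
        genic = self.per_gene[self.per_gene["region_class"] == "genic"]
        by_pop = genic[genic["population"] != "total"]
        taj_sets, taj_overlap = integration.tajima_outliers(by_pop, q=cfg.tajima_q)
        taj_genes = sorted(set().union(*(set(s.genes) for s in taj_sets.values())))
        self.candidates["tajima_d"] = integration.CandidateSet(
            method="tajima_d", genes=taj_genes
        )
        sets = [
            self.candidates[m]
            for m in ("tajima_d", "xtx", "lfmm", "bayenv")
            if m in self.candidates
        ]
        venn = integration.overlap_sets(sets)
        pairs = integration.pairwise_overlaps(sets)
        p1 = self._path("venn_partition.tsv")
        p2 = self._path("pairwise_overlaps.tsv")
        p3 = self._path("candidates.tsv")
        gio.write_table(venn, p1)
        gio.write_table(pairs, p2)
        cand_rows = [
            (s.method, g) for s in sets for g in s.genes
        ] + [("tajima_d_overlap", g) for g in taj_overlap]
        gio.write_table(
            pd.DataFrame(cand_rows, columns=["method", "gene"]), p3
        )
        self._register("integrate", len(venn), [p1, p2, p3])

    def stage_enrich(self) -> None:
        cfg = self.config
        universe = sorted(
            set(
                self.per_gene.loc[
                    self.per_gene["region_class"] == "genic", "gene_id"
                ]
            )
        )
        if cfg.annotation_path:
            ann = gio.read_table(cfg.annotation_path)
        else:
            ann = synthetic_annotation(universe, cfg.n_annotation_terms, cfg.seed)
        candidates = sorted(
            set().union(*(set(s.genes) for s in self.candidates.values()))
            & set(universe)
        )
        enr = integration.fisher_enrichment(
            candidates, ann, universe, fdr=cfg.enrichment_fdr
        )
        p1 = self._path("enrichment.tsv")
        p2 = self._path("annotation.tsv")
        gio.write_table(enr, p1)
        gio.write_table(ann, p2)
        self._register("enrich", len(enr), [p1, p2])

    # -- driver ---------------------------------------------------------------

    def run(self, from_stage: str | None = None, to_stage: str | None = None) -> dict:
        start = STAGES.index(from_stage) if from_stage else 0
        stop = STAGES.index(to_stage) + 1 if to_stage else len(STAGES)
        if start > 0:
            # partial run: keep the prior stages' manifest entries
            man_path = self._path("manifest.json")
            if os.path.exists(man_path):
                with open(man_path) as fh:
                    prior = json.load(fh)
                self.manifest["stages"].update(prior.get("stages", {}))
            self._load_upstream()
            if start > STAGES.index("diversity") and self.per_gene is None:
                self.per_gene = gio.read_table(self._path("diversity_per_gene.tsv"))
        for stage in STAGES[start:stop]:
            fn = getattr(self, f"stage_{stage}")
            try:
                fn()
            except Exception as exc:  # halt with stage context
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        man_path = self._path("manifest.json")
        with open(man_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.manifest


def run_pipeline(
    config: PipelineConfig,
    out_dir: str,
    from_stage: str | None = None,
    to_stage: str | None = None,
) -> dict:
    """Run the pipeline and return the manifest."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PipelineRun(config, out_dir).run(from_stage, to_stage)
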