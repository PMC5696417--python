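"""Reading, writing and filtering of genotype data.

Formats: VCF 4.2 for genotypes (INFO ``MQ``/``SP``/``EDB`` carry mapping
quality and the strand / end-distance bias p-values; ``GENE``/``RC`` carry
region membership; FORMAT ``GT:GQ:DP``), BED-style 0-based half-open
interval tables for gene and intergenic regions, and TSV for ancestry
coefficients and environment tables.

The SNP filter applies, in order: site-level rules (site quality, mapping
quality, strand bias, end-distance bias), then per-genotype masking (low GQ
or low DP set to missing), then the missingness rule — so masking happens
*before* per-locus missingness is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    LOCUS_COLUMNS,
    MISSING,
    GeneRegion,
    GenotypeMatrix,
    SubpopAssignment,
    frame_to_regions,
    regions_to_frame,
)

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=deltapop
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=SP,Number=1,Type=Float,Description="Strand bias p-value">
##INFO=<ID=EDB,Number=1,Type=Float,Description="End-distance bias p-value">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene or intergenic region id">
##INFO=<ID=RC,Number=1,Type=String,Description="Region class (genic/intergenic)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed VCF 4.2 text file."""
    loci = matrix.loci
    gq = matrix.gq
    dp = matrix.dp
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        chroms = pd.unique(loci["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, row in enumerate(loci.itertuples(index=False)):
            info = (
                f"MQ={row.mq:g};SP={row.strand_bias_p:.6g};"
                f"EDB={row.end_dist_bias_p:.6g};GENE={row.gene_id};"
                f"RC={row.region_class}"
            )
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                f"{row.chrom}:{int(row.pos)}",
                str(row.ref),
                str(row.alt),
                f"{row.qual:g}",
                "PASS",
                info,
                "GT:GQ:DP",
            ]
            col = matrix.genotypes[:, j]
            gqc = gq[:, j] if gq is not None else None
            dpc = dp[:, j] if dp is not None else None
            for i in range(matrix.n_samples):
                g = _GT_STRINGS[int(col[i])]
                gq_s = str(int(gqc[i])) if gqc is not None else "."
                dp_s = str(int(dpc[i])) if dpc is not None else "."
                fields.append(f"{g}:{gq_s}:{dp_s}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str, multiallelic: str = "drop") -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are dropped by default (``multiallelic="error"``
    rejects the file instead).  Raises a ``ValueError`` naming the field if
    the GT FORMAT field is absent; GQ/DP are optional and default to None.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    genotypes, gq_cols, dp_cols, meta = [], [], [], []
    has_gq = has_dp = True
    for v in vcf:
        if v.num_called + v.num_unknown == 0 or v.FORMAT is None or "GT" not in v.FORMAT:
            raise ValueError("required FORMAT field GT is missing")
        if len(v.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(
                    f"multi-allelic record at {v.CHROM}:{v.POS}; "
                    "only biallelic SNPs are supported"
                )
            continue
        g = v.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown
        g[g == 3] = MISSING
        genotypes.append(g)
        if has_gq:
            try:
                arr = v.format("GQ")
            except KeyError:
                arr = None
            if arr is None:
                has_gq = False
            else:
                gq_cols.append(arr.reshape(-1).astype(np.int16))
        if has_dp:
            try:
                arr = v.format("DP")
            except KeyError:
                arr = None
            if arr is None:
                has_dp = False
            else:
                dp_cols.append(arr.reshape(-1).astype(np.int16))
        info = dict(v.INFO)
        meta.append(
            (
                v.CHROM,
                v.POS,
                v.REF,
                v.ALT[0],
                v.QUAL if v.QUAL is not None else np.nan,
                float(info.get("MQ", np.nan)),
                float(info.get("SP", np.nan)),
                float(info.get("EDB", np.nan)),
                info.get("GENE", ""),
                info.get("RC", ""),
            )
        )
    loci = pd.DataFrame(meta, columns=LOCUS_COLUMNS)
    if not genotypes:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(
        samples=samples,
        loci=loci,
        genotypes=np.column_stack(genotypes),
        gq=np.column_stack(gq_cols) if has_gq and gq_cols else None,
        dp=np.column_stack(dp_cols) if has_dp and dp_cols else None,
    )


# ---------------------------------------------------------------------------
# BED and TSV tables
# ---------------------------------------------------------------------------


def write_regions_bed(regions: list[GeneRegion], path: str) -> None:
    """BED-like table: chrom, start (0-based), end (half-open), gene_id,
    surveyed_length, region_class."""
    regions_to_frame(regions)[
        ["chrom", "start", "end", "gene_id", "surveyed_length", "region_class"]
    ].to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path: str) -> list[GeneRegion]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "surveyed_length", "region_class"],
    )
    return frame_to_regions(df)


def write_q_matrix(q: pd.DataFrame, path: str) -> None:
    q.rename_axis("sample").to_csv(path, sep="\t")


def read_q_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str, **kw) -> pd.DataFrame:
    kw.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", **kw)


# ---------------------------------------------------------------------------
# SNP and genotype filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterThresholds:
    """Default thresholds of the hard-filtering protocol for GATK-style SNPs:
    sites need quality >= 50, mapping quality >= 30 and bias p-values above
    1e-5; genotypes with GQ < 20 or DP < 8 are set to missing; loci with more
    than 25% missing genotypes afterwards are dropped."""

    min_site_qual: float = 50.0
    min_mapping_quality: float = 30.0
    max_strand_bias_p: float = 1e-5  # removed when p <= this
    max_end_dist_bias_p: float = 1e-5
    min_gq: int = 20
    min_dp: int = 8
    max_missing: float = 0.25  # removed when fraction > this
    mask_rule: str = "or"  # mask genotype if GQ fails OR DP fails


@dataclass
class FilterReport:
    """Counts of loci removed per rule, in application order, plus the rule
    that fired first for every removed locus."""

    n_input: int
    removed: dict[str, int]
    n_output: int
    fired: pd.DataFrame  # columns: locus, rule

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("output", self.n_output))
        return pd.DataFrame(rows, columns=["step", "count"])


_SITE_RULES = ("site_quality", "mapping_quality", "strand_bias", "end_distance_bias")


def mask_genotypes(
    matrix: GenotypeMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> GenotypeMatrix:
    """Set genotypes failing the GQ/DP rule to missing (never imputed)."""
    g = matrix.genotypes.copy()
    if matrix.gq is not None or matrix.dp is not None:
        fail_gq = (
            matrix.gq < thresholds.min_gq
            if matrix.gq is not None
            else np.zeros(g.shape, dtype=bool)
        )
        fail_dp = (
            matrix.dp < thresholds.min_dp
            if matrix.dp is not None
            else np.zeros(g.shape, dtype=bool)
        )
        if thresholds.mask_rule == "or":
            fail = fail_gq | fail_dp
        elif thresholds.mask_rule == "and":
            fail = fail_gq & fail_dp
        else:
            raise ValueError("mask_rule must be 'or' or 'and'")
        g[fail] = MISSING
    return GenotypeMatrix(
        samples=list(matrix.samples),
        loci=matrix.loci.copy(),
        genotypes=g,
        gq=matrix.gq,
        dp=matrix.dp,
        haplotypes=matrix.haplotypes,
    )


def filter_snps(
    matrix: GenotypeMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full SNP filter and report removals per rule.

    Site-level rules are evaluated in a fixed order and each removed locus is
    attributed to the first rule it violates; genotype masking is applied to
    the survivors before the missingness rule.
    """
    loci = matrix.loci
    n_input = matrix.n_loci
    qual = loci["qual"].to_numpy(dtype=float)
    mq = loci["mq"].to_numpy(dtype=float)
    sb = loci["strand_bias_p"].to_numpy(dtype=float)
    edb = loci["end_dist_bias_p"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        fails = {
            "site_quality": qual < thresholds.min_site_qual,
            "mapping_quality": mq < thresholds.min_mapping_quality,
            "strand_bias": sb <= thresholds.max_strand_bias_p,
            "end_distance_bias": edb <= thresholds.max_end_dist_bias_p,
        }
    removed: dict[str, int] = {}
    fired_rule = np.full(n_input, "", dtype=object)
    dropped = np.zeros(n_input, dtype=bool)
    for rule in _SITE_RULES:
        new = fails[rule] & ~dropped
        removed[rule] = int(new.sum())
        fired_rule[new] = rule
        dropped |= fails[rule]

    survivors = np.flatnonzero(~dropped)
    masked = mask_genotypes(matrix.take_loci(survivors), thresholds)
    miss = masked.missing_fraction()
    fail_miss = miss > thresholds.max_missing
    removed["missingness"] = int(fail_miss.sum())
    fired_rule[survivors[fail_miss]] = "missingness"

    out = masked.take_loci(np.flatnonzero(~fail_miss))
    locus_names = (
        matrix.loci["chrom"].astype(str) + ":" + matrix.loci["pos"].astype(str)
    ).to_numpy()
    fired = pd.DataFrame(
        {
            "locus": locus_names[fired_rule != ""],
            "rule": fired_rule[fired_rule != ""],
        }
    )
    report = FilterReport(
        n_input=n_input, removed=removed, n_output=out.n_loci, fired=fired
    )
    if out.n_loci == 0:
        warnings.warn("all loci removed by filtering", stacklevel=2)
    return out, report


# ---------------------------------------------------------------------------
# Allele frequencies and pruning
# ---------------------------------------------------------------------------


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor allele frequency over non-missing genotypes.

    All-missing loci get NaN (callers drop them with a warning).
    """
    p = matrix.alt_allele_frequency()
    return np.minimum(p, 1.0 - p)


def filter_by_maf(
    matrix: GenotypeMatrix, cutoff: float, keep: str = "greater"
) -> GenotypeMatrix:
    """Keep loci whose MAF clears the cutoff.

    ``keep="greater"`` (default) keeps MAF > cutoff; ``keep="geq"`` keeps
    MAF >= cutoff.  All-missing loci are always dropped (undefined MAF).
    """
    maf = minor_allele_frequency(matrix)
    undefined = np.isnan(maf)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} all-missing loci dropped (undefined MAF)",
            stacklevel=2,
        )
    if keep == "greater":
        ok = maf > cutoff
    elif keep == "geq":
        ok = maf >= cutoff
    else:
        raise ValueError("keep must be 'greater' or 'geq'")
    ok &= ~undefined
    return matrix.take_loci(np.flatnonzero(ok))


def ld_prune(
    matrix: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_bp: int | None = None,
    require_complete: bool = False,
) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of retained loci.

    Within each chromosome, loci are scanned in position order and a locus is
    removed when its r^2 with an already retained locus exceeds the
    threshold.  ``window_bp`` limits comparisons to retained loci within that
    distance (None compares against all retained loci on the chromosome).
    ``require_complete`` additionally drops loci with any missing genotype
    first (the convention used when selecting loci for covariance
    estimation).  Deterministic given the input order.
    """
    from .ld import genotype_r2

    loci = matrix.loci
    candidates = np.arange(matrix.n_loci)
    if require_complete:
        complete = (matrix.genotypes != MISSING).all(axis=0)
        candidates = candidates[complete[candidates]]
    retained: list[int] = []
    for chrom in pd.unique(loci["chrom"]):
        on_chrom = candidates[loci["chrom"].to_numpy()[candidates] == chrom]
        order = np.argsort(loci["pos"].to_numpy()[on_chrom], kind="mergesort")
        kept_here: list[int] = []
        for j in on_chrom[order]:
            pos_j = loci["pos"].iat[j]
            ok = True
            for k in reversed(kept_here):
                if window_bp is not None and pos_j - loci["pos"].iat[k] > window_bp:
                    break
                r2 = genotype_r2(matrix.genotypes[:, j], matrix.genotypes[:, k])
                if np.isfinite(r2) and r2 > r2_threshold:
                    ok = False
                    break
            if ok:
                kept_here.append(j)
        retained.extend(kept_here)
    return np.asarray(sorted(retained), dtype=int)


# ---------------------------------------------------------------------------
# Subpopulation assignment
# ---------------------------------------------------------------------------


def assign_subpopulations(
    q: pd.DataFrame, cutoff: float = 0.8, strict: bool = True
) -> SubpopAssignment:
    """Label samples by their dominant ancestry coefficient.

    A sample is assigned to the subpopulation whose coefficient exceeds the
    cutoff (strictly, by default — a coefficient exactly at the cutoff is
    admixed); all other samples are labeled ``admixed``.
    """
    arr = q.to_numpy(dtype=float)
    if (arr < -1e-12).any():
        raise ValueError("ancestry coefficients must be non-negative")
    sums = arr.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = q.index[np.abs(sums - 1.0) > 1e-6][0]
        raise ValueError(f"ancestry coefficients of sample {bad} do not sum to 1")
    # columns named "__other__" (unlisted groups after regrouping) hold
    # leftover ancestry mass and can never be assigned
    assignable = np.array([not str(c).startswith("__") for c in q.columns])
    masked = np.where(assignable[None, :], arr, -1.0)
    best = masked.argmax(axis=1)
    best_val = masked[np.arange(len(q)), best]
    passes = best_val > cutoff if strict else best_val >= cutoff
    labels = pd.Series(
        np.where(passes, q.columns.to_numpy()[best], "admixed"),
        index=q.index,
        name="subpop",
    )
    return SubpopAssignment(labels=labels, q_matrix=q.copy(), cutoff=cutoff)


def regroup_q_matrix(q: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Merge ancestry-coefficient columns for hierarchical regrouping.

    E.g. ``{"west": ["pop1", "pop2"], "east": ["pop4"]}`` sums the western
    coefficients into one column; samples dominated by an unlisted
    subpopulation then fall below the cutoff and become admixed when the
    merged matrix is re-assigned.
    """
    out = {}
    listed: set[str] = set()
    for new, old_cols in groups.items():
        missing = [c for c in old_cols if c not in q.columns]
        if missing:
            raise ValueError(f"unknown subpopulation columns: {missing}")
        out[new] = q[old_cols].sum(axis=1)
        listed.update(old_cols)
    rest = [c for c in q.columns if c not in listed]
    merged = pd.DataFrame(out, index=q.index)
    if rest:
        merged["__other__"] = q[rest].sum(axis=1)
    return merged


def assign_regions(matrix: GenotypeMatrix, regions: list[GeneRegion]) -> GenotypeMatrix:
    """Annotate loci with gene_id / region_class from an interval table
    (for VCFs that do not carry the GENE/RC INFO tags)."""
    loci = matrix.loci.copy()
    gene = loci["gene_id"].to_numpy(dtype=object)
    rclass = loci["region_class"].to_numpy(dtype=object)
    pos0 = loci["pos"].to_numpy() - 1  # BED is 0-based half-open
    chrom = loci["chrom"].to_numpy()
    for r in regions:
        inside = (chrom == r.chrom) & (pos0 >= r.start) & (pos0 < r.end)
        gene[inside] = r.gene_id
        rclass[inside] = r.region_class
    loci["gene_id"] = gene
    loci["region_class"] = rclass
    return GenotypeMatrix(
        samples=list(matrix.samples),
        loci=loci,
        genotypes=matrix.genotypes.copy(),
        gq=matrix.gq,
        dp=matrix.dp,
        haplotypes=matrix.haplotypes,
    )
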