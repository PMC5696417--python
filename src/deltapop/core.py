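"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as a dense ``samples x loci`` int8 array with the codes
0/1/2 for the alternate-allele dosage and -1 for a missing call.  Locus
metadata (coordinates, quality annotations, gene membership) lives in a
parallel :class:`pandas.DataFrame` whose row order always matches the
column order of the genotype array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns every locus table carries, in canonical order
LOCUS_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "mq",
    "strand_bias_p",
    "end_dist_bias_p",
    "gene_id",
    "region_class",
]


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for a cohort.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``genotypes``.
    loci
        Locus metadata table; one row per column of ``genotypes``.
    genotypes
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages with -1
        coding a missing genotype.
    gq, dp
        Optional per-genotype quality and read-depth arrays with the same
        shape as ``genotypes``.
    haplotypes
        Optional phased haplotypes, shape ``(2 * n_samples, n_loci)``;
        synthetic cohorts carry them so phase-aware statistics are exact.
    """

    samples: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_loci(self, idx) -> "GenotypeMatrix":
        """Return a new matrix restricted to the locus positions ``idx``."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx].copy(),
            gq=None if self.gq is None else self.gq[:, idx].copy(),
            dp=None if self.dp is None else self.dp[:, idx].copy(),
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[:, idx].copy(),
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
            hap = self.haplotypes[hap_idx].copy()
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci.copy(),
            genotypes=self.genotypes[idx].copy(),
            gq=None if self.gq is None else self.gq[idx].copy(),
            dp=None if self.dp is None else self.dp[idx].copy(),
            haplotypes=hap,
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing genotype calls."""
        return (self.genotypes == MISSING).mean(axis=0)

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over non-missing calls.

        Loci with no non-missing call get NaN.
        """
        called = self.genotypes != MISSING
        n_chrom = 2.0 * called.sum(axis=0)
        alt = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / n_chrom, np.nan)


@dataclass(frozen=True)
class GeneRegion:
    """A captured gene (or intergenic) region.

    ``surveyed_length`` is the number of bases actually assayed (probe
    footprint), used as the per-site denominator for diversity statistics —
    not the full genomic span of the gene.
    """

    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    surveyed_length: int
    region_class: str = "genic"  # or "intergenic"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.gene_id}")
        if self.surveyed_length < 1:
            raise ValueError(f"surveyed_length < 1 for {self.gene_id}")


@dataclass
class SubpopAssignment:
    """Sample-to-subpopulation labels derived from ancestry coefficients."""

    labels: pd.Series  # index = sample id, values = subpop label or "admixed"
    q_matrix: pd.DataFrame  # samples x K ancestry coefficients
    cutoff: float = 0.8

    def samples_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def population_labels(self) -> list[str]:
        """Non-admixed labels in stable order."""
        out = []
        for lab in self.labels:
            if lab != "admixed" and lab not in out:
                out.append(lab)
        return sorted(out)

    def indices_by_population(self, samples: Sequence[str]) -> dict[str, np.ndarray]:
        """Map each subpopulation label to row indices into ``samples``."""
        pos = {s: i for i, s in enumerate(samples)}
        out: dict[str, np.ndarray] = {}
        for lab in self.population_labels():
            idx = [pos[s] for s in self.samples_in(lab) if s in pos]
            out[lab] = np.asarray(idx, dtype=int)
        return out


def regions_to_frame(regions: Sequence[GeneRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "surveyed_length": [r.surveyed_length for r in regions],
            "region_class": [r.region_class for r in regions],
        }
    )


def frame_to_regions(df: pd.DataFrame) -> list[GeneRegion]:
    return [
        GeneRegion(
            gene_id=row.gene_id,
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            surveyed_length=int(row.surveyed_length),
            region_class=str(row.region_class),
        )
        for row in df.itertuples(index=False)
    ]
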