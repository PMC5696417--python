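"""Candidate-set integration and functional enrichment.

Collects the gene sets flagged by each scan (Tajima's D outliers, the
differentiation scan, and both environmental-association engines), computes
every region of their Venn partition, and tests candidate sets for
annotation-term enrichment with a one-sided Fisher's exact (hypergeometric)
test under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg


@dataclass
class CandidateSet:
    """Genes flagged by one detection method."""

    method: str  # tajima_d | xtx | lfmm | bayenv
    genes: list[str]
    provenance: pd.DataFrame | None = None  # which SNP / variable triggered

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)

    def as_set(self) -> set[str]:
        return set(self.genes)


def tajima_outliers(
    per_gene: pd.DataFrame, q: float = 0.01
) -> tuple[dict[str, CandidateSet], list[str]]:
    """Most-negative Tajima's D genes per population, plus the overlap.

    For each population the floor(q * G) genes with the lowest D are flagged
    (G = genes with a defined D in that population).  Positive-D outliers are
    deliberately not called: a genome-wide excess of intermediate frequencies
    can also arise from duplicated regions mistaken for polymorphism, so
    positive tails are not interpretable as diversifying selection here.
    Returns ({population: CandidateSet}, overlap gene list).
    """
    sets: dict[str, CandidateSet] = {}
    for pop, grp in per_gene.groupby("population", sort=True):
        defined = grp[np.isfinite(grp["tajima_d"])]
        n_out = int(np.floor(q * len(defined)))
        if len(defined) < 100:
            raise ValueError(
                f"population {pop}: Tajima's D defined for only "
                f"{len(defined)} genes; need >= 100 for a stable 1% tail"
            )
        picked = defined.nsmallest(n_out, "tajima_d", keep="first")
        # only negative values qualify as sweep/purifying-selection candidates
        picked = picked[picked["tajima_d"] < 0]
        sets[pop] = CandidateSet(
            method="tajima_d",
            genes=list(picked["gene_id"]),
            provenance=picked[["gene_id", "tajima_d"]].reset_index(drop=True),
        )
    pops = list(sets)
    overlap: list[str] = []
    if len(pops) >= 2:
        common = set(sets[pops[0]].genes)
        for p in pops[1:]:
            common &= set(sets[p].genes)
        overlap = sorted(common)
    return sets, overlap


def overlap_sets(sets: list[CandidateSet]) -> pd.DataFrame:
    """Every region of the Venn partition of the candidate sets.

    One row per non-empty membership pattern: the methods present, the exact
    region size (genes in all of those sets and none of the others), and the
    gene list.  Rows are ordered by pattern (deterministic).  The region
    sizes sum to the size of the union (conservation).
    """
    methods = [s.method for s in sets]
    if len(set(methods)) != len(methods):
        raise ValueError("candidate sets must have distinct method tags")
    gene_sets = {s.method: s.as_set() for s in sets}
    universe = sorted(set().union(*gene_sets.values())) if sets else []
    rows = []
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            inside = set(universe)
            for m in combo:
                inside &= gene_sets[m]
            for m in methods:
                if m not in combo:
                    inside -= gene_sets[m]
            rows.append(
                (
                    "&".join(combo),
                    len(combo),
                    len(inside),
                    ",".join(sorted(inside)),
                )
            )
    return pd.DataFrame(rows, columns=["methods", "n_methods", "n_genes", "genes"])


def pairwise_overlaps(sets: list[CandidateSet]) -> pd.DataFrame:
    """Plain pairwise intersection cardinalities (not exclusive regions)."""
    rows = []
    for a, b in combinations(sets, 2):
        inter = a.as_set() & b.as_set()
        rows.append((a.method, b.method, len(a.genes), len(b.genes), len(inter)))
    return pd.DataFrame(
        rows, columns=["method_a", "method_b", "n_a", "n_b", "n_overlap"]
    )


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    q: float = float("nan")
    significant: bool = False


def fisher_enrichment(
    candidates: list[str] | set[str],
    annotation: pd.DataFrame,
    universe: list[str] | set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher's exact test per annotation term.

    ``annotation`` is a two-column table (gene, term); genes may carry many
    terms.  The universe is the gene set that entered the scan producing the
    candidates, not the whole genome, so the test conditions on the same
    ascertainment as the scan.  P-values are hypergeometric upper tails;
    q-values are Benjamini-Hochberg; ``significant`` flags q <= fdr.
    """
    universe = set(universe)
    cand = set(candidates)
    outside = cand - universe
    if outside:
        raise ValueError(
            f"candidate gene {sorted(outside)[0]} is not in the universe"
        )
    ann = annotation[annotation.iloc[:, 0].isin(universe)]
    gene_col, term_col = ann.columns[0], ann.columns[1]
    n_universe = len(universe)
    n_cand = len(cand)
    rows = []
    for term, grp in ann.groupby(term_col, sort=True):
        term_genes = set(grp[gene_col])
        k = len(term_genes & cand)
        m = len(term_genes)
        # P(X >= k) for X ~ Hypergeom(N=n_universe, K=m, n=n_cand)
        p = float(stats.hypergeom.sf(k - 1, n_universe, m, n_cand))
        rows.append((term, k, n_cand, m, n_universe, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "overlap", "set_size", "term_size", "universe_size", "p"]
    )
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["q"] <= fdr
        out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
        out["significant"] = []
    return out
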