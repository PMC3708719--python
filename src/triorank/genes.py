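"""SNP-to-gene assignment and gene-level association summaries.

A SNP is assigned to a gene when it lies within the gene body or within a
flanking window (20 kb by default — most trait-associated loci fall within
genes or no more than 20 kb outside them) on either side.  The window
boundary is inclusive at exactly the window size in 1-based inclusive
user arithmetic; internally coordinates are BED-style 0-based half-open.
A gene's association p-value is the minimum p over its mapped SNPs (no
size correction here; the per-gene SNP count is reported so gene-size bias
can be judged, and the enrichment module corrects for it separately).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from triorank.ranking import RankedSnpList

__all__ = ["map_snps_to_genes", "gene_level_p", "genes_from_top_snps",
           "gene_overlap"]

DEFAULT_WINDOW = 20_000


def map_snps_to_genes(snps: pd.DataFrame, genes: pd.DataFrame,
                      window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Many-to-many SNP-gene assignment within ``window`` bp.

    ``snps`` needs columns ``snp, chrom, pos`` (1-based marker positions, as
    in a MAP file); ``genes`` needs ``gene, chrom, start, end`` (0-based
    half-open).  A SNP maps to a gene iff the chromosome matches and its
    0-based position lies in ``[start - window, end + window)``.  Returns
    columns ``snp, gene, distance`` with distance 0 inside the gene body and
    the bp offset to the nearer edge otherwise.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    rows: list[tuple[str, str, int]] = []
    gene_groups = dict(tuple(genes.groupby("chrom", sort=False)))
    for chrom, snp_sub in snps.groupby("chrom", sort=False):
        gsub = gene_groups.get(chrom)
        if gsub is None:
            continue
        pos0 = snp_sub["pos"].to_numpy() - 1  # MAP is 1-based
        ids = snp_sub["snp"].to_numpy()
        order = np.argsort(pos0, kind="mergesort")
        pos0s, idss = pos0[order], ids[order]
        for g in gsub.itertuples(index=False):
            lo = np.searchsorted(pos0s, g.start - window, side="left")
            hi = np.searchsorted(pos0s, g.end + window, side="left")
            for k in range(lo, hi):
                p = pos0s[k]
                if p < g.start:
                    dist = int(g.start - p)
                elif p >= g.end:
                    dist = int(p - (g.end - 1))
                else:
                    dist = 0
                rows.append((idss[k], g.gene, dist))
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"])


def gene_level_p(mapping: pd.DataFrame, tdt_results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene best-SNP p-value table.

    For every gene with at least one mapped SNP that has a defined p-value,
    report ``gene, best_snp, p, n_snps`` where p is the minimum over its
    SNPs and best_snp the SNP attaining it (ties broken by chromosome then
    position).  Genes with no mapped scored SNP are absent.
    """
    cols = ["snp", "chrom", "pos", "p"]
    scored = tdt_results[cols][np.isfinite(tdt_results["p"])]
    merged = mapping.merge(scored, on="snp", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["gene", "best_snp", "p", "n_snps"])
    merged = merged.sort_values(["p", "chrom", "pos"], kind="mergesort")
    best = merged.groupby("gene", sort=True).first().reset_index()
    n = merged.groupby("gene", sort=True).size().rename("n_snps").reset_index()
    out = best.merge(n, on="gene")
    return out.rename(columns={"snp": "best_snp"})[
        ["gene", "best_snp", "p", "n_snps"]]


def genes_from_top_snps(mapping: pd.DataFrame,
                        top_set: set[str]) -> tuple[pd.DataFrame, int]:
    """Genes hit by a top-n SNP set.

    Returns ``(table, n_top_mapped)``: a table of ``gene, n_top_snps`` for
    genes with at least one SNP in ``top_set``, and the number of top SNPs
    that mapped to at least one gene.
    """
    hit = mapping[mapping["snp"].isin(top_set)]
    table = (hit.groupby("gene").size().rename("n_top_snps")
             .reset_index().sort_values("gene").reset_index(drop=True))
    return table, int(hit["snp"].nunique())


def gene_overlap(gene_sets: dict[str, set[str]], gene_universe: int) -> pd.DataFrame:
    """Observed vs expected shared-gene counts across populations.

    Expectations treat each population's mapped-gene set as a uniform random
    subset of the ``gene_universe`` annotated genes: ``g_a g_b / G`` pairwise
    and ``g_a g_b g_c / G^2`` three-way.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two populations")
    if gene_universe <= 0:
        raise ValueError("gene_universe must be positive")
    labels = list(gene_sets)
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        obs = len(gene_sets[la] & gene_sets[lb])
        exp = len(gene_sets[la]) * len(gene_sets[lb]) / gene_universe
        rows.append((f"{la}&{lb}", obs, exp))
    if len(labels) > 2:
        obs = len(set.intersection(*gene_sets.values()))
        exp = np.prod([len(s) for s in gene_sets.values()]) / gene_universe ** (
            len(labels) - 1)
        rows.append(("&".join(labels), obs, float(exp)))
    return pd.DataFrame(rows, columns=["comparison", "observed", "expected"])
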