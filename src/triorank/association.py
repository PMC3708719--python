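"""SNP quality control and the transmission disequilibrium test (TDT).

For each biallelic marker M with alleles M1/M2, every parent with a complete
genotype in a Mendelian-consistent trio contributes one tally to the 2x2
table of (transmitted, non-transmitted) alleles:

    a: M1/M1    b: M1/M2    c: M2/M1    d: M2/M2

Only heterozygous parents are informative; the TDT statistic is
``chi2 = (b - c)^2 / (b + c)``, asymptotically chi-square with 1 df under
the null of no linkage/association (transmission probability 0.5).  QC
filters follow the trio-GWAS convention: a SNP passes when its missing-call
proportion is below ``max_missing`` and the parental Hardy-Weinberg
goodness-of-fit p-value exceeds ``hwe_min_p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from triorank.simulate import MISSING, TrioCohort

logger = logging.getLogger(__name__)

__all__ = [
    "QcCriteria", "TransmissionCounts",
    "filter_snps", "hwe_test", "count_transmissions", "tdt_statistic",
    "compute_maf", "genomic_inflation", "tdt_table", "mega_tdt",
    "CHI2_1DF_MEDIAN",
]

#: Median of the chi-square distribution with 1 df (~0.4549), the null
#: reference for the genomic inflation factor.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class QcCriteria:
    """SNP inclusion thresholds: maximum missing-call proportion and minimum
    Hardy-Weinberg p-value (computed on parents)."""

    max_missing: float = 0.15
    hwe_min_p: float = 1e-6
    hwe_exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.max_missing < 1.0:
            raise ValueError("max_missing must be in (0, 1)")
        if not 0.0 < self.hwe_min_p < 1.0:
            raise ValueError("hwe_min_p must be in (0, 1)")


@dataclass(frozen=True)
class TransmissionCounts:
    """Tallies of (transmitted, non-transmitted) parental alleles at one SNP.

    ``q`` is the number of complete, Mendelian-consistent trios that
    contributed; ``a + b + c + d == 2 q``.
    """

    a: int
    b: int
    c: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.q) < 0:
            raise ValueError("negative transmission count")
        if self.a + self.b + self.c + self.d != 2 * self.q:
            raise ValueError("counts must sum to 2 x contributing trios")

    def __add__(self, other: "TransmissionCounts") -> "TransmissionCounts":
        return TransmissionCounts(self.a + other.a, self.b + other.b,
                                  self.c + other.c, self.d + other.d,
                                  self.q + other.q)


def _hwe_chi2_p(n_hom1: np.ndarray, n_het: np.ndarray,
                n_hom2: np.ndarray) -> np.ndarray:
    """Vectorised 1-df chi-square goodness-of-fit p-value for HWE.

    Monomorphic SNPs (one allele absent) fit HWE exactly and return p = 1.
    """
    n = n_hom1 + n_het + n_hom2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * n_hom1 + n_het) / (2 * n)
        exp = np.stack([n * p1**2, 2 * n * p1 * (1 - p1), n * (1 - p1) ** 2])
        obs = np.stack([n_hom1, n_het, n_hom2]).astype(float)
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0)
        chi2 = chi2.sum(axis=0)
    chi2 = np.where((n > 0) & (p1 > 0) & (p1 < 1), chi2, 0.0)
    return stats.chi2.sf(chi2, df=1)


def _hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE test: sum of probabilities of heterozygote counts no more
    likely than the observed one, conditional on the allele counts."""
    n = n_hom1 + n_het + n_hom2
    n1 = 2 * n_hom1 + n_het  # copies of the rarer-or-either allele
    if n == 0 or n1 == 0 or n1 == 2 * n:
        return 1.0
    n1, n2 = min(n1, 2 * n - n1), max(n1, 2 * n - n1)
    hets = np.arange(n1 % 2, n1 + 1, 2)
    logp = _hwe_log_probs(n1, n2, n, hets)  # log P(het = h | allele counts) + const
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def _hwe_log_probs(n1: int, n2: int, n: int, hets: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    hom1 = (n1 - hets) // 2
    hom2 = n - hets - hom1
    return (hets * np.log(2.0) + gammaln(n + 1)
            - gammaln(hom1 + 1) - gammaln(hets + 1) - gammaln(hom2 + 1))


def _parent_genotype_counts(cohort: TrioCohort) -> tuple[np.ndarray, ...]:
    parents = np.vstack([cohort.father, cohort.mother])
    n_hom1 = (parents == 2).sum(axis=0)
    n_het = (parents == 1).sum(axis=0)
    n_hom2 = (parents == 0).sum(axis=0)
    return n_hom1, n_het, n_hom2


def filter_snps(cohort: TrioCohort, criteria: QcCriteria = QcCriteria()) -> pd.DataFrame:
    """Per-SNP QC: missingness over all individuals, parental HWE, monomorphy.

    Returns a table aligned with ``cohort.markers`` with columns
    ``snp, missing_prop, hwe_p, monomorphic, qc_pass, reason``.  A SNP passes
    iff missingness < ``max_missing`` and HWE p > ``hwe_min_p``; monomorphic
    SNPs pass HWE trivially and are flagged.
    """
    if cohort.n_trios == 0 or cohort.n_snps == 0:
        raise ValueError("empty cohort")
    all_geno = np.vstack([cohort.father, cohort.mother, cohort.child])
    missing_prop = (all_geno == MISSING).mean(axis=0)
    n_hom1, n_het, n_hom2 = _parent_genotype_counts(cohort)
    if criteria.hwe_exact:
        hwe_p = np.array([_hwe_exact_p(int(h1), int(ht), int(h2))
                          for h1, ht, h2 in zip(n_hom1, n_het, n_hom2)])
    else:
        hwe_p = _hwe_chi2_p(n_hom1, n_het, n_hom2)
    allele1 = 2 * n_hom1 + n_het
    allele2 = 2 * n_hom2 + n_het
    monomorphic = (allele1 == 0) | (allele2 == 0)

    fail_miss = missing_prop >= criteria.max_missing
    fail_hwe = hwe_p <= criteria.hwe_min_p
    reason = np.where(fail_miss & fail_hwe, "missingness+hwe",
                      np.where(fail_miss, "missingness",
                               np.where(fail_hwe, "hwe", "")))
    return pd.DataFrame({
        "snp": cohort.markers["snp"].to_numpy(),
        "missing_prop": missing_prop,
        "hwe_p": hwe_p,
        "monomorphic": monomorphic,
        "qc_pass": ~(fail_miss | fail_hwe),
        "reason": reason,
    })


def hwe_test(n_hom1: int, n_het: int, n_hom2: int, exact: bool = False) -> float:
    """Hardy-Weinberg p-value from genotype counts (founders)."""
    if exact:
        return _hwe_exact_p(n_hom1, n_het, n_hom2)
    return float(_hwe_chi2_p(*(np.array([x]) for x in (n_hom1, n_het, n_hom2)))[0])


def _count_all_transmissions(cohort: TrioCohort) -> pd.DataFrame:
    """Vectorised transmission tallies for every SNP.

    A trio contributes at a SNP only when all three genotypes are present and
    jointly Mendelian-consistent; each parent then adds one tally among
    a/b/c/d.  The lone phase-ambiguous configuration (both parents and child
    heterozygous) adds one b and one c, which is what either phase implies.
    """
    F, M, C = cohort.father, cohort.mother, cohort.child
    complete = (F != MISSING) & (M != MISSING) & (C != MISSING)

    c0 = complete & (C == 0)
    c1 = complete & (C == 1)
    c2 = complete & (C == 2)
    # which parental transmissions can produce the child: x/y = allele-1 copies
    v00 = c0 & (F < 2) & (M < 2)            # both transmit allele 2
    v11 = c2 & (F > 0) & (M > 0)            # both transmit allele 1
    v10 = c1 & (F > 0) & (M < 2)            # father allele 1, mother allele 2
    v01 = c1 & (F < 2) & (M > 0)
    ambi = v10 & v01                        # only F==1 and M==1 with het child
    only10 = v10 & ~v01
    only01 = v01 & ~v10
    valid = v00 | v11 | v10 | v01

    def s(mask: np.ndarray) -> np.ndarray:
        return mask.sum(axis=0).astype(np.int64)

    a = s(v11 & (F == 2)) + s(v11 & (M == 2)) \
        + s(only10 & (F == 2)) + s(only01 & (M == 2))
    d = s(v00 & (F == 0)) + s(v00 & (M == 0)) \
        + s(only10 & (M == 0)) + s(only01 & (F == 0))
    b = s(v11 & (F == 1)) + s(v11 & (M == 1)) \
        + s(only10 & (F == 1)) + s(only01 & (M == 1)) + s(ambi)
    c = s(v00 & (F == 1)) + s(v00 & (M == 1)) \
        + s(only10 & (M == 1)) + s(only01 & (F == 1)) + s(ambi)
    q = s(valid)
    n_excluded = s(complete & ~valid)
    return pd.DataFrame({"snp": cohort.markers["snp"].to_numpy(),
                         "a": a, "b": b, "c": c, "d": d, "q": q,
                         "mendel_excluded": n_excluded})


def count_transmissions(cohort: TrioCohort, snp_id: str) -> TransmissionCounts:
    """Transmission tallies a/b/c/d for one SNP (see module docstring)."""
    j = cohort.snp_index(snp_id)
    sub = TrioCohort(markers=cohort.markers.iloc[[j]].reset_index(drop=True),
                     father=cohort.father[:, [j]], mother=cohort.mother[:, [j]],
                     child=cohort.child[:, [j]], population=cohort.population)
    row = _count_all_transmissions(sub).iloc[0]
    return TransmissionCounts(int(row.a), int(row.b), int(row.c), int(row.d),
                              int(row.q))


def tdt_statistic(counts: TransmissionCounts) -> tuple[float, float]:
    """TDT chi-square ``(b - c)^2 / (b + c)`` and its 1-df upper-tail p.

    Uninformative SNPs (no heterozygous-parent transmissions, b + c = 0)
    return ``(nan, nan)`` rather than raising: such markers simply carry no
    linkage information.
    """
    b, c = counts.b, counts.c
    if b + c == 0:
        return float("nan"), float("nan")
    chi2 = (b - c) ** 2 / (b + c)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compute_maf(cohort: TrioCohort, snp_id: str,
                who: str = "offspring") -> float:
    """Minor-allele frequency from the selected individuals' genotypes.

    ``who`` is ``"offspring"`` (the affected children; the convention used
    for reporting) or ``"parents"``.  Returns ``nan`` when every genotype in
    the subset is missing.
    """
    j = cohort.snp_index(snp_id)
    if who == "offspring":
        g = cohort.child[:, j]
    elif who == "parents":
        g = np.concatenate([cohort.father[:, j], cohort.mother[:, j]])
    else:
        raise ValueError(f"who must be 'offspring' or 'parents', got {who!r}")
    g = g[g != MISSING]
    if g.size == 0:
        return float("nan")
    f = g.sum() / (2 * g.size)  # allele-1 frequency
    return float(min(f, 1.0 - f))


def allele1_frequencies(cohort: TrioCohort, who: str = "parents") -> np.ndarray:
    """Per-SNP allele-1 frequency from offspring or parents (nan if all missing)."""
    if who == "offspring":
        g = cohort.child
    elif who == "parents":
        g = np.vstack([cohort.father, cohort.mother])
    else:
        raise ValueError(f"who must be 'offspring' or 'parents', got {who!r}")
    present = g != MISSING
    n = present.sum(axis=0)
    tot = np.where(present, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, tot / (2 * n), np.nan)


def genomic_inflation(chi2_values: np.ndarray) -> float:
    """Genomic inflation factor: median observed chi2 over the null median.

    lambda near 1 indicates no residual confounding; dividing every statistic
    by lambda is a strictly monotone transform and leaves the p-value ranking
    of SNPs unchanged.
    """
    chi2_values = np.asarray(chi2_values, dtype=float)
    chi2_values = chi2_values[~np.isnan(chi2_values)]
    if chi2_values.size == 0:
        raise ValueError("no valid chi-square statistics")
    return float(np.median(chi2_values) / CHI2_1DF_MEDIAN)


def tdt_table(cohort: TrioCohort, criteria: QcCriteria = QcCriteria(),
              gc_correct: bool = False) -> pd.DataFrame:
    """Full per-SNP association table for one cohort.

    Columns: ``snp, chrom, pos, a, b, c, d, q, chi2, p, maf_offspring,
    missing_prop, hwe_p, monomorphic, qc_pass, reason``; with ``gc_correct``
    an extra ``p_gc`` column holds genomic-control-corrected p-values
    (never used for ranking — the correction is rank-preserving).
    """
    qc = filter_snps(cohort, criteria)
    counts = _count_all_transmissions(cohort)
    b, c = counts["b"].to_numpy(float), counts["c"].to_numpy(float)
    bc = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(bc > 0, (b - c) ** 2 / np.where(bc > 0, bc, 1), np.nan)
    p = np.where(np.isnan(chi2), np.nan, stats.chi2.sf(chi2, df=1))

    child = cohort.child
    present = child != MISSING
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f1 = np.where(n > 0, np.where(present, child, 0).sum(axis=0) / (2 * n),
                      np.nan)
    maf = np.minimum(f1, 1 - f1)

    out = pd.DataFrame({
        "snp": cohort.markers["snp"].to_numpy(),
        "chrom": cohort.markers["chrom"].to_numpy(),
        "pos": cohort.markers["pos"].to_numpy(),
        "a": counts["a"], "b": counts["b"], "c": counts["c"], "d": counts["d"],
        "q": counts["q"], "chi2": chi2, "p": p, "maf_offspring": maf,
        "missing_prop": qc["missing_prop"], "hwe_p": qc["hwe_p"],
        "monomorphic": qc["monomorphic"], "qc_pass": qc["qc_pass"],
        "reason": qc["reason"],
    })
    if gc_correct:
        lam = genomic_inflation(out.loc[out["qc_pass"], "chi2"].to_numpy())
        out["p_gc"] = np.where(np.isnan(out["chi2"]), np.nan,
                               stats.chi2.sf(out["chi2"] / max(lam, 1.0), df=1))
    return out


def mega_tdt(cohorts: list[TrioCohort],
             criteria: QcCriteria = QcCriteria()) -> pd.DataFrame:
    """Pooled-cohort TDT on SNPs passing QC in every cohort.

    Transmission counts are summed across cohorts before the statistic is
    computed; the TDT remains valid under population structure, which is what
    makes this pooled mega-analysis legitimate.  Returns the same columns as
    :func:`tdt_table` (without QC detail), restricted to the shared passing
    SNPs; empty (with a logged warning) if no SNP passes everywhere.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    tables = [tdt_table(co, criteria) for co in cohorts]
    passing = [set(t.loc[t["qc_pass"], "snp"]) for t in tables]
    shared = set.intersection(*passing)
    if not shared:
        logger.warning("mega-analysis: no SNP passes QC in all %d cohorts",
                       len(cohorts))
        return pd.DataFrame(columns=["snp", "chrom", "pos", "a", "b", "c", "d",
                                     "q", "chi2", "p", "maf_offspring"])
    base = tables[0]
    keep = base["snp"].isin(shared)
    merged = base.loc[keep, ["snp", "chrom", "pos"]].reset_index(drop=True)
    sums = None
    for t in tables:
        part = t.loc[t["snp"].isin(shared),
                     ["snp", "a", "b", "c", "d", "q"]].set_index("snp")
        sums = part if sums is None else sums.add(part, fill_value=0)
    sums = sums.loc[merged["snp"]].reset_index(drop=True)

    # pooled offspring MAF weighted by per-cohort non-missing offspring counts
    num = np.zeros(len(merged))
    den = np.zeros(len(merged))
    for co in cohorts:
        idx = co.markers.set_index("snp").index.get_indexer(merged["snp"])
        child = co.child[:, idx]
        present = child != MISSING
        num += np.where(present, child, 0).sum(axis=0)
        den += 2 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(den > 0, num / den, np.nan)

    b, c = sums["b"].to_numpy(float), sums["c"].to_numpy(float)
    bc = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(bc > 0, (b - c) ** 2 / np.where(bc > 0, bc, 1), np.nan)
    out = merged.assign(a=sums["a"].astype(int), b=sums["b"].astype(int),
                        c=sums["c"].astype(int), d=sums["d"].astype(int),
                        q=sums["q"].astype(int), chi2=chi2,
                        p=np.where(np.isnan(chi2), np.nan,
                                   stats.chi2.sf(chi2, df=1)),
                        maf_offspring=np.minimum(f1, 1 - f1))
    return out
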