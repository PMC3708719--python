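"""Per-SNP population differentiation (FST) versus association-rank difference.

The question this module answers: are the SNPs whose allele frequencies
differ most between two populations also the SNPs whose disease-association
rankings differ most?  Differentiation is measured per SNP by the fixation
index FST; the association side by DRP, the absolute difference between the
SNP's p-value ranks in the two populations (re-ranked within the shared SNP
set).  Both variables are dichotomized at their means and independence is
tested with a 1-df Pearson chi-square on the 2x2 table; an observed
high-FST/high-DRP count exceeding expectation with a significant p indicates
that ancestry-informative SNPs also tend to differ in disease association.

Two FST estimators are offered.  The default is the Nei-style GST computed
from allele frequencies, ``(HT - HS) / HT`` with ``HT = 2 p̄ (1 - p̄)`` and
``HS`` the mean within-population heterozygosity — deterministic, bounded in
[0, 1], and 0 when the frequencies coincide.  The Weir-Cockerham
two-population estimator corrects for sample size (and may be negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from triorank.ranking import RankedSnpList

logger = logging.getLogger(__name__)

__all__ = ["fst_per_snp", "recover_fst_param", "drp", "dependence_test",
           "DependenceSummary"]


def fst_per_snp(p_a: np.ndarray, p_b: np.ndarray, estimator: str = "nei",
                n_a: int | None = None, n_b: int | None = None,
                clamp: bool = False) -> np.ndarray:
    """Per-SNP fixation index between two populations.

    ``p_a, p_b`` are allele-1 frequency vectors (nan where undefined, e.g.
    all calls missing; nan propagates).  For ``estimator="weir_cockerham"``
    the per-population sample sizes ``n_a, n_b`` (diploid individuals) are
    required; heterozygosity is taken at its Hardy-Weinberg expectation.
    With ``clamp`` the (possibly negative) Weir-Cockerham values are clipped
    to [0, 1].
    """
    p_a = np.atleast_1d(np.asarray(p_a, dtype=float))
    p_b = np.atleast_1d(np.asarray(p_b, dtype=float))
    if p_a.shape != p_b.shape:
        raise ValueError("frequency vectors must have the same shape")
    if estimator == "nei":
        pbar = (p_a + p_b) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = (2 * p_a * (1 - p_a) + 2 * p_b * (1 - p_b)) / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1), 0.0)
        fst = np.where(np.isnan(p_a) | np.isnan(p_b), np.nan, fst)
        return fst
    if estimator == "weir_cockerham":
        if n_a is None or n_b is None:
            raise ValueError("weir_cockerham needs sample sizes n_a and n_b")
        r = 2
        n_i = np.array([n_a, n_b], dtype=float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        p_i = np.stack([p_a, p_b])
        pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * 2 * p_i * (1 - p_i)).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = a + b + c
            fst = np.where(denom != 0, a / np.where(denom != 0, denom, 1), 0.0)
        fst = np.where(np.isnan(p_a) | np.isnan(p_b), np.nan, fst)
        return np.clip(fst, 0.0, 1.0) if clamp else fst
    raise ValueError(f"estimator must be 'nei' or 'weir_cockerham', "
                     f"got {estimator!r}")


def recover_fst_param(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Estimate the Balding-Nichols F from two population frequency vectors.

    The two-population Nei GST computed as a ratio of sums across SNPs,
    ``GST = sum(HT - HS) / sum(HT)``, has expectation ``F / (2 - F)`` when
    both populations are independent Balding-Nichols draws at parameter F
    (``E[HT - HS] = F p(1-p)`` and ``E[HT] = 2 p(1-p) (1 - F/2)`` per SNP).
    Inverting gives the estimator ``F = 2 GST / (1 + GST)``, which corrects
    the well-known factor-(r-1)/r attenuation of GST at r = 2 populations.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    ok = np.isfinite(p_a) & np.isfinite(p_b)
    p_a, p_b = p_a[ok], p_b[ok]
    pbar = (p_a + p_b) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = p_a * (1 - p_a) + p_b * (1 - p_b)
    if ht.sum() == 0:
        return 0.0
    gst = float((ht - hs).sum() / ht.sum())
    return 2 * gst / (1 + gst)


def drp(ranked_a: RankedSnpList, ranked_b: RankedSnpList) -> pd.DataFrame:
    """Absolute rank difference per SNP over the shared SNP set.

    Both rankings are restricted to their intersection and re-ranked within
    it (same p-then-position order), so DRP compares like with like even
    when the cohorts scored different marker panels.  Returns columns
    ``snp, rank_a, rank_b, drp``.
    """
    ta, tb = ranked_a.table, ranked_b.table
    shared = set(ta["snp"]) & set(tb["snp"])
    if not shared:
        raise ValueError("rankings share no SNPs")

    def rerank(t: pd.DataFrame) -> pd.Series:
        sub = t[t["snp"].isin(shared)]
        return pd.Series(np.arange(1, len(sub) + 1), index=sub["snp"])

    ra, rb = rerank(ta), rerank(tb)
    out = pd.DataFrame({"snp": ra.index, "rank_a": ra.to_numpy(),
                        "rank_b": rb.loc[ra.index].to_numpy()})
    out["drp"] = np.abs(out["rank_a"] - out["rank_b"])
    return out.reset_index(drop=True)


@dataclass
class DependenceSummary:
    """2x2 dependence of (DRP > mean DRP) x (FST > mean FST).

    ``counts`` is ordered [[high-high, high-low], [low-high, low-low]] with
    the first axis DRP and the second FST.  ``observed_hh`` and
    ``expected_hh`` are the observed and margins-expected counts of SNPs
    high on both; ``p`` is nan for a degenerate table (an empty margin).
    """

    counts: np.ndarray
    observed_hh: int
    expected_hh: float
    chi2: float
    p: float
    n: int
    mean_fst: float
    mean_drp: float


def dependence_test(records: pd.DataFrame) -> DependenceSummary:
    """Chi-square independence test of mean-dichotomized FST vs DRP.

    ``records`` needs columns ``fst`` and ``drp``; rows with undefined FST
    are excluded (logged).  Each variable is split at its mean (strictly
    greater = high; values at the mean count as low), and the resulting 2x2
    table is tested with a Pearson chi-square, 1 df, no continuity
    correction.
    """
    df = records[["fst", "drp"]]
    n_bad = int(df["fst"].isna().sum() + df["drp"].isna().sum())
    if n_bad:
        logger.info("dependence_test: excluding %d records with undefined "
                    "values", n_bad)
        df = df.dropna()
    if df["fst"].nunique() < 2 or df["drp"].nunique() < 2:
        raise ValueError("need at least two distinct values of fst and drp")
    mean_fst = float(df["fst"].mean())
    mean_drp = float(df["drp"].mean())
    hi_f = (df["fst"] > mean_fst).to_numpy()
    hi_d = (df["drp"] > mean_drp).to_numpy()
    counts = np.array([[(hi_d & hi_f).sum(), (hi_d & ~hi_f).sum()],
                       [(~hi_d & hi_f).sum(), (~hi_d & ~hi_f).sum()]],
                      dtype=np.int64)
    n = int(counts.sum())
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    expected_hh = row[0] * col[0] / n
    if (row == 0).any() or (col == 0).any():
        logger.warning("dependence_test: degenerate dichotomization "
                       "(empty margin); p undefined")
        return DependenceSummary(counts, int(counts[0, 0]), float(expected_hh),
                                 float("nan"), float("nan"), n,
                                 mean_fst, mean_drp)
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return DependenceSummary(counts, int(counts[0, 0]), float(expected_hh),
                             float(chi2), float(p), n, mean_fst, mean_drp)
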