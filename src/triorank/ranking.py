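"""Rank-based cross-population comparison of association results.

Instead of holding every population to one p-value threshold — fragile when
allele frequencies, LD and effect sizes differ across ancestries — each
population's SNPs are ranked by association p-value and the top-n sets are
compared directly.  Observed overlaps are reported against the expectation
for independent uniform random subsets of the same sizes drawn from the
shared-SNP universe: ``n_a n_b / N`` pairwise and ``n_a n_b n_c / N^2``
three-way.  Replication of one population's top SNPs in another is counted
at a nominal threshold alpha, against the null expectation ``n * alpha``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["RankedSnpList", "rank_snps", "top_n", "overlap_counts",
           "expected_overlap", "replication_count"]


@dataclass
class RankedSnpList:
    """SNPs ordered from most to least significant.

    ``table`` has columns ``snp, chrom, pos, p, rank`` with rank 1 the
    smallest p; ties in p are broken by (chromosome, position) ascending so
    the order is deterministic across runs and platforms.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp"])

    def p_map(self) -> pd.Series:
        return self.table.set_index("snp")["p"]

    def rank_map(self) -> pd.Series:
        return self.table.set_index("snp")["rank"]


def rank_snps(results: pd.DataFrame) -> RankedSnpList:
    """Rank a TDT result table by ascending p-value.

    Only QC-passing SNPs with a defined statistic are ranked (uninformative
    markers with no heterozygous-parent transmissions carry no evidence and
    are excluded).  Duplicate SNP identifiers are an error.
    """
    df = results
    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise ValueError(f"duplicate SNP id in results: {dup!r}")
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    df = df[np.isfinite(df["p"])]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out = df[["snp", "chrom", "pos", "p"]].copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return RankedSnpList(out)


def top_n(ranked: RankedSnpList, n: int) -> set[str]:
    """The identifiers of the n most significant SNPs."""
    if not 1 <= n <= len(ranked):
        raise ValueError(f"n must be in [1, {len(ranked)}], got {n}")
    return set(ranked.table["snp"].iloc[:n])


def overlap_counts(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Observed intersection sizes for every pair and for all sets jointly.

    Returns a table with columns ``comparison, observed`` where comparison is
    e.g. ``"EA&AA"`` or ``"EA&AA&HA"`` (labels joined in input order).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    labels = list(sets)
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        rows.append((f"{la}&{lb}", len(sets[la] & sets[lb])))
    if len(labels) > 2:
        rows.append(("&".join(labels), len(set.intersection(*sets.values()))))
    return pd.DataFrame(rows, columns=["comparison", "observed"])


def expected_overlap(ns: list[int], N: int, order: str = "pairwise") -> float:
    """Expected overlap of independent uniform random subsets of a universe.

    For subsets of sizes ``n_a, n_b`` from N items the expected intersection
    is ``n_a n_b / N`` (each item is in both with probability
    ``(n_a/N)(n_b/N)``); three-way, ``n_a n_b n_c / N^2``.
    """
    if any(n > N for n in ns):
        raise ValueError(f"subset sizes {ns} exceed universe {N}")
    if any(n < 0 for n in ns) or N <= 0:
        raise ValueError("sizes must be non-negative and N positive")
    if order == "pairwise":
        if len(ns) != 2:
            raise ValueError("pairwise expectation needs two sizes")
        return ns[0] * ns[1] / N
    if order == "threeway":
        if len(ns) != 3:
            raise ValueError("three-way expectation needs three sizes")
        return ns[0] * ns[1] * ns[2] / N**2
    raise ValueError(f"order must be 'pairwise' or 'threeway', got {order!r}")


def replication_count(top_set: set[str], other_p: pd.Series | dict,
                      alpha: float = 0.05) -> dict:
    """Count top SNPs of one population replicating in another at alpha.

    A SNP replicates when its p-value in the other population is below
    ``alpha``; under the null those p-values are uniform, so the chance
    expectation is ``|top_set| * alpha`` (e.g. 5 of a top-100 at 0.05).
    SNPs absent from the other cohort are dropped with a logged count, and
    the expectation uses the retained size.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    other_p = pd.Series(other_p)
    present = [s for s in top_set if s in other_p.index]
    n_dropped = len(top_set) - len(present)
    if n_dropped:
        logger.info("replication_count: %d of %d top SNPs absent in the other "
                    "cohort; dropped", n_dropped, len(top_set))
    vals = other_p.loc[present]
    observed = int((vals < alpha).sum())
    return {"observed": observed, "expected": len(present) * alpha,
            "n_top": len(present), "n_dropped": n_dropped, "alpha": alpha}
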