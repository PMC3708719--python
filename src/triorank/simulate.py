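"""Synthetic multi-population affected-offspring trio cohorts.

The generator emulates the design of a trans-ancestral trio GWAS: several
populations whose allele frequencies diverge from a shared ancestral
frequency under the Balding-Nichols model, affected-offspring trios drawn
under Hardy-Weinberg equilibrium within each population, and a transmission
model in which heterozygous parents transmit the risk allele to the affected
child with probability ``tau`` (``tau = 0.5`` is the TDT null).  Gene
annotations on a simple coordinate system and named gene sets (one of which
may be enriched for the genes harbouring risk SNPs) complete the inputs the
downstream pipeline needs.

Genotypes are stored as the number of copies of allele 1 (``A``, the M1
allele of the TDT contingency notation); ``-1`` marks a missing call.  The
risk allele is allele 1, so ``tau`` is directly the binomial transmission
probability that the TDT estimates from heterozygous parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "PopulationModel",
    "RiskModel",
    "TrioCohort",
    "simulate_ancestral_frequencies",
    "draw_population_frequencies",
    "simulate_trios",
    "generate_gene_annotation",
    "generate_gene_sets",
]


@dataclass(frozen=True)
class PopulationModel:
    """One simulated population: a label, its Balding-Nichols differentiation
    parameter relative to the ancestral frequencies, and its trio count."""

    name: str
    fst_param: float
    n_trios: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst_param < 1.0:
            raise ValueError(f"fst_param must be in [0, 1), got {self.fst_param}")
        if self.n_trios < 1:
            raise ValueError(f"n_trios must be >= 1, got {self.n_trios}")


@dataclass(frozen=True)
class RiskModel:
    """Planted association signal.

    ``tau`` is the probability that a heterozygous parent transmits the risk
    allele (allele 1) to the affected offspring at each SNP in
    ``risk_snp_ids``; 0.5 recovers the null.  ``planted_gene_set_id`` names
    the gene set that is enriched for risk-harbouring genes, if any.
    """

    risk_snp_ids: frozenset = field(default_factory=frozenset)
    tau: float = 0.5
    planted_gene_set_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {self.tau}")
        object.__setattr__(self, "risk_snp_ids", frozenset(self.risk_snp_ids))


NULL_RISK = RiskModel()


@dataclass
class TrioCohort:
    """Genotypes of father/mother/affected-offspring trios at a set of markers.

    ``markers`` is a DataFrame with columns ``snp, chrom, pos, a1, a2``
    (positions strictly increasing within a chromosome).  ``father``,
    ``mother`` and ``child`` are ``(n_trios, n_snps)`` int8 arrays counting
    copies of allele 1, with ``-1`` for missing calls.
    """

    markers: pd.DataFrame
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray
    population: str = "pop"

    def __post_init__(self) -> None:
        n = self.n_snps
        for name in ("father", "mother", "child"):
            g = getattr(self, name)
            if g.ndim != 2 or g.shape[1] != n:
                raise ValueError(f"{name} genotypes shape {g.shape} does not match "
                                 f"{n} markers")
            if g.shape[0] != self.n_trios:
                raise ValueError("trio count inconsistent across members")
            bad = ~np.isin(g, (MISSING, 0, 1, 2))
            if bad.any():
                raise ValueError(f"invalid genotype codes in {name}")
        m = self.markers
        if m["snp"].duplicated().any():
            raise ValueError("duplicate marker identifiers")
        for _, sub in m.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("marker positions must be strictly increasing "
                                 "within a chromosome")

    @property
    def n_trios(self) -> int:
        return self.father.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def snp_index(self, snp_id: str) -> int:
        idx = self.markers.index[self.markers["snp"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in cohort")
        return int(idx[0])


def simulate_ancestral_frequencies(n_snps: int, maf_low: float = 0.05,
                                   maf_high: float = 0.5,
                                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ancestral allele-1 frequencies uniformly in ``[maf_low, maf_high]``."""
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError(f"require 0 < maf_low <= maf_high <= 0.5, "
                         f"got ({maf_low}, {maf_high})")
    rng = np.random.default_rng(seed)
    return rng.uniform(maf_low, maf_high, size=n_snps)


def draw_population_frequencies(ancestral: np.ndarray, fst_param: float,
                                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Balding-Nichols population frequencies around ``ancestral``.

    Each SNP's frequency is drawn from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with
    ancestral frequency ``p`` and differentiation ``F = fst_param``; the Beta
    mean is ``p`` and its variance ``F p (1-p)``, so ``F`` is the expected
    fixation index between two populations drawn independently.  ``F = 0``
    is the degenerate (point-mass) limit and returns ``ancestral`` unchanged.
    """
    ancestral = np.asarray(ancestral, dtype=float)
    if not 0.0 <= fst_param < 1.0:
        raise ValueError(f"fst_param must be in [0, 1), got {fst_param}")
    if ancestral.size and not ((ancestral > 0) & (ancestral < 1)).all():
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if fst_param == 0.0:
        return ancestral.copy()
    rng = np.random.default_rng(seed)
    scale = (1.0 - fst_param) / fst_param
    return rng.beta(ancestral * scale, (1.0 - ancestral) * scale)


def _default_markers(n_snps: int, chrom_lengths: dict[int, int] | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Markers spread over chromosomes: uniform random distinct positions."""
    if chrom_lengths is None:
        chrom_lengths = {1: 120_000_000, 2: 100_000_000, 3: 80_000_000}
    rng = rng or np.random.default_rng(0)
    chroms = sorted(chrom_lengths)
    per = np.full(len(chroms), n_snps // len(chroms))
    per[: n_snps % len(chroms)] += 1
    rows = []
    for chrom, k in zip(chroms, per):
        pos = np.sort(rng.choice(chrom_lengths[chrom] - 1, size=k, replace=False)) + 1
        for p in pos:
            rows.append((f"snp_{chrom}_{p}", chrom, int(p), "A", "B"))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2"])


def simulate_trios(pop_freqs: np.ndarray, n_trios: int,
                   risk: RiskModel = NULL_RISK, missing_rate: float = 0.0,
                   seed: int | np.random.Generator = 0,
                   markers: pd.DataFrame | None = None,
                   population: str = "pop",
                   mendel_error_rate: float = 0.0) -> TrioCohort:
    """Simulate a cohort of affected-offspring trios.

    Parents are drawn under Hardy-Weinberg at the population allele-1
    frequencies.  Each parent transmits one allele: a heterozygous parent
    transmits allele 1 with probability 0.5 at null SNPs and ``risk.tau`` at
    planted risk SNPs; homozygous parents have no choice.  Genotype entries
    are then masked missing independently at ``missing_rate``, and child
    genotypes are corrupted at ``mendel_error_rate`` to exercise
    Mendelian-inconsistency handling (default off).
    """
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if pop_freqs.ndim != 1:
        raise ValueError("pop_freqs must be one-dimensional")
    if not ((pop_freqs >= 0) & (pop_freqs <= 1)).all():
        raise ValueError("frequencies must lie in [0, 1]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if not 0.0 <= mendel_error_rate < 1.0:
        raise ValueError("mendel_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_snps = pop_freqs.size
    if markers is None:
        markers = _default_markers(n_snps, rng=np.random.default_rng(rng.integers(2**31)))
    if len(markers) != n_snps:
        raise ValueError("marker table length does not match frequency vector")
    unknown = set(risk.risk_snp_ids) - set(markers["snp"])
    if unknown:
        raise ValueError(f"risk SNP ids not in marker list: {sorted(unknown)[:5]}")

    father = rng.binomial(2, pop_freqs, size=(n_trios, n_snps))
    mother = rng.binomial(2, pop_freqs, size=(n_trios, n_snps))

    tau = np.full(n_snps, 0.5)
    if risk.risk_snp_ids:
        tau[markers["snp"].isin(risk.risk_snp_ids).to_numpy()] = risk.tau

    def transmit(par: np.ndarray) -> np.ndarray:
        # hom parents transmit their only allele; hets transmit allele 1 w.p. tau
        t = (par == 2).astype(np.int8)
        het = par == 1
        t[het] = (rng.random(size=(n_trios, n_snps)) < tau)[het]
        return t

    child = transmit(father) + transmit(mother)

    geno = {"father": father.astype(np.int8), "mother": mother.astype(np.int8),
            "child": child.astype(np.int8)}
    if mendel_error_rate > 0:
        flip = rng.random(size=(n_trios, n_snps)) < mendel_error_rate
        geno["child"][flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.int8)
    if missing_rate > 0:
        for g in geno.values():
            g[rng.random(size=(n_trios, n_snps)) < missing_rate] = MISSING

    return TrioCohort(markers=markers.reset_index(drop=True), population=population,
                      **geno)


def generate_gene_annotation(n_genes: int, chrom_lengths: dict[int, int],
                             gene_length_range: tuple[int, int] = (5_000, 100_000),
                             min_gap: int = 10_000,
                             seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Place non-overlapping genes on the given chromosomes.

    Returns a BED-convention table (``gene, chrom, start, end``; 0-based
    half-open) sorted by (chromosome, start), with every adjacent pair on a
    chromosome separated by at least ``min_gap`` bp.  Raises if the requested
    genes cannot be packed into the chromosome lengths.
    """
    lo, hi = gene_length_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid gene_length_range {gene_length_range}")
    if n_genes == 0:
        return pd.DataFrame(columns=["gene", "chrom", "start", "end"])
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    per = np.full(len(chroms), n_genes // len(chroms))
    per[: n_genes % len(chroms)] += 1
    rows = []
    gi = 0
    for chrom, k in zip(chroms, per):
        if k == 0:
            continue
        length = chrom_lengths[chrom]
        lens = rng.integers(lo, hi + 1, size=k)
        slack = length - int(lens.sum()) - min_gap * (k - 1)
        if slack < 0:
            raise ValueError(f"cannot pack {k} genes of total span {lens.sum()} "
                             f"plus gaps into chromosome {chrom} ({length} bp)")
        # distribute the leftover space as random extra gaps before each gene
        extra = np.sort(rng.integers(0, slack + 1, size=k))
        extra = np.diff(np.concatenate(([0], extra)))
        start = 0
        for j in range(k):
            start += int(extra[j]) + (min_gap if j > 0 else 0)
            rows.append((f"gene_{gi:05d}", chrom, start, start + int(lens[j])))
            start += int(lens[j])
            gi += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def generate_gene_sets(genes: pd.DataFrame, n_sets: int,
                       size_range: tuple[int, int] = (10, 50),
                       planted_genes: list[str] | None = None,
                       seed: int | np.random.Generator = 0,
                       planted_set_name: str = "PLANTED_SET") -> dict[str, list[str]]:
    """Draw named gene sets; one set optionally contains all planted genes.

    Set sizes are uniform on ``size_range`` and members are sampled without
    replacement from the annotation.  When ``planted_genes`` is given, the
    set named ``planted_set_name`` contains all of them (padded with random
    genes up to a drawn size).
    """
    names = list(genes["gene"])
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(names):
        raise ValueError(f"size_range {size_range} incompatible with "
                         f"{len(names)} genes")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if planted_genes is not None:
        missing = set(planted_genes) - set(names)
        if missing:
            raise ValueError(f"planted genes absent from annotation: {sorted(missing)[:5]}")
        if len(planted_genes) > hi:
            raise ValueError(f"{len(planted_genes)} planted genes exceed the "
                             f"maximum set size {hi}")
        size = int(rng.integers(max(lo, len(planted_genes)), hi + 1))
        others = [g for g in names if g not in set(planted_genes)]
        pad = list(rng.choice(others, size=size - len(planted_genes), replace=False))
        sets[planted_set_name] = sorted(planted_genes) + sorted(pad)
    n_random = n_sets - (1 if planted_genes is not None else 0)
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET_{i:04d}"] = sorted(rng.choice(names, size=size, replace=False))
    return sets
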