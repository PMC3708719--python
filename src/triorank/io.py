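"""Readers and writers for the pipeline's text formats.

PLINK text PED/MAP carries the trio genotypes (one cohort per file pair),
4-column BED the gene annotation, GMT the gene sets, and YAML the pipeline
configuration.  The PED convention used throughout: family ``fam<i>`` holds
father ``fam<i>_f`` (sex 1), mother ``fam<i>_m`` (sex 2) and affected child
``fam<i>_c`` (phenotype 2; parents 1); alleles are ``A``/``B`` with ``0``
for missing.  Reading tolerates arbitrary whitespace separation.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from triorank.simulate import MISSING, TrioCohort

__all__ = [
    "write_ped_map", "read_ped_map",
    "write_bed", "read_bed",
    "write_gmt", "read_gmt",
    "load_config",
]

_ALLELES = ("A", "B")
# genotype code (# of allele-1 copies) -> allele pair
_GENO_TO_PAIR = {2: ("A", "A"), 1: ("A", "B"), 0: ("B", "B"), MISSING: ("0", "0")}
_PAIR_TO_GENO = {("A", "A"): 2, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 0}


def write_ped_map(cohort: TrioCohort, ped_path: str | Path,
                  map_path: str | Path) -> None:
    """Write a trio cohort as PLINK text PED/MAP (deterministic output)."""
    m = cohort.markers
    with open(map_path, "w") as fh:
        for row in m.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")

    # index by genotype code + 1 (missing = -1 -> slot 0)
    pair_str = np.array(["0\t0", "B\tB", "A\tB", "A\tA"])

    def geno_fields(g_row: np.ndarray) -> str:
        return "\t".join(pair_str[g_row.astype(np.int64) + 1])

    with open(ped_path, "w") as fh:
        for i in range(cohort.n_trios):
            fam = f"fam{i}"
            fh.write(f"{fam}\t{fam}_f\t0\t0\t1\t1\t{geno_fields(cohort.father[i])}\n")
            fh.write(f"{fam}\t{fam}_m\t0\t0\t2\t1\t{geno_fields(cohort.mother[i])}\n")
            fh.write(f"{fam}\t{fam}_c\t{fam}_f\t{fam}_m\t0\t2\t"
                     f"{geno_fields(cohort.child[i])}\n")


class PedFormatError(ValueError):
    """Malformed PED/MAP content; the message carries the offending line."""


def read_ped_map(ped_path: str | Path, map_path: str | Path,
                 population: str = "pop") -> TrioCohort:
    """Read a trio cohort from PLINK text PED/MAP.

    Trio structure is recovered from the father/mother id columns: each
    family must contain exactly one offspring whose parent ids resolve to
    records in the same family.  Allele symbols outside ``{A, B, 0}``,
    duplicate individual ids and orphan offspring raise :class:`PedFormatError`
    naming the line or individual.
    """
    markers = pd.read_csv(map_path, sep=r"\s+", header=None,
                          names=["chrom", "snp", "cm", "pos"])
    n_snps = len(markers)
    by_id: dict[str, tuple[int, str, str, np.ndarray]] = {}
    families: dict[str, list[str]] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PedFormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} fields, "
                    f"found {len(fields)}")
            fam, iid, fid, mid = fields[:4]
            key = f"{fam}:{iid}"
            if key in by_id:
                raise PedFormatError(f"{ped_path} line {lineno}: duplicate "
                                     f"individual id {iid!r} in family {fam!r}")
            geno = np.empty(n_snps, dtype=np.int8)
            pairs = fields[6:]
            for j in range(n_snps):
                a, b = pairs[2 * j], pairs[2 * j + 1]
                if a == "0" or b == "0":
                    geno[j] = MISSING
                elif (a, b) in _PAIR_TO_GENO:
                    geno[j] = _PAIR_TO_GENO[(a, b)]
                else:
                    raise PedFormatError(
                        f"{ped_path} line {lineno}: allele symbol outside "
                        f"{{A,B,0}} at marker {j + 1}: {a!r}/{b!r}")
            by_id[key] = (lineno, fid, mid, geno)
            families.setdefault(fam, []).append(iid)

    fathers, mothers, children = [], [], []
    for fam in families:
        offspring = [iid for iid in families[fam]
                     if by_id[f"{fam}:{iid}"][1] != "0"]
        if len(offspring) != 1:
            raise PedFormatError(f"family {fam!r}: expected exactly one offspring "
                                 f"record, found {len(offspring)}")
        child_id = offspring[0]
        _, fid, mid, cg = by_id[f"{fam}:{child_id}"]
        for pid, role in ((fid, "father"), (mid, "mother")):
            if f"{fam}:{pid}" not in by_id:
                raise PedFormatError(f"offspring {child_id!r} in family {fam!r}: "
                                     f"{role} id {pid!r} has no record")
        fathers.append(by_id[f"{fam}:{fid}"][3])
        mothers.append(by_id[f"{fam}:{mid}"][3])
        children.append(cg)

    return TrioCohort(markers=markers[["snp", "chrom", "pos"]]
                      .assign(a1="A", a2="B"),
                      father=np.vstack(fathers), mother=np.vstack(mothers),
                      child=np.vstack(children), population=population)


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene annotation as 4-column BED (chrom, start, end, name)."""
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read 4-column BED into a (gene, chrom, start, end) table."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "gene"])
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"BED interval with start >= end: {bad['gene']}")
    return df[["gene", "chrom", "start", "end"]]


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT (set name, description, member genes, tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"{path} line {lineno}: GMT rows need "
                                     f"name, description and >=1 gene")
                continue
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path} line {lineno}: duplicate set {name!r}")
            if not members:
                raise ValueError(f"{path} line {lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
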