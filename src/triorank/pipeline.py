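"""Configured end-to-end pipeline: QC -> TDT -> ranking -> overlap ->
gene mapping -> enrichment -> FST x DRP, with TSV outputs and a run manifest.

Every stage writes a headed TSV into the output directory; the manifest
(``manifest.json``) records the configuration snapshot, package version,
derived stage seeds, SHA-256 hashes of the input files, and which stages
completed, so a run is auditable and byte-reproducible under a fixed master
seed.  Stage seeds are derived from the master seed by stable hashing of the
stage name — reproducible but independent streams.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import triorank
from triorank import io as trio_io
from triorank.association import QcCriteria, allele1_frequencies, mega_tdt, tdt_table
from triorank.enrichment import rank_gene_sets, resampling_null
from triorank.fst import dependence_test, drp, fst_per_snp
from triorank.genes import gene_level_p, gene_overlap, genes_from_top_snps, \
    map_snps_to_genes
from triorank.ranking import expected_overlap, overlap_counts, rank_snps, \
    replication_count, top_n
from triorank.simulate import PopulationModel, RiskModel, TrioCohort, \
    draw_population_frequencies, generate_gene_annotation, generate_gene_sets, \
    simulate_ancestral_frequencies, simulate_trios, _default_markers

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "simulate_study"]

#: top-n grid used for the cross-population overlap tables
DEFAULT_TOP_N_GRID = (1_000, 2_000, 5_000, 10_000, 50_000)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML mapping."""

    populations: dict[str, dict[str, str]] = field(default_factory=dict)
    annotation: str | None = None
    gene_sets: str | None = None
    qc: QcCriteria = field(default_factory=QcCriteria)
    top_n_grid: tuple[int, ...] = DEFAULT_TOP_N_GRID
    gene_window: int = 20_000
    replication_alpha: float = 0.05
    replication_top: int = 100
    enrichment_reps: int = 1_000
    enrichment_mode: str = "snp"
    enrichment_top_n: int = 1_000
    fst_estimator: str = "nei"
    fst_freq_source: str = "parents"
    seed: int = 0
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = trio_io.load_config(path)
        qc = QcCriteria(**raw.get("qc", {}))
        enr = raw.get("enrichment", {})
        fst = raw.get("fst", {})
        cfg = cls(
            populations=raw.get("populations", {}),
            annotation=raw.get("annotation"),
            gene_sets=raw.get("gene_sets"),
            qc=qc,
            top_n_grid=tuple(raw.get("top_n_grid", DEFAULT_TOP_N_GRID)),
            gene_window=int(raw.get("gene_window", 20_000)),
            replication_alpha=float(raw.get("replication_alpha", 0.05)),
            replication_top=int(raw.get("replication_top", 100)),
            enrichment_reps=int(enr.get("reps", 1_000)),
            enrichment_mode=str(enr.get("mode", "snp")),
            enrichment_top_n=int(enr.get("top_n", 1_000)),
            fst_estimator=str(fst.get("estimator", "nei")),
            fst_freq_source=str(fst.get("freq_source", "parents")),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
        )
        for pop, paths in cfg.populations.items():
            for key in ("ped", "map"):
                if key not in paths:
                    raise ValueError(f"population {pop!r}: missing {key} path")
                if not Path(paths[key]).exists():
                    raise FileNotFoundError(f"population {pop!r}: {paths[key]}")
        return cfg

    def snapshot(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        return d


# --------------------------------------------------------------------------
# synthetic study generation (the `simulate` stage / subcommand)

#: Default synthetic study: three cohorts mirroring a European-American /
#: African-American / Hispanic-American trio design (429/52/46 trios), a
#: desk-scale marker panel, 50 risk SNPs at transmission probability 0.65,
#: and one gene set enriched for the risk genes.
DEFAULT_SIMULATION = {
    "n_snps": 20_000,
    "maf_range": (0.05, 0.5),
    "chrom_lengths": {1: 120_000_000, 2: 100_000_000, 3: 80_000_000},
    "populations": [
        {"name": "EA", "fst_param": 0.05, "n_trios": 429},
        {"name": "AA", "fst_param": 0.15, "n_trios": 52},
        {"name": "HA", "fst_param": 0.10, "n_trios": 46},
    ],
    "n_risk_snps": 50,
    "tau": 0.65,
    "missing_rate": 0.01,
    "mendel_error_rate": 0.0,
    "n_genes": 1_000,
    "gene_length_range": (5_000, 100_000),
    "min_gap": 10_000,
    "n_gene_sets": 200,
    "gene_set_size_range": (10, 50),
    "planted_fraction": 0.8,
}


def simulate_study(params: dict | None = None, seed: int = 0,
                   out_dir: str | Path | None = None) -> dict:
    """Generate a full synthetic study: cohorts, annotation, gene sets.

    Returns a dict with ``cohorts`` (name -> TrioCohort), ``genes``,
    ``gene_sets``, ``risk`` and ``markers``; when ``out_dir`` is given the
    PED/MAP/BED/GMT files are also written there.  All randomness flows from
    ``seed`` via stable stage-derived streams.
    """
    p = dict(DEFAULT_SIMULATION)
    if params:
        p.update(params)
    chrom_lengths = {int(k): int(v) for k, v in p["chrom_lengths"].items()}

    anc = simulate_ancestral_frequencies(
        p["n_snps"], *p["maf_range"], seed=stage_seed(seed, "ancestral"))
    markers = _default_markers(p["n_snps"], chrom_lengths,
                               rng=np.random.default_rng(stage_seed(seed, "markers")))

    genes = generate_gene_annotation(p["n_genes"], chrom_lengths,
                                     tuple(p["gene_length_range"]), p["min_gap"],
                                     seed=stage_seed(seed, "genes"))

    rng = np.random.default_rng(stage_seed(seed, "risk"))
    mapping = map_snps_to_genes(markers, genes, window=0)
    genic = mapping["snp"].unique()
    n_risk = min(p["n_risk_snps"], len(genic))
    risk_ids = list(rng.choice(genic, size=n_risk, replace=False)) if n_risk else []
    risk_genes = sorted(mapping.loc[mapping["snp"].isin(risk_ids), "gene"].unique())
    n_plant = max(1, int(round(p["planted_fraction"] * len(risk_genes)))) \
        if risk_genes else 0
    planted = risk_genes[:n_plant] if n_plant else None
    risk = RiskModel(risk_snp_ids=frozenset(risk_ids), tau=p["tau"],
                     planted_gene_set_id="PLANTED_SET" if planted else None)

    gene_sets = generate_gene_sets(genes, p["n_gene_sets"],
                                   tuple(p["gene_set_size_range"]),
                                   planted_genes=planted,
                                   seed=stage_seed(seed, "gene_sets"))

    cohorts = {}
    for pop_cfg in p["populations"]:
        pm = PopulationModel(pop_cfg["name"], float(pop_cfg["fst_param"]),
                             int(pop_cfg["n_trios"]))
        freqs = draw_population_frequencies(
            anc, pm.fst_param, seed=stage_seed(seed, f"freqs:{pm.name}"))
        cohorts[pm.name] = simulate_trios(
            freqs, pm.n_trios, risk=risk, missing_rate=p["missing_rate"],
            seed=stage_seed(seed, f"trios:{pm.name}"), markers=markers,
            population=pm.name, mendel_error_rate=p["mendel_error_rate"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, co in cohorts.items():
            trio_io.write_ped_map(co, out / f"{name}.ped", out / f"{name}.map")
        trio_io.write_bed(genes, out / "genes.bed")
        trio_io.write_gmt(gene_sets, out / "gene_sets.gmt")
        with open(out / "truth.json", "w") as fh:
            json.dump({"risk_snp_ids": sorted(risk.risk_snp_ids),
                       "tau": risk.tau, "risk_genes": risk_genes,
                       "planted_gene_set_id": risk.planted_gene_set_id,
                       "planted_genes": planted or []}, fh, indent=1)

    return {"cohorts": cohorts, "genes": genes, "gene_sets": gene_sets,
            "risk": risk, "markers": markers, "ancestral": anc}


# --------------------------------------------------------------------------
# the full pipeline

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest["outputs"].append({"stage": stage, "file": path.name})


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on the configured cohorts and write the report bundle.

    Single-cohort configs skip the cross-population stages (overlap,
    gene overlap, FST x DRP) with logged notices.  Returns the manifest
    dict, which is also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": triorank.__version__,
                      "config": config.snapshot(),
                      "inputs": {}, "outputs": [], "stages": [],
                      "complete": False, "notices": []}

    def done(stage: str) -> None:
        manifest["stages"].append(stage)

    try:
        cohorts: dict[str, TrioCohort] = {}
        for pop, paths in config.populations.items():
            cohorts[pop] = trio_io.read_ped_map(paths["ped"], paths["map"],
                                                population=pop)
            manifest["inputs"][pop] = {k: _sha256(v) for k, v in paths.items()}
        if not cohorts:
            raise ValueError("no populations configured")
        pops = list(cohorts)
        done("load")

        # per-cohort QC + TDT (+ Manhattan data), mega-analysis
        tables: dict[str, pd.DataFrame] = {}
        for pop, co in cohorts.items():
            t = tdt_table(co, config.qc, gc_correct=True)
            tables[pop] = t
            _write(t, out / f"tdt_{pop}.tsv", manifest, "tdt")
            man = t.loc[t["qc_pass"] & np.isfinite(t["p"]),
                        ["chrom", "pos", "p"]].copy()
            man["neg_log10_p"] = -np.log10(man.pop("p"))
            _write(man, out / f"manhattan_{pop}.tsv", manifest, "tdt")
        done("tdt")

        mega = mega_tdt(list(cohorts.values()), config.qc)
        _write(mega, out / "tdt_mega.tsv", manifest, "mega")
        done("mega")

        ranked = {pop: rank_snps(tables[pop]) for pop in pops}
        ranked["Mega"] = rank_snps(mega) if len(mega) else None
        done("rank")

        multi = len(pops) >= 2
        shared_universe = set.intersection(
            *(set(r.snp_ids) for p, r in ranked.items() if p in pops)) \
            if multi else set()
        if multi:
            # top-n overlap grid
            rows = []
            n_min = min(len(ranked[p]) for p in pops)
            for n in config.top_n_grid:
                if n > n_min:
                    manifest["notices"].append(
                        f"top-n {n} exceeds smallest ranking ({n_min}); skipped")
                    continue
                tops = {p: top_n(ranked[p], n) for p in pops}
                obs = overlap_counts(tops)
                N = len(shared_universe)
                for _, r in obs.iterrows():
                    labs = r["comparison"].split("&")
                    exp = expected_overlap([n] * len(labs), N,
                                           "pairwise" if len(labs) == 2
                                           else "threeway")
                    rows.append((n, r["comparison"], r["observed"], exp, N))
            _write(pd.DataFrame(rows, columns=["n", "comparison", "observed",
                                               "expected", "universe"]),
                   out / "snp_overlap.tsv", manifest, "overlap")

            # Table-4-style replication matrix
            rep_rows = []
            all_ranked = {**{p: ranked[p] for p in pops}}
            if ranked["Mega"] is not None:
                all_ranked["Mega"] = ranked["Mega"]
            k = config.replication_top
            for src, r_src in all_ranked.items():
                if k > len(r_src):
                    manifest["notices"].append(
                        f"replication top {k} exceeds ranking of {src}; skipped")
                    continue
                tops = top_n(r_src, k)
                for dst, r_dst in all_ranked.items():
                    rep = replication_count(tops, r_dst.p_map(),
                                            config.replication_alpha)
                    rep_rows.append((src, dst, rep["observed"], rep["expected"],
                                     rep["n_top"], rep["n_dropped"]))
            _write(pd.DataFrame(rep_rows,
                                columns=["top_of", "counted_in", "observed",
                                         "expected", "n_top", "n_dropped"]),
                   out / "replication.tsv", manifest, "overlap")
            done("overlap")
        else:
            notice = "single cohort: overlap stage skipped"
            logger.info(notice)
            manifest["notices"].append(notice)

        # gene mapping + gene-level results
        if config.annotation:
            genes = trio_io.read_bed(config.annotation)
            manifest["inputs"]["annotation"] = _sha256(config.annotation)
            any_co = cohorts[pops[0]]
            mapping = map_snps_to_genes(any_co.markers, genes,
                                        config.gene_window)
            _write(mapping, out / "snp_gene_mapping.tsv", manifest, "map-genes")
            gene_sets_by_pop: dict[str, set[str]] = {}
            for pop in pops:
                glp = gene_level_p(mapping, tables[pop][tables[pop]["qc_pass"]])
                _write(glp, out / f"gene_level_{pop}.tsv", manifest, "map-genes")
                n_top = min(config.enrichment_top_n, len(ranked[pop]))
                gtab, n_mapped = genes_from_top_snps(
                    mapping, top_n(ranked[pop], n_top))
                gene_sets_by_pop[pop] = set(gtab["gene"])
                manifest["notices"].append(
                    f"{pop}: {n_mapped} of top {n_top} SNPs mapped to "
                    f"{len(gtab)} genes")
            if multi:
                _write(gene_overlap(gene_sets_by_pop, len(genes)),
                       out / "gene_overlap.tsv", manifest, "map-genes")
            done("map-genes")

            # enrichment
            if config.gene_sets:
                collection = trio_io.read_gmt(config.gene_sets)
                manifest["inputs"]["gene_sets"] = _sha256(config.gene_sets)
                enr_by_pop = {}
                for pop in pops:
                    n_top = min(config.enrichment_top_n, len(ranked[pop]))
                    res = resampling_null(
                        mapping, ranked[pop], n_top, collection,
                        reps=config.enrichment_reps,
                        mode=config.enrichment_mode,
                        seed=stage_seed(config.seed, f"enrich:{pop}"))
                    enr_by_pop[pop] = res
                    _write(res, out / f"enrichment_{pop}.tsv", manifest,
                           "enrich")
                if multi:
                    _write(rank_gene_sets(enr_by_pop),
                           out / "pathway_shared_grid.tsv", manifest, "enrich")
                done("enrich")

        # FST x DRP
        if multi:
            fst_rows = []
            for pa, pb in itertools.combinations(pops, 2):
                r = drp(ranked[pa], ranked[pb])
                fa = allele1_frequencies(cohorts[pa], config.fst_freq_source)
                fb = allele1_frequencies(cohorts[pb], config.fst_freq_source)
                ia = cohorts[pa].markers.set_index("snp").index
                ib = cohorts[pb].markers.set_index("snp").index
                fst = fst_per_snp(
                    fa[ia.get_indexer(r["snp"])], fb[ib.get_indexer(r["snp"])],
                    estimator=config.fst_estimator,
                    n_a=2 * cohorts[pa].n_trios, n_b=2 * cohorts[pb].n_trios)
                rec = r.assign(fst=fst)
                _write(rec, out / f"fst_drp_{pa}_{pb}.tsv", manifest, "fst-drp")
                summ = dependence_test(rec)
                fst_rows.append((f"{pa}&{pb}", config.fst_freq_source,
                                 float(np.nanmean(fst)),
                                 float(np.nanmedian(fst)),
                                 float(np.nanmin(fst)), float(np.nanmax(fst)),
                                 summ.observed_hh, summ.expected_hh,
                                 summ.chi2, summ.p))
            _write(pd.DataFrame(fst_rows,
                                columns=["pair", "freq_source", "mean_fst",
                                         "median_fst", "min_fst", "max_fst",
                                         "observed", "expected", "chi2", "p"]),
                   out / "fst_drp_summary.tsv", manifest, "fst-drp")
            done("fst-drp")
        else:
            notice = "single cohort: FST-DRP stage skipped"
            logger.info(notice)
            manifest["notices"].append(notice)

        manifest["complete"] = True
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest
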