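"""End-to-end orchestration: simulate -> map -> test -> interpret.

`run_pipeline` chains the library stages on one simulated (or supplied)
experiment and writes every intermediate as a TSV/VCF/JSON with a
provenance header, plus a machine-readable report summarising the stage
metrics (DE counts, mapping peak, linkage coefficient and odds ratio,
enriched chromosomes, GO-set Jaccard, classification tallies).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import de, enrichment, go, haplotypes as hp, io, ldmap, linkage
from .sim import CrossConfig, simulate_go, simulate_four_genotype_experiment, simulate_incross

log = logging.getLogger("asemap")

ALL_STAGES = (
    "simulate",
    "ldmap",
    "detest",
    "linkage",
    "enrich",
    "haplotypes",
    "go-compare",
    "classify",
)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    simulate: dict = field(default_factory=dict)  # CrossConfig overrides
    span: float = 0.3
    min_quality: float = 100.0
    alpha: float = 0.05
    window: float = 20e6
    bin_size: int = 1_000_000
    min_depth: int = 5
    min_calls: int = 5
    min_callable_fraction: float = 0.8
    go_terms: int = 150
    go_term_size: tuple = (5, 50)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("span", "min_quality", "alpha", "window", "bin_size", "min_depth", "min_calls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def write_experiment(exp, outdir, seed=None) -> dict:
    """Write every simulated input the downstream stages consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = exp.config
    meta = dict(seed=cfg.seed if seed is None else seed, config=cfg.to_dict())
    paths = {}

    lengths = {c: cfg.chrom_length for c in cfg.chrom_names()}
    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    io.write_tsv(
        pd.DataFrame({"chrom": list(lengths), "length": list(lengths.values())}),
        paths["chrom_lengths"], stage="simulate", **meta,
    )

    ann = exp.gene_table[["chrom", "start"]]
    paths["genes_bed"] = outdir / "genes.bed"
    io.write_gene_bed(ann, paths["genes_bed"])
    paths["gene_truth"] = outdir / "gene_truth.tsv"
    io.write_tsv(exp.gene_table.reset_index(), paths["gene_truth"], stage="simulate", **meta)

    if exp.counts is not None:
        paths["counts"] = outdir / "counts.tsv"
        io.write_counts(exp.counts, paths["counts"], **meta)
        design = pd.DataFrame(
            {"sample": exp.sample_names, "group": np.where(exp.mutant, "mut", "sib")}
        )
        paths["design"] = outdir / "design.tsv"
        io.write_tsv(design, paths["design"], stage="simulate", **meta)
    if exp.pool_sites is not None:
        paths["pool_vcf"] = outdir / "pools.vcf"
        io.write_pooled_vcf(exp.pool_sites, paths["pool_vcf"], lengths)
        paths["pool_tsv"] = outdir / "pools.tsv"
        io.write_variant_sites_tsv(exp.pool_sites, paths["pool_tsv"], **meta)
    if exp.embryo_snp_calls is not None:
        paths["embryo_snps"] = outdir / "embryo_snps.tsv"
        io.write_tsv(exp.embryo_snp_calls, paths["embryo_snps"], stage="simulate", **meta)
        paths["informative_snps"] = outdir / "informative_snps.tsv"
        io.write_tsv(
            exp.snp_table[["chrom", "pos", "alt_strain"]],
            paths["informative_snps"], stage="simulate", **meta,
        )
        paths["parent_genotypes"] = outdir / "parent_genotypes.tsv"
        io.write_tsv(exp.parent_snp_genotypes, paths["parent_genotypes"], stage="simulate", **meta)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order on one simulation.

    Returns (and writes as ``report.json``) a summary with per-stage
    metrics.  Any stage failure aborts the run with the stage name attached.
    """
    logging.basicConfig(level=config.log_level, format="%(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    stage = None
    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, state, report)
    except Exception as err:  # noqa: BLE001 - report which stage failed
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _stage_simulate(config: RunConfig, state: dict, report: dict) -> None:
    cross = CrossConfig(**{"seed": config.seed, **config.simulate})
    exp = simulate_incross(cross)
    state["exp"] = exp
    state["paths"] = write_experiment(exp, Path(config.outdir) / "inputs", seed=config.seed)
    state["annotation"] = exp.gene_table[["chrom", "start"]].copy()
    state["lengths"] = {c: cross.chrom_length for c in cross.chrom_names()}
    report["stages"]["simulate"] = {
        "n_embryos": cross.n_embryos,
        "n_mutant": int(exp.mutant.sum()),
        "n_genes": cross.n_genes,
        "n_ase_genes": int(exp.gene_table["is_ase"].sum()),
    }


def _stage_ldmap(config: RunConfig, state: dict, report: dict) -> None:
    exp = state["exp"]
    if exp.pool_sites is None:
        report["stages"]["ldmap"] = {"skipped": "no pooled sites (no causal locus)"}
        return
    profiles = ldmap.ld_profiles(
        exp.pool_sites, span=config.span, min_quality=config.min_quality
    )
    peak = ldmap.find_peak(profiles)
    state["profiles"], state["peak"] = profiles, peak
    outdir = Path(config.outdir) / "ldmap"
    for chrom, p in profiles.items():
        io.write_tsv(p.to_frame(), outdir / f"profile_chr{chrom}.tsv", stage="ldmap",
                     seed=config.seed)
    with open(outdir / "peak.json", "w") as fh:
        json.dump(dataclasses.asdict(peak), fh, indent=2)
    report["stages"]["ldmap"] = {
        "peak_chrom": peak.chrom, "peak_pos": peak.pos, "peak_value": peak.value,
    }


def _stage_detest(config: RunConfig, state: dict, report: dict) -> None:
    exp = state["exp"]
    groups = pd.Series(
        np.where(exp.mutant, "mut", "sib"), index=exp.counts.columns
    )
    results = de.nb_test(exp.counts, groups, alpha=config.alpha, reference="sib")
    state["de"] = results
    io.write_de_results(
        results, state["annotation"], Path(config.outdir) / "de_results.tsv", seed=config.seed
    )
    report["stages"]["detest"] = {
        "n_tested": int(results["tested"].sum()),
        "n_de": int(results["de"].sum()),
    }


def _stage_linkage(config: RunConfig, state: dict, report: dict) -> None:
    if "profiles" not in state:
        report["stages"]["linkage"] = {"skipped": "no LD profiles"}
        return
    table = linkage.gene_ld_table(state["de"], state["profiles"], state["annotation"])
    fit = linkage.LinkageLogit.from_table(table).fit()
    ld_max, ld_median = float(table["ld"].max()), float(table["ld"].median())
    adj = linkage.adjust_across_lines([fit])
    summary = {
        "alpha": fit.alpha, "beta": fit.beta, "sem": fit.beta_se,
        "p": fit.pvalue, "padj": float(adj["padj"].iloc[0]),
        "stars": adj["stars"].iloc[0],
        "odds_ratio": fit.odds_ratio(ld_max, ld_median) if fit.converged else None,
        "ld_max": ld_max, "ld_median": ld_median,
        "n_de": fit.n_de, "n_total": fit.n,
    }
    with open(Path(config.outdir) / "linkage.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    state["linkage"] = summary
    report["stages"]["linkage"] = summary


def _stage_enrich(config: RunConfig, state: dict, report: dict) -> None:
    results = state["de"]
    de_genes = results.index[results["de"]]
    table = enrichment.binomial_enrichment(state["annotation"], de_genes, alpha=config.alpha)
    io.write_tsv(table, Path(config.outdir) / "enrichment.tsv", stage="enrich", seed=config.seed)
    out = {
        "n_enriched": int(table["enriched"].sum()) if len(table) else 0,
        "enriched_chroms": table.loc[table["enriched"], "chrom"].tolist() if len(table) else [],
    }
    if "peak" in state:
        ann = state["annotation"]
        de_pos = ann.loc[de_genes.intersection(ann.index)]
        stats_win = enrichment.nearby_de_genes(
            de_pos, state["peak"], window=config.window,
            chrom_length=state["lengths"].get(state["peak"].chrom),
        )
        with open(Path(config.outdir) / "window_stats.json", "w") as fh:
            json.dump(stats_win, fh, indent=2)
        out["window"] = stats_win
    report["stages"]["enrich"] = out


def _stage_haplotypes(config: RunConfig, state: dict, report: dict) -> None:
    exp = state["exp"]
    if exp.embryo_snp_calls is None:
        report["stages"]["haplotypes"] = {"skipped": "no embryo SNP calls"}
        return
    snps = exp.snp_table[["chrom", "pos", "alt_strain"]]
    pw = hp.parental_window_genotypes(
        exp.parent_snp_genotypes, snps, window_size=config.bin_size, min_calls=config.min_calls
    )
    hap_map = hp.build_haplotype_map(
        exp.embryo_snp_calls, snps, window_size=config.bin_size,
        min_depth=config.min_depth, min_calls=config.min_calls,
        parental_windows=pw, chrom_lengths=state["lengths"],
    )
    regions = hp.define_informative_regions(pw, hap_map, config.min_callable_fraction)
    scan = hp.ase_scan(regions, hap_map, exp.counts, state["annotation"], alpha=config.alpha)
    outdir = Path(config.outdir) / "haplotypes"
    io.write_tsv(hap_map.to_long(), outdir / "haplotype_map.tsv", stage="haplotypes",
                 seed=config.seed)
    io.write_tsv(scan, outdir / "ase_scan.tsv", stage="ase-scan", seed=config.seed)
    groupings = {
        r.region_id: hp.group_embryos(r, hap_map).map(hp.GENOTYPE_LABELS).to_dict()
        for r in regions
    }
    with open(outdir / "groupings.json", "w") as fh:
        json.dump(groupings, fh, indent=2)
    state["hap_map"], state["regions"], state["scan"] = hap_map, regions, scan
    hh = scan[scan["contrast"] == "hom_vs_hom"] if len(scan) else scan
    report["stages"]["haplotypes"] = {
        "n_regions": len(regions),
        "n_de_rows": int(len(scan)),
        "mean_abs_log2fc_hom_vs_hom": float(hh["log2fc"].abs().mean()) if len(hh) else None,
    }


def _stage_go_compare(config: RunConfig, state: dict, report: dict) -> None:
    exp = state["exp"]
    results = state["de"]
    rng = np.random.default_rng(config.seed + 1)
    universe = results.index[results["tested"]]
    de_genes = results.index[results["de"]].tolist()
    if not de_genes:
        report["stages"]["go-compare"] = {"skipped": "no DE genes"}
        return
    annotation_go = simulate_go(
        len(universe), config.go_terms, tuple(config.go_term_size), rng,
        gene_ids=list(universe),
    )
    ann = state["annotation"]
    if exp.config.causal_locus is not None:
        chrom, pos = exp.config.causal_locus
        on_chrom = ann[ann["chrom"] == str(chrom + 1)]
        mutant_gene = (on_chrom["start"] - pos).abs().idxmin()
    else:
        mutant_gene = de_genes[0]
    trimmed = go.remove_linked_genes(de_genes, ann, mutant_gene)
    enr_all = go.go_enrich(de_genes, universe, annotation_go, alpha=config.alpha)
    enr_trim = go.go_enrich(trimmed, universe, annotation_go, alpha=config.alpha)
    set_all, set_trim = set(enr_all["term_id"]), set(enr_trim["term_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        jac = go.jaccard(set_all, set_trim)
    edges = go.term_overlap_network(
        sorted(set_all | set_trim), annotation_go, universe
    )
    outdir = Path(config.outdir) / "go"
    io.write_tsv(enr_all, outdir / "enrichment_all.tsv", stage="go", seed=config.seed)
    io.write_tsv(enr_trim, outdir / "enrichment_trimmed.tsv", stage="go", seed=config.seed)
    io.write_tsv(edges, outdir / "term_network.tsv", stage="go", seed=config.seed)
    comparison = {
        "jaccard": jac,
        "n_both": len(set_all & set_trim),
        "n_all_only": len(set_all - set_trim),
        "n_removed_only": len(set_trim - set_all),
        "mutant_gene": mutant_gene,
        "n_de_all": len(de_genes),
        "n_de_trimmed": len(trimmed),
    }
    with open(outdir / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2)
    report["stages"]["go-compare"] = comparison


def _stage_classify(config: RunConfig, state: dict, report: dict) -> None:
    counts, design, truth = simulate_four_genotype_experiment(seed=config.seed + 2)
    groups = design.map(lambda g: "sib" if g != "comphet" else "mut")
    results = de.nb_test(counts, groups, alpha=config.alpha, reference="sib")
    ann = truth[["chrom", "start"]]
    calls = cls.classify_chromosome(counts, design, results, ann, mutant_chrom="3")
    io.write_tsv(
        calls.reset_index(), Path(config.outdir) / "classification.tsv",
        stage="classify", seed=config.seed,
    )
    tally = calls["call"].value_counts().to_dict()
    report["stages"]["classify"] = {
        "n_classified": int(len(calls)),
        "calls": {k: int(v) for k, v in tally.items()},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ldmap": _stage_ldmap,
    "detest": _stage_detest,
    "linkage": _stage_linkage,
    "enrich": _stage_enrich,
    "haplotypes": _stage_haplotypes,
    "go-compare": _stage_go_compare,
    "classify": _stage_classify,
}
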