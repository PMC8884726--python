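"""Synthetic incross simulator with known ground truth.

Emulates the data-generating process behind pooled mutant-mapping and
haplotype-resolved wild-type crosses in zebrafish:

* two parental strains (``A`` and ``B``, e.g. AB and Tübingen) whose
  haplotypes recombine through meiosis (Haldane model: Poisson crossovers,
  no interference);
* an F2/F3-style incross of two parents heterozygous at a recessive causal
  locus, so ~25% of embryos are homozygous mutants;
* per-gene *cis* allelic effects (allele-specific expression): each strain-B
  gene copy contributes ``2**c`` times the strain-A expression, with ``c``
  drawn from a centred normal whose scale is calibrated so that
  ``E|c| = 0.5`` — the mean absolute homozygote-vs-homozygote log2 fold
  change this kind of cross exhibits;
* *trans* response genes whose expression tracks causal-allele dosage;
* negative-binomial count noise, binomial read sampling at pooled SNP
  sites, and per-embryo read sampling at strain-informative SNPs.

All randomness flows from ``CrossConfig.seed``; identical configs give
bit-identical experiments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "STRAIN_A",
    "STRAIN_B",
    "ConfigError",
    "CrossConfig",
    "HaplotypeCopy",
    "EmbryoGenome",
    "SimulatedExperiment",
    "simulate_meiosis",
    "simulate_parents",
    "simulate_embryos",
    "simulate_incross",
    "simulate_counts",
    "simulate_pool_sites",
    "simulate_embryo_snp_calls",
    "simulate_go",
    "simulate_four_genotype_experiment",
]

#: Parental strain codes. Strain B carries the causal allele in mapping crosses.
STRAIN_A = 0
STRAIN_B = 1

#: Default strain display names (AB and Tübingen, the two founder haplotypes).
STRAIN_NAMES = ("AB", "Tu")


class ConfigError(ValueError):
    """Raised for invalid simulator configuration."""


# calibration: for c ~ Normal(0, sd), E|c| = sd * sqrt(2/pi); sd below gives E|c| = 0.5
_CIS_SD_FOR_MEAN_ABS_HALF = 0.5 * math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class CrossConfig:
    """Complete description of a simulated cross.

    The defaults describe a pooled mutant-mapping incross at desk scale:
    five 25-Mbp chromosomes of one Morgan each, 200 embryos from a het x het
    cross segregating a recessive causal locus, 2,000 genes, and pooled
    sequencing of mutant and sibling groups.  Use :meth:`sat_cross` for a
    SAT-style haplotype-resolved wild-type incross.
    """

    n_chromosomes: int = 5
    chrom_length: int = 25_000_000
    map_length: float = 1.0  # Morgans per chromosome
    n_embryos: int = 200
    causal_locus: tuple[int, int] | None = (1, 12_500_000)  # (chrom, 1-based pos)
    n_genes: int = 2000
    baseline_mean: float = 500.0
    dispersion: float = 0.01
    cis_effect_sd: float = _CIS_SD_FOR_MEAN_ABS_HALF
    frac_ase_genes: float = 0.25
    response_genes: tuple[tuple[int, float], ...] = ()  # (gene index, trans log2 effect)
    het_trans_factor: float = 0.5  # heterozygote trans effect as fraction of homozygote
    n_snps_per_chrom: int = 500
    read_depth: float = 60.0  # mean pooled reads per SNP per pool
    embryo_read_depth: float = 12.0  # mean reads per informative SNP per embryo
    low_quality_frac: float = 0.1  # fraction of pooled sites with QUAL < 100
    alt_strain_b_frac: float = 1.0  # fraction of SNPs whose alternate allele rides strain B
    parent_style: str = "mapping"  # "mapping": het A/B genome-wide; "mosaic": SAT-style
    mosaic_switch_rate: float = 2.0  # expected strain switches per parental copy per chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("n_chromosomes and chrom_length must be positive")
        if self.map_length < 0:
            raise ConfigError("map_length must be non-negative")
        if self.n_embryos < 1:
            raise ConfigError("n_embryos must be positive")
        if self.n_genes < 0 or self.n_snps_per_chrom < 0:
            raise ConfigError("n_genes and n_snps_per_chrom must be non-negative")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if not 0.0 <= self.frac_ase_genes <= 1.0:
            raise ConfigError("frac_ase_genes must lie in [0, 1]")
        if not 0.0 <= self.alt_strain_b_frac <= 1.0:
            raise ConfigError("alt_strain_b_frac must lie in [0, 1]")
        if self.parent_style not in ("mapping", "mosaic"):
            raise ConfigError(f"unknown parent_style {self.parent_style!r}")
        if self.causal_locus is not None:
            chrom, pos = self.causal_locus
            if not (0 <= chrom < self.n_chromosomes) or not (1 <= pos <= self.chrom_length):
                raise ConfigError("causal_locus outside the simulated genome")
        for gene, _effect in self.response_genes:
            if not 0 <= gene < max(self.n_genes, 1):
                raise ConfigError(f"response gene index {gene} out of range")

    @classmethod
    def sat_cross(cls, **overrides) -> "CrossConfig":
        """SAT-style wild-type incross: mosaic parents, 96 embryos, 25 chromosomes.

        No causal locus; differential expression arises solely from cis
        allelic effects revealed by regional homozygosity.
        """
        base = dict(
            n_chromosomes=25,
            n_embryos=96,
            causal_locus=None,
            parent_style="mosaic",
            alt_strain_b_frac=0.5,
            n_genes=2500,
        )
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "CrossConfig":
        return replace(self, seed=int(seed))

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class HaplotypeCopy:
    """One chromosome copy as contiguous strain segments covering [1, length].

    ``breaks[i]`` is the (1-based, inclusive) end of segment i; the final
    break equals the chromosome length.  ``labels[i]`` is the parental
    strain of segment i.
    """

    breaks: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.breaks.ndim != 1 or self.breaks.shape != self.labels.shape:
            raise ValueError("breaks and labels must be 1-D and equal length")
        if len(self.breaks) == 0 or np.any(np.diff(self.breaks) <= 0):
            raise ValueError("segment ends must be strictly increasing and non-empty")

    @property
    def length(self) -> int:
        return int(self.breaks[-1])

    def strain_at(self, positions) -> np.ndarray:
        """Strain label at each 1-based position (vectorised)."""
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.breaks, pos, side="left")
        return self.labels[np.minimum(idx, len(self.labels) - 1)]

    def segments(self) -> list[tuple[int, int, int]]:
        """(start, end, strain) triples, 1-based inclusive."""
        starts = np.concatenate([[1], self.breaks[:-1] + 1])
        return [
            (int(s), int(e), int(l))
            for s, e, l in zip(starts, self.breaks, self.labels)
        ]

    @classmethod
    def uniform(cls, length: int, strain: int) -> "HaplotypeCopy":
        return cls(np.array([length]), np.array([strain]))

    def simplified(self) -> "HaplotypeCopy":
        """Merge adjacent segments with identical labels."""
        keep = np.concatenate([self.labels[1:] != self.labels[:-1], [True]])
        return HaplotypeCopy(self.breaks[keep], self.labels[keep])


@dataclass
class EmbryoGenome:
    """Two haplotype copies per chromosome."""

    chromosomes: list[tuple[HaplotypeCopy, HaplotypeCopy]]

    def n_b_alleles(self, chrom: int, positions) -> np.ndarray:
        """Count of strain-B alleles (0, 1 or 2) at each position on a chromosome."""
        c1, c2 = self.chromosomes[chrom]
        return (
            c1.strain_at(positions).astype(np.int8)
            + c2.strain_at(positions).astype(np.int8)
        )


@dataclass
class SimulatedExperiment:
    """Everything the analysis pipeline consumes, plus the generating truth."""

    config: CrossConfig
    parents: tuple[EmbryoGenome, EmbryoGenome]
    genomes: list[EmbryoGenome]
    mutant: np.ndarray  # bool per embryo; all False when no causal locus
    gene_table: pd.DataFrame  # gene_id, chrom, start, cis_effect, is_ase, trans_effect
    snp_table: pd.DataFrame  # chrom, pos, alt_strain
    counts: pd.DataFrame | None = None  # genes x embryos
    pool_sites: pd.DataFrame | None = None  # chrom, pos, ref/alt depths per pool, qual
    embryo_snp_calls: pd.DataFrame | None = None  # embryo, chrom, pos, ref_depth, alt_depth
    parent_snp_genotypes: pd.DataFrame | None = None  # chrom, pos, gt_p1, gt_p2, gq, depth

    @property
    def sample_names(self) -> list[str]:
        return [f"embryo_{i:03d}" for i in range(len(self.genomes))]

    @property
    def ase_genes(self) -> pd.Index:
        return self.gene_table.index[self.gene_table["is_ase"]]

    @property
    def response_gene_ids(self) -> pd.Index:
        return self.gene_table.index[self.gene_table["trans_effect"] != 0.0]


# ---------------------------------------------------------------------------
# meiosis and genomes


def simulate_meiosis(
    parent: EmbryoGenome, map_length: float, rng: np.random.Generator
) -> list[HaplotypeCopy]:
    """One gamete: per chromosome, Poisson(map_length) crossovers at uniform positions.

    Haldane's model — crossovers land as a Poisson process along the genetic
    map with no interference; the gamete alternates between the parent's two
    copies at each breakpoint.
    """
    if map_length < 0:
        raise ConfigError("map_length must be non-negative")
    gamete = []
    for c1, c2 in parent.chromosomes:
        length = c1.length
        n_xo = rng.poisson(map_length)
        current = int(rng.integers(2))
        copies = (c1, c2)
        if n_xo == 0:
            gamete.append(copies[current])
            continue
        xo = np.sort(rng.integers(1, length, size=n_xo))
        # piece together [prev+1, xo1], (xo1, xo2], ... alternating source copies
        breaks_out: list[int] = []
        labels_out: list[int] = []
        prev = 0
        for bound in list(xo) + [length]:
            if bound <= prev:
                current ^= 1  # zero-length piece: crossover still switches copy
                continue
            src = copies[current]
            lo = np.searchsorted(src.breaks, prev + 1, side="left")
            hi = np.searchsorted(src.breaks, bound, side="left")
            for j in range(lo, hi + 1):
                end = min(int(src.breaks[j]), bound)
                breaks_out.append(end)
                labels_out.append(int(src.labels[j]))
                if end == bound:
                    break
            prev = bound
            current ^= 1
        gamete.append(HaplotypeCopy(np.array(breaks_out), np.array(labels_out)).simplified())
    return gamete


def _mosaic_copy(config: CrossConfig, rng: np.random.Generator) -> HaplotypeCopy:
    """A parental copy as an alternating A/B mosaic (accumulated recombination)."""
    n_switch = rng.poisson(config.mosaic_switch_rate)
    start = int(rng.integers(2))
    if n_switch == 0:
        return HaplotypeCopy.uniform(config.chrom_length, start)
    cuts = np.sort(rng.integers(1, config.chrom_length, size=n_switch))
    breaks = np.concatenate([cuts, [config.chrom_length]])
    labels = (start + np.arange(n_switch + 1)) % 2
    return HaplotypeCopy(breaks, labels).simplified()


def simulate_parents(
    config: CrossConfig, rng: np.random.Generator
) -> tuple[EmbryoGenome, EmbryoGenome]:
    """The two parents of the cross.

    ``mapping`` style: both parents heterozygous A/B along every chromosome
    (one copy per strain), so they are carriers at the causal locus and every
    SNP segregates.  ``mosaic`` style: each copy is an A/B mosaic, as in a
    line maintained by incrossing for generations — parents are homozygous
    in some regions and heterozygous in others.
    """
    parents = []
    for _ in range(2):
        chroms = []
        for _c in range(config.n_chromosomes):
            if config.parent_style == "mapping":
                chroms.append(
                    (
                        HaplotypeCopy.uniform(config.chrom_length, STRAIN_A),
                        HaplotypeCopy.uniform(config.chrom_length, STRAIN_B),
                    )
                )
            else:
                chroms.append((_mosaic_copy(config, rng), _mosaic_copy(config, rng)))
        parents.append(EmbryoGenome(chroms))
    return parents[0], parents[1]


def simulate_embryos(
    config: CrossConfig,
    rng: np.random.Generator,
    parents: tuple[EmbryoGenome, EmbryoGenome] | None = None,
) -> tuple[list[EmbryoGenome], np.ndarray]:
    """Embryos from independent gametes of the two parents, plus mutant labels.

    An embryo is a mutant iff it is homozygous strain-B at the causal locus
    (the causal allele rides strain B).  With het x het parents this happens
    in ~25% of embryos.
    """
    if parents is None:
        parents = simulate_parents(config, rng)
    p1, p2 = parents
    genomes = []
    for _ in range(config.n_embryos):
        g1 = simulate_meiosis(p1, config.map_length, rng)
        g2 = simulate_meiosis(p2, config.map_length, rng)
        genomes.append(EmbryoGenome(list(zip(g1, g2))))
    mutant = np.zeros(config.n_embryos, dtype=bool)
    if config.causal_locus is not None:
        chrom, pos = config.causal_locus
        for i, g in enumerate(genomes):
            mutant[i] = g.n_b_alleles(chrom, [pos])[0] == 2
    return genomes, mutant


# ---------------------------------------------------------------------------
# layout and effects


def _place_genes(config: CrossConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    rows = []
    for c, n in enumerate(per_chrom):
        pos = np.sort(rng.integers(1, config.chrom_length + 1, size=n))
        for p in pos:
            rows.append((str(c + 1), int(p), c))
    table = pd.DataFrame(rows, columns=["chrom", "start", "chrom_idx"])
    table.index = pd.Index([f"g{i:05d}" for i in range(len(table))], name="gene_id")

    n_ase = int(round(config.frac_ase_genes * len(table)))
    ase_idx = rng.choice(len(table), size=n_ase, replace=False)
    cis = np.zeros(len(table))
    cis[ase_idx] = rng.normal(0.0, config.cis_effect_sd, size=n_ase)
    table["cis_effect"] = cis
    table["is_ase"] = False
    table.iloc[ase_idx, table.columns.get_loc("is_ase")] = True

    trans = np.zeros(len(table))
    for gene, effect in config.response_genes:
        trans[gene] = effect
    table["trans_effect"] = trans
    return table


def _place_snps(config: CrossConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.integers(1, config.chrom_length + 1, size=config.n_snps_per_chrom))
        pos = np.unique(pos)
        alt_b = rng.random(len(pos)) < config.alt_strain_b_frac
        for p, ab in zip(pos, alt_b):
            rows.append((str(c + 1), int(p), STRAIN_B if ab else STRAIN_A, c))
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt_strain", "chrom_idx"])


def _causal_dose(config: CrossConfig, genomes: list[EmbryoGenome]) -> np.ndarray:
    """Causal-allele dosage factor per embryo: 1 hom mutant, het_trans_factor het, 0 wt."""
    dose = np.zeros(len(genomes))
    if config.causal_locus is None:
        return dose
    chrom, pos = config.causal_locus
    for i, g in enumerate(genomes):
        nb = int(g.n_b_alleles(chrom, [pos])[0])
        dose[i] = 1.0 if nb == 2 else (config.het_trans_factor if nb == 1 else 0.0)
    return dose


# ---------------------------------------------------------------------------
# counts, pools, embryo SNP reads


def simulate_counts(
    genomes: list[EmbryoGenome],
    gene_table: pd.DataFrame,
    config: CrossConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Gene x embryo negative-binomial counts under the cis/trans effect model.

    Each strain-A copy of gene g contributes ``baseline/2`` to the expected
    count; each strain-B copy contributes ``(baseline/2) * 2**c_g``.  A
    heterozygote therefore expects ``baseline * (1 + 2**c) / 2`` and the
    hom-B vs hom-A expected log2 ratio equals ``c`` exactly.  Response genes
    are additionally scaled by ``2**(t * dose)`` with dose 1 in causal
    homozygotes and ``het_trans_factor`` in carriers.  Counts are drawn
    NB(mean mu, dispersion phi) via gamma-Poisson mixing (variance
    mu + phi * mu**2).
    """
    if config.baseline_mean <= 0 or config.dispersion < 0:
        raise ConfigError("baseline_mean must be positive and dispersion non-negative")
    n_emb, n_genes = len(genomes), len(gene_table)
    n_b = np.zeros((n_genes, n_emb), dtype=np.int8)
    for c in range(config.n_chromosomes):
        mask = gene_table["chrom_idx"].to_numpy() == c
        if not mask.any():
            continue
        pos = gene_table.loc[mask, "start"].to_numpy()
        for j, g in enumerate(genomes):
            n_b[mask, j] = g.n_b_alleles(c, pos)

    cis = gene_table["cis_effect"].to_numpy()[:, None]
    half = config.baseline_mean / 2.0
    mu = half * ((2 - n_b) + n_b * np.exp2(cis))

    trans = gene_table["trans_effect"].to_numpy()
    if np.any(trans != 0.0):
        dose = _causal_dose(config, genomes)[None, :]
        mu = mu * np.exp2(trans[:, None] * dose)

    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=gene_table.index,
        columns=[f"embryo_{i:03d}" for i in range(n_emb)],
    )


def simulate_pool_sites(
    genomes: list[EmbryoGenome],
    mutant: np.ndarray,
    snp_table: pd.DataFrame,
    config: CrossConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pooled ref/alt read depths per SNP for the mutant and sibling pools.

    Alt reads are Binomial(depth, pool alt-allele frequency); the frequency
    is the exact mean alt dosage over pool members' genomes at that site.
    Site qualities come from a two-component mixture so that the QUAL < 100
    filter is exercised.
    """
    mutant = np.asarray(mutant, dtype=bool)
    if mutant.all() or (~mutant).all():
        raise ConfigError("both pools must be non-empty")
    pools = {"mut": np.where(mutant)[0], "sib": np.where(~mutant)[0]}

    n_sites = len(snp_table)
    freqs = {}
    for name, members in pools.items():
        alt_dose = np.zeros(n_sites)
        for c in range(config.n_chromosomes):
            mask = snp_table["chrom_idx"].to_numpy() == c
            if not mask.any():
                continue
            pos = snp_table.loc[mask, "pos"].to_numpy()
            alt_strain = snp_table.loc[mask, "alt_strain"].to_numpy()
            acc = np.zeros(mask.sum())
            for j in members:
                nb = genomes[j].n_b_alleles(c, pos).astype(np.int64)
                acc += np.where(alt_strain == STRAIN_B, nb, 2 - nb)
            alt_dose[mask] = acc / (2.0 * len(members))
        freqs[name] = alt_dose

    out = snp_table[["chrom", "pos"]].copy()
    for name in ("mut", "sib"):
        depth = rng.poisson(config.read_depth, size=n_sites)
        alt = rng.binomial(depth, freqs[name])
        out[f"ref_{name}"] = depth - alt
        out[f"alt_{name}"] = alt
    low = rng.random(n_sites) < config.low_quality_frac
    qual = np.where(
        low,
        rng.uniform(0.0, 99.0, size=n_sites),
        rng.uniform(100.0, 999.0, size=n_sites),
    )
    out["qual"] = np.round(qual, 1)
    return out.reset_index(drop=True)


def simulate_embryo_snp_calls(
    genomes: list[EmbryoGenome],
    snp_table: pd.DataFrame,
    config: CrossConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-embryo ref/alt read depths at informative SNPs (long table)."""
    frames = []
    names = [f"embryo_{i:03d}" for i in range(len(genomes))]
    n_sites = len(snp_table)
    alt_strain = snp_table["alt_strain"].to_numpy()
    for j, g in enumerate(genomes):
        alt_dose = np.zeros(n_sites, dtype=np.int8)
        for c in range(config.n_chromosomes):
            mask = snp_table["chrom_idx"].to_numpy() == c
            if not mask.any():
                continue
            nb = g.n_b_alleles(c, snp_table.loc[mask, "pos"].to_numpy())
            alt_dose[mask] = np.where(alt_strain[mask] == STRAIN_B, nb, 2 - nb)
        depth = rng.poisson(config.embryo_read_depth, size=n_sites)
        alt = rng.binomial(depth, alt_dose / 2.0)
        frames.append(
            pd.DataFrame(
                {
                    "embryo": names[j],
                    "chrom": snp_table["chrom"].to_numpy(),
                    "pos": snp_table["pos"].to_numpy(),
                    "ref_depth": depth - alt,
                    "alt_depth": alt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _parent_snp_genotypes(
    parents: tuple[EmbryoGenome, EmbryoGenome], snp_table: pd.DataFrame, config: CrossConfig
) -> pd.DataFrame:
    """Noise-free parental alt-dosage genotypes at the simulated SNPs.

    Stands in for deep parental exome/genome sequencing; quality and depth
    columns are set comfortably above the downstream filters.
    """
    out = snp_table[["chrom", "pos"]].copy()
    for label, parent in zip(("p1", "p2"), parents):
        dose = np.zeros(len(snp_table), dtype=np.int8)
        for c in range(config.n_chromosomes):
            mask = snp_table["chrom_idx"].to_numpy() == c
            if not mask.any():
                continue
            nb = parent.n_b_alleles(c, snp_table.loc[mask, "pos"].to_numpy())
            alt_strain = snp_table.loc[mask, "alt_strain"].to_numpy()
            dose[mask] = np.where(alt_strain == STRAIN_B, nb, 2 - nb)
        out[f"gt_{label}"] = dose
    out["gq"] = 200
    out["depth"] = 50
    return out


# ---------------------------------------------------------------------------
# top-level experiment


def simulate_incross(
    config: CrossConfig,
    include_counts: bool = True,
    include_pools: bool = True,
    include_embryo_snps: bool = True,
) -> SimulatedExperiment:
    """Simulate a full incross experiment from a :class:`CrossConfig`.

    The heavy components (counts matrix, pooled sites, per-embryo SNP reads)
    can be switched off individually when only genotype-level truth is
    needed, e.g. for Mendelian-ratio checks on very large clutches.
    """
    rng = np.random.default_rng(config.seed)
    parents = simulate_parents(config, rng)
    gene_table = _place_genes(config, rng)
    snp_table = _place_snps(config, rng)
    genomes, mutant = simulate_embryos(config, rng, parents)

    counts = pool_sites = embryo_calls = None
    if include_counts and config.n_genes > 0:
        counts = simulate_counts(genomes, gene_table, config, rng)
    if include_pools and len(snp_table) and config.causal_locus is not None:
        pool_sites = simulate_pool_sites(genomes, mutant, snp_table, config, rng)
    if include_embryo_snps and len(snp_table):
        embryo_calls = simulate_embryo_snp_calls(genomes, snp_table, config, rng)

    return SimulatedExperiment(
        config=config,
        parents=parents,
        genomes=genomes,
        mutant=mutant,
        gene_table=gene_table,
        snp_table=snp_table,
        counts=counts,
        pool_sites=pool_sites,
        embryo_snp_calls=embryo_calls,
        parent_snp_genotypes=_parent_snp_genotypes(parents, snp_table, config),
    )


# ---------------------------------------------------------------------------
# GO annotation fixture


def simulate_go(
    n_genes: int,
    n_terms: int,
    term_size_range: tuple[int, int],
    rng: np.random.Generator,
    spiked_terms: dict[str, list[str]] | None = None,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Random gene-to-term annotation, optionally with enriched (spiked) terms.

    Returns a two-column table (gene_id, term_id).  ``n_terms = 0`` with no
    spiked terms yields an empty annotation.
    """
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise ConfigError("term_size_range must satisfy 1 <= lo <= hi")
    if hi > n_genes:
        raise ConfigError("term sizes cannot exceed the number of genes")
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        term = f"GO:{t:07d}"
        rows.extend((gene_ids[m], term) for m in members)
    for term, members in (spiked_terms or {}).items():
        rows.extend((g, term) for g in members)
    return pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates(
        ignore_index=True
    )


# ---------------------------------------------------------------------------
# four-genotype compound-heterozygote cross


def simulate_four_genotype_experiment(
    n_per_group: int = 8,
    n_genes: int = 200,
    n_ase: int = 10,
    n_response: int = 15,
    ase_log2_effect: float = 1.0,
    response_log2_effect: float = 1.0,
    baseline_mean: float = 500.0,
    dispersion: float = 0.01,
    seed: int = 0,
    mutant_chrom: str = "3",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Counts for a cross of two mutant alleles of the same gene (m1/+ x +/m2).

    Offspring genotypes are +/+, m1/+, +/m2 and m1/m2 (compound
    heterozygotes, the phenotypic mutants).  Planted ASE genes track one
    parental wild-type chromosome: the groups sharing the wild-type copy
    from the m2 parent (+/+ and m1/+) expereince a cis boost of
    ``ase_log2_effect`` per carried copy.  Planted response genes scale
    with functional-allele dosage (2, 1, 1, 0) at half ``response_log2_effect``
    per lost allele.  Remaining genes are null.

    Returns (counts, genotype per sample, truth table with a ``truth``
    column in {"ase", "response", "null"}).
    """
    rng = np.random.default_rng(seed)
    genotypes = ["wt", "het_m1", "het_m2", "comphet"]
    # copies of the wild-type chromosome inherited from the m2 parent
    wt_m2parent_copies = {"wt": 1, "het_m1": 1, "het_m2": 0, "comphet": 0}
    dosage = {"wt": 2, "het_m1": 1, "het_m2": 1, "comphet": 0}

    samples, labels = [], []
    for g in genotypes:
        for i in range(n_per_group):
            samples.append(f"{g}_{i:02d}")
            labels.append(g)
    design = pd.Series(labels, index=samples, name="genotype")

    truth = np.array(
        ["ase"] * n_ase + ["response"] * n_response + ["null"] * (n_genes - n_ase - n_response)
    )
    rng.shuffle(truth)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    mu = np.full((n_genes, len(samples)), baseline_mean)
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    for gi in range(n_genes):
        for sj, g in enumerate(labels):
            if truth[gi] == "ase":
                # expression rises with carriage of the tracked wild-type chromosome
                boost = wt_m2parent_copies[g] * ase_log2_effect * signs[gi]
                mu[gi, sj] *= 2.0 ** boost
            elif truth[gi] == "response":
                lost = 2 - dosage[g]
                mu[gi, sj] *= 2.0 ** (0.5 * lost * response_log2_effect * signs[gi])
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    else:
        lam = mu
    counts = pd.DataFrame(rng.poisson(lam), index=gene_ids, columns=samples)
    truth_table = pd.DataFrame(
        {"truth": truth, "chrom": mutant_chrom, "start": np.arange(1, n_genes + 1) * 10_000},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts, design, truth_table
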