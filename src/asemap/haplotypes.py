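"""Per-embryo haplotype calling in 1-Mbp windows and the region-wise ASE scan.

A cross of two parents descended from two sequenced founder haplotypes
(strains A and B, e.g. the double-haploid AB and Tübingen fish) lets every
offspring genotype be read off RNA-seq reads: at *informative* SNPs — sites
homozygous-reference in one founder and homozygous-alternate in the other —
the allele observed names the strain of origin.  Per-embryo genotype calls
are aggregated into fixed 1-Mbp windows by majority vote, producing a
haplotype map (embryos x windows) with five states: homozygous A,
heterozygous, homozygous B, NC (majority call impossible given the parents'
haplotypes) and NA (insufficient data or a tied vote).

*Informative regions* are runs of windows where the parents' combined
genotypes allow at least two offspring genotypes, so allele-specific
expression is observable.  Embryos are grouped by their regional genotype
(recombinants resolved by their longest contiguous run), and a
differential-expression scan between genotype groups reveals cis-driven
expression differences: DE genes concentrated in or near the defining
region with homozygote-vs-homozygote fold changes larger than
heterozygote-vs-homozygote ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import nb_test

__all__ = [
    "HOM_A",
    "HET",
    "HOM_B",
    "NC",
    "NA",
    "GENOTYPE_LABELS",
    "HaplotypeMap",
    "InformativeRegion",
    "select_informative_snps",
    "genotype_embryo_site",
    "strain_dosage",
    "call_window_haplotype",
    "window_start",
    "build_haplotype_map",
    "parental_window_genotypes",
    "possible_offspring",
    "define_informative_regions",
    "group_embryos",
    "ase_scan",
]

# genotype codes = number of strain-B alleles; negative codes are non-calls
HOM_A, HET, HOM_B = 0, 1, 2
NC = -1  # majority call inconsistent with parental haplotypes
NA = -2  # no call (insufficient data or tied vote)

GENOTYPE_LABELS = {HOM_A: "A/A", HET: "A/B", HOM_B: "B/B", NC: "NC", NA: "NA"}
LABEL_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}

DEFAULT_WINDOW = 1_000_000


def select_informative_snps(
    founder_a: pd.DataFrame,
    founder_b: pd.DataFrame | None = None,
    min_gq: float = 100.0,
    min_depth: float = 10.0,
) -> pd.DataFrame:
    """Sites homozygous-reference in one founder and homozygous-alternate in the other.

    ``founder_a``/``founder_b`` carry ``chrom, pos, gt`` (alt-allele dosage
    0/1/2) and optionally ``gq`` (genotype quality) and ``depth``; when the
    optional columns are present, sites below ``min_gq`` or with mean depth
    below ``min_depth`` are dropped.  Alternatively a single pre-merged
    frame with ``gt_a``/``gt_b`` columns may be given.  Returns ``chrom,
    pos, alt_strain`` where ``alt_strain`` is 0 (strain A) or 1 (strain B):
    the strain whose founder carries the alternate allele.
    """
    if founder_b is not None:
        merged = founder_a.merge(
            founder_b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner"
        )
        if merged.empty:
            raise ValueError("founders share no genotyped positions")
    else:
        merged = founder_a.copy()
        if not {"gt_a", "gt_b"}.issubset(merged.columns):
            raise ValueError("merged founder table needs gt_a and gt_b columns")

    keep = ((merged["gt_a"] == 0) & (merged["gt_b"] == 2)) | (
        (merged["gt_a"] == 2) & (merged["gt_b"] == 0)
    )
    for col in ("gq_a", "gq_b", "gq"):
        if col in merged.columns:
            keep &= merged[col] >= min_gq
    depth_cols = [c for c in ("depth_a", "depth_b", "depth") if c in merged.columns]
    if depth_cols:
        keep &= merged[depth_cols].mean(axis=1) >= min_depth

    out = merged.loc[keep, ["chrom", "pos"]].copy()
    out["alt_strain"] = np.where(merged.loc[keep, "gt_b"] == 2, 1, 0)
    return out.reset_index(drop=True)


def genotype_embryo_site(ref_depth, alt_depth, min_depth: int = 5):
    """Raw alt-allele dosage call from read depths (vectorised).

    No-call (NA) below ``min_depth`` total reads; hom-ref at alt fraction
    <= 0.1, hom-alt at >= 0.9, het in [0.3, 0.7]; intermediate fractions are
    no-calls.  A simple allele-fraction caller; its thresholds are validated
    against simulation truth, not against any external caller.
    """
    ref = np.asarray(ref_depth)
    alt = np.asarray(alt_depth)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read depths must be non-negative")
    total = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
    out = np.full(ref.shape, NA, dtype=np.int8)
    out[frac <= 0.1] = 0
    out[(frac >= 0.3) & (frac <= 0.7)] = 1
    out[frac >= 0.9] = 2
    out[total < min_depth] = NA
    return out if out.ndim else int(out)


def strain_dosage(alt_dosage, alt_strain):
    """Convert alt-allele dosage to strain-B dosage given each site's alt strain."""
    alt_dosage = np.asarray(alt_dosage)
    alt_strain = np.asarray(alt_strain)
    out = np.where(alt_strain == 1, alt_dosage, 2 - alt_dosage).astype(np.int8)
    return np.where(alt_dosage < 0, alt_dosage, out).astype(np.int8)


def call_window_haplotype(calls, min_calls: int = 5, possible=None) -> int:
    """Majority-vote strain genotype for one embryo in one window.

    NA when fewer than ``min_calls`` informative calls or the vote is tied;
    NC when the winning genotype is impossible given the parental
    haplotypes in the window (``possible``, a set of genotype codes).
    """
    calls = np.asarray(calls)
    calls = calls[calls >= 0]
    if len(calls) < min_calls:
        return NA
    counts = np.bincount(calls, minlength=3)
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    if len(winners) > 1:
        return NA
    call = int(winners[0])
    if possible is not None and call not in possible:
        return NC
    return call


def window_start(pos, window_size: int = DEFAULT_WINDOW):
    """Start coordinate of the fixed window containing each 1-based position."""
    pos = np.asarray(pos, dtype=np.int64)
    out = ((pos - 1) // window_size) * window_size + 1
    return out if out.ndim else int(out)


@dataclass
class HaplotypeMap:
    """Embryo x window matrix of strain-genotype codes.

    ``calls`` is indexed by embryo; columns are a (chrom, window_start)
    MultiIndex tiling each chromosome in fixed bins from coordinate 1.
    """

    calls: pd.DataFrame
    window_size: int = DEFAULT_WINDOW

    @property
    def embryos(self) -> pd.Index:
        return self.calls.index

    def labelled(self) -> pd.DataFrame:
        """Calls as display labels (A/A, A/B, B/B, NC, NA)."""
        return self.calls.replace(GENOTYPE_LABELS)

    def to_long(self) -> pd.DataFrame:
        long = self.calls.stack([0, 1], future_stack=True).rename("call").reset_index()
        long.columns = ["embryo", "chrom", "window_start", "call"]
        long["call"] = long["call"].map(GENOTYPE_LABELS)
        return long


def build_haplotype_map(
    embryo_calls: pd.DataFrame,
    informative_snps: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    min_depth: int = 5,
    min_calls: int = 5,
    parental_windows: pd.DataFrame | None = None,
    chrom_lengths: dict | None = None,
) -> HaplotypeMap:
    """Call every embryo's strain genotype in fixed windows from SNP read depths.

    ``embryo_calls`` is the long table (embryo, chrom, pos, ref_depth,
    alt_depth); sites are genotyped with :func:`genotype_embryo_site`,
    converted to strain space via the informative-SNP table, and windows
    called by majority vote.  When ``parental_windows`` (gt_p1/gt_p2 codes
    per window) is supplied, majority calls impossible under the parents are
    marked NC.  ``chrom_lengths`` extends the tiling to SNP-free windows
    (all NA).
    """
    merged = embryo_calls.merge(
        informative_snps[["chrom", "pos", "alt_strain"]], on=["chrom", "pos"], how="inner"
    )
    raw = genotype_embryo_site(
        merged["ref_depth"].to_numpy(), merged["alt_depth"].to_numpy(), min_depth
    )
    merged["strain_gt"] = strain_dosage(raw, merged["alt_strain"].to_numpy())
    merged["window_start"] = window_start(merged["pos"].to_numpy(), window_size)

    possible_lookup = None
    if parental_windows is not None:
        possible_lookup = {
            idx: possible_offspring(int(row["gt_p1"]), int(row["gt_p2"]))
            for idx, row in parental_windows.iterrows()
        }

    embryos = sorted(embryo_calls["embryo"].unique())
    windows: list[tuple[str, int]] = []
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            starts = range(1, int(length) + 1, window_size)
            windows.extend((str(chrom), s) for s in starts)
    else:
        seen = merged[["chrom", "window_start"]].drop_duplicates()
        windows = [(str(c), int(w)) for c, w in seen.itertuples(index=False)]
        windows.sort(key=lambda t: ((0, int(t[0])) if t[0].isdigit() else (1, t[0]), t[1]))

    columns = pd.MultiIndex.from_tuples(windows, names=["chrom", "window_start"])

    # vectorised majority vote: genotype tallies per (embryo, chrom, window)
    valid = merged[merged["strain_gt"] >= 0]
    tab = (
        valid.groupby(["embryo", "chrom", "window_start"])["strain_gt"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=[HOM_A, HET, HOM_B], fill_value=0)
    )
    n_calls = tab.sum(axis=1)
    top = tab.max(axis=1)
    tied = tab.eq(top, axis=0).sum(axis=1) > 1
    call = tab.idxmax(axis=1).astype(np.int8)
    call[tied | (n_calls < min_calls)] = NA
    if possible_lookup is not None:
        keys = [(str(c), int(w)) for _, c, w in call.index]
        inconsistent = np.array(
            [
                g >= 0 and bool(possible_lookup.get(k)) and g not in possible_lookup[k]
                for g, k in zip(call.to_numpy(), keys)
            ]
        )
        call[inconsistent] = NC

    mat = call.unstack("embryo").T.reindex(index=embryos, columns=columns)
    mat = mat.fillna(NA).astype(np.int8)
    mat.index.name = "embryo"
    return HaplotypeMap(mat, window_size)


def parental_window_genotypes(
    parent_genotypes: pd.DataFrame,
    informative_snps: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    min_calls: int = 5,
) -> pd.DataFrame:
    """Window-level strain genotypes of the two cross parents.

    ``parent_genotypes`` carries per-SNP alt dosages ``gt_p1, gt_p2`` (from
    deep parental sequencing).  Dosages are converted to strain space and
    windows called by majority vote, mirroring the embryo pipeline.
    Returns a frame indexed by (chrom, window_start) with ``gt_p1, gt_p2``
    codes (NA where a parent is uncallable).
    """
    merged = parent_genotypes.merge(
        informative_snps[["chrom", "pos", "alt_strain"]], on=["chrom", "pos"], how="inner"
    )
    merged["window_start"] = window_start(merged["pos"].to_numpy(), window_size)
    alt_strain = merged["alt_strain"].to_numpy()
    for p in ("p1", "p2"):
        merged[f"strain_{p}"] = strain_dosage(merged[f"gt_{p}"].to_numpy(), alt_strain)
    rows = {}
    for (chrom, wstart), grp in merged.groupby(["chrom", "window_start"], sort=False):
        rows[(str(chrom), int(wstart))] = tuple(
            call_window_haplotype(grp[f"strain_{p}"].to_numpy(), min_calls=min_calls)
            for p in ("p1", "p2")
        )
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["gt_p1", "gt_p2"])
    out.index = pd.MultiIndex.from_tuples(out.index, names=["chrom", "window_start"])
    return out.sort_index()


def possible_offspring(gt_p1: int, gt_p2: int) -> frozenset:
    """Offspring genotype codes a parental genotype pair can produce."""
    def alleles(gt):
        return {0: (0,), 1: (0, 1), 2: (1,)}.get(gt, ())

    return frozenset(a + b for a in alleles(gt_p1) for b in alleles(gt_p2))


@dataclass
class InformativeRegion:
    """Run of contiguous windows with >= 2 possible offspring genotypes."""

    chrom: str
    start: int  # first window start (1-based)
    end: int  # last window end (inclusive)
    window_starts: list = field(default_factory=list)
    possible: frozenset = frozenset()

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def define_informative_regions(
    parental_windows: pd.DataFrame,
    hap_map: HaplotypeMap,
    min_callable_fraction: float = 0.8,
) -> list[InformativeRegion]:
    """Maximal runs of contiguous windows permitting >= 2 offspring genotypes.

    A window qualifies when both parents have window calls, the parental
    combination allows at least two offspring genotypes, and at least
    ``min_callable_fraction`` of embryos have a non-NA call there.  Runs
    break where the set of possible genotypes changes (a different grouping
    applies) or windows are non-adjacent.
    """
    w = hap_map.window_size
    regions: list[InformativeRegion] = []
    current: InformativeRegion | None = None
    for (chrom, wstart), row in parental_windows.sort_index().iterrows():
        chrom = str(chrom)
        wstart = int(wstart)
        possible = possible_offspring(int(row["gt_p1"]), int(row["gt_p2"]))
        ok = len(possible) >= 2 and int(row["gt_p1"]) >= 0 and int(row["gt_p2"]) >= 0
        if ok:
            key = (chrom, wstart)
            if key in hap_map.calls.columns:
                callable_frac = (hap_map.calls[key] != NA).mean()
            else:
                callable_frac = 0.0
            ok = callable_frac >= min_callable_fraction
        if ok and (
            current is not None
            and current.chrom == chrom
            and current.window_starts[-1] + w == wstart
            and current.possible == possible
        ):
            current.window_starts.append(wstart)
            current.end = wstart + w - 1
        elif ok:
            current = InformativeRegion(chrom, wstart, wstart + w - 1, [wstart], possible)
            regions.append(current)
        else:
            current = None
    return regions


def group_embryos(region: InformativeRegion, hap_map: HaplotypeMap) -> pd.Series:
    """Assign each embryo a genotype group within an informative region.

    Embryos with a single genotype across the region get that group;
    recombinants (>= 2 genotypes) get the genotype of their longest
    contiguous window run, with ties left unassigned (NA).  NC and NA
    windows break contiguity but never form groups.
    """
    cols = [(region.chrom, w) for w in region.window_starts]
    sub = hap_map.calls[cols].to_numpy()
    out = np.full(len(sub), NA, dtype=np.int8)
    for i, row in enumerate(sub):
        valid = [c if (c >= 0 and c in region.possible) else None for c in row]
        present = {c for c in valid if c is not None}
        if not present:
            continue
        if len(present) == 1:
            out[i] = present.pop()
            continue
        # longest contiguous run per genotype
        best_len: dict[int, int] = {}
        run_val, run_len = None, 0
        for c in valid + [None]:
            if c is not None and c == run_val:
                run_len += 1
            else:
                if run_val is not None:
                    best_len[run_val] = max(best_len.get(run_val, 0), run_len)
                run_val, run_len = c, 1 if c is not None else 0
        top = max(best_len.values())
        winners = [g for g, l in best_len.items() if l == top]
        out[i] = winners[0] if len(winners) == 1 else NA
    return pd.Series(out, index=hap_map.embryos, name=region.region_id)


_CONTRASTS = {
    "hom_vs_hom": (HOM_A, HOM_B),
    "het_vs_hom_a": (HOM_A, HET),
    "het_vs_hom_b": (HOM_B, HET),
}


def ase_scan(
    regions: list[InformativeRegion],
    hap_map: HaplotypeMap,
    counts: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    alpha: float = 0.05,
    min_group: int = 2,
    contrasts: tuple = ("hom_vs_hom", "het_vs_hom_a", "het_vs_hom_b"),
    keep_all: bool = False,
) -> pd.DataFrame:
    """Region-wise differential expression between genotype groups.

    For every informative region and every requested contrast with at least
    ``min_group`` embryos per side, runs the negative-binomial test over all
    genes and annotates each result with whether the gene lies inside the
    defining region.  By default only DE rows are returned (set
    ``keep_all`` for the full table).  Fold changes are oriented as second
    group vs first (e.g. hom-B vs hom-A, het vs hom).
    """
    frames = []
    for region in regions:
        assignment = group_embryos(region, hap_map)
        for name in contrasts:
            g_ref, g_alt = _CONTRASTS[name]
            if g_ref not in region.possible or g_alt not in region.possible:
                continue
            ref_ids = assignment.index[assignment == g_ref]
            alt_ids = assignment.index[assignment == g_alt]
            if len(ref_ids) < min_group or len(alt_ids) < min_group:
                warnings.warn(
                    f"region {region.region_id} contrast {name}: undersized groups; skipped"
                )
                continue
            members = ref_ids.tolist() + alt_ids.tolist()
            groups = pd.Series(
                ["ref"] * len(ref_ids) + ["alt"] * len(alt_ids), index=members
            )
            res = nb_test(counts[members], groups, alpha=alpha, reference="ref")
            res = res if keep_all else res[res["de"]]
            if res.empty:
                continue
            res = res.copy()
            ann = gene_annotation.reindex(res.index)
            res["chrom"] = ann["chrom"].astype(str)
            res["start"] = ann["start"]
            res["inside_region"] = (
                (res["chrom"] == region.chrom)
                & (res["start"] >= region.start)
                & (res["start"] <= region.end)
            )
            res["region_id"] = region.region_id
            res["contrast"] = name
            res["n_ref"] = len(ref_ids)
            res["n_alt"] = len(alt_ids)
            frames.append(res.reset_index())
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id", "base_mean", "log2fc", "se", "stat", "pvalue", "padj",
                "de", "tested", "chrom", "start", "inside_region", "region_id",
                "contrast", "n_ref", "n_alt",
            ]
        )
    return pd.concat(frames, ignore_index=True)
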