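"""Pooled allele-balance LD mapping.

Locates a recessive causal locus from mutant-vs-sibling pooled RNA-seq: at
each SNP the allele balance (fraction of reads carrying the alternate
allele) is computed per pool, the per-pool balances are LOESS-smoothed
along each chromosome, and the absolute difference of the two smoothed
curves measures how strongly that region segregates with the phenotype.
The genome-wide maximum of the difference curve is the mapping peak; the
smoothed curve is interpolated to assign an LD value to any genomic
position (e.g. a gene start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "VariantSite",
    "LoessCurve",
    "LdProfile",
    "LdPeak",
    "filter_variants",
    "allele_balance",
    "loess_smooth",
    "ld_profiles",
    "ld_difference",
    "find_peak",
    "interpolate_ld",
    "plot_profiles",
]

POOL_COLUMNS = ["ref_mut", "alt_mut", "ref_sib", "alt_sib"]


@dataclass(frozen=True)
class VariantSite:
    """One SNP with per-pool read depths — the LD-mapping atom."""

    chrom: str
    pos: int
    ref_mut: int
    alt_mut: int
    ref_sib: int
    alt_sib: int
    quality: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if min(self.ref_mut, self.alt_mut, self.ref_sib, self.alt_sib) < 0:
            raise ValueError("read counts must be non-negative")


def _as_frame(sites) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of VariantSite."""
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref_mut": s.ref_mut,
                "alt_mut": s.alt_mut,
                "ref_sib": s.ref_sib,
                "alt_sib": s.alt_sib,
                "qual": s.quality,
            }
            for s in sites
        ]
    )


def filter_variants(sites, min_quality: float = 100.0):
    """Drop SNPs below the quality threshold or covered in only one pool.

    A site must have quality >= ``min_quality`` and nonzero total read depth
    in *both* pools to be retained; order is preserved.  Returns the same
    container kind it was given (DataFrame in, DataFrame out).
    """
    frame = _as_frame(sites)
    keep = (
        (frame["qual"] >= min_quality)
        & (frame["ref_mut"] + frame["alt_mut"] > 0)
        & (frame["ref_sib"] + frame["alt_sib"] > 0)
    )
    out = frame.loc[keep].reset_index(drop=True)
    if isinstance(sites, pd.DataFrame):
        return out
    return [
        VariantSite(r.chrom, r.pos, r.ref_mut, r.alt_mut, r.ref_sib, r.alt_sib, r.qual)
        for r in out.itertuples()
    ]


def allele_balance(ref_count, alt_count):
    """Proportion of reads carrying the alternate allele: alt / (ref + alt)."""
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    total = ref + alt
    if np.any(total <= 0):
        raise ValueError("allele balance undefined at zero total depth; filter first")
    out = alt / total
    return float(out) if out.ndim == 0 else out


@dataclass
class LoessCurve:
    """A smoothed curve evaluable anywhere in its x-range (clamped outside)."""

    grid: np.ndarray
    values: np.ndarray

    def __call__(self, positions):
        out = np.interp(np.asarray(positions, dtype=float), self.grid, self.values)
        return float(out) if out.ndim == 0 else out


def loess_smooth(positions, values, span: float = 0.3, delta_frac: float = 0.0) -> LoessCurve:
    """LOESS (locally weighted linear regression, tricube weights) of values on position.

    ``span`` is the fraction of points in each local neighbourhood.
    ``delta_frac > 0`` enables the standard LOESS speed-up that fits only at
    points at least ``delta_frac * range`` apart and interpolates linearly
    between them.  Output is clamped to [0, 1] (allele balances are
    proportions).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty set of points")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size == 1:
        warnings.warn("single data point: returning a constant curve")
        return LoessCurve(x, np.clip(y, 0.0, 1.0))
    delta = delta_frac * (x[-1] - x[0])
    fitted = _sm_lowess(y, x, frac=span, it=0, delta=delta, return_sorted=False)
    return LoessCurve(x, np.clip(fitted, 0.0, 1.0))


@dataclass
class LdProfile:
    """Per-chromosome smoothed pool balances and their absolute difference."""

    chrom: str
    positions: np.ndarray
    mut: np.ndarray
    sib: np.ndarray
    diff: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.mut) == len(self.sib) == len(self.diff) == n):
            raise ValueError("curves must share the grid")

    def interpolate(self, positions):
        """Linear interpolation of the difference curve; clamps outside the grid."""
        out = np.interp(np.asarray(positions, dtype=float), self.positions, self.diff)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions.astype(np.int64),
                "mut_smooth": self.mut,
                "sib_smooth": self.sib,
                "difference": self.diff,
            }
        )


@dataclass(frozen=True)
class LdPeak:
    """Genome-wide maximum of the smoothed allele-balance difference."""

    chrom: str
    pos: int
    value: float


def ld_difference(
    chrom: str, positions, mut_curve: np.ndarray, sib_curve: np.ndarray
) -> LdProfile:
    """Assemble an :class:`LdProfile` as |mut - sib| on a shared grid."""
    mut = np.asarray(mut_curve, dtype=float)
    sib = np.asarray(sib_curve, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if mut.shape != sib.shape or mut.shape != pos.shape:
        raise ValueError("mutant and sibling curves must share the grid")
    return LdProfile(chrom, pos, mut, sib, np.abs(mut - sib))


def ld_profiles(
    sites: pd.DataFrame,
    span: float = 0.3,
    min_quality: float = 100.0,
    delta_frac: float = 0.0,
    prefiltered: bool = False,
) -> dict[str, LdProfile]:
    """Filter sites and build smoothed LD profiles for every chromosome.

    Chromosomes left with fewer than two usable SNPs are skipped with a
    warning.  The smoothing grid is the retained SNP positions themselves.
    """
    frame = sites if prefiltered else filter_variants(_as_frame(sites), min_quality)
    profiles: dict[str, LdProfile] = {}
    for chrom, grp in frame.groupby("chrom", sort=False):
        if len(grp) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 SNPs after filtering; skipped")
            continue
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy(dtype=float)
        bal_mut = allele_balance(grp["ref_mut"].to_numpy(), grp["alt_mut"].to_numpy())
        bal_sib = allele_balance(grp["ref_sib"].to_numpy(), grp["alt_sib"].to_numpy())
        mut = loess_smooth(pos, bal_mut, span=span, delta_frac=delta_frac)
        sib = loess_smooth(pos, bal_sib, span=span, delta_frac=delta_frac)
        profiles[str(chrom)] = ld_difference(str(chrom), pos, mut.values, sib.values)
    return profiles


def _chrom_sort_key(name: str):
    return (0, int(name)) if name.isdigit() else (1, name)


def find_peak(profiles: dict[str, LdProfile]) -> LdPeak:
    """Genome-wide argmax of the difference curves at SNP positions.

    Ties are broken toward the smallest (chromosome, position).
    """
    best: LdPeak | None = None
    for chrom in sorted(profiles, key=_chrom_sort_key):
        p = profiles[chrom]
        if len(p.positions) == 0:
            continue
        i = int(np.argmax(p.diff))  # first occurrence -> smallest position
        if best is None or p.diff[i] > best.value:
            best = LdPeak(chrom, int(p.positions[i]), float(p.diff[i]))
    if best is None:
        raise ValueError("no non-empty LD profiles")
    return best


def interpolate_ld(profiles: dict[str, LdProfile] | LdProfile, chrom: str, positions):
    """LD (smoothed |mut - sib|) at arbitrary positions on one chromosome."""
    if isinstance(profiles, LdProfile):
        profile = profiles
        if profile.chrom != str(chrom):
            raise KeyError(f"profile is for chromosome {profile.chrom}, not {chrom}")
    else:
        try:
            profile = profiles[str(chrom)]
        except KeyError:
            raise KeyError(f"no LD profile for chromosome {chrom!r}") from None
    return profile.interpolate(positions)


def plot_profiles(profiles: dict[str, LdProfile], path: str, de_positions=None) -> None:
    """One panel per chromosome: pool balances, difference curve, optional DE gene ticks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(profiles, key=_chrom_sort_key)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.8 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        p = profiles[chrom]
        mb = p.positions / 1e6
        ax.plot(mb, p.mut, color="tab:blue", lw=1, label="mutant pool")
        ax.plot(mb, p.sib, color="tab:orange", lw=1, label="sibling pool")
        ax.plot(mb, p.diff, color="tab:green", lw=1.2, label="|difference|")
        if de_positions is not None:
            on = de_positions[de_positions["chrom"] == chrom]
            for x in on["start"] / 1e6:
                ax.axvline(x, color="grey", alpha=0.3, lw=0.5)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel(f"chr{chrom}")
    axes[0, 0].legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
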