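"""Logistic-regression test of linkage between LD and differential expression.

The central question: does physical proximity to the mapping peak (high
pooled-LD value) raise a gene's probability of being called differentially
expressed?  Each gene contributes one Bernoulli observation (its DE flag)
and one covariate (the smoothed allele-balance difference interpolated at
the gene start).  The model

    P(DE) = logistic(alpha + beta * LD)

is fitted by maximum likelihood (iteratively reweighted least squares),
with a Wald test on beta.  The effect is summarised as an odds ratio
comparing DE odds at the genome-wide maximum gene-level LD against the
median: ``OR = exp(beta * (ld_max - ld_median))``.  P-values from several
mutant lines are combined with a Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinkageLogit",
    "LinkageLogitResults",
    "fit_logit",
    "gene_ld_table",
    "odds_ratio",
    "adjust_across_lines",
    "significance_stars",
]

_MAX_ITER = 100
_TOL = 1e-8
_SEPARATION_ETA = 30.0  # |linear predictor| beyond which fitted probs are 0/1 numerically


@dataclass
class LinkageLogitResults:
    """Fitted linkage logit: estimates, uncertainty and diagnostics."""

    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    pvalue: float  # two-sided Wald p for beta
    converged: bool
    separation: bool
    n_iter: int
    llf: float
    n: int
    n_de: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.alpha_se, self.beta_se])

    def predict(self, ld) -> np.ndarray:
        eta = self.alpha + self.beta * np.asarray(ld, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))

    def odds_ratio(self, ld_max: float, ld_median: float) -> float:
        """Ratio of DE odds at maximum vs median LD: exp(beta * (ld_max - ld_median))."""
        if not self.converged:
            raise ValueError("odds ratio undefined for a non-converged fit")
        return float(np.exp(self.beta * (ld_max - ld_median)))

    def summary(self) -> str:
        lines = [
            "Linkage logistic regression (DE ~ LD)",
            f"  n genes      {self.n:>10d}",
            f"  n DE         {self.n_de:>10d}",
            f"  alpha        {self.alpha:>10.4f} (SE {self.alpha_se:.4f})",
            f"  beta         {self.beta:>10.4f} (SE {self.beta_se:.4f})",
            f"  Wald p(beta) {self.pvalue:>10.3g}",
            f"  converged    {str(self.converged):>10s}"
            + ("  [perfect separation suspected]" if self.separation else ""),
        ]
        return "\n".join(lines)


class LinkageLogit:
    """Maximum-likelihood logistic regression of DE status on gene-level LD.

    Parameters
    ----------
    de : array-like of bool
        Per-gene DE flags (the response).
    ld : array-like of float in [0, 1]
        Interpolated LD value at each gene's start.
    """

    def __init__(self, de, ld):
        self.endog = np.asarray(de, dtype=float)
        self.ld = np.asarray(ld, dtype=float)
        if self.endog.shape != self.ld.shape or self.endog.ndim != 1:
            raise ValueError("de and ld must be 1-D and equal length")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("de must be binary")
        n_de = int(self.endog.sum())
        if n_de == 0 or n_de == len(self.endog):
            raise ValueError("degenerate outcome: need at least one DE and one non-DE gene")
        self.exog = np.column_stack([np.ones_like(self.ld), self.ld])

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LinkageLogit":
        """Build from a gene table with ``ld`` and ``de`` columns (see gene_ld_table)."""
        return cls(table["de"].to_numpy(), table["ld"].to_numpy())

    def loglike(self, params) -> float:
        eta = self.exog @ np.asarray(params, dtype=float)
        # log(1 + e^eta) computed stably
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(self, tol: float = _TOL, maxiter: int = _MAX_ITER) -> LinkageLogitResults:
        """IRLS fit; convergence when the max parameter change drops below ``tol``.

        Perfect separation is flagged (``converged = False``) when the
        parameters diverge so that fitted probabilities saturate at 0/1.
        """
        y, X = self.endog, self.exog
        params = np.zeros(2)
        converged = False
        separation = False
        it = 0
        for it in range(1, maxiter + 1):
            eta = X @ params
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
            w = mu * (1.0 - mu)
            if np.all(np.abs(eta[w > 0]) > _SEPARATION_ETA) or w.max() < 1e-12:
                separation = True
                break
            WX = X * w[:, None]
            hess = X.T @ WX
            grad = X.T @ (y - mu)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                separation = True
                break
            params = params + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        if np.max(np.abs(X @ params)) > _SEPARATION_ETA and not converged:
            separation = True
        if separation:
            warnings.warn("perfect separation suspected; fit flagged as not converged")
            converged = False

        eta = X @ params
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = mu * (1.0 - mu)
        hess = X.T @ (X * w[:, None])
        try:
            cov = np.linalg.inv(hess)  # observed information
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            ses = np.array([np.nan, np.nan])
        z = params[1] / ses[1] if ses[1] > 0 else np.nan
        pvalue = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        return LinkageLogitResults(
            alpha=float(params[0]),
            beta=float(params[1]),
            alpha_se=float(ses[0]),
            beta_se=float(ses[1]),
            pvalue=max(pvalue, np.finfo(float).tiny) if np.isfinite(pvalue) else pvalue,
            converged=converged,
            separation=separation,
            n_iter=it,
            llf=self.loglike(params),
            n=len(y),
            n_de=int(y.sum()),
        )


def fit_logit(records: pd.DataFrame) -> LinkageLogitResults:
    """Functional wrapper: fit the linkage logit from a gene LD/DE table."""
    return LinkageLogit.from_table(records).fit()


def gene_ld_table(
    de_results: pd.DataFrame,
    profiles,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Join DE flags with interpolated LD at each gene start.

    ``annotation`` maps gene -> (chrom, start).  Genes on chromosomes
    without an LD profile are excluded (their count is reported in a
    warning), as are genes absent from the annotation.
    """
    from .ldmap import interpolate_ld

    genes = de_results.index.intersection(annotation.index)
    missing_ann = len(de_results) - len(genes)
    ann = annotation.loc[genes]
    rows = []
    n_no_profile = 0
    for chrom, grp in ann.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in profiles:
            n_no_profile += len(grp)
            continue
        ld = interpolate_ld(profiles, chrom, grp["start"].to_numpy())
        sub = pd.DataFrame(
            {
                "chrom": chrom,
                "start": grp["start"].to_numpy(),
                "ld": np.atleast_1d(ld),
                "de": de_results.loc[grp.index, "de"].to_numpy(),
            },
            index=grp.index,
        )
        rows.append(sub)
    if missing_ann or n_no_profile:
        warnings.warn(
            f"excluded {missing_ann} genes without annotation and "
            f"{n_no_profile} genes on chromosomes without SNP coverage"
        )
    if not rows:
        raise ValueError("no genes with both annotation and LD coverage")
    return pd.concat(rows).sort_index()


def odds_ratio(fit: LinkageLogitResults, ld_max: float, ld_median: float) -> float:
    """Module-level alias for :meth:`LinkageLogitResults.odds_ratio`."""
    return fit.odds_ratio(ld_max, ld_median)


def significance_stars(padj: float) -> str:
    if padj < 0.001:
        return "***"
    if padj < 0.01:
        return "**"
    if padj < 0.05:
        return "*"
    return "-"


def adjust_across_lines(pvalues) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment across mutant lines, with star codes.

    Accepts a sequence/Series of per-line Wald p-values, or a list of
    :class:`LinkageLogitResults` (their ``pvalue`` attributes are used).
    """
    items = list(pvalues) if not isinstance(pvalues, pd.Series) else pvalues
    if len(items) == 0:
        raise ValueError("need at least one fitted line")
    if not isinstance(items, pd.Series) and hasattr(items[0], "pvalue"):
        raw = np.array([f.pvalue for f in items])
        index = pd.RangeIndex(len(items))
    else:
        series = pd.Series(pvalues, dtype=float)
        raw, index = series.to_numpy(), series.index
    padj = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "pvalue": raw,
            "padj": padj,
            "stars": [significance_stars(q) for q in padj],
        },
        index=index,
    )
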