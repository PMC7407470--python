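"""Summary statistics: distinguishability, gene diversity, coancestry, ROC, OLS.

Distinguishability D~VH of two log-likelihood-ratio distributions is the
squared difference of their means over the sum of their (n−1) sample
variances — a separation index akin to a squared two-sample effect size.
Coancestry θ̂ between populations uses the Weir & Cockerham (1984)
variance-components estimator, combining per-allele, per-locus components
as a ratio of sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .genotype_io import MISSING, GenotypeTable

__all__ = [
    "DistinguishabilityResult",
    "CoancestryEstimate",
    "ROCCurve",
    "distinguishability",
    "gene_diversity",
    "mean_gene_diversity",
    "wc_theta",
    "roc",
    "ols_line",
]


@dataclass
class DistinguishabilityResult:
    mean_log_lr_related: float
    mean_log_lr_unrelated: float
    var_log_lr_related: float
    var_log_lr_unrelated: float
    d_vh: float
    central95_related: tuple[float, float]
    central95_unrelated: tuple[float, float]
    n_related: int
    n_unrelated: int


@dataclass
class CoancestryEstimate:
    theta_hat: float
    per_locus: pd.DataFrame  # columns: numerator (a) and denominator (a+b+c) sums
    locus_set: str = ""

    def __post_init__(self) -> None:
        num = self.per_locus["numerator"].sum()
        den = self.per_locus["denominator"].sum()
        if not np.isclose(self.theta_hat, num / den):
            raise ValueError("theta_hat must be the ratio of summed components")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def distinguishability(
    log_lrs_related: np.ndarray, log_lrs_unrelated: np.ndarray
) -> DistinguishabilityResult:
    """Separation of related vs unrelated log-LR distributions.

    ``D~VH = (mean_r − mean_u)² / (s_r² + s_u²)`` with unbiased sample
    variances; the central 95% intervals are the empirical 2.5%/97.5%
    quantiles (linear interpolation).
    """
    r = np.asarray(log_lrs_related, dtype=float)
    u = np.asarray(log_lrs_unrelated, dtype=float)
    if r.size < 2 or u.size < 2:
        raise ValueError("each log-LR vector needs at least two values")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(u))):
        raise ValueError("log-LR vectors must be finite")
    sr2 = r.var(ddof=1)
    su2 = u.var(ddof=1)
    if sr2 + su2 == 0:
        raise ValueError("distinguishability undefined: both variances are zero")
    d = (r.mean() - u.mean()) ** 2 / (sr2 + su2)
    return DistinguishabilityResult(
        mean_log_lr_related=float(r.mean()),
        mean_log_lr_unrelated=float(u.mean()),
        var_log_lr_related=float(sr2),
        var_log_lr_unrelated=float(su2),
        d_vh=float(d),
        central95_related=tuple(np.quantile(r, [0.025, 0.975])),
        central95_unrelated=tuple(np.quantile(u, [0.025, 0.975])),
        n_related=r.size,
        n_unrelated=u.size,
    )


# ---------------------------------------------------------------------------
# gene diversity
# ---------------------------------------------------------------------------


def gene_diversity(genotypes: np.ndarray) -> float:
    """Bias-corrected expected heterozygosity of one population at one locus.

    ``genotypes`` is an ``(n, 2)`` array of allele labels.  With observed
    frequencies p̃ over the 2n allele copies,
    ``H̃ = 2n/(2n−1) · (1 − Σ p̃²)``.  Missing data must be excluded
    beforehand (the sample size is shared across copies).
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] != 2 or g.shape[0] < 1:
        raise ValueError("expected an (n, 2) genotype array with n >= 1")
    if np.any(g == MISSING):
        raise ValueError(
            "missing data at this locus; exclude incomplete individuals first"
        )
    copies = g.ravel()
    n2 = copies.size
    _, counts = np.unique(copies, return_counts=True)
    p = counts / n2
    return float(n2 / (n2 - 1) * (1.0 - np.sum(p**2)))


def mean_gene_diversity(
    table: GenotypeTable, population: str, loci: Sequence[str] | None = None
) -> tuple[pd.Series, float]:
    """Per-locus gene diversity for one prior population and its unweighted mean."""
    loci = list(loci) if loci is not None else list(table.loci)
    sub = table.subset_loci(loci).subset_individuals(table.population_indices(population))
    sub.require_complete()
    h = pd.Series(
        [gene_diversity(sub.genotypes[:, j]) for j in range(len(loci))],
        index=pd.Index(loci, name="locus"),
        name="gene_diversity",
    )
    return h, float(h.mean())


# ---------------------------------------------------------------------------
# Weir & Cockerham coancestry
# ---------------------------------------------------------------------------


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Summed (a, a+b+c) variance components over the alleles of one locus.

    Implements the r = 2 population case of the 1984 three-component
    estimator: per allele, ``a`` captures between-population variance,
    ``b`` within-population between-individual variance and ``c`` the
    within-individual (heterozygote) term.
    """
    r = 2
    pops = [np.asarray(g1), np.asarray(g2)]
    n = np.array([g.shape[0] for g in pops], dtype=float)
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    num = den = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in pops])
        # observed frequency of heterozygotes carrying allele `al` exactly once
        h_i = np.array([np.mean(np.sum(g == al, axis=1) == 1) for g in pops])
        pbar = np.sum(n * p_i) / (r * nbar)
        s2 = np.sum(n * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(n * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num, den


def wc_theta(
    pop1: GenotypeTable | np.ndarray,
    pop2: GenotypeTable | np.ndarray,
    loci: Sequence[str] | None = None,
    locus_set: str = "",
) -> CoancestryEstimate:
    """Pairwise coancestry θ̂ between two population samples.

    Accepts two :class:`GenotypeTable` slices (sharing loci) or raw
    ``(n, L, 2)`` genotype arrays.  θ̂ is the ratio of the summed
    between-population components to the summed totals across loci and
    alleles — a ratio of sums, not a mean of per-locus ratios.
    """
    if isinstance(pop1, GenotypeTable):
        loci_names = list(loci) if loci is not None else list(pop1.loci)
        t1 = pop1.subset_loci(loci_names)
        t2 = pop2.subset_loci(loci_names)
        t1.require_complete()
        t2.require_complete()
        a1, a2 = t1.genotypes, t2.genotypes
    else:
        a1, a2 = np.asarray(pop1), np.asarray(pop2)
        loci_names = [f"L{j + 1}" for j in range(a1.shape[1])]
    if a1.shape[0] < 2 or a2.shape[0] < 2:
        raise ValueError("each population needs at least two individuals")
    rows = []
    for j, name in enumerate(loci_names):
        num, den = _wc_components(a1[:, j], a2[:, j])
        rows.append((name, num, den))
    per_locus = pd.DataFrame(
        rows, columns=["locus", "numerator", "denominator"]
    ).set_index("locus")
    den_total = per_locus["denominator"].sum()
    if den_total == 0:
        raise ValueError("theta undefined: no allele-frequency variance at any locus")
    theta = per_locus["numerator"].sum() / den_total
    return CoancestryEstimate(theta_hat=float(theta), per_locus=per_locus, locus_set=locus_set)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc(
    scores,
    truth=None,
    *,
    related_label: str = "related",
) -> ROCCurve:
    """ROC curve for classifying pairs as related by thresholding log LR.

    ``scores`` may be a DataFrame with ``log_lr``/``truth`` columns, or an
    array paired with ``truth`` labels.  Ties are grouped: all records at
    one log-LR value move together.  AUC is the trapezoid area, which for
    a tie-grouped curve equals the rank (concordance) statistic.
    """
    if isinstance(scores, pd.DataFrame):
        truth = scores["truth"].to_numpy()
        scores = scores["log_lr"].to_numpy()
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    y = truth == related_label if truth.dtype.kind in "OUS" else truth.astype(bool)
    if y.all() or not y.any():
        raise ValueError("ROC requires both related and unrelated records")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def ols_line(x, y) -> tuple[float, float]:
    """Ordinary-least-squares line through (x, y); returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept)
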