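"""Genotype PCA, single-site GLM association with PC covariates, haplotype
grouping, and the phenotype formulas (relative conductivity, anthocyanin
content) plus the two-group comparison.

The association model is the fixed-effect general linear model

    phenotype ~ intercept + dosage + PC_1 + ... + PC_k

fit site-by-site by least squares; the reported p-value is the two-sided test
on the dosage term (squared-t, equivalent to the partial F test). The
multiple-testing threshold is Bonferroni-style, p* = alpha / n with n the
number of tested sites, unless an effective number of independent sites is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

DEFAULT_N_COMPONENTS = 2
DEFAULT_ALPHA = 0.05


@dataclass
class PcaResult:
    coordinates: np.ndarray        # (n_samples, n_components)
    explained_variance: np.ndarray  # fractions


@dataclass
class GwasResult:
    table: pd.DataFrame            # chrom, pos, beta, stat, p
    n_tested: int
    alpha: float
    p_threshold: float

    @property
    def neg_log10_threshold(self) -> float:
        return round(-np.log10(self.p_threshold), 2)


def _imputed_dosages(gm: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the site mean."""
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def genotype_pca(gm: GenotypeMatrix, n_components: int = DEFAULT_N_COMPONENTS) -> PcaResult:
    """PCA of mean-centred dosages scaled by sqrt(p(1-p)) per site.

    Monomorphic sites are dropped; missing calls are mean-imputed (so they
    contribute nothing after centring). Sample coordinates come from the SVD
    of the standardised matrix, equivalent to eigen-decomposition of the
    sample covariance.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("need at least 2 samples and 2 sites")
    d = _imputed_dosages(gm)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all sites monomorphic")
    d = d[:, poly]
    p = p[poly]
    z = (d - 2 * p) / np.sqrt(p * (1.0 - p))
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    n_components = min(n_components, len(s))
    coords = u[:, :n_components] * s[:n_components]
    var = s**2
    return PcaResult(
        coordinates=coords,
        explained_variance=var[:n_components] / var.sum(),
    )


def glm_scan(
    phenotype: np.ndarray,
    gm: GenotypeMatrix,
    covariates: PcaResult | np.ndarray | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
    alpha: float = DEFAULT_ALPHA,
    n_eff: int | None = None,
) -> GwasResult:
    """Per-site least-squares association of phenotype on dosage with PC
    covariates.

    All sites are fit against the same covariate design, so the covariates
    are projected out of the phenotype and of every dosage column once
    (Frisch-Waugh) and the dosage slope, its t statistic and the two-sided
    p-value follow from the residualised regression. Constant-dosage sites
    are skipped.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != gm.n_samples:
        raise ValueError("phenotype length != number of samples")
    if np.isnan(y).any():
        raise ValueError("phenotypes must be complete")
    if isinstance(covariates, PcaResult):
        cov = covariates.coordinates[:, :n_components]
    elif covariates is None:
        cov = np.empty((gm.n_samples, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
    n, k = gm.n_samples, cov.shape[1]
    if k >= n - 2:
        raise ValueError("too many covariates for the sample size")

    x_cov = np.column_stack([np.ones(n), cov])
    q, _ = np.linalg.qr(x_cov)
    proj = lambda v: v - q @ (q.T @ v)  # noqa: E731
    y_res = proj(y)
    d = _imputed_dosages(gm)
    keep = d.std(axis=0) > 0
    d = d[:, keep]
    d_res = proj(d)

    sxx = (d_res**2).sum(axis=0)
    sxy = d_res.T @ y_res
    beta = sxy / sxx
    df = n - k - 2
    rss = (y_res**2).sum() - beta * sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "chrom": gm.chroms[keep],
            "pos": gm.positions[keep],
            "beta": beta,
            "stat": t,
            "p": p,
        }
    )
    n_tested = len(table)
    p_star, _ = significance_threshold(n_tested, alpha, n_eff)
    return GwasResult(table=table, n_tested=n_tested, alpha=alpha, p_threshold=p_star)


def significance_threshold(
    n: int, alpha: float = DEFAULT_ALPHA, n_eff: int | None = None
) -> tuple[float, float]:
    """Bonferroni-style threshold p* = alpha / n (or alpha / n_eff when the
    effective number of independent sites is supplied). Returns
    (p*, -log10(p*) rounded to 2 decimals)."""
    denom = n_eff if n_eff is not None else n
    if denom < 1:
        raise ValueError("site count must be >= 1")
    p_star = alpha / denom
    return p_star, round(-np.log10(p_star), 2)


# ---------------------------------------------------------------------------
# haplotypes and group comparison
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAssignment:
    site_ids: list[tuple[str, int]]
    patterns: dict[str, str]       # sample -> dosage string ("" if unassigned)
    groups: dict[str, str]         # sample -> "A" / "B" / "unassigned" / pattern id

UNASSIGNED = "unassigned"


def assign_haplotypes(
    gm: GenotypeMatrix,
    site_ids: list[tuple[str, int]],
    phenotype: dict[str, float] | None = None,
) -> HaplotypeAssignment:
    """Group samples by their joint dosage pattern at the defining sites.

    A sample with any missing call at those sites is unassigned. The two
    largest groups are labelled "A" and "B"; with a phenotype supplied, "A"
    is the group with the higher mean phenotype (the tolerant haplotype),
    otherwise the larger group. Remaining patterns keep a "hap3", ... label.
    """
    cols = []
    for chrom, pos in site_ids:
        hit = np.flatnonzero((gm.chroms == chrom) & (gm.positions == pos))
        if hit.size == 0:
            raise ValueError(f"site {chrom}:{pos} not in matrix")
        cols.append(int(hit[0]))
    sub = gm.dosages[:, cols]
    patterns: dict[str, str] = {}
    for i, sample in enumerate(gm.samples):
        row = sub[i]
        patterns[sample] = (
            "" if (row == MISSING).any() else "".join(str(int(x)) for x in row)
        )
    counts = pd.Series([p for p in patterns.values() if p]).value_counts()
    order = list(counts.index)
    top = order[:2]
    if phenotype is not None and len(top) == 2:
        means = {
            pat: np.mean([phenotype[s] for s, p in patterns.items() if p == pat])
            for pat in top
        }
        top = sorted(top, key=lambda pat: -means[pat])
    label_of = {}
    for rank, pat in enumerate(top):
        label_of[pat] = "AB"[rank]
    for rank, pat in enumerate(order[2:], start=3):
        label_of[pat] = f"hap{rank}"
    groups = {
        s: (label_of[p] if p else UNASSIGNED) for s, p in patterns.items()
    }
    return HaplotypeAssignment(site_ids=site_ids, patterns=patterns, groups=groups)


def compare_groups(values1, values2) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) two-sample t-test."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# phenotype formulas
# ---------------------------------------------------------------------------

def relative_conductivity(e0: float, e1: float, e2: float, conventional: bool = False) -> float:
    """Electrolyte-leakage ratio from conductivities before shaking (E0),
    after shaking (E1) and after boiling (E2).

    The default returns (E2-E0)/(E1-E0) as used in the source protocol; the
    ``conventional`` switch returns the usual leakage fraction
    (E1-E0)/(E2-E0).
    """
    if conventional:
        if e2 == e0:
            raise ValueError("E2 == E0: relative conductivity undefined")
        return (e1 - e0) / (e2 - e0)
    if e1 == e0:
        raise ValueError("E1 == E0: relative conductivity undefined")
    return (e2 - e0) / (e1 - e0)


def anthocyanin_content(a535: float, fresh_weight: float) -> float:
    """Anthocyanin content expressed as A535 absorbance per gram fresh weight."""
    if fresh_weight <= 0:
        raise ValueError("fresh weight must be positive")
    return a535 / fresh_weight
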