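"""Animal-model variance components and mixed-model single-SNP association.

The polygenic covariance uses the pedigree numerator relationship matrix
(NRM, tabular method).  REML maximizes the restricted likelihood over the
variance ratio after an eigendecomposition of the NRM; per-SNP tests are
generalized least squares with the variance structure fixed at the null
fit (the two-stage approximation popularized by EMMAX), with a Wald
p-value.  Phenotypes are pre-adjusted by subtracting contemporary-group
means before any model fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from awmnet.core import UNKNOWN, GenotypeMatrix, Pedigree


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    boundary: bool = False


# --------------------------------------------------------------------------
# Pedigree NRM
# --------------------------------------------------------------------------

def pedigree_nrm(pedigree: Pedigree) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular (recursive) method.

    Parents referenced but without their own record (e.g. ungenotyped
    dams) are added as unrelated founders; the returned matrix covers all
    animals, recorded or implied, with the id list giving row order
    (parents before offspring).  Raises on pedigree cycles.
    """
    ped = pedigree.table
    parents: dict[str, tuple[str, str]] = {}
    for _, row in ped.iterrows():
        parents[row["animal"]] = (row["sire"], row["dam"])
    # implied founders
    for s, d in list(parents.values()):
        for p in (s, d):
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)

    # topological order (parents first); cycle -> error
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(a: str) -> None:
        st = state.get(a, 0)
        if st == 1:
            raise ValueError(f"pedigree cycle involving {a}")
        if st == 2:
            return
        state[a] = 1
        for p in parents[a]:
            if p != UNKNOWN:
                visit(p)
        state[a] = 2
        order.append(a)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(parents) * 2 + 100))
    try:
        for a in parents:
            visit(a)
    finally:
        sys.setrecursionlimit(old)

    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    a_mat = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = parents[animal]
        si = pos.get(s, -1) if s != UNKNOWN else -1
        di = pos.get(d, -1) if d != UNKNOWN else -1
        a_mat[i, i] = 1.0 + (0.5 * a_mat[si, di] if si >= 0 and di >= 0 else 0.0)
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a_mat[:i, si]
        if di >= 0:
            row += 0.5 * a_mat[:i, di]
        a_mat[i, :i] = row
        a_mat[:i, i] = row
    return a_mat, order


def nrm_submatrix(
    a_mat: np.ndarray, order: list[str], animals: list[str]
) -> np.ndarray:
    pos = {a: i for i, a in enumerate(order)}
    idx = [pos[a] for a in animals]
    return a_mat[np.ix_(idx, idx)]


# --------------------------------------------------------------------------
# Contemporary-group pre-adjustment
# --------------------------------------------------------------------------

def adjust_contemporary_groups(
    phenotypes: pd.Series, grouping: pd.Series
) -> pd.Series:
    """Subtract the contemporary-group mean: y' = y - mean(y | group).

    Group means of the result are exactly zero.  Singleton groups yield
    y' = 0 and are warned about.
    """
    grouping = grouping.reindex(phenotypes.index)
    sizes = phenotypes.groupby(grouping).transform("size")
    singles = sorted(set(grouping[sizes == 1]))
    if singles:
        warnings.warn(f"singleton contemporary groups: {singles}")
    return phenotypes - phenotypes.groupby(grouping).transform("mean")


# --------------------------------------------------------------------------
# REML animal model
# --------------------------------------------------------------------------

def _reml_loglik(
    log_gamma: float, yr: np.ndarray, xr: np.ndarray, d: np.ndarray
) -> float:
    """Restricted log-likelihood profiled over sigma_e2.

    gamma = sigma_g2 / sigma_e2; yr, xr are rotated by the NRM
    eigenvectors and d holds the eigenvalues.
    """
    gamma = math.exp(log_gamma)
    v = gamma * d + 1.0
    n, p = xr.shape
    w = 1.0 / v
    xtwx = xr.T @ (xr * w[:, None])
    xtwy = xr.T @ (yr * w)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = yr - xr @ beta
    rss = float(resid @ (resid * w))
    if rss <= 0:
        return -np.inf
    sigma_e2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    ll = -0.5 * (
        (n - p) * math.log(sigma_e2)
        + np.log(v).sum()
        + logdet_xtwx
        + (n - p)
    )
    return ll


def reml_animal_model(
    y: np.ndarray,
    covariates: np.ndarray,
    a_matrix: np.ndarray,
    tol: float = 1e-8,
) -> VarianceComponents:
    """REML variance components for y = Xb + g + e with g ~ N(0, A sigma_g2).

    One-dimensional optimization over log(sigma_g2/sigma_e2) after an
    eigendecomposition of A.  The h2 standard error is information-based
    (numerical curvature of the restricted likelihood, delta method).
    Boundary solutions (h2 near 0 or 1) are flagged.
    """
    y = np.asarray(y, float)
    x = np.column_stack([np.ones(len(y)), np.atleast_2d(covariates).reshape(len(y), -1)]) \
        if covariates is not None and np.size(covariates) else np.ones((len(y), 1))
    d, u = np.linalg.eigh(a_matrix)
    if d.min() < -1e-8:
        raise ValueError("NRM is not positive semi-definite")
    d = np.clip(d, 0.0, None)
    yr = u.T @ y
    xr = u.T @ x

    res = optimize.minimize_scalar(
        lambda lg: -_reml_loglik(lg, yr, xr, d),
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lg = float(res.x)
    gamma = math.exp(lg)
    v = gamma * d + 1.0
    w = 1.0 / v
    xtwx = xr.T @ (xr * w[:, None])
    beta = np.linalg.solve(xtwx, xr.T @ (yr * w))
    resid = yr - xr @ beta
    n, p = xr.shape
    sigma_e2 = float(resid @ (resid * w)) / (n - p)
    sigma_g2 = gamma * sigma_e2
    h2 = gamma / (1.0 + gamma)

    # curvature of the restricted loglik in log-gamma -> SE of h2
    eps = 1e-3
    f0 = _reml_loglik(lg, yr, xr, d)
    fp = _reml_loglik(lg + eps, yr, xr, d)
    fm = _reml_loglik(lg - eps, yr, xr, d)
    curv = -(fp - 2 * f0 + fm) / eps**2
    se_h2 = np.nan
    if np.isfinite(curv) and curv > 0:
        se_lg = 1.0 / math.sqrt(curv)
        # dh2/dlog_gamma = gamma / (1+gamma)^2
        se_h2 = se_lg * gamma / (1.0 + gamma) ** 2
    boundary = lg <= -11.9 or lg >= 11.9
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, h2=h2, se_h2=se_h2,
        loglik=float(f0), boundary=boundary,
    )


# --------------------------------------------------------------------------
# Per-SNP GLS association
# --------------------------------------------------------------------------

def snp_association(
    y: np.ndarray,
    covariates: np.ndarray | None,
    a_matrix: np.ndarray,
    genotypes: GenotypeMatrix,
    sample_index: np.ndarray,
    trait: str = "",
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Two-stage mixed-model GWAS: null REML once, then per-SNP GLS.

    ``sample_index`` maps phenotype rows to genotype rows.  SNPs that are
    monomorphic among the phenotyped animals get a missing effect and a
    ``monomorphic`` flag.  Allele dosages are mean-imputed for testing.

    Returns a DataFrame with snp, chrom, bp, trait, effect, se, p, n_used
    and monomorphic columns.
    """
    y = np.asarray(y, float)
    n = len(y)
    x = np.column_stack([np.ones(n), np.atleast_2d(covariates).reshape(n, -1)]) \
        if covariates is not None and np.size(covariates) else np.ones((n, 1))
    if a_matrix.shape != (n, n):
        raise ValueError("A matrix dimension does not match phenotypes")
    if vc is None:
        vc = reml_animal_model(y, covariates, a_matrix)

    d, u = np.linalg.eigh(a_matrix)
    d = np.clip(d, 0.0, None)
    # whiten by V^{-1/2}, V = sigma_g2 A + sigma_e2 I
    scale = 1.0 / np.sqrt(vc.sigma_g2 * d + vc.sigma_e2)
    yt = (u.T @ y) * scale
    xt = (u.T @ x) * scale[:, None]

    dos = genotypes.dosages[sample_index, :]
    freqs = np.nanmean(dos, axis=0) / 2.0
    mono = np.isnan(freqs) | (freqs <= 0) | (freqs >= 1)
    n_used = (~np.isnan(dos)).sum(axis=0)
    filled = np.where(np.isnan(dos), 2.0 * freqs[None, :], dos)
    st = (u.T @ filled) * scale[:, None]

    # residualize the SNP and the outcome on the covariates (FWL)
    q, _ = np.linalg.qr(xt)
    yr = yt - q @ (q.T @ yt)
    sr = st - q @ (q.T @ st)
    ss = (sr**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = (sr.T @ yr) / ss
        se = np.sqrt(1.0 / ss)  # whitened noise has unit variance
        z = effect / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    effect[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan
    out = genotypes.snp_map[["snp", "chrom", "bp"]].copy()
    out["trait"] = trait
    out["effect"] = effect
    out["se"] = se
    out["p"] = p
    out["n_used"] = n_used
    out["monomorphic"] = mono
    return out


def genomic_inflation(p_values: np.ndarray) -> float:
    """Lambda_GC: median chi-squared over its null median."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def fdr_at_threshold(p_threshold: float, n_significant: int, n_tests: int) -> float:
    """FDR at a p-value cutoff: P (1 - A/T) / ((A/T)(1 - P)).

    With no significant tests (A = 0) the rate is undefined and reported
    as 1.0.
    """
    if n_significant == 0:
        warnings.warn("no significant tests; FDR undefined, reporting 1.0")
        return 1.0
    frac = n_significant / n_tests
    return p_threshold * (1.0 - frac) / (frac * (1.0 - p_threshold))


def phenotype_correlations(
    phenotypes: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between (adjusted) traits.

    Returns the correlation matrix and the per-pair sample sizes.
    """
    cols = traits if traits is not None else list(phenotypes.columns)
    sub = phenotypes[cols]
    corr = sub.corr(method="pearson", min_periods=2)
    notna = sub.notna().astype(int)
    n = pd.DataFrame(notna.T @ notna, index=cols, columns=cols)
    return corr, n
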