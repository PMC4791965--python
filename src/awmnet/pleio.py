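"""Multi-trait pleiotropy statistic over studentized SNP effects.

Each SNP's effects across the trait panel are studentized (effect / SE),
V is the trait-by-trait correlation matrix of those studentized effects
across all SNPs, and the quadratic form t' V^-1 t is referred to a
chi-squared with df = number of traits — an approximate multi-trait test
of "this SNP affects none of the traits".  SNPs are ranked by the
statistic and mapped to genes for ranked-list enrichment tools.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, stats


def studentize_effects(assoc_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """SNP x trait matrix of t = effect / SE (NaN where monomorphic)."""
    cols = {}
    for trait, tab in assoc_tables.items():
        t = tab.set_index("snp")
        cols[trait] = t["effect"] / t["se"]
    return pd.DataFrame(cols)


def effect_correlation(
    tmatrix: pd.DataFrame, null_only: bool = False, null_cut: float = 2.0
) -> pd.DataFrame:
    """Trait x trait Pearson correlation of studentized effects across SNPs.

    ``null_only`` restricts to SNPs with |t| < null_cut in every trait
    (reduces contamination by true signal).  The result is projected to
    the nearest positive semi-definite correlation matrix when sampling
    noise pushes it outside the cone (logged via warning).
    """
    tm = tmatrix
    if null_only:
        tm = tm[(tm.abs() < null_cut).all(axis=1)]
    sds = tm.std()
    zero = sds[(sds == 0) | sds.isna()]
    if len(zero):
        raise ValueError(f"traits with zero effect variance: {list(zero.index)}")
    v = tm.corr(method="pearson", min_periods=3)
    vals = v.to_numpy()
    w = np.linalg.eigvalsh(vals)
    if w.min() < -1e-10:
        warnings.warn("projecting V to the nearest PSD correlation matrix")
        evals, evecs = np.linalg.eigh(vals)
        vals = (evecs * np.clip(evals, 0, None)) @ evecs.T
        d = np.sqrt(np.diag(vals))
        vals = vals / np.outer(d, d)
        v = pd.DataFrame(vals, index=v.index, columns=v.columns)
    return v


def multitrait_statistic(
    tmatrix: pd.DataFrame, v: pd.DataFrame
) -> pd.DataFrame:
    """Per-SNP quadratic form t' V^-1 t with chi-squared(df = #traits) p.

    Missing t-values (monomorphic SNPs) contribute zero to the quadratic
    form and such SNPs are flagged and ranked last among equals.  A
    singular V is ridge-regularized (lambda = 1e-8) with a warning.
    Returns columns snp, statistic, p, complete, rank (statistic
    descending, ties by snp id).
    """
    traits = list(v.columns)
    tm = tmatrix[traits]
    vv = v.to_numpy()
    try:
        cho = linalg.cho_factor(vv)
        solve = lambda b: linalg.cho_solve(cho, b)
    except linalg.LinAlgError:
        warnings.warn("singular V; applying ridge regularization 1e-8")
        cho = linalg.cho_factor(vv + 1e-8 * np.eye(len(traits)))
        solve = lambda b: linalg.cho_solve(cho, b)
    tvals = tm.to_numpy()
    complete = ~np.isnan(tvals).any(axis=1)
    filled = np.nan_to_num(tvals)
    stat = np.einsum("ij,ij->i", filled, solve(filled.T).T)
    stat = np.clip(stat, 0.0, None)
    p = stats.chi2.sf(stat, df=len(traits))
    out = pd.DataFrame(
        {"snp": tm.index, "statistic": stat, "p": p, "complete": complete}
    )
    out = out.sort_values(
        ["complete", "statistic", "snp"], ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def ranked_gene_list(
    results: pd.DataFrame, snp2gene: pd.DataFrame
) -> list[str]:
    """Genes ordered by their best SNP's pleiotropy rank, deduplicated."""
    merged = results.merge(snp2gene[["snp", "gene"]], on="snp", how="left")
    merged = merged.dropna(subset=["gene"]).sort_values("rank", kind="stable")
    seen: set[str] = set()
    out: list[str] = []
    for gene in merged["gene"]:
        if gene not in seen:
            seen.add(gene)
            out.append(gene)
    return out


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
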