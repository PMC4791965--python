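"""GRM-based population-structure profiling.

Covers the genomic relationship matrix (VanRaden method 1), genomic
inbreeding from its diagonal (F_GRM) and from runs of homozygosity
(F_ROH), PCA and hierarchical clustering of the GRM, Weir–Cockerham Fst,
inbreeding-depression regression, a windowed heterozygosity profile, and
per-lineage pedigree summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from awmnet.core import GenotypeMatrix, Pedigree


@dataclass
class GRM:
    """Genomic relationship matrix G = ZZ' / (2 sum p(1-p))."""

    matrix: np.ndarray
    samples: list[str]
    allele_freqs: np.ndarray = field(repr=False)
    n_snps: int = 0


@dataclass
class ROHSegment:
    animal: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int


@dataclass
class FstResult:
    per_snp: pd.DataFrame = field(repr=False)  # snp, a, b, c, fst
    genomewide: float = np.nan
    grouping: str = ""


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM with observed allele frequencies.

    Missing dosages are mean-imputed to 2p (zero contribution after
    centering).  Monomorphic SNPs make the scaling ill-defined and raise.
    """
    p = genotypes.allele_freq()
    if np.any((p <= 0) | (p >= 1) | np.isnan(p)):
        raise ValueError(
            "monomorphic or all-missing SNPs present; run qc.apply_qc first"
        )
    z = genotypes.dosages - 2.0 * p
    z[np.isnan(z)] = 0.0  # mean imputation after centering
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0
    return GRM(matrix=g, samples=list(genotypes.samples),
               allele_freqs=p, n_snps=genotypes.n_snps)


def fgrm(grm: GRM) -> pd.Series:
    """Genomic inbreeding: diagonal of the GRM minus one (may be negative)."""
    return pd.Series(np.diag(grm.matrix) - 1.0, index=grm.samples, name="fgrm")


def detect_roh(
    genotypes: GenotypeMatrix,
    min_snps: int = 30,
    max_gap_bp: int = 1_000_000,
    max_het: int = 0,
) -> list[ROHSegment]:
    """Maximal homozygous runs per animal.

    A run may contain up to ``max_het`` heterozygous calls and no
    inter-SNP gap above ``max_gap_bp``; runs shorter than ``min_snps``
    markers are dropped.  Missing calls do not break a run and count
    toward its marker total.  With ``max_het > 0`` maximal runs can
    overlap; overlaps are merged by :func:`froh`.
    """
    if not genotypes.map_is_sorted():
        raise ValueError("marker map must be sorted by chrom, bp")
    segments: list[ROHSegment] = []
    snp_map = genotypes.snp_map
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        gap_break = np.flatnonzero(np.diff(bp) > max_gap_bp)  # break after these
        for ai, animal in enumerate(genotypes.samples):
            d = genotypes.dosages[ai, idx]
            het = d == 1.0
            # chunks between large gaps
            bounds = np.concatenate(([0], gap_break + 1, [len(idx)]))
            for b0, b1 in zip(bounds[:-1], bounds[1:]):
                segments.extend(
                    _max_runs(animal, str(chrom), bp[b0:b1], het[b0:b1],
                              min_snps, max_het)
                )
    return segments


def _max_runs(
    animal: str, chrom: str, bp: np.ndarray, het: np.ndarray,
    min_snps: int, max_het: int,
) -> list[ROHSegment]:
    """Maximal windows with at most max_het heterozygous calls."""
    n = len(bp)
    if n == 0:
        return []
    out = []
    left = 0
    count = 0
    prev_left = -1
    for right in range(n):
        count += het[right]
        while count > max_het:
            count -= het[left]
            left += 1
        is_max = right == n - 1 or (count + het[right + 1] > max_het)
        if is_max and right - left + 1 >= min_snps and left > prev_left:
            out.append(
                ROHSegment(animal, chrom, int(bp[left]), int(bp[right]),
                           right - left + 1)
            )
            prev_left = left
    return out


def froh(
    segments: list[ROHSegment], genotypes: GenotypeMatrix
) -> pd.Series:
    """F_ROH per animal: merged segment span / autosomal map span.

    The denominator is the first-to-last bp per chromosome summed over
    chromosomes (the span the map can possibly cover).
    """
    span = 0.0
    for _, grp in genotypes.snp_map.groupby("chrom", sort=False):
        span += float(grp["bp"].max() - grp["bp"].min())
    per_animal = dict.fromkeys(genotypes.samples, 0.0)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        by_key.setdefault((s.animal, s.chrom), []).append((s.start_bp, s.end_bp))
    for (animal, _), ivals in by_key.items():
        ivals.sort()
        merged_len = 0
        cur_s, cur_e = ivals[0]
        for s0, e0 in ivals[1:]:
            if s0 <= cur_e:
                cur_e = max(cur_e, e0)
            else:
                merged_len += cur_e - cur_s
                cur_s, cur_e = s0, e0
        merged_len += cur_e - cur_s
        per_animal[animal] += merged_len
    return pd.Series(
        {a: v / span if span > 0 else 0.0 for a, v in per_animal.items()},
        name="froh",
    )


def pca_from_grm(grm: GRM, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the (double-centered) GRM.

    Returns ``(components, eigenvalues, variance_explained)`` with
    components as an ``n x k`` array.  Eigenvalues are non-increasing;
    variance explained is relative to the sum of positive eigenvalues.
    Component signs are fixed so the largest-|loading| entry is positive.
    """
    n = grm.matrix.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of animals")
    h = np.eye(n) - np.ones((n, n)) / n
    g = h @ grm.matrix @ h
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    var_exp = pos / pos.sum() if pos.sum() > 0 else np.zeros_like(pos)
    comps = vecs[:, :k] * np.sqrt(pos[:k])
    for j in range(k):
        i = int(np.argmax(np.abs(comps[:, j])))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    return comps, vals[:k], var_exp[:k]


def hierarchical_cluster(
    grm: GRM, linkage: str = "average"
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Average-linkage clustering of GRM dissimilarities.

    Distance transform: ``d = max(G) - G`` (darker heatmap cells = less
    related).  Returns ``(leaf_order, linkage_matrix, reordered_grm)``.
    """
    n = grm.matrix.shape[0]
    if n == 1:
        return [0], np.empty((0, 4)), grm.matrix.copy()
    d = grm.matrix.max() - grm.matrix
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = hierarchy.leaves_list(z).tolist()
    return order, z, grm.matrix[np.ix_(order, order)]


def compute_fst(
    genotypes: GenotypeMatrix, grouping: dict[str, str], label: str = ""
) -> FstResult:
    """Weir–Cockerham Fst across subpopulations.

    Per-SNP variance components a (among populations), b (among
    individuals within populations) and c (within individuals); the
    genome-wide estimate is the ratio of sums.  Subpopulations with fewer
    than two genotyped animals are excluded with a warning.
    """
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(genotypes.samples):
        g = grouping.get(a)
        if g is not None:
            groups.setdefault(g, []).append(i)
    small = [g for g, idx in groups.items() if len(idx) < 2]
    if small:
        warnings.warn(f"excluding subpopulations with <2 animals: {small}")
        for g in small:
            del groups[g]
    if len(groups) < 2:
        raise ValueError("need at least two subpopulations of size >= 2")

    pops = sorted(groups)
    r = len(pops)
    dos = genotypes.dosages
    rows = []
    for s in range(genotypes.n_snps):
        ni, pi, hi = [], [], []
        for gname in pops:
            d = dos[groups[gname], s]
            d = d[~np.isnan(d)]
            if len(d) < 2:
                continue
            ni.append(len(d))
            pi.append(d.mean() / 2.0)
            hi.append(np.mean(d == 1.0))
        if len(ni) < 2:
            continue
        ni = np.asarray(ni, float)
        pi = np.asarray(pi, float)
        hi = np.asarray(hi, float)
        rr = len(ni)
        nbar = ni.mean()
        nc = (rr * nbar - (ni**2).sum() / (rr * nbar)) / (rr - 1)
        pbar = (ni * pi).sum() / (rr * nbar)
        s2 = (ni * (pi - pbar) ** 2).sum() / ((rr - 1) * nbar)
        hbar = (ni * hi).sum() / (rr * nbar)
        if nbar <= 1 or nc <= 0:
            continue
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (rr - 1) / rr - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (rr - 1) / rr
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
        tot = a + b + c
        rows.append(
            dict(
                snp=genotypes.snp_ids[s], a=a, b=b, c=c,
                fst=a / tot if tot != 0 else np.nan,
            )
        )
    per_snp = pd.DataFrame(rows)
    denom = (per_snp["a"] + per_snp["b"] + per_snp["c"]).sum()
    gw = float(per_snp["a"].sum() / denom) if denom != 0 else np.nan
    return FstResult(per_snp=per_snp, genomewide=gw, grouping=label)


def inbreeding_depression(
    phenotypes: pd.Series, f: pd.Series
) -> tuple[float, float, float]:
    """Regression of adjusted phenotype on inbreeding, per 1 % increase in F.

    Returns ``(estimate_per_pct, se_per_pct, p_value)`` from ordinary
    least squares of phenotype on F, rescaled to 0.01-F units.
    """
    joined = pd.concat([phenotypes, f], axis=1, join="inner").dropna()
    y = joined.iloc[:, 0].to_numpy(float)
    x = joined.iloc[:, 1].to_numpy(float)
    if np.var(x) == 0:
        raise ValueError("inbreeding coefficient has zero variance")
    res = stats.linregress(x, y)
    return res.slope * 0.01, res.stderr * 0.01, res.pvalue


def heterozygosity_profile(
    genotypes: GenotypeMatrix,
    snps_per_point: int = 100,
    smooth_points: int = 5,
) -> pd.DataFrame:
    """Observed heterozygosity along the map, one point per SNP window.

    Window means are smoothed with a centered moving average of
    ``smooth_points`` windows (a simple boxcar kernel).
    """
    het = genotypes.dosages == 1.0
    with np.errstate(invalid="ignore"):
        obs = np.where(
            np.isnan(genotypes.dosages).all(axis=0),
            np.nan,
            np.nanmean(np.where(np.isnan(genotypes.dosages), np.nan, het), axis=0),
        )
    rows = []
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for w0 in range(0, len(idx), snps_per_point):
            sl = idx[w0 : w0 + snps_per_point]
            rows.append(
                dict(
                    chrom=chrom,
                    mid_bp=float(grp.loc[sl, "bp"].mean()),
                    het=float(np.nanmean(obs[sl])),
                )
            )
    prof = pd.DataFrame(rows)
    prof["het_smooth"] = (
        prof.groupby("chrom")["het"]
        .transform(lambda s: s.rolling(smooth_points, center=True, min_periods=1).mean())
    )
    return prof


def lineage_summary(pedigree: Pedigree) -> pd.DataFrame:
    """Per-lineage descendant counts (sires + their sibs) and sire mtDNA mix."""
    ped = pedigree.table
    rows = []
    for lineage, grp in ped.groupby("lineage", sort=True):
        sires = grp[grp["role"] == "sire"]
        sibs = grp[grp["role"] == "sib"]
        known = sires[sires["mtdna"].isin(("Taurus", "Indicus"))]
        rows.append(
            dict(
                lineage=lineage,
                n_sires=len(sires),
                n_sibs=len(sibs),
                descendants=len(sires) + len(sibs),
                pct_taurus_mtdna=(
                    100.0 * (known["mtdna"] == "Taurus").mean()
                    if len(known)
                    else np.nan
                ),
            )
        )
    return pd.DataFrame(rows)
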