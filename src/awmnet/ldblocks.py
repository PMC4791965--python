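"""Pairwise LD, haplotype-frequency EM, Gabriel blocks and LD-based Ne.

Phase is resolved pair-at-a-time with a two-locus EM over the
double-heterozygote ambiguity (both parental haplotypes of every animal
enter the counts).  D' confidence intervals come from a seeded multinomial
bootstrap of the 3x3 genotype table.  Effective population size follows
Sved's relation r2 = 1 / (4 c Ne + 1) with physical distance converted at
1 cM per Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from awmnet.core import GenotypeMatrix

MORGAN_PER_BP = 1e-8

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class HaplotypeBlock:
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e3

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class BlockSummary:
    n_blocks: int
    mean_length_kb: float
    pct_snps_in_blocks3: float  # % of SNPs inside blocks of >= 3 SNPs
    genome_fraction_covered: float


@dataclass
class NeEstimate:
    chrom: str
    bin_lo_bp: float
    bin_hi_bp: float
    bin_c_morgan: float
    bin_mean_r2: float
    ne: float
    generations_ago: float


# --------------------------------------------------------------------------
# Two-locus EM (numba kernels)
# --------------------------------------------------------------------------

@njit(cache=True)
def _em_kernel(n9):
    """EM haplotype frequencies from a flattened 3x3 genotype count table.

    n9[3*g1 + g2] = count of animals with dosages (g1, g2).  Returns
    (pAB, pAb, paB, pab, converged) where A/B denote the alt alleles.
    """
    total = n9.sum()
    if total == 0:
        return 0.25, 0.25, 0.25, 0.25, 1.0
    # allele freqs for initialization
    pa = (2 * (n9[6] + n9[7] + n9[8]) + n9[3] + n9[4] + n9[5]) / (2 * total)
    pb = (2 * (n9[2] + n9[5] + n9[8]) + n9[1] + n9[4] + n9[7]) / (2 * total)
    p11, p10, p01, p00 = pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)
    ndh = n9[4]  # double heterozygotes
    converged = 0.0
    for _ in range(EM_MAX_ITER):
        denom = p11 * p00 + p10 * p01
        w = 0.5 if denom == 0.0 else p11 * p00 / denom
        c11 = 2 * n9[8] + n9[7] + n9[5] + ndh * w
        c00 = 2 * n9[0] + n9[1] + n9[3] + ndh * w
        c10 = 2 * n9[6] + n9[7] + n9[3] + ndh * (1 - w)
        c01 = 2 * n9[2] + n9[1] + n9[5] + ndh * (1 - w)
        q11, q10, q01, q00 = (
            c11 / (2 * total), c10 / (2 * total), c01 / (2 * total), c00 / (2 * total),
        )
        delta = max(
            abs(q11 - p11), abs(q10 - p10), abs(q01 - p01), abs(q00 - p00)
        )
        p11, p10, p01, p00 = q11, q10, q01, q00
        if delta < EM_TOL:
            converged = 1.0
            break
    return p11, p10, p01, p00, converged


@njit(cache=True)
def _dprime_r2(p11, p10, p01, p00):
    pa = p11 + p10
    pb = p11 + p01
    d = p11 - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom if denom > 0 else np.nan
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dp = d / dmax if dmax > 0 else np.nan
    return d, dp, r2


@njit(cache=True)
def _bootstrap_dprime(n9, n_boot, seed):
    """Bootstrap |D'| by multinomial resampling of the 3x3 table."""
    np.random.seed(seed)
    total = int(n9.sum())
    probs = n9 / n9.sum()
    out = np.empty(n_boot)
    sample = np.empty(9)
    for b in range(n_boot):
        remaining = total
        psum = 1.0
        for cell in range(9):
            if cell == 8:
                sample[cell] = remaining
            else:
                p = probs[cell] / psum if psum > 0 else 0.0
                if p >= 1.0:
                    k = remaining
                elif p <= 0.0:
                    k = 0
                else:
                    k = np.random.binomial(remaining, p)
                sample[cell] = k
                remaining -= k
                psum -= probs[cell]
        p11, p10, p01, p00, _ = _em_kernel(sample)
        _, dp, _ = _dprime_r2(p11, p10, p01, p00)
        out[b] = abs(dp) if not np.isnan(dp) else 0.0
    return out


def _count_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(x) & ~np.isnan(y)
    idx = (3 * x[ok] + y[ok]).astype(np.int64)
    return np.bincount(idx, minlength=9).astype(float)


def two_locus_em(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, bool]:
    """MLE haplotype frequencies (pAB, pAb, paB, pab) for two dosage vectors.

    Non-convergence after 1000 iterations is flagged (frequencies from the
    last iterate are still returned).
    """
    n9 = _count_table(np.asarray(x, float), np.asarray(y, float))
    p11, p10, p01, p00, conv = _em_kernel(n9)
    return np.array([p11, p10, p01, p00]), bool(conv)


def em_loglik(n9: np.ndarray, p: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 table under haplotype freqs."""
    p11, p10, p01, p00 = p
    # genotype-pair probabilities under HWE at the haplotype level
    probs = np.empty(9)
    probs[0] = p00**2
    probs[1] = 2 * p00 * p01
    probs[2] = p01**2
    probs[3] = 2 * p00 * p10
    probs[4] = 2 * (p11 * p00 + p10 * p01)
    probs[5] = 2 * p01 * p11
    probs[6] = p10**2
    probs[7] = 2 * p10 * p11
    probs[8] = p11**2
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    lp[probs == 0] = -np.inf
    ll = float((n9 * np.where(np.isfinite(lp), lp, -1e12))[n9 > 0].sum())
    return ll


# --------------------------------------------------------------------------
# Pairwise LD
# --------------------------------------------------------------------------

def pairwise_r2(
    genotypes: GenotypeMatrix,
    max_distance_bp: int,
    compute_ci: bool = False,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """r², D' (and optionally a bootstrap |D'| CI) for intra-chromosome pairs.

    Returns a DataFrame with columns snp_a, snp_b, chrom, distance_bp, r2,
    d_prime, and ci_low/ci_high when requested.
    """
    rows = []
    dos = genotypes.dosages
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = bp[b] - bp[a]
                if dist > max_distance_bp:
                    break
                n9 = _count_table(dos[:, idx[a]], dos[:, idx[b]])
                p11, p10, p01, p00, _ = _em_kernel(n9)
                _, dp, r2 = _dprime_r2(p11, p10, p01, p00)
                row = dict(
                    snp_a=genotypes.snp_ids[idx[a]],
                    snp_b=genotypes.snp_ids[idx[b]],
                    chrom=chrom,
                    distance_bp=int(dist),
                    r2=r2,
                    d_prime=dp,
                )
                if compute_ci:
                    bs = _bootstrap_dprime(
                        n9, n_boot, (seed + 1009 * a + b) % 2**31
                    )
                    row["ci_low"] = float(np.quantile(bs, 0.05))
                    row["ci_high"] = float(np.quantile(bs, 0.95))
                rows.append(row)
    return pd.DataFrame(rows)


def ld_decay(
    pairs: pd.DataFrame,
    bin_edges_bp: np.ndarray,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Arithmetic mean r² within distance bins, per chromosome.

    Bins with fewer than ``min_pairs`` pairs are flagged (column
    ``sparse``), not dropped.
    """
    edges = np.asarray(bin_edges_bp, float)
    out = []
    for chrom, grp in pairs.groupby("chrom", sort=False):
        which = np.digitize(grp["distance_bp"], edges) - 1
        for b in range(len(edges) - 1):
            sel = grp[which == b]
            if len(sel) == 0:
                continue
            out.append(
                dict(
                    chrom=chrom,
                    bin_lo_bp=edges[b],
                    bin_hi_bp=edges[b + 1],
                    mean_r2=float(sel["r2"].mean()),
                    n_pairs=len(sel),
                    sparse=len(sel) < min_pairs,
                )
            )
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# Gabriel-style haplotype blocks
# --------------------------------------------------------------------------

STRONG_LD = 1
STRONG_RECOMB = 2
UNINFORMATIVE = 0


def classify_pairs(
    pairs: pd.DataFrame,
    ci_strong: tuple[float, float] = (0.70, 0.98),
    ci_recomb_high: float = 0.90,
) -> pd.Series:
    """Strong-LD / strong-recombination classes from |D'| CIs."""
    lo, hi = pairs["ci_low"], pairs["ci_high"]
    cls = np.full(len(pairs), UNINFORMATIVE)
    cls[(lo >= ci_strong[0]) & (hi >= ci_strong[1])] = STRONG_LD
    cls[hi < ci_recomb_high] = STRONG_RECOMB
    return pd.Series(cls, index=pairs.index, name="class")


def gabriel_blocks(
    genotypes: GenotypeMatrix,
    ci_strong: tuple[float, float] = (0.70, 0.98),
    ci_recomb_high: float = 0.90,
    strong_fraction: float = 0.95,
    max_span_snps: int = 50,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[list[HaplotypeBlock], BlockSummary]:
    """Haplotype blocks from D' confidence intervals.

    A candidate interval's outermost pair must be strong LD and at least
    ``strong_fraction`` of its informative pairs must be strong LD;
    accepted blocks are non-overlapping, longest (in bp) first.
    """
    if not genotypes.map_is_sorted():
        raise ValueError("marker map must be sorted by chrom, bp")
    blocks: list[HaplotypeBlock] = []
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        m = len(idx)
        span = min(max_span_snps, m)
        # banded pair classification
        cls = np.zeros((m, span), dtype=np.int8)  # cls[i, j-i-1]
        for i in range(m):
            for j in range(i + 1, min(i + span, m)):
                n9 = _count_table(
                    genotypes.dosages[:, idx[i]], genotypes.dosages[:, idx[j]]
                )
                p11, p10, p01, p00, _ = _em_kernel(n9)
                bs = _bootstrap_dprime(n9, n_boot, (seed + 7919 * i + j) % 2**31)
                lo_q = float(np.quantile(bs, 0.05))
                hi_q = float(np.quantile(bs, 0.95))
                if hi_q < ci_recomb_high:
                    cls[i, j - i - 1] = STRONG_RECOMB
                elif lo_q >= ci_strong[0] and hi_q >= ci_strong[1]:
                    cls[i, j - i - 1] = STRONG_LD
        for i, j in blocks_from_classes(cls, bp, strong_fraction):
            blocks.append(
                HaplotypeBlock(
                    chrom=str(chrom),
                    start_bp=int(bp[i]),
                    end_bp=int(bp[j]),
                    snp_ids=[genotypes.snp_ids[k] for k in idx[i : j + 1]],
                )
            )
    summary = summarize_blocks(blocks, genotypes)
    return blocks, summary


def blocks_from_classes(
    cls: np.ndarray, bp: np.ndarray, strong_fraction: float = 0.95
) -> list[tuple[int, int]]:
    """Block index intervals from a banded pair-class matrix.

    ``cls[i, j-i-1]`` holds the class of pair (i, j).  Candidate intervals
    (endpoints strong LD, >= strong_fraction of informative pairs strong)
    are accepted greedily, longest span in bp first, non-overlapping.
    """
    cands = _candidate_intervals(cls, strong_fraction)
    cands.sort(key=lambda ij: (-(bp[ij[1]] - bp[ij[0]]), ij[0]))
    m = cls.shape[0]
    taken = np.zeros(m, dtype=bool)
    out: list[tuple[int, int]] = []
    for i, j in cands:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        out.append((i, j))
    out.sort()
    return out


def _candidate_intervals(
    cls: np.ndarray, strong_fraction: float
) -> list[tuple[int, int]]:
    m, band = cls.shape
    out = []
    for i in range(m):
        n_strong = 0
        n_inf = 0
        for j in range(i + 1, min(i + band + 1, m)):
            # add pairs (k, j) for k in [i, j-1]
            for k in range(i, j):
                c = cls[k, j - k - 1] if j - k - 1 < band else UNINFORMATIVE
                if c == STRONG_LD:
                    n_strong += 1
                    n_inf += 1
                elif c == STRONG_RECOMB:
                    n_inf += 1
            if (
                j - i - 1 < band
                and cls[i, j - i - 1] == STRONG_LD
                and n_inf > 0
                and n_strong / n_inf >= strong_fraction
            ):
                out.append((i, j))
    return out


def summarize_blocks(
    blocks: list[HaplotypeBlock], genotypes: GenotypeMatrix
) -> BlockSummary:
    n_snps_in3 = sum(b.n_snps for b in blocks if b.n_snps >= 3)
    total_bp = 0.0
    for _, grp in genotypes.snp_map.groupby("chrom", sort=False):
        total_bp += float(grp["bp"].max() - grp["bp"].min())
    covered = sum(b.end_bp - b.start_bp for b in blocks)
    return BlockSummary(
        n_blocks=len(blocks),
        mean_length_kb=(
            float(np.mean([b.length_kb for b in blocks])) if blocks else 0.0
        ),
        pct_snps_in_blocks3=100.0 * n_snps_in3 / genotypes.n_snps,
        genome_fraction_covered=covered / total_bp if total_bp > 0 else 0.0,
    )


# --------------------------------------------------------------------------
# Effective population size
# --------------------------------------------------------------------------

def estimate_ne(
    decay: pd.DataFrame,
    bp_to_morgan: float = MORGAN_PER_BP,
) -> tuple[list[NeEstimate], pd.DataFrame]:
    """Sved Ne per chromosome per distance bin, with a cross-chromosome CI.

    ``Ne = (1/r2 - 1) / (4 c)`` at the bin-midpoint genetic distance c;
    ``generations_ago = 1 / (2 c)``.  Bins with mean r² outside (0, 1) are
    skipped with a warning column in the aggregate.  Returns the per-bin
    estimates and an aggregate table (bin, mean Ne, 95 % t-interval
    half-width across chromosomes).
    """
    ests: list[NeEstimate] = []
    for _, row in decay.iterrows():
        r2 = row["mean_r2"]
        if not (0.0 < r2 < 1.0):
            continue
        c = 0.5 * (row["bin_lo_bp"] + row["bin_hi_bp"]) * bp_to_morgan
        ests.append(
            NeEstimate(
                chrom=str(row["chrom"]),
                bin_lo_bp=row["bin_lo_bp"],
                bin_hi_bp=row["bin_hi_bp"],
                bin_c_morgan=c,
                bin_mean_r2=float(r2),
                ne=(1.0 / r2 - 1.0) / (4.0 * c),
                generations_ago=1.0 / (2.0 * c),
            )
        )
    rows = []
    df = pd.DataFrame([e.__dict__ for e in ests])
    if len(df):
        for (lo, hi), grp in df.groupby(["bin_lo_bp", "bin_hi_bp"]):
            ne = grp["ne"].to_numpy()
            half = np.nan
            if len(ne) > 1 and ne.std(ddof=1) > 0:
                half = float(
                    stats.t.ppf(0.975, len(ne) - 1) * ne.std(ddof=1) / np.sqrt(len(ne))
                )
            rows.append(
                dict(
                    bin_lo_bp=lo,
                    bin_hi_bp=hi,
                    mean_ne=float(ne.mean()),
                    ci_half_width=half,
                    n_chromosomes=len(ne),
                    generations_ago=float(grp["generations_ago"].iloc[0]),
                )
            )
    return ests, pd.DataFrame(rows)
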