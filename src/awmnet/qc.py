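"""Genotype quality control and TagSNP selection.

QC applies, in order: sample call rate, SNP call rate, then minor allele
frequency (monomorphic SNPs are a MAF-0 special case and reported with
their own reason).  TagSNP selection is a greedy sliding-window tagger:
within a window of neighboring SNPs, repeatedly promote the untagged SNP
that tags the most untagged neighbors at r² at or above the threshold,
with ties broken by genomic order — a deterministic stand-in for
LD-redundancy reduction taggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from awmnet.core import GenotypeMatrix


class EmptyPanelError(ValueError):
    """All SNPs (or samples) removed by QC."""


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_snps: pd.DataFrame = field(repr=False)  # columns: snp, reason
    removed_samples: pd.DataFrame = field(repr=False)  # columns: animal, reason
    order: tuple[str, ...] = ("sample_callrate", "snp_callrate", "maf")

    def __post_init__(self) -> None:
        assert self.n_snps_in - len(self.removed_snps) == self.n_snps_out
        assert self.n_samples_in - len(self.removed_samples) == self.n_samples_out


@dataclass
class TagSet:
    tag_snps: list[str]
    tagged_by: dict[str, str]
    r2_threshold: float

    def __post_init__(self) -> None:
        for t in self.tag_snps:
            if self.tagged_by.get(t) != t:
                raise ValueError("every tag must map to itself")


def apply_qc(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove low-call-rate samples/SNPs and low-MAF SNPs.

    Raises :class:`EmptyPanelError` if nothing survives on either axis.
    """
    if genotypes.n_snps == 0 or genotypes.n_animals == 0:
        raise EmptyPanelError("empty genotype matrix")
    n_snps_in, n_samples_in = genotypes.n_snps, genotypes.n_animals

    # the filter sequence is repeated to a fixed point: dropping SNPs can
    # push a sample's call rate below threshold on the reduced panel
    g = genotypes
    removed_samples_rows = []
    removed_snps_rows = []
    while True:
        bad_samples = g.sample_callrate() < callrate_min
        if bad_samples.any():
            removed_samples_rows.extend(
                dict(animal=g.samples[i], reason="callrate")
                for i in np.flatnonzero(bad_samples)
            )
            g = g.subset(samples=~bad_samples)
            if g.n_animals == 0:
                raise EmptyPanelError("all samples removed by call-rate filter")

        snp_cr = g.snp_callrate()
        maf = g.maf()
        mono = (maf == 0) | np.isnan(maf)
        bad_cr = snp_cr < callrate_min
        bad_maf = ~bad_cr & ~mono & (maf < maf_min)
        reasons = np.where(bad_cr, "callrate",
                           np.where(mono, "monomorphic", "maf"))
        bad = bad_cr | mono | bad_maf
        if not bad.any() and not bad_samples.any():
            break
        removed_snps_rows.extend(
            dict(snp=s, reason=r) for s, r in zip(g.snp_ids[bad], reasons[bad])
        )
        g = g.subset(snps=~bad)
        if g.n_snps == 0:
            raise EmptyPanelError("all SNPs removed by QC filters")
    removed_samples = pd.DataFrame(removed_samples_rows,
                                   columns=["animal", "reason"])
    removed_snps = pd.DataFrame(removed_snps_rows, columns=["snp", "reason"])

    report = QCReport(
        n_snps_in=n_snps_in,
        n_snps_out=g.n_snps,
        n_samples_in=n_samples_in,
        n_samples_out=g.n_animals,
        removed_snps=removed_snps,
        removed_samples=removed_samples,
    )
    return g, report


def _window_r2(dos: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    x, y = dos[:, i], dos[:, j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return r * r


def select_tagsnps(
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_snps: int = 50,
) -> TagSet:
    """Greedy windowed TagSNP selection (deterministic, genomic-order ties)."""
    if window_snps < 2:
        raise ValueError("window_snps must be at least 2")
    n = genotypes.n_snps
    ids = genotypes.snp_ids
    chroms = genotypes.snp_map["chrom"].to_numpy()
    dos = genotypes.dosages

    # neighbor lists at r2 >= threshold within the window, same chromosome
    neighbors: list[set[int]] = [set() for _ in range(n)]
    has_missing = np.isnan(dos).any()
    if not has_missing:
        mu = dos.mean(axis=0)
        sd = dos.std(axis=0)
        z = (dos - mu) / np.where(sd == 0, 1.0, sd)
        z[:, sd == 0] = 0.0
    for i in range(n):
        hi = min(i + window_snps, n)
        if not has_missing:
            r = (z[:, i] @ z[:, i + 1 : hi]) / dos.shape[0]
            for off, rv in enumerate(r, start=1):
                j = i + off
                if chroms[j] != chroms[i]:
                    break
                if rv * rv >= r2_threshold:
                    neighbors[i].add(j)
                    neighbors[j].add(i)
        else:
            for j in range(i + 1, hi):
                if chroms[j] != chroms[i]:
                    break
                if _window_r2(dos, i, j) >= r2_threshold:
                    neighbors[i].add(j)
                    neighbors[j].add(i)

    # greedy cover: promote the SNP covering the most untagged SNPs;
    # np.argmax takes the first maximum, i.e. ties break by genomic order
    score = np.array([1 + len(nb) for nb in neighbors], dtype=float)
    covered = np.zeros(n, dtype=bool)
    tagged_by: dict[str, str] = {}
    tags: list[int] = []
    while not covered.all():
        best = int(np.argmax(score))
        tags.append(best)
        cover = [j for j in {best} | neighbors[best] if not covered[j]]
        for j in cover:
            tagged_by[ids[j]] = ids[best]
            covered[j] = True
            score[j] = -np.inf
            for k in neighbors[j]:
                if not covered[k]:
                    score[k] -= 1.0

    tags.sort()
    return TagSet(
        tag_snps=[ids[i] for i in tags],
        tagged_by=tagged_by,
        r2_threshold=r2_threshold,
    )
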