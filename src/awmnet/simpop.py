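"""Synthetic half-sib population generator with known ground truth.

Emulates a commercial beef-cattle half-sib design: a few dozen widely used
sires, each with a family of half-sibs out of ungenotyped commercial dams.
Founder haplotypes are drawn from a finite pool generated by a first-order
Markov chain along each chromosome, giving linkage disequilibrium with a
tunable per-bp decay hazard; the implied two-locus r² curve (and hence the
pool's Sved Ne-equivalent at any distance) is available in closed numeric
form so downstream LD/Ne estimators can be checked against ground truth.

Phenotypes follow the standard animal-model generative form
``y = mean + CG + sum(QTL dosage x effect) + polygenic + residual`` with
component variances solved so realized narrow-sense heritabilities hit
their targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from awmnet.core import UNKNOWN, GenotypeMatrix, Pedigree

# --------------------------------------------------------------------------
# Reference design: 34 widely disseminated Nelore sires and their half-sib
# family sizes, paternal-line lineage, and mtDNA origin (None = untyped).
# Used as the default template for desk-scale emulation of the breed's
# commercial family structure (780 animals: 34 sires + 746 sibs).
# --------------------------------------------------------------------------
REFERENCE_SIRE_PANEL: tuple[tuple[str, int, str | None, str], ...] = (
    ("NE001388", 36, "Taurus", "Akasamu"),
    ("NE001398", 43, "Indicus", "Godar Imp."),
    ("NE001390", 20, "Taurus", "Godhavari"),
    ("NE001358", 31, "Taurus", "Golias"),
    ("NE001389", 36, "Taurus", "IRCA"),
    ("NE001361", 35, "Indicus", "IZ"),
    ("NE001386", 14, "Taurus", "IZ"),
    ("NE001392", 13, "Taurus", "IZ"),
    ("NE001395", 25, "Indicus", "IZ"),
    ("NE004368", 4, None, "IZ"),
    ("NE001357", 17, "Taurus", "Karvadi"),
    ("NE001360", 19, "Taurus", "Karvadi"),
    ("NE001383", 40, "Taurus", "Karvadi"),
    ("NE001385", 5, "Taurus", "Karvadi"),
    ("NE001393", 19, "Taurus", "Karvadi"),
    ("NE001394", 23, "Taurus", "Karvadi"),
    ("NE001397", 14, "Indicus", "Kurupathy"),
    ("NE001381", 36, "Taurus", "Lengruber"),
    ("NE001384", 12, "Taurus", "Lengruber"),
    ("NE001710", 14, "Taurus", "Lengruber"),
    ("NE003322", 10, None, "Lengruber"),
    ("NE001391", 34, "Taurus", "Mocho GR"),
    ("NE001380", 37, "Taurus", "Nagpur Imp"),
    ("NE001707", 18, "Indicus", "NO"),
    ("NE003323", 22, None, "OB"),
    ("NE001359", 26, "Taurus", "Padhu"),
    ("NE001379", 19, "Taurus", "Padhu-Akasamu"),
    ("NE001362", 36, "Indicus", "Taj Mahal"),
    ("NE001378", 10, "Taurus", "Taj Mahal"),
    ("NE001382", 24, "Taurus", "Taj Mahal"),
    ("NE001387", 13, "Taurus", "Taj Mahal"),
    ("NE001712", 16, "Indicus", "Taj Mahal"),
    ("NE004369", 2, None, "Taj Mahal"),
    ("NE001711", 23, "Taurus", "Visual"),
)

DEFAULT_LINEAGES = tuple(dict.fromkeys(row[3] for row in REFERENCE_SIRE_PANEL))

#: growth / meat-quality trait panel: (name, target h2, mean, SD, unit)
REFERENCE_TRAITS: tuple[tuple[str, float, float, float, str], ...] = (
    ("TCW", 0.26, 250.26, 27.88, "kg"),
    ("DRE", 0.09, 56.22, 3.63, "%"),
    ("REA", 0.55, 60.45, 7.26, "cm2"),
    ("BFT", 0.15, 6.16, 2.25, "mm"),
    ("LM", 0.03, 40.09, 3.18, "L*"),
    ("LF", 0.09, 19.94, 5.41, "L*"),
    ("PH", 0.04, 15.31, 3.15, "pH"),
    ("CLO", 0.04, 75.65, 4.45, "%"),
)

MORGAN_PER_BP = 1e-8  # 1 cM ~ 1 Mb


class SpecError(ValueError):
    """Invalid population or trait specification (names the field)."""


@dataclass
class PopulationSpec:
    """Parameters of a synthetic half-sib population.

    ``ld_decay_rate`` is the per-bp hazard of the founder Markov chain
    losing haplotype identity; ``founder_pool_size`` is the number of
    founder chromosomes in the pool (the drift Ne proxy);
    ``sire_autozygosity`` is the per-chromosome probability that a sire
    carries two copies of one founder haplotype (plants sire inbreeding).
    """

    n_sires: int = 34
    sibs_per_sire: list[int] = field(default_factory=lambda: [22] * 34)
    n_snps: int = 2000
    n_chromosomes: int = 2
    chrom_length_bp: int = 10_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay_rate: float = 5e-6
    founder_pool_size: int = 400
    shared_dam_prob: float = 0.05
    sire_autozygosity: float = 0.0
    missing_rate: float = 0.0
    sire_ids: list[str] | None = None
    sire_lineages: list[str] | None = None
    sire_mtdna: list[str | None] | None = None
    origins: tuple[str, ...] = ("O1", "O2", "O3", "O4", "O5")
    birth_years: tuple[str, ...] = ("Y1", "Y2", "Y3")
    seed: int = 0

    def validate(self) -> None:
        if self.n_sires < 1:
            raise SpecError("n_sires must be positive")
        if len(self.sibs_per_sire) != self.n_sires:
            raise SpecError("sibs_per_sire must have one entry per sire")
        if any(s < 1 for s in self.sibs_per_sire):
            raise SpecError("sibs_per_sire entries must be positive")
        for name in ("n_snps", "n_chromosomes", "chrom_length_bp", "founder_pool_size"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecError("maf_range must lie within (0, 0.5]")
        if self.ld_decay_rate < 0:
            raise SpecError("ld_decay_rate must be non-negative")
        if not 0.0 <= self.shared_dam_prob <= 1.0:
            raise SpecError("shared_dam_prob must be a probability")
        if not 0.0 <= self.sire_autozygosity <= 1.0:
            raise SpecError("sire_autozygosity must be a probability")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecError("missing_rate must be in [0, 1)")
        for name in ("sire_ids", "sire_lineages", "sire_mtdna"):
            val = getattr(self, name)
            if val is not None and len(val) != self.n_sires:
                raise SpecError(f"{name} must have one entry per sire")


@dataclass
class TraitSpec:
    """One simulated trait: target heritability, scale and QTL architecture."""

    name: str
    target_h2: float
    mean: float
    sd: float
    n_qtl: int = 50
    polygenic_fraction: float = 0.5
    cg_effect_sd: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.target_h2 <= 1.0:
            raise SpecError(f"{self.name}: target_h2 must be in [0, 1]")
        if self.sd <= 0:
            raise SpecError(f"{self.name}: sd must be positive")
        if self.n_qtl < 0:
            raise SpecError(f"{self.name}: n_qtl must be non-negative")
        if not 0.0 <= self.polygenic_fraction <= 1.0:
            raise SpecError(f"{self.name}: polygenic_fraction must be in [0, 1]")
        if self.target_h2 > 0 and self.n_qtl == 0 and self.polygenic_fraction == 0:
            raise SpecError(
                f"{self.name}: target_h2 > 0 is infeasible with zero QTL "
                "and zero polygenic variance"
            )


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated phenotypes."""

    qtl_ids: dict[str, np.ndarray]
    qtl_effects: dict[str, np.ndarray]
    true_h2: dict[str, float]
    true_genetic_values: pd.DataFrame  # animals x traits, total additive value
    true_polygenic_values: pd.DataFrame  # animals x traits, polygenic part


def reference_population_spec(**overrides) -> PopulationSpec:
    """Spec templated on the 34-sire commercial Nelore half-sib design."""
    ids = [r[0] for r in REFERENCE_SIRE_PANEL]
    sibs = [r[1] for r in REFERENCE_SIRE_PANEL]
    mtdna = [r[2] for r in REFERENCE_SIRE_PANEL]
    lineages = [r[3] for r in REFERENCE_SIRE_PANEL]
    base = dict(
        n_sires=len(ids),
        sibs_per_sire=sibs,
        sire_ids=ids,
        sire_lineages=lineages,
        sire_mtdna=mtdna,
    )
    base.update(overrides)
    return PopulationSpec(**base)


def reference_trait_specs(
    n_qtl: int = 50, cg_effect_sd_frac: float = 0.25
) -> list[TraitSpec]:
    """The eight growth/meat-quality traits at their reference h2/mean/SD."""
    return [
        TraitSpec(
            name=name,
            target_h2=h2,
            mean=mean,
            sd=sd,
            n_qtl=n_qtl,
            cg_effect_sd=cg_effect_sd_frac * sd,
        )
        for name, h2, mean, sd, _unit in REFERENCE_TRAITS
    ]


# --------------------------------------------------------------------------
# Pedigree
# --------------------------------------------------------------------------

def simulate_pedigree(spec: PopulationSpec) -> Pedigree:
    """Draw the half-sib pedigree: sires, dams-with-reuse, CG labels."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sire_ids = spec.sire_ids or [f"S{i + 1:03d}" for i in range(spec.n_sires)]
    lineages = spec.sire_lineages or [
        DEFAULT_LINEAGES[i % len(DEFAULT_LINEAGES)] for i in range(spec.n_sires)
    ]
    mtdna = spec.sire_mtdna or [None] * spec.n_sires

    rows: list[dict] = []
    for sid, lin, mt in zip(sire_ids, lineages, mtdna):
        rows.append(
            dict(
                animal=sid, sire=UNKNOWN, dam=UNKNOWN, role="sire",
                lineage=lin, mtdna=mt if mt is not None else "", cg="",
                origin="", birth_year="",
            )
        )

    dams: list[str] = []
    k = 0
    for sid, lin, nsib in zip(sire_ids, lineages, spec.sibs_per_sire):
        for _ in range(nsib):
            k += 1
            if dams and rng.random() < spec.shared_dam_prob:
                dam = dams[int(rng.integers(len(dams)))]
            else:
                dam = f"D{len(dams) + 1:04d}"
                dams.append(dam)
            origin = spec.origins[int(rng.integers(len(spec.origins)))]
            year = spec.birth_years[int(rng.integers(len(spec.birth_years)))]
            rows.append(
                dict(
                    animal=f"{sid}.{k:04d}", sire=sid, dam=dam, role="sib",
                    lineage=lin, mtdna="", cg=f"{origin}x{year}",
                    origin=origin, birth_year=year,
                )
            )
    return Pedigree(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# Founder pool and gene drop
# --------------------------------------------------------------------------

def _chrom_layout(spec: PopulationSpec) -> list[tuple[str, np.ndarray]]:
    """Evenly spread SNP positions over chromosomes; returns (label, bp)."""
    per = np.full(spec.n_chromosomes, spec.n_snps // spec.n_chromosomes)
    per[: spec.n_snps % spec.n_chromosomes] += 1
    out = []
    for c, m in enumerate(per, start=1):
        if m == 0:
            continue
        bp = np.linspace(1, spec.chrom_length_bp, int(m)).round().astype(np.int64)
        bp = np.maximum.accumulate(bp + np.arange(m))  # strictly increasing
        out.append((str(c), bp))
    return out


def _founder_pool(
    rng: np.random.Generator, n_hap: int, bp: np.ndarray, p: np.ndarray, lam: float
) -> np.ndarray:
    """Markov-chain haplotype pool on one chromosome.

    A latent Gaussian AR(1) process with per-gap autocorrelation
    ``exp(-lam * gap)`` is thresholded at ``Phi^-1(p_j)``, so every SNP has
    exactly its drawn allele frequency while adjacent SNPs stay correlated
    with a per-bp decay hazard ``lam``.
    """
    m = len(bp)
    w = np.empty((n_hap, m))
    w[:, 0] = rng.standard_normal(n_hap)
    gaps = np.diff(bp).astype(float)
    a = np.exp(-lam * gaps)
    innov = rng.standard_normal((n_hap, m - 1)) if m > 1 else None
    for j in range(1, m):
        w[:, j] = a[j - 1] * w[:, j - 1] + math.sqrt(1.0 - a[j - 1] ** 2) * innov[:, j - 1]
    thresh = stats.norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))
    return (w < thresh[None, :]).astype(np.int8)


def _meiosis(
    rng: np.random.Generator, h1: np.ndarray, h2: np.ndarray, bp: np.ndarray
) -> np.ndarray:
    """One gamete from a haplotype pair; Haldane crossovers at 1 cM/Mb."""
    m = len(bp)
    if m == 1:
        return (h1 if rng.random() < 0.5 else h2).copy()
    c = np.diff(bp) * MORGAN_PER_BP
    rec = 0.5 * (1.0 - np.exp(-2.0 * c))
    switch = rng.random(m - 1) < rec
    source = (int(rng.integers(2)) + np.concatenate(([0], np.cumsum(switch)))) % 2
    return np.where(source == 0, h1, h2)


def simulate_genotypes(pedigree: Pedigree, spec: PopulationSpec) -> GenotypeMatrix:
    """Gene-drop genotypes: pool founders -> sires/dams -> half-sibs.

    Sires carry two pool haplotypes per chromosome (or one duplicated
    haplotype with probability ``sire_autozygosity``); dams are ungenotyped
    founders whose haplotypes are fresh pool draws; each sib receives one
    recombined sire gamete and one recombined dam gamete, so Mendelian
    consistency with the sire holds at every SNP.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    layout = _chrom_layout(spec)
    maf_lo, maf_hi = spec.maf_range

    ped = pedigree.table
    sire_ids = ped.loc[ped["role"] == "sire", "animal"].tolist()
    sib_rows = ped[ped["role"] == "sib"]
    dam_ids = sorted(set(sib_rows["dam"]))
    samples = sire_ids + sib_rows["animal"].tolist()

    chrom_blocks: list[np.ndarray] = []
    map_rows: list[pd.DataFrame] = []
    for chrom, bp in layout:
        m = len(bp)
        p = rng.uniform(maf_lo, maf_hi, size=m)
        flip = rng.random(m) < 0.5  # which allele is minor
        p = np.where(flip, p, 1.0 - p)
        pool = _founder_pool(rng, spec.founder_pool_size, bp, p, spec.ld_decay_rate)

        def draw_pair(autozygosity: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
            i = int(rng.integers(spec.founder_pool_size))
            if autozygosity > 0 and rng.random() < autozygosity:
                return pool[i], pool[i]
            j = int(rng.integers(spec.founder_pool_size))
            return pool[i], pool[j]

        sire_hap = {s: draw_pair(spec.sire_autozygosity) for s in sire_ids}
        dam_hap = {d: draw_pair() for d in dam_ids}

        geno = np.empty((len(samples), m), dtype=np.int8)
        for i, s in enumerate(sire_ids):
            geno[i] = sire_hap[s][0] + sire_hap[s][1]
        for i, (_, row) in enumerate(sib_rows.iterrows(), start=len(sire_ids)):
            pat = _meiosis(rng, *sire_hap[row["sire"]], bp)
            mat = _meiosis(rng, *dam_hap[row["dam"]], bp)
            geno[i] = pat + mat
        chrom_blocks.append(geno)
        map_rows.append(
            pd.DataFrame(
                {"snp": [f"snp{chrom}_{j + 1}" for j in range(m)],
                 "chrom": chrom, "bp": bp,
                 # realized founder-pool frequency: ground truth for drift checks
                 "founder_freq": pool.mean(axis=0)}
            )
        )

    dosages = np.concatenate(chrom_blocks, axis=1).astype(float)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages, samples, pd.concat(map_rows, ignore_index=True))


# --------------------------------------------------------------------------
# Phenotypes
# --------------------------------------------------------------------------

def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    v = float(np.var(x))
    if target_var <= 0 or v <= 0:
        return np.zeros_like(x)
    return x * math.sqrt(target_var / v)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    traits: list[TraitSpec],
    seed: int,
    qtl_sharing: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate sib phenotypes under the animal-model generative form.

    ``qtl_sharing[i, 0]`` is the fraction of trait *i*'s QTL drawn from the
    first (key) trait's QTL set; effects at shared QTL are reused so that
    sharing induces genetic correlation.  Component variances are solved
    empirically so the realized narrow-sense h2 (var(genetic) / var(genetic
    + residual)) matches ``target_h2``; contemporary-group shifts are drawn
    once per group and sit on top of that variance (they are removed by
    pre-adjustment downstream).

    Returns a phenotype table (one row per sib: trait columns, ``cg`` label
    and ``slaughter_age``) and a :class:`TruthRecord`.
    """
    if not traits:
        raise SpecError("traits must be non-empty")
    for t in traits:
        t.validate()
    n_traits = len(traits)
    if qtl_sharing is None:
        qtl_sharing = np.eye(n_traits)
    qtl_sharing = np.asarray(qtl_sharing, dtype=float)
    if qtl_sharing.shape != (n_traits, n_traits):
        raise SpecError("qtl_sharing must be n_traits x n_traits")
    if not np.allclose(qtl_sharing, qtl_sharing.T) or not np.allclose(
        np.diag(qtl_sharing), 1.0
    ):
        raise SpecError("qtl_sharing must be symmetric with unit diagonal")

    rng = np.random.default_rng(seed)
    ped = pedigree.table
    sibs = ped[ped["role"] == "sib"].reset_index(drop=True)
    samples = genotypes.samples
    sample_idx = {a: i for i, a in enumerate(samples)}
    snp_ids = genotypes.snp_ids

    # mean-imputed dosage matrix for QTL lookups
    dos = genotypes.dosages.copy()
    p2 = 2.0 * genotypes.allele_freq()
    nan = np.isnan(dos)
    if nan.any():
        dos[nan] = np.broadcast_to(p2, dos.shape)[nan]

    # polygenic gene-drop on the pedigree, one independent series per trait
    founders = ped.loc[ped["role"] == "sire", "animal"].tolist() + sorted(
        set(sibs["dam"])
    )
    poly: dict[str, dict[str, float]] = {}
    for t in traits:
        g = {f: rng.standard_normal() for f in founders}
        for _, row in sibs.iterrows():
            ms = rng.standard_normal() * math.sqrt(0.5)
            g[row["animal"]] = 0.5 * (g[row["sire"]] + g[row["dam"]]) + ms
        poly[t.name] = g

    sib_rows = np.array([sample_idx[a] for a in sibs["animal"]])
    qtl_ids: dict[str, np.ndarray] = {}
    qtl_eff: dict[str, np.ndarray] = {}
    gv_all: dict[str, np.ndarray] = {}
    pv_all: dict[str, np.ndarray] = {}
    true_h2: dict[str, float] = {}
    pheno = pd.DataFrame({"animal": sibs["animal"], "cg": sibs["cg"]})

    cg_labels = sorted(set(sibs["cg"]))
    key_qtl: np.ndarray | None = None
    key_effects: np.ndarray | None = None
    for ti, t in enumerate(traits):
        # QTL set: share a fraction with the key (first) trait
        if t.n_qtl > 0:
            n_shared = int(round(qtl_sharing[ti, 0] * t.n_qtl)) if ti > 0 else 0
            n_shared = min(n_shared, 0 if key_qtl is None else len(key_qtl), t.n_qtl)
            if ti == 0 or key_qtl is None:
                idx = rng.choice(genotypes.n_snps, size=min(t.n_qtl, genotypes.n_snps),
                                 replace=False)
                eff = rng.standard_normal(len(idx))
                key_qtl, key_effects = idx, eff
            else:
                shared = rng.choice(len(key_qtl), size=n_shared, replace=False)
                rest_pool = np.setdiff1d(np.arange(genotypes.n_snps), key_qtl[shared])
                fresh = rng.choice(rest_pool, size=t.n_qtl - n_shared, replace=False)
                idx = np.concatenate([key_qtl[shared], fresh])
                eff = np.concatenate(
                    [key_effects[shared], rng.standard_normal(t.n_qtl - n_shared)]
                )
        else:
            idx = np.array([], dtype=int)
            eff = np.array([])

        qv = dos[:, idx] @ eff if len(idx) else np.zeros(len(samples))
        pv = np.array([poly[t.name][a] for a in samples])

        var_g = t.target_h2 * t.sd**2
        qv_sib = qv[sib_rows] - qv[sib_rows].mean()
        pv_sib = pv[sib_rows] - pv[sib_rows].mean()
        # empirical scales so realized sib genetic variance hits the target;
        # the polygenic split is dropped when a component is degenerate
        pi = t.polygenic_fraction if len(idx) else 1.0
        if np.var(pv_sib) == 0:
            pi = 0.0
        scale_q = (
            math.sqrt(var_g * (1.0 - pi) / np.var(qv_sib))
            if np.var(qv_sib) > 0 and var_g > 0
            else 0.0
        )
        scale_p = (
            math.sqrt(var_g * pi / np.var(pv_sib))
            if np.var(pv_sib) > 0 and var_g > 0
            else 0.0
        )
        genetic_sib = qv_sib * scale_q + pv_sib * scale_p
        resid = rng.standard_normal(len(sib_rows))
        resid = _scale_to_var(resid - resid.mean(), (1.0 - t.target_h2) * t.sd**2)
        cg_eff = {c: rng.standard_normal() * t.cg_effect_sd for c in cg_labels}
        y = (
            t.mean
            + genetic_sib
            + resid
            + np.array([cg_eff[c] for c in sibs["cg"]])
        )
        pheno[t.name] = y

        qtl_ids[t.name] = snp_ids[idx]
        qtl_eff[t.name] = eff * scale_q
        gv_full = (qv - qv[sib_rows].mean()) * scale_q + (
            pv - pv[sib_rows].mean()
        ) * scale_p
        gv_all[t.name] = gv_full
        pv_all[t.name] = (pv - pv[sib_rows].mean()) * scale_p
        denom_var = np.var(genetic_sib) + np.var(resid)
        true_h2[t.name] = float(np.var(genetic_sib) / denom_var) if denom_var else 0.0

    pheno["slaughter_age"] = rng.normal(640.0, 30.0, size=len(sibs)).round(1)
    truth = TruthRecord(
        qtl_ids=qtl_ids,
        qtl_effects=qtl_eff,
        true_h2=true_h2,
        true_genetic_values=pd.DataFrame(gv_all, index=samples),
        true_polygenic_values=pd.DataFrame(pv_all, index=samples),
    )
    return pheno, truth


def simulate_annotation(
    spec: PopulationSpec,
    gene_every_bp: int = 40_000,
    tf_fraction: float = 0.08,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic SNP-to-gene annotation scaffold.

    Genes are placed at regular intervals along each chromosome (roughly
    one per ``gene_every_bp``, emulating mammalian gene density at desk
    scale) and a fraction are flagged as transcription factors.  Returns
    a table with gene, chrom, position, tf_flag.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    rows = []
    k = 0
    for c in range(1, spec.n_chromosomes + 1):
        pos = np.arange(gene_every_bp // 2, spec.chrom_length_bp, gene_every_bp)
        for p in pos:
            k += 1
            rows.append(
                dict(
                    gene=f"GENE{k:05d}",
                    chrom=str(c),
                    position=int(p),
                    tf_flag=bool(rng.random() < tf_fraction),
                )
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Documented LD ground truth of the founder pool
# --------------------------------------------------------------------------

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal via Owen's T."""
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.clip(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0, None)
    h = np.where(np.abs(h) < 1e-10, 1e-10, h)
    k = np.where(np.abs(k) < 1e-10, 1e-10, k)
    s = math.sqrt(1.0 - rho * rho)
    a1 = (k - rho * h) / (h * s)
    a2 = (h - rho * k) / (k * s)
    beta = np.where(h * k < 0, 0.5, 0.0)
    return (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a1)
        - special.owens_t(k, a2)
        - beta
    )


def expected_r2(
    lam: float,
    distance_bp: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_grid: int = 10,
) -> float:
    """Expected two-locus r² of the founder pool at a given distance.

    Integrates the thresholded-Gaussian two-locus correlation over the MAF
    distribution by Gauss–Legendre quadrature; this is pure theory for the
    generator, independent of any sample estimator.
    """
    rho = math.exp(-lam * distance_bp)
    lo, hi = maf_range
    nodes, weights = np.polynomial.legendre.leggauss(n_grid)
    p_minor = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    w = weights / weights.sum()

    def mean_r2(p1: np.ndarray, p2: np.ndarray) -> float:
        t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
        P1, P2 = np.meshgrid(p1, p2, indexing="ij")
        T1, T2 = np.meshgrid(t1, t2, indexing="ij")
        p11 = _bvn_cdf(T1.ravel(), T2.ravel(), rho).reshape(T1.shape)
        denom = np.sqrt(P1 * (1 - P1) * P2 * (1 - P2))
        r = (p11 - P1 * P2) / denom
        return float((np.outer(w, w) * r**2).sum())

    # each SNP's threshold frequency is the minor value or its complement
    # with equal probability; flipping both margins is a symmetry, so two
    # configurations suffice
    return 0.5 * (mean_r2(p_minor, p_minor) + mean_r2(p_minor, 1.0 - p_minor))


def ne_equivalent(
    lam: float,
    bin_lo_bp: float,
    bin_hi_bp: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    bp_to_morgan: float = MORGAN_PER_BP,
) -> float:
    """Sved Ne-equivalent of the pool over a distance bin.

    Mean expected r² over distances uniform in the bin, then
    ``Ne = (1/r2 - 1) / (4 c)`` at the bin-midpoint genetic distance.
    """
    ds = np.linspace(bin_lo_bp, bin_hi_bp, 9)
    r2 = float(np.mean([expected_r2(lam, d, maf_range) for d in ds]))
    r2 = max(r2, 1e-12)  # rho -> 0 limit
    c = 0.5 * (bin_lo_bp + bin_hi_bp) * bp_to_morgan
    return (1.0 / r2 - 1.0) / (4.0 * c)


def decay_rate_for_ne(
    ne: float,
    bin_lo_bp: float,
    bin_hi_bp: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Solve for the decay hazard whose Ne-equivalent over a bin equals ne."""
    f = lambda lam: ne_equivalent(lam, bin_lo_bp, bin_hi_bp, maf_range) - ne
    return float(optimize.brentq(f, 1e-9, 1e-3, xtol=1e-12))


def decay_rate_for_target_r2(
    r2: float,
    bin_lo_bp: float,
    bin_hi_bp: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> float:
    """Solve for the decay hazard giving a target mean r² over a bin."""
    ds = np.linspace(bin_lo_bp, bin_hi_bp, 9)

    def f(lam: float) -> float:
        return float(np.mean([expected_r2(lam, d, maf_range) for d in ds])) - r2

    return float(optimize.brentq(f, 1e-9, 1e-3, xtol=1e-12))
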