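"""Association Weight Matrix construction.

The AWM is a genes x traits matrix of standardized SNP effects anchored
on a key trait: a SNP enters if it associates with the key trait at the
selection alpha, or with at least ``min_other_traits`` of the remaining
traits; SNPs are then reduced to one per gene (smallest key-trait p), and
the gene-by-gene Pearson correlation of AWM row vectors feeds the network
inference step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GeneAnnotation:
    """Gene id / chromosome / representative position / TF flag table."""

    table: pd.DataFrame = field(repr=False)  # gene, chrom, position, tf_flag

    def __post_init__(self) -> None:
        need = {"gene", "chrom", "position"}
        if need - set(self.table.columns):
            raise ValueError("annotation needs gene, chrom, position columns")
        if self.table["gene"].duplicated().any():
            raise ValueError("gene ids must be unique")
        if "tf_flag" not in self.table.columns:
            self.table = self.table.assign(tf_flag=False)
        self.table = self.table.reset_index(drop=True)


@dataclass
class AWM:
    """Genes x traits standardized-effect matrix with a designated key trait."""

    values: pd.DataFrame = field(repr=False)  # index: gene, columns: traits
    key_trait: str = ""
    snp_of_gene: pd.Series = field(default=None, repr=False)
    selection_log: pd.DataFrame = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.key_trait not in self.values.columns:
            raise ValueError("key trait column missing from AWM")


def assign_nearest_gene(
    snp_map: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Nearest gene (absolute bp distance, same chromosome) per SNP.

    Equidistant genes resolve to the lower-coordinate one; SNPs on
    chromosomes absent from the annotation come back unassigned (gene =
    NaN) and flagged.  Returns columns snp, gene, distance_bp.
    """
    out_rows = []
    ann = annotation.table
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        genes = ann[ann["chrom"].astype(str) == str(chrom)]
        if len(genes) == 0:
            for _, row in grp.iterrows():
                out_rows.append(dict(snp=row["snp"], gene=np.nan, distance_bp=np.nan))
            continue
        genes = genes.sort_values(["position", "gene"], kind="stable")
        gpos = genes["position"].to_numpy(float)
        gid = genes["gene"].to_numpy()
        for _, row in grp.iterrows():
            d = np.abs(gpos - row["bp"])
            best = np.min(d)
            cands = np.flatnonzero(d == best)
            pick = cands[0]  # sorted by position: lowest coordinate wins ties
            out_rows.append(
                dict(snp=row["snp"], gene=gid[pick], distance_bp=float(best))
            )
    return pd.DataFrame(out_rows)


def build_awm(
    assoc_tables: dict[str, pd.DataFrame],
    key_trait: str,
    snp2gene: pd.DataFrame,
    alpha: float = 0.05,
    min_other_traits: int = 3,
    standardize: str = "se",
    trait_sds: dict[str, float] | None = None,
) -> AWM:
    """Select SNPs, standardize effects and reduce to one SNP per gene.

    ``standardize='se'`` divides each effect by its standard error (the
    studentized form); ``'trait_sd'`` divides by the trait's phenotypic
    SD (requires ``trait_sds``).  Selection: p(key) <= alpha OR at least
    ``min_other_traits`` non-key traits with p <= alpha.
    """
    if key_trait not in assoc_tables:
        raise ValueError(f"key trait {key_trait!r} has no association table")
    traits = list(assoc_tables)
    key = assoc_tables[key_trait].set_index("snp")
    pmat = pd.DataFrame({t: assoc_tables[t].set_index("snp")["p"] for t in traits})
    emat = pd.DataFrame(
        {t: assoc_tables[t].set_index("snp")["effect"] for t in traits}
    )
    if standardize == "se":
        semat = pd.DataFrame(
            {t: assoc_tables[t].set_index("snp")["se"] for t in traits}
        )
        cells = emat / semat
    elif standardize == "trait_sd":
        if trait_sds is None:
            raise ValueError("trait_sds required for standardize='trait_sd'")
        cells = emat / pd.Series(trait_sds)
    else:
        raise ValueError("standardize must be 'se' or 'trait_sd'")

    key_hit = pmat[key_trait] <= alpha
    others = [t for t in traits if t != key_trait]
    n_other = (pmat[others] <= alpha).sum(axis=1)
    selected = key_hit | (n_other >= min_other_traits)
    reason = np.where(key_hit, "key-trait", "multi-trait")

    sel = pd.DataFrame(
        {
            "snp": pmat.index,
            "selected": selected.to_numpy(),
            "reason": np.where(selected, reason, ""),
            "p_key": pmat[key_trait].to_numpy(),
        }
    ).merge(snp2gene[["snp", "gene"]], on="snp", how="left")

    chosen = sel[sel["selected"] & sel["gene"].notna()]
    # one SNP per gene: the one with the smallest key-trait p (ties by snp id)
    chosen = chosen.sort_values(["gene", "p_key", "snp"], kind="stable")
    chosen = chosen.drop_duplicates("gene", keep="first")

    values = cells.loc[chosen["snp"]].copy()
    values.index = chosen["gene"].to_numpy()
    values.index.name = "gene"
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing gene rows")
        values = values[~all_missing]
        chosen = chosen[~all_missing.to_numpy()]
    return AWM(
        values=values,
        key_trait=key_trait,
        snp_of_gene=pd.Series(chosen["snp"].to_numpy(), index=values.index),
        selection_log=sel,
    )


def awm_correlation(awm: AWM) -> pd.DataFrame:
    """Gene x gene Pearson correlation of AWM row vectors.

    Rows with zero variance across traits have undefined correlations and
    are dropped with a warning.
    """
    vals = awm.values
    sd = vals.std(axis=1, ddof=0)
    bad = (sd == 0) | sd.isna()
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} zero-variance AWM rows: "
            f"{list(vals.index[bad][:5])}..."
        )
        vals = vals[~bad]
    corr = vals.T.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
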