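"""Partial Correlation and Information Theory (PCIT) network inference.

For every gene trio (x, y, z) the three first-order partial correlations
are computed; their mean ratio to the direct correlations gives a local
tolerance epsilon, and the edge (x, y) is discarded if its correlation is
within epsilon of both correlations through some third gene z.  Surviving
non-zero correlations are the significant edges.  The O(n^3) scan is a
compiled (numba) triple loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

_EPS_DIRECT = 1e-12


@dataclass
class PCITResult:
    significant: np.ndarray  # boolean gene x gene
    r: pd.DataFrame = field(repr=False)
    eps_min: np.ndarray = field(default=None, repr=False)

    @property
    def genes(self) -> list[str]:
        return list(self.r.index)

    def edge_list(self) -> pd.DataFrame:
        genes = self.genes
        ii, jj = np.where(np.triu(self.significant, k=1))
        return pd.DataFrame(
            {
                "gene_a": [genes[i] for i in ii],
                "gene_b": [genes[j] for j in jj],
                "r": self.r.values[ii, jj],
            }
        )


@njit(cache=True)
def _pcit_kernel(r, signed_ratios):
    """Returns (keep, eps_min): keep[x,y] False when some z explains (x,y)."""
    n = r.shape[0]
    keep = np.ones((n, n), dtype=np.bool_)
    eps_min = np.full((n, n), np.inf)
    for z in range(n):
        for x in range(n):
            if x == z:
                continue
            rxz = r[x, z]
            dxz = 1.0 - rxz * rxz
            for y in range(x + 1, n):
                if y == z:
                    continue
                rxy = r[x, y]
                ryz = r[y, z]
                dxy = 1.0 - rxy * rxy
                dyz = 1.0 - ryz * ryz
                # first-order partials for the trio
                den1 = dxz * dyz
                den2 = dxy * dyz
                den3 = dxy * dxz
                p_xy = (rxy - rxz * ryz) / np.sqrt(den1) if den1 > 0 else 0.0
                p_xz = (rxz - rxy * ryz) / np.sqrt(den2) if den2 > 0 else 0.0
                p_yz = (ryz - rxy * rxz) / np.sqrt(den3) if den3 > 0 else 0.0
                t1 = p_xy / rxy if abs(rxy) >= _EPS_DIRECT else 0.0
                t2 = p_xz / rxz if abs(rxz) >= _EPS_DIRECT else 0.0
                t3 = p_yz / ryz if abs(ryz) >= _EPS_DIRECT else 0.0
                if signed_ratios:
                    eps = (t1 + t2 + t3) / 3.0
                else:
                    eps = (abs(t1) + abs(t2) + abs(t3)) / 3.0
                if eps < eps_min[x, y]:
                    eps_min[x, y] = eps
                    eps_min[y, x] = eps
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    keep[x, y] = False
                    keep[y, x] = False
    return keep, eps_min


def pcit(
    r: pd.DataFrame | np.ndarray,
    signed_ratios: bool = False,
) -> PCITResult:
    """Run PCIT on a symmetric correlation matrix with unit diagonal.

    ``signed_ratios=False`` (default) takes the trio tolerance as the mean
    of absolute partial/direct ratios.  With fewer than three genes no
    trio exists and every non-zero off-diagonal correlation is
    significant.
    """
    if isinstance(r, pd.DataFrame):
        genes = list(r.index)
        mat = r.to_numpy(float)
    else:
        mat = np.asarray(r, float)
        genes = [f"g{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n) or not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.nanmax(np.abs(mat)) > 1.0 + 1e-8:
        raise ValueError("correlations must lie in [-1, 1]")

    rdf = pd.DataFrame(mat, index=genes, columns=genes)
    if n < 3:
        sig = (mat != 0) & ~np.eye(n, dtype=bool)
        return PCITResult(significant=sig, r=rdf)
    keep, eps_min = _pcit_kernel(np.ascontiguousarray(mat), signed_ratios)
    sig = keep & (mat != 0) & ~np.eye(n, dtype=bool)
    return PCITResult(significant=sig, r=rdf, eps_min=eps_min)


def magnitude_filter(result: PCITResult, min_abs_r: float = 0.95) -> pd.DataFrame:
    """Edges that are PCIT-significant AND |r| >= min_abs_r."""
    edges = result.edge_list()
    return edges[np.abs(edges["r"]) >= min_abs_r].reset_index(drop=True)


def mask_below(r: pd.DataFrame, min_abs_r: float = 0.95) -> pd.DataFrame:
    """Pre-filter mode: zero out correlations below the magnitude cutoff.

    The diagonal is kept at one; the result can be fed straight to
    :func:`pcit` (edge-eligibility mask applied before inference).
    """
    out = r.copy()
    vals = out.to_numpy()
    vals[np.abs(vals) < min_abs_r] = 0.0
    np.fill_diagonal(vals, 1.0)
    return out
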