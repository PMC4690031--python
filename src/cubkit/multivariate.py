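"""Neutrality-plot statistics, correspondence analysis of the
gene x codon RSCU matrix, and the Spearman correlation table of
per-gene indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import INFORMATIVE_CODONS

_NAN = float("nan")


@dataclass(frozen=True)
class NeutralityStats:
    """OLS fit of GC12 on GC3 plus Spearman rank correlation.

    A slope near 1 with a significant positive correlation is the
    classical signature of mutation-dominated codon evolution: the
    same compositional pressure drives all three codon positions.
    """

    slope: float
    intercept: float
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CoaResult:
    """Correspondence analysis of a genes x codons RSCU matrix.

    ``gene_coords`` / ``codon_coords`` hold principal coordinates on
    the retained axes; ``inertia_fraction`` covers *all* non-trivial
    axes and sums to 1. Axis signs are arbitrary in CA; axis 1 is
    oriented so its Spearman correlation with gene GC3 is non-negative
    (when GC3 is supplied), remaining axes so the largest-magnitude
    codon loading is positive.
    """

    gene_coords: pd.DataFrame
    codon_coords: pd.DataFrame
    inertia_fraction: np.ndarray
    axes_kept: int
    imputed_genes: tuple[str, ...] = field(default_factory=tuple)


def neutrality_stats(gc12, gc3) -> NeutralityStats:
    """Regress GC12 on GC3 (OLS) and rank-correlate them (Spearman).

    Pairs with a missing value are dropped; a constant GC3 leaves the
    slope undefined (NaN).
    """
    gc12 = np.asarray(gc12, dtype=float)
    gc3 = np.asarray(gc3, dtype=float)
    mask = ~(np.isnan(gc12) | np.isnan(gc3))
    x, y = gc3[mask], gc12[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 genes with defined GC12 and GC3, got {n}")
    if np.ptp(x) == 0:
        return NeutralityStats(_NAN, _NAN, _NAN, _NAN, n)
    fit = stats.linregress(x, y)
    if np.ptp(y) == 0:
        rho, p = 0.0, 1.0
    else:
        spear = stats.spearmanr(x, y)
        rho, p = float(spear.statistic), float(spear.pvalue)
    return NeutralityStats(float(fit.slope), float(fit.intercept), rho, p, n)


def coa_rscu(
    rscu_matrix: pd.DataFrame,
    gc3: pd.Series | None = None,
    axes_kept: int = 4,
) -> CoaResult:
    """Correspondence analysis of a non-negative genes x codons matrix.

    The input is typically per-gene RSCU over the 59 informative codons
    (following the CodonW convention of ordinating RSCU rather than raw
    counts); missing family values are imputed as 0 and the affected
    genes reported. Rows/columns with zero mass would make the row or
    column profile undefined and raise.

    The decomposition is the standard one: correspondence matrix
    P = X / total, residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},
    SVD of S, principal coordinates F = D_r^{-1/2} U S and
    G = D_c^{-1/2} V S, per-axis inertia sigma_i^2 / sum(sigma^2).
    """
    X = rscu_matrix.astype(float).copy()
    imputed = tuple(X.index[X.isna().any(axis=1)])
    X = X.fillna(0.0)
    if (X.values < 0).any():
        raise ValueError("RSCU matrix must be non-negative")
    if X.shape[0] < 5:
        raise ValueError("need >= 5 genes for correspondence analysis")
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("zero-mass row or column in the RSCU matrix")

    M = X.values
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    # drop numerically-zero axes (a one-distinct-row matrix has none left)
    keep = sv > max(sv[0], 1.0) * 1e-12 if sv.size else np.array([], bool)
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]
    n_axes = min(axes_kept, sv.size)

    inertia = sv**2
    inertia_fraction = (
        inertia / inertia.sum() if inertia.sum() > 0 else inertia
    )
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (Vt.T * sv) / np.sqrt(c)[:, None]

    for j in range(n_axes):
        flip = 1.0
        if j == 0 and gc3 is not None:
            rho = stats.spearmanr(F[:, 0], np.asarray(gc3, float)).statistic
            if not np.isnan(rho) and rho < 0:
                flip = -1.0
        elif G[np.argmax(np.abs(G[:, j])), j] < 0:
            flip = -1.0
        F[:, j] *= flip
        G[:, j] *= flip

    cols = [f"Axis{i + 1}" for i in range(n_axes)]
    return CoaResult(
        gene_coords=pd.DataFrame(F[:, :n_axes], index=X.index, columns=cols),
        codon_coords=pd.DataFrame(G[:, :n_axes], index=X.columns, columns=cols),
        inertia_fraction=inertia_fraction,
        axes_kept=n_axes,
        imputed_genes=imputed,
    )


def rscu_matrix_from_tables(rscu_by_gene: dict[str, "RscuTable"]) -> pd.DataFrame:
    """Stack per-gene RSCU into a genes x 59-informative-codon matrix."""
    rows = {
        gid: [table.get(c) for c in INFORMATIVE_CODONS]
        for gid, table in rscu_by_gene.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(INFORMATIVE_CODONS)
    )


def correlation_table(
    indices: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and two-sided p over index columns.

    Defaults to the conventional variable list of codon-usage reports:
    GC12, GC3, GCall, ENC, CAI, Axis1, protein length (columns missing
    from the input are skipped). A constant variable has NaN
    correlations against everything else.
    """
    if variables is None:
        variables = [
            v
            for v in ("gc12", "gc3", "gc_all", "enc", "cai", "axis1",
                      "protein_length")
            if v in indices.columns
        ]
    if len(indices) < 5:
        raise ValueError("need >= 5 genes for the correlation table")
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j in range(i + 1, k):
            b = variables[j]
            x = indices[a].astype(float).values
            y = indices[b].astype(float).values
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
                r_ab = p_ab = _NAN
            else:
                res = stats.spearmanr(x[mask], y[mask])
                r_ab, p_ab = float(res.statistic), float(res.pvalue)
            rho.loc[a, b] = rho.loc[b, a] = r_ab
            p.loc[a, b] = p.loc[b, a] = p_ab
    return rho, p


def stars(p_value: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 thresholds."""
    if np.isnan(p_value):
        return ""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""
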