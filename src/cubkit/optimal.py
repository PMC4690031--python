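"""Optimal-codon determination via an expression contrast.

The procedure: rank genes by CAI (a proxy for expression level), take
the extreme top/bottom fractions as the "highly expressed" and "lowly
expressed" datasets, pool each group's codon counts, and test every
informative codon with a 2x2 chi-square of codon vs the other codons of
its own synonymous family, high group vs low group. A codon is optimal
when it is used significantly more (p < alpha) AND relatively more
(RSCU difference >= delta_min) in the high group — significance plus
direction-and-effect-size, the CodonW convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .genetic_code import AA_OF, FAMILIES, MULTI_CODON_AAS, aa3, to_rna
from .indices import RscuTable, rscu
from .sequence_io import CodonCounts

_NAN = float("nan")

DEFAULT_ALPHA = 0.01
DEFAULT_DELTA_MIN = 0.08


@dataclass(frozen=True)
class GroupComparison:
    high_counts: CodonCounts
    low_counts: CodonCounts
    high_rscu: RscuTable
    low_rscu: RscuTable
    table: pd.DataFrame  # one row per informative codon, with evidence
    alpha: float
    delta_min: float


def partition_by_cai(
    cai_by_gene: list[tuple[str, float]], fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """Extreme-CAI partition: ids of the top and bottom ``fraction``.

    Group size is floor(fraction * N), at least 1; ties break on gene
    id so the partition is deterministic; NaN CAI genes are excluded
    from ranking.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    ranked = sorted(
        ((gid, v) for gid, v in cai_by_gene if not math.isnan(v)),
        key=lambda t: (-t[1], t[0]),
    )
    if len(ranked) < 40:
        raise ValueError(f"need >= 40 ranked genes, got {len(ranked)}")
    k = max(int(math.floor(fraction * len(ranked))), 1)
    high = [gid for gid, _ in ranked[:k]]
    low = [gid for gid, _ in ranked[-k:]]
    return high, low


def codon_chi_square(
    high: CodonCounts, low: CodonCounts, codon: str, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df = 1) of codon vs rest-of-family, by group.

    The 2x2 table is [[high_codon, high_rest], [low_codon, low_rest]]
    where "rest" is the other synonymous codons of the codon's family —
    the family-relative contrast that matches an RSCU comparison.
    Continuity correction is off by default (counts are large in this
    design). Returns (NaN, NaN) when either group's family total is 0.
    """
    aa = AA_OF[codon]
    fam = FAMILIES[aa]
    if len(fam) < 2:
        raise ValueError(f"{codon} has no synonymous alternative")
    h_c, l_c = high.get(codon), low.get(codon)
    h_tot = sum(high.get(c) for c in fam)
    l_tot = sum(low.get(c) for c in fam)
    if h_tot == 0 or l_tot == 0:
        return _NAN, _NAN
    table = [[h_c, h_tot - h_c], [l_c, l_tot - l_c]]
    if h_c == l_c == 0 or (h_tot - h_c) == (l_tot - l_c) == 0:
        return 0.0, 1.0  # degenerate margin: no signal
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def compare_groups(
    high: CodonCounts,
    low: CodonCounts,
    alpha: float = DEFAULT_ALPHA,
    delta_min: float = DEFAULT_DELTA_MIN,
    yates: bool = False,
) -> GroupComparison:
    """Pooled-group RSCU, per-codon chi-square, and optimal flags.

    The evidence table has one row per informative codon: amino acid,
    RNA codon label, group RSCU and counts, chi2, p, delta_rscu
    (high - low) and the optimal flag.
    """
    high_rscu = rscu(high, scope="high")
    low_rscu = rscu(low, scope="low")
    rows = []
    for aa in MULTI_CODON_AAS:
        for codon in FAMILIES[aa]:
            chi2, p = codon_chi_square(high, low, codon, yates=yates)
            h_r, l_r = high_rscu.get(codon), low_rscu.get(codon)
            delta = h_r - l_r
            optimal = (
                not math.isnan(p)
                and not math.isnan(delta)
                and p < alpha
                and delta >= delta_min
            )
            rows.append(
                {
                    "aa": aa3(aa),
                    "codon": to_rna(codon),
                    "high_rscu": h_r,
                    "high_n": high.get(codon),
                    "low_rscu": l_r,
                    "low_n": low.get(codon),
                    "chi2": chi2,
                    "p_value": p,
                    "delta_rscu": delta,
                    "optimal": optimal,
                }
            )
    return GroupComparison(
        high_counts=high,
        low_counts=low,
        high_rscu=high_rscu,
        low_rscu=low_rscu,
        table=pd.DataFrame(rows),
        alpha=alpha,
        delta_min=delta_min,
    )


def optimal_codon_set(comparison: GroupComparison) -> set[str]:
    """RNA labels of the codons flagged optimal in the comparison."""
    t = comparison.table
    return set(t.loc[t["optimal"], "codon"])
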