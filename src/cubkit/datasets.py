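"""Bundled reference data.

The only bundled table is the published high/low-expression codon usage
comparison for the *Paeonia lactiflora* (herbaceous peony) transcriptome:
pooled codon counts and group RSCU for the 5% highest- and lowest-CAI
gene sets of a 24,216-CDS collection. Because pooled counts plus the
RSCU definition fully determine the printed RSCU values, the table
doubles as a worked example and a regression oracle for the RSCU
implementation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genetic_code import to_dna
from .sequence_io import CodonCounts


def load_expression_groups() -> pd.DataFrame:
    """The published P. lactiflora high/low-expression codon table.

    Columns: ``aa`` (three-letter), ``codon`` (RNA label), ``high_rscu``,
    ``high_n``, ``low_rscu``, ``low_n``, ``starred`` (bool; codons the
    original analysis reported as significantly high-group-enriched).
    """
    path = resources.files("cubkit.data") / "plactiflora_expression_groups.tsv"
    with path.open() as handle:
        df = pd.read_csv(handle, sep="\t", comment="#")
    df["starred"] = df["starred"].astype(bool)
    return df


def expression_group_counts() -> tuple[CodonCounts, CodonCounts]:
    """The published pooled counts as (high, low) codon count vectors."""
    df = load_expression_groups()
    high = CodonCounts(
        counts={to_dna(c): int(n) for c, n in zip(df["codon"], df["high_n"])},
        source_ids=("plactiflora_high",),
    )
    low = CodonCounts(
        counts={to_dna(c): int(n) for c, n in zip(df["codon"], df["low_n"])},
        source_ids=("plactiflora_low",),
    )
    return high, low
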