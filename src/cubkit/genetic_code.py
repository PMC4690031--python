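"""Standard genetic code bookkeeping shared by every index.

All tables are derived at import time from Biopython's standard nuclear
code (translation table 1), so codon/amino-acid assignments are never
hand-typed. Codons are stored in DNA form (T, not U) internally;
:func:`to_rna` converts labels for reports, which conventionally print
RNA codons (AUG, GCU, ...).
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: The 61 sense codons, sorted alphabetically (DNA alphabet).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

ALL_CODONS: tuple[str, ...] = tuple(
    sorted(_TABLE.forward_table) + sorted(_TABLE.stop_codons)
)

#: codon (DNA) -> one-letter amino acid, sense codons only.
AA_OF: dict[str, str] = dict(_TABLE.forward_table)

#: one-letter amino acid -> sorted tuple of its synonymous codons.
#: Six-fold amino acids (Leu, Ser, Arg) are kept as single families.
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(AA_OF[_codon], ())
for _codon in SENSE_CODONS:
    _aa = AA_OF[_codon]
    FAMILIES[_aa] = tuple(sorted(FAMILIES[_aa] + (_codon,)))

#: codon -> size of its synonymous family (1, 2, 3, 4 or 6).
DEGENERACY: dict[str, int] = {c: len(FAMILIES[AA_OF[c]]) for c in SENSE_CODONS}

#: Amino acids encoded by a single codon (Met, Trp): no synonymous choice,
#: excluded from RSCU normalisation, ENC and CAI.
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, fam in FAMILIES.items() if len(fam) == 1)
)

#: Amino acids with >= 2 synonymous codons (18 families covering 59 codons).
MULTI_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, fam in FAMILIES.items() if len(fam) > 1)
)

#: The 59 "informative" codons: sense codons excluding Met and Trp.
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if AA_OF[c] in MULTI_CODON_AAS
)

#: degeneracy class (2, 3, 4, 6) -> amino acids in that class.
#: Class sizes are 9/1/5/3, summing with Met+Trp to the 20 families.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _fam in FAMILIES.items():
    if len(_fam) > 1:
        DEGENERACY_CLASSES.setdefault(len(_fam), ())
for _aa in MULTI_CODON_AAS:
    _k = len(FAMILIES[_aa])
    DEGENERACY_CLASSES[_k] = tuple(sorted(DEGENERACY_CLASSES[_k] + (_aa,)))

#: first-two-base prefix -> four codons, for the eight fourfold-degenerate
#: boxes (Ala GC*, Arg CG*, Gly GG*, Leu CT*, Pro CC*, Ser TC*, Thr AC*,
#: Val GT*). Only these third positions enter PR2-bias coordinates; the
#: two-fold sub-boxes of Leu/Arg/Ser are excluded.
FOURFOLD_BOXES: dict[str, tuple[str, ...]] = {}
for _prefix in sorted({c[:2] for c in SENSE_CODONS}):
    _box = tuple(_prefix + b for b in "ACGT")
    if all(c in AA_OF for c in _box) and len({AA_OF[c] for c in _box}) == 1:
        FOURFOLD_BOXES[_prefix] = _box

FOURFOLD_CODONS: frozenset[str] = frozenset(
    c for box in FOURFOLD_BOXES.values() for c in box
)


def to_rna(codon: str) -> str:
    """DNA codon label -> RNA label (``GCT`` -> ``GCU``)."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """RNA codon label -> DNA label (``GCU`` -> ``GCT``)."""
    return codon.replace("U", "T")


def aa3(aa: str) -> str:
    """One-letter amino acid -> three-letter name used in report tables."""
    return _AA3[aa]


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
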