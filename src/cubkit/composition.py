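"""Nucleotide composition, positional GC metrics, and PR2-bias coordinates.

All functions operate on :class:`~cubkit.sequence_io.CodonCounts`, so a
"gene" here is any codon count vector — one CDS or a pooled group.

GC3 is reported in two variants, which the literature often conflates:

* ``gc3`` — G+C fraction at third positions of *all* counted codons
  (stop codons included), the quantity conventionally plotted in
  neutrality plots;
* ``gc3s`` — G+C fraction at third positions of *synonymous* codons
  only (Met, Trp and stops excluded), the ``s`` that parameterizes the
  expected-ENC null curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genetic_code import AA_OF, FOURFOLD_CODONS, SINGLE_CODON_AAS, STOP_CODONS
from .sequence_io import CodonCounts

_NAN = float("nan")


@dataclass(frozen=True)
class GcProfile:
    """Per-gene composition summary (all values are fractions in [0, 1])."""

    frac_a: float
    frac_c: float
    frac_g: float
    frac_t: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_all: float
    gc3s: float


@dataclass(frozen=True)
class Pr2Point:
    """Third-position base counts within fourfold-degenerate boxes.

    ``au_bias`` = A3/(A3+T3) is the conventional ordinate of a PR2 plot,
    ``gc_bias`` = G3/(G3+C3) the abscissa; (0.5, 0.5) is the point of
    intrastrand parity expected under strand-symmetric mutation with no
    selection.
    """

    a3: int
    t3: int
    g3: int
    c3: int

    @property
    def au_bias(self) -> float:
        return self.a3 / (self.a3 + self.t3) if self.a3 + self.t3 else _NAN

    @property
    def gc_bias(self) -> float:
        return self.g3 / (self.g3 + self.c3) if self.g3 + self.c3 else _NAN


_MISSING_PROFILE = GcProfile(*([_NAN] * 10))


def gc_profile(counts: CodonCounts) -> GcProfile:
    """Base fractions, positional GC, GC12, overall GC and GC3s.

    Fractions are over all counted codon positions (stops included);
    ``gc3s`` restricts to third positions of synonymous codons and is
    NaN when the gene has none.
    """
    if counts.n_codons == 0:
        return _MISSING_PROFILE
    base = {b: 0 for b in "ACGT"}
    gc_pos = [0, 0, 0]
    syn3_total = 0
    syn3_gc = 0
    for codon, n in counts.counts.items():
        for pos, ch in enumerate(codon):
            base[ch] += n
            if ch in "GC":
                gc_pos[pos] += n
        if codon not in STOP_CODONS and AA_OF[codon] not in SINGLE_CODON_AAS:
            syn3_total += n
            if codon[2] in "GC":
                syn3_gc += n
    n_pos = 3 * counts.n_codons
    gc1, gc2, gc3 = (g / counts.n_codons for g in gc_pos)
    return GcProfile(
        frac_a=base["A"] / n_pos,
        frac_c=base["C"] / n_pos,
        frac_g=base["G"] / n_pos,
        frac_t=base["T"] / n_pos,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2,
        gc_all=(base["G"] + base["C"]) / n_pos,
        gc3s=syn3_gc / syn3_total if syn3_total else _NAN,
    )


def base_composition(counts: CodonCounts) -> GcProfile:
    """Alias of :func:`gc_profile` emphasising the A/C/G/T fractions."""
    return gc_profile(counts)


def gc_by_position(counts: CodonCounts) -> GcProfile:
    """Alias of :func:`gc_profile` emphasising the positional GC fields."""
    return gc_profile(counts)


def pr2_coords(counts: CodonCounts) -> Pr2Point:
    """Third-position base counts over the eight fourfold boxes only.

    Accumulation is commutative, so the point is invariant to gene and
    pooling order. With no fourfold-box codons all four counts are zero
    and both biases are NaN.
    """
    acc = {b: 0 for b in "ACGT"}
    for codon, n in counts.counts.items():
        if codon in FOURFOLD_CODONS:
            acc[codon[2]] += n
    return Pr2Point(a3=acc["A"], t3=acc["T"], g3=acc["G"], c3=acc["C"])


def mean_pr2(points: list[Pr2Point]) -> tuple[float, float, float, float]:
    """Mean and SD of per-gene (au_bias, gc_bias), NaN points dropped.

    Returns ``(mean_au, sd_au, mean_gc, sd_gc)`` — the summary usually
    drawn as the highlighted centre point of a PR2 plot.
    """
    au = [p.au_bias for p in points if not math.isnan(p.au_bias)]
    gc = [p.gc_bias for p in points if not math.isnan(p.gc_bias)]

    def _msd(xs: list[float]) -> tuple[float, float]:
        if not xs:
            return _NAN, _NAN
        m = sum(xs) / len(xs)
        var = sum((x - m) ** 2 for x in xs) / len(xs)
        return m, math.sqrt(var)

    mean_au, sd_au = _msd(au)
    mean_gc, sd_gc = _msd(gc)
    return mean_au, sd_au, mean_gc, sd_gc
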