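"""Core codon-bias indices: RSCU, Wright's ENC, the expected-ENC null
curve, and CAI with explicit reference-set construction.

Conventions adopted throughout (and shared with the report layer):

* the six-fold amino acids Leu, Ser, Arg are single families of k = 6,
  so 59 informative codons partition into 18 families (9 two-fold,
  Ile three-fold, 5 four-fold, 3 six-fold);
* stop codons and the single-codon families Met/Trp never enter RSCU
  normalisation, ENC or CAI;
* ENC uses Wright's estimator with per-family codon homozygosity
  F = (n * sum(p^2) - 1) / (n - 1), class means over degeneracy classes
  {2, 3, 4, 6}, the (F2 + F4)/2 fallback when no three-fold family is
  estimable, and a cap at 61. Values below 20 are reported as computed
  (short, highly biased genes can fall below the theoretical floor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .composition import gc_profile
from .genetic_code import (
    DEGENERACY_CLASSES,
    FAMILIES,
    MULTI_CODON_AAS,
    SINGLE_CODON_AAS,
)
from .sequence_io import CodonCounts, pool_counts

_NAN = float("nan")

DEFAULT_MIN_CODONS = 30
DEFAULT_WEIGHT_FLOOR = 0.01


@dataclass(frozen=True)
class RscuTable:
    """Per-codon relative synonymous codon usage.

    A codon of a family observed N_f > 0 times has
    ``rscu[c] = count[c] / (N_f / k)``; unobserved families are NaN
    (absent amino acid, as opposed to an avoided codon at 0.0).
    """

    rscu: Mapping[str, float]
    counts: CodonCounts
    scope: str = "gene"

    def get(self, codon: str) -> float:
        return self.rscu.get(codon, _NAN)


@dataclass(frozen=True)
class EncResult:
    enc_obs: float
    enc_exp: float
    deviation: float
    f_bar_by_class: Mapping[int, float]
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class CaiModel:
    """Relative-adaptiveness weights w (max 1 within each family)."""

    weights: Mapping[str, float]
    reference_ids: tuple[str, ...]
    floor: float = DEFAULT_WEIGHT_FLOOR


def rscu(counts: CodonCounts, scope: str = "gene") -> RscuTable:
    """RSCU over the 18 multi-codon families plus Met/Trp at 1.0.

    Within each observed family the values average to 1 by
    construction; a k-fold family's values lie in [0, k].
    """
    values: dict[str, float] = {}
    for aa in MULTI_CODON_AAS:
        fam = FAMILIES[aa]
        total = sum(counts.get(c) for c in fam)
        if total == 0:
            for c in fam:
                values[c] = _NAN
        else:
            expected = total / len(fam)
            for c in fam:
                values[c] = counts.get(c) / expected
    for aa in SINGLE_CODON_AAS:
        (codon,) = FAMILIES[aa]
        values[codon] = 1.0 if counts.get(codon) > 0 else _NAN
    return RscuTable(rscu=values, counts=counts, scope=scope)


def _family_homozygosity(counts: CodonCounts, fam: Sequence[str]) -> float | None:
    """Wright's F-hat for one family; None when not estimable (n<=1 or F<=0)."""
    obs = [counts.get(c) for c in fam]
    n = sum(obs)
    if n <= 1:
        return None
    sum_p2 = sum((x / n) ** 2 for x in obs)
    f_hat = (n * sum_p2 - 1) / (n - 1)
    if f_hat <= 0:
        return None
    return f_hat


def enc(counts: CodonCounts, min_codons: int = DEFAULT_MIN_CODONS) -> EncResult:
    """Wright's effective number of codons, expected value and deviation.

    ``enc_exp`` is :func:`expected_enc` at the gene's own GC3s and
    ``deviation`` is (enc_exp - enc_obs) / enc_exp. Genes with fewer
    than ``min_codons`` counted codons, or with a whole degeneracy class
    (2, 4 or 6) inestimable, are reported NaN with an explanatory flag
    rather than silently extrapolated.
    """
    flags: set[str] = set()
    profile = gc_profile(counts)
    enc_exp = (
        expected_enc(profile.gc3s) if not math.isnan(profile.gc3s) else _NAN
    )
    if counts.n_codons < min_codons:
        flags.add("TOO_FEW_CODONS")
        return EncResult(_NAN, enc_exp, _NAN, {}, frozenset(flags))

    f_bar: dict[int, float] = {}
    for k, aas in sorted(DEGENERACY_CLASSES.items()):
        f_hats = [
            f
            for aa in aas
            if (f := _family_homozygosity(counts, FAMILIES[aa])) is not None
        ]
        if f_hats:
            f_bar[k] = sum(f_hats) / len(f_hats)

    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
        flags.add("F3_INTERPOLATED")
    missing = [k for k in (2, 3, 4, 6) if k not in f_bar]
    if missing:
        flags.update(f"MISSING_CLASS_{k}" for k in missing)
        return EncResult(_NAN, enc_exp, _NAN, dict(f_bar), frozenset(flags))

    n_families = {k: len(aas) for k, aas in DEGENERACY_CLASSES.items()}
    raw = 2.0 + sum(n_families[k] / f_bar[k] for k in (2, 3, 4, 6))
    enc_obs = min(raw, 61.0)
    if raw > 61.0:
        flags.add("CAPPED_AT_61")
    deviation = (
        (enc_exp - enc_obs) / enc_exp if not math.isnan(enc_exp) else _NAN
    )
    return EncResult(enc_obs, enc_exp, deviation, dict(f_bar), frozenset(flags))


def expected_enc(gc3s: float) -> float:
    """Wright's null ENC at synonymous third-position GC content ``s``:
    2 + s + 29 / (s^2 + (1 - s)^2), the curve genes follow when codon
    usage is shaped by compositional (mutational) pressure alone.
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def enc_deviation(enc_obs: float, gc3s: float) -> float:
    """(ENC_exp - ENC_obs) / ENC_exp; NaN propagates from enc_obs."""
    if math.isnan(enc_obs):
        return _NAN
    exp = expected_enc(gc3s)
    return (exp - enc_obs) / exp


def weights_from_reference(
    reference: CodonCounts,
    reference_ids: tuple[str, ...] = (),
    floor: float = DEFAULT_WEIGHT_FLOOR,
) -> CaiModel:
    """Relative adaptiveness w[c] = RSCU_ref[c] / max family RSCU_ref.

    Codons unobserved in the reference (including whole missing
    families) are floored at ``floor`` so the geometric mean can never
    hit zero; Met and Trp carry weight 1 (they are excluded from CAI
    regardless).
    """
    ref_rscu = rscu(reference, scope="reference")
    weights: dict[str, float] = {}
    for aa in MULTI_CODON_AAS:
        fam = FAMILIES[aa]
        fam_max = max(
            (v for c in fam if not math.isnan(v := ref_rscu.get(c))),
            default=_NAN,
        )
        for c in fam:
            v = ref_rscu.get(c)
            if math.isnan(v) or fam_max <= 0:
                weights[c] = floor
            else:
                weights[c] = max(v / fam_max, floor)
    for aa in SINGLE_CODON_AAS:
        (codon,) = FAMILIES[aa]
        weights[codon] = 1.0
    return CaiModel(weights=weights, reference_ids=reference_ids, floor=floor)


def build_cai_model(
    genes: Sequence[tuple[str, CodonCounts]],
    fraction: float = 0.05,
    refine: bool = True,
    min_reference: int = 5,
    min_codons: int = DEFAULT_MIN_CODONS,
    floor: float = DEFAULT_WEIGHT_FLOOR,
) -> CaiModel:
    """Build a CAI model without external expression data.

    The reference set seeds from the ``fraction`` of genes with lowest
    ENC (most biased), then, if ``refine``, one refinement pass scores
    all genes with the seed weights and re-selects the top ``fraction``
    by CAI before recomputing the weights. Ties break on gene id so the
    model is deterministic.
    """
    if len(genes) < 20:
        raise ValueError(f"need >= 20 genes to build a CAI model, got {len(genes)}")
    n_ref = max(int(math.floor(fraction * len(genes))), 1)
    if n_ref < min_reference:
        raise ValueError(
            f"reference set of {n_ref} genes is below the minimum of "
            f"{min_reference}; supply more genes or a larger fraction"
        )
    scored = [
        (gid, counts, enc(counts, min_codons=min_codons).enc_obs)
        for gid, counts in genes
    ]
    ranked = sorted(
        (t for t in scored if not math.isnan(t[2])), key=lambda t: (t[2], t[0])
    )
    if len(ranked) < n_ref:
        raise ValueError("too few genes with estimable ENC for the reference set")
    seed = ranked[:n_ref]
    model = weights_from_reference(
        pool_counts(c for _, c, _ in seed),
        reference_ids=tuple(gid for gid, _, _ in seed),
        floor=floor,
    )
    if refine:
        rescored = sorted(
            ((gid, counts, cai(counts, model)) for gid, counts, _ in scored),
            key=lambda t: (-t[2] if not math.isnan(t[2]) else math.inf, t[0]),
        )
        top = rescored[:n_ref]
        model = weights_from_reference(
            pool_counts(c for _, c, _ in top),
            reference_ids=tuple(gid for gid, _, _ in top),
            floor=floor,
        )
    return model


def cai(counts: CodonCounts, model: CaiModel) -> float:
    """Codon adaptation index: the geometric mean of the weights of a
    gene's codons, Met/Trp/stops excluded; NaN when no codon is eligible.
    """
    log_sum = 0.0
    n = 0
    for aa in MULTI_CODON_AAS:
        for codon in FAMILIES[aa]:
            k = counts.get(codon)
            if k:
                log_sum += k * math.log(model.weights[codon])
                n += k
    if n == 0:
        return _NAN
    return math.exp(log_sum / n)
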