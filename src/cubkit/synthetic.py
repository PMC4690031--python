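"""Synthetic CDS genomes with controlled mutational GC pressure,
translational selection, and expression structure.

The generative model, per gene:

1. a protein length L is drawn from a clipped log-normal;
2. a third-position GC target ``t`` is drawn from a Beta distribution
   wide enough to span roughly 5-90% GC3, as transcriptome-scale CDS
   collections of AT-rich plants show; the first/second-position GC
   target is coupled to it as ``0.5 + coupling * (t - 0.5)`` — the
   shared mutational pressure that produces neutrality-plot structure;
3. amino acids are drawn from the uniform baseline re-weighted by each
   family's total mutational mass under the gene's base composition
   (mutation acts on all positions, so AT-poor amino acids become rare
   in AT-rich genes, as in real mutation-dominated genomes);
4. within each family, codons are drawn with probability proportional
   to mutational weight times ``exp(s)`` for the planted preferred
   codon, where ``s >= 0`` is the gene's translational selection
   strength; a uniformly chosen stop codon is appended.

Genes with high ``s`` therefore over-use the planted preferred set,
have lower ENC and higher CAI, and stand in for "highly expressed"
genes; the truth table records every per-gene parameter so recovery can
be tested against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genetic_code import FAMILIES, MULTI_CODON_AAS, STOP_CODONS
from .sequence_io import CdsRecord, make_record, write_cds_fasta

#: One planted "optimal" codon per multi-codon family (DNA form): the
#: most-used high-expression-group codon of each family in the published
#: P. lactiflora comparison table, i.e. a realistic AT-leaning preferred
#: set for a eudicot transcriptome.
DEFAULT_PREFERRED: tuple[str, ...] = (
    "GCT",  # Ala
    "AGA",  # Arg
    "AAT",  # Asn
    "GAT",  # Asp
    "TGT",  # Cys
    "CAA",  # Gln
    "GAA",  # Glu
    "GGT",  # Gly
    "CAT",  # His
    "ATT",  # Ile
    "TTG",  # Leu
    "AAG",  # Lys
    "TTT",  # Phe
    "CCA",  # Pro
    "TCT",  # Ser
    "ACT",  # Thr
    "TAT",  # Tyr
    "GTT",  # Val
)

_AAS = tuple(sorted(FAMILIES))  # 20 amino acids, fixed order


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    Defaults emulate an AT-rich plant transcriptome CDS collection:
    overall GC about 44%, per-gene GC3 spanning roughly 5-90%, CDS of
    at least 100 codons, and a quarter of genes under translational
    selection of strength ``s_high``.
    """

    n_genes: int = 2000
    length_log_mean: float = math.log(220.0)
    length_log_sigma: float = 0.45
    min_protein_len: int = 100
    max_protein_len: int = 3000
    gc3_alpha: float = 3.0
    gc3_beta: float = 4.12
    gc12_coupling: float = 0.85
    p_high: float = 0.25
    s_high: float = 1.0
    s_low: float = 0.0
    preferred_codons: tuple[str, ...] = DEFAULT_PREFERRED
    aa_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.min_protein_len < 1 or self.max_protein_len < self.min_protein_len:
            raise ValueError("infeasible protein length bounds")
        by_aa: dict[str, list[str]] = {}
        for codon in self.preferred_codons:
            aa = next((a for a, fam in FAMILIES.items() if codon in fam), None)
            if aa is None or len(FAMILIES[aa]) == 1:
                raise ValueError(f"{codon} is not a multi-codon-family sense codon")
            by_aa.setdefault(aa, []).append(codon)
        if any(len(v) > 1 for v in by_aa.values()):
            raise ValueError("at most one preferred codon per family")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GenomeSpec":
        raw = json.loads(text)
        for key in ("preferred_codons", "aa_weights"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def mutation_only_spec(n_genes: int = 1000, seed: int = 0, **kw) -> GenomeSpec:
    """A genome shaped by compositional pressure alone (s = 0 everywhere)."""
    return GenomeSpec(n_genes=n_genes, seed=seed, p_high=0.0, s_high=0.0, **kw)


def selection_spec(
    n_genes: int = 2000, seed: int = 0, s_high: float = 1.0, **kw
) -> GenomeSpec:
    """A genome with a planted selected gene class and a narrow GC3
    distribution (same mean as the default), so expression contrast is
    the dominant axis of variation rather than compositional spread."""
    kw.setdefault("gc3_alpha", 15.0)
    kw.setdefault("gc3_beta", 20.6)
    return GenomeSpec(n_genes=n_genes, seed=seed, s_high=s_high, **kw)


def _base_probs(gc: float) -> dict[str, float]:
    gc = min(max(gc, 1e-4), 1.0 - 1e-4)
    return {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}


def codon_sampling_probs(
    gc3_target: float,
    s: float,
    gc12_coupling: float = 0.85,
    preferred: Iterable[str] = DEFAULT_PREFERRED,
    aa_weights: tuple[float, ...] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sampling law for one gene: (amino-acid probs, per-family codon probs).

    Exposed separately so goodness-of-fit of the generator against its
    own law can be tested directly.
    """
    pi3 = _base_probs(gc3_target)
    pi12 = _base_probs(0.5 + gc12_coupling * (gc3_target - 0.5))
    preferred = set(preferred)
    fam_probs: dict[str, np.ndarray] = {}
    fam_mass = np.empty(len(_AAS))
    for i, aa in enumerate(_AAS):
        fam = FAMILIES[aa]
        mut = np.array([pi12[c[0]] * pi12[c[1]] * pi3[c[2]] for c in fam])
        fam_mass[i] = mut.sum()
        sel = np.array([math.exp(s) if c in preferred else 1.0 for c in fam])
        w = mut * sel
        fam_probs[aa] = w / w.sum()
    base = np.ones(len(_AAS)) if aa_weights is None else np.asarray(aa_weights)
    aa_p = base * fam_mass
    return aa_p / aa_p.sum(), fam_probs


def generate_genome(spec: GenomeSpec) -> tuple[list[CdsRecord], pd.DataFrame]:
    """Sample a genome; returns FASTA-ready records and the truth table.

    The truth table has one row per gene: id, protein_length,
    gc3_target, realized_gc3 (third-position GC over all codons of the
    written CDS, terminal stop included), selection strength s, and the
    expression label (``high`` for the top ``p_high`` quantile of s,
    provided s varies at all).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    lengths = np.clip(
        np.round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma, n)),
        spec.min_protein_len,
        spec.max_protein_len,
    ).astype(int)
    gc3_targets = rng.beta(spec.gc3_alpha, spec.gc3_beta, n)
    s_values = np.where(rng.random(n) < spec.p_high, spec.s_high, spec.s_low)

    if s_values.max() > s_values.min():
        threshold = np.quantile(s_values, 1.0 - spec.p_high)
        # when the realized high class is smaller than p_high the quantile
        # collapses to the minimum; require strict excess in that case
        if threshold <= s_values.min():
            labels = np.where(s_values > threshold, "high", "low")
        else:
            labels = np.where(s_values >= threshold, "high", "low")
    else:
        labels = np.full(n, "low")

    records: list[CdsRecord] = []
    rows = []
    width = len(str(n))
    for i in range(n):
        aa_p, fam_probs = codon_sampling_probs(
            gc3_targets[i],
            s_values[i],
            spec.gc12_coupling,
            spec.preferred_codons,
            spec.aa_weights,
        )
        aa_counts = rng.multinomial(lengths[i], aa_p)
        codons: list[str] = []
        for aa, m in zip(_AAS, aa_counts):
            if m == 0:
                continue
            fam = FAMILIES[aa]
            codon_counts = rng.multinomial(m, fam_probs[aa])
            for codon, k in zip(fam, codon_counts):
                codons.extend([codon] * int(k))
        order = rng.permutation(len(codons))
        codons = [codons[j] for j in order]
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        seq = "".join(codons)
        gene_id = f"g{i + 1:0{width}d}"
        records.append(make_record(gene_id, seq))
        realized_gc3 = sum(1 for c in codons if c[2] in "GC") / len(codons)
        rows.append(
            {
                "gene_id": gene_id,
                "protein_length": int(lengths[i]),
                "gc3_target": float(gc3_targets[i]),
                "realized_gc3": realized_gc3,
                "s": float(s_values[i]),
                "expression": labels[i],
            }
        )
    truth = pd.DataFrame(rows)
    truth.attrs["preferred_codons"] = spec.preferred_codons
    return records, truth


def _qc_stress_records() -> tuple[list[CdsRecord], pd.DataFrame]:
    """Hand-built defect set: planted QC failures with known tallies."""
    good = ("ATGGCT" + "GAAGGTCTTCCA" * 25 + "TAA")  # 309 nt, clean
    cases = [
        ("ok1", good, []),
        ("ok2", good.replace("GAA", "GAG"), []),
        ("short1", "ATGGCTTAA", ["TOO_SHORT"]),
        ("short2", "ATG" + "GCT" * 40, ["TOO_SHORT"]),  # 123 nt
        ("nontriplet1", good + "GC", ["NOT_TRIPLET"]),
        ("ambig1", good[:60] + "NNN" + good[63:], ["HAS_AMBIGUITY"]),
        ("internalstop1", good[:30] + "TAA" + good[33:], ["INTERNAL_STOP"]),
        (
            "multi1",
            "ATGNNNTAATAA",  # short, ambiguous, internal stop
            ["TOO_SHORT", "HAS_AMBIGUITY", "INTERNAL_STOP"],
        ),
    ]
    records = [make_record(gid, seq) for gid, seq, _ in cases]
    truth = pd.DataFrame(
        [{"gene_id": gid, "planted_flags": ";".join(flags)} for gid, _, flags in cases]
    )
    return records, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 20150
                       ) -> dict[str, Path]:
    """Write the standard test fixture files; returns name -> path.

    * ``mutation_only`` — wide GC3, no selection: ENC-curve/neutrality.
    * ``selection`` — planted preferred set, bimodal s: CAI/optimal-codon
      recovery.
    * ``tiny`` — five short hand-checkable genes.
    * ``qc_stress`` — planted QC defects with exact expected tallies.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _emit(name: str, records: list[CdsRecord], truth: pd.DataFrame,
              spec: GenomeSpec | None) -> None:
        fasta = out / f"{name}.fasta"
        write_cds_fasta(records, fasta)
        truth.to_csv(out / f"{name}.truth.tsv", sep="\t", index=False)
        if spec is not None:
            (out / f"{name}.spec.json").write_text(spec.to_json())
        paths[name] = fasta

    spec_a = mutation_only_spec(n_genes=400, seed=seed)
    _emit("mutation_only", *generate_genome(spec_a), spec_a)

    spec_b = selection_spec(n_genes=600, seed=seed + 1)
    _emit("selection", *generate_genome(spec_b), spec_b)

    spec_c = GenomeSpec(
        n_genes=5, seed=seed + 2, min_protein_len=100, max_protein_len=140
    )
    _emit("tiny", *generate_genome(spec_c), spec_c)

    _emit("qc_stress", *_qc_stress_records(), None)
    return paths
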