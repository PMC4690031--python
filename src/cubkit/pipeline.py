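"""Single-command orchestration: FASTA in, report bundle out.

Every number written to the bundle is computed by the public module
functions with the same configuration — the report layer adds
formatting only. Given the same input and configuration the bundle is
byte-identical across runs (no stage is stochastic; ``seed`` is carried
for the synthetic generator and recorded in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import gc_profile, mean_pr2, pr2_coords
from .genetic_code import aa3, AA_OF, MULTI_CODON_AAS, FAMILIES, to_rna
from .indices import (
    DEFAULT_MIN_CODONS,
    build_cai_model,
    cai,
    enc,
    rscu,
)
from .multivariate import (
    coa_rscu,
    correlation_table,
    neutrality_stats,
    rscu_matrix_from_tables,
    stars,
)
from .optimal import compare_groups, optimal_codon_set, partition_by_cai
from .sequence_io import (
    DEFAULT_MIN_LEN,
    count_codons,
    pool_counts,
    qc_filter,
    read_cds_fasta,
    write_qc_report,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that parameterizes one analysis run.

    Round-trips losslessly through JSON (:meth:`to_json` /
    :meth:`from_json`), which is also the on-disk ``--config`` format.
    """

    input: str
    out_dir: str
    min_len: int = DEFAULT_MIN_LEN
    drop_not_triplet: bool = False
    drop_internal_stop: bool = False
    min_codons: int = DEFAULT_MIN_CODONS
    cai_fraction: float = 0.05
    partition_fraction: float = 0.05
    alpha: float = 0.01
    delta_min: float = 0.08
    axes_kept: int = 4
    gc_color_low: float = 0.45
    gc_color_high: float = 0.60
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.min_len <= 0:
            raise ValueError("min_len must be positive")
        if not 0 < self.partition_fraction < 0.5:
            raise ValueError("partition_fraction must be in (0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: dict[str, int]
    gene_table: pd.DataFrame
    pooled_rscu: pd.DataFrame
    neutrality: "object"
    coa: "object"
    correlation_rho: pd.DataFrame
    correlation_p: pd.DataFrame
    comparison: "object"
    optimal_codons: set[str]
    pr2_mean: tuple[float, float, float, float]
    files: dict[str, Path] = field(default_factory=dict)


def _fmt_float(x: float, nd: int) -> str:
    return "" if isinstance(x, float) and math.isnan(x) else f"{x:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute QC -> composition -> indices -> multivariate -> optimal
    codons and write the TSV/figure bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    logger.info("reading %s", config.input)
    records = read_cds_fasta(config.input, min_len=config.min_len)
    kept, qc_report = qc_filter(
        records,
        min_len=config.min_len,
        drop_not_triplet=config.drop_not_triplet,
        drop_internal_stop=config.drop_internal_stop,
    )
    logger.info("QC kept %d/%d records", len(kept), len(records))
    if not kept:
        raise RuntimeError("sequence_io: no records survive QC")
    files["qc_report"] = out / "qc_report.tsv"
    write_qc_report(qc_report, files["qc_report"])

    counts = {rec.id: count_codons(rec) for rec in kept}
    gene_ids = [rec.id for rec in kept]

    # per-gene composition + indices
    rows = []
    rscu_by_gene = {}
    pr2_points = []
    for gid in gene_ids:
        c = counts[gid]
        prof = gc_profile(c)
        e = enc(c, min_codons=config.min_codons)
        p2 = pr2_coords(c)
        pr2_points.append(p2)
        rscu_by_gene[gid] = rscu(c)
        rows.append(
            {
                "gene_id": gid,
                "n_codons": c.n_codons,
                "protein_length": sum(
                    n for cod, n in c.counts.items() if cod in AA_OF
                ),
                "frac_a": prof.frac_a,
                "frac_t": prof.frac_t,
                "frac_g": prof.frac_g,
                "frac_c": prof.frac_c,
                "gc1": prof.gc1,
                "gc2": prof.gc2,
                "gc3": prof.gc3,
                "gc12": prof.gc12,
                "gc_all": prof.gc_all,
                "gc3s": prof.gc3s,
                "enc": e.enc_obs,
                "enc_exp": e.enc_exp,
                "enc_deviation": e.deviation,
                "au_bias": p2.au_bias,
                "gc_bias": p2.gc_bias,
            }
        )
    gene_table = pd.DataFrame(rows).set_index("gene_id", drop=False)

    # pooled RSCU across the whole collection
    pooled = pool_counts(counts[g] for g in gene_ids)
    pooled_rscu_table = rscu(pooled, scope="pooled")
    pooled_rows = [
        {
            "aa": aa3(aa),
            "codon": to_rna(codon),
            "rscu": pooled_rscu_table.get(codon),
            "count": pooled.get(codon),
        }
        for aa in sorted(FAMILIES)
        for codon in FAMILIES[aa]
    ]
    pooled_df = pd.DataFrame(pooled_rows)
    files["pooled_rscu"] = out / "pooled_rscu.tsv"
    pooled_df.assign(rscu=pooled_df["rscu"].map(lambda v: _fmt_float(v, 3))).to_csv(
        files["pooled_rscu"], sep="\t", index=False
    )

    # neutrality
    neutrality = neutrality_stats(gene_table["gc12"], gene_table["gc3"])

    # CAI
    model = build_cai_model(
        [(g, counts[g]) for g in gene_ids],
        fraction=config.cai_fraction,
        min_codons=config.min_codons,
    )
    gene_table["cai"] = [cai(counts[g], model) for g in gene_ids]

    # correspondence analysis on RSCU
    matrix = rscu_matrix_from_tables(rscu_by_gene)
    coa = coa_rscu(matrix, gc3=gene_table["gc3"], axes_kept=config.axes_kept)
    for j in range(coa.axes_kept):
        gene_table[f"axis{j + 1}"] = coa.gene_coords[f"Axis{j + 1}"]

    files["gene_indices"] = out / "gene_indices.tsv"
    gene_table.to_csv(files["gene_indices"], sep="\t", index=False,
                      float_format="%.6f")
    files["coa_gene_coords"] = out / "coa_gene_coordinates.tsv"
    coa.gene_coords.to_csv(files["coa_gene_coords"], sep="\t",
                           float_format="%.6f")
    files["coa_codon_coords"] = out / "coa_codon_coordinates.tsv"
    codon_coords = coa.codon_coords.copy()
    codon_coords.index = [to_rna(c) for c in codon_coords.index]
    codon_coords.to_csv(files["coa_codon_coords"], sep="\t",
                        float_format="%.6f")
    files["coa_inertia"] = out / "coa_inertia.tsv"
    pd.DataFrame(
        {
            "axis": range(1, len(coa.inertia_fraction) + 1),
            "inertia_fraction": coa.inertia_fraction,
        }
    ).to_csv(files["coa_inertia"], sep="\t", index=False, float_format="%.6f")

    # correlation table with stars
    rho, p = correlation_table(gene_table)
    starred = rho.round(3).astype(str) + p.map(stars)
    files["correlation"] = out / "correlation_table.tsv"
    starred.to_csv(files["correlation"], sep="\t")

    # PR2 mean
    pr2_summary = mean_pr2(pr2_points)

    # expression contrast -> optimal codons
    high_ids, low_ids = partition_by_cai(
        list(zip(gene_table["gene_id"], gene_table["cai"])),
        fraction=config.partition_fraction,
    )
    comparison = compare_groups(
        pool_counts(counts[g] for g in high_ids),
        pool_counts(counts[g] for g in low_ids),
        alpha=config.alpha,
        delta_min=config.delta_min,
    )
    optimal = optimal_codon_set(comparison)
    files["group_comparison"] = out / "group_comparison.tsv"
    comp_out = comparison.table.copy()
    for col in ("high_rscu", "low_rscu", "delta_rscu"):
        comp_out[col] = comp_out[col].map(lambda v: _fmt_float(v, 3))
    comp_out["chi2"] = comp_out["chi2"].map(lambda v: _fmt_float(v, 2))
    comp_out["p_value"] = comp_out["p_value"].map(
        lambda v: "" if math.isnan(v) else f"{v:.3g}"
    )
    comp_out.to_csv(files["group_comparison"], sep="\t", index=False)

    result = PipelineResult(
        config=config,
        qc_report=qc_report,
        gene_table=gene_table,
        pooled_rscu=pooled_df,
        neutrality=neutrality,
        coa=coa,
        correlation_rho=rho,
        correlation_p=p,
        comparison=comparison,
        optimal_codons=optimal,
        pr2_mean=pr2_summary,
        files=files,
    )

    if config.make_plots:
        from . import plots

        files.update(plots.make_figure_bundle(result, out))

    # run manifest
    manifest = {
        "tool": f"cubkit {__version__}",
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            config.to_json().encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_input": len(records),
        "n_kept": len(kept),
        "n_optimal_codons": len(optimal),
        "neutrality_slope": neutrality.slope,
        "neutrality_rho": neutrality.rho,
        "pr2_mean_au": pr2_summary[0],
        "pr2_mean_gc": pr2_summary[2],
    }
    files["manifest"] = out / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
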