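"""Figure bundle: the conventional diagnostic plots of a codon-usage
study (GC histogram, neutrality plot, ENC plot with the null curve,
deviation histogram, CA scatters, PR2 plot, ENC vs CAI / length)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .indices import expected_enc


def _save(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_figure_bundle(result, out_dir: str | Path) -> dict[str, Path]:
    """Write all figures for a :class:`~cubkit.pipeline.PipelineResult`."""
    out = Path(out_dir)
    gt = result.gene_table
    files: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(100 * gt["gc_all"].dropna(), bins=30, color="#4477aa")
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("Number of genes")
    files["fig_gc_hist"] = _save(fig, out / "fig_gc_histogram.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(100 * gt["gc3"], 100 * gt["gc12"], s=4, alpha=0.4)
    nt = result.neutrality
    if not np.isnan(nt.slope):
        xs = np.linspace(gt["gc3"].min(), gt["gc3"].max(), 50)
        ax.plot(100 * xs, 100 * (nt.intercept + nt.slope * xs), "r-",
                label=f"slope = {nt.slope:.3f}")
        ax.legend()
    ax.set_xlabel("GC3 (%)")
    ax.set_ylabel("GC12 (%)")
    files["fig_neutrality"] = _save(fig, out / "fig_neutrality.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gt["gc3s"], gt["enc"], s=4, alpha=0.4)
    s = np.linspace(0, 1, 200)
    ax.plot(s, [expected_enc(v) for v in s], "k-", label="expected ENC")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(0, 62)
    ax.legend()
    files["fig_enc_plot"] = _save(fig, out / "fig_enc_plot.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    dev = gt["enc_deviation"].dropna()
    edges = np.arange(
        np.floor(dev.min() * 10) / 10, np.ceil(dev.max() * 10) / 10 + 0.1, 0.1
    )
    ax.hist(dev, bins=edges, color="#cc6677")
    ax.set_xlabel("(ENCexp − ENCobs) / ENCexp")
    ax.set_ylabel("Number of genes")
    files["fig_enc_deviation"] = _save(fig, out / "fig_enc_deviation.png")

    cfg = result.config
    if result.coa.axes_kept >= 2:
        fig, ax = plt.subplots(figsize=(5, 4.5))
        gc = gt["gc_all"]
        groups = [
            (gc >= cfg.gc_color_high, "red", "^",
             f"GC ≥ {100 * cfg.gc_color_high:.0f}%"),
            ((gc >= cfg.gc_color_low) & (gc < cfg.gc_color_high), "blue", "o",
             f"{100 * cfg.gc_color_low:.0f}% ≤ GC < {100 * cfg.gc_color_high:.0f}%"),
            (gc < cfg.gc_color_low, "green", "o",
             f"GC < {100 * cfg.gc_color_low:.0f}%"),
        ]
        for mask, color, marker, label in groups:
            ax.scatter(gt.loc[mask, "axis1"], gt.loc[mask, "axis2"], s=6,
                       c=color, marker=marker, alpha=0.5, label=label)
        ax.set_xlabel("Axis 1")
        ax.set_ylabel("Axis 2")
        ax.legend(fontsize=7)
        files["fig_coa_genes"] = _save(fig, out / "fig_coa_genes.png")

        fig, ax = plt.subplots(figsize=(5, 4.5))
        cc = result.coa.codon_coords
        ends = np.array([c[-1] for c in cc.index])
        for base, color in zip("AUGC", ("#228833", "#66ccee", "#ee6677",
                                        "#aa3377")):
            mask = ends == ("U" if base == "U" else base)
            ax.scatter(cc.loc[mask, "Axis1"], cc.loc[mask, "Axis2"], c=color,
                       s=12, label=f"{base}-ending")
        ax.set_xlabel("Axis 1")
        ax.set_ylabel("Axis 2")
        ax.legend(fontsize=7)
        files["fig_coa_codons"] = _save(fig, out / "fig_coa_codons.png")

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(gt["gc_bias"], gt["au_bias"], s=4, alpha=0.4)
    mean_au, _, mean_gc, _ = result.pr2_mean
    ax.plot([0.5, 0.5], [0, 1], "k-", lw=0.8)
    ax.plot([0, 1], [0.5, 0.5], "k-", lw=0.8)
    ax.plot(mean_gc, mean_au, "o", mfc="none", mec="red", ms=10)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+U3)")
    files["fig_pr2"] = _save(fig, out / "fig_pr2.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gt["cai"], gt["enc"], s=4, alpha=0.4)
    ax.set_xlabel("CAI")
    ax.set_ylabel("ENC")
    files["fig_enc_vs_cai"] = _save(fig, out / "fig_enc_vs_cai.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gt["protein_length"], gt["enc"], s=4, alpha=0.4)
    ax.set_xlabel("Protein length (codons)")
    ax.set_ylabel("ENC")
    files["fig_enc_vs_length"] = _save(fig, out / "fig_enc_vs_length.png")
    return files
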