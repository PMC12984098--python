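"""Standard scatter/bar plots for the pipeline outputs.

Panels mirror the usual presentation of codon bias studies: a mean-RSCU
bar chart grouped by amino acid, PCA score scatter, k-means clusters in
CAI space, and the four diagnostic panels (ENC-CAI, PR2, ENC-GC3s with
Wright's expected curve, neutrality with the y = x reference).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .diagnostics import enc_expected  # noqa: E402

__all__ = ["plot_all"]


def _colors_for(species: Sequence[str], taxonomy: Mapping[str, str] | None):
    if taxonomy is None:
        return {"(all)": list(species)}
    groups: dict[str, list[str]] = {}
    for sp in species:
        groups.setdefault(taxonomy.get(sp, "other"), []).append(sp)
    return groups


def _scatter_by_group(ax, xs: pd.Series, ys: pd.Series, groups, highlight=()):
    for name, members in sorted(groups.items()):
        members = [m for m in members if m in xs.index]
        ax.scatter(xs.loc[members], ys.loc[members], s=18, label=name, alpha=0.8)
    for sp in highlight:
        if sp in xs.index:
            ax.annotate(sp, (xs.loc[sp], ys.loc[sp]), fontsize=7)
    if len(groups) > 1:
        ax.legend(fontsize=6, frameon=False)


def plot_all(plotdir: Path, metrics_df: pd.DataFrame, mean_rscu_path,
             pca_results: Mapping[str, object], kmeans_result, pr2_path,
             code, taxonomy=None, highlight: Sequence[str] = ()) -> list[Path]:
    written: list[Path] = []
    genes = sorted(metrics_df["gene"].unique())

    # mean RSCU bars, one panel per gene
    if mean_rscu_path is not None:
        rscu = pd.read_csv(mean_rscu_path, sep="\t", comment="#")
        fig, axes = plt.subplots(len(genes), 1, figsize=(12, 3.2 * len(genes)),
                                 squeeze=False)
        for ax, gene in zip(axes.ravel(), genes):
            sub = (rscu[rscu["gene"] == gene]
                   .sort_values(["amino_acid", "codon"]))
            ax.bar(range(len(sub)), sub["mean_rscu"],
                   color=["tab:red" if f else "tab:gray" for f in sub["favored"]])
            ax.axhline(1.0, color="k", lw=0.6, ls="--")
            ax.set_xticks(range(len(sub)))
            ax.set_xticklabels(sub["codon"], rotation=90, fontsize=5)
            ax.set_ylabel("mean RSCU")
            ax.set_title(f"{gene}: favored codons in red")
        fig.tight_layout()
        out = plotdir / "mean_rscu.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)

    # PCA score scatter
    for gene, res in pca_results.items():
        fig, ax = plt.subplots(figsize=(5, 4.5))
        groups = _colors_for(res.scores.index, taxonomy)
        _scatter_by_group(ax, res.scores["PC1"],
                          res.scores["PC2"] if "PC2" in res.scores else
                          res.scores["PC1"] * 0, groups, highlight)
        ve = res.variance_explained
        ax.set_xlabel(f"PC1 ({100 * ve[0]:.2f}%)")
        if len(ve) > 1:
            ax.set_ylabel(f"PC2 ({100 * ve[1]:.2f}%)")
        ax.set_title(f"PCA of RSCU, {gene}")
        fig.tight_layout()
        out = plotdir / f"pca_{gene}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)

    # k-means clusters in CAI space
    if kmeans_result is not None:
        z = kmeans_result.standardized
        fig, ax = plt.subplots(figsize=(5, 4.5))
        for label in sorted(kmeans_result.assignments.unique()):
            members = kmeans_result.assignments.index[
                kmeans_result.assignments == label]
            ax.scatter(z.loc[members, z.columns[0]],
                       z.loc[members, z.columns[1]], s=18,
                       label=f"cluster {label}")
        ax.scatter(kmeans_result.centers[:, 0], kmeans_result.centers[:, 1],
                   marker="x", c="k", s=60)
        for sp in highlight:
            if sp in z.index:
                ax.annotate(sp, (z.loc[sp, z.columns[0]], z.loc[sp, z.columns[1]]),
                            fontsize=7)
        ax.set_xlabel(f"{z.columns[0]} (standardized)")
        ax.set_ylabel(f"{z.columns[1]} (standardized)")
        ax.legend(fontsize=7, frameon=False)
        ax.set_title(f"k-means (k={kmeans_result.k}) in CAI space")
        fig.tight_layout()
        out = plotdir / "kmeans_cai.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)

    # diagnostics: ENC-CAI, PR2, ENC-GC3s with Wright curve, neutrality
    pr2 = (pd.read_csv(pr2_path, sep="\t", comment="#")
           if pr2_path is not None else None)
    for gene in genes:
        sub = metrics_df[metrics_df["gene"] == gene].set_index("species")
        fig, axes = plt.subplots(2, 2, figsize=(9, 8))
        groups = _colors_for(sub.index, taxonomy)

        ax = axes[0, 0]
        _scatter_by_group(ax, sub["CAI"], sub["ENC"], groups, highlight)
        ax.set_xlabel("CAI")
        ax.set_ylabel("ENC")
        ax.set_title("ENC vs CAI")

        ax = axes[0, 1]
        if pr2 is not None:
            p = pr2[pr2["gene"] == gene].set_index("species")
            _scatter_by_group(ax, p["G3/(G3+C3)"], p["A3/(A3+T3)"],
                              groups, highlight)
        ax.axhline(0.5, color="k", lw=0.6)
        ax.axvline(0.5, color="k", lw=0.6)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("G3/(G3+C3)")
        ax.set_ylabel("A3/(A3+T3)")
        ax.set_title("PR2")

        ax = axes[1, 0]
        s_grid = np.linspace(0, 1, 200)
        ax.plot(s_grid, [enc_expected(s) for s in s_grid], "k-", lw=1,
                label="expected")
        _scatter_by_group(ax, sub["GC3s"], sub["ENC"], groups, highlight)
        ax.set_xlabel("GC3s")
        ax.set_ylabel("ENC")
        ax.set_title("ENC vs GC3s")

        ax = axes[1, 1]
        _scatter_by_group(ax, sub["GC3"], sub["GC12"], groups, highlight)
        lims = (0, 1)
        ax.plot(lims, lims, "k--", lw=0.8)
        x = sub["GC3"].to_numpy(dtype=float)
        y = sub["GC12"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0:
            b, a = np.polyfit(x[ok], y[ok], 1)
            grid = np.linspace(x[ok].min(), x[ok].max(), 2)
            ax.plot(grid, a + b * grid, "r-", lw=1)
        ax.set_xlabel("GC3")
        ax.set_ylabel("GC12")
        ax.set_title("Neutrality")

        fig.suptitle(gene)
        fig.tight_layout()
        out = plotdir / f"diagnostics_{gene}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
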