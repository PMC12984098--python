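"""End-to-end orchestration: QC -> metrics -> RSCU/optimal codons ->
diagnostics -> PCA/k-means, with tabular and plot outputs.

Every output table starts with a ``# columns:`` header comment and
round-trips through :func:`read_table`. The run manifest records the
configuration, input hashes, package versions, seed and per-stage row
counts, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genetic_code import standard_table
from .io_qc import dedupe_by_species, pair_species, read_cds_fasta
from .metrics import (GeneCodonProfile, ReferenceWeights, get_reference,
                      metrics_table, profile_gene)
from .diagnostics import (correlation_matrix, enc_cai_regression,
                          enc_gc3s_deviation, neutrality_regression,
                          pr2_table)
from .optimal_codons import favored_codons, mean_rscu, optimal_codon_scan, stratify_by_enc
from .multivariate import kmeans_cai, pca, rscu_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "RunResult",
           "run_pipeline", "summarize", "write_table", "read_table"]

ALL_STAGES = ("qc", "metrics", "rscu", "optimal", "diagnostics",
              "pca", "kmeans", "plots")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; CLI flags mirror these fields."""

    fasta_by_gene: Mapping[str, str | Path]
    outdir: str | Path = "codonbias_out"
    taxonomy_tsv: str | Path | None = None      # species -> order, for coloring
    abbreviations_tsv: str | Path | None = None
    highlight_species: tuple[str, ...] = ()
    cai_reference: str = "ecoli"                # name or path to a weights TSV
    pr2_codon_set: str = "fourfold"             # or "all"
    pca_scale: bool = False
    delta_rscu_threshold: float = 0.08
    group_size: int = 5
    k: int = 3
    n_starts: int = 100
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        for gene, path in self.fasta_by_gene.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"FASTA for gene {gene}: {path}")
        for path in (self.taxonomy_tsv, self.abbreviations_tsv):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(str(path))
        if self.delta_rscu_threshold <= 0 or self.group_size <= 0:
            raise ValueError("thresholds must be positive")

    def reference(self) -> ReferenceWeights:
        if Path(str(self.cai_reference)).exists():
            return ReferenceWeights.from_tsv(self.cai_reference)
        return get_reference(str(self.cai_reference))


@dataclass
class RunResult:
    outdir: Path
    tables: dict[str, Path]
    manifest: dict
    profiles: dict[str, dict[str, GeneCodonProfile]]  # gene -> species -> profile


def write_table(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    """TSV with a '# columns:' schema comment header."""
    cols = (list(df.index.names) if index and df.index.name else []) + list(df.columns)
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(str(c) for c in cols) + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def summarize(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and sample SD (n−1 denominator) of every index."""
    numeric = metrics.select_dtypes(include=[np.number]).columns
    agg = metrics.groupby("gene")[list(numeric)].agg(["mean", lambda s: s.std(ddof=1)])
    agg.columns = [f"{col}_{'sd' if name == '<lambda_0>' else name}"
                   for col, name in agg.columns]
    return agg.reset_index()


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_two_col_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["key", "value"], dtype=str)
    return dict(zip(df["key"], df["value"]))


def run_pipeline(config: PipelineConfig,
                 stages: Sequence[str] = ALL_STAGES) -> RunResult:
    """Run the analysis end to end and write its result bundle.

    Stages whose preconditions are unmet on small inputs (PCA with
    fewer than 3 species, k-means with fewer than k, optimal codons
    with fewer than 2·g) are skipped and noted in the manifest rather
    than failing the run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = standard_table()
    ref = config.reference()
    stages = tuple(stages)
    tables: dict[str, Path] = {}
    manifest: dict = {
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "fasta_by_gene"},
        "inputs": {g: {"path": str(p), "sha256": _sha256(p)}
                   for g, p in config.fasta_by_gene.items()},
        "stages": {},
        "skipped": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest["config"]["fasta_by_gene"] = {g: str(p) for g, p in
                                           config.fasta_by_gene.items()}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]

    def _stage(name):
        def wrap(fn):
            if name not in stages and name != "qc":
                return None
            t0 = time.time()
            try:
                out = fn()
            except Exception as exc:  # abort with a stage-named error
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(outdir, manifest, tables)
                raise PipelineStageError(name, exc) from exc
            manifest["stages"][name] = {"status": "ok",
                                        "elapsed_s": round(time.time() - t0, 3)}
            return out
        return wrap

    # ---- QC ---------------------------------------------------------------
    def do_qc():
        by_gene: dict[str, dict] = {}
        qc_rows = []
        for gene, path in config.fasta_by_gene.items():
            records, report = read_cds_fasta(path, gene)
            selected = dedupe_by_species(records, report)
            by_gene[gene] = selected
            for rec in records:
                qc_rows.append({"record_id": rec.record_id, "species": rec.species_id,
                                "gene": gene, "status": "pass", "reason": "",
                                "length_nt": rec.length_nt})
            for rej in report.rejections:
                qc_rows.append({"record_id": rej.record_id, "species": rej.species_id,
                                "gene": gene, "status": "reject",
                                "reason": rej.reason, "length_nt": rej.length_nt})
            logger.info("qc %s: %d/%d records pass, %d species",
                        gene, report.n_passed, report.n_input, len(selected))
        tables["qc_report"] = write_table(pd.DataFrame(qc_rows),
                                          outdir / "qc_report.tsv")
        species, _orphans = pair_species(*by_gene.values())
        manifest["stages"].setdefault("qc", {})
        manifest["n_species"] = len(species)
        return by_gene, species

    by_gene, species = _stage("qc")(do_qc)

    # ---- metrics ----------------------------------------------------------
    profiles: dict[str, dict[str, GeneCodonProfile]] = {}

    def do_metrics():
        for gene, selected in by_gene.items():
            profiles[gene] = {sp: profile_gene(selected[sp], ref, code)
                              for sp in species}
        df = metrics_table(p for g in profiles.values() for p in g.values())
        tables["metrics"] = write_table(df, outdir / "metrics.tsv")
        tables["metrics_summary"] = write_table(summarize(df),
                                                outdir / "metrics_summary.tsv")
        return df

    metrics_df = _stage("metrics")(do_metrics)

    # ---- mean RSCU / favored codons --------------------------------------
    matrices: dict[str, pd.DataFrame] = {}

    def do_rscu():
        rows = []
        for gene in profiles:
            matrix, imputed = rscu_matrix(profiles[gene].values(), code)
            matrices[gene] = matrix
            means = mean_rscu(matrix)
            fav = favored_codons(means)
            for codon in matrix.columns:
                rows.append({"gene": gene, "codon": codon,
                             "amino_acid": code.codon_to_aa[codon],
                             "third_base": codon[2],
                             "mean_rscu": means[codon],
                             "favored": codon in fav.codons})
            logger.info("rscu %s: %d favored codons (%.0f%% A/T-ending); "
                        "%d species had imputed entries", gene, fav.n,
                        100 * (fav.third_base_fraction("AT") if fav.n else 0),
                        len(imputed))
        tables["mean_rscu"] = write_table(pd.DataFrame(rows),
                                          outdir / "mean_rscu.tsv")

    _stage("rscu")(do_rscu)

    # ---- optimal codons ---------------------------------------------------
    def do_optimal():
        frames = []
        for gene in profiles:
            enc_by_sp = {sp: p.enc.value for sp, p in profiles[gene].items()}
            n_defined = sum(1 for v in enc_by_sp.values() if not np.isnan(v))
            if n_defined < 2 * config.group_size:
                manifest["skipped"][f"optimal:{gene}"] = (
                    f"needs {2 * config.group_size} species with defined ENC, "
                    f"have {n_defined}")
                continue
            groups = stratify_by_enc(enc_by_sp, config.group_size)
            report = optimal_codon_scan(matrices[gene], groups,
                                        config.delta_rscu_threshold, code)
            frame = report.table.copy()
            frame.insert(0, "gene", gene)
            frames.append(frame)
            manifest.setdefault("optimal_groups", {})[gene] = {
                "high_bias": list(report.high_bias_species),
                "low_bias": list(report.low_bias_species),
                "delta_threshold": report.delta_threshold,
                "group_size": report.group_size}
        if frames:
            tables["optimal_codons"] = write_table(
                pd.concat(frames, ignore_index=True), outdir / "optimal_codons.tsv")

    _stage("optimal")(do_optimal)

    # ---- diagnostics ------------------------------------------------------
    regression_rows = []

    def do_diagnostics():
        pr2_frames, dev_frames, neut_rows, enccai_rows = [], [], [], []
        for gene in profiles:
            cdss = [by_gene[gene][sp] for sp in species]
            pr2_frames.append(pr2_table(cdss, code, config.pr2_codon_set))
            dev_frames.append(enc_gc3s_deviation(profiles[gene].values()))
            sub = metrics_df[metrics_df["gene"] == gene]
            for _, row in sub.iterrows():
                neut_rows.append({"gene": gene, "species": row["species"],
                                  "GC3": row["GC3"], "GC12": row["GC12"]})
                enccai_rows.append({"gene": gene, "species": row["species"],
                                    "CAI": row["CAI"], "ENC": row["ENC"]})
            neut = neutrality_regression(sub["GC3"], sub["GC12"])
            enccai = enc_cai_regression(sub["CAI"], sub["ENC"])
            for name, res in (("neutrality_gc12_on_gc3", neut),
                              ("enc_on_cai", enccai)):
                regression_rows.append({"gene": gene, "analysis": name,
                                        "slope": res.slope,
                                        "intercept": res.intercept,
                                        "r": res.r, "r_squared": res.r_squared,
                                        "n": res.n})
            if len(sub) >= 3:
                corr = correlation_matrix(sub)
                tables[f"correlations_{gene}"] = write_table(
                    corr, outdir / f"correlations_{gene}.tsv", index=True)
            else:
                manifest["skipped"][f"correlations:{gene}"] = "fewer than 3 species"
        tables["pr2"] = write_table(pd.concat(pr2_frames, ignore_index=True),
                                    outdir / "pr2.tsv")
        tables["enc_gc3s"] = write_table(pd.concat(dev_frames, ignore_index=True),
                                         outdir / "enc_gc3s.tsv")
        tables["neutrality"] = write_table(pd.DataFrame(neut_rows),
                                           outdir / "neutrality.tsv")
        tables["enc_cai"] = write_table(pd.DataFrame(enccai_rows),
                                        outdir / "enc_cai.tsv")
        tables["regressions"] = write_table(pd.DataFrame(regression_rows),
                                            outdir / "regressions.tsv")

    _stage("diagnostics")(do_diagnostics)

    # ---- PCA --------------------------------------------------------------
    pca_results = {}

    def do_pca():
        summary_rows = []
        for gene, matrix in matrices.items():
            if len(matrix) < 3:
                manifest["skipped"][f"pca:{gene}"] = "fewer than 3 species"
                continue
            res = pca(matrix, center=True, scale=config.pca_scale)
            pca_results[gene] = res
            tables[f"pca_scores_{gene}"] = write_table(
                res.scores, outdir / f"pca_scores_{gene}.tsv", index=True)
            loadings = res.loadings.copy()
            loadings["d"] = res.loading_distance
            tables[f"pca_loadings_{gene}"] = write_table(
                loadings, outdir / f"pca_loadings_{gene}.tsv", index=True)
            for i, v in enumerate(res.variance_explained):
                summary_rows.append({"gene": gene, "component": f"PC{i + 1}",
                                     "variance_fraction": float(v)})
        if summary_rows:
            tables["pca_summary"] = write_table(pd.DataFrame(summary_rows),
                                                outdir / "pca_summary.tsv")

    _stage("pca")(do_pca)

    # ---- k-means in CAI space --------------------------------------------
    kmeans_result = {}

    def do_kmeans():
        if len(profiles) < 2:
            manifest["skipped"]["kmeans"] = "needs at least 2 genes"
            return
        cai_table = pd.DataFrame(
            {f"CAI_{gene}": {sp: p.cai for sp, p in profiles[gene].items()}
             for gene in profiles}).loc[species]
        if cai_table.isna().any().any() or len(cai_table) < config.k:
            manifest["skipped"]["kmeans"] = (
                f"needs {config.k}+ species with complete CAI pairs")
            return
        res = kmeans_cai(cai_table, k=config.k, n_starts=config.n_starts,
                         seed=config.seed)
        kmeans_result["result"] = res
        out = cai_table.copy()
        out["cluster"] = res.assignments
        out.index.name = "species"
        tables["kmeans_assignments"] = write_table(
            out, outdir / "kmeans_assignments.tsv", index=True)
        manifest["kmeans"] = {"k": res.k, "n_starts": res.n_starts,
                              "seed": res.seed, "inertia": res.inertia}

    _stage("kmeans")(do_kmeans)

    # ---- plots ------------------------------------------------------------
    def do_plots():
        if not config.make_plots:
            return
        from . import plotting
        taxonomy = (_load_two_col_tsv(config.taxonomy_tsv)
                    if config.taxonomy_tsv else None)
        plotdir = outdir / "plots"
        plotdir.mkdir(exist_ok=True)
        plotting.plot_all(
            plotdir, metrics_df=metrics_df, mean_rscu_path=tables.get("mean_rscu"),
            pca_results=pca_results, kmeans_result=kmeans_result.get("result"),
            pr2_path=tables.get("pr2"), code=code, taxonomy=taxonomy,
            highlight=config.highlight_species)

    _stage("plots")(do_plots)

    for name, path in tables.items():
        df = read_table(path)
        manifest["stages"].setdefault("rows", {})[name] = len(df)
    _write_manifest(outdir, manifest, tables)
    return RunResult(outdir=outdir, tables=tables, manifest=manifest,
                     profiles=profiles)


def _write_manifest(outdir: Path, manifest: dict, tables: dict[str, Path]) -> None:
    manifest["outputs"] = {k: str(v) for k, v in tables.items()}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
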