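"""Synthetic multi-species CDS collections with controllable codon bias.

The generator emulates the statistical structure of a cross-species,
two-gene CDS dataset so that every pipeline stage is testable offline:

* per-gene third-position composition (an AT-leaning gene vs a
  GC-leaning gene), set by ``gc3_target``;
* bias strength, set by the concentration ``kappa`` — within each
  synonymous family codon c gets weight

      w(c) ∝ exp(kappa * (log p(base3(c)) + tiny per-codon tiebreak))

  with p(G) = p(C) = t/2 and p(A) = p(T) = (1−t)/2 for target t.
  kappa = 0 gives uniform synonymous usage (ENC → 61); kappa = 1
  reproduces the target composition in expectation (exactly so for
  every family except the threefold Ile box); large kappa collapses
  each family onto a single codon (ENC → 20);
* realistic length variation and per-species jitter of the composition
  target (``interspecies_sd``).

Sequences start with ATG, contain no internal stop, and end with a
terminal stop, so they pass the screening filters by construction.
``inject_defects`` then corrupts records on purpose (ambiguous base,
internal stop, frameshift) to exercise those filters, returning a
manifest that should match the QC report one-to-one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCodeTable, standard_table
from .io_qc import CodingSequence, validate_cds

__all__ = [
    "GeneSpec",
    "SyntheticCollectionSpec",
    "SyntheticCollection",
    "DefectRates",
    "VERTEBRATE_AA_FREQS",
    "vertebrate_demo_spec",
    "family_codon_probs",
    "generate_gene",
    "generate_collection",
    "inject_defects",
    "neutrality_cloud",
    "cai_blobs",
]

_AAS = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate average vertebrate protein amino-acid composition.
VERTEBRATE_AA_FREQS: dict[str, float] = {
    "A": 0.070, "R": 0.055, "N": 0.040, "D": 0.050, "C": 0.022,
    "Q": 0.044, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.044,
    "L": 0.099, "K": 0.058, "M": 0.022, "F": 0.037, "P": 0.061,
    "S": 0.083, "T": 0.054, "W": 0.011, "Y": 0.027, "V": 0.060,
}


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters for one gene across the collection."""

    gene_id: str
    length_codons_mean: float = 1500.0
    length_codons_sd: float = 150.0
    gc3_target: float = 0.5
    bias_concentration: float = 1.0  # kappa
    interspecies_sd: float = 0.0
    aa_frequencies: Mapping[str, float] | None = None  # None -> uniform over 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc3_target <= 1.0:
            raise ValueError("gc3_target must lie in [0, 1]")
        if self.bias_concentration < 0:
            raise ValueError("bias_concentration must be >= 0")
        if self.length_codons_mean < 30:
            raise ValueError("mean length must be at least 30 codons")
        if self.aa_frequencies is not None:
            total = sum(self.aa_frequencies.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"aa_frequencies must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticCollectionSpec:
    n_species: int
    genes: tuple[GeneSpec, ...]
    seed: int = 0

    def species_ids(self) -> list[str]:
        return [f"species{i + 1:02d}" for i in range(self.n_species)]


def vertebrate_demo_spec(n_species: int = 49, seed: int = 0,
                         length_codons_mean: float = 1500.0) -> SyntheticCollectionSpec:
    """The default study conditions: 49 species, an AT-leaning gene
    (gc3 target 0.31) and a GC-leaning gene (0.68), vertebrate-like
    amino-acid composition, mild interspecies jitter."""
    common = dict(length_codons_mean=length_codons_mean,
                  length_codons_sd=length_codons_mean / 10,
                  bias_concentration=1.0, interspecies_sd=0.02,
                  aa_frequencies=VERTEBRATE_AA_FREQS)
    return SyntheticCollectionSpec(
        n_species=n_species,
        genes=(GeneSpec(gene_id="geneAT", gc3_target=0.31, **common),
               GeneSpec(gene_id="geneGC", gc3_target=0.68, **common)),
        seed=seed)


def family_codon_probs(family: Sequence[str], gc3: float, kappa: float,
                       ) -> np.ndarray:
    """Within-family codon probabilities of the generative model."""
    t = min(max(gc3, 1e-6), 1 - 1e-6)
    base_p = {"G": t / 2, "C": t / 2, "A": (1 - t) / 2, "T": (1 - t) / 2}
    # the index-dependent term breaks ties at large kappa so that each
    # family has a unique preferred codon (ENC -> 20 limit)
    logits = np.array([kappa * (math.log(base_p[c[2]]) + i * 1e-3)
                       for i, c in enumerate(family)])
    w = np.exp(logits - logits.max())
    return w / w.sum()


def _sample_raw_gene(spec: GeneSpec, species_id: str, rng: np.random.Generator,
                     code: GeneticCodeTable) -> tuple[str, float]:
    """Draw one raw CDS (ATG ... terminal stop); returns (seq, gc3 used)."""
    gc3 = spec.gc3_target
    if spec.interspecies_sd > 0:
        gc3 = float(np.clip(gc3 + rng.normal(0.0, spec.interspecies_sd), 0.01, 0.99))
    n_codons = max(30, int(round(rng.normal(spec.length_codons_mean,
                                            spec.length_codons_sd))))
    if spec.aa_frequencies is None:
        aa_p = np.full(len(_AAS), 1.0 / len(_AAS))
    else:
        aa_p = np.array([spec.aa_frequencies[a] for a in _AAS])
        aa_p = aa_p / aa_p.sum()

    fam_probs = {aa: family_codon_probs(code.families[aa], gc3,
                                        spec.bias_concentration)
                 for aa in code.families}
    body_aas = rng.choice(list(_AAS), size=n_codons - 1, p=aa_p)
    codons = ["ATG"]
    for aa in body_aas:
        fam = code.families[aa]
        codons.append(fam[rng.choice(len(fam), p=fam_probs[aa])])
    codons.append("TAA")
    return "".join(codons), gc3


def generate_gene(spec: GeneSpec, species_id: str, rng: np.random.Generator,
                  code: GeneticCodeTable | None = None) -> CodingSequence:
    """Generate one validated CDS for one species (terminal stop trimmed)."""
    code = code or standard_table()
    raw, _ = _sample_raw_gene(spec, species_id, rng, code)
    clean, reason, had_stop, has_atg = validate_cds(raw, code)
    assert reason is None, f"generated sequence failed QC: {reason}"
    return CodingSequence(species_id=species_id, gene_id=spec.gene_id,
                          sequence=clean, record_id=f"{species_id}|{spec.gene_id}",
                          had_terminal_stop=had_stop, starts_with_atg=has_atg)


@dataclass
class SyntheticCollection:
    """A generated multi-species collection plus its ground truth."""

    spec: SyntheticCollectionSpec
    raw_records: dict[str, list[tuple[str, str]]]  # gene -> [(record_id, raw_seq)]
    ground_truth: pd.DataFrame  # species, gene, gc3_used, kappa, n_codons

    def coding_sequences(self, gene_id: str) -> list[CodingSequence]:
        out = []
        for rec_id, raw in self.raw_records[gene_id]:
            clean, reason, had_stop, has_atg = validate_cds(raw)
            assert reason is None
            species = rec_id.split("|")[0]
            out.append(CodingSequence(species_id=species, gene_id=gene_id,
                                      sequence=clean, record_id=rec_id,
                                      had_terminal_stop=had_stop,
                                      starts_with_atg=has_atg))
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write per-gene FASTA, ground_truth.tsv and a spec echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for gene_id, records in self.raw_records.items():
            path = outdir / f"{gene_id}.fasta"
            seq_records = [SeqRecord(Seq(seq), id=rec_id, description="")
                           for rec_id, seq in records]
            SeqIO.write(seq_records, str(path), "fasta")
            paths[gene_id] = path
        gt_path = outdir / "ground_truth.tsv"
        self.ground_truth.to_csv(gt_path, sep="\t", index=False)
        paths["ground_truth"] = gt_path
        echo = outdir / "collection_spec.txt"
        with open(echo, "w") as fh:
            fh.write(f"n_species\t{self.spec.n_species}\n")
            fh.write(f"seed\t{self.spec.seed}\n")
            for g in self.spec.genes:
                fh.write(f"gene\t{g.gene_id}\tgc3_target={g.gc3_target}\t"
                         f"kappa={g.bias_concentration}\t"
                         f"length_mean={g.length_codons_mean}\t"
                         f"length_sd={g.length_codons_sd}\t"
                         f"interspecies_sd={g.interspecies_sd}\n")
        paths["spec"] = echo
        return paths


def generate_collection(spec: SyntheticCollectionSpec,
                        code: GeneticCodeTable | None = None,
                        ) -> SyntheticCollection:
    """Generate the full collection, bit-reproducible from ``spec.seed``.

    Each (species, gene) pair draws from its own deterministic RNG
    substream, so adding species or genes never perturbs the others.
    """
    code = code or standard_table()
    raw_records: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for gi, gene in enumerate(spec.genes):
        records: list[tuple[str, str]] = []
        for si, species in enumerate(spec.species_ids()):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(gi, si)))
            raw, gc3_used = _sample_raw_gene(gene, species, rng, code)
            records.append((f"{species}|{gene.gene_id}", raw))
            rows.append({"species": species, "gene": gene.gene_id,
                         "gc3_used": gc3_used,
                         "kappa": gene.bias_concentration,
                         "n_codons": len(raw) // 3 - 1})
        raw_records[gene.gene_id] = records
    return SyntheticCollection(spec=spec, raw_records=raw_records,
                               ground_truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefectRates:
    """Per-record probabilities; at most one defect is applied per
    record so the manifest maps one-to-one onto QC rejection reasons."""

    ambiguous_base: float = 0.0
    internal_stop: float = 0.0
    frameshift: float = 0.0

    def total(self) -> float:
        return self.ambiguous_base + self.internal_stop + self.frameshift


#: defect type -> the QC rejection reason it must trigger
DEFECT_TO_REASON = {
    "ambiguous_base": "ambiguous-base",
    "internal_stop": "internal-stop",
    "frameshift": "length-not-multiple-of-3",
}


def inject_defects(records: Sequence[tuple[str, str]], rates: DefectRates,
                   seed: int = 0) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Corrupt raw FASTA records at the given rates.

    Returns the (possibly corrupted) records and a manifest with one
    row per injected defect (record_id, defect, expected QC reason).
    """
    if rates.total() > 1.0:
        raise ValueError("defect rates sum to more than 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    manifest_rows = []
    for rec_id, seq in records:
        u = rng.random()
        if u < rates.ambiguous_base:
            defect = "ambiguous_base"
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "N" + seq[pos + 1:]
        elif u < rates.ambiguous_base + rates.internal_stop:
            defect = "internal_stop"
            n_codons = len(seq) // 3
            # replace a body codon (never the start or the last two slots)
            pos = int(rng.integers(1, max(2, n_codons - 2)))
            seq = seq[:3 * pos] + "TAA" + seq[3 * (pos + 1):]
        elif u < rates.total():
            defect = "frameshift"
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + seq[pos + 1:]
        else:
            out.append((rec_id, seq))
            continue
        out.append((rec_id, seq))
        manifest_rows.append({"record_id": rec_id, "defect": defect,
                              "expected_reason": DEFECT_TO_REASON[defect]})
    manifest = pd.DataFrame(manifest_rows,
                            columns=["record_id", "defect", "expected_reason"])
    return out, manifest


# ---------------------------------------------------------------------------
# numeric fixtures for diagnostics and clustering
# ---------------------------------------------------------------------------

def neutrality_cloud(slope: float, n: int = 49, noise_sd: float = 0.01,
                     intercept: float | None = None,
                     gc3_range: tuple[float, float] = (0.25, 0.75),
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A (GC3, GC12) point cloud with a planted regression slope."""
    rng = np.random.default_rng(seed)
    if intercept is None:
        intercept = 0.45 - slope * 0.5  # keep GC12 near a plausible 0.45
    gc3 = rng.uniform(*gc3_range, size=n)
    gc12 = intercept + slope * gc3 + rng.normal(0.0, noise_sd, size=n)
    return gc3, np.clip(gc12, 0.0, 1.0)


def cai_blobs(centers: Sequence[tuple[float, float]], sd: float = 0.05,
              n_per_cluster: int = 16, seed: int = 0,
              columns: tuple[str, str] = ("CAI_geneAT", "CAI_geneGC"),
              ) -> tuple[pd.DataFrame, pd.Series]:
    """Planted Gaussian clusters in two-gene CAI space.

    Returns the species × 2 CAI table and the true labels (1-based).
    """
    rng = np.random.default_rng(seed)
    rows, labels, idx = [], [], []
    for ci, (cx, cy) in enumerate(centers, start=1):
        for j in range(n_per_cluster):
            rows.append([cx + rng.normal(0, sd), cy + rng.normal(0, sd)])
            labels.append(ci)
            idx.append(f"c{ci}_sp{j + 1:02d}")
    table = pd.DataFrame(rows, index=idx, columns=list(columns))
    return table, pd.Series(labels, index=idx, name="true_cluster")
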