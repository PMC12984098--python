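"""Per-gene codon usage statistics.

Implements the index set used in cross-species codon bias studies:

* codon counts and relative synonymous codon usage (RSCU),
* nucleotide composition indices — overall GC, positional GC1/GC2/GC3,
  GC12, GC3s, and the silent-site base frequencies A3s/T3s/C3s/G3s,
* Wright's effective number of codons (ENC, a.k.a. Nc), and
* the codon adaptation index (CAI) in the Sharp–Li formulation.

Conventions follow the CodonW lineage of tools. In particular the
"3s" base frequencies use the silent-site convention: for base X the
denominator is the number of synonymous codons whose family offers an
X-ending synonym, not all synonymous codons — so the four values need
not sum to 1.

Degenerate inputs (an amino acid never observed, a gene of only Met and
Trp) yield NaN plus an explicit entry in the profile's ``flags``; they
are never silently reported as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetic_code import STOP, GeneticCodeTable, standard_table
from .io_qc import CodingSequence

logger = logging.getLogger(__name__)

__all__ = [
    "CodonCountTable",
    "RscuProfile",
    "CompositionIndices",
    "EncResult",
    "ReferenceWeights",
    "GeneCodonProfile",
    "count_codons",
    "rscu",
    "composition",
    "enc",
    "cai",
    "profile_gene",
    "metrics_table",
    "get_reference",
    "list_references",
]

_BASES = "TCAG"


# ---------------------------------------------------------------------------
# codon counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonCountTable:
    """Observed counts over the 61 sense codons of one CDS."""

    counts: Mapping[str, int]
    total_codons: int

    def family_counts(self, code: GeneticCodeTable, aa: str) -> list[int]:
        return [self.counts[c] for c in code.families[aa]]


def count_codons(cds: CodingSequence, code: GeneticCodeTable | None = None) -> CodonCountTable:
    """Tally sense-codon usage of a validated CDS (terminal stop already trimmed)."""
    code = code or standard_table()
    counts = dict.fromkeys(code.sense_codons, 0)
    for codon in cds.codons:
        counts[codon] += 1
    return CodonCountTable(counts=counts, total_codons=cds.n_codons)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RscuProfile:
    """RSCU over the 59 synonymous-analysis codons.

    RSCU_ij = X_ij / ((1/N_i) * sum_j X_ij) for codon j of amino acid i
    with N_i synonymous codons. Amino acids never observed have NaN
    entries and appear in ``undefined_aas``.
    """

    rscu: Mapping[str, float]
    family_size: Mapping[str, int]
    undefined_aas: frozenset[str]


def rscu(counts: CodonCountTable, code: GeneticCodeTable | None = None) -> RscuProfile:
    code = code or standard_table()
    values: dict[str, float] = {}
    fam_size: dict[str, int] = {}
    undefined: set[str] = set()
    for aa, fam in code.multi_codon_families.items():
        total = sum(counts.counts[c] for c in fam)
        for c in fam:
            fam_size[c] = len(fam)
            if total == 0:
                values[c] = math.nan
            else:
                values[c] = counts.counts[c] / (total / len(fam))
        if total == 0:
            undefined.add(aa)
    return RscuProfile(rscu=values, family_size=fam_size,
                       undefined_aas=frozenset(undefined))


# ---------------------------------------------------------------------------
# composition indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionIndices:
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float
    gc12: float
    flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {"A3s": self.a3s, "T3s": self.t3s, "C3s": self.c3s,
                "G3s": self.g3s, "GC": self.gc, "GC1": self.gc1,
                "GC2": self.gc2, "GC3": self.gc3, "GC3s": self.gc3s,
                "GC12": self.gc12}


def _gc_fraction(bases: str) -> float:
    return sum(1 for b in bases if b in "GC") / len(bases) if bases else math.nan


def composition(cds: CodingSequence, code: GeneticCodeTable | None = None) -> CompositionIndices:
    """Compute GC, positional GC, GC3s and the silent-site X3s frequencies.

    X3s: for base X, the numerator counts synonymous codons ending in X
    and the denominator counts synonymous codons whose family contains
    an X-ending codon; Met, Trp and stops are excluded everywhere.
    """
    code = code or standard_table()
    seq = cds.sequence
    codons = cds.codons
    flags: set[str] = set()

    gc = _gc_fraction(seq)
    pos = ["".join(c[i] for c in codons) for i in range(3)] if codons else ["", "", ""]
    gc1, gc2, gc3 = (_gc_fraction(p) for p in pos)
    gc12 = (gc1 + gc2) / 2

    # family -> set of third bases available synonymously
    fam_third = {aa: {c[2] for c in fam} for aa, fam in code.multi_codon_families.items()}
    syn_codons = [c for c in codons if code.codon_to_aa[c] != STOP
                  and len(code.families[code.codon_to_aa[c]]) >= 2]
    x3s: dict[str, float] = {}
    if not syn_codons:
        flags.update({"GC3s", "A3s", "T3s", "C3s", "G3s"})
        x3s = dict.fromkeys(_BASES, math.nan)
        gc3s = math.nan
    else:
        for base in _BASES:
            num = sum(1 for c in syn_codons if c[2] == base)
            den = sum(1 for c in syn_codons
                      if base in fam_third[code.codon_to_aa[c]])
            x3s[base] = num / den if den else math.nan
            if den == 0:
                flags.add(f"{base}3s")
        gc3s = sum(1 for c in syn_codons if c[2] in "GC") / len(syn_codons)

    return CompositionIndices(
        a3s=x3s["A"], t3s=x3s["T"], c3s=x3s["C"], g3s=x3s["G"],
        gc=gc, gc1=gc1, gc2=gc2, gc3=gc3, gc3s=gc3s, gc12=gc12,
        flags=frozenset(flags))


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncResult:
    """ENC with its per-degeneracy-class mean homozygosities.

    ``partial`` marks genes where a whole degeneracy class had no usable
    family (its term is dropped rather than rescaled); ``value`` is NaN
    when no family has two or more observations.
    """

    value: float
    f_bar: Mapping[int, float]
    partial: bool = False

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


#: codons contributed by each degeneracy class to Wright's formula
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(counts: CodonCountTable, code: GeneticCodeTable | None = None) -> EncResult:
    """Wright's ENC: 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6.

    For a family with n observed codons and usage proportions p_i,
    F = (n·Σp_i² − 1)/(n − 1); families with n ≤ 1 are excluded from
    their class mean. An empty threefold class (Ile unobserved) is
    imputed as the mean of F̄2 and F̄4; any other empty class drops its
    term and flags the result partial. Values are capped at 61.
    """
    code = code or standard_table()
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.multi_codon_families.items():
        fam_counts = counts.family_counts(code, aa)
        n = sum(fam_counts)
        if n <= 1:
            continue
        s = sum((x / n) ** 2 for x in fam_counts)
        f_by_class[len(fam)].append((n * s - 1) / (n - 1))

    f_bar: dict[int, float] = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if not f_bar:
        return EncResult(value=math.nan, f_bar={}, partial=True)
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2  # Wright's imputation for Ile

    partial = False
    value = 2.0
    for k, weight in _CLASS_WEIGHT.items():
        fk = f_bar.get(k)
        if fk is None or fk <= 0:
            partial = True
            continue
        value += weight / fk
    return EncResult(value=min(value, 61.0), f_bar=f_bar, partial=partial)


# ---------------------------------------------------------------------------
# CAI and reference weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w per codon, max 1 within each family."""

    name: str
    w: Mapping[str, float]
    provenance: str = ""

    @classmethod
    def from_counts(cls, name: str, counts: Mapping[str, float],
                    code: GeneticCodeTable | None = None,
                    provenance: str = "") -> "ReferenceWeights":
        """Build weights from reference codon counts/frequencies.

        w_ij = X_ij / max_j X_ij within each family; codons unobserved
        in the reference get the Sharp–Li small-value convention
        0.5 / max_j X_ij.
        """
        code = code or standard_table()
        w: dict[str, float] = {}
        for aa, fam in code.families.items():
            fam_counts = [float(counts.get(c, 0.0)) for c in fam]
            top = max(fam_counts)
            if top <= 0:
                raise ValueError(f"reference has no usage for amino acid {aa}")
            for c, x in zip(fam, fam_counts):
                w[c] = (x if x > 0 else 0.5) / top
        return cls(name=name, w=w, provenance=provenance)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "ReferenceWeights":
        """Load a two-column TSV (codon, w); '#' lines are provenance."""
        prov_lines: list[str] = []
        w: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    prov_lines.append(line.lstrip("# "))
                    continue
                codon, value = line.split("\t")[:2]
                if codon.lower() == "codon":
                    continue
                w[codon.upper()] = float(value)
        return cls(name=name or str(path), w=w, provenance="\n".join(prov_lines))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.provenance:
                for line in self.provenance.splitlines():
                    fh.write(f"# {line}\n")
            fh.write("codon\tw\n")
            for codon in sorted(self.w):
                fh.write(f"{codon}\t{self.w[codon]:.6g}\n")


# Relative adaptiveness of the highly expressed Escherichia coli
# reference gene set in the Sharp-Li formulation (values transcribed
# from the standard published table, rounded). This mirrors the default
# built into the CodonW lineage; CAI is reference-dependent and should
# be read in a relative sense across species computed with one table.
_ECOLI_W = {
    "TTT": 0.296, "TTC": 1.0, "TTA": 0.020, "TTG": 0.020,
    "CTT": 0.042, "CTC": 0.037, "CTA": 0.007, "CTG": 1.0,
    "ATT": 0.185, "ATC": 1.0, "ATA": 0.003, "ATG": 1.0,
    "GTT": 1.0, "GTC": 0.066, "GTA": 0.495, "GTG": 0.221,
    "TCT": 1.0, "TCC": 0.744, "TCA": 0.077, "TCG": 0.017,
    "AGT": 0.085, "AGC": 0.410,
    "CCT": 0.070, "CCC": 0.012, "CCA": 0.135, "CCG": 1.0,
    "ACT": 0.965, "ACC": 1.0, "ACA": 0.076, "ACG": 0.099,
    "GCT": 1.0, "GCC": 0.122, "GCA": 0.586, "GCG": 0.424,
    "TAT": 0.239, "TAC": 1.0,
    "CAT": 0.291, "CAC": 1.0, "CAA": 0.124, "CAG": 1.0,
    "AAT": 0.051, "AAC": 1.0, "AAA": 1.0, "AAG": 0.253,
    "GAT": 0.434, "GAC": 1.0, "GAA": 1.0, "GAG": 0.259,
    "TGT": 0.5, "TGC": 1.0, "TGG": 1.0,
    "CGT": 1.0, "CGC": 0.356, "CGA": 0.004, "CGG": 0.004,
    "AGA": 0.004, "AGG": 0.002,
    "GGT": 1.0, "GGC": 0.724, "GGA": 0.010, "GGG": 0.019,
}

# Genome-wide human synonymous codon usage fractions (rounded to two
# decimals); weights are derived as fraction / family max.
_HUMAN_FRACTIONS = {
    "TTT": 0.45, "TTC": 0.55, "TTA": 0.07, "TTG": 0.13,
    "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.41,
    "ATT": 0.36, "ATC": 0.48, "ATA": 0.16, "ATG": 1.0,
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.11, "GTG": 0.47,
    "TCT": 0.18, "TCC": 0.22, "TCA": 0.15, "TCG": 0.06,
    "AGT": 0.15, "AGC": 0.24,
    "CCT": 0.28, "CCC": 0.33, "CCA": 0.27, "CCG": 0.11,
    "ACT": 0.24, "ACC": 0.36, "ACA": 0.28, "ACG": 0.12,
    "GCT": 0.26, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11,
    "TAT": 0.43, "TAC": 0.57,
    "CAT": 0.41, "CAC": 0.59, "CAA": 0.25, "CAG": 0.75,
    "AAT": 0.46, "AAC": 0.54, "AAA": 0.42, "AAG": 0.58,
    "GAT": 0.46, "GAC": 0.54, "GAA": 0.42, "GAG": 0.58,
    "TGT": 0.45, "TGC": 0.55, "TGG": 1.0,
    "CGT": 0.08, "CGC": 0.19, "CGA": 0.11, "CGG": 0.21,
    "AGA": 0.20, "AGG": 0.20,
    "GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25,
}


def _builtin_references() -> dict[str, ReferenceWeights]:
    ecoli = ReferenceWeights(
        name="ecoli",
        w=dict(_ECOLI_W),
        provenance=("Sharp-Li relative adaptiveness of the highly expressed "
                    "E. coli reference gene set (transcribed, rounded); the "
                    "classic default of CodonW-style CAI."))
    human = ReferenceWeights.from_counts(
        "human", _HUMAN_FRACTIONS,
        provenance=("Genome-wide human synonymous codon usage fractions "
                    "(rounded); w = fraction / family max."))
    return {"ecoli": ecoli, "human": human}


def list_references() -> list[str]:
    return sorted(_builtin_references())


def get_reference(name: str) -> ReferenceWeights:
    """Look up a built-in reference table by name ('ecoli' or 'human')."""
    refs = _builtin_references()
    try:
        return refs[name]
    except KeyError:
        raise KeyError(f"unknown reference table {name!r}; "
                       f"available: {sorted(refs)}") from None


def cai(counts: CodonCountTable, ref: ReferenceWeights,
        code: GeneticCodeTable | None = None) -> float:
    """Codon adaptation index: geometric mean of w over codon
    occurrences, excluding ATG and TGG (single-codon amino acids)."""
    code = code or standard_table()
    log_sum = 0.0
    n = 0
    for codon in code.synonymous_codons:
        x = counts.counts[codon]
        if x == 0:
            continue
        w = ref.w.get(codon)
        if w is None:
            continue  # codon undefined in the reference: skipped per convention
        log_sum += x * math.log(max(w, 1e-4))
        n += x
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# per-gene bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneCodonProfile:
    """All metrics for one (species, gene) CDS, computed once."""

    species_id: str
    gene_id: str
    counts: CodonCountTable
    rscu: RscuProfile
    comp: CompositionIndices
    enc: EncResult
    cai: float
    cai_reference: str
    flags: frozenset[str] = frozenset()

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {"species": self.species_id, "gene": self.gene_id}
        comp = self.comp.as_dict()
        row.update({"T3s": comp["T3s"], "C3s": comp["C3s"], "A3s": comp["A3s"],
                    "G3s": comp["G3s"], "CAI": self.cai, "ENC": self.enc.value,
                    "GC3s": comp["GC3s"], "GC": comp["GC"], "GC1": comp["GC1"],
                    "GC2": comp["GC2"], "GC3": comp["GC3"], "GC12": comp["GC12"]})
        return row


def profile_gene(cds: CodingSequence, ref: ReferenceWeights,
                 code: GeneticCodeTable | None = None) -> GeneCodonProfile:
    """Compute the full metric bundle for one CDS.

    Undefined components surface as NaN values plus entries in
    ``flags`` — never as silent zeros.
    """
    code = code or standard_table()
    counts = count_codons(cds, code)
    prof = rscu(counts, code)
    comp = composition(cds, code)
    enc_res = enc(counts, code)
    cai_val = cai(counts, ref, code)

    flags: set[str] = set(comp.flags)
    if prof.undefined_aas:
        flags.add("rscu-undefined:" + ",".join(sorted(prof.undefined_aas)))
    if math.isnan(enc_res.value):
        flags.add("enc-undefined")
    elif enc_res.partial:
        flags.add("enc-partial")
    if math.isnan(cai_val):
        flags.add("cai-undefined")
    if flags:
        logger.warning("%s/%s: flagged metrics: %s",
                       cds.species_id, cds.gene_id, ", ".join(sorted(flags)))
    return GeneCodonProfile(
        species_id=cds.species_id, gene_id=cds.gene_id, counts=counts,
        rscu=prof, comp=comp, enc=enc_res, cai=cai_val,
        cai_reference=ref.name, flags=frozenset(flags))


def metrics_table(profiles: Iterable[GeneCodonProfile]) -> pd.DataFrame:
    """Tabulate profiles: one row per (species, gene), index columns."""
    rows = [p.as_row() for p in profiles]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["gene", "species"]).reset_index(drop=True)
    return df
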