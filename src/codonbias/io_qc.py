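"""CDS input and quality screening.

Reads per-gene multi-species FASTA files and applies the screening
filters used for cross-species codon analyses: length divisible by
three, no ambiguous bases, no internal stop codon. A terminal stop, if
present, is recorded and trimmed so that downstream codon statistics run
on sense codons only. For species with several passing transcripts the
longest is kept (ties broken by lexicographic record id), and only
species present for every gene are retained.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

from Bio import SeqIO

from .genetic_code import GeneticCodeTable, normalize_sequence, standard_table

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "Rejection",
    "QcReport",
    "QC_CHECK_ORDER",
    "validate_cds",
    "read_cds_fasta",
    "select_transcript",
    "pair_species",
    "default_species_parser",
    "EmptyIntersectionError",
]

# Fixed evaluation order; the first failing check is the recorded reason.
QC_CHECK_ORDER = ("length-not-multiple-of-3", "ambiguous-base", "internal-stop")


class EmptyIntersectionError(RuntimeError):
    """No species carries all genes — the cross-species analysis is empty."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated protein-coding sequence for one species and gene.

    ``sequence`` holds sense codons only: a terminal stop present in the
    input is trimmed and remembered via ``had_terminal_stop``.
    """

    species_id: str
    gene_id: str
    sequence: str
    record_id: str = ""
    had_terminal_stop: bool = False
    starts_with_atg: bool = True

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.sequence[i:i + 3] for i in range(0, len(self.sequence), 3))

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass(frozen=True)
class Rejection:
    record_id: str
    species_id: str
    reason: str
    length_nt: int


@dataclass
class QcReport:
    """Per-file accounting: every input record is passed or rejected."""

    gene_id: str
    n_input: int = 0
    n_passed: int = 0
    rejections: list[Rejection] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    duplicates_resolved: list[str] = field(default_factory=list)

    def reason_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rej in self.rejections:
            out[rej.reason] = out.get(rej.reason, 0) + 1
        return out

    def check(self) -> None:
        assert self.n_passed + len(self.rejections) == self.n_input


def default_species_parser(header: str) -> str:
    """Extract a species id from a FASTA header.

    Takes the first ``|``-separated field of the record id and
    normalizes spaces to underscores, so headers like
    ``Sus_scrofa|CD2AP description`` or plain ``Sus_scrofa`` both work.
    """
    return header.split("|")[0].strip().replace(" ", "_")


def validate_cds(seq: str, code: GeneticCodeTable | None = None,
                 ) -> tuple[str | None, str | None, bool, bool]:
    """Apply the screening filters to one raw sequence.

    Returns ``(clean_sequence, reason, had_terminal_stop, starts_with_atg)``;
    ``clean_sequence`` is None when a filter fails, and ``reason`` is the
    first failing check in :data:`QC_CHECK_ORDER`.
    """
    code = code or standard_table()
    seq = normalize_sequence(seq)
    if len(seq) == 0 or len(seq) % 3 != 0:
        return None, "length-not-multiple-of-3", False, False
    if any(b not in "ACGT" for b in seq):
        return None, "ambiguous-base", False, False
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    had_terminal_stop = code.is_stop(codons[-1])
    body = codons[:-1] if had_terminal_stop else codons
    if any(code.is_stop(c) for c in body):
        return None, "internal-stop", had_terminal_stop, False
    return "".join(body), None, had_terminal_stop, bool(body) and body[0] == "ATG"


def read_cds_fasta(
    path,
    gene_id: str,
    species_name_parser: Callable[[str], str] = default_species_parser,
    code: GeneticCodeTable | None = None,
) -> tuple[list[CodingSequence], QcReport]:
    """Read one gene's FASTA and return passing records plus a QC report.

    Records failing a filter are rejected with the first failing reason;
    a missing ATG start is only a logged warning (reference CDSs
    occasionally use non-AUG starts).
    """
    code = code or standard_table()
    report = QcReport(gene_id=gene_id)
    passed: list[CodingSequence] = []
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("FASTA %s contains no records", path)
        report.warnings.append(f"empty FASTA: {path}")
    for rec in records:
        report.n_input += 1
        species = species_name_parser(rec.id)
        raw = str(rec.seq)
        clean, reason, had_stop, has_atg = validate_cds(raw, code)
        if reason is not None:
            report.rejections.append(
                Rejection(record_id=rec.id, species_id=species,
                          reason=reason, length_nt=len(raw)))
            continue
        if not has_atg:
            msg = f"{rec.id}: CDS does not start with ATG"
            logger.warning(msg)
            report.warnings.append(msg)
        passed.append(CodingSequence(
            species_id=species, gene_id=gene_id, sequence=clean,
            record_id=rec.id, had_terminal_stop=had_stop,
            starts_with_atg=has_atg))
        report.n_passed += 1
    report.check()
    return passed, report


def select_transcript(records: Sequence[CodingSequence]) -> CodingSequence:
    """Pick one transcript per species: longest CDS, ties broken by the
    lexicographically smallest record id."""
    if not records:
        raise ValueError("no passing records to select from")
    return min(records, key=lambda r: (-r.length_nt, r.record_id))


def dedupe_by_species(
    records: Iterable[CodingSequence], report: QcReport | None = None,
) -> dict[str, CodingSequence]:
    """Collapse multiple transcripts per species via :func:`select_transcript`."""
    by_species: dict[str, list[CodingSequence]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)
    out: dict[str, CodingSequence] = {}
    for species in sorted(by_species):
        recs = by_species[species]
        chosen = select_transcript(recs)
        if len(recs) > 1 and report is not None:
            dropped = sorted(r.record_id for r in recs if r is not chosen)
            report.duplicates_resolved.append(
                f"{species}: kept {chosen.record_id}, dropped {','.join(dropped)}")
        out[species] = chosen
    return out


def pair_species(
    *gene_records: dict[str, CodingSequence],
) -> tuple[list[str], list[set[str]]]:
    """Intersect species across genes.

    Returns the sorted species list present for every gene and, per
    gene, the orphan species present for that gene only.
    """
    if not gene_records:
        raise ValueError("need at least one gene record set")
    common = set(gene_records[0])
    for recs in gene_records[1:]:
        common &= set(recs)
    if not common:
        raise EmptyIntersectionError("no species has all genes")
    orphans = [set(recs) - common for recs in gene_records]
    for i, orph in enumerate(orphans):
        if orph:
            logger.warning("gene set %d: %d species without a partner gene: %s",
                           i, len(orph), ", ".join(sorted(orph)))
    return sorted(common), orphans
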