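"""Standard genetic code tables and synonymous-family structure.

Everything downstream (RSCU, ENC, CAI, composition indices) is defined on
top of the synonymous codon families of the standard nuclear code:
61 sense codons, 3 stop codons (TAA, TAG, TGA), and the 59-codon
"synonymous analysis" set obtained by dropping the two single-codon amino
acids (ATG/Met and TGG/Trp).

The DNA alphabet (T, not U) is used throughout; ``normalize_sequence``
maps RNA input onto it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP",
    "GeneticCodeTable",
    "standard_table",
    "normalize_sequence",
    "InvalidCodonError",
]

#: Symbol used for the three translation terminators.
STOP = "*"

_BASES = "TCAG"


class InvalidCodonError(ValueError):
    """Raised for codons outside the A/C/G/T triplet space."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA (U) onto DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCodeTable:
    """The standard nuclear genetic code with its degeneracy structure.

    Attributes
    ----------
    codon_to_aa
        All 64 codons mapped to a one-letter amino acid or ``STOP``.
    families
        Amino acid -> ordered tuple of its synonymous codons.
    stop_codons, sense_codons
        The 3 terminators and the 61 coding codons.
    synonymous_codons
        The 59 codons used in RSCU-based analyses: sense codons minus
        ATG and TGG.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...]
    synonymous_codons: tuple[str, ...]
    _codon_family_index: Mapping[str, int] = field(repr=False, default=None)

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; returns ``STOP`` for TAA/TAG/TGA.

        Raises
        ------
        InvalidCodonError
            If the codon is not a triplet over A/C/G/T (after
            normalization of case and U->T).
        """
        codon = normalize_sequence(codon)
        aa = self.codon_to_aa.get(codon)
        if aa is None:
            raise InvalidCodonError(f"not a valid DNA codon: {codon!r}")
        return aa

    def family_of(self, codon: str) -> tuple[str, int, int]:
        """Return (amino acid, family size, index within the family).

        The index is the codon's position in the family's canonical
        TCAG ordering. Stop codons are a domain error here.
        """
        aa = self.translate_codon(codon)
        if aa == STOP:
            raise InvalidCodonError(f"{codon!r} is a stop codon, has no synonymous family")
        fam = self.families[aa]
        return aa, len(fam), fam.index(normalize_sequence(codon))

    def degeneracy_class(self, aa: str) -> int:
        """Family size of an amino acid: 1, 2, 3, 4 or 6."""
        return len(self.families[aa])

    def is_stop(self, codon: str) -> bool:
        return normalize_sequence(codon) in self.stop_codons

    @property
    def multi_codon_families(self) -> dict[str, tuple[str, ...]]:
        """Families of size >= 2 (the 18 amino acids entering RSCU/ENC)."""
        return {aa: fam for aa, fam in self.families.items() if len(fam) >= 2}

    def fourfold_boxes(self) -> dict[str, tuple[str, ...]]:
        """Fourfold-degenerate codon boxes: quartets sharing their first
        two bases and coding one amino acid.

        Includes the fourfold sub-boxes of the sixfold families (CTN,
        CGN, TCN), giving 8 boxes; this is the codon set of the Sueoka
        PR2 convention.
        """
        boxes: dict[str, tuple[str, ...]] = {}
        prefixes = {c[:2] for c in self.sense_codons}
        for pre in sorted(prefixes):
            quartet = tuple(pre + b for b in _BASES)
            aas = {self.codon_to_aa[c] for c in quartet}
            if len(aas) == 1 and STOP not in aas:
                boxes[pre] = quartet
        return boxes


@lru_cache(maxsize=1)
def standard_table() -> GeneticCodeTable:
    """Build the standard-code :class:`GeneticCodeTable` (cached)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    codon_to_aa: dict[str, str] = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                if codon in bio.stop_codons:
                    codon_to_aa[codon] = STOP
                else:
                    codon_to_aa[codon] = bio.forward_table[codon]

    families: dict[str, list[str]] = {}
    # canonical TCAG codon order within families
    for codon, aa in codon_to_aa.items():
        if aa != STOP:
            families.setdefault(aa, []).append(codon)
    order = {b1 + b2 + b3: i for i, (b1, b2, b3) in enumerate(
        (x, y, z) for x in _BASES for y in _BASES for z in _BASES)}
    fam_frozen = {aa: tuple(sorted(cods, key=order.__getitem__))
                  for aa, cods in families.items()}

    sense = tuple(sorted(
        (c for c, aa in codon_to_aa.items() if aa != STOP), key=order.__getitem__))
    synonymous = tuple(c for c in sense if c not in ("ATG", "TGG"))
    return GeneticCodeTable(
        codon_to_aa=codon_to_aa,
        families=fam_frozen,
        stop_codons=frozenset(bio.stop_codons),
        sense_codons=sense,
        synonymous_codons=synonymous,
    )
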