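"""Favored and optimal codon identification.

Favored codons are those with mean RSCU > 1 across all species.
Optimal codons are detected by contrasting a high-bias group (the g
species with the lowest ENC) against a low-bias group (the g highest):
a codon is optimal when

    ΔRSCU = mean RSCU(high) − mean RSCU(low) > threshold   (default 0.08)

and additionally mean RSCU(high) > 1 and mean RSCU(low) < 1.
Group means average per-species RSCU values, not pooled counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import GeneticCodeTable, standard_table

logger = logging.getLogger(__name__)

__all__ = [
    "FavoredCodonSummary",
    "OptimalCodonReport",
    "stratify_by_enc",
    "mean_rscu",
    "favored_codons",
    "optimal_codon_scan",
]


@dataclass(frozen=True)
class FavoredCodonSummary:
    """Codons with mean RSCU > 1, partitioned by their third base."""

    codons: tuple[str, ...]
    by_third_base: Mapping[str, tuple[str, ...]]

    @property
    def n(self) -> int:
        return len(self.codons)

    def third_base_fraction(self, bases: str) -> float:
        """Fraction of favored codons ending in any of ``bases``."""
        if not self.codons:
            return float("nan")
        hit = sum(len(self.by_third_base.get(b, ())) for b in bases)
        return hit / self.n


@dataclass
class OptimalCodonReport:
    """Per-codon ΔRSCU scan plus the configuration that produced it."""

    table: pd.DataFrame  # codon, amino_acid, third_base, rscu_high, rscu_low, delta_rscu, favored, optimal
    high_bias_species: tuple[str, ...]
    low_bias_species: tuple[str, ...]
    delta_threshold: float
    group_size: int

    @property
    def optimal(self) -> tuple[str, ...]:
        sub = self.table[self.table["optimal"]]
        return tuple(sub["codon"])


def stratify_by_enc(enc_by_species: Mapping[str, float], g: int = 5,
                    ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split species into (high-bias, low-bias) groups of size g.

    High bias = the g lowest-ENC species, low bias = the g highest;
    ties at a boundary are broken by lexicographic species id. Species
    with undefined ENC are excluded beforehand.
    """
    defined = {sp: v for sp, v in enc_by_species.items() if not np.isnan(v)}
    if len(defined) < 2 * g:
        raise ValueError(
            f"need at least {2 * g} species with defined ENC, have {len(defined)}")
    ascending = sorted(defined, key=lambda sp: (defined[sp], sp))
    descending = sorted(defined, key=lambda sp: (-defined[sp], sp))
    high = tuple(ascending[:g])
    low = tuple(descending[:g])
    if set(high) & set(low):
        raise ValueError("high- and low-bias groups overlap; too few species")
    return high, low


def mean_rscu(rscu_by_species: pd.DataFrame,
              species: Sequence[str] | None = None) -> pd.Series:
    """Column-wise mean RSCU over (a subset of) species, ignoring NaN.

    ``rscu_by_species`` is species (rows) × codons (columns).
    """
    sub = rscu_by_species if species is None else rscu_by_species.loc[list(species)]
    return sub.mean(axis=0, skipna=True)


def favored_codons(mean_rscu_values: Mapping[str, float] | pd.Series,
                   ) -> FavoredCodonSummary:
    """Codons whose mean RSCU exceeds 1, grouped by third base."""
    series = pd.Series(mean_rscu_values, dtype=float)
    chosen = tuple(sorted(series.index[series > 1.0]))
    by_base: dict[str, tuple[str, ...]] = {}
    for base in "TCAG":
        group = tuple(c for c in chosen if c.endswith(base))
        if group:
            by_base[base] = group
    return FavoredCodonSummary(codons=chosen, by_third_base=by_base)


def optimal_codon_scan(rscu_by_species: pd.DataFrame,
                       groups: tuple[Sequence[str], Sequence[str]],
                       delta_threshold: float = 0.08,
                       code: GeneticCodeTable | None = None,
                       ) -> OptimalCodonReport:
    """Score every synonymous-analysis codon with the ΔRSCU criterion.

    NaN RSCU entries inside a group (amino acid unobserved in that
    species) are excluded from that group's mean and logged. The
    returned table is sorted by ΔRSCU descending.
    """
    code = code or standard_table()
    high, low = (tuple(groups[0]), tuple(groups[1]))
    n_nan = int(rscu_by_species.loc[list(high) + list(low)].isna().sum().sum())
    if n_nan:
        logger.warning("%d undefined RSCU entries excluded from group means", n_nan)

    high_mean = mean_rscu(rscu_by_species, high)
    low_mean = mean_rscu(rscu_by_species, low)
    all_mean = mean_rscu(rscu_by_species)

    rows = []
    for codon in code.synonymous_codons:
        h, lo = float(high_mean.get(codon, np.nan)), float(low_mean.get(codon, np.nan))
        delta = h - lo
        rows.append({
            "codon": codon,
            "amino_acid": code.codon_to_aa[codon],
            "third_base": codon[2],
            "rscu_high": h,
            "rscu_low": lo,
            "delta_rscu": delta,
            "favored": bool(all_mean.get(codon, np.nan) > 1.0),
            "optimal": bool(delta > delta_threshold and h > 1.0 and lo < 1.0),
        })
    table = (pd.DataFrame(rows)
             .sort_values("delta_rscu", ascending=False, kind="mergesort")
             .reset_index(drop=True))
    return OptimalCodonReport(table=table, high_bias_species=high,
                              low_bias_species=low,
                              delta_threshold=delta_threshold,
                              group_size=len(high))
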