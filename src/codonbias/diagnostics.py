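"""Evolutionary-force diagnostics across species.

Four complementary views on what shapes synonymous codon usage:

* **PR2** — third-position parity, y = A3/(A3+T3) against x = G3/(G3+C3);
  under strand-symmetric mutation with no selection both are 0.5.
* **ENC–GC3s** — observed ENC against Wright's composition-only
  expectation ENC_exp(S) = 2 + S + 29/(S² + (1−S)²) with S = GC3s;
  points below the curve indicate bias beyond composition.
* **Neutrality** — OLS of GC12 on GC3; slope near 1 means third-position
  composition propagates to positions 1–2 (mutation dominance), slope
  near 0 means positions 1–2 are selectively constrained.
* **ENC–CAI regression and Pearson correlation matrices** among indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCodeTable, standard_table
from .io_qc import CodingSequence
from .metrics import GeneCodonProfile

__all__ = [
    "Pr2Point",
    "RegressionResult",
    "pr2_point",
    "pr2_table",
    "enc_expected",
    "enc_gc3s_deviation",
    "neutrality_regression",
    "enc_cai_regression",
    "correlation_matrix",
]


@dataclass(frozen=True)
class Pr2Point:
    """One species' PR2 coordinates; ``defined`` is False when a
    denominator vanished (point excluded from plots)."""

    x: float  # G3/(G3+C3)
    y: float  # A3/(A3+T3)
    species_id: str = ""
    gene_id: str = ""
    defined: bool = True


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.slope)


def pr2_point(cds: CodingSequence, code: GeneticCodeTable | None = None,
              codon_set: str = "fourfold") -> Pr2Point:
    """Third-position base parity for one CDS.

    ``codon_set`` selects the codons whose third positions are tallied:
    ``"fourfold"`` (default, the Sueoka convention — fourfold-degenerate
    boxes only, including the NNx sub-boxes of the sixfold families) or
    ``"all"`` (all synonymous codons).
    """
    code = code or standard_table()
    if codon_set == "fourfold":
        eligible = {c for box in code.fourfold_boxes().values() for c in box}
    elif codon_set == "all":
        eligible = set(code.synonymous_codons)
    else:
        raise ValueError(f"codon_set must be 'fourfold' or 'all', got {codon_set!r}")

    tally = dict.fromkeys("ACGT", 0)
    for codon in cds.codons:
        if codon in eligible:
            tally[codon[2]] += 1
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    if at == 0 or gc == 0:
        return Pr2Point(x=math.nan, y=math.nan, species_id=cds.species_id,
                        gene_id=cds.gene_id, defined=False)
    return Pr2Point(x=tally["G"] / gc, y=tally["A"] / at,
                    species_id=cds.species_id, gene_id=cds.gene_id)


def pr2_table(cdss: Iterable[CodingSequence],
              code: GeneticCodeTable | None = None,
              codon_set: str = "fourfold") -> pd.DataFrame:
    rows = []
    for cds in cdss:
        p = pr2_point(cds, code, codon_set)
        rows.append({"species": p.species_id, "gene": p.gene_id,
                     "G3/(G3+C3)": p.x, "A3/(A3+T3)": p.y, "defined": p.defined})
    return pd.DataFrame(rows)


def enc_expected(s: float) -> float:
    """Wright's composition-only ENC expectation at GC3s = s.

    ENC_exp = 2 + s + 29 / (s² + (1−s)²), defined for s in [0, 1].
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2)


def enc_gc3s_deviation(profiles: Iterable[GeneCodonProfile]) -> pd.DataFrame:
    """Per-species deviation of observed ENC from the expected-ENC curve.

    Returns columns species, gene, GC3s, ENC_obs, ENC_exp, deviation
    (obs − exp); rows with undefined ENC or GC3s carry NaN.
    """
    rows = []
    for p in profiles:
        s, obs = p.comp.gc3s, p.enc.value
        exp = enc_expected(s) if not math.isnan(s) else math.nan
        rows.append({"species": p.species_id, "gene": p.gene_id,
                     "GC3s": s, "ENC_obs": obs, "ENC_exp": exp,
                     "deviation": obs - exp})
    return pd.DataFrame(rows)


def _ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3 or np.ptp(x) == 0:
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, n)
    fit = stats.linregress(x, y)
    return RegressionResult(slope=fit.slope, intercept=fit.intercept,
                            r=fit.rvalue, r_squared=fit.rvalue ** 2, n=n)


def neutrality_regression(gc3: Sequence[float], gc12: Sequence[float]) -> RegressionResult:
    """OLS of GC12 on GC3 across species (the neutrality plot fit)."""
    return _ols(gc3, gc12)


def enc_cai_regression(cai_values: Sequence[float], enc_values: Sequence[float]) -> RegressionResult:
    """OLS of ENC on CAI across species; r measures overall association."""
    return _ols(cai_values, enc_values)


DEFAULT_CORRELATION_VARS = ("A3s", "T3s", "C3s", "G3s", "ENC", "CAI", "GC", "GC3s")


def correlation_matrix(table: pd.DataFrame,
                       variables: Sequence[str] = DEFAULT_CORRELATION_VARS,
                       ) -> pd.DataFrame:
    """Pearson correlation matrix among index columns of a per-species
    table; constant columns yield NaN rows/columns (flagged by NaN)."""
    sub = table.loc[:, list(variables)].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 species for correlations")
    corr = sub.corr(method="pearson")
    # pandas leaves the diagonal of a constant column at 1; flag it fully
    for col in variables:
        if sub[col].nunique(dropna=True) <= 1:
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
    return corr
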