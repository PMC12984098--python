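"""Naive reference implementations used as independent oracles.

These are deliberately plain re-derivations of each definition (loops,
closed forms, eigendecompositions) kept separate from the package's
code paths.
"""

from __future__ import annotations

import math

import numpy as np


def rscu_oracle(counts: dict[str, int], families: dict[str, tuple[str, ...]]
                ) -> dict[str, float]:
    out: dict[str, float] = {}
    for aa, fam in families.items():
        if len(fam) < 2:
            continue
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = math.nan if total == 0 else counts.get(c, 0) * len(fam) / total
    return out


def enc_oracle(counts: dict[str, int], families: dict[str, tuple[str, ...]]
               ) -> float:
    """Wright's Nc assembled step by step from its definition."""
    per_class: dict[int, list[float]] = {}
    for aa, fam in families.items():
        k = len(fam)
        if k < 2:
            continue
        ns = [counts.get(c, 0) for c in fam]
        n = sum(ns)
        if n <= 1:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        per_class.setdefault(k, []).append((n * sum_p2 - 1.0) / (n - 1.0))
    fbar = {k: sum(v) / len(v) for k, v in per_class.items()}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    nc = 2.0
    for k, codons_contributed in ((2, 9), (3, 1), (4, 5), (6, 3)):
        if k in fbar and fbar[k] > 0:
            nc += codons_contributed / fbar[k]
    return min(nc, 61.0)


def cai_oracle(counts: dict[str, int], w: dict[str, float],
               synonymous_codons: tuple[str, ...]) -> float:
    logs = []
    for codon in synonymous_codons:
        x = counts.get(codon, 0)
        wi = w.get(codon)
        if x == 0 or wi is None:
            continue
        logs.extend([math.log(max(wi, 1e-4))] * x)
    return math.exp(sum(logs) / len(logs)) if logs else math.nan


def composition_oracle(seq: str, families: dict[str, tuple[str, ...]],
                       codon_to_aa: dict[str, str]) -> dict[str, float]:
    """Brute-force per-position tallies of every composition index."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    gc_all = sum(1 for b in seq if b in "GC") / len(seq)
    gc_pos = []
    for i in range(3):
        bases = [c[i] for c in codons]
        gc_pos.append(sum(1 for b in bases if b in "GC") / len(bases))
    syn = [c for c in codons
           if codon_to_aa[c] != "*" and len(families[codon_to_aa[c]]) >= 2]
    out = {"GC": gc_all, "GC1": gc_pos[0], "GC2": gc_pos[1], "GC3": gc_pos[2],
           "GC12": (gc_pos[0] + gc_pos[1]) / 2,
           "GC3s": sum(1 for c in syn if c[2] in "GC") / len(syn)}
    for base in "TCAG":
        num = sum(1 for c in syn if c[2] == base)
        den = 0
        for c in syn:
            fam = families[codon_to_aa[c]]
            if any(fc[2] == base for fc in fam):
                den += 1
        out[f"{base}3s"] = num / den if den else math.nan
    return out


def pr2_oracle(seq: str, eligible: set[str]) -> tuple[float, float]:
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    thirds = [c[2] for c in codons if c in eligible]
    a, t = thirds.count("A"), thirds.count("T")
    g, c = thirds.count("G"), thirds.count("C")
    return g / (g + c), a / (a + t)


def ols_oracle(x, y) -> tuple[float, float, float]:
    """(slope, intercept, r) from the textbook covariance formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    sxx = ((x - x.mean()) ** 2).sum()
    syy = ((y - y.mean()) ** 2).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean(), sxy / math.sqrt(sxx * syy)


def pearson_matrix_oracle(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            out[i, j] = ols_oracle(X[:, i], X[:, j])[2]
    return out


def pca_oracle(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(scores, loadings, variance_fractions) via eigendecomposition of
    the sample covariance of the column-centered matrix."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = Xc @ vecs
    return scores, vecs, vals / vals.sum()
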