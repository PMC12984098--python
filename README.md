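# codonbias

Cross-species codon usage bias analysis for protein-coding sequences.

Synonymous codons are not used at random: mutation pressure shapes the
base composition of silent third positions, while translational
selection can favor codons matched to the tRNA pool. `codonbias` is a
library and CLI pipeline for quantifying and dissecting this bias for
one or more genes across a panel of species — the typical setting of
comparative molecular-evolution studies that contrast, say, an
AT-leaning and a GC-leaning immune gene across vertebrates. It is
aimed at researchers who have per-gene CDS FASTA files (one record per
species) and want the full standard analysis without stitching
together CodonW, R scripts and spreadsheets.

## What it computes

For each species × gene CDS (after QC screening: length divisible by
three, no ambiguous bases, no internal stop; terminal stop trimmed):

- **RSCU** — relative synonymous codon usage,
  `RSCU_ij = X_ij / ((1/N_i) Σ_j X_ij)` for codon *j* of amino acid *i*
  with *N_i* synonymous codons; stop codons and the single-codon amino
  acids (Met, Trp) are excluded, leaving 59 codons.
- **Composition indices** — GC, GC1/GC2/GC3, GC12 = (GC1+GC2)/2, GC3s,
  and the silent-site base frequencies A3s/T3s/C3s/G3s (CodonW
  convention; the four values need not sum to 1).
- **ENC** (effective number of codons, Wright) —
  `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` with per-family
  homozygosity `F = (nΣp² − 1)/(n − 1)`; range 20 (maximal bias) to 61
  (no bias).
- **CAI** (codon adaptation index, Sharp–Li) — geometric mean of
  relative adaptiveness weights *w*; reference-dependent, two built-in
  tables (`ecoli`, `human`) plus TSV loading.

Across species it then runs the standard diagnostics and multivariate
summaries:

- **PR2** parity plots, y = A3/(A3+T3) vs x = G3/(G3+C3) at
  fourfold-degenerate sites (or all synonymous sites);
- **ENC–GC3s** with Wright's expected curve
  `ENC_exp = 2 + S + 29/(S² + (1−S)²)` and per-species deviations;
- **neutrality regression** of GC12 on GC3 (slope ≈ 1: mutation
  dominance; ≈ 0: selective constraint on positions 1–2);
- **ENC–CAI regression** and Pearson **correlation matrices**;
- **favored codons** (mean RSCU > 1) and **optimal codons** by the
  ΔRSCU contrast between the five lowest-ENC and five highest-ENC
  species (`ΔRSCU > 0.08`, high-group mean > 1, low-group mean < 1);
- **PCA** of the species × 59-codon RSCU matrix with loading distance
  `d = √(loading_PC1² + loading_PC2²)` per codon;
- **k-means** (k = 3, 100 restarts) of species in standardized
  two-gene CAI space.

A synthetic CDS generator produces multi-species two-gene collections
with controllable third-position composition and bias strength, so the
whole pipeline is testable without any sequence download.

## Worked example

Simulate a 49-species collection with an AT-leaning gene (GC3s target
0.31) and a GC-leaning gene (0.68), then run the full pipeline:

```sh
codonbias simulate -o data --n-species 49 --length 1500 --seed 1
codonbias run --fasta geneAT=data/geneAT.fasta \
              --fasta geneGC=data/geneGC.fasta -o out --seed 1
```

or in Python:

```python
from codonbias import (vertebrate_demo_spec, generate_collection,
                       PipelineConfig, run_pipeline, read_table)

spec = vertebrate_demo_spec(n_species=49, seed=1)
paths = generate_collection(spec).write("data")
res = run_pipeline(PipelineConfig(
    fasta_by_gene={g: paths[g] for g in ("geneAT", "geneGC")},
    outdir="out", seed=1))
print(read_table(res.tables["metrics_summary"])
      .set_index("gene")[["GC3s_mean", "ENC_mean", "CAI_mean"]])
```

which prints (seed 1):

```
        GC3s_mean   ENC_mean  CAI_mean
gene
geneAT   0.307440  53.871345  0.189196
geneGC   0.672963  54.274148  0.213772
```

The two genes recover their planted third-position composition
(GC3s ≈ 0.31 vs ≈ 0.67) while showing comparable overall bias strength
(ENC ≈ 54 for both) — composition, not bias intensity, separates them.
`out/` then contains the QC report, per-species metrics, mean-RSCU and
favored/optimal codon tables, PR2/ENC–GC3s/neutrality/ENC–CAI tables
and regressions, PCA scores/loadings, k-means assignments, plots, and
a run manifest (config hash, input hashes, seed) sufficient to
reproduce the run bit-exactly.

Note on CAI: absolute values depend on the reference table (default
`ecoli`, the classic Sharp–Li highly-expressed set); interpret them
relatively across species computed with one table.

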