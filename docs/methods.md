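# Methods notes

This note records the statistical conventions, defaults and design
choices behind `codonbias`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Genetic code and codon sets

All analyses use the standard nuclear code (built from Biopython's
table 1) on the DNA alphabet; RNA input is normalized U→T. Three codon
sets recur:

- 61 sense codons (counting);
- 59 synonymous-analysis codons — sense minus ATG and TGG — for RSCU,
  ΔRSCU, PCA;
- 8 fourfold-degenerate boxes (the five fourfold families plus the
  CTN/CGN/TCN quartets of the sixfold families) for the default PR2
  coordinates.

No alternative genetic codes are supported: the intended inputs are
vertebrate nuclear CDSs.

## QC screening

Checks run in a fixed order — length divisible by three, then
ambiguous bases, then internal stops — so a record failing several
checks always reports the same single reason. A terminal stop codon is
trimmed, not treated as an error, because reference CDS records
conventionally include it while all downstream statistics are defined
on sense codons. A missing ATG start is a warning only (some reference
CDSs use non-AUG starts). "Best transcript" per species is
operationalized as the longest passing CDS, ties broken by
lexicographic record id; annotation completeness is not recoverable
from FASTA alone. Species enter the cross-species analyses only if
they have a passing CDS for every gene.

## Composition indices

GC1/GC2/GC3 are positional G+C fractions over all codons. GC3s
restricts to synonymous codons (Met, Trp, stops excluded). The
silent-site base frequencies X3s (X ∈ {A,T,C,G}) follow the CodonW
convention: the numerator counts synonymous codons ending in X, and
the denominator counts synonymous codons whose family *offers* an
X-ending synonym. Because the denominators differ per base, the four
values are not a partition and their sum typically exceeds 1; a unit
test asserts this on a random gene. GC12 is the arithmetic mean of GC1
and GC2. Degenerate inputs (e.g. a Met/Trp-only sequence) yield NaN
plus an explicit flag, never a silent zero.

## ENC

Wright's estimator with the customary handling of sparse data:
families with ≤ 1 observation are excluded from their degeneracy-class
mean; an empty threefold class (Ile unobserved) is imputed as the mean
of the two- and fourfold class means; any other empty class — or a
class mean ≤ 0, which extreme sampling can produce — drops its term
and marks the estimate `partial` rather than rescaling. Estimates are
capped at 61, since sampling noise can push the raw value above the
theoretical maximum.

## CAI

Sharp–Li formulation: the geometric mean of relative adaptiveness w
over all occurrences of the 59 synonymous-analysis codons. Two named
reference tables ship in-source — `ecoli` (the classic Sharp–Li
highly-expressed E. coli weights, transcribed and rounded) and `human`
(weights derived from rounded genome-wide human codon usage
fractions) — and any two-column TSV can be loaded. When weights are
built from reference counts, unobserved codons get 0.5/(family max)
rather than zero. Weights are floored at 1e-4 inside the log to keep
the geometric mean finite. CAI is reference-dependent; cross-species
values are comparable only within one table, and the pipeline records
the table name per profile.

## Diagnostics

Regressions are ordinary least squares (scipy), reported with Pearson
r, r², and n; fits with n < 3 or zero predictor variance are flagged
undefined. The neutrality fit regresses GC12 on positional GC3 (not
GC3s, which is reserved for the ENC–GC3s plot). The ENC–CAI fit
regresses ENC on CAI. PR2 defaults to the Sueoka fourfold-site
convention with a switch for all synonymous third positions; both
readings appear in the literature and neither is asserted as canonical.
Pearson correlation matrices mark constant columns as NaN.

## Optimal codons

Groups are the g = 5 lowest-ENC (high-bias) and g = 5 highest-ENC
(low-bias) species, ties broken by species id. Group RSCU means average
per-species RSCU values, not pooled counts, and NaN entries (amino acid
unobserved in one species) are excluded from that mean. A codon is
optimal when ΔRSCU = mean_high − mean_low > 0.08 and mean_high > 1 and
mean_low < 1; both the threshold and g are configuration values
surfaced in the report. "High-group RSCU > 1" is read as the group
mean, consistent with the ΔRSCU mean formulation.

## PCA and k-means

PCA treats species as observations and the 59 codons as variables,
column-centered but not variance-scaled by default (RSCU is already a
common scale); a scaling switch exists because reported variance
percentages depend on this choice. Signs are fixed by making each
component's largest-magnitude loading positive, so scores, loadings
and the loading distance d = √(l₁² + l₂²) are reproducible across runs
and row orders. Undefined RSCU entries are imputed with the neutral
value 1.0 (invisible after centering) and flagged; species with > 20%
undefined codons are dropped with a warning.

k-means on CAI space standardizes each gene's CAI column (mean 0,
SD 1, population denominator), then runs Lloyd's algorithm from random
partitions, 100 seeded restarts by default, keeping the lowest
within-cluster sum of squares; empty clusters are repaired by
reassigning the farthest point of the largest cluster. This variant
was implemented directly (rather than delegating to scikit-learn's
k-means++ initialization) to keep initialization, restart accounting
and empty-cluster policy explicit and bit-reproducible from one seed.

## Synthetic collections

The generator emulates the statistical structure of a two-gene,
N-species vertebrate CDS panel, not its phylogeny. Within each
synonymous family, codon c is drawn with weight
∝ exp(κ·(log p(base₃(c)) + ε·index)), where p(G) = p(C) = t/2 and
p(A) = p(T) = (1−t)/2 for the gene's GC3 target t, and ε = 10⁻³ is a
per-codon tiebreak. Properties that follow and are tested:

- κ = 0 gives uniform synonymous usage (ENC → 61);
- κ = 1 reproduces t as the expected GC3s exactly in every family
  except the threefold Ile box (whose GC fraction is t/(2−t)); with
  Ile at its vertebrate frequency the aggregate error is < 0.01;
- very large κ (≫ 1/ε) leaves a unique winner per family (ENC → 20);
- ENC is monotone non-increasing in κ and measured GC3s monotone in t.

Defaults are the study conditions the package is tested under:
49 species, genes at GC3 targets 0.31 (AT-leaning) and 0.68
(GC-leaning), mean length 1500 codons (SD 150), vertebrate-like
amino-acid frequencies, per-species jitter of t with SD 0.02, κ = 1.
Each (species, gene) pair uses its own spawned RNG substream, so
collections are bit-reproducible and extensible.

What the generator does **not** emulate: lineage structure
(species are exchangeable, so PCA finds no taxonomic clusters and
PC1/PC2 variance stays near the noise floor, unlike real panels where
shared ancestry concentrates variance), selection differences between
species (all species share κ, so high- and low-ENC groups differ only
by sampling noise and the ΔRSCU scan correctly returns an empty or
near-empty optimal set), codon-context effects, and indels. With a
fixed amino-acid profile, GC12 is essentially independent of the GC3
target (the first/second-position composition of each family barely
depends on third-base choice), so sequence-level neutrality slopes sit
near 0; planted-slope recovery (slopes 0.2 and 1.0) is therefore
tested on numeric GC3/GC12 clouds from `neutrality_cloud`. Passing
tests demonstrate correctness of the estimators and pipeline plumbing
under controlled composition/bias regimes — not that any biological
inference holds for a particular real dataset.

Defect injection applies at most one defect per record (N
substitution, internal-stop substitution, or single-base deletion),
which makes the injection manifest map one-to-one onto QC rejection
reasons — this is deliberate, to make the QC contract exactly
checkable.

## Pipeline and problem sizes

All tables are TSV with a `# columns:` schema comment and round-trip
through `read_table`; the run manifest stores the configuration and
its hash, input SHA-256 digests, package versions, seed, and per-stage
status/row counts. Stages whose preconditions fail on small inputs
(PCA < 3 species, k-means < k, optimal codons < 2g) are skipped and
recorded, not errored. The test suite and acceptance script run the
full study scale (49 species × 2 genes × ~1500 codons, a few seconds)
and smaller collections (2–12 species, 120–800 codons) for unit and
property tests; these sizes were chosen as the smallest that leave the
tested statistical signals well clear of sampling noise.

## Known limitations

- ENC/CAI conventions vary slightly between published tools
  (imputation of missing classes, zero-count weights); values here
  follow the CodonW/Wright and Sharp–Li conventions documented above
  and can differ from other implementations in the second decimal.
- The shipped CAI reference tables are rounded transcriptions;
  absolute CAI levels inherit that rounding (cross-species contrasts,
  the intended use, are unaffected).
- No phylogenetic correction: correlations and regressions across
  species treat species as independent points.
- The screening step enforces sequence-level filters only; it cannot
  judge annotation quality or isoform choice.
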