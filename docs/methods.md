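# Methods

## The rarity index

For a reference set of n species, each contributing the set S_i of distinct
k-mers observed in its genome (DNA, alphabet ACGT) or proteome (20 standard
residues), the rarity index of a k-mer K is

    I_K = |{ i : K ∉ S_i }| / n,

the fraction of species from which K is absent. I_K = 0 marks a k-mer
carried by every species; I_K = 1 marks a *prime*, a k-mer absent from the
whole reference set. The index is a per-k-mer summary of presence/absence
only: multiplicity within a genome does not enter. Internally every index is
held as an exact rational (I_K · n is an integer by construction) and
converted to float only at output boundaries, because the downstream
decimal-digit binning would otherwise be sensitive to representation error.

Typical working ranges are k = 6–12 for nucleic k-mers and k = 2–6 for
peptides: below these lengths nearly every k-mer occurs in nearly every
species (all indices ≈ 0), and above them nearly every k-mer is absent
everywhere (all indices ≈ 1), so the informative band of the spectrum moves
with k and the distribution of I shifts monotonically toward 1 as k grows.

## K-mer extraction and counting

Per species, the k-mer set is the union over FASTA records of every
length-k window consisting solely of canonical characters. Ambiguity codes
(N, X, B, Z, U, O) and stop codons (*) are flagged at load time rather than
rejected; any window overlapping a flagged position is skipped, and windows
never span record boundaries. Counting streams species one at a time, so
peak memory is one species' set plus the aggregate hash map — this bounds
each run to a single k, and the CLI is correspondingly invoked per k.
Nucleic k-mers are counted on the forward strand by default; a `canonical`
option folds each k-mer onto the lexicographic minimum of itself and its
reverse complement for strand-symmetric analyses.

Absent k-mers are implicit (count 0, index 1). Operations that need them
explicitly (prime detection, cross-scope comparison) materialize the
|alphabet|^k universe, refused above a cap of 4^12 entries so a protein
k = 6 universe (6.4 × 10^7) is never accidentally instantiated.

## Per-taxonomy tables and comparisons

Rarity is additionally computed within each taxonomy (archaea, bacteria,
eukaryota, viruses, or any labels the manifest carries), each table using
only that taxon's species count as its n. Cross-taxonomy agreement is
summarized by a Spearman rank-correlation matrix computed over the union of
k-mers observed in any compared taxon, with unobserved k-mers entering at
their implicit index 1 — the only convention under which primes remain
comparable across scopes. A zero-variance taxon yields NaN (undefined), not
zero. Taxonomy-discriminative k-mers are those with I ≥ rare_min (default
0.95) in one taxon and I ≤ common_max (default 0.5) in every other; both
thresholds are exposed because no canonical values exist for this contrast.

## Composition across the rarity spectrum

Unit frequencies ("frequency of each amino acid / dinucleotide as a
function of the rarity index") are compositional: for the k-mers at a given
rarity value, the frequency of a unit is its share of all overlapping
windows across that group (k monomer windows and k − 1 dimer windows per
k-mer), so each stratum's vector sums to 1. Enrichment between the rare
(I > high_min) and common (I < low_max) ends of the spectrum is the ratio
of these frequencies; a unit absent from the low stratum gives an infinite
fold by default, with an optional add-one pseudocount for smoothed, finite
folds (no smoothing is applied unless asked for).

Rare k-mers are defined as the top quartile by rarity index — everything at
or above the 75th percentile, ties included, which is deterministic and
inclusive. They are grouped by their index rounded half-away-from-zero to 3
decimal digits (4 for 12-mer oligonucleotides, 5 for 6-mer oligopeptides,
where the spectrum is compressed against 1). The species × bin occurrence
matrix divides the number of a bin's k-mers present in a species by that
species' total distinct k-mer count, normalizing out genome/proteome size.
Species are clustered on the rows of this matrix by average-linkage
(UPGMA) agglomeration on Euclidean distances — the defaults of the usual
clustered-heatmap tooling — with rows pre-sorted by species_id so ties
merge deterministically; the tree is exported as Newick.

## Physicochemical descriptors

Eight classical peptide descriptors form the biochemical feature space:

| descriptor | scale / model | units |
|---|---|---|
| molecular weight | average residue masses + 1 H₂O (18.0153) | Da |
| isoelectric point | bisection root of the charge curve, tol 1e-4 | pH |
| net charge | Henderson–Hasselbalch sum, EMBOSS pKa set, pH 7.0 | e |
| hydrophobicity | mean Kyte–Doolittle hydropathy (GRAVY) | — |
| hydrophobic moment | Eisenberg consensus scale, δ = 100° | — |
| Boman index | mean per-residue solubility (Boman 2003; Pro = 0) | kcal/mol |
| aliphatic index | 100·(f_A + 2.9 f_V + 3.9 (f_I + f_L)) | — |
| instability index | (10/L)·Σ Guruprasad dipeptide weights | — |

The charge model titrates both termini plus H, K, R (basic) and C, D, E, Y
(acidic) side chains; it is strictly decreasing in pH, so the isoelectric
point is its unique root (e.g. a free dialanine, with only the two termini,
has pI = (8.6 + 3.6)/2 = 6.1). Scale variants differ across published
implementations; these choices are fixed and documented so results are
reproducible, and cross-checks against other implementations are
tolerance-based (1%), not exact. The charge pH default of 7.0 is a
package choice. All descriptors except the hydrophobic moment and the
instability index are permutation-invariant in the sequence.

## Predictive models

Feature spaces: (a) sequence composition — monomer and overlapping dimer
counts of each k-mer (4 + 16 columns for DNA, 20 + 400 for protein; counts,
not frequencies, which differ only by a constant factor at fixed k); (b)
the eight physicochemical descriptors (peptides only). Models: ridge
regression with α = 0.01 and an unpenalized intercept, and a random forest
of 100 trees (unlimited depth, seeded, impurity-based importances summing
to 1). Evaluation uses a seeded 80/20 hold-out plus seeded shuffled 5-fold
cross-validation, reporting R², MAE and per-fold scores; ridge reports
signed coefficients and the forest importances, ranked with lexicographic
tie-breaks.

One numerical caveat documented deliberately: monomer counts sum to k and
dimer counts to k − 1 within every row, so the design matrix has two exact
collinear directions absorbed by the intercept. Ridge therefore identifies
coefficients only up to a per-block additive shift and returns the
minimum-norm representative — coefficient vectors whose blocks are centred
are recovered exactly; others are recovered up to that small shift. This
is a property of the feature space itself, not of the fitting code.

## Synthetic corpora

The generator draws each species' sequence from a first-order Markov chain
whose transition matrix is the row-normalized table of per-taxon dimer
weights (unspecified dimers weight 1), with the initial symbol drawn from
the stationary distribution. A first-order chain, rather than i.i.d.
letters, is used precisely so dimer-level biases — the TA-depletion and
CpG-suppression analogues that drive the real compositional signal — can
be planted and recovered. The long-run dimer law of such a chain is
π_a P(a→b) (π the stationary distribution), which row normalization does
not leave equal to the normalized weight table; `expected_unit_frequencies`
computes the correct law from a config and is what convergence tests
compare against.

The default corpus mirrors the structure of a reference-genome collection
at desk scale: viruses most numerous and shortest (12 species, 0.5–1.5 kb),
eukaryotes fewest-but-longest (6 species, 8–12 kb), bacteria TA-depleted
(10 species, 3–6 kb), archaea mildly GC/CG-enriched (4 species, 3–5 kb).
Sequence lengths of a few kb against the 4^6 universe put per-species 6-mer
coverage near 60%, the regime where presence/absence actually varies.
What the generator does *not* emulate: repeats, genes, codon structure,
phylogenetic correlation between species, or realistic genome sizes —
so passing tests demonstrate that the pipeline recovers planted
compositional structure, not that real taxa will separate as cleanly.

`planted_rarity_regression_set` samples uniform random k-mers and assigns
y = clip(0.5 + Σ coef·count + N(0, 0.02), 0, 1); the default planted map
{TA: +0.12, CC: −0.08, A: +0.04, T: −0.04} keeps the linear response inside
[0, 1] except for vanishingly rare extreme k-mers, so clipping bias is
negligible, and gives a signal-to-noise ratio around R² ≈ 0.96 at n = 5000.

## Problem sizes and determinism

Tests and the acceptance script run on corpora of 10–32 species with
sequences of 0.2–12 kb and k ≤ 10, and on regression sets of ≤ 5000 rows —
sizes at which every stage completes in seconds while leaving the
presence/absence spectrum informative. Every stochastic step (corpus
generation, train/test splits, fold shuffling, forests) is driven by an
explicit integer seed; identical config plus seed reproduces byte-identical
corpora and identical model reports.

## Known limitations

- Presence/absence only: a k-mer occurring once counts as much as one
  occurring a million times; the index deliberately ignores abundance.
- The index inherits the composition of the reference set: adding species
  changes every I_K, and taxon tables with small n are coarsely quantized
  (steps of 1/n).
- Enumeration of absent k-mers is capped; protein k ≥ 6 primes must be
  sought by streaming the complement rather than materializing it.
- Descriptor values match other software only to the extent the same scale
  variants are chosen; comparisons should be tolerance-based.
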