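# Methods

## Classification model

`gtascan` frames GTA-vs-virus discrimination as binary classification of
protein homologs with a weighted soft-margin SVM. The only departure from
the textbook soft-margin machine is the per-sample cost: the regularization
term is Σᵢ C·dᵢ·ξᵢ, so the box constraint of the dual becomes
0 ≤ αᵢ ≤ C·dᵢ. The weights dᵢ are not class-balance weights — class
imbalance (real training sets range from 12 to 1,646 viral homologs against
~60–70 GTA homologs per gene) is deliberately left uncorrected in the
optimization and is instead handled in scoring, where both classes receive
weight 0.5 in WAS. The dᵢ correct a different bias: overrepresented taxa
contribute many near-identical sequences, which would otherwise dominate
the margin. Sequences are grouped by complete-linkage clustering of their
pairwise phylogenetic distances; merging continues while the
complete-linkage distance is strictly below the threshold t, so t = 0
disables weighting even in the presence of identical sequences, and each
member of a group of size s gets dᵢ = 1/s.

### Solver

The dual QP is solved by sequential minimal optimization with first-order
maximal-violating-pair working-set selection and per-sample upper bounds,
run to a duality-gap tolerance of 1e-8 (1e-10 in oracle comparisons).
The solver is fully deterministic: no shrinking, no caching heuristics, no
randomized pivoting. The bias b is the mean over margin support vectors
(tolerance 1e-8 relative to each sample's bound C·dᵢ) of yᵢ − Σⱼ αⱼyⱼK(xⱼ,xᵢ);
when no margin support vector exists, b is the midpoint of the interval
allowed by the KKT conditions of the bound samples. Agreement with an
independent reference implementation (libsvm via scikit-learn, with
`sample_weight` producing the same per-sample bounds) is a test-suite
invariant, at 1e-4 on decision values over seeded random problems.

The kernel is linear by default. Nothing in the formulation pins a kernel;
linear is the natural choice for compositional count features, keeps the
model interpretable (w is a weight per k-mer), and is what the grid search
assumes. A Gaussian kernel is available (`kernel="rbf"`) but is not part of
the default grid. Features are not scaled before the QP; an optional
normalized k-mer mode (counts/(L−k+1)) exists but defaults to off, keeping
raw counts.

Decision rule: f(x) < 0 ⇒ GTA (y = −1), otherwise virus. An exact f(x) = 0
is labelled virus and logged; with continuous features this is a measure-zero
tie and the conservative call (not-a-GTA) is preferred.

## Features

* **k-mers** — raw counts of overlapping subsequences, k ∈ 1…6. The
  vocabulary is the lexicographically sorted union over the *training*
  sequences and is frozen into the model; query k-mers outside the
  vocabulary are ignored, missing ones are zero-filled. Prediction therefore
  never depends on the composition of the query batch.
* **PseAAC** — dimension 20 + λ, λ ∈ {3, 6}, ω = 0.05. The first 20
  components are residue counts rᵢ and the last λ are order-correlation
  factors s_k, the mean over positions of J(i, i+k) where J is the mean
  squared difference of standardized hydrophobicity, hydrophilicity and
  side-chain mass; all components share the denominator Σr + ω·Σs, so the
  vector sums to 1. Using counts rather than frequencies for rᵢ only
  rescales ω's relative influence, since the denominator normalizes either
  way. Scales are standardized to zero mean and unit root-mean-square over
  the 20 residues; a constant raw scale is rejected. The raw scale table
  ships as an editable TSV (`data/aa_scales.tsv`) carrying the classical
  PseAAC values; substituting a custom table changes the feature space, and
  serialized models record table checksums so a mismatch on reload is
  detected and warned about.
* **Physicochemical classes** — 19 overlapping residue classes
  (`data/physchem_classes.tsv`), each feature the length-normalized count
  of residues in a class. The shipped table is an in-house assembly of
  standard groupings (size, polarity, charge, chemistry, secondary-structure
  propensity, flexibility); it is editable but validated to exactly 19
  non-empty classes.

Active encoders are concatenated in fixed order: k-mer block, PseAAC block,
physchem block.

Sequences are cleaned on input to the 20-letter alphabet: ambiguity codes
(B, J, O, U, X, Z), stops and gaps are removed, not recoded, because every
feature above is defined only over canonical residues; removal counts are
logged. Coordinates are 1-based inclusive (GenBank convention) whether they
arrive in structured FASTA headers (`id|genome|replicon|start|end|strand`)
or via a BED sidecar (0-based half-open, converted on read).

## Curation

Deduplication removes exact within-class sequence duplicates (first
occurrence kept); the same sequence in both classes is kept in both and
logged as a label conflict. Outlier filtering computes, per bacterial
homolog, the mean distance o to all other bacterial homologs, flags
o > Q3 + 1.5·(Q3 − Q1) over the distribution of o values, and removes a
flagged homolog only when o also exceeds its nearest viral distance — the
rationale being that such sequences are likely re-acquisitions from the
viral side and would inject label noise. Quartiles use linear interpolation
between order statistics (the common "type 7" rule); at least 3 bacterial
sequences are required for the fence to be meaningful. Distances are
consumed from a square labelled TSV; computing them (alignment + ML
distance estimation) is outside this package, though a plain p-distance
helper over pre-aligned sequences exists for testing and is explicitly
non-canonical.

## Cross-validation and parameter selection

Stratified 5-fold splits (each class dealt round-robin after shuffling),
repeated 10 times. Stratification is a deliberate choice: with as few as 12
sequences in a class, unstratified splits can produce folds with an empty
class and undefined per-class accuracy. Per class, AAS is the mean of
fold-level accuracies over all folds and repeats; WAS = 100·(½AAS_GTA +
½AAS_virus) exactly; MCC is computed from confusion counts pooled over all
folds and repeats (pooling is stabler than averaging per-fold MCCs when a
fold contains only a handful of minority-class members; GTA is bookkept as
the positive class, which MCC's symmetry makes cosmetic). Taxonomic weights
are recomputed inside each training fold from the distance submatrix of
that fold's members, so held-out sequences never influence the weights.

The default grid crosses 41 feature combinations (at most one k, at most
one λ, physchem on/off, at least one active) with 5 C values and 7 t
values: 1,435 points. Ties at the maximal WAS are resolved by a fixed
cascade: (1) keep candidates whose k-mer size has the highest mean WAS
across all evaluated points sharing that size; (2) drop candidates using
PseAAC or physchem features unless that empties the set; (3) keep the C
with the highest mean WAS among the remaining candidates; (4) likewise for
t; any residual tie falls to the smallest (k, C, t), with "no k-mer encoder"
ordered before k = 1. Steps 3–4 average over the remaining candidate set
(for step 4 the candidates are all tied, making it a formal no-op kept for
fidelity to the cascade's statement).

## Cluster calling and abundance correction

One-dimensional density chaining per (genome, replicon): loci sorted by
start, adjacent loci linked when the intergenic gap (next.start − prev.end
− 1) is ≤ eps, maximal chains of ≥ min_size members reported. Two operating
points are exposed as constants: candidate training regions (eps = 5,000 bp,
min_size = 9) and prediction regions (eps = 8,000 bp, min_size = 6); the
looser prediction setting reflects that only 11 of the 17 head–tail genes
are classified, so gaps between detected genes can be larger. Replicons are
treated as linear — a cluster spanning the origin of a circular replicon
would be split, a known limitation. The ≥ min_size rule counts distinct
GTA-classified loci, not distinct gene families; member ids are reported
per cluster so stricter post-filters can be applied.

OTUs are connected components of the graph with edges at ANI ≥ 95 %
(single-linkage closure — two genomes linked through an intermediate fall
in one OTU even if their direct ANI is lower; the table format cannot
express a stricter rule without a full matrix). Each called cluster
contributes 1/|OTU of its genome| to its taxonomic group's corrected
abundance, so the corrected count never exceeds the raw count, with
equality iff all cluster-bearing OTUs are singletons.

## Synthetic data

The generator produces the three structures the pipeline assumes, at desk
scale, as pure functions of (parameters, seed):

* **Skewed composition profiles.** The virus profile is a Dirichlet(5·1₂₀)
  draw; the GTA profile is the same draw with Ala and Gly mass multiplied
  by (1 + 2·skew) and renormalized, emulating the observed Ala/Gly
  enrichment of GTA head–tail proteins. Sequences are i.i.d. residues from
  the profile, lengths uniform in 400–700 aa — the typical length of phage
  head–tail structural proteins (portal, terminase, major capsid), and long
  enough that 3-mer count vectors are informative at 60 sequences per class.
  Default class size is 60 + 60, matching the scale of the real per-gene
  GTA training sets.
* **Planted genomes** for cluster calling, with background gene gaps
  strictly above eps and planted within-cluster gaps ≤ eps.
* **Block distance matrices** for weighting/outlier tests, with bounded
  symmetric noise (< (inter − intra)/2) so block recovery is unambiguous.

What the fixtures do *not* emulate: positional sequence structure (i.i.d.
residues make k ≥ 2 k-mer frequencies products of marginals), phylogenetic
correlation among sequences, indel/length correlation between classes, and
circular replicons. Passing the synthetic recovery tests therefore
demonstrates that the estimator recovers a compositional signal of
realistic magnitude at realistic sample sizes — not performance on real
homolog sets, which differ in all the above ways.

## Numerical and degenerate-input conventions

* SMO duality-gap tolerance 1e-8; support-vector identification at 1e-8
  relative to each sample's bound; KKT residual |Σαᵢyᵢ| is tracked and must
  stay below 1e-6.
* MCC returns 0 when any denominator factor is zero (logged).
* Distance matrices must be symmetric within 1e-6 on read (averaged after
  the check); DistanceMatrix enforces symmetry within 1e-9, non-negativity
  and a zero diagonal.
* Complete-linkage ties are made irrelevant to the output by processing ids
  in sorted order; weighting and outlier filtering are invariant to input
  permutation.
* One-class training input, k > sequence length, λ ≥ sequence length,
  empty-after-cleaning sequences, non-square or asymmetric matrices, and
  ANI outside [0, 100] are all hard errors, not warnings.

## Known limitations

* The shipped physicochemical class table and PseAAC scale table are
  faithful in structure (19 overlapping classes; hydrophobicity/
  hydrophilicity/side-chain mass) but are this package's own data
  artifacts; models trained with different tables are not comparable, which
  is why serialized models embed table checksums.
* Exact reproduction of published per-gene WAS/MCC values for the real
  RcGTA training sets requires the original curated FASTAs and distance
  matrices as inputs; with those files in hand, the `xval` subcommand over
  the default grid is the complete recipe.
* The SMO solver targets training-set sizes in the low thousands (dense
  kernel matrix); it is not meant for corpus-scale training.
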