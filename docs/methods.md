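# Methods

## Problem and model

Pyruvoyl-dependent enzymes mature by an autocatalytic serinolysis at a
conserved serine. The predictor treats site identification as binary
classification of serine-centered peptide windows: each serine in a
protein produces one `2w+1`-residue window, padded with `X` where the
window overruns a chain end; windows at annotated pyruvoyl serines are
positives, every other serine window is a negative. Serines without an
annotation are assumed negative — there is no "unknown" class, which
means label noise from not-yet-characterized sites is absorbed into the
negative class. Cysteine-centered self-cleavage (as in glycine/proline
reductases) is out of scope.

Supported window lengths are any odd `2w+1 ≥ 3`; the pipeline evaluates
15, 17, 19 and 21 and resolves ties in average MCC toward the larger
window (more sequence context at equal measured performance).

## Feature encoding

A window of length `2w+1` maps to `64w + 26` features in a fixed catalog
order (family, then window offset, then detail alphabetical). Offsets are
1-based within the window; the center is offset `w+1`.

- **PSSM (20 per site).** Per-residue substitution probabilities from an
  iterative profile search. The reader consumes the PSI-BLAST ASCII
  matrix and returns the weighted-percentage block divided by 100; these
  are probabilities in [0, 1], which matches the "probability against
  mutation" reading of profile conservation. The log-odds block is
  available behind a switch for users who prefer raw scores, but
  percentages are the default and what the pipeline uses.
- **Disorder (1 per site).** A propensity in [0, 1] from any per-residue
  disorder predictor.
- **Secondary structure (3 per site) and accessibility (2 per site).**
  One-hot: helix=100, strand=010, other=001; buried=10, exposed=01. Bits
  of a real residue sum to 1; padded sites contribute all zeros.
- **Atchley factors (5 per flanking site).** The embedded 20×5 constant
  table of multivariate amino-acid property scores (polarity, secondary
  structure propensity, molecular volume, codon diversity, electrostatic
  charge). The center is excluded (always serine, zero variance); `X`
  maps to zeros.
- **Positional frequency (1 per flanking site).** A per-offset symbol
  frequency table over the 21 window symbols (20 amino acids + `X`) is
  fit on the positive training windows; the feature value is the learned
  frequency of the symbol the window actually carries at that offset.
  One value per offset (not a 21-wide one-hot) keeps the catalog at
  `1·2w` for this family. Fitting on positives only is the default —
  the table then characterizes the composition around true sites, which
  is the discriminative signal; `on="all"` fits on every training window
  instead. The table is always fit on the *training* split so held-out
  evaluation never sees test-derived frequencies.

No rescaling or standardization is applied anywhere: the random forest is
scale-insensitive and the raw values keep their physical meaning.

## Feature selection

Mutual information is the plug-in (maximum-likelihood) estimate in bits
over observed cells; zero joint cells contribute nothing and no
pseudo-counts are added. Continuous features are discretized into three
levels at mean ± one standard deviation (the long-standing convention of
the original mRMR program); features with at most three distinct values —
one-hot bits in particular — pass through as categorical codes. A
constant feature keeps a single code and has zero MI with everything.

MaxRel ranks features by `D(f) = I(f; class)` descending. mRMR is greedy:
round 1 picks the MaxRel top (empty selected set, so redundancy is zero);
each later round picks the remaining feature maximizing `D(f) − R(f)`
with `R(f)` the mean MI between `f` and the selected set. All argmax ties
break toward the lower catalog index, so rankings are bit-reproducible.
The ranking is invariant to the MI logarithm base (a base change rescales
`D` and `R` by the same factor); bits are used for reporting.

IFS evaluates every prefix of the mRMR ranking with a fresh 10-tree
forest per fold under stratified 10-fold cross-validation, reusing one
fold partition across all prefix sizes so curve points are comparable.
Fold metrics are averaged per fold (not pooled), matching the convention
of reporting cross-validation measurements as the mean over the ten
repetitions; pooling would weight folds by their realized class mix. The
optimal prefix is the smallest `k` attaining the maximum cross-validated
MCC — at equal measured performance, fewer features generalize better
and read more cleanly.

## Classifier

A 10-tree random forest (scikit-learn `RandomForestClassifier` with
library defaults apart from the tree count — the original analysis used a
different implementation's defaults, so exact hyperparameter parity is
not claimed). Classification is by counting tree votes, not by averaging
leaf probabilities: the positive-vote fraction (11 possible values with
10 trees) is the ranking score for ROC curves, and an exact 5–5 tie
resolves to negative, the conservative call in a rare-positive screen.
MCC with any zero denominator factor is defined as 0 (the
"no relationship" convention extended to degenerate counts); a request
for Sn or Sp with an empty class raises rather than silently returning 0.
Reported percentages round half-up to two decimals.

## Dataset handling

With roughly one annotated site per protein and ~9 background serines,
the raw sample set is ≈1:9. Negatives are shuffled with a seeded
generator and cut into four disjoint near-equal parts (sizes differ by at
most one, larger parts first: 407 negatives → 102/102/102/101); each
balanced dataset holds all positives plus one part (≈1:2). Which part
ends up one sample short is arbitrary under shuffling, so part sizes are
meaningful as a multiset. Each dataset is split per class with a seeded
stratified rule: ⌈0.8·n⌉ of each class to training (46 positives →
37 train / 9 test). Stratification everywhere (split and CV folds)
prevents positive-free folds, which would make MCC degenerate.

## Synthetic corpus generator

The generator emulates the shape of the curated corpus the method was
designed for — 46 proteins of 110–170 residues, one annotated site each,
background composition near UniProt frequencies (~6.6% serine, giving
~400 background serines) — together with every annotation track, written
in the same file formats the real-data path reads.

Six hallmark signals are planted around each annotated serine, mirroring
what is known about self-processing sites: sharply conserved profile
columns at offsets −1 (glycine — the most common residue preceding the
nucleophile), +2 and +3; β-strand two residues upstream; buried residues
at ±1. Each site *expresses* a random 3 of the 6 hallmarks, always
including at least one conserved column (conservation is the universal
hallmark; structural context varies across enzyme families). Expressed
hallmarks are planted near-deterministically against low background
rates, so the corpus is cleanly separable once most of the planted set is
assembled — deliberately mirroring the perfectly separable character of
the real curated corpus (cross-validated MCC of exactly 1 is attainable) —
while no small feature subset covers every site. When the −1 column is
expressed, the sequence residue there is glycine with probability 0.75
(conserved columns peak at the wild-type residue). Disorder is drawn from
Beta(2, 4) background and Beta(1.7, 4.5) near sites (bounded in [0, 1]
like real disorder scores, and nearly uninformative by design). Sites are
placed in [4, L−3], so positives near chain ends acquire window padding
just as negatives do — placement deep inside the chain would otherwise
make padding itself a class giveaway.

`zero_signal()` collapses every planted probability to its background
rate, giving a null corpus for chance-level baselines.

What the generator does **not** emulate: homology between proteins (every
sequence is independent; real PSSMs correlate along the chain and across
related proteins), realistic secondary-structure segment lengths (states
are drawn per residue), annotation-tool error structure, and any coupling
between disorder, structure and composition. Passing recovery tests
therefore demonstrates that the pipeline's machinery — encoding, ranking,
prefix selection, evaluation — extracts planted signal correctly at
realistic sample sizes; it does not certify performance on real
annotation tracks.

## Problem sizes and numerical choices

Recovery experiments run one balanced dataset per corpus with window
length 17, stratified 10-fold CV, 10 trees, and the IFS scan truncated at
the first 30 mRMR rounds — the planted signal saturates within the first
ten features, and the untruncated 538-point curve adds nothing but
forest fits. Library users get the full curve by default
(`max_k=None`). Ten seeded corpora (plus ten null corpora) are used for
averaged recovery statistics. Randomness is confined to explicit integer
seeds: corpus generation, negative partitioning, the train/test split,
fold assignment and forest training are all seeded, and a fixed seed
reproduces every artifact byte for byte.

Numerical conventions collected in one place: MI in bits with plug-in
estimates and no pseudo-counts; discretization at mean ± 1σ into three
bins; argmax ties by catalog index; prediction ties to negative; MCC 0 on
degenerate denominators; smallest-k / larger-window tie rules; percentage
rounding half-up at two decimals; trapezoid-rule AUC with tied scores
grouped.

## Known limitations

- The real curated corpus requires external resources (UniProt sequences,
  a PSI-BLAST run against UniRef100, disorder and structure predictors),
  so the specific published feature lists and held-out numbers depend on
  inputs this package does not fetch; the package reproduces the
  *procedure* and verifies the published arithmetic and combinatorics.
- Exact hyperparameter parity with the original forest implementation is
  not attempted beyond the 10-tree count.
- With ~46 positives, cross-validated MCC has high fold variance; on
  plateaued IFS curves the smallest-k rule can land anywhere ties or
  noise place the maximum. This is a property of the selection rule at
  this sample size, visible in the synthetic experiments as occasional
  large optimal prefixes.
- The plug-in MI estimator is biased upward at small samples; since all
  features share the estimator and ranking is comparative, this mainly
  matters when comparing MI values across very different cardinalities.
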