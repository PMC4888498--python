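# Methods

## Problem and model

Given an aptamer (single-stranded DNA or RNA) and a candidate target protein,
predict whether the pair interacts. Each pair is encoded as a fixed-length
numeric vector built only from sequence-derived inputs; a feature selector
prunes the vector; a partition-ensemble random forest classifies it. Class
imbalance is structural — realistic pair collections carry roughly three
non-interacting pairs per interacting one — and the design choices below
follow from it.

## Feature encoders

### Pseudo K-tuple nucleotide composition (aptamers)

For K ∈ {2, 3}, the encoder combines the 4^K overlapping K-mer frequencies
f_u (lexicographic order A<C<G<T) with λ sequence-order correlation factors.
θ_j averages, over all positions i, the squared physicochemical dissimilarity
Θ_{i,i+j} between the tuples at i and i+j, where Θ is the mean squared
difference over the N per-tuple property values, standardized to mean 0 /
population sd 1 across the 4^K tuples. The joint normalization
d_u = f_u / (Σf + ωΣθ), d_{4^K+j} = ωθ_j / (Σf + ωΣθ) makes each block a
non-negative vector summing to one.

Parameters:

* **λ (per K)** — defaults to L_min − K where L_min is the minimum aptamer
  length of the corpus being encoded; with the benchmark minimum of 8 this is
  λ₂ = 6, λ₃ = 5 and a 91-dimensional aptamer block, which together with the
  563 protein features reaches the 654-feature hybrid space. λ is always
  carried as an explicit configuration value, never hard-coded, because it
  changes the feature dimension.
* **ω (weight factor)** — default 0.5, the conventional PseKNC choice;
  controls how much sequence-order signal enters relative to composition.
* **U→T mapping** — RNA and DNA aptamers share one property table; uracil is
  mapped to thymine for encoding while the original letters are kept for
  display. Whether RNA-specific property values should differ is an open
  modelling question; a single table is this package's documented choice.

Property tables ship as TSV data files and are standardized at load, so any
complete, non-degenerate table yields a valid encoder. The dinucleotide table
carries six consensus crystallographic B-DNA base-step parameters (twist,
tilt, roll, shift, slide, rise; complementary steps share twist/roll/slide/
rise with tilt and shift sign-flipped). The trinucleotide table
(`trinucleotide_properties.synthetic.tsv`) is a constructed 12-property
stand-in — step-averaged helical parameters, composition fractions, and
step-to-step parameter differences — derived deterministically from the
dinucleotide table; it fills the structural role of a published trinucleotide
physicochemical compendium and is user-replaceable via TSV.

### DCT hydropathy spectra (proteins)

The per-residue hydrophobicity (Kyte–Doolittle) and hydrophilicity
(Hopp–Woods) signals — both standardized over the 20 residues, both
user-replaceable — are transformed with the orthonormal DCT-II
(`scipy.fft.dct(norm="ortho")`, which is exactly G(k) = a(k) Σ H(p_n)
cos[(2n+1)kπ/2L] with a(0)=√(1/L), a(k>0)=√(2/L)). The first 52 coefficients
per scale are kept: 52 is the benchmark minimum protein length, so every
protein supports them. Proteins shorter than 52 residues error by default;
`pad_short` zero-pads for exploratory use. The transform is energy-preserving
(Parseval), which the tests exploit as an oracle-free identity.

### Bi-gram PSSM (proteins)

B_{m,n} = Σ_{i=1}^{L−1} P_{i→m} P_{i+1→n} over the L×20 PSI-BLAST profile,
flattened row-major to 400 features. Two normalization modes are provided
because the right choice is genuinely open: the default squashes each
log-odds entry through the logistic 1/(1+e^{−x}) (products of raw log-odds
are scale-unstable and dominated by extreme scores); `none` keeps raw values.
A protein with no detectable homologs gets a zero profile; its bi-gram block
is zero in both modes (the zero matrix is passed through untransformed under
the sigmoid mode as well, so the fallback stays a recognizable null signal
rather than acquiring a constant offset). Missing PSSM files substitute this
zero profile with a logged warning; missing disorder tracks are hard errors,
since no convention exists for them.

### Disorder descriptors (proteins)

From a per-residue disorder-score track in [0,1]: autocovariance
AC_λ = (1/(L−λ)) Σ (d_i − d̄)(d_{i+λ} − d̄) at lags 1..51 (51 = benchmark
minimum length − 1), plus eight summaries — mean, population sd (matching the
population-style 1/(L−λ) normalization of AC), counts of disorder and
non-disorder segments, and min/max lengths of each segment class. A disorder
segment is a maximal run of scores ≥ 0.5 (the usual binary convention of
disorder predictors; configurable). An absent segment class reports
min = max = 0 as an explicit sentinel.

## Feature selection

Relief assigns each feature a weight accumulated over sampled instances:
subtract the per-feature difference to the nearest same-class neighbors,
add the difference to the nearest other-class neighbors. Differences are
normalized by the feature's range over the data (zero-range features
contribute exactly 0), and inter-instance distance is the Manhattan sum of
those normalized diffs — so the ranking is invariant to affine rescaling of
any single feature. Defaults are the common ReliefF convention: 10 neighbors,
every instance sampled deterministically; `n_neighbors=1` reproduces the
original single-neighbor update and is what the brute-force oracle tests pin
down. Ties in weight keep original column order.

IFS evaluates prefixes of the ranking (sizes step, 2·step, …, plus the full
set) with a caller-supplied evaluator — canonically the partition-ensemble
cross-validation below, sharing one fold seed across prefixes so curve points
are comparable — and selects the prefix maximizing mean Youden's index,
breaking ties toward the smallest prefix (parsimony). `step` exists because a
one-by-one sweep of 654 prefixes with 10-fold CV each is expensive; the
default step=1 keeps the exact one-by-one procedure.

## Classifier and evaluation

N = ⌊n_neg/n_pos⌋ negative partitions (shuffled, sizes differing by ≤1 when N
does not divide n_neg; the exact-division case matches the plain quotient).
Each part + all positives trains one random forest; prediction averages the
base forests' positive-class probabilities, with label positive iff the
average ≥ 0.5 (ties positive, documented). For a 580/1740 training set this
gives N = 3 sub-training sets of 1160 pairs.

Random-forest hyperparameters are deliberately exposed: 500 trees and √d
features per split by default, seeded per base model from (seed, part index)
via a seed sequence. Cross-validation is stratified k-fold (k = 10 by
default): stratification keeps each fold near the global 1:3 ratio and is
the field norm even where plain random splitting would also do. Within each
training fold the partition and all base forests are rebuilt from scratch, so
no test-fold information leaks. Metrics (Sn, Sp, Acc, MCC, Youden's
J = Sn + Sp − 1) are averaged across folds; pooled-confusion-count metrics
are also returned for comparison. Undefined ratios (zero denominators) report
0 with a warning rather than NaN. Rounding happens only at reporting time
(3 decimals).

## Synthetic corpora

The generator emulates the four input kinds with a planted, tunable class
signal in all channels simultaneously, so feature-family ablations can be
exercised qualitatively:

* aptamers: first-order Markov chains; positives get transition logits tilted
  toward CG/GC and away from AT/TA steps (strength 0.7·effect_size);
* PSSMs: integer log-odds in [−10, 10] (rounded N(0, 4)); positives shift
  hydrophobic columns (I/L/V/F) up and charged columns (D/E/K/R) down by
  1.2·effect_size; a configurable fraction (default 5 %) of proteins are
  homolog-free and get zero profiles;
* disorder: a two-state ordered/disordered Markov chain (scores N(0.8, 0.1)
  vs N(0.2, 0.1), clipped); positives start disordered more often and dwell
  longer in the disordered state, with the shift saturating via tanh so
  probabilities stay valid;
* protein sequences themselves are label-independent uniform draws — the
  protein signal lives in the PSSM and disorder channels.

At effect_size = 0 every class-conditional parameter reduces to the
background, so positives and negatives are identically distributed (null
calibration: mean CV Youden within ±0.1 of 0 across seeds). Defaults are a
50/150 corpus (the 1:3 imbalance of the motivating benchmark), aptamers of
length 8–40 and proteins of 52–120 with the first pair pinned to the minimum
lengths so corpus-derived encoder parameters are fixed by configuration, and
effect_size = 1. What the generator does **not** emulate: real binding
chemistry, homology structure between proteins, sequence composition biases
of real aptamer libraries, or correlated noise across channels — so passing
tests demonstrate correctness and calibration of the pipeline, not field
performance on real corpora.

## Problem sizes used in the checks

The stochastic end-to-end checks run at reduced scale, chosen once: the
imbalance contrast uses 40/120 corpora at effect_size 0.5 (the regime where a
single forest visibly collapses to high-Sp/low-Sn) with 5-fold CV and
60-tree forests over 5 seeds; null calibration uses 30/90 corpora over 10
seeds with 50-tree forests. Fold counts and tree numbers below the defaults
trade variance for runtime without changing any qualitative conclusion;
oracle-equivalence checks run at full precision (tolerance 1e-10) on 100
random small instances per encoder.

## Known limitations

* Reproducing published benchmark performance on the real aptamer–protein
  corpus requires PSI-BLAST profiles against a protein database and VSL2
  disorder tracks for those proteins; both are consumed as files here, never
  computed, so no claim is made about real-data metrics.
* The trinucleotide property table is a constructed stand-in (see above);
  rankings of individual pse3 features should not be interpreted against
  literature property names.
* Relief weights are computed with a dense pairwise-distance pass per sampled
  instance — fine for thousands of pairs, not for millions.
* The ensemble assumes negatives are the majority class; the partitioner
  refuses inverted inputs rather than silently swapping roles.
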