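# Methods

## Classification model

`lncspect` frames plant lncRNA identification as binary classification of
transcript sequences (lncRNA vs mRNA, lncRNA positive) using three
features per transcript and a gradient-boosted tree ensemble.

**ORF coverage.** The feature convention scans the forward strand only
(assembled transcripts are sense-stranded), three frames, ATG-initiated,
stop codon required (TAA/TAG/TGA, standard code). Coverage is the longest
such ORF's length divided by transcript length. When no complete ORF
exists, the longest ATG-to-end open span stands in, so transcripts with a
truncated frame score small-but-nonzero coverage rather than an exact
zero. Nested internal ATGs never extend spans: only maximal ORFs per
frame count. A separate configuration (`ncbi_style_scan`: both strands,
75 nt minimum) mirrors NCBI ORF Finder defaults for auditing individual
transcripts; it is never used for the model feature.

**Spectral features.** A sequence is mapped to a numeric series and
Fourier-transformed. Conventions:

* unnormalized DFT, `F[k] = Σₙ x[n]·e^(−2πikn/N)`;
* descriptors computed on power `P[k] = |F[k]|²`, multi-channel mappings
  summing power across channels, so Parseval's identity holds uniformly
  as `Σₖ P[k] = N · Σ_c Σₙ |x_c[n]|²`;
* the DC bin `k = 0` is excluded from the descriptor band by default. DC
  encodes only composition sums and would dominate the range statistic.
  Both the power-vs-magnitude choice and the band are configuration
  switches; the shipped classifier is trained under the package's own
  conventions, so internal consistency — not bit-compatibility with any
  other descriptor suite — is the contract.

The two model features are the **mean** of the complex-number-mapping
spectrum and the **range (max − min)** of the atomic-number-mapping
spectrum. Both scale with transcript length (power grows with N) and the
atomic amplitude additionally responds to the period-3 codon signal,
which appears as an elevated bin near `k = N/3`.

A useful exact property: under the complex table every base has
`|x[n]|² = 2`, so by Parseval the banded mean is
`(2N² − |F[0]|²)/(N − 1)` — a function of length and base composition
only. The feature is therefore a length/composition summary, while the
atomic amplitude carries the periodicity signal; the ORF feature captures
reading-frame structure directly. The three are complementary, which is
why so small a feature set suffices.

**Encoding tables.** All per-base constants (EIIP potentials, atomic
numbers, complex/real/integer assignments) live in
`src/lncspect/data/encodings.json`, versioned and overridable at call
time. The defaults follow the conventions of the MathFeature descriptor
suite; the source literature names the encodings without printing the
constants, so the tables are flagged as auditable configuration rather
than hard-coded logic.

**Nineteen spectral descriptors** are computed per mapping (mean, median,
max, min, period-3 peak, sample/population SD, 15/25/50/75th percentiles,
range, variance, IQR, semi-IQR, coefficient of variation, skewness,
kurtosis, and the fraction of bins above the mean). The last statistic
("none_levated") reconstructs an underdocumented upstream descriptor and
is excluded from the default feature registry. The period-3 "peak" is the
power at bin `round(N/3)` of the full spectrum regardless of band.

## Auxiliary features

k-mer frequencies (k ≤ 5, counts over N−k+1 windows, per-k sums exactly
1), the Fickett TESTCODE statistic (position and content parameters
discretized through the published 1982 lookup tables, stored as data in
`src/lncspect/data/fickett.json`), and Shannon (k = 1..10) plus Tsallis
(k = 1..9, q = 2) entropies of k-mer distributions — 19 entropy features.
These families exist so the feature-selection study can *reject* them:
they carry weaker class signal than the key trio.

## Feature selection

Variance thresholding (default 0.01, population variance) removes
near-constant columns first. Five ranking methods: absolute Pearson
correlation with the 0/1 class, one-way ANOVA F (perfect separation ranks
at +inf), mutual information with deterministic 16-bin quantile
discretization (chosen over k-NN estimators to avoid hidden
stochasticity), random-forest importance (RFI: 500 trees, sqrt feature
subsampling, seed 42), and RFE wrapping the same forest, eliminating 10%
of remaining features per round and scoring by elimination round. Ties
break lexicographically, so rankings are fully deterministic given a
seed. The production protocol is RFI followed by top-k with k = 3.

## Classifier

XGBoost (`binary:logistic`, exact tree method, single thread, seeded) is
the default backend; LightGBM is supported when installed. Defaults when
no tuning is run: depth 6, 500 boosting rounds, learning rate 0.05, L2
regularization 1.0. Decision threshold 0.5, boundary counted positive.
Hyperparameter tuning is a seeded random search over depth 3–10, rounds
100–800, log-uniform learning rate 0.01–0.3 and L2 0.1–10, scored by
stratified CV AUC; configurations are drawn sequentially from one seeded
stream, so the best score is non-decreasing in budget at fixed seed.
Model bundles serialize to a single zip (booster blob + JSON metadata:
feature contract, threshold, training-set hash, seed, hyperparameters,
library versions); prediction refuses tables whose column *set* differs
from the contract and normalizes column order.

Evaluation reports the six standard metrics as percentages. AUC is the
tie-aware Mann-Whitney statistic (ties count half), identical to
trapezoidal ROC integration and to the pairwise-ordering probability,
which makes it exactly testable against a brute-force pair count.
Cross-validation is stratified, fold assignment seeded; per-fold metrics
are averaged and confusion counts summed. PCA exploration standardizes
columns and reports full-rank explained-variance fractions.

## Synthetic data generator

The generator provides labeled transcript sets with the statistical
structure the classifier exploits, standing in for curated corpora.

* **Coding-like records**: 5′UTR + ATG + stop-free codon run + stop codon
  + 3′UTR. Codons are drawn from a plant-like usage table built as the
  independence product of per-codon-position base compositions (first
  position G-rich, second A/T-rich, third T-leaning), restricted to the
  61 sense codons. Total UTR fraction ~ Beta(2, 5) (mean ≈ 0.29), split
  uniformly between ends, giving an ORF-coverage mode near 0.7. UTRs are
  drawn at background GC.
* **Noncoding-like records**: order-1 Markov chains at GC 0.43 with a
  0.30 self-transition bias; any draw whose longest complete forward ORF
  covers more than 40% of its length is rejected and resampled, so
  noncoding coverage stays low without artificial zeros.
* **Lengths**: log-normal, truncated to [200, 5000] nt, median 1600 nt
  (coding) and 600 nt (noncoding), sigma 0.5 — mRNAs are substantially
  longer than lncRNAs in real annotation sets, and the spectral features
  scale with length, so class-specific length laws are part of what makes
  them informative. A uniform codon-usage table is available as an
  alternative; note that uniform usage gives codon positions 2 and 3
  identical expected encodings, leaving the period-3 peak below the
  spectral noise floor.

Everything is deterministic given the config seed. What the generator
does **not** emulate: splicing isoforms, expression levels, sequencing
error, genuine codon-usage correlations between adjacent codons, UTR
composition structure, or the annotation noise of real corpora. Passing
recovery tests on this generator therefore demonstrates that the pipeline
detects the class signal it is built to detect — not that the quoted
metric levels transfer to any particular species' annotation.

The feature-selection toy (`generate_feature_toy`) is a separate fixture:
3 informative Gaussian columns at effect size d = 2 among N(0,1) noise
columns, balanced labels — easy by construction, so exact top-3 recovery
is a correctness check of the ranking plumbing, not a hard benchmark.

## Numerical and edge-case choices

* Sequence floor 30 nt (shortest length at which every extractor is
  defined); the conventional ≥ 200 nt lncRNA rule is not enforced, but a
  warning is logged for sub-200 nt records labeled lncRNA.
* U → T transparently; any other non-ACGT character skips the record
  (default) or raises, per policy.
* Flat spectra: skewness/kurtosis/CV are defined as 0 when the band has
  zero variance.
* Zero-variance features score 0 (not NaN) under Pearson/ANOVA/MI.
* Precision and F1 are 0 when no positive predictions exist.
* Parseval residual is asserted at 1e−6 relative; FFT agreement with the
  direct O(N²) DFT at 1e−8 relative.

## Problem sizes

The test suite and the acceptance script run on synthetic draws of 500
records/class for separation checks and 2000/class for classifier
recovery, with 100–200 random sequences for the numerical oracles —
sizes at which every distributional claim in the docs is comfortably
resolved while a full run stays around a minute.

## Known limitations

* The catboost backend named in the interface is not bundled; xgboost is
  the default implementation and lightgbm the comparator.
* Tuning is random search, not a surrogate-model Bayesian optimizer; at
  the budgets used here (tens of trials over a 4-dimensional space) random
  search is a standard, reproducible choice.
* The complex-mapping mean being composition/length-determined means that
  on corpora where lncRNAs and mRNAs have matched length distributions its
  discriminative power drops to whatever composition differences remain.
* CD-HIT-EST redundancy removal (used upstream of model training on real
  corpora, at 80% identity: `cd-hit-est -c 0.8 -n 5 -i in.fa -o out.fa`)
  is an external preprocessing step, documented here only.
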