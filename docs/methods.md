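# Methods

## Model and assumptions

`epibayes` treats linear B-cell epitope prediction as binary classification
of fixed-length peptides, followed by integration of window-level
predictions into per-residue scores on whole antigens.

The central modelling assumption, inherited by both the propensity analysis
and the bi-profile encoding, is **per-position independence**: the
information carried by the residue at position *j* is treated as
independent of the residues at other positions. A bi-profile feature
vector is exactly the vector of class-conditional marginal probabilities of
the observed residues under this independence assumption — a naive-Bayes
summary handed to a discriminative (RBF-SVM) classifier. Correlated
structure (di-peptide preferences, local motifs) is deliberately outside
the model; the synthetic generator makes the same assumption so that the
generator's parameters are exactly the quantities the analysis estimates.

## Estimators and conventions

**Position profiles.** `f(a, j) = (count(a, j) + c) / (n + 20 c)` with
pseudocount `c ≥ 0`. Matrix rows are always the 20 standard amino acids in
alphabetical order (`ACDEFGHIKLMNPQRSTVWY`); exports use this order too.

**Propensity ratios.** `P_x = f_pos / f_neg`, both frequencies with the
same pseudocount. Default pseudocount for propensity analysis is 1
(Laplace): zero counts are common at n of a few hundred per pool and raw
ratios are then undefined or infinite. With `c = 0`, a 0/0 cell is stored
as NaN ("undefined") and excluded from summary statistics; a positive
numerator over a zero denominator raises with instructions to use a
positive pseudocount. The per-position dispersion statistic is the
population standard deviation (÷20): the 20 amino acids are the complete
set, not a sample.

A practical note on calibration: `P_x` is a ratio of two noisy frequencies,
so even for identically distributed pools its mean sits slightly above 1
(Jensen's inequality on 1/f̂; at n = 2000 per pool the bias is ≈ +0.01).
Tests therefore bound the control-split mean in [1.000, 1.020], an interval
frozen from a 300-replicate sampling experiment, rather than asserting
exact unity.

**Binary encoding.** One-hot blocks are laid out reverse-alphabetically —
alanine is `[0,…,0,1]`, cysteine `[0,…,0,1,0]`. The layout carries no
information for the SVM but is fixed so encodings are bit-reproducible.

**BFE encoding.** Profiles are estimated from the training split only, and
re-estimated inside each cross-validation fold from that fold's training
portion, so a held-out peptide never contributes to the profiles used to
encode it. The default encoding pseudocount is 0 (raw frequencies); a
smoothing knob exists because at small pool sizes zero-frequency entries
make test peptides partially invisible to the positive half of the vector.
Profile objects are immutable after construction.

**Classifier.** RBF-kernel C-SVM (scikit-learn/libsvm). Grid search
maximizes mean stratified k-fold CV accuracy over
`C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` (the standard libsvm
starting grid), folds seeded and stratified by class; ties resolve to the
smallest `C`, then the smallest `γ`, so selection is deterministic. No
feature scaling is applied: binary features are already in {0,1} and BFE
features in [0,1]. The decision threshold is the SVM's natural 0; scores
are raw decision values, not probabilities.

**Metrics.** Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N, reported
as percentages; on a balanced test set Acc = (Sn+Sp)/2 exactly. AUROC uses
midrank tie handling; with a one-class truth vector it is reported as
missing, never as 0.

**Antigen scanning.** Windows advance one residue at a time; `E_p(i)` sums
the decision scores of all windows containing residue *i*. Only interior
residues covered by exactly *w* windows (positions *w* … L−w+1) are scored
by default, keeping `E_p` magnitudes comparable across positions; terminal
residues are reported as `unscored`. Partial sums at the termini are
available behind `termini="partial"`. An antigen with L < 2w−1 has an
empty interior: a warning, not an error. Accuracy against an annotation
mask is computed over scored residues only, alongside the mean `E_p` of
annotated epitope vs non-epitope residues.

## Synthetic study conditions

The generator draws every residue independently per position. Negatives
come from a background distribution (uniform by default — analytically
transparent; a natural amino-acid-frequency preset exists); positives apply
multiplicative factors to selected (residue, position) cells and
renormalize. For factor *r* on background mass *b*, the implied propensity
is `r / (1 − b + r b)` — e.g. a 2× factor on a uniform background implies
P_x = 40/21 ≈ 1.905, not 2, and recovery tests target this exact value
(interval frozen from a 200-replicate sampling experiment).

The canonical "strong enrichment" condition is **tryptophan and proline
enriched 4× at every position**. The residues mirror those reported
enriched in real epitope pools; the factor comes from an a-priori power
calculation: the count of enriched residues in a 20-mer is binomial in
each class, giving the Bayes-optimal AUROC in closed form — 0.896 at r = 3
but 0.952 at r = 4. r = 4 is therefore the weakest integer factor at which
a well-trained classifier can clear AUROC 0.9 with sampling margin, which
is what the directional BFE-vs-binary comparison requires.

Benchmark-style sizes are used throughout: 600/600 training and 200/200
independent test peptides for classifier comparisons, 2000 per pool for
propensity calibration, 5000 per pool for enrichment recovery, and
150-residue antigens with a 50-residue annotated interval for scanning.
These sizes put sampling noise well below the effects being measured while
keeping the full suite and the acceptance script in the seconds-to-minutes
range.

What the synthetic conditions do **not** emulate: homology structure
between peptides, di-peptide/motif correlations, natural length variation,
and database sampling biases of real epitope collections. Passing the
recovery suite shows the estimators and the pipeline are correct and
well-calibrated under the model's own assumptions; it does not certify
accuracy figures on real antigens, which depend on how far those
assumptions hold.

## Numerical and design choices

- Annotation coordinates are 1-based inclusive, matching residue-position
  language in the immunology literature; FASTA, plain peptide lists and
  TSV reports are the only file formats.
- Non-standard residues (B, J, O, U, X, Z, \*) are rejected by default.
  The opt-in policy keeps the letter and spreads its profile contribution
  uniformly (1/20 per residue); binary blocks become uniform 1/20 and BFE
  lookups use the column mean. Nothing is silently dropped.
- `E_p` integration is a convolution; tests compare it to an explicit
  (residue × window) double loop at atol 1e-9 (float summation order).
- All randomness flows from explicit integer seeds (`numpy` Generator;
  seeded stratified CV splits); identical seed + config gives identical
  outputs, which the CLI records in a provenance JSON per run.
- Hyperparameters used in the fixed-configuration comparisons are C = 8,
  γ = 0.5 for 40-dimensional BFE vectors and C = 8, γ = 1/400 for
  400-dimensional binary vectors — mid-grid values appropriate to each
  feature dimension; full grid search is available and exposed in the CLI.

## Known limitations

- Classification operates on one fixed peptide length per model; a
  20-residue scanning window cannot resolve epitopes much shorter than the
  window, and antigens shorter than 39 residues yield no scored residues
  under the default interior-only rule.
- The per-position independence assumption discards correlated sequence
  structure known to exist in real epitopes.
- Decision scores are uncalibrated margins; `E_p` magnitudes are
  comparable within a model but not across models.
- The mean-`E_p` split between annotated epitope and non-epitope residues
  is reported without an attached significance test.
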