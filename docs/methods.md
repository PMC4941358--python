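# Methods

## The classification problem

Anticancer peptides (ACPs) are short, mostly cationic peptides — in
curated collections roughly 80% are under 30 residues — that show
selective toxicity toward cancer cell membranes. `acpred` predicts, from
sequence alone, whether a peptide is an ACP. The model is a soft-margin
support vector machine with an RBF kernel over *g*-gap dipeptide
composition features, pruned by ANOVA F-value ranking with incremental
feature selection.

## Feature model

A peptide P = R₁R₂…R_L is encoded as a fixed-length frequency vector.

* **Amino-acid composition (AAC).** f_i = count(residue i) / L over the
  20 standard residues, alphabetical by one-letter code. Order-free
  baseline, Ω = 20.
* ***g*-gap dipeptide composition.** For gap g ∈ {0,…,4}, every ordered
  pair (R_i, R_{i+g+1}), i = 1…L−g−1, increments the count n_u^g of its
  dipeptide u; the feature is d_u^g = n_u^g / (L−g−1), giving Ω = 400
  components that sum to one. g = 0 is the ordinary adjacent-dipeptide
  composition; larger g captures longer-range residue correlations.
  Gaps above 4 are pointless for peptides this short.

The canonical dipeptide ordering is alphabetical, first residue major
(AA, AC, …, YY): u = 20·rank(first) + rank(second). Any bijection is
mathematically equivalent; one must be frozen for file outputs and the
signed 20×20 matrix, and alphabetical is the least surprising. Positions
are 1-based in prose and 0-based in emitted column indices.

A peptide with L − g − 1 < 1 has no counted pair and is a hard error
under the strict policy (a zero vector would silently break the
unit-sum invariant); under the skip policy the record is dropped and
logged, and the encoded matrix records which rows were kept.

## Feature selection

Per feature, the one-way ANOVA F-value between the positive and negative
groups is F = MSB/MSW with df_B = K−1 = 1 and df_W = M−K; MSB is the
group-size-weighted squared deviation of group means about the grand
mean and MSW the pooled within-group mean square. Degenerate cases:
MSW = 0 with MSB > 0 (a perfectly separating feature) gets a +∞
sentinel and outranks every finite F; a constant feature gets F = 0.
Ties in the descending-F ranking break by ascending canonical index, so
the ranking is deterministic.

Incremental feature selection (IFS) trains an SVM on each prefix
S_τ = {f₁…f_τ} of the ranked list, τ = 1…Ω, scoring each prefix by
pooled k-fold cross-validated accuracy (all held-out predictions pooled
into one confusion table, metrics computed once — not a mean of
per-fold accuracies). The optimum Θ is the smallest τ attaining the
maximal accuracy. Design choices here:

* **Frozen folds.** One stratified k-fold partition is drawn from the
  seed and reused for every τ and every g in a selection run, so curves
  differ only through the features. This removes the dominant variance
  source and makes Θ reproducible.
* **No early stopping.** The IFS curve is not assumed unimodal; the
  full curve to τ = Ω is always computed.
* **No per-τ hyperparameter retuning.** (C, γ) stay fixed during IFS
  unless the caller explicitly runs the grid search.
* Peak ties resolve to the smallest Θ (parsimony), and gap ties to the
  smaller g.

## Classifier and evaluation

The SVM uses the RBF kernel exp(−γ‖x−y‖²) with defaults C = 2 and
γ = 0.125, the grid-search optimum for these features; the default grid
is C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} in powers of two (odd exponents
skipped by default for speed), ties to smaller C then smaller γ.
Features are used as raw frequencies in [0, 1] with no rescaling —
rescaling would silently change the meaning of γ. Labels are +1 (ACP)
and −1; a decision value of exactly zero predicts the positive class
(conservative toward sensitivity).

Metrics are computed in the misclassification-count form: with N⁺, N⁻
the class totals and N⁻⁺, N⁺⁻ the cross-class errors,
Sn = 1 − N⁻⁺/N⁺, Sp = 1 − N⁺⁻/N⁻, Acc = 1 − (N⁻⁺+N⁺⁻)/(N⁺+N⁻), and
MCC = [1 − (N⁻⁺/N⁺ + N⁺⁻/N⁻)] / √[(1 + (N⁺⁻−N⁻⁺)/N⁺)(1 + (N⁻⁺−N⁺⁻)/N⁻)].
This MCC is algebraically the classical contingency-table Matthews
coefficient wherever both are defined (property-tested exhaustively at
small counts). When a square-root factor is non-positive — exactly the
all-one-class prediction degeneracies — MCC is reported as an explicit
`None`/`NA` marker, never coerced to 0; likewise Sn or Sp when a class
is absent.

Protocols: the jackknife (leave-one-out) is deterministic and
partition-free; k-fold uses a seeded stratified partition and pools
counts; k = M reduces to the jackknife exactly (each sample its own
fold). The feature subset is selected once on the full dataset and
*not* re-selected inside each jackknife fold, matching the usual
selection-then-evaluation presentation; this carries a known optimistic
bias and is flagged here deliberately. Independent-set evaluation warns
(not errors) on exact-sequence overlap with the training set.

## Synthetic data generator

The generator emulates the summary statistics of curated ACP
collections, not their biophysics:

* **Lengths.** A two-stratum mixture: with probability 0.8 uniform on
  [5, 29], else uniform on [30, 50] — matching the ~80%-under-30
  statistic without claiming the true distribution's shape.
* **Composition contrast.** Positives multiply the sampling weight of
  an enriched residue set (default {C, E, F, G, I, K}, the residues
  over-represented in real ACPs) by `enrichment_factor` (default 3, a
  contrast strong enough that enriched dipeptides reliably reach the
  top of the F ranking at n = 100+100). The background is uniform over
  the 20 residues (the simplest exchangeable null); a natural-abundance
  background is available as an option.
* **Planted gap signal.** Optionally a residue pair is planted at
  offset g+1 in positives (density = planted pairs per counted
  position, default 0.2). Negatives receive the *same residues at
  uncorrelated positions*, so single-residue composition stays matched
  between classes and only the pair geometry is informative — a clean
  ground truth for gap selection.

Default class sizes are 138 positives and 206 negatives, the benchmark
proportions.

What passing synthetic tests does and does not show: the generator has
no residue autocorrelation, no physicochemical structure and no
homology, so results on it validate the pipeline's statistical
machinery (ranking, selection, evaluation, reproducibility), not
biological accuracy on real peptides.

### A numerical caveat worth knowing

On sparse short-peptide dipeptide vectors the squared distances between
samples are small (~0.1–0.2), so at γ = 0.125 the RBF kernel is nearly
constant and the fixed C = 2 machine underfits weak class contrasts: on
composition-bias-only synthetic data it degenerates to majority-class
prediction even though the ANOVA ranking sees the signal clearly. Real
benchmark data evidently carries a stronger contrast. Demonstrations
that exercise the SVM stage therefore use the planted-pair mode (which
concentrates signal in few coordinates at separable magnitudes), and
the null-data tests rely on the same behaviour to keep the false-
positive side honest.

## Numerical conventions

* Feature vectors are exact ratios in float64; emitted tables use 6
  decimals for features, 2 for percentages, 3 for MCC.
* Unit-sum invariants are asserted to 1e-9; ANOVA agreement with an
  independent implementation to 1e-9.
* All randomness (fold partitions, generator draws) flows through
  explicit integer seeds; the jackknife needs none.
* Problem sizes in the shipped statistical tests (60+60 to 100+100
  peptides, 3-fold IFS, ten seeds) were chosen as the smallest sizes at
  which the planted-structure recovery properties hold with comfortable
  margins; the pipeline itself has no size limits beyond memory.

## Known limitations

* Binary, single-label classification only; multi-label metrics are out
  of scope.
* No redundancy reduction (CD-HIT-style) or dataset curation: the
  package consumes ready FASTA pairs.
* Feature selection inside the jackknife is not re-run per fold (see
  above).
* The signed F matrix fixes the "signed F" convention (direction × F);
  separating magnitude and sign into two channels is presentation, not
  contract.
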