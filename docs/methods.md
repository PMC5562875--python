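# Methods

## The prediction problem

Early-folding residues are defined operationally: in pulsed-labelling
hydrogen/deuterium exchange (HDX) NMR, they are the residues whose
backbone amide proton is already protected by a hydrogen bond in the
low-millisecond phase of folding. Such residues nucleate local structure
and sit preferentially in the helices and strands of the final fold. The
predictor treats this as per-residue binary classification from sequence,
with a strong class imbalance (roughly one positive per six residues in
curated compilations).

## Features

Five per-residue channels are used, in the fixed order DYNA, SIDE,
HELIX, STRAND, COIL (backbone dynamics, side-chain dynamics, and the
three secondary-structure propensities). Each channel is itself a
sequence-based prediction: an ordinary least-squares linear regression
from a one-hot encoding of an 11-residue window (half-width `w_p = 5`,
configurable) onto per-residue channel values. The one-hot design is
structurally rank-deficient (every window block sums to the intercept
column), so the fit is the minimum-norm least-squares solution; a warning
is emitted only when the rank falls below the structural maximum
`(2·w_p+1)·19 + 1`, which signals genuinely degenerate training data.
Non-canonical residues (X, B, Z) are accepted and encoded as an all-zero
block — a neutral encoding that contributes nothing to any regression
term.

Channel predictors are retrained from user-supplied profile data; the
package deliberately ships no fixed channel weights, and reproducing any
particular external predictor's numeric outputs is a non-goal.

The DYNA channel is min–max shifted to [0, 1] within each sequence
(`(v − min)/(max − min)`); a constant profile maps to 0.5, keeping the
degenerate case centred in the admissible range. The other four channels
pass through raw by default (`normalize_all=True` shifts all five). The
classifier input for residue *i* concatenates, channel by channel, the
values at window positions *i−2 … i+2*, clamping positions past a
terminus to the terminal residue's value (clamping repeats a real
physical value instead of injecting a sentinel). The vector is therefore
always 5 × 5 = 25-dimensional, for every residue of every sequence length
≥ 1.

## Classifier and calibration

The classifier is an SVM with RBF kernel, C = 100 and γ = 0.04, with
class weights inversely proportional to class frequency ("balanced"; an
explicit weight map is accepted). The underlying solver is run at a
tight tolerance (1e-6) so refitting after a row permutation reproduces
the decision function to numerical noise.

Probabilities come from Platt scaling, `p = 1/(1+exp(A·s+B))` on the
hyperplane distance s, fitted by Newton iteration with backtracking on
the regularized binomial likelihood (smoothed targets
`t+ = (N₊+1)/(N₊+2)`, `t− = 1/(N₋+2)`, which keep the optimum finite for
separable scores). When calibration is performed on training data, the
decision scores are produced by an internal stratified cross-validation
(default 3-fold): each score comes from a classifier that never saw that
row, avoiding the optimistic calibration a direct training-set fit gives
with a separable kernel. Calibration is monotone, so it never reorders
examples.

The binary call is `p ≥ τ` — the comparison is inclusive, fixed as a
package convention for reproducibility. The default τ = 0.163. (The
historical description of this protocol prints 0.169 in one table row
and 0.163 in the running text; this package adopts 0.163 and surfaces
the discrepancy here without resolving intent.)

## Stratified cross-validation

Pairwise sequence identity and coverage are computed from a global
alignment (BLOSUM62, gap open −11 / extend −1): identity is the fraction
of identical columns after trimming terminal gaps; coverage is the
fraction of the longer sequence inside the trimmed region. Proteins are
clustered by single linkage over the graph with an edge whenever
identity > 0.25 **and** coverage ≥ 0.90. This replaces the deprecated
BLASTCLUST tool while preserving its cutoffs and linkage semantics;
cluster-for-cluster agreement with BLASTCLUST is not promised.

Cross-validation holds out one cluster per fold. Within each fold the
classifier, the Platt coefficients (internal-CV protocol above) and the
decision threshold (the Youden-J maximizer over the training-side
calibrated probabilities, ties broken toward the larger threshold) are
all fitted without the held-out cluster. Fold metrics are averaged
unweighted across folds, following the fold-average reading of the
protocol; pooled scoring of all held-out predictions is available as an
option (`pooled=True`), since the historical description does not state
which was used.

Metric conventions: any confusion-derived ratio with a zero denominator
is 0 (with a warning), keeping fold averages computable; folds whose test
set contains a single class get NaN for the class-dependent metrics and
are excluded from the average, with a warning. AUC is the rank statistic
(ties half), top-fraction PPV selects `ceil(f·n)` residues with inclusive
boundary ties.

## Structure metrics

**RSA** divides the DSSP per-residue accessible area by the residue
type's maximum accessible area. The default scale is Sander/Rost
(Ala = 106 Å² etc., as tabulated in Biopython); the Wilke and Miller
scales are selectable. Values above 1 are possible for unusual
conformations and are flagged, not clipped.

**Contact S²** estimates backbone amide rigidity from packing:

    S²(i) = tanh( b · [ Σ_k w·exp(−d_k^H/r0) + Σ_k exp(−d_k^O/r0) ] ) − c

where the sums run over heavy atoms outside residues *i* and *i−1*,
d^H is the distance to the amide proton of residue *i* and d^O the
distance to the carbonyl oxygen of residue *i−1*. Defaults b = 0.8,
w = 0.8, r0 = 1 Å, c = 0.1 follow the contact-model literature and are
plain configuration, not hard-coded truth; quantitative claims tied to
specific constants are out of scope. When the structure lacks hydrogens
(typical for X-ray models), the amide proton is rebuilt geometrically
from N(i), Cα(i) and C′(i−1) at 1.01 Å along the bisector direction. The
value is undefined (NaN, never a silent 0) for the first residue of a
chain or when probe atoms are missing.

**Bias correction.** Distribution comparisons across residue classes are
confounded by amino-acid composition (hydrophobic types fold early more
often). The correction subtracts each amino-acid type's median and adds
back the global median, so every type's corrected median equals the
global one; it is idempotent, and corrected values are meaningful only
relatively.

**Tests.** Group comparisons use the two-sided Wilcoxon rank-sum test —
exact permutation p-values for combined tie-free samples of n ≤ 20,
normal approximation with continuity and tie correction otherwise — with
Benjamini–Hochberg step-up adjustment across all group pairs and
significance stars at adjusted p < 0.05 / 0.01 / 0.001. Box-plot notch
half-widths (1.57·IQR/√n) are exposed as numbers; no plotting is done.

## Synthetic data generator

The generator emulates the statistical shape of a small curated HDX
compilation, and these defaults are the package's study conditions:
30 proteins; lengths drawn from a normal centred at 121 (s.d. 28) and
clipped to [56, 164]; amino acids drawn from typical globular-protein
frequencies; target positive fraction 0.142.

Each protein receives a latent "foldability" track: Gaussian noise
smoothed by a 7-residue moving average (normalized to unit variance)
plus 0.15 × the smoothed Kyte–Doolittle hydropathy of the local segment
— hydrophobic *segments*, not single residues, drive early folding, and
smoothing the offsets keeps threshold exceedances contiguous. Residues
above the dataset-wide (1 − 0.142) quantile of the track are labelled
EARLY, which pins the realized fraction to the target and yields
contiguous runs of typically 2–8 residues. Each profile channel is a
distinct monotone transform of the track (tanh, linear, sigmoid,
arcsinh, negated tanh for COIL) plus independent Gaussian noise of
s.d. 0.25; `signal_strength` scales the track's contribution, with 0
producing label-independent noise for leakage controls.

What the generator does **not** emulate: real channel predictors are
imperfect, correlated estimators trained on NMR observables, not clean
monotone transforms of a shared latent cause; real homology produces
partial, structured sequence similarity rather than the i.i.d. sequences
generated here; and real label noise (HDX classification ambiguity) is
absent. Passing the planted-signal test therefore demonstrates that the
pipeline is correct and leak-free — cross-validated AUC ≈ 0.99 on
synthetic data is an upper bound, not an estimate, of performance on
experimental data, where published figures for this family of methods
are near AUC 0.8.

Structure fixtures place 5 backbone atoms per residue (N, Cα, C′, O, H)
on either an ideal-helix Cα spiral (radius 2.3 Å, rise 1.5 Å, 100° per
residue) or an extended zigzag, both with consecutive Cα–Cα ≈ 3.8 Å;
the helix's denser packing makes its mean contact S² strictly larger.
Score fixtures use the binormal model — negatives N(0,1), positives
N(δ,1) with δ = √2·Φ⁻¹(AUC) — whose expected AUC is the target in closed
form (disjoint uniform bands for a target of exactly 1).

## Problem sizes and numerical choices

The shipped evaluation and the reproduction script run the default
30-protein synthetic conditions (~3300–3600 residues, ~30 folds, 3-fold
internal calibration per fold), which completes in about a minute per
cross-validation on one CPU. Platt recovery checks use n = 5000 scores
drawn uniformly on [−2, 2], where the likelihood is well conditioned for
both parameters. Wilcoxon exact-vs-enumeration checks enumerate every
rank split up to combined n = 10. All random draws in tests and scripts
are seeded; the model file is plain versioned JSON (support vectors,
dual coefficients, intercept, Platt A/B, τ, and optionally the channel
predictor weights), so loading reconstructs the decision function
without unpickling code.

## Known limitations

- Channel predictors are linear and window-local; they cannot express
  non-local context, and no attempt is made to match any external
  dynamics predictor's numeric output.
- The single-linkage clusterer is quadratic in the number of proteins
  and alignment-based; it is meant for dataset-scale (tens to hundreds)
  redundancy grouping, not proteome-scale clustering.
- `contact_s2` is O(atoms) per residue with a Python inner loop —
  adequate for single structures, not for large structure surveys.
- The pooled cross-validation report uses the mean of the per-fold
  thresholds for its binary metrics, which is a convention, not a fitted
  quantity.
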