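# earlyfold

Sequence-based prediction of **early-folding residues** — the positions of
a protein whose backbone amide protons become protected from
hydrogen/deuterium exchange within milliseconds of the start of folding,
marking where local structure forms first. These residues are observable
only through demanding pulsed-labelling HDX-NMR experiments; `earlyfold`
predicts them from the amino-acid sequence alone, for structural
biologists and protein engineers who want to locate likely folding
initiation sites without the experiment.

## Method

Per residue *i*, five biophysical profiles are first predicted from
sequence by per-channel linear regressions over a one-hot windowed
encoding (backbone dynamics **DYNA**, side-chain dynamics **SIDE**, and
the secondary-structure propensities **HELIX**, **STRAND**, **COIL**).
The DYNA profile is min–max shifted to [0, 1] within each sequence, each
channel is sampled over the window *i−2 … i+2*, and the resulting
25-dimensional vector x_i is classified by a class-weighted SVM with RBF
kernel (C = 100, γ = 0.04; class weights inverse to class frequency).
Calibrated probabilities come from Platt scaling of the signed hyperplane
distance s:

    p(early | s) = 1 / (1 + exp(A·s + B)),  A < 0

and the binary call is p ≥ τ with τ = 0.163 by default.

Evaluation is leakage-aware: proteins are clustered by single linkage
over a global-alignment graph (edge when identity > 25% at ≥ 90%
coverage) and cross-validation holds out one whole cluster per fold, so
no held-out sequence has a close homologue in training. Reported
measures are sensitivity, specificity, accuracy, balanced accuracy,
precision, MCC, ROC AUC and the precision of the top-10%/top-5% most
confident calls.

The package also implements the structure-derived validation metrics used
to interpret such predictions — DSSP-based relative solvent accessibility
(RSA), a contact-model order parameter S² for backbone amide rigidity —
and the accompanying statistics (per-amino-acid bias correction, Wilcoxon
rank-sum tests with Benjamini–Hochberg correction).

## Worked example

Everything is exercisable on synthetic data with the statistical shape of
a small pulsed-labelling HDX compilation (30 proteins of 56–164 residues,
~14% positive residues arranged in contiguous runs, profile channels
carrying a noisy planted signal):

```python
from earlyfold.synthetic import SyntheticConfig, generate_dataset
from earlyfold.evaluate import crossvalidate

synth = generate_dataset(SyntheticConfig(seed=7))
print(f"{len(synth.dataset)} proteins, {synth.dataset.n_residues} residues, "
      f"{synth.dataset.n_positive} early ({synth.positive_fraction:.1%})")

result = crossvalidate(synth.dataset, synth.profiles)
avg = result.average
print(f"{len(result.folds)} folds | AUC {avg.auc:.3f}  Sen {avg.sen:.3f}  "
      f"Spe {avg.spe:.3f}  Bac {avg.bac:.3f}  MCC {avg.mcc:.3f}  "
      f"PPV10 {avg.ppv_top10:.3f}")
```

prints

```
30 proteins, 3287 residues, 467 early (14.2%)
30 folds | AUC 0.988  Sen 0.964  Spe 0.920  Bac 0.942  MCC 0.760  PPV10 0.845
```

i.e. on this synthetic dataset the stratified cross-validation recovers
the planted signal almost perfectly (AUC 0.99); with the signal switched
off (`signal_strength=0`) the same pipeline returns chance-level AUC,
confirming the stratification leaks nothing. Real HDX data is far
noisier than the generator's planted signal, so these numbers are an
upper bound on, not an estimate of, real-data performance (see
`docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
earlyfold simulate --n-proteins 30 --seed 7 --out-dir data/
earlyfold crossval --fasta data/sequences.fasta \
    --annotations data/annotations.tsv --profiles data/profiles.tsv \
    -o report.tsv
earlyfold train --fasta data/sequences.fasta \
    --annotations data/annotations.tsv --profiles data/profiles.tsv \
    -o model.json
earlyfold predict --fasta data/sequences.fasta --model model.json \
    -o scores.tsv
earlyfold analyze-structure --pdb protein.pdb --dssp protein.dssp \
    -o structure_metrics.tsv
```

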