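# ictalemo

Automated recognition of ictal (seizure) versus interictal patterns in
single-channel EEG, for signal-processing and machine-learning
researchers working on epilepsy detection. The package implements a
complete expert-system pipeline — wavelet-packet feature engineering,
evolutionary multi-objective feature selection, and a generalized
regression neural network classifier — and ships a synthetic two-class
EEG generator so every stage runs and is testable without clinical data.

## The method

Each EEG segment x(n) is decomposed to level l = 7 of the full
wavelet-packet tree (Coiflet mother wavelet), giving coefficient vectors
W_f^l for 2^7 = 128 terminal nodes in ascending frequency order, node f
covering ((f−1)·Fs/256, f·Fs/256) Hz. Per node, four features are
computed from the 3-dimensional delay embedding
PSR(m) = [V(m), V(m+τ), V(m+2τ)] and its distance series
ED(m) = √(V(m)² + V(m+τ)² + V(m+2τ)²):

* **F1** — sample standard deviation of ED,
* **F2** — range (max − min) of ED,
* **F3** — largest singular value of the trajectory matrix,
* **F4** — band energy Σ W_f^l(k)²,

concatenated as F_pq = [F1 | F2 | F3 | F4] into a p × 512 matrix.

NSGA-II then searches binary feature masks, minimizing simultaneously
**O1** = number of selected features and **O2** = mean error rate
Er = 100 − CA over 10 iterations of randomized sub-sampling
cross-validation of a GRNN on the training partition. The GRNN predicts

    Ŷ(X) = Σᵢ Yᵢ e^(−δᵢ²/2σ²) / Σᵢ e^(−δᵢ²/2σ²),  δᵢ² = (X−Xᵢ)ᵀ(X−Xᵢ)

in z-scored feature space, and Ŷ ≥ 0.5 is called ictal. The mask chosen
from the rank-1 Pareto front (tournament selection under the crowded
comparison operator) is transferred to the held-out partition, where
CA, SN, SP, MCC and the classification time CT are reported for both
the full 512-feature mask and the selected mask.

## Worked example

Write a config and run the full experiment on synthetic data (30
segments per class, ictal rhythmic amplitude 4× background RMS):

```sh
cat > demo.yaml <<EOF
synth: {n_per_class: 30, seed: 5}
ea: {pop_size: 10, n_generations: 50}
seed: 2
EOF
ictalemo run --config demo.yaml
```

which prints:

```
    full: O1=512  O2=0.00%  CA=100.00%  SN=100.00%  SP=100.00%  MCC=1.000  CT=0.3 ms
selected: O1=172  O2=0.00%  CA=100.00%  SN=100.00%  SP=100.00%  MCC=1.000  CT=0.1 ms
```

Read: with all 512 features the GRNN classifies the held-out 30% of
segments perfectly (CA, SN, SP = 100%, MCC = 1); the evolutionary
selection reaches the same held-out accuracy with 172 of 512 features
(O1), i.e. the feature matrix shrinks by two thirds at no accuracy
cost, and O2 is the training-partition cross-validated error of each
mask. CT is the wall-clock time of the classification call. Synthetic
data at this amplitude ratio is deliberately well separated; the point
of the example is the pipeline mechanics and the feature reduction, not
a clinical difficulty level.

Other subcommands: `ictalemo simulate` (write a synthetic segment CSV +
labels sidecar), `ictalemo extract-features`, `ictalemo optimize`
(NSGA-II on a stored feature matrix, writes the Pareto front CSV and
scatter plot), `ictalemo evaluate` (CV error of a stored mask). See
`docs/methods.md` for model details and design choices.

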