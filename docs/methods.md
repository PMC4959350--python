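# Methods

## Model

The core model is a binary restricted Boltzmann machine: an undirected
bipartite graph over `m` visible and `n` hidden binary units with energy
`E(v,h) = −b·v − c·h − vᵀWh` and Boltzmann distribution
`p(v,h) = e^{−E}/Z`. Because no within-layer edges exist, both
conditionals factorize into logistics, and the hidden layer can be summed
out exactly, giving the free energy
`f(v) = −b·v − Σⱼ softplus(cⱼ + W:ⱼ·v)` with `p(v) = e^{−f(v)}/Z`.

For classification the binary pain label joins the visible layer as the
**last** unit (the index convention is fixed and used everywhere). The
posterior over the label for features `x` follows from the cancellation
of `Z` in the ratio of `p(x⊕c)` for the two completions, and is computed
as `p₁ = logistic(f(x⊕0) − f(x⊕1))` — algebraically identical to the
ratio form but overflow-safe, and making `p₀ + p₁ = 1` exact by
construction. Ties at the decision threshold classify as "pain", the
conservative direction for this use case. A second route to
classification — feeding the hidden activation probabilities (label unit
clamped to 0) into any downstream classifier — is provided as
`hidden_representation`.

### Assumptions

- Rows are treated as exchangeable: no temporal structure is modelled.
- Features are binary normal/abnormal indicators; a binary coding cannot
  distinguish high from low excursions (see Limitations).
- One model per patient; baselines and classifiers never pool patients.

## Training

Training is minibatch stochastic gradient ascent on the data
log-likelihood with the CD-1 estimator: positive statistics
`⟨v·p(h=1|v)ᵀ⟩` from the data, negative statistics after one Gibbs step
started at the data. Along the chain hidden states are *sampled* but the
final reconstruction and final hidden statistics use conditional
probabilities — the standard variance-reduction choice. Weights are
initialized `N(0, 0.01²)`, biases at zero.

Defaults (all exposed in `TrainingConfig`): `n_hidden=20` (the midpoint
of the 15–30 range appropriate for a couple of dozen visible units),
`k=1`, `learning_rate=0.1`, `epochs=800`, `batch_size=64`. The optimizer
defaults are sized for cohort-scale inputs (~10³ rows of a few dozen
bits), where CD-1 needs this much data exposure for the label unit to
couple to the features reliably; smaller problems train fine with far
fewer epochs. A seeded generator drives initialization, epoch shuffles
and every Gibbs sample, so training is bit-reproducible.

CD-1 on interaction-only targets (e.g. the XOR cohort) occasionally
converges to a mode where the label unit stays decoupled from the
features (roughly one training seed in ten in our development runs). The
pipeline therefore supports restart selection (`n_restarts`): several
RBMs are trained from derived seeds and the one with the best
**training-set** AUC is kept — the same pattern as k-means restarts;
test data never informs the choice. The canonical separation experiment
uses 3 restarts and 30 hidden units (the top of the 15–30 range; the
extra random hidden directions help symmetry breaking on the XOR rule).

### Exact oracles

`exact_log_partition`, `exact_mean_log_likelihood` and
`exact_log_likelihood_gradient` enumerate all visible states with
log-sum-exp and refuse models with more than 20 units in a layer. They
exist to check the closed forms and the CD estimator on small models and
are not production inference paths.

## Personalized binarization

"Normal" physiology differs across individuals, so a Gaussian baseline
`(μᵢ, σᵢ)` is fitted per patient and per data item, ignoring missing
cells, with the n−1 denominator for σ. Items with fewer than two
observations or zero variance are dropped (with a recorded warning). A
reading `t` maps to the abnormality probability

```
p(abnormal) = 2Φ(|t − μ|/σ) − 1,
```

the central coverage of the baseline Gaussian at `t`: zero at the mean,
symmetric, strictly increasing in `|t − μ|`, and invariant under affine
rescaling of the measurement units. The probability-to-density notation
commonly used for this step is not by itself a well-defined probability;
central coverage is the unique symmetric, monotone-in-`|z|` reading with
range [0, 1) and a meaningful 0.5 threshold, and is the interpretation
adopted here throughout. Thresholding at 0.5 is equivalent to
`|t − μ| > Φ⁻¹(0.75)·σ ≈ 0.674σ`, so exactly half of in-regime Gaussian
readings are coded abnormal — a deliberate property of the threshold,
verified by simulation. A reading displaced by 2σ from the true baseline
crosses the cut with probability `2 − Φ(z₀−2) − Φ(z₀+2) ≈ 0.907`; this
detection rate is what "recovery" means in the tests, since the 50%
in-regime flag rate bounds any whole-matrix accuracy. Missing cells are
imputed as 0 ("normal") and flagged in a mask.

## Evaluation

ROC curves are built by sweeping the decision threshold over the distinct
score values (ties grouped), with the convention "predict pain when
score ≥ threshold", a leading (0,0) point at threshold +∞ and a
guaranteed (1,1) endpoint. AUC is the trapezoidal area, identical to the
Mann–Whitney pairwise statistic with ties counted ½ (asserted against a
brute-force pairwise count and against scikit-learn in the tests). The
reported operating point minimizes the Euclidean distance to (0,1); ties
break toward higher TPR, then lower threshold. Sensitivity/specificity
with an absent class are reported as NaN, never silently 0.

By default the operating point is selected on the **test** ROC itself.
This mirrors how such operating points are commonly reported but is
optimistic; `threshold_protocol="train"` selects the threshold on the
training ROC instead (AUC is unaffected).

## Baselines

- **Linear discriminant**: the classical pooled-covariance direction
  `Σ⁻¹(μ₁ − μ₀)`, implemented directly (binary indicator matrices are
  frequently rank-deficient, and the singular-covariance behaviour is
  part of the contract: `ridge=0` raises an explicit error recommending
  regularization; the default adds `1e-6·I`).
- **PCA + max-margin**: scikit-learn PCA onto the top `k=4` variance
  directions (reduced to the matrix rank with a warning if needed),
  followed by a linear-kernel SVM with `C=1` (kernel and C are fixed but
  configurable; they are controls, not contributions).

Both return the same scoring-function contract as the RBM discriminant,
so the evaluation code is model-agnostic.

## Synthetic cohorts

The generator emulates per-patient flowsheets: defaults of 25 items and
1200 labeled rows per patient match the scale of the records this
package targets (22–28 items, >1000 labels). Per patient, baselines are
drawn `μᵢ ~ U(10, 150)`, `σᵢ ~ U(1, 15)` (vitals-like magnitudes). Per
row, feature `i` is latently abnormal with rate `rᵢ`; abnormal readings
are displaced by `shift·σᵢ` (default 2) in a direction fixed per feature.
The fixed sign is deliberate: whether a signal runs high or low is
exactly the information two-sided binarization destroys, and the
generator makes that loss measurable. The label is a rule over the
latent bits — `linear` (weighted sum over designated bits vs a cut),
`count_threshold`, or `xor_pair` (linearly inseparable by construction)
— flipped with probability `label_noise` (default 0.05). Ground truth
(latent bits, baselines, signs, pre-noise labels) is returned with the
data.

Canonical cohorts: designated (label-relevant) features use rate 0.5 —
balancing the label and, for XOR, removing all linear signal — while
background features use 0.2, so the informative bits also carry the
largest Bernoulli variance and the 4-component PCA retains them; this
keeps the linear cohort a fair test for the PCA pipeline.

### What the separation experiment does and does not show

The model-separation experiment runs on the generator's latent
abnormality bits (`feature_source="latent"`), not through the numeric
binarization channel. This is a mathematical necessity, not a
convenience: with a fixed per-feature shift sign, a feature with
abnormality rate 0.5 produces a numeric mixture that is symmetric about
its fitted mean, and since the abnormality flag depends only on
`|t − μ̂|`, the resulting bit is *exactly independent* of the latent
state — the binary channel carries zero signal there, for every model.
At any other rate the XOR label acquires a linear component through the
unbalanced marginal, so "linear models at chance" and "informative
features" cannot hold simultaneously through that channel. The
experiment therefore isolates model capacity (can the classifier
represent an interaction?) while binarization fidelity is validated
separately (coverage and detection rates above). Passing it shows the
discriminant RBM learns nonlinear label structure from binary features;
it does not show that real flowsheet binarization preserves such
structure — see Limitations.

## Problem sizes

Test and acceptance runs use: ≥200 random models (≤10+10 units) for the
free-energy oracle, 50 for normalization, ~40 models × 4 inputs (≤16
total units) for the posterior oracle, 1000 seeded CD-1 estimates on a
4+3-unit model, 500 training samples from a known 6+3-unit model,
10,000 draws for binarization rates, and full-scale cohorts (25×1200,
20% test) for the separation experiment. These sizes give Monte-Carlo
bands comfortably tighter than the effects being checked.

## Known limitations

- Temporal structure is ignored; autocorrelated pain episodes would
  violate the exchangeability assumption and the random-split protocol.
- Binary coding cannot represent direction (high vs low) or magnitude of
  excursions; the symmetric-mixture blindness described above is the
  sharpest form of that loss. Richer visible units (softmax/Gaussian)
  are out of scope.
- CD-1 is a biased gradient estimator; we assert directional agreement
  with the exact gradient, not unbiasedness.
- The test-selected operating threshold is optimistic; the train-selected
  protocol is provided but not the default.
- Posteriors are used as ranking scores and are not calibrated.
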