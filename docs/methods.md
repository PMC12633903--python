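# Methods

## Problem and model

`cmfp` predicts whether a Parkinson's disease patient will progress over
five years — defined as a Hoehn–Yahr stage (HYS) at follow-up strictly
above baseline — from several baseline feature *modalities*: a clinical
table (demographics, motor/cognitive scores, CSF proteins), regional
white-matter mean diffusivity from DTI, and striatal DAT uptake values.
Patients whose stage is unchanged or lower are labelled stable; progression
is the positive class (coded 1), and every probability η in the package is
a positive-class probability.

Rather than concatenating features, the method fuses *decisions*: one
classifier per modality produces a triplet — predicted label ρ, probability
η, and the model's held-out accuracy φ — and a pairwise Cross-Modal Fusion
(CMF) rule combines two triplets into one prediction Φ = [ρ, η].

### The CMF rule

For predictions (ρ_a, η_a, φ_a) and (ρ_b, η_b, φ_b), define

- category difference Ω = ρ_a − ρ_b,
- accuracy difference σ = φ_a − φ_b (only its sign drives branching;
  the raw value is stored),
- probability difference υ = η_a − η_b,

and the logistic adjustment η_new = ι / (1 + e^{−α υ}) with defaults
α = 0.4, ι = 1.

Branches:

- **Agreement (Ω = 0).** Keep the common label; fused
  η = (φ_a η_a + φ_b η_b)/(φ_a + φ_b), falling back to the plain mean when
  both accuracies are zero. The logistic adjustment is *not* applied here:
  with α = 0.4 it maps every input into ≈ [0.40, 0.60], which would
  collapse all agreed probabilities into a narrow band and destroy their
  ranking value.
- **Disagreement, σ ≠ 0.** The more accurate modality supplies the label;
  fused η = η_new evaluated at (η_chosen − η_other). Orienting the
  argument as chosen-minus-other (instead of the raw υ) makes the fused
  label and probability provably consistent under the strict threshold
  rule ρ = [η > t] whenever the inputs are.
- **Disagreement, σ = 0.** Choose the side whose probability is further
  from the threshold (larger |η − t|). At an exact confidence tie, choose
  the larger η; if the probabilities are identical too, prefer the
  positive label. Every stage of this tie-break is a function of the
  unordered pair, so fusion is commutative — an argument-order-dependent
  tie-break ("always side a") would silently make cmf_fuse(a, b) ≠
  cmf_fuse(b, a) at ties, which we consider a defect, and is therefore
  not used.

The branch taken is recorded per patient for audit.

### Per-modality learners

The default base learner is AdaBoost over depth-1 decision stumps
(50 estimators): misclassified samples are up-weighted before each new
stump is fitted. Probabilities come from the standard SAMME margin
transform: with stump votes s_i(x) ∈ {−1, +1} and weights a_i,
D(x) = 2 Σ a_i s_i(x) / Σ a_i and η = 1/(1 + e^{−D}). This choice is
fixed and is bit-identical to scikit-learn's `predict_proba` for the
binary case (a test asserts agreement to 1e-12). Labels use the strict
rule ρ = [η > t], t = 0.5, so η = t maps to the stable class.

Fitted ensembles are immediately converted to a portable stump list
(feature index, threshold, two class votes, weight). All predictions —
including at test time — flow through this portable form, which is what
the JSON archive stores; a saved and reloaded archive therefore reproduces
its outputs exactly, byte for byte.

A registry of substitute base learners (logistic regression, Gaussian
naive Bayes, decision tree, SVM, k-NN, random forest, extra trees) lets
the comparison harness run the identical pipeline with each learner
swapped in; those fitted models live behind the same interface but are
not archived.

### Feature selection

Selection is an L1-penalised logistic regression of the label on the
modality's standardised features, fitted **only on the training rows** of
the current split; λ is chosen by 5-fold cross-validated deviance on those
same rows (a fixed-λ override exists for reproducibility). Retained
features are ordered by decreasing |coefficient| (source-column order on
ties) and truncated per modality — defaults clinical 4, DTI 7, DAT 4.
Constant columns are dropped with a warning; an all-zero fit is a valid
empty selection at the API level, while the training loop falls back (to
the weakest penalty in the path, then to source-column order) so a single
unlucky resplit cannot kill a run. The grid enumerator turns an ordered
selection into nested prefix combinations (sizes 2…k plus the all-features
set) for feature-combination sweeps, and accepts an explicit user-supplied
order to reproduce any fixed published grid.

### Training protocol

Training runs `epochs` cycles (default 120). Each epoch re-partitions the
non-test patients into training and validation rows at a 2:1 ratio (the
60/30 part of the 60/30/10 protocol), re-runs selection, fits the
per-modality learners, scores the validation rows, and fuses the pair.
Per-epoch seeds are a pure function of (master seed, epoch index), so any
epoch can be recomputed independently and two runs with equal seeds
produce byte-identical archives.

The archive keeps the best single-modal model per modality (Ms = argmax
validation φ, earliest epoch on ties) and the fusion configuration from
the epoch with the best fused validation accuracy (Mc). At test time each
Ms predicts the held-out rows and its *archived* validation φ enters the
fusion rule — test-set accuracy is unknowable at prediction time.

**Held-out test discipline.** The 10% test set is carved out once, before
the loop, and no epoch's training or validation rows may touch it
(`fixed_test=True`, the default; a test asserts the disjointness across
all epochs). Re-partitioning all three sets each epoch — the literal
reading of the repeated-resplit protocol — would entangle best-model
selection with the eventual test rows; that variant remains available via
`fixed_test=False` for fidelity experiments only.

## Synthetic cohorts

The generator emulates the *shape* of the study cohort — 123 patients,
74 progressing / 49 stable, 16 clinical features, 50 DTI regional MD
values, 6 DAT uptake measures (of which 4/7/4 are informative) — with a
latent-factor model: a shared standard-normal risk factor z_s, one private
factor z_m per modality, composite risk r = (w_s z_s + Σ w_m z_m)/‖w‖,
and outcome = the n_pos patients with the largest r (exact-count mode, so
the 74/49 split is reproduced for every seed; a Bernoulli-link mode exists
for power studies). Modality m's informative features load on its visible
risk w_s z_s + w_m z_m plus N(0, σ²) noise; the rest are pure noise.
Defaults: shared weight 0.6, private weights 0.5, loading 0.8, noise sd
1.0, link slope 3.0 — chosen once to put single-modality AUC in the 0.6–
0.75 range typical of tabular clinical predictors, with genuine headroom
for fusion. DTI/DAT loadings are negative by convention (disease lowers
uptake and raises diffusivity); the sign has no statistical consequence.
Synthetic HYS records (baseline stage 2; follow-up = baseline + label)
let the CSV pipeline run end to end.

What the generator does **not** emulate: feature-feature correlation
structure within a modality beyond the single factor, site effects,
non-Gaussian marginals, missingness, and longitudinal trajectories.
Passing tests on these cohorts demonstrate that the pipeline's machinery
behaves as specified — not that the headline performance numbers transfer
to any real cohort.

## Evaluation

AUC is the rank statistic (ties = ½, equal to trapezoidal ROC area, and
cross-checked against U/(n₊ n₋) in tests); ACC/SEN/SPE/F1 come from the
2×2 confusion table; MAE and RMSE are computed on probabilities against
the 0/1 outcome (computing them on labels would just reproduce 1 − ACC).
ROC confidence bands are pointwise percentile bootstrap, stratified within
class so every resample has a defined curve, on a common FPR grid.
Mann-Whitney U uses full enumeration when n_a·n_b ≤ 400 and the pooled
sample is tie-free, else the normal approximation with tie and continuity
corrections; the model-comparison form applies it to per-run AUC
collections from repeated seeded runs. Repeated-run variances are
population variances (divide by n). The 8-fold comparison harness runs
the complete pipeline — selection, training, fusion, best-model tracking —
inside each stratified fold, once per registered base learner.

## The fusion-gain experiment

The central scientific claim is that fusing two modalities carrying
*complementary* signal beats each modality alone. The experiment: 50
master seeds; per seed, an n=123 cohort with the shared risk component
off (w_s = 0) and two informative modalities with equal private weights
(clinical- and DTI-shaped); the full protocol (12 epochs at this problem
size) fits an archive; the archive is then scored on an independently
drawn 500-patient evaluation cohort from the same generative model, never
touched during training. The claim holds when the fused mean AUC exceeds
each single-modality mean with a one-sided paired Wilcoxon p < 0.05.

The evaluation cohort — rather than the protocol's internal 12-patient
test split — is the measurement instrument because a 12-row AUC has a
per-replicate standard deviation near 0.15, which drowns a ~0.02–0.03 AUC
gain at 50 replicates; the larger held-out sample measures the same
out-of-sample quantity with adequate resolution. (Measured at the package
defaults: fused ≈ 0.62 vs ≈ 0.59 for each single modality, Wilcoxon
p < 1e-3.)

## Numerical choices and degenerate inputs

- Split sizes: ⌊n·f⌋ per fraction, leftovers assigned train → val → test.
  Splits are not stratified by default (the protocol partitions purely at
  random); a stratified option exists.
- Missing or non-finite cells are rejected with the offending patient and
  column named — never imputed, mirroring an exclusion-criterion design.
- A constant feature column is dropped at selection time (detected with a
  relative tolerance of 1e-12, since a float mean subtraction leaves
  ~1e-16 residues).
- Single-class training splits are redrawn once with a derived alternate
  seed, then rejected; single-class cohorts are rejected outright.
- Seeds everywhere are explicit; all derived seeds stay below 2^31.

## Known limitations

- Fusion is strictly pairwise; three-modality fusion would require
  composing pairs and is out of scope.
- φ at test time is a validation accuracy — an optimistic, winner-selected
  estimate; with few epochs and small validation sets the σ-branch can
  effectively pick a side at random between near-equal modalities.
- Best-model selection by validation accuracy is subject to winner's
  curse on small validation sets; the archived φ overstates test accuracy.
- The probability transform of boosted stumps concentrates η near 0.5;
  fused probabilities are rank-informative but not calibrated.
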