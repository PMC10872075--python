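# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `mmdrp`, in the order the pipeline runs.

## Prediction target and preprocessing

The target is the area above the dose–response curve (AAC): one minus the
trapezoidal mean viability over the log10-dose window, bounded in [0, 1],
higher = stronger response (`generate_dose_response` makes this definition
concrete for a descending Hill curve `v(d) = 1 / (1 + (d/EC50)^h)`). AAC is
preferred over IC50 because it is defined for every tested pair and
distinguishes compounds with equal half-maximal points but different
potency profiles.

Omic matrices are standardized per feature with statistics estimated **on the
training split of the current fold only** and applied identically to both
splits. Columns constant on the training rows get σ := 1 (the feature maps to
zero) rather than being dropped, so feature indices stay aligned for
attribution. Missing cells are an error in strict mode and mean-imputed with
a logged count otherwise. Identifier matching is exact-string; a strip/upper
normalization hook is opt-in. MUT is accepted only as binary per-gene
indicators.

## Label distribution smoothing (LDS)

Screened pairs pile up near AAC 0. LDS estimates the label density with a
histogram over [0, 1] (default 100 bins) convolved with a Gaussian kernel
(window 5 bins, σ = 2 bins; triangular and no-kernel variants available).
Kernel mass falling outside [0, 1] is truncated and the kernel renormalized
per bin, avoiding edge down-weighting. Each sample's weight is the inverse of
its bin's smoothed density, floored at 1e-4 and normalized to mean one so the
weighted loss stays on the unweighted scale. Weights act as loss multipliers,
not resampling probabilities — deterministic and seed-free.

One property worth recording: widening the kernel does *not* monotonically
shrink the max/min weight ratio from the unsmoothed end — a small kernel
moves an isolated rare sample's own mass out of its bin and so *raises* its
weight. Shrinkage toward uniformity is monotone from the default width
upward, which is what the property test asserts.

## Drug representations

`featurize_smiles` builds a heavy-atom graph with a fixed, documented feature
layout: element one-hot over (C, N, O, S, F, Cl, Br, I, P, B, other), degree
one-hot 0–5, formal charge, hybridization one-hot, aromaticity, and total-H
one-hot 0–4; bonds carry type, conjugation, ring membership, and stereo
one-hots. Out-of-vocabulary elements map to `other` with a warning.

The graph encoder follows the AttentiveFP recipe: K rounds (default 2) of
atom-level message passing — neighbour messages formed from the neighbour
state and the bond features, attention scores from (state, message) pairs
normalized per destination atom, context aggregated and fed to a shared GRU
update — then T rounds (default 2) in which a virtual super node initialized
with the atom-state sum attends over all atoms with its own GRU. The final
super-node state is linearly projected to the drug latent. Isolated atoms
receive a zero-featured self-loop so their context reduces to self; all
aggregation uses segment sums/softmaxes, making the encoding invariant to
atom order (tested to 1e-5). Many molecules are encoded as one disjoint
batch graph for speed; batch and per-molecule paths agree to 1e-9.

ECFP (Morgan) fingerprints and Bemis–Murcko scaffolds come from RDKit.
Acyclic molecules have an empty scaffold and map to the sentinel
`ACYCLIC:<canonical smiles>` so each forms its own split group.

## Fusion

LMF augments each modality latent with a constant 1 and projects it through
r factor matrices of shape (d_m + 1, d_out); the fused vector is the sum over
rank terms of the elementwise product across modalities — exactly the
contraction of the latents' outer product with the rank-r reconstructed
fusion tensor (verified against a brute-force tensor oracle to 1e-6). Because
of the 1-augmentation, additive fusion is a special case.

Two stabilizations matter in practice and are deliberate design choices:
latents pass through tanh before the multiplicative product (bounding the
product's dynamic range), and factors use an *additive warm start* — bias
rows start at 1 and weight rows small, so each rank term begins as
`prod_m(1 + eps_m) ≈ 1 + sum_m eps_m` and multiplicative interactions grow
during training. Without these, LMF optimisation at desk scale is
high-variance.

## Assembled model and training

Encoders (optionally warm-started from reconstruction-pretrained
autoencoders; `freeze_encoders` pins them), the drug encoder, the fuser and a
one-hidden-layer head form one differentiable model on the package's numpy
autodiff engine. Training minimises weighted RMSE
`sqrt(Σ w e² / Σ w)` with Adam (lr 2e-3) plus decoupled weight decay (1e-2),
minibatches of 512, up to 400 epochs. The head's output layer is initialized
near zero so the network starts at the zero function; predictions for unseen
cell lines then stay tame early in training and early stopping (patience 80)
can select the generalising phase. Early stopping tracks the *training
objective on validation data*: when LDS is on, validation labels are scored
by the train-fitted smoothed density — leakage-free, and it keeps snapshot
selection aligned with the skew-aware objective. Predictions are clipped to
[0, 1] at report time only.

Presets: `mmdrp-base` = ECFP + concatenation + no LDS;
`mmdrp-refined` = graph encoder + LMF + LDS. The elastic-net control uses
identical folds and fold-local standardization on concatenated omics + ECFP
bits. `random_search` samples configurations seed-deterministically and
scores them by mean cross-validation RMSE.

## Cross-validation schemes

Four grouping keys — cell line, drug scaffold, both simultaneously, cancer
type — with groups shuffled by seed and dealt to the lightest fold by record
count (lexical base order for reproducibility). The simultaneous scheme
partitions cell lines and scaffolds independently; fold i validates on
(cell-line group i × scaffold group i), trains on records touching neither,
and *discards* the mixed quadrants — the stricter of the two possible
constructions, and the discard count is reported. The complete-profile filter
keeps records whose cell line appears in every supplied omic matrix and
reports retention percentages.

## Evaluation and the repurposing screen

Combined validation predictions (exactly one per non-discarded record) feed:
a trailing moving-average MAE over a 500-sample window along the true-AAC
sorted range (ties broken by record order); subgroup RMSE with explicit
"empty" results rather than zeros (note the RMSE of a single prediction
equals its MAE); and a repurposing screen that flags (drug, cell line) pairs
whose measured AAC exceeds every cognate (approved-lineage) AAC by ≥ 0.2
while the model predicted that response with MAE ≤ 0.2 on a first-seen cell
line. Drugs without approved lineages are skipped with a warning. The
"targeted" flag is catalog data, not computed.

## Integrated gradients

Attribution of one prediction to its inputs: `(x_j − x'_j)` times the
quadrature of `∂F/∂x_j` along the straight path from baseline x' to input x
(trapezoid rule, 64 steps by default; right-Riemann available). For
standardized omics the zeros baseline *is* the training-mean profile. Drug
attributions target the atom feature matrix (a continuous relaxation) and can
be summed per atom; bond features are excluded — their gradient path through
both endpoints makes per-bond credit ambiguous, a known limitation. The
completeness residual `|Σ attributions − (F(x) − F(x'))|` is always computed
and reported. Exact for linear models at any step count; < 1e-3 relative at
512 steps on smooth two-layer models; relu kinks in the full pipeline limit
quadrature accuracy to ~1e-2 relative.

## Synthetic study conditions

The generator emulates the properties the method is built around, not real
biology:

* **AAC skew.** Base responses follow a two-component Beta mixture,
  `0.8511·Beta(0.7498, 6.42) + 0.1489·Beta(2.79, 4.63)`, calibrated
  (scripts/calibrate_skew.py, grid + simplex moment/quantile matching) so the
  population mean/median are 0.14499/0.09100 — matching the published CTRPv2
  summary of mean 0.145, median 0.091 within sampling error at n = 1e5.
* **Structured drug effects.** The base draw passes through a Gaussian
  copula whose latent carries a per-drug main effect (75% of z-variance): the
  marginal stays exactly the calibrated mixture, but some compounds are
  broadly potent and others inert, as in real screens. A per-record i.i.d.
  base would make most of the variance irreducible and no model could beat a
  mean predictor by a meaningful margin. The per-drug effect is a sparse
  random linear function of 16 shared ECFP bits (a pharmacophore-style
  synthetic QSAR), residualized against the warhead flag — so potency follows
  structure (learnable by both fingerprint and graph encoders) while the
  planted interaction below stays identifiable.
* **Planted interaction.** AAC gains `β · Φ(x_causal) · s_drug` (defaults
  β = 0.3) where x_causal is the first expression feature and s_drug flags an
  acryloyl/acrylamide substructure (SMARTS `C=CC(=O)N`), plus N(0, 0.03)
  noise, clipped to [0, 1]. Ridge regression on the oracle regressor recovers
  β within 20% at n = 2000.
* **Omics.** Rows are standard normal with equicorrelated feature blocks
  (size 5, ρ = 0.5) and lineage-specific block shifts (σ = 0.4); MUT
  thresholds the latent Gaussian at a 10% mutation rate. Block-diagonal
  covariance is deliberate: no attempt to mimic real gene–gene covariance.
* **Drugs.** A hard-coded fixture of 50 valid SMILES over 35 Murcko
  scaffolds, 10 of them warhead-bearing; targeted drugs receive 1–2 approved
  lineages at generation time. Hard-coding keeps scaffold splits
  deterministic and chemically valid.

What passing tests on this cohort do **not** show: robustness to real
gene–gene covariance, assay noise structure, missing profiles across
consortia, or dose-range heterogeneity; the generator's conditional
independencies are far cleaner than DepMap/CTRPv2.

## Problem sizes used in the deepest checks

The end-to-end signal-recovery check trains on the generator's default cohort
(100 cell lines × 40 drugs = 4000 pairs), fold 0 of split-by-cell-line, seeds
1–5, comparing the refined preset to the base preset and to a shuffled-label
control (training labels permuted, validation intact), and ranking the causal
expression feature by mean absolute integrated gradients over the ten
highest-AAC warhead validation pairs. The full run takes about six minutes of
CPU.

## Known limitations

* One model per omic combination; no modality dropout or missing-modality
  token — prediction with an absent configured modality is an error.
* The autodiff engine is float64, single-threaded numpy; it is sized for
  desk-scale cohorts, not 300k-pair screens.
* Bond features do not receive attributions.
* The narrow-kernel LDS non-monotonicity described above.
* GNN hyperparameters are deliberately small (hidden 48, K = T = 2); no
  pretraining of the drug encoder.
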