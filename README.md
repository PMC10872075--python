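# mmdrp — multi-modal drug response prediction

`mmdrp` predicts how strongly a cancer cell line responds to a drug, expressed
as the **area above the dose–response curve (AAC)**, a [0, 1] summary of
viability loss across the tested dose range (higher = stronger response). It
is aimed at computational pharmacogenomics: combining several kinds of
cell-line molecular profiles (mutation, copy number, expression, proteomics,
miRNA, metabolomics, histone marks, RPPA) with a learned representation of
drug structure to predict responses for *unseen* cell lines, drug scaffolds,
or cancer types.

## The model

For a cell line *c* with omic profiles {x_m} and a drug *d* with molecular
graph G:

1. **Per-omic encoders.** Each profile x_m is standardized with fold-local
   statistics and compressed to a latent z_m by an autoencoder-style encoder
   (pretrainable by reconstruction, fine-tuned or frozen downstream).
2. **Drug encoder.** An AttentiveFP-style graph attention network encodes G:
   rounds of attention-weighted neighbour aggregation with gated (GRU) state
   updates per atom, then a molecule-level super node, giving a drug latent
   z_d. The ablation baseline uses extended-connectivity fingerprints (ECFP)
   instead.
3. **Low-rank multimodal fusion (LMF).** Each latent is augmented with a
   constant 1 and projected through rank-decomposed factors; the fused vector
   is `sum_i prod_m ([z_m, 1] W_m^(i))` — the contraction of the latents'
   outer product with a rank-r fusion tensor. Concatenation and summation
   fusers are available as baselines.
4. **Head + weighted RMSE.** A small MLP maps the fused vector to the
   predicted AAC. Training minimises `sqrt(sum w_i e_i^2 / sum w_i)` where the
   weights come from **label distribution smoothing (LDS)**: each training
   label's weight is inversely proportional to the kernel-smoothed histogram
   density of the AAC target, countering the heavy skew toward ineffective
   pairs.

Two presets bracket the design space: `mmdrp-base` (ECFP + concatenation, no
LDS) and `mmdrp-refined` (graph encoder + LMF + LDS). An elastic-net linear
regression on omics + fingerprint bits serves as the classical control.

Evaluation is leakage-free by construction: 5-fold cross-validation grouped
by cell line, Bemis–Murcko drug scaffold, both simultaneously, or cancer
type, with fold-local standardization and LDS weights. Combined validation
predictions feed a trailing moving-average MAE curve over the AAC range,
subgroup RMSEs (e.g. AAC ≥ 0.7, targeted vs untargeted drugs), a drug
repurposing screen, and integrated-gradients attribution of single
predictions to omic features and drug atoms.

All neural components run on a small numpy reverse-mode autodiff engine
included in the package, so the library needs no deep-learning framework.

## Worked example

Because real screens (DepMap omics, CTRPv2 dose–response) are external and
GPU-scale, the package ships a synthetic cohort generator whose AAC marginal
is calibrated to the published CTRPv2 summary (mean 0.145, median 0.091) and
which plants a known omic-feature × drug-substructure interaction (an
acryloyl/acrylamide warhead, as carried by covalent kinase inhibitors such as
ibrutinib).

```python
import numpy as np
from mmdrp import (SyntheticConfig, generate_cohort, ModelConfig,
                   train_fold, split, subgroup_rmse)

matrices, catalog, records, truth = generate_cohort(SyntheticConfig(seed=101))
fold = split(records, "cell_line", 5, seed=1)[0]
config = ModelConfig.mmdrp_refined(omic_types=["EXP", "CNV"], seed=1)
model, preds = train_fold(records, fold, matrices, catalog, config)

err = np.array([p.pred_aac - p.true_aac for p in preds])
print(f"validation RMSE: {np.sqrt((err ** 2).mean()):.3f}")
print(subgroup_rmse(preds, aac_range=(0.7, 1.0)))
```

Output from this exact snippet:

```
validation RMSE: 0.134
{'empty': False, 'n': 13, 'rmse': 0.13412771986267308}
```

The overall validation RMSE (0.134) sits well below the label standard
deviation of the cohort (~0.19): the model generalises to unseen cell lines.
The second line is the strong-response subgroup (true AAC ≥ 0.7): 13
validation pairs predicted with RMSE 0.134 — the range that single-score
reporting hides and that LDS training targets.

The same pipeline is scriptable from the shell:

```bash
mmdrp simulate  -c config.yaml
mmdrp split     -c config.yaml
mmdrp train     -c config.yaml          # --no-lds / --fusion concat for ablations
mmdrp evaluate  -c config.yaml
mmdrp attribute -c config.yaml --checkpoint out/model_fold0.npz \
                --cell-line CL0001 --drug ibrutinib
```

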