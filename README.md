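# sigsurvnet

Pathway-masked deep survival-time regression for cancer multi-omics, with
smoothgrad pathway-relevance attribution.

## The problem

Survival prediction from tumour molecular profiles usually feeds thousands
of gene-level features into dense networks that are accurate but opaque.
`sigsurvnet` takes the opposite route: it wires gene expression and copy
number through **known signaling-pathway membership**, so the network's
middle layer has one unit per pathway (45 KEGG signaling pathways plus the
cell cycle — 46 in total) and the question *"which signaling pathways drive
this cohort's survival predictions?"* has a direct, per-patient answer.

It is aimed at computational biologists who have gene-level expression
(log2-scale, e.g. Xena `HiSeqV2_PANCAN`), GISTIC-thresholded copy number,
and a clinical table (age, gender, stage, vital status, survival days), and
want both a survival-time regressor and a ranked account of pathway
relevance.

## The model

For patient *i* with expression x<sub>g</sub> and copy number c<sub>g</sub>
per gene g:

1. **gene state** s<sub>g</sub> = ReLU(w<sub>g1</sub>x<sub>g</sub> + w<sub>g2</sub>c<sub>g</sub> + b<sub>g</sub>) — per-gene weights, not shared;
2. **pathway layer** a<sub>p</sub> = ReLU(Σ<sub>g∈p</sub> v<sub>gp</sub>s<sub>g</sub> + b<sub>p</sub>) — the binary gene×pathway mask M is a hard
   structural constraint: v<sub>gp</sub> exists only where M<sub>gp</sub>=1;
3. the 46-vector **a** (fixed canonical pathway order) passes through 1-D
   **inception blocks** (parallel convolutions with kernel sizes 1/3/5 plus a
   max-pool branch, channel-concatenated, dropout) and a 1×1
   dimension-reduction convolution;
4. the flattened output is concatenated with clinical covariates
   (standardized age, gender, ordinal stage, vital status) and with **a**
   itself (a skip path), then a dense ReLU layer with L2 and dropout feeds a
   single linear unit predicting survival time (days / 1000).

Training: MSE loss, Adadelta, batch size 32; after every epoch the
**concordance index**

&nbsp;&nbsp;&nbsp;&nbsp;c-index = (C + T/2) / (C + D + T)

is computed on the train and held-out partitions and the parameters with the
best held-out c-index are kept.  Pathway relevance uses **smoothgrad**: the
gradient of predicted survival with respect to each pathway activation,
averaged over replicates perturbed with Gaussian noise of standard deviation
(max − min) × 0.1 of the activation range; per-pathway score distributions
are summarized by Gaussian KDE and ranked by mean absolute relevance.

A linear-Gaussian **synthetic-data generator** with known causal pathways
makes the whole method testable offline, and a random-forest regression on
the same flattened features serves as the baseline.

## Worked example

```python
import sigsurvnet as ssn

# a synthetic cohort: 400 patients, 46 pathways, 5 causal at ±300 days
ds = ssn.generate(ssn.SyntheticSpec(seed=1), out_dir="cohort/")
data, mask = ssn.assemble_dataset(
    ssn.load_matrix("cohort/expression.tsv"),
    ssn.load_matrix("cohort/copy_number.tsv", "integer"),
    ssn.load_clinical("cohort/clinical.tsv"),
    ssn.load_pathways("cohort/pathways.gmt"))

split = ssn.split_samples(data.n_samples, 0.8, seed=7)
est = ssn.DeepSigSurvNet(mask=mask, epochs=30, random_state=7)
ssn.train(est, data, split)
print(f"best held-out c-index {est.best_test_cindex_:.4f} "
      f"at epoch {est.best_epoch_}")

rel = ssn.smoothgrad_relevance(est, data, n_noise_samples=50, seed=7)
ranked = ssn.rank_pathways(ssn.density_summary(rel))
print(ranked.head(6)[["rank", "pathway", "mean", "sd", "mean_abs"]].to_string(index=False))
print("causal truth:", [ds.pathways.names[i] for i in ds.truth.causal_pathways])
```

Output:

```
best held-out c-index 0.6465 at epoch 27
 rank         pathway       mean        sd  mean_abs
    1        PI3K-Akt -59.374060 22.503850 59.374060
    2 Phospholipase D -49.867204 18.734392 49.912380
    3        TGF-beta  44.054946 19.513302 44.160194
    4             Wnt  38.220555 18.616085 38.504012
    5            mTOR  30.708179 18.539988 31.684999
    6        JAK-STAT -22.475340 16.255232 24.049916
causal truth: ['TGF-beta', 'Phospholipase D', 'mTOR', 'PI3K-Akt', 'Wnt']
```

The held-out c-index of 0.65 says that for about two patient pairs in three
the model orders survival correctly (0.5 is chance).  The five planted
causal pathways occupy the top five relevance ranks, the signs of their mean
relevance match the planted effect directions (±300 days per unit
activity), and there is a visible gap to the first non-causal pathway.
Relevance units are days of predicted survival per unit pathway activation.

The same pipeline is available from the shell:

```bash
sigsurvnet pipeline --config run.yaml --seed 1 --out results_dir/
```

with stages `simulate`, `assemble`, `train`, `evaluate`, `interpret`,
`experiment` (repeated-subsampling sweeps over training fraction or number
of pathways) also runnable individually.

## Layout

| path | contents |
| --- | --- |
| `src/sigsurvnet/pathway_data.py` | GMT / Xena-TSV / clinical loaders, dataset assembly, connection mask |
| `src/sigsurvnet/synthetic.py` | ground-truth generator |
| `src/sigsurvnet/model.py` | the estimator (`DeepSigSurvNet`) and training protocol |
| `src/sigsurvnet/_nn.py` | numpy layers, backprop, Adadelta |
| `src/sigsurvnet/evaluation.py` | c-index, splits, random-forest baseline, sweep experiments |
| `src/sigsurvnet/interpretation.py` | smoothgrad relevance, KDE summaries, ranking |
| `src/sigsurvnet/cli.py` | `sigsurvnet` command-line pipeline |
| `docs/methods.md` | modelling assumptions, parameter choices, limitations |
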