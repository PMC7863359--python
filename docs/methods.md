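# Methods

This note documents the modelling choices behind `sigsurvnet`: the network
and its training protocol, the evaluation metric, the attribution method,
the synthetic-data generator the tests rely on, and the numerical decisions
taken where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and filters

Inputs are gene-level expression (log2-scale, mean-normalized values of the
kind Xena's `HiSeqV2_PANCAN` provides), GISTIC-thresholded integer copy
number in {−2…2}, and a clinical table.  Assembly intersects the three
sources on sample ids and intersects genes with the pathway union, then
applies two filters:

* samples with survival **greater than** 3000 days are excluded (3000
  itself is retained — the boundary follows the strict inequality);
* genes whose expression is **exactly 0.0 in every training sample** are
  excluded, from the inputs and from the mask.  No epsilon threshold is
  applied, and only the training partition is consulted so the test
  partition cannot influence the input space.

Stage strings collapse a/b/c sub-stages to the parent (I–IV → 1–4);
unparsable stages are flagged and imputed to the median ordinal of the
parsable rows.  Samples with any missing omics or age value are dropped
(counted and logged).  Gene symbols are taken as-is; no identifier
conversion is attempted.  Pathway genes absent from the data are dropped
from the mask; a pathway left with no genes is an error, because its
network column would be untrainable.

## Network

The architecture is a sparse, pathway-structured regressor:

1. **Gene state.** Each gene has its own affine map
   (expression, copy number) → ReLU state.  Genes in several pathways share
   one state; the edges to each pathway have separate weights.
2. **Masked pathway layer.** One unit per pathway.  The binary membership
   mask multiplies both the weight matrix and its gradient, so a masked-out
   connection is exactly zero at every step of training — verified by
   finite differences in the tests.
3. **Inception stack.** The pathway vector is a 1-channel sequence in the
   fixed canonical pathway order.  Two inception blocks apply parallel 1-D
   convolutions (kernels 1/3/5, 8 filters each, 'same' padding) plus a
   width-3 max-pool branch, concatenate on channels and apply dropout.
   Note the convolution is ordering-sensitive: permuting pathway order
   changes the model family.  The canonical order is fixed once (the order
   of the packaged gene-set file) and used everywhere.
4. **Dimension reduction and skip.** A 1×1 convolution compresses the
   concatenated channels to 2 before flattening.  Without it the flattened
   head has ~72k parameters and memorizes cohorts of a few hundred samples
   (observed as train c-index ≫ test c-index).  The flattened output is
   concatenated with the standardized clinical covariates *and with the raw
   pathway vector*.  The skip path exists because convolution filters are
   shared across positions: they cannot express "weight pathway 27
   specifically", and on short training schedules the dense layer alone did
   not recover that information through the conv features.  Both parts are
   configuration flags (`reduce_channels`, `pathway_skip`); setting
   `reduce_channels=0, pathway_skip=False` restores the plain
   flatten-then-dense head.
5. **Head.** One dense ReLU layer (32 units, dropout, L2) and a single
   linear output unit.

**Initialization.** Fan-in-scaled uniform, but *non-negative* for the two
omics-facing layers (gene state and masked layer).  With symmetric signs
the member-gene states of a pathway cancel inside the pathway unit at
initialization, and the few hundred optimizer steps of a typical run are
not enough to undo that: pathway activations stayed nearly uncorrelated
with the signal their member genes carry.  Non-negative initialization
starts each pathway unit as a consensus aggregate of its member genes.  The
convolutional and dense layers use symmetric fan-in-scaled uniform init.
The output bias starts at the mean scaled training survival so short runs
do not spend their first epochs learning the offset.

**Training.** MSE on survival scaled by 1000 (days/1000 keeps targets O(1);
raw-day targets destabilize training), Adadelta with its canonical settings
(lr 1.0, decay 0.95, epsilon 1e−6), batch size 32, dropout 0.3 and L2 1e−4
by default.  After each epoch the c-index is computed on the train and
held-out partitions; the parameters with the best held-out c-index are
checkpointed and restored at the end, and the full per-epoch log is kept.
Same seed + config + data gives identical results on one machine; bitwise
equality across BLAS builds is not promised.

**Vital status as an input.** The clinical block includes vital status, as
the method specifies.  For censored patients this leaks information about
the recorded (censored) time; the flag `include_vital_status=False` drops
it, but the default follows the method as stated rather than silently
fixing it.

## Concordance index

c-index = (C + T/2) / (C + D + T) over unordered sample pairs.  Pairs with
tied **true** times carry no ordering information and are excluded; tied
**predictions** earn half credit (T).  The alternative reading — counting
true-time ties into T — is available via `tied_truth="count"`.  Censoring
plays no role in pair eligibility: all samples are treated as events,
matching a formula that never references vital status.  This is a known
limitation relative to censoring-aware concordance (e.g. Harrell's c with
admissible pairs); the tests cross-check the implementation against a
brute-force enumerator and against lifelines on event-only data.

## Smoothgrad pathway relevance

Relevance of pathway p for one patient is the average, over `n_noise`
replicates, of ∂(predicted survival)/∂(pathway activation p), where each
replicate adds i.i.d. Gaussian noise to the pathway activations.  Choices:

* **Attribution point**: the pathway-layer activations, not the raw gene
  inputs — the perturbation is applied to "individual signaling pathways".
  Input-level gradients aggregated per pathway would be an alternative;
  the activations are where the pathway abstraction lives.
* **Noise scale** = (max − min) × 0.1 of the pathway-activation matrix over
  the whole dataset.  A constant matrix yields scale 0 with a warning.
* **n_noise defaults to 50**; with scale 0 and one replicate the estimate
  equals the plain gradient exactly (tested), and for a purely linear head
  it equals the analytic coefficients regardless of noise (tested).
* Relevance is reported in days of predicted survival per unit activation
  (the internal 1/1000 target scaling is undone).

Per-pathway scores pooled over patients are summarized by Gaussian KDE with
Scott's bandwidth on a grid spanning [min − 3bw, max + 3bw]; zero-variance
columns are flagged as point masses rather than smoothed.  Pathways are
ranked by **mean absolute relevance**; pathways whose |mean| is below a
configurable fraction (default 0.25) of their SD are flagged
"high-variance / zero-mean" — their relevance sign is inconsistent across
patients, so a density plot shows a wide zero-centred hump.

## Synthetic-data generator

A linear-Gaussian model chosen for analytical transparency:

| parameter | default | meaning |
| --- | --- | --- |
| `n_samples` | 400 | cohort size (order of a TCGA cohort) |
| `n_pathways` | 46 | canonical pathway count and names |
| `genes_per_pathway` | 43 | ≈1800 unique genes, the scale of the real gene universe |
| `overlap_fraction` | 0.1 | fraction of genes shared between adjacent pathways |
| `causal_pathways` | 5 indices | pathways whose activity drives survival |
| `effect_sizes` | ±300 days | survival shift per unit causal activity |
| `noise_sd_expression` | 1.0 | gene-level expression noise (log-scale units) |
| `noise_sd_survival` | 200 days | survival noise |
| `cnv_coupling` | 0.3 | probability a gene's copy number tracks its pathway activity |
| `censor_fraction` | 0.2 | fraction censored uniformly below their event time |
| `baseline_days` | 1500 | survival intercept |

Latent pathway activities are i.i.d. standard normal per sample; expression
is a loading-weighted (U(0.5, 1.5)) sum of the member activities plus
noise, shifted to be non-negative; copy number is rounded, clipped activity
plus noise for coupled genes, pure noise otherwise; survival is baseline +
Σ effect·activity + small fixed clinical effects (−5 days/year of age
beyond 60, −100 days/stage beyond II) + noise, clipped to [1, 3000] so the
survival-cap filter removes nothing (an `n_over_cap` option injects samples
above the cap to exercise the filter; a `zero_genes` option zeroes chosen
genes to exercise the expression filter).  Censoring is uninformative.  The
defaults put the pathway signal (sd ≈ √5·300 ≈ 670 days) well above the
noise and clinical terms, so relevance recovery is attributable to the
pathways; censoring at 0.2 keeps the observed-time signal dominant while
still exercising the censoring path.

What the generator does **not** emulate: TCGA marginal distributions, batch
effects, real KEGG memberships, heavy-tailed expression, informative
censoring, or correlated clinical covariates.  Passing tests show the
method recovers planted linear-Gaussian signal; they do not certify
performance on real cohorts.

The packaged 46-pathway gene-set file carries the canonical pathway names
with synthetic placeholder memberships (the real ~1967-gene membership is
not published); users supply their own GMT for real analyses.

## Experiment protocols and problem sizes

`ratio_sweep_experiment` redraws a seeded split per repetition at each
training fraction and records train/held-out c-index for the network and
the random-forest baseline (same flattened features: expression ⊕ copy
number ⊕ clinical).  `pathway_subset_experiment` samples a pathway subset
per repetition, rebuilds the mask on the member genes and retrains.  The
full protocol uses 50 repetitions at training fractions 50–90% and subset
sizes 10/20/30/40; the package's test suite and acceptance script run the
desk-scale version — 10 repetitions, fractions {0.5, 0.7, 0.9}, subset
sizes {10, 40}, 25 epochs — which preserves the compared quantities at
sizes a laptop CPU handles in minutes.  All per-repetition values and seeds
are stored in the report; printed means are re-aggregated from the stored
rows.

## Numerical details and degenerate inputs

* Convolutions are stride-1 'same'-padded; kernel and pool widths must be
  odd.  Max-pool padding uses −∞ so edge windows never invent values.
* Dropout is inverted (scaling at train time); inference is deterministic.
* An all-zero mask column raises at construction (an untrainable pathway).
* c-index with all true times equal raises (no evaluable pairs); training
  logs NaN for such an epoch partition instead of aborting.
* `epochs=0` returns the initialized model with an empty log.
* Expression is standardized per gene at fit time (constant genes get
  sd 1); age likewise.  Copy number, gender, stage and vital status enter
  raw.  Whether the original method standardized clinical features is
  unstated; standardizing age (the only wide-range clinical covariate) is
  this package's choice.
* A non-finite training loss raises immediately, reporting the epoch.

## Known limitations

* The MSE loss treats censored times as exact event times; only the vital-
  status covariate tells the model otherwise.  A censoring-aware loss is
  deliberately out of scope.
* Attribution is sensitivity-based: a pathway the model is sensitive to is
  not necessarily causal in the biological sense, and relevance scores are
  a function of the trained model, not of the data alone.
* The pathway ordering entering the convolution is a modelling artifact;
  results for ordering-sensitive configurations should be compared only
  under the same canonical order.
* Cross-platform bitwise reproducibility is not guaranteed (BLAS reduction
  order); statistical conclusions are insensitive to this.
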