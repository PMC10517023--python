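# Methods

## Problem

Polygenic risk models trained predominantly on one ancestry transfer poorly
to other ancestries and to admixed individuals: allele frequencies, LD
patterns and confounding differ across populations, so a score fitted to
European-ancestry dosages degrades on everyone else.  `dispred` addresses
this by separating what in the genotype signal is *ancestry* from what is
*phenotype*, building the risk model on the phenotype part only, and then
recombining it with a sparse model on the raw dosages.

## The three-stage model

**Stage 1 — disentangling autoencoder.**  An encoder F_θ maps the dosage
vector x ∈ [0,2]^m to two latent blocks, z_a (ancestry-specific) and z_d
(phenotype-specific); a decoder G_θ′ reconstructs x from [z_a ‖ z_d].
Training minimises

    L = L_recon + ramp(t)·α_d·L_SC(z_d | y) + ramp(t)·α_a·L_SC(z_a | a)

where L_recon is the mean squared reconstruction error and L_SC is the
supervised contrastive loss: the batch is duplicated into 2N views, each
embedding is L2-normalised, and for every view i with same-label set S(i)

    L_SC = −Σ_i (1/|S(i)|) Σ_{s∈S(i)} log [ exp(u_i·u_s/τ) / Σ_{r≠i} exp(u_i·u_r/τ) ].

The temperature τ sits inside the exponentials; placing the division by τ
outside both exponentials would cancel in the ratio and make the parameter
inert.  Same-phenotype pairs are pulled together in z_d, same-ancestry pairs
in z_a, so each block organises around one factor.  The ramp holds both
contrastive weights at zero for the first N₁ epochs (pure reconstruction
warm-up), rises linearly to the full α_* between N₁ and N₂, and stays there.
Ancestry labels are needed only during training; embedding a new individual
requires genotypes alone.

**Stage 2 — latent risk model.**  Ordinary least squares of the binary
phenotype on z_d; scores p_z are the fitted linear values.  Rank-deficient
designs fall back to the minimum-norm solution and are flagged.

**Stage 3 — ensemble.**  p_e = α·p_z + β·p_x, where p_x comes from a Lasso
on the raw dosages (regularisation path of 10 penalties, 5-fold CV,
max_iter 5000, tol 1e-3).  (α, β) are found either by exhaustive search of
the grid {0.1, …, 1.5}² maximising validation AUC (ties broken toward the
smallest α, then β), or by full-batch gradient descent from (1.1, 0.9) for
5000 epochs.  AUC is not differentiable, so the gradient search minimises
the mean squared error between p_e and the labels, consistent with the
least-squares choice of stage 2; a logistic-loss variant is available.
Batching is unnecessary for a convex two-parameter objective.

## Default hyperparameters

| parameter | default | notes |
|---|---|---|
| dim_za, dim_zd | 40, 40 | latent widths |
| τ | 0.03 | contrastive temperature |
| α_d, α_a | 1e-4 | latent-loss weights (real-cohort scale) |
| N, N₁, N₂ | 500, 100, 250 | epochs and ramp breakpoints |
| batch, lr | 256, 5e-3 | Adam, constant rate |
| encoder | m→512→256→128→80 | ReLU hidden, linear output |
| decoder | 80→256→512→m | mirror taper |

Hidden widths are configurable; the taper matches the stated layer counts
(four encoder layers, three decoder layers).  Inputs are raw dosages after
per-SNP mean imputation — no standardisation, because reconstruction is
defined in dosage space.  The last incomplete mini-batch is kept (the
contrastive loss handles any batch size ≥ 2); singleton remainders are
skipped because the loss is undefined there.

### Unit-norm latent blocks

The contrastive loss L2-normalises embeddings before the dot products, so it
only ever constrains latent *directions*.  The block *magnitudes* remain
free, and the decoder will happily use them as an unconstrained side channel
for whatever reconstruction finds useful — including ancestry information
that the loss was supposed to keep out of z_d.  In our synthetic
experiments a linear probe read ancestry from raw z_d at 0.85–0.94 accuracy
even when the normalised directions probed at chance (~0.46).  The
`unit_norm_latents` option therefore constrains each block to the unit
hypersphere (L2 normalisation as the encoder's final operation, decoder
consuming the normalised concatenation), closing the side channel.  It is
off by default and switched on in the synthetic experiment configurations.

### Synthetic-scale contrastive weights

At the simulated-cohort scale (hundreds of SNPs, ~10³ training individuals)
the reconstruction and contrastive terms balance differently than on real
cohorts, and α_* = 1e-4 leaves the contrastive term essentially inert.  The
canned experiments (`dispred.experiments.SYNTHETIC_DAE`) use α_* = 0.01,
τ = 0.03, 250 epochs with the ramp over epochs 30–80, and unit-norm latent
blocks.  These were tuned once on the probe-recovery design and then frozen.

## Baselines

* **PRS-Clumping** — greedy LD thinning by GWAS significance: the most
  significant unremoved SNP is retained and removes same-chromosome SNPs
  within 1 Mb whose squared Pearson correlation (computed on the training
  cohort's dosages) exceeds 0.5; the APOE variants rs429358/rs7412 are
  anchors, retained unconditionally.  Whether anchors themselves prune
  neighbours is ambiguous; by default they do not (`anchors_prune` flips
  it).  The score is the β-weighted dosage sum over retained SNPs.
* **PRS-Bayes** — Gaussian naive Bayes on all SNPs (no sparsity); the only
  free hyperparameter, the variance-smoothing floor, is chosen on a log grid
  by 5-fold CV AUC.
* **PRS-Lasso** — the stage-3 raw-dosage Lasso evaluated alone.
* **NN** — feed-forward ReLU network with a sigmoid output and
  cross-entropy loss; 200 epochs, lr 5e-3, batch 64, Adam.  Hidden widths
  default to (64, 32) and are configurable.

Neural components (autoencoder and NN baseline) run on a compact numpy MLP
engine with hand-derived backpropagation and Adam (`dispred._mlp`); the
contrastive gradient is analytic and verified against finite differences.
All arithmetic is float64, so identically configured runs are bit-identical.

## Synthetic cohorts

The simulator produces the structure the method assumes, with known ground
truth:

* **Allele frequencies** — ancestral frequencies uniform on [0.05, 0.95];
  per-population frequencies Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F)
  with drift F per population, clipped to [0.01, 0.99] so no SNP is
  monomorphic (degenerate columns would break correlation-based clumping).
* **Admixture** — per-individual proportions i.i.d. Dirichlet(α); the
  default α = 0.2 (symmetric, K = 3) yields a majority of near-pure
  individuals plus a substantial admixed minority, the regime the
  evaluation protocol needs.  Self-reported ancestry is the argmax of the
  proportion row, mirroring how self-report tracks majority ancestry.
* **Genotypes** — dosage_ij ~ Binomial(2, q_i·p_j), independent across
  entries; no within-population LD beyond the admixture-induced correlation.
* **Phenotype** — liability = Σ β_j g_ij + c·(q·s) + ε, ε ~ N(0,1), with 20
  causal SNPs, β ~ N(0, 0.35²), a fixed per-population shift vector s
  (evenly spaced in [−1, 1]) scaled by confound_strength (default 1.0), and
  the case threshold at the empirical (1−prevalence) liability quantile so
  the case fraction is exact per draw.  Default prevalence 0.5 reflects a
  balanced case-control sampling design.  Defaults give roughly equal
  genetic and noise liability variance with a moderate ancestry confounder —
  ancestry alone is predictive of the label, which is exactly the structure
  the disentangler must strip from z_d.
* **Missingness** — entries dropped i.i.d. at rate 0.05 by default,
  exercising the >10% per-SNP missingness filter and mean imputation.

What the simulator does **not** emulate: haplotype structure and
recombination LD, relatedness, age/sex covariates, genotyping batch
effects, and the scale of biobank cohorts.  Passing tests therefore show
the machinery is correct under the assumed generative model, not that the
method's real-cohort performance numbers transfer.

## Evaluation protocol

AUC is the Mann–Whitney probability that a random case outscores a random
control, ties counted ½.  Test individuals are stratified by ancestry
proportions: group k if q_k exceeds the cut-off (0.90 by default; 0.65 is
the lenient variant), else "admixed".  The heterogeneity analysis sorts
individuals by decreasing population variance of their proportion rows
(homogeneous → admixed; any positive rescaling of the variance gives the
same ordering, so the population/sample-variance choice is immaterial) and
reports per-method AUCs in fixed windows (750 wide, stride 50 at full
scale; clamped to the cohort when smaller).  Trailing individuals short of
a full window are dropped; single-class windows report NaN rather than
aborting.  Disentanglement probes are 5-fold cross-validated
logistic-regression accuracies on a latent block.

## Canned experiments and problem sizes

* **Probe recovery** (`experiments.probe_recovery_trial`): 3 populations,
  FST 0.1, Dirichlet 0.2, n = 2000, m = 500, 20 causal SNPs,
  confound 1.0; expected outcome: ancestry probe ≥ 0.9 on z_a, within 0.15
  of chance on z_d, phenotype probe above chance on z_d.  Because the
  confounder makes ancestry partially predictable from the phenotype label
  itself, a per-cohort floor exists: on some draws predicting population
  from y alone already exceeds chance + 0.15, and no representation that
  predicts y can probe below that.  The criterion is therefore evaluated
  across seeds (4 of 5 expected to pass).
* **Cross-population transfer** (`experiments.crosspop_trial`): train and
  validate only on individuals assignable (q > 0.9) to populations 1–2,
  test on the admixed group; n = 1500, m = 300, 120 epochs.  Expected
  outcome: the ensemble's admixed-test AUC within 0.02 of the raw Lasso's
  in ≥ 8/10 replicates.

These sizes keep a full test run and the acceptance script each under
~10 minutes on a single CPU while leaving the qualitative behaviour intact.

## Numerical notes and limitations

* Contrastive softmax rows are max-shifted before exponentiation; the
  diagonal is excluded via −∞ similarity.  Zero-norm embeddings are guarded
  at 1e-12.
* Split rounding uses largest-remainder allocation per phenotype class, so
  realised fractions deviate by at most one individual per class.
* Grid search returns the lexicographically smallest optimum; gradient
  search is unconstrained (negative weights are possible in principle).
* Zero-variance dosage columns are skipped from LD pruning (correlation
  undefined) with a warning, and guarded by the NB smoothing floor.
* The latent OLS treats a binary y as continuous; it is a ranking score,
  not a calibrated probability.  No covariate adjustment is performed.
* On cohorts whose latent model transfers poorly, the validation-tuned
  ensemble can underperform the Lasso alone on a shifted test group; the
  grid's minimum weight of 0.1 per component guarantees both models always
  contribute.
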