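# Methods

## The question and the estimand

Two diseases measured in separate case/control cohorts on a common gene
universe share a set of differentially expressed genes (DEGs). Classifying
each shared DEG as concordantly (co-up / co-down) or inversely regulated
gives two substantial camps in realistic data, so no overall direction of
association follows from counting. The package's estimand is instead a
single rank correlation: compress each disease's shared-DEG profile to a
one-dimensional autoencoder bottleneck score ("pseudogene"), score each
disease's held-out patients under **both** encoders, and take Spearman's ρ
between the paired scores. The direction call is *positive* if ρ > 0 with
p < α, *inverse* if ρ < 0 with p < α, else *indeterminate*; α defaults to
0.05. Both per-cohort evaluations are always reported; the consensus
direction is their agreement (discarding indeterminate calls), otherwise
indeterminate.

Why this works: each encoder, trained to reconstruct its disease's profiles
through a one-node bottleneck, learns (an approximately monotone transform
of) the dominant variance axis — the disease's severity axis over its
dysregulated genes. Applying disease B's encoder to disease A's patients
asks "how far along B's dysregulation axis does this A patient sit"; if the
shared genes move predominantly the same way in both diseases the two
scores rise together, if they move oppositely the scores anticorrelate.

## Stage order

ingest / probe-collapse → per-cohort batch adjustment → per-cohort DEG
tables → overlap classification → feature selection (shared DEGs, or
per-disease enriched-pathway genes) → stratified 3:2 split → autoencoder per
disease (optional grid search) → cross-projection of held-out cases →
Spearman + direction call → optional over-representation analysis and
hub-gene ranking.

## Differential expression

Per gene, `logFC = mean(case) − mean(control)` on log2 values and the
pooled two-group variance s²_g with d_g = n₁ + n₂ − 2 degrees of freedom.
The moderated t shrinks s²_g toward a prior:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)
    t̃_g  = logFC_g / (s̃_g √(1/n₁ + 1/n₂)),   t̃_g ~ t(d₀ + d_g) under H₀.

(d₀, s₀²) are estimated by moment-matching the log sample variances: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the model implies
Var(e) = ψ′(d_g/2) + ψ′(d₀/2) and the excess over ψ′(d_g/2) is inverted
through the monotone trigamma (Newton iteration, relative tolerance 1e-10);
s₀² follows from mean(e) via digamma terms. Non-positive excess ⇒ d₀ = ∞
(all genes share one variance); d₀ = 0 is allowed as the no-moderation
limit (ordinary pooled t). The chain reproduces the R `limma` eBayes prior
and statistics to ~1e-12 on a frozen fixture (`tests/data/limma_*`).

Multiple testing uses Benjamini–Hochberg step-up (via statsmodels). DEG
calls use FDR < 0.05 (exclusive) and |logFC| ≥ 0.5 (inclusive) — inclusive
vs exclusive chosen once for determinism. Two-sided p-values throughout.
Degenerate variances: s̃² = 0 with logFC ≠ 0 gives t̃ = ±∞, p = 0; with
logFC = 0 gives t̃ = 0, p = 1.

## Batch adjustment

Location/scale ComBat with parametric empirical Bayes, applied per cohort
with that cohort's studies as batches. Gene-wise standardization fits batch
indicators plus (by default) a case/control covariate by least squares, so
the biological contrast is protected from absorption into batch means; the
pooled variance uses the n-denominator convention of the reference
implementation. Batch location (γ̂) and scale (δ̂²) estimates are shrunk with
a normal prior on locations and an inverse-gamma prior on scales,
hyperparameters by method of moments, iterating the coupled γ*/δ*² updates
to relative convergence 1e-4 (cap 100 iterations). A single batch is a
no-op; singleton batches and (with protection on) group⇄batch confounding
are errors. Output matches R `sva::ComBat` (mod = ~group) to < 1e-5 on a
frozen 50×20 fixture.

Note a property of the EB step: because γ* ≠ γ̂, the batch-size-weighted
mean of the adjusted residuals is not exactly zero, so per-gene grand means
move slightly (≈0.01–0.02 on study-condition data — the reference
implementation behaves identically). Tests assert preservation at < 0.05
rather than exactness.

## Autoencoder

Architecture `n → w₁ → w₂ → w₃ → 1 → w₃ → w₂ → w₁ → n` with defaults
(w₁,w₂,w₃) = (128, 64, 10). ReLU on all hidden layers, linear bottleneck
and linear output; inverted dropout (rate 0.2) after every hidden layer
except bottleneck and output, active only during training. A ReLU
bottleneck would clip half of the latent axis, hence linear. Inputs are
per-gene z-scores with mean/sd from the training split only (zero-variance
genes get sd = 1 and a warning). Loss is mean squared reconstruction
error; optimizer Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) at learning rate 5e-4,
batch size 16.

Training uses a stratified 3:2 train/holdout split (cases and controls
split separately, so the case fraction matches to within one sample;
deterministic per seed). Early stopping monitors holdout MSE with patience
30 and restores best-epoch weights, capped at 500 epochs; any strict
improvement resets the patience counter because reconstruction of a weak
latent factor improves by ~1e-4/epoch and a coarser improvement threshold
stops training before the bottleneck has aligned with the factor. Since a
one-node bottleneck under dropout occasionally converges to a dead-ReLU
optimum (holdout MSE stuck at the reconstruction floor ≈ 1.0 on
standardized data vs ≈ 0.75 when the factor is learned), `fit_encoder`
restarts training `n_restarts = 4` times from seeds derived from the
configured seed and keeps the restart with the lowest holdout MSE — a
within-disease criterion that never sees the other cohort.

A bottleneck score's sign is not identifiable (negating the bottleneck
weights and the first decoder layer preserves the reconstruction), so every
encoder is oriented at training time such that mean(score | training
cases) ≥ mean(score | training controls). Without canonical orientation the
cross-cohort ρ would have an arbitrary sign; a test exercises exactly this
flip. Inference is dropout-free and deterministic.

The hyperparameter grid spans learning rates {1e-4, 5e-4, 1e-3, 2e-3},
network depths {6, 8, 10} (counting dense maps including the output layer;
depth d uses (d−2)/2 encoder hidden layers, so 6 → (w₁,w₂), 8 → (w₁,w₂,w₃),
10 appends a fourth layer of width w₃//2 — the depth options and the
three listed widths do not pin down a unique reading, and this is the one
implemented), w₁ ∈ {64, 96, 128}, w₂ ∈ {32, 48, 64}, w₃ ∈ {10, 12, 16} and
dropout {0.1, 0.2, 0.3}: 972 combinations, each trained once with a shared
seed, selected by minimal holdout MSE, ties to the first in enumeration
order.

## Association

Only held-out **cases** enter the correlation by default (the association
of interest is among patients; a flag adds controls for sensitivity
analysis). Spearman's ρ uses average ranks for ties; the two-sided p-value
comes from t = ρ√((n−2)/(1−ρ²)) with n−2 df, with an exact permutation
option for n ≤ 9. A constant score vector — which can happen when a
counterfactual projection saturates an encoder's ReLU paths, see
limitations — makes that cohort's call indeterminate instead of aborting
the run.

## Over-representation and hubs

ORA is the upper-tail hypergeometric test P(X ≥ k) for a hit list of size n
against a set with K members in a universe of size N, BH-adjusted across
sets, significance at FDR < 0.2. The universe is the measured gene universe
of the cohort under test (the correct sampling frame), sets come from GMT
files, sets with fewer than 3 members in the universe are skipped, and GO
structure is ignored (flat sets). Hub genes: edges below confidence 0.7
are dropped, self-loops removed, duplicate edges keep maximal confidence,
and the top 50 nodes by degree are reported (ties alphabetical).

## Synthetic cohorts

The generator emulates the structure the pipeline assumes — and only that:

    x_gi = μ_g + λ_g^c · z_i + γ_{g,b(i)} + ε_gi

with a per-gene baseline μ_g ~ N(7, 1) shared by both cohorts (one
platform), latent severity z_i ~ N(case_latent_mean·1[case], latent_sd²)
per sample (continuous, so within-group ranks are informative — a binary
severity would make the Spearman degenerate), additive batch offsets
γ ~ N(0, batch_shift_sd²) with round-robin batch assignment, optional
multiplicative per-batch residual scale (lognormal, off by default), and
residual ε ~ N(0, noise_sd²). Loadings λ are nonzero only for planted DEGs:
`n_shared_deg` genes loaded in both cohorts (a `frac_concordant` fraction
with equal signs, the rest opposite) and `n_private_deg_per_cohort` genes
per cohort loaded in one; magnitudes are effect_sd·U(0.8, 1.2). The true
association sign is sign(Σ_g λ_g^A λ_g^B) over the shared genes.

Defaults are the study conditions used throughout testing: 2,000 genes, 200
shared + 100 private DEGs, effect_sd 1.0 (log2 units), case latent mean 1.0
with within-group spread 0.5, 3 batches/cohort with shift sd 0.5 (log2),
noise sd 1.0 (log2, a typical microarray residual scale), 60 cases/60
controls per cohort. At these settings a called shared DEG has mean
|logFC| ≈ 1 against the 0.5 threshold, and the 40% holdout leaves 24 cases
per cohort for the correlation.

What the generator does **not** emulate: probe-level intensities,
gene–gene correlation beyond the single latent factor, heavy-tailed or
heteroscedastic noise, and disease heterogeneity (multiple latent axes).
Passing the sign-recovery suite therefore shows the pipeline recovers a
planted one-factor association under realistic noise and batch structure —
not that any real pair of diseases has a particular association.

## Numerical and design choices

- Probe collapsing keeps the probe with max |logFC|; ties take the
  lexicographically smallest probe id. Cohort alignment uses the sorted
  gene intersection.
- The 40% holdout doubles as the early-stopping monitor and the evaluation
  ("test") set for the association; an optional three-way split exists but
  is off by default.
- All randomness flows through named integer seeds (simulation, split,
  training); replicate seeds are derived by fixed offsets. Same seeds ⇒
  bit-identical runs (single-threaded NumPy).
- Pipeline stages cache their outputs keyed by a hash of the resolved run
  configuration; a rerun with an unchanged configuration reloads
  ingest/adjust/DEG intermediates and reproduces identical downstream
  results.
- Test problem sizes: unit tests use tens-of-genes fixtures; the
  sign-recovery suite runs the full study conditions (10 seeds × 2
  concordance settings), several minutes on one CPU.

## Known limitations

- **Counterfactual saturation.** Under a strongly inverse association the
  other disease's cases project *beyond* an encoder's training range
  (inverse cases look like "super-controls"); a ReLU net extrapolates
  linearly at best and can saturate to a constant score. One cohort's
  evaluation then returns indeterminate (nan ρ) and the direction call
  rests on the other cohort. Orientation, restarts and the holdout-MSE
  selection mitigate but do not eliminate this.
- The bottleneck captures the *dominant* variance axis; if batch or
  technical variance dominated the shared-DEG signal after adjustment, the
  pseudogene would track the wrong axis. Batch adjustment before feature
  selection is therefore not optional in multi-study cohorts.
- The moderated-t stage assumes complete matrices (no missing values) and
  a common d_g across genes.
- The direction call is correlational; nothing here supports causal or
  epidemiological claims about comorbidity.
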