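# Methods

`lbptrial` implements the statistical pipeline used to analyse a
randomized, placebo-controlled trial of a vaginal live-biotherapeutic
product (LBP) carrying *Lactobacillus crispatus* strain CTV-05, given after
intravaginal metronidazole (MTZ) for bacterial vaginosis (BV).  This note
documents the models, the tunable parameters that matter, the synthetic
cohort the test suite runs on, and the numerical choices made where the
design was genuinely open.

## Compositional summaries

Counts are species-level aggregates of 16S amplicon data, held as a
sample × species DataFrame with a taxonomy table flagging *Lactobacillus*
species.  Samples are classified into three colonization categories:

- **LC_DOM** — ≥ 50% *L. crispatus* relative abundance;
- **OTHER_LACTO_DOM** — summed *Lactobacillus* ≥ 50% but *L. crispatus*
  < 50%;
- **NON_LACTO_DOM** — summed *Lactobacillus* < 50%.

Both thresholds are inclusive ("at least half counts as dominant").
Bray-Curtis dissimilarity is computed on proportion vectors as
1 − Σ min(pᵥ, qᵥ), clamped to [0, 1] against float noise.  Alpha
diversity defaults to Shannon entropy in nats; the index is configurable
(Simpson, richness) because no single convention dominates in this
literature.  Category transition tables pair only *consecutively
scheduled* visits — a missing middle visit breaks the chain, so no pair
spans a gap.

## Constrained topic model

Topics are constrained to be composed entirely of either *Lactobacillus*
or non-*Lactobacillus* species, which keeps the *Lactobacillus* side
interpretable as single species:

- Any *Lactobacillus* species reaching ≥ 50% of a sample's composition in
  ≥ 10 samples (both thresholds inclusive) gets a **pure topic**; its
  per-sample topic proportion is simply the species proportion.
- Remaining *Lactobacillus* species are pooled into one **"Other L."**
  topic whose composition is their mean relative abundance across the
  cohort, renormalized.  (Mean abundance was chosen over prevalence: it
  yields a proper probability vector directly and matches how the pooled
  proportion is computed per sample.)
- The non-*Lactobacillus* side is a latent Dirichlet allocation (LDA) fit
  to the non-*Lactobacillus* counts only.  Per-sample topic proportions
  π̂ (summing to 1 within the non-*Lactobacillus* fraction) are rescaled
  by the sample's total non-*Lactobacillus* proportion Π̂:
  p̂ₖᵢ = π̂ₖᵢ · Π̂ᵢ, so that *Lactobacillus* topic proportions plus
  rescaled non-*Lactobacillus* proportions sum to exactly 1 per sample.
  Samples with zero non-*Lactobacillus* reads have undefined π̂; they are
  excluded from the LDA fit and get all-zero p̂ rows (consistent with
  Π̂ = 0).

LDA uses scikit-learn's batch variational inference with symmetric priors
α = 1/K on topic proportions and η = 0.1 on compositions, max 500
iterations, and a bound-based early-stopping tolerance of 1e−3.  The
tolerance matters: a loose bound (0.05) stops after ~15 iterations and
leaves profiles visibly under-converged (total-variation error against
planted profiles ~0.10 instead of ~0.07).  K = 1 is handled in closed
form (the pooled empirical distribution).

### Choosing K by topic alignment

Models are fitted over a K grid and aligned between consecutive
resolutions with **product weights**: w[k, l] ∝ Σᵢ π̂ₖᵢ · π̂ₗᵢ, normalized
over all pairs.  Topics are chained into paths by greedy maximum-weight
matching (largest weights first, each topic used once).  The open design
question is what to do with the extra topic that appears at K+1:

- If its composition is close (cosine ≥ 0.6) to the sibling topic matched
  to its strongest parent, it is a **duplicate** — it joins that parent's
  path and the path count does not grow.
- Otherwise it is a genuinely distinct subcommunity emerging as a mixture
  resolves, and it starts a **new path**.

The cosine threshold sits in a wide empirical gap: clone topics score
≥ 0.8 while genuinely distinct subcommunities score ≤ 0.35 on the
synthetic cohorts.  A matched link whose affinity falls below 0.05 in
both directions is severed (grids of mutually unrelated topics then
produce max-K paths).  Coherence of a topic is the minimum link
similarity (the smaller of row- and column-normalized matched weights)
along its path.  K is selected as the smallest resolution where no
coherence falls below 0.25 and the path count equals that of the next
resolution (a plateau); if no resolution qualifies the argmin of the
spurious-topic count is returned with a warning.

## Cytokine preprocessing

Concentrations below the lower limit of quantification (LLOQ) are imputed
at LLOQ/2, values above the upper limit (ULOQ) at the ULOQ, then
everything is log10-transformed.  Analytes below the LLOQ in ≥ 60% of
samples or above the ULOQ in ≥ 30% (inclusive) are excluded before any
multivariate step.

Swab sampling introduces a **size effect**: between-swab variation in
collected biomass inflates all analytes jointly, showing up as a dominant
first principal component.  Adjustment standardizes columns, zeroes the
scores on the first right-singular direction (equivalently subtracts the
rank-1 term t₁p₁ᵀ), and de-standardizes back to the log10 scale so
downstream within-participant deltas remain interpretable as log10
concentration changes.  The pipeline exposes a sensitivity mode that
skips the subtraction.  Missing (unmeasured) entries are disallowed in
the PCA input; assay-dropout imputation is out of scope.

## Multi-table association

- **RV coefficient**: tr(SₓSᵧ)/√(tr(Sₓ²)tr(Sᵧ²)) on column-centered
  tables; p-values by permuting rows of one table with the add-one
  estimator p = (1 + #{RV* ≥ RV}) / (1 + B), which can never return 0.
- **PERMANOVA**: one-way pseudo-F computed from the within/among
  sums-of-squares identity on squared distances; label permutations for
  the p-value.  The statistic is verified against scikit-bio's
  implementation in the test suite.
- **DiSTATIS**: each distance matrix is double-centered (−½ J D² J by
  default; a direct −½ J D J mode is available for semimetrics such as
  Bray-Curtis, with negative compromise eigenvalues truncated at zero for
  scores) and normalized by its first eigenvalue.  Table weights are the
  first eigenvector of the inter-table RV (congruence) matrix, rescaled
  to sum to 1; the compromise is the weighted sum; factor scores are
  eigenvectors scaled by √eigenvalue; variable correlations with the
  latent dimensions are plain Pearson correlations.

## Treatment effects

Benefit ratios (risk ratios where the event is favorable) use Wald's
method: CI = exp(log RR ± z·SE) with SE = √(1/a − 1/n₁ + 1/b − 1/n₂),
z = 1.959964 at 95%.  The two-sided p-value is taken from the Wald z on
the log scale, consistent with the CI construction.  Arm percentages are
rounded half-even to integers.  Stratum rates use Wilson score intervals
(better small-sample coverage than Wald); strata with fewer than two
participants per arm are excluded.

Heterogeneity of treatment effect compares nested logistic models — null:
outcome ~ arm; full: outcome ~ arm × baseline covariates — by an analysis
of deviance **F test**: F = (Δdeviance/Δdf) / φ̂ with the dispersion φ̂
estimated as Pearson χ²/(n − p_full) and denominator df = n − p_full.
Simulated type-I error at n = 180 with four strata is ≈ 0.05 (slightly
conservative).  Families of tests are BH-adjusted.  Counterfactual
per-participant success probabilities set the arm covariate to each level
in the fitted full model; CIs are delta-method on the linear predictor
mapped through the inverse logit, and participant odds ratios are the
ratio of the two predicted odds.  Perfect separation is flagged rather
than penalized; stratum rates remain the fallback summary.

## Strain-category dynamics

Strain inference is only attempted on samples with ≥ 5% total
*L. crispatus* (relative abundance from the count table).  Eligible
samples are classified by CTV-05 fractional abundance: > 90% High-CTV-05,
10–90% Mixed, < 10% Low-CTV-05; the boundaries 0.9 and 0.1 fall in Mixed
(the stated band is inclusive while the outer categories are strict).
Transition tables include a below-eligibility destination; pairs touching
a technically failed inference are excluded.  The native-strain histogram
counts distinct non-LBP strain IDs ever detected at ≥ 10% fractional
abundance per participant, capped at "3+"; strain identity across visits
is taken from the input table's IDs (genotype matching is upstream of
this package).

## Multiblock PLS-DA

Explanatory variables are grouped into thematic blocks.  Variables are
standardized, each block scaled to unit total variance (division by √p_b
after standardization), and the 3-category response one-hot encoded and
centered.  A super-block NIPALS loop extracts components: per iteration,
block weights wᵦ = Xᵦᵀu (normalized), block scores tᵦ = Xᵦwᵦ, super
weights a = Tᵀu (normalized), unit-norm super score t, response loadings
q = Yᵀt, u = Yq.  Deflation is on the super score for both X blocks and
Y.  Predictions propagate the stored weights through the same deflation
sequence; classes are assigned by argmax of the predicted response.

Block importance per component is the squared super weight; cumulative
importance (BIPC) weights components by the share of response variance
each explains, so Σ_b BIPC = 1.  The **relative** importance divides BIPC
by the block's share of variables; its variable-share-weighted mean is 1
by construction, making 1 the "all variables equally important" null
line.  Sparse one-hot columns (fewer than 5 positives) receive Gaussian
jitter with variance 10⁻³ × the column's empirical variance so refits
under resampling stay well-posed.  Blocks can be residualized against
another block via PLS regression (residual = observed − predicted),
e.g. cytokines against microbiota composition.

Component count is chosen by 40 random stratified 75/25
calibration/validation splits scored by macro-F1, with a
one-standard-error parsimony rule: the smallest count within one SE of
the best mean F1 wins, so an extra component must earn a gain that split
noise cannot explain.  Stratification (the trial's own splits may have
been unstratified) avoids class-empty calibration sets at these sample
sizes.  Uncertainty in block importance uses a participant-level
percentile bootstrap (≥ 200 resamples; class-empty resamples are
redrawn).

## The synthetic cohort

`lbptrial.synth` generates trial-shaped data so every stage is testable
offline.  What it emulates, with defaults:

- 213 participants randomized 2:1 (LBP:placebo) over six visits
  (pre-MTZ, post-MTZ, weeks 4/8/12/24); 5% of visits missing completely
  at random.
- A latent colonization category per visit: pre-MTZ almost all
  non-*Lactobacillus* (everyone has BV at screening), post-MTZ mostly
  other-*Lactobacillus* (the *L. iners* bloom after antibiotics), and a
  week-4 state drawn so that 30% of LBP vs 9% of placebo participants are
  *L. crispatus*-dominant — the arms' reported week-12 rates, used as the
  durable colonization probabilities.  Later visits follow a Markov step:
  stay with probability 0.70, otherwise redraw from the arm's base
  distribution restricted to the other categories.  The self-transition
  probability is therefore exactly the persistence parameter, and
  arm-wise marginals stay near the configured rates (0.70² ≈ 0.49 matches
  the reported two-visit persistence of early colonizers).
- Week-4 category is thresholded on a standard-normal **colonization
  propensity** per participant, which also drives the post-MTZ covariate
  block (bacterial load, pH, alpha diversity), making that block the
  truly discriminative one for the multiblock analysis — mirroring the
  finding that the post-MTZ environment best predicts week-4 colonization.
- Compositions: category-conditioned Dirichlet topic weights
  (concentration 50 × the category mean — separable categories with
  realistic within-category spread) over 4 *Lactobacillus* topics and 4
  planted non-*Lactobacillus* subcommunity profiles (dominated by
  *Ca.* Lachnocurva vaginae, *G. swidsinskii/leopoldii*, *P. amnii*,
  *P. bivia*); multinomial counts at log-normal depth with median 31,000
  reads (σ = 0.4, matching the reported depth IQR).
- Bacterial load: post-MTZ wide and low (biomass collapse, median
  10^2.69 copies/swab), other visits narrow and high (median 10^7.52).
- Cytokines: log10 concentration = analyte base + shared swab-size factor
  (SD 0.5 by default; with the default noise SD 0.35 the first PC carries
  roughly two thirds of standardized variance) + effect × total
  *Lactobacillus* proportion + noise, censored at per-analyte LOQs.
  Planted effects are negative for pro-inflammatory analytes (IL-1α/β,
  TNF-α) and positive for IP-10/MIG/ITAC, zero for IL-6.
- Strains: LBP-arm eligible samples start mostly High-CTV-05; mixed
  states resolve to native dominance with probability 0.35 per visit
  (the reported Mixed→native rate) and native dominance is never re-taken
  by CTV-05; placebo samples carry native strains only apart from a 5%
  false-positive CTV-05 rate.  0–3 native strains per participant.

What it does **not** emulate: read-level sequencing error, PCR/primer
bias, chimeras, assay plate effects, informative missingness, strain
genotype uncertainty, within-visit repeat swabs, or clinical covariate
structure beyond the blocks above.  Passing tests therefore demonstrate
that the algorithms recover planted structure under the stated noise
model, not that the trial's biological conclusions replicate from raw
data.

## Validation problem sizes

The benchmark suite (also run by `scripts/acceptance.py`) uses: the
published 2×2 endpoint counts directly; a 300-sample cohort at depth
30,000 over a K = 2…8 grid for topic recovery; 80 participants with a
size-factor SD of 1.2 for the adjustment check; 500 replicates × 199
permutations at n = 80 for RV calibration; 1,000 null simulations at
n = 180 with four strata for the F test; 50 replicate cohorts for block
recovery plus 5 replicates of a planted two-component structure for
component selection (reported as the modal choice, since single-cohort
selection at these sizes carries sampling variability); and a hand-built
nine-case fixture covering every strain-category boundary.

## Known limitations

- The LDA fit is variational and seed-dependent; topic recovery is judged
  after optimal matching, and alignment path structure can differ at
  resolutions far above the true K.
- The alignment duplicate/split rule depends on a cosine threshold; data
  whose true subcommunities are compositionally similar (cosine > 0.6)
  would under-count paths.
- The heterogeneity F test is slightly conservative at stratum counts and
  sample sizes like those validated here.
- DiSTATIS normalization conventions vary across implementations; this
  one normalizes cross-products by their first eigenvalue (MFA-style),
  with trace normalization switchable.
- The benefit-ratio p-value uses the log-scale Wald z; score-based or
  chi-square p-values for the same table can be smaller.
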