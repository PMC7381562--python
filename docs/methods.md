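# Methods

## Model

The package treats reproductive isolation between two parapatric ecotypes as
a sequence of barriers acting in life-cycle order: ecogeographic separation,
flowering phenology, pollinator assemblages, then three post-pollination
stages measured by hand crosses (pollen adhesion, pollen-tube germination,
fertilization/seed development). Each barrier is scored by the member of the
Sobel–Chen RI4 family that matches its data type; all indices equal 1 at
complete isolation, 0 at random mating, and (for the signed forms) −1 at
complete disassortative mating.

**RI4C** (co-occurrence): RI = 1 − S/(S+U). Used for habitat overlap
(S = shared pixels, U = focal-exclusive pixels, so the two directions differ)
and for pollinator assemblages (U = Bray–Curtis dissimilarity of the two
visit-count vectors, S = 1 − U, so the index equals the dissimilarity and is
direction-free).

**RI4S2** (temporal, abundance-weighted): per period *i* with A_i of A_total
focal trees and B_i of B_total other trees in flower,

    H_i = (A_i/A_total) (B_i/(A_i+B_i)) (B_total/(A_total+B_total))
    C_i = (A_i/A_total) (A_i/(A_i+B_i)) (A_total/(A_total+B_total))
    RI  = 1 − 2 ΣH_i / (ΣH_i + ΣC_i)

Periods with A_i + B_i = 0 offer no mating opportunity and contribute zero
to both sums (the 0/0 term is resolved to 0). The index is invariant to a
common rescaling of all counts and totals, and is directional: with
identical per-capita phenology, the rarer ecotype receives proportionally
more heterospecific pollen and can score negative.

**RI4A** (mating): RI = 1 − 2H/(H+C) with H and C the heterospecific and
conspecific success in identical units — mean adhered grains per flower,
mean per-flower germination proportion, or seed-set rate. The germination
metric is the mean of per-flower proportions, not the pooled grain ratio:
this weights flowers equally and matches how stage success rates are usually
reported. Flowers with zero adhered grains carry no germination information
and are excluded from that stage.

**Totals and contributions.** Barriers are combined with the sequential
multiplicative cascade RI_total = 1 − Π(1 − RI_k). The absolute contribution
of barrier k is AC_k = RI_k·Π_{j<k}(1 − RI_j) — the gene flow it removes
given that earlier-acting barriers act first — which telescopes exactly to
the total; relative contributions are AC_k/total. Negative strengths
propagate unchanged through factors (1 − RI_k) > 1, so a disassortative
barrier correctly *increases* downstream gene flow. Unmeasured barriers are
skipped, never imputed as zero. Omitting the ecogeographic barrier yields
the "sympatry" total, i.e. isolation among individuals at a contact zone.

**RI4E.** The co-occurrence-conditioned total form
RI4E = 1 − 2(S·P(H|S) + U·P(H|U)) / (S·P(H|S) + U·P(H|U) + S·P(C|S) + U·P(C|U))
is provided as a separate operation. Because field studies rarely report the
conditional probabilities, a default mapping from a barrier cascade is
supplied: S = 1 − RI_eco; heterospecific gene flow impossible in unshared
habitat (P(H|U) = 0); conspecific gene flow at a baseline probability
everywhere (default 0.5, random mating); and within shared habitat the
heterospecific rate is the baseline discounted by the compounded mating
ratio r = (1 − RI)/(1 + RI) of every later-acting barrier. With no unshared
habitat this reduces exactly to RI4A on the pooled sympatric success
probabilities. The cascade, not RI4E, is the default for reporting because
the cascade's contribution decomposition is what barrier-strength figures
display and it requires no unobserved conditional probabilities; both totals
are written by the pipeline, and they need not agree exactly — the mapping
from barrier strengths to RI4E's conditional probabilities is a modeling
choice, not an identity.

## Ecogeographic stage

Suitability grids (scores in [0, 1], NaN = missing, missing counts as
unsuitable) are binarized at the ETSS threshold: scanning the sorted unique
pooled presence + background scores, choose the candidate minimizing
|sensitivity − specificity|, where sensitivity is the fraction of presence
scores ≥ t and specificity the fraction of background scores < t; ties
(within float rounding of the count ratios) resolve to the smallest
candidate. Background scores are caller-supplied; the pipeline draws them
uniformly from the grid's non-missing pixels (default 10,000, seeded).

A dispersal buffer models pollen transfer across habitat edges: suitable
habitat is dilated by ceil(radius/pixel_size) pixels (default 500 m on a
250 m grid → 2 pixels) using a Chebyshev (square) structuring element; a
Euclidean disk option is exposed for sensitivity analysis, and the square
default is the plainer raster reading of a fixed-radius boundary. A pixel
is *shared* when both models predict it, or when one ecotype's buffer
reaches a pixel predicted for the other: shared = (F∧O) ∨ (dilate(F)∧O) ∨
(F∧dilate(O)). Focal-only and other-only pixels are the remainders, so
focal_only + other_only + shared always equals the union of suitable pixels
regardless of radius.

Occurrence points map to pixels via half-open intervals from the top-left
grid origin (row = ⌊(y0 − y)/pixel⌋, col = ⌊(x − x0)/pixel⌋). Rasters are
exchanged as single-band ESRI ASCII grids — a plain-text header + matrix
format readable everywhere.

## Phenology and pollinator stages

Surveys aggregate to calendar months by default (the temporal index is
defined over months; censuses are nominally biweekly), a tree counting as
flowering in a period if flagged in ≥ 1 census of it; census-level
aggregation is available. Trees without a record in a period are treated as
not flowering — absence of record is read as absence of flowers.

Visit counts are pooled across trees per ecotype. Differential visitation is
screened with a two-sample Wilcoxon rank-sum across morphospecies (midranks,
tie-corrected normal approximation); a paired signed-rank variant exists but
the unpaired form is the default since morphospecies counts at the two
ecotypes are not naturally paired observations of one unit.

## Crossing stage

Treatment is derived per flower: parental if pollen and maternal ecotype
match, hybrid otherwise; controls carry no pollen ecotype. Adhesion and
germination are compared with two-sample Mann–Whitney U on per-flower
values; seed set with a two-sided Fisher exact test (sum of all
equally-marginal tables with probability ≤ the observed one). A dataset
fails validation outright if any negative control sets seed, or if
germinated > adhered on any flower. Per-inflorescence clustering is ignored
(data are pooled); the inflorescence id is retained in the schema for future
mixed-model extensions.

## Synthetic data

The generator exists so the full pipeline can run and be tested end to end
with no field data. One root seed spawns independent substreams per module
(`numpy.random.SeedSequence`), so identical configs give byte-identical
outputs and any one module's inputs can be regenerated alone.

- *Habitat*: a Gaussian random field (kernel-smoothed white noise,
  correlation length 4 px) mapped through a logistic link with slope
  ±contrast (default 3) gives anti-correlated suitability surfaces for the
  two soil specialists; occurrences (defaults 103 and 76 points) are sampled
  proportional to suitability at pixel centers. Default grid 80×100 at
  250 m.
- *Phenology*: each tree flowers independently per month with probability
  level × seasonal bump (Gaussian in month-of-year, width 2 months, floor
  0.05); defaults 12 vs 39 trees over 36 months with levels 0.35 vs 0.6 —
  same timing, higher flowering abundance in the brown-sand population, the
  asymmetry that makes the rarer ecotype's RI negative. Two censuses per
  month are emitted.
- *Pollinators*: multinomial counts per ecotype (defaults 40 and 177 total
  visits over 15 morphospecies) around profile vectors taken from the
  observed assemblage skew, giving an expected dissimilarity ≈ 0.82; an
  optional Dirichlet concentration jitters the profiles per seed.
- *Crosses*: adhered ~ negative binomial (treatment means 159/112, shape
  k = 3 — the study's reported standard errors imply strong overdispersion
  relative to Poisson, and k ≈ 3 matches the parental-arm SE; an infinite k
  degenerates to constant counts), germinated ~ Binomial(adhered, 0.46/0.44),
  seed set ~ Bernoulli(0.39/0.164); defaults 38 parental, 104 hybrid, 20
  negative controls, all maternal trees from one ecotype (crossing measured
  in one direction only, as in the motivating study).

What the generator does **not** emulate: spatial clustering of trees and
occurrence sampling bias, within-tree correlation of flowering across months
(bouts are iid per month), per-tree and per-inflorescence random effects in
crossing outcomes, observation-time differences behind visit counts, and
landscape anisotropy. Passing recovery tests therefore demonstrates
correctness of the estimators under clean sampling assumptions, not
robustness to these real-data features.

## Numerical choices and test design

- RI values are kept at full precision internally; rounding is a
  presentation option (`--round`).
- Degenerate inputs (S+U = 0, H+C = 0, all-zero temporal mass, empty
  communities) raise a dedicated undefined-input error rather than returning
  NaN.
- The temporal index is validated against an exact-rational (Fraction)
  direct-summation oracle to 1e−12; overlap classification against a
  brute-force pixel scan; Fisher p-values against full hypergeometric
  enumeration over all 2×2 tables with row margins up to 30.
- Parameter recovery is checked at 1,000 samples per arm: replicate
  estimates (16 replicates for crossing stages, 8 for phenology, 32 for
  visitation — enough that the Monte-Carlo standard error of the mean is
  well below each target's scale while the whole check stays fast) must
  bracket the closed-form RI of the generating parameters within two
  standard errors of the replicate mean. The ecogeographic barrier has no
  closed form under the random-field generator and is instead checked for
  stability against a larger replicate run.
- RI4S2 has a small positive finite-census bias under identical phenology
  (the conspecific term A_i²/(A_i+B_i) is favored by Jensen's inequality for
  iid counts); with ~60 trees per population it is ≈ 0.03 and it vanishes as
  censuses grow. Null-behavior tests allow for it explicitly.

## Known limitations

- ETSS thresholds depend on the background sample; with few background
  pixels the threshold (hence the ecogeographic RI) is noisy. The pipeline
  seeds and records the background draw.
- The cascade assumes barriers act independently in sequence; shared causes
  (e.g. pollinators tracking habitat) make contributions non-identifiable in
  principle, a caveat inherent to the decomposition rather than this
  implementation.
- Rank-sum and Mann–Whitney p-values use the tie-corrected normal
  approximation; at very small sample sizes exact enumeration (available in
  scipy for tie-free data) is preferable.
- No confidence intervals are attached to RI values; the indices are point
  descriptors and the upstream sampling designs rarely support clean
  interval estimates.
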