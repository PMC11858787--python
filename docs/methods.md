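# Methods

## The problem

Herbarium vouchers record, for a single date and place, whether a tree was
flowering — information usually buried in free-text field notes ("flores
blancas", "frutos verdes", "sterile"). Pooled over decades of collecting,
such records can reconstruct the annual flowering calendar of species that
have never been followed in the field, which is the situation for most
tropical montane forest trees. `phenocal` implements that reconstruction
as a four-stage pipeline: curate occurrence tables, classify flowering
status from label text, model the annual distribution of flowering dates
with circular statistics, and stratify the results by climate.

## Circular model of the flowering year

Dates are mapped to angles with 0° = 1 January and 30° per calendar month;
days interpolate linearly within their month, so the mapping is
month-based rather than day-of-year-based (31-day and 28-day months both
span 30°). A record with a month but no day is placed mid-month (the
15th), which is adequate at a 30°-per-month resolution; 29 February folds
onto the 28th. The month-based scale makes December and January flowering
30° apart instead of 11 months apart.

The annual distribution of a sample of flowering angles is described by a
lattice of ten candidate models, all of the form

    f(θ) = λ·VM(θ; μ1, k1) + (1 − λ)·C2(θ)

with VM a von Mises density, k the concentration (k = 0 is uniform; larger
k means a narrower peak) and λ the weight of the first peak. The candidate
set is one uniform model (continuous flowering), three unimodal models
(one annual peak: a pure peak, and peak-plus-uniform-background variants
with fixed or free λ) and six bimodal models (two peaks: axial variants
with the second peak fixed 180° away, with shared or separate
concentrations and fixed or free λ, plus fully free two-peak variants):

| model | constraint set                                | free parameters |
|-------|-----------------------------------------------|-----------------|
| M1    | uniform                                       | 0 |
| M2A   | single von Mises                              | μ1, k1 |
| M2B   | VM + uniform, λ = 0.5                         | μ1, k1 |
| M2C   | VM + uniform, λ free                          | μ1, k1, λ |
| M3A   | μ2 = μ1+180°, k2 = k1, λ = 0.5                | μ1, k1 |
| M3B   | μ2 = μ1+180°, k2 = k1, λ free                 | μ1, k1, λ |
| M4A   | μ2 = μ1+180°, k2 free, λ = 0.5                | μ1, k1, k2 |
| M4B   | μ2 = μ1+180°, k2 free, λ free                 | μ1, k1, k2, λ |
| M5A   | μ2, k2 free, λ = 0.5                          | μ1, k1, μ2, k2 |
| M5B   | everything free                               | μ1, k1, μ2, k2, λ |

Fits are reported with the dominant component first (λ ≥ 0.5, swapping
components where the constraint set permits) and μ in [0, 360).

### Estimation

Each model is fitted by bounded L-BFGS-B on the negative log-likelihood
with an analytic gradient (Bessel terms via exponentially scaled I0/I1,
stable at large k). Starting values are drawn per start (5 by default,
seeded) as jitter around the circular moment anchors of the sample — the
first-moment direction and the two directions of the doubled-angle
(axial) moment, with concentrations scaled to the moment estimate of k.
Diffuse uniform-box starts were rejected: they let the optimizer wander
into degenerate minority-spike optima (below). The uniform model has a
closed-form likelihood, −n·log 2π.

Bounds: μ ∈ [0, 360], k ∈ [0, 50], λ ∈ [0.05, 0.95] for two-peak mixtures
(canonicalised to λ ≥ 0.5 afterwards) and λ ∈ [0.5, 0.95] for
peak-plus-uniform mixtures, whose components cannot be swapped. The k
bound is deliberate and load-bearing: the likelihood of a mixture is
effectively unbounded as a minority component collapses onto a few nearly
coincident dates (the circular analogue of the vanishing-variance
degeneracy of normal mixtures), and such spike "fits" — k in the hundreds
and λ at its bound, absorbing 2–3 records — otherwise win AIC spuriously
on uniform or unimodal data. k = 50 corresponds to a component sd of
about 8°, roughly ±8 days, which is about the sharpest flowering peak
herbarium dating precision (and the lag between flowering and collection)
can support; genuinely sharper peaks saturate at the bound and still
dominate model selection.

### Selection and consensus

Candidates are compared by AIC = 2·(free parameters) − 2·logL. Among
models within 2 AIC units of the minimum, the most parsimonious (fewest
free parameters; ties by AIC, then id) is selected. This is the standard
substantial-support convention, and it matters here: with nine
alternatives each free to absorb sampling noise, plain argmin-AIC selects
a spurious structured model on truly uniform data roughly a third of the
time (the null likelihood-ratio improvements are chi-square-scale and
independent of n), whereas requiring an extra component to earn clearly
more than its AIC price keeps family recovery at the level the method
needs to be useful.

The stability of the selection is probed by repeating it 100 times with
fresh random starts (run i seeds its starts with base_seed + i). If one
model wins strictly more than 75 of the 100 runs, the pattern is deemed
consistent. Otherwise a fallback picks among the two–three most prevalent
winners the one with the lowest median AIC across its winning runs (ties:
fewer parameters, then lexicographic id) and the calendar is flagged as a
fallback selection. Pattern class (uniform / unimodal / bimodal) is the
family of the final model; peaks are μ1 (and μ2, or μ1 + 180° for axial
models) converted back to calendar dates.

## Label-text classification

Field notes are lowercased, accent-folded, stripped of digits and
punctuation, tokenized, and filtered against a small trilingual
(Spanish/Portuguese/English) stopword list; tokens shorter than two
characters are dropped. Documents become bag-of-words count vectors
(vocabulary sorted, min_df configurable, default 2 in the pipeline).
Three standard text classifiers — multinomial naive Bayes, L2 logistic
regression, and a 500-tree random forest — are compared by stratified
fivefold cross-validation on accuracy, precision, recall, F1 and AUROC;
the best model by mean F1 (ties by AUROC) is retrained on all labelled
records and scores every record. Only records predicted flowering enter
the calendars. On separable synthetic corpora all three classifiers are
essentially perfect; the comparison harness exists to mirror the
real-data workflow, where the ensemble tree model is the expected winner.

## Climate regionalization and strata

Each grid cell's seasonality is summarised by 24 features: 12 monthly
precipitation shares (month / annual total; an all-zero year degrades to
uniform shares) and 12 within-cell z-scored temperatures. Both blocks are
scale-free on purpose — a wet and a less-wet cell with the same rhythm
should cluster together. Cells are clustered by k-means (k = 6 by
default, 10 seeded restarts, cells processed in cell-id order so the
partition is independent of row order). Records join the region of their
nearest grid cell by great-circle distance (ties to the lowest cell id;
points more than 5° outside the grid bounding box stay unassigned).
Independently, records get one of five 10° latitudinal bands between 25°N
and 25°S, and one of three subcontinental zones (CAC, WSA, ESA) by
point-in-polygon test — boundary points resolve in CAC, WSA, ESA order. A
coarse built-in box fixture stands in for the authoritative IPCC zone
polygons; real analyses should supply their own GeoJSON.

## Calendars, overlays and synchrony

Pooled samples are formed at three scopes — region, region–zone, and
species × region–zone — keeping units with at least 20 predicted-flowering
records. Each calendar carries monthly record counts (conserving n), the
consensus model, peak dates, dry months (mean monthly precipitation over
the cells hosting the unit's records, strictly below 100 mm), and
optional irradiance peak months (circular strict local maxima of a
user-supplied monthly series; plateaus count their first month; constant
series have none). A flowering peak "coincides" with drought or
irradiance when its month is within ±1 month circularly — an explicit
stand-in for visual assessment. Species spanning two or more regions are
compared across their calendars: "consistent" requires one shared pattern
class and all pairwise peak separations within 30° (bimodal peak lists are
matched under the better of the two pairings), anything else is
"variable". Per-species record counts across region–zone units are also
reported normalized by the unit with the most records.

## Synthetic data: what it emulates and what it does not

The generator plants known truth at every stage: per-species circular
models (cycling uniform / unimodal M2A with k ∈ [2, 4] / bimodal M5B with
peak separations of 150–210° and λ ∈ [0.5, 0.65]); a configurable
flowering fraction (default 0.55); multilingual label text that
contradicts the truth at a configurable noise rate (default 5%; the
contradiction is symmetric — a noisy label is indistinguishable from an
opposite-class label, so held-out accuracy is capped near 1 − noise);
month-precision dates for a configurable fraction of records (default
10%); synonym spellings for a fraction of names (default 10%); and six
climate templates with disjoint geographic extents, realistic neotropical
seasonality, and seeded multiplicative jitter (default 5% relative).

It does not emulate: georeferencing error or coordinate–label mismatch,
collector bias toward flowering individuals, vocabulary drift across
herbaria and decades, supra-annual (masting-like) cycles, or spatially
continuous climate gradients (cells are template + noise, so clustering
recovery is easier than on real rasters). Passing tests therefore certify
the machinery — recovery of planted structure under controlled noise —
not real-data accuracy of any particular classifier or regionalization.

## Problem sizes used by the test suite

Family recovery uses 100 replicates per generating family at n = 200;
detectability checks 200 replicates at (n = 20, k = 1.5) and (n = 100,
k = 0.4), where the unimodal family must win a majority — the second
setting sits deliberately at the detection edge. The end-to-end run uses
30 species × 90 records across the six templates with 5% label noise and
the full 100-run consensus, executed twice to verify byte-identical
outputs; species pattern classes are judged on each species'
best-covered calendar unit (≥80% must match the generator). Classifier
calibration uses a 2 000-document corpus at 10% noise.

## Known limitations

- The ten-model constraint table follows the reference circular-MLE
  tooling's documentation; the three unimodal variants in particular are
  conventions, not uniquely determined by the method description.
- AIC (not AICc) is used throughout; at n = 20 with 4–5 parameter models
  AICc would penalise harder. The parsimony-within-2 rule absorbs most of
  the practical difference.
- Consensus variability comes entirely from random starting values; with
  strongly identified optima all 100 runs agree and the procedure is
  conservative in flagging inconsistency.
- The fallback rule and the ±1-month coincidence window operationalize
  what is, in field practice, a visual judgement; both are configurable.
- Region assignment is nearest-cell, not polygon membership; with coarse
  grids, records near region boundaries can flip with the grid resolution.
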