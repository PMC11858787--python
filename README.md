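# phenocal

Phenological calendars for neotropical trees, reconstructed from
herbarium occurrence records.

Most tropical montane forest tree species have never had their flowering
followed in the field, but decades of herbarium collecting have left tens
of thousands of dated, georeferenced vouchers whose labels say things
like *"flores blancas"* or *"frutos verdes"*. `phenocal` turns such
occurrence tables into flowering calendars. It is aimed at plant
ecologists and biodiversity informaticians working with Darwin-Core-style
occurrence data.

The pipeline:

1. **ingest** — read occurrence CSV/TSV, resolve synonyms against a local
   table, deduplicate, and drop records without label text, a resolvable
   name, or a collection month (every drop is counted and the accounting
   balances).
2. **phenoclass** — classify flowering status from label text: trilingual
   cleaning, bag-of-words counts, three classifiers (multinomial naive
   Bayes, logistic regression, 500-tree random forest) compared by
   stratified fivefold cross-validation on five metrics; the best model
   is retrained on all labelled data and scores every record.
3. **circstats** — the analytical core. Flowering dates map to the annual
   circle (0° = 1 January, 30° per month), and each pooled sample is fit
   by maximum likelihood to ten candidate circular models — one uniform,
   three unimodal, six bimodal von Mises mixtures
   f(θ) = λ·VM(θ; μ₁, k₁) + (1−λ)·C₂(θ) — compared by
   AIC = 2p − 2·logL. Selection stability is probed by 100 repeated
   multi-start fits: a pattern is *consistent* if one model wins more
   than 75 runs, otherwise a most-prevalent-model fallback decides.
4. **stratify** — cluster a monthly climate grid (precipitation shares +
   temperature z-scores) into six climatic regions; assign records to
   regions, 10° latitudinal bands (25°N–25°S), and CAC/WSA/ESA
   subcontinental zones.
5. **calendars** — pool units with ≥20 flowering records at region,
   region–zone, and species×region–zone scopes; build calendars with
   monthly counts, peak dates, dry-month overlays (<100 mm), irradiance
   peak months, ±1-month coincidence flags, cross-region intraspecific
   comparisons and synchrony summaries.

A first-class synthetic-data module generates specimen tables, label
corpora and climate grids with known ground truth, so the whole pipeline
is testable offline. See `docs/methods.md` for the model details and the
design choices.

## Worked example

Fit the circular model lattice to 120 flowering dates drawn from a single
October peak (μ = 275°, k = 3):

```python
from phenocal import select_model, run_consensus
from phenocal.circstats import angle_to_month_day
from phenocal.synthetic import sample_angles

angles = sample_angles("M2A", {"mu1": 275.0, "k1": 3.0}, n=120, seed=42)

sel = select_model(angles, seed=0)
f = sel.best
print("best:", sel.best_id, f.family)
print(f"mu1={f.mu1:.1f}  k1={f.k1:.2f}  logL={f.logL:.2f}  AIC={f.AIC:.2f}")

res = run_consensus(angles, runs=100, threshold=75, seed=0)
print("consensus:", res.win_counts, "consistent:", res.consistent)
print("peak date:", angle_to_month_day(f.mu1))
```

prints

```
best: M2A unimodal
mu1=280.0  k1=3.53  logL=-106.51  AIC=217.01
consensus: {'M2A': 100} consistent: True
peak date: (10, 11)
```

i.e. the pure von Mises model wins all 100 consensus runs; the estimated
mean flowering direction (280°, close to the planted 275°) corresponds to
a peak around 11 October, and the concentration ≈3.5 describes a clearly
peaked but multi-week flowering season.

The same end to end from a shell:

```bash
phenocal simulate --seed 3 --n-species 12 --out data/
phenocal run --config config.yaml   # paths + thresholds + seed, see docs
```

Every run writes curated records, predictions, strata, one CSV row per
calendar, synchrony summaries, and a log whose per-stage record counts
always balance. Identical config + seed reproduces byte-identical CSVs.

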