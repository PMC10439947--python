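# ecograde

Weight-free dynamic grade evaluation of slope ecological restoration
effect. The pipeline:

1. **Grade standard** — each evaluation index gets five half-open value
   intervals `(lo, hi]` (quantitative) or fixed ordinal scores 1–5
   (qualitative), one per quality grade I (very good) … V (very poor).
2. **Representative sampling** — per Monte-Carlo trial, one synthetic
   object per grade is drawn, every quantitative value uniform on that
   grade's interval.
3. **Sqrt-cosine classification** — the observed site is assigned the
   grade of its most similar representative, using the Hellinger-affinity
   similarity `Σ√(a·b) / (√Σa · √Σb)`; no index weights anywhere.
4. **Trial probabilities** — classification counts over N trials
   (default 1000) give the grade-probability vector; the modal grade is
   the evaluation result.
5. **Markov projection** — that vector seeds a five-state Markov chain
   whose row-stochastic transition matrix is fitted to sparse calibration
   distributions by constrained multi-start SLSQP (absorbing endpoint
   grades by default), then propagated forward in time.
6. **Sensitivity** — local finite-difference sensitivity of the output to
   each index, with common random numbers and an optional
   Normal-uncertainty draw mode.

A 15-index grade standard and seven observed restoration slopes are
bundled as fixtures (`ecograde.datasets`).

## CLI

```sh
# write the bundled fixtures as CSV
ecograde fixtures data/

# Monte-Carlo grade probabilities (Table-style report + JSON)
ecograde evaluate --standard data/slope_standard.csv \
    --objects data/slope_sites.csv --trials 1000 --seed 1 --out report.json

# dynamic projection with a calibration file (CSV: step,p1..p5)
ecograde dynamic --standard data/slope_standard.csv \
    --objects data/slope_sites.csv --calibration cal.csv \
    --steps 4 --seed 1 --out dynamic.json

# local index sensitivity (Normal-uncertainty mode shown)
ecograde sensitivity --standard data/slope_standard.csv \
    --objects data/slope_sites.csv --normal-draws 100 --seed 1

# within- vs between-grade similarity separation diagnostic
ecograde diagnose --standard data/slope_standard.csv --seed 1
```

Every command honors `--seed` end to end and echoes its effective
configuration into the report.

## File formats

- **Grade standard** (CSV): `index_id,name,kind,units,g1_lo,g1_hi,…,g5_lo,g5_hi`;
  qualitative rows put the five scores in the `*_lo` fields. A YAML
  mapping with an `indexes` list of the same keys is also accepted.
- **Objects** (CSV): `object_id` plus one column per index id.
- **Calibration** (CSV): `step,p1,…,p5`, each row a grade distribution
  after that many transfer steps (renormalized with a warning if needed).
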