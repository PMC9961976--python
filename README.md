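# sachetcu

Monte Carlo model of the risk that a batch of mini-tablet sachets fails
USP <905> content-uniformity (CU) testing.

## The problem

Pediatric mini-tablets (compressed tablets ≤2.5 mm in diameter) are dosed
by filling a target count *n* of them into a sachet; each sachet is one
dosage unit. Two stochastic mechanisms threaten dose uniformity:

* **bulk tablet variability** — per-tablet drug content varies through
  weight (RSD σ_w) and potency-per-weight, i.e. blend uniformity
  (RSD σ_p), conveniently collapsed into a single *composite RSD*
  σ_c = √(σ_w² + σ_p²);
* **fill-count errors** — each tablet passed into a sachet carries an
  independent probability *p* of a ±1 miscount (overfill or underfill),
  which weight checkers often cannot detect. A single miscount shifts the
  dose by 100/n percent of label claim.

Batch release hinges on the two-stage USP <905> test: 10 sachets are
assayed and the acceptance value AV = |M − x̄| + k·s (k = 2.4, M = x̄
clamped to 98.5–101.5 %LC) is compared with L1 = 15; if it exceeds L1,
20 more sachets are pooled (n = 30, k = 2.0) and, in addition to
AV ≤ L1, every individual unit must lie within (1 ± 0.25)·M. The test
anticipates Gaussian content variance, so the discrete dose steps caused
by miscounts interact with it in unintuitive ways — e.g. failure
probability can *rise* with fill count below 5, and drops sharply at the
4→5 and 8→9 count transitions where a single (or double) miscount stops
crossing the ±25% individual limit.

`sachetcu` simulates sets of 30 sachet assays from the model above,
applies the decision procedure exactly, and estimates the stage-1
(AV₁ > L1) and stage-2 (batch release) failure probabilities with Wilson
95% intervals, down to a reporting floor of 1/n_sets. Inverse-design
solvers answer the practical questions: which fill counts keep failure
risk below a limit, and how large a per-tablet error probability a
filling process may tolerate.

## Worked example

A product with 5% weight RSD and 5% potency RSD (composite RSD
`sachetcu composite-rsd 0.05 0.05` → `0.0707107`), filled four tablets
per sachet with a 0.1% per-tablet miscount probability:

```sh
sachetcu estimate --weight-rsd 0.05 --potency-rsd 0.05 -n 4 -p 0.001 \
    --n-sets 200000 --seed 42
```

```json
{
 "p_stage1_fail": 0.03999,
 "p_stage2_fail": 0.01724,
 "ci95_stage2_low": 0.016678742116658752,
 "ci95_stage2_high": 0.017819802553751093,
 "mean_av1": 8.893163627198634,
 "mean_av2_all": 7.55952159381408,
 "mean_av2_conditional": 11.845120993227575,
 "n_fail_stage1": 7998,
 "n_fail_stage2": 3448
}
```

(abridged): 4.0% of simulated sets trigger stage 2 and 1.7% fail batch
release; the mean stage-1 acceptance value is 8.9%. Note how uninformative
the mean AV is about the miscount-driven failure risk — with p = 0 it
changes by well under one point while the failure probability collapses
below the detection floor.

Judging a measured assay table (one %LC value per line, 10 or 30 lines):

```sh
sachetcu judge assays.txt
```

```json
{
 "n_values": 30,
 "outcome": "FAIL",
 "av1": 20.83261259945068,
 "av2": 9.493857663422878,
 "M2": 99.13333333333334,
 "n_individual_violations": 1,
 "violation_indices": [0]
}
```

Here a single 74 %LC sachet (a one-tablet underfill of a 4-count product,
74 < 0.75·M₂ = 74.35) fails the batch on the individual criterion even
though the stage-2 AV is comfortable — the single-miscount mechanism that
makes counts below five risky.

Solvers and sweeps:

```sh
sachetcu solve-counts --max-fail 1e-4 --composite-rsd 0.022 -p 1e-4 --n-sets 150000
sachetcu solve-error-prob --max-fail 1e-3 --composite-rsd 0.02 -n 5
sachetcu grid --n-sets 100000 --csv grid.csv
```

`solve-counts` certifies a count only when the Wilson upper bound of its
failure estimate clears the limit; for the parameters above it returns
counts 5–10. `solve-error-prob` evaluates its whole probability lattice
under common random numbers so the comparisons are paired.

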