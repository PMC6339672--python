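# irtlink

Calibrate, link and score polytomous questionnaires on a common latent
metric. `irtlink` implements the full pipeline for building an item-response
theory (IRT) common metric from several linked datasets that each administer
a subset of instruments:

* **Assumption checks** — kernel-smoothed monotonicity curves of item scores
  against rest scores; essential unidimensionality via mixed
  polychoric/polyserial/Pearson correlations, hierarchical exploratory factor
  analysis with a Schmid-Leiman orthogonalization, omega-hierarchical and
  explained common variance (cutoffs 0.70 / 0.60).
* **Sparse-category collapsing** — response options with fewer than 20
  observed responses are merged toward the scale interior.
* **Concurrent calibration** — multi-group marginal maximum likelihood EM for
  the partial credit model (PCM) and generalized partial credit model (GPCM)
  over a common-item non-equivalent-groups design, with dataset-specific
  latent normal distributions (reference dataset pinned at N(0,1)).
  PCM-vs-GPCM likelihood-ratio test and AIC comparison.
* **Fit and invariance screens** — LM-type item-fit and DIF statistics with an
  effect-size companion (flag only when significant *and* ES > 0.05),
  subgroup parameter assignment for flagged items, and Yen's Q3 residual
  correlations for local dependence (flag at |Q3| > 0.25).
* **Stocking-Lord linking** — place an externally calibrated instrument on the
  common scale by matching scale characteristic curves.
* **Scoring** — EAP latent estimates, a standardized reporting metric
  (0 anchored at the measurable floor, 10 points per logit), crosswalk tables
  from summed scores, marginal/conditional/GLB reliability, score-level
  correlations with overlap correction, and cross-instrument congruence
  reports (paired tests, Bonferroni, Cohen's d).
* **Synthetic data** — a first-class generator for linked multi-dataset
  studies with anchor instruments, dataset-specific latent distributions,
  injected uniform DIF, testlet local dependence, sparse extreme categories
  and MCAR missingness; everything deterministic under a seed.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which exercises the
end-to-end statistical guarantees (parameter recovery, DIF/LD operating
characteristics, linking recovery, congruence) on seeded simulations; it
takes several minutes.

## Command line

Every stage is exposed through one CLI:

```bash
irtlink simulate   --config cfg.yaml --out-dir out/sim
irtlink diagnose   --responses out/sim/responses.csv --out-dir out/diag
irtlink calibrate  --responses out/sim/responses.csv \
                   --metadata out/sim/metadata.csv --out-dir out/cal
irtlink link       --source-bank ext.json --target-bank out/cal/bank.json \
                   --common ANCHOR --out-dir out/link
irtlink score      --responses out/cal/responses_analyzed.csv \
                   --bank out/cal/bank.json --out out/scores.csv
irtlink crosswalk  --bank out/cal/bank.json --out-dir out/cw
irtlink congruence --responses out/cal/responses_analyzed.csv \
                   --bank out/cal/bank.json --instruments Q00,Q01 \
                   --out out/congruence.json
```

`calibrate` collapses sparse categories, fits PCM and GPCM, picks the better
model by AIC, runs DIF/item-fit/Q3 screens, assigns subgroup parameters to
flagged items, anchors the standardized metric, and writes the item bank
(JSON + CSV), group distributions, flag tables and an append-only JSON-lines
run log stamped with the config hash and seed. Note that `calibrate` also
writes `responses_analyzed.csv` (category codes after collapsing) — score
against that file, not the raw responses.

Configs are YAML/JSON; all decision thresholds (min category count 20,
Q3 0.25, ES-DIF 0.05, omega 0.70, ECV 0.60, conditional reliability 0.70,
congruence effect size 0.20) default to the standard rules and are
overridable under `thresholds:`.

## Package layout

| module | contents |
|---|---|
| `irtlink.core` | GPCM/PCM probabilities, information, scale characteristic curves and inverses, item banks, quadrature grids |
| `irtlink.simulate` | link designs, group distributions, bank/response generation, category collapsing |
| `irtlink.calibrate` | multi-group MML-EM, model comparison, LM DIF/fit screens, Q3, subgroup respecification |
| `irtlink.linking` | Stocking-Lord coefficients and bank transforms |
| `irtlink.diagnostics` | monotonicity smooths, mixed correlations, hierarchical omega/ECV |
| `irtlink.scoring` | EAP scores, standardized metric, reliabilities, score correlations, congruence |
| `irtlink.io` | CSV/JSON formats, run configuration, crosswalks, logging |
| `irtlink.cli` | the `irtlink` command |
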