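# ipfcost

A prevalence-based cost-of-illness model for idiopathic pulmonary
fibrosis (IPF), built as a tested, configurable pipeline:

* **Epidemiology** — prevalent/diagnosed case counts, the
  incidence-over-prevalence annualization ratio, and DEALE (declining
  exponential approximation to life expectancy) annual mortality rates.
* **Cost components** — five annual per-patient cost components per
  disease course (diagnosis, treatment incl. adverse-event costing with a
  strict >5 % grade-3/4 inclusion rule, monitoring, acute exacerbations,
  end-of-life care).
* **Aggregation** — per-course totals, the course-weighted breakdown
  table, and category shares (largest-remainder rounding to one decimal).
* **Sensitivity** — one-at-a-time scenarios (multipliers, substitute
  values, or unit-cost min/max column switches) with tornado ranking.
* **Synthetic Delphi panel** — reproducible multi-round expert-panel
  simulation whose per-question medians form a consensus input set, so
  the whole pipeline is testable end-to-end without external data.

A calibrated Spanish IPF baseline (`ipfcost.baseline.baseline_inputs()`)
reproduces the published base case: 5,525 prevalent / 4,696 diagnosed
patients, a weighted annual cost of €26,435 per patient with category
shares 4.5 / 27.0 / 22.5 / 44.1 / 1.9 %, and the ±25 % prevalence and
incidence sensitivity results.

## CLI

```sh
# write the input template used throughout
python - <<'EOF'
import json
from ipfcost.baseline import baseline_inputs
print(json.dumps(baseline_inputs().model_dump(mode="json"), indent=2))
EOF
# > inputs.json

ipfcost run --inputs inputs.json --out results/
ipfcost sensitivity --inputs inputs.json --scenarios scenarios.json --out results/ [--plot]
ipfcost synth --inputs inputs.json --out panel/ --seed 42 [--experts 15 --rounds 3 --dispersion 0.1]
ipfcost schema   # JSON Schema of the input document
```

`run` writes `breakdown.csv` (categories × courses + weighted column,
2-decimal EUR, half-up) and `summary.json` (unrounded and rounded
totals, shares, case counts). `sensitivity` writes `tornado.csv` ordered
by swing. `synth` writes `panel.csv`, the derived
`consensus_inputs.json`, and `panel_meta.json`; identical seeds give
byte-identical output. Exit codes: 1 I/O, 2 validation, 3 unresolvable
reference, 4 domain error.

Input documents are JSON or YAML validated against
`schemas/model_inputs.schema.json`; the `unit_costs` and `diagnosis_use`
blocks may point to CSV side-tables (UTF-8, comma-separated, header
row). Scenario files are lists of
`{"parameter_id": ..., "low": {"multiply": 0.75}, "high": {"column": "max"}}`.

## Notes on calibration

Per-course treatment and monitoring costs and exacerbation rates in the
baseline are calibrated inputs (the underlying doses, durations, and
panel ranges were never published at line level); the computation engine
itself is validated against an independent flat-enumeration oracle on
randomized fixtures — see `tests/flat_oracle.py`.
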