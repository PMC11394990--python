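# fsindex

Composite food-safety index construction from sampling-and-inspection
records. Each record (one sample × one test project) is scored against its
permissible limits, corrected by consumption, hazard, sales-channel,
production-region and factor-analysis-of-mixed-data weights, and aggregated
into 0–100 safety indexes per city and per food category. A paired-t test
compares the factor-corrected indexes against an expert-elicitation
baseline.

## Modules

| module | what it does |
| --- | --- |
| `fsindex.qualification` | piecewise `[0,1]` qualification score `Q` from a test result and its (min, max) permissible limits |
| `fsindex.weights` | consumption-proportion, 1–5 hazard, channel-size and production-region weight lookups |
| `fsindex.famd` | mixed-data factor analysis: block scaling by first eigenvalues, SVD, factor scores, bounded exponential transform, per-sample composite factor weight |
| `fsindex.index` | comprehensive degree (product of `Q` and all weights), group means, min–max scaling to 0–100 |
| `fsindex.compare` | paired-sample t-test between the two index series |
| `fsindex.synthetic` | seeded generator of realistic inspection campaigns (cities, 8 categories, 16 channels, mixed auxiliary variables, controllable contamination) |
| `fsindex.io` / `fsindex.cli` | CSV/JSON readers and writers, run configuration, pipeline orchestration, CLI |

## CLI

```bash
# generate a synthetic campaign with its config tables
fsindex simulate --n 5000 --contamination 0.1 --seed 1 --out runs/sim

# full pipeline: score -> weights -> factor analysis -> indexes -> comparison
fsindex run-all \
    --records runs/sim/records.csv \
    --consumption runs/sim/consumption.csv \
    --hazards runs/sim/hazards.csv \
    --channels runs/sim/channels.csv \
    --variable-spec runs/sim/variable_spec.csv \
    --region-parents runs/sim/region_parents.csv \
    --out runs/out

# paired-t comparison from an existing indexes table
fsindex compare --indexes runs/out/indexes.csv --grouping city
```

`run-all` writes `scored.csv`, `indexes.csv`, `comparison.json`,
`famd_summary.json`, `exclusions.log` and a `manifest.json` with input
checksums; outputs are byte-identical across reruns with the same inputs.
A YAML run configuration can replace the per-file flags (`--config
run.yaml`); flags override file entries. Useful knobs: `--k` (transform
ceiling, default 100), `--retention` (`cumulative:0.8`, `kaiser` or
`fixed:R`), `--scaling` (`minmax` or `raw`).

A small bundled fixture (200 synthetic records) ships with the package;
`fsindex.io.RunConfig.for_fixture()` builds a run configuration for it.

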