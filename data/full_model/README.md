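# Full-model drop-in

The reference 60-component / 264-interaction chondrocyte model is published
upstream as supplementary material (rule equations and SBML-qual files) and
is not redistributable inside this repository. To enable the
full-model acceptance criteria and targets, transcribe it here as:

- `network.tsv` — TSV edge table with columns
  `source  target  sign  layer  provenance` (sign `+`/`-`, layer
  `fast`/`slow`), one row per interaction (264 rows).
- `network.rules.yaml` — rules sidecar declaring, per component, layer
  participation and role, plus `saturation_default`, per-rule saturation
  values and any `product`-combiner exceptions:

  ```yaml
  saturation_default: <value from the published equations>
  components:
    SOX9: {role: transcription_factor, has_fast_layer: true, has_slow_layer: true}
    ...
  rules:
    - {target: <id>, layer: fast, combiner: product}
    - {target: <id>, layer: slow, saturation: <value>}
  ```

- `scenarios.yaml` — named clamp sets for the scenario experiments:

  ```yaml
  scenarios:
    inflammation: {<component>: 1.0, ...}
    inflammation_plus_tgfb: {<component>: 1.0, ..., TGFB: 1.0}
  ```

With these files present, `tests/test_acceptance.py` runs the full-model
criteria and `scripts/acceptance.py` emits targets t1-t9 (and t11/t12 when
`scenarios.yaml` exists).
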