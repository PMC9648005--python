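# chondro

A virtual-cell toolkit for two-layer regulatory networks: semi-quantitative
network simulation with priority-class asynchronous updates, Monte Carlo
attractor discovery, exhaustive in-silico perturbation screening, and a
consensus gene-regulatory-network (GRN) inference pipeline for multi-batch
expression data.

Each network component carries up to two sub-variables in `[0, 1]`: a *fast*
protein-activation level and a *slow* gene-expression level. The value a
component exposes downstream (its *global activity*) is the product of the
two. Updates are additive-saturating (`clamp((sum activators - sum
inhibitors) / saturation)`, with a product combiner for exceptional
mechanisms), applied asynchronously in random order with fast reactions
relaxed before each slow update, until nothing moves beyond a tolerance
(default `1e-2`). Stable states are grouped across random initializations,
labeled by marker signatures (Healthy / Hypertrophic / None), and probed by
clamping components for a finite number of steps and watching where the
system settles.

## Layout

| Module | Contents |
|---|---|
| `chondro.model` | `ComponentSpec`, `InteractionSpec`, `UpdateRuleSpec`, `LayeredNetwork` |
| `chondro.io` | TSV edge-table (+ YAML rules sidecar) and SBML-qual read/write |
| `chondro.topology` | node/edge counts, unique-neighbor degree, mean shortest path |
| `chondro.engine` | the two-priority-class asynchronous simulator |
| `chondro.attractors` | Monte Carlo canalization, state grouping, phenotype signatures |
| `chondro.screen` | single/pairwise/scenario/dose-grid perturbation experiments, Markov summary, candidate selection |
| `chondro.grn` | quantile normalization, empirical-Bayes batch correction, clustering QC, three edge scorers (MI+DPI, tree importances, stability selection), mean-minus-SD consensus with Spearman signs |
| `chondro.fixtures` | toy networks, a brute-force fixed-point oracle, and a linear-Gaussian expression generator with known ground truth |
| `chondro.cli` | the `chondro` command-line app |

## CLI

```sh
# build a demo network and inspect it
chondro fixtures make mini_chondro --out mini.tsv
chondro net stats mini.tsv
chondro net convert mini.tsv mini.xml --to sbml_qual

# attractors and basins
chondro attractors mini.tsv --n-init 2000 --seed 1 --out attractors.json

# perturbation screening from a discovered attractor
chondro screen single mini.tsv --attractors attractors.json \
    --source Hypertrophic --seed 1 --out single.csv
chondro screen pairwise mini.tsv --attractors attractors.json \
    --source Hypertrophic --seed 1 --out pairwise.jsonl   # resumable stream
chondro screen dose mini.tsv --attractors attractors.json --source Hypertrophic \
    --comp-x SOX9 --comp-y RUNX2 --levels 0:1:0.1 --seed 1 --out dose.json

# one app-style condition from a YAML run config (see `chondro app --help`)
chondro app run.yaml

# synthetic expression data and consensus GRN inference
chondro fixtures expr --n-genes 20 --n-tfs 5 --n-batches 2 --seed 1 \
    --out expr.tsv --annotations ann.csv --edges-out truth.csv
chondro infer expr.tsv ann.csv --tf TF0 --tf TF1 --tf TF2 --tf TF3 --tf TF4 \
    --seed 1 --out edges.csv
```

Every output embeds the master seed (and, where relevant, a config hash), so
a run reproduces byte-for-byte.

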