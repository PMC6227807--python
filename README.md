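# entroscape

Binary Shannon entropy landscapes of single-cell gene expression along
differentiation orderings.

The package binarizes single-cell expression tables (strictly positive =
"on"), estimates per-population marginal and pairwise-joint binary entropies
in bits with jackknife standard errors, and traces entropy along a
user-supplied differentiation path or tree to locate entropy peaks. Three
entropy estimators are available: maximum-likelihood (plug-in),
Miller–Madow, and a James–Stein-type shrinkage estimator toward the uniform
distribution. A synthetic-data module generates populations as seeded
mixtures of discrete regulatory-network substates (with detection-limit
dropout), together with closed-form true entropies for testing.

## Layout

- `src/entroscape/io.py` — expression tables, the two qPCR Ct conventions
  (background-28 raw Ct; detection-limit-30 ΔCt), binarization.
- `src/entroscape/entropy.py` — binary/joint entropy, mutual information,
  Bernoulli variance, the three count-based estimators.
- `src/entroscape/resampling.py` — generic delete-one jackknife.
- `src/entroscape/pipeline.py` — population profiles, per-gene entropy
  tables, pairwise joint-entropy matrices, trajectory peak detection, and
  the report writer. Population SEs use a closed-form leave-one-out path
  (deleting a cell shifts one count per gene/pair state); the generic
  jackknife loop serves as its cross-check in the tests.
- `src/entroscape/synthetic.py` — substate-mixture generator, scenario
  specs (YAML), exact mixture entropies.

## CLI

Generate a synthetic dataset (built-in three-stage commitment scenario, or a
YAML scenario file):

```sh
entroscape simulate --seed 3 --out cells.csv
entroscape simulate --scenario scenario.yaml --seed 3 --out cells.csv
```

Run the full analysis:

```sh
printf 'precursor\ncommitment\ndifferentiated\n' > ordering.txt
entroscape run --input cells.csv --dialect csv --transform none \
    --label-col population --estimator ml \
    --ordering ordering.txt --outdir out --z 2.0
```

The ordering file is either one population label per line (a linear path) or
two whitespace/comma-separated columns of parent→child edges (a tree).
`--transform guo|pina` inverts the corresponding Ct convention before
binarization. A YAML config can be passed with `--config`; command-line
flags override its keys. Outputs are TSV tables (`population_profile.tsv`,
`gene_entropies.tsv`, `joint_entropy_<population>.tsv`, `trajectory.tsv`)
with a commented header recording version and parameters; identical configs
give identical numbers.

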