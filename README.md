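# phyloshape

Phylogenetic body-shape allometry toolkit: skeletal elongation morphometrics,
phylogenetic generalized least squares (PGLS) with maximum-likelihood Pagel's
λ, bootstrap allometry classification, randomized-residual-permutation (RRPP)
variance decomposition, and a synthetic-data generator with known ground
truth.

## What it does

Given specimen-level skeletal measurements (or a pre-aggregated species
table), a Newick phylogeny, and an ecotype label per species, the pipeline:

1. computes formula-defined shape statistics per specimen — whole-body
   elongation ratio `(cranial length + summed centrum lengths) / body depth`,
   head elongation `cranial length / cranial height`, per-region axial
   elongation `Σ centrum length / mean vertebral height`, geometric-mean body
   size (11 cranial/axial measurements), and full/reduced limb lengths — and
   averages them to species;
2. prunes the tree to the shared species, builds the Brownian-motion
   covariance, and fits PGLS regressions whose residual phylogenetic signal
   (Pagel's λ) is estimated by profile maximum likelihood;
3. classifies allometry per ecotype from parametric-bootstrap 95% CIs around
   the interaction-model slopes (isometric slope 0 for dimensionless ratios);
4. size-corrects traits via PGLS residuals against ln body size and compares
   ecotype group means by bootstrap CI exclusion;
5. decomposes body shape into six morphological components with a
   phylogenetic multiple regression and sequential (entry-order) sums of
   squares, using RRPP permutation p-values, log-F effect sizes Z, and
   Benjamini–Hochberg adjustment per table.

## CLI

```bash
# generate a fully synthetic bundle (measurements, species table, tree, truth)
phyloshape simulate --outdir synthetic --n-species 87 --seed 1

# full pipeline from the species table
phyloshape run-all --tree synthetic/tree.nwk --species-csv synthetic/species.csv \
    --outdir results --bootstrap-reps 1000 --rrpp-iters 1000 --seed 1

# or from raw specimen measurements
phyloshape run-all --tree synthetic/tree.nwk --measurements-csv synthetic/measurements.csv \
    --outdir results --seed 1
```

Subcommands `compute-traits`, `fit-allometry`, `fit-components`, `fit-limbs`
and `decompose-shape` run individual stages; `run-config` reads a flat
`key = value` config file. Outputs are tidy CSVs (with seed/version/checksum
header comments), `summary.json`, a taxa-overlap report and a run log.
Identical seeds give byte-identical outputs.

## Layout

```
src/phyloshape/
  morphometrics.py   specimen statistics, species aggregation, CSV I/O
  phylo.py           Newick I/O, pruning, covariance + lambda transform
  pgls.py            PGLS/ML-lambda engine, ANCOVA, bootstrap, allometry calls
  rrpp.py            sequential SS decomposition with RRPP and BH adjustment
  simulate.py        pure-birth trees, trait simulation, specimen synthesis
  pipeline.py        end-to-end orchestration
  cli.py             click command line
```
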