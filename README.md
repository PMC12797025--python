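# fibrilscreen

A data-efficient ligand-discovery pipeline for binder classification and
scaffold-aware compound-library curation:

- **Labeling** — binder/non-binder labels from measured Ki with a strict
  25 nM threshold; "no binding" records censored at 1 µM count as
  non-binders; stratified train/test splitting with largest-remainder
  allocation.
- **Featurization** — Morgan fingerprints (radius 3, 1024 bits) combined
  with 2D physicochemical/topological descriptors; descriptor columns with
  any missing value in the fitting set are dropped, the rest are z-scored
  with training-row statistics only.
- **Model selection** — logistic regression, k-nearest neighbours and
  decision-tree families tuned by stratified five-fold cross-validation
  optimising macro F1, with two-stage feature selection (constant/duplicate
  filtering, then L1-logistic ranking with CV-chosen retained-set size)
  refit inside every fold.
- **Similarity baseline** — binder iff the maximum Tanimoto similarity to
  any training-set binder exceeds τ (default 0.5).
- **Curation** — assign library molecules to their nearest of three
  reference chemotypes, emit per-reference similarity histograms, and
  select a prospective set mixing top-similarity picks (round-robin across
  chemotypes) with a seeded uniform sample of "alternative" compounds
  scoring < 0.2 against all references.
- **Synthetic benchmark** — scaffold-decorated SMILES libraries with a
  latent fragment-pharmacophore affinity model
  (`log10 Ki = intercept − slope · Tanimoto + noise`, censored at 1 µM,
  quantile-calibrated to a target binder fraction), so the whole pipeline
  is exercisable without external data.

## Command line

Every stage is a subcommand of `fibrilscreen`:

```bash
fibrilscreen simulate --n 315 --seed 0 --out study.csv
fibrilscreen split study.csv --out split.json --seed 7
fibrilscreen train study.csv --split-manifest split.json --out model
fibrilscreen evaluate study.csv --split-manifest split.json --model model
fibrilscreen baseline study.csv study.csv --tau 0.5 --out baseline.csv
fibrilscreen curate library.smi --n-high 14 --n-low 16 --out selection.csv
fibrilscreen predict query.csv --model model --train-table study.csv --out preds.csv
fibrilscreen prospective-eval preds.csv measured.csv
fibrilscreen run-all --config config.yaml --out rundir --seed 0
```

`run-all` executes the full study (synthetic by default) and writes every
artifact — dataset, split manifest, CV logs, model bundle, classification
reports in both text and JSON, similarity histograms, prospective
selection/predictions — plus a manifest that reproduces the run
byte-for-byte under the same seed. A YAML config may set any `RunConfig`
field (see `fibrilscreen.cli.build_run_config`); CLI flags override.

## Layout

```
src/fibrilscreen/
  chem.py         parsing, fingerprints, Tanimoto, descriptors, matrices
  labeling.py     Ki-threshold labels, stratified splits
  models.py       CV engine, grids, reports, trained-model bundles
  baseline.py     max-Tanimoto similarity baseline
  curation.py     chemotype assignment, histograms, prospective selection
  simulate.py     synthetic libraries + latent affinity model
  workflow.py     end-to-end orchestration (run_study, evaluate_prospective)
  prospective.py  bundled prospective campaign outcome table
  io.py           delimited-text readers/writers
  cli.py          click CLI
tests/            pytest suite (test_acceptance.py holds the criteria)
scripts/acceptance.py
```
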