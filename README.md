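# tmesig

Target-agnostic consensus random-forest signatures of a query gene's
microenvironment, for multi-entity bulk expression cohorts.

Given a gene × sample expression matrix (FPKM/RSEM/RPM-like, raw scale) and a
sample → entity annotation, the pipeline:

1. **select** — dichotomizes samples into *target-high* vs. *rest* by
   per-entity z-score of the query gene (default: log2(x+1), sample sd,
   inclusive threshold z ≥ 1.5);
2. **signature** — trains repeated random-forest classifiers
   (default 100 models × 1000 trees) on independent stratified 50/50
   train/evaluation splits, collects each model's top-200 genes by impurity
   importance, and ranks genes by occurrence count across models into a
   consensus signature; a *leave-target-out* rerun (target gene removed from
   the features) measures how much of the signature depends on the
   label-defining gene itself;
3. **validate** — majority-votes each sample's evaluation-half predictions
   into one cohort-level confusion matrix with accuracy, F1 and MCC;
4. **correlate** — per-entity Pearson/Spearman panels of the target vs.
   candidate genes with joint Benjamini–Hochberg adjustment, plus
   direction-splitting of signatures (Kruskal–Wallis) and two-group
   mean ± sd tables for companion miR matrices;
5. **enrich** — local hypergeometric over-representation of signature gene
   lists against user-supplied GMT collections.

A bundled synthetic-cohort generator (**simulate**) plants a
latent-factor-correlated gene module with known ground truth, so the whole
workflow is testable offline; `recovery_score` measures how much of the
planted module a signature recovers.

## CLI

Each stage runs standalone:

```sh
tmesig simulate --n-entities 4 --samples-per-entity 250 --n-genes 2000 \
    --module-size 100 --seed 0 --out-dir run/
tmesig select --expression run/expression.tsv --annotation run/annotation.tsv \
    --gene TARGET --threshold 1.5 --min-entity-size 60 --out run/labels.tsv
tmesig signature --expression run/expression.tsv --labels run/labels.tsv \
    --gene TARGET --n-models 100 --n-trees 1000 --top-k 200 --seed 0 \
    --leave-target-out --out-dir run/sig/
tmesig validate --votes run/sig/model_votes.json --labels run/labels.tsv \
    --out run/metrics.json
tmesig correlate --expression run/expression.tsv --annotation run/annotation.tsv \
    --target TARGET --panel G00001,G00002 --out run/corr.tsv
tmesig enrich --query run/sig/signature.tsv --gmt sets.gmt \
    --universe run/expression.tsv --out run/enrichment.tsv
```

or end-to-end from one YAML config with a reproducibility manifest:

```sh
tmesig run-all --config config.yaml --out-dir run/
```

```yaml
# config.yaml
seed: 0
target_gene: TARGET
simulate: {n_entities: 4, samples_per_entity: 250, n_genes: 2000, module_size: 100}
select: {threshold: 1.5, min_entity_size: 60}
signature: {n_models: 100, n_trees: 100, top_k: 200, leave_target_out: true}
# optional: mir: {n_mirs: 50, mir_module_size: 10}
```

Identical config + seed ⇒ byte-identical outputs (manifest records digests).

## File formats

Expression matrices are TSV, genes × samples, first column `gene_id`, raw
(unlogged) non-negative values, no missing cells. Annotations are TSV with
columns `sample_id`, `entity`. Gene sets are standard 3+-field GMT. All
outputs are TSV/JSON.

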