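# tissuescore

Benchmarked confidence scoring and integration of gene–tissue expression
evidence across organisms and platforms.

Heterogeneous gene×tissue expression matrices (microarray intensities,
FPKM/TPM, arbitrary units) are converted into unified confidence scores by

1. standardizing identifiers (probe→gene collapsing by arithmetic mean,
   ambiguous probes removed) and tissue labels (free text → ontology terms);
2. benchmarking each dataset against a gold standard of trusted gene–tissue
   pairs: pairs are sorted by raw expression and **fold enrichment** is
   computed in sliding windows (default 100 pairs) — the fraction of a
   window's pairs found in the gold standard divided by the fraction
   expected at random;
3. fitting a sigmoid `score(x) = a0 + (a1−a0)/(1 + exp(−a2·(log10 x − a3)))`
   to the (raw expression, fold enrichment) curve, which turns raw values
   into confidence scores;
4. mapping confidences onto a common 0–5 **star** scale through a single
   monotone piecewise-linear calibration anchored on quantiles of a
   reference channel (text mining by default); associations with negative
   pre-clamp scores are removed;
5. propagating scores up the tissue ontology (is_a DAG, max semantics) and
   integrating evidence channels (knowledge / experiments / text mining)
   by taking the per-pair maximum.

Gold standards for organisms lacking curated annotations are produced by
transferring annotations through strict 1:1 orthologs extracted from
orthologous-group files. Agreement between datasets is quantified by
Pearson correlation of star scores (within or across organisms, via 1:1
orthologs) and by ROC curves against the gold standard.

A synthetic-world generator (ontology, planted expression truth, ortholog
groups, datasets of controlled quality, incomplete gold standards, toy
literature corpora) makes the entire pipeline testable offline.

## CLI

The `tissuescore` command exposes one subcommand per pipeline stage:
`simulate`, `ingest`, `map-tissues`, `propagate`, `transfer-gs`,
`benchmark`, `fit`, `score`, `calibrate`, `integrate`, `correlate`, `roc`,
`run`, `report`. For example:

```sh
# generate a synthetic world with planted truth
tissuescore simulate --seed 1 --outdir world/

# benchmark a dataset, fit the sigmoid, score the dataset
tissuescore benchmark --dataset world/human.expression.tsv \
    --gold world/human.gold.tsv --window 50 --out curve.tsv
tissuescore fit --curve curve.tsv --out fit.json
tissuescore score --dataset world/human.expression.tsv --fit fit.json \
    --out channel.tsv

# or run the whole workflow from a config file
tissuescore run --seed 1 --outdir run/
tissuescore report --outdir run/
```

`run` executes simulate → gold-standard transfer → text mining → fold
enrichment → sigmoid fit → scoring → calibration → propagation →
integration → correlations/ROC, writing every intermediate (TSV/JSON/OBO)
under the output directory. Output is byte-deterministic for a fixed seed.

## File dialects

All tabular files are TSV (tab separator, `.` decimal, no quoting):
expression matrices (header = tissue labels, column 0 = gene ids), gold
standards (`gene<TAB>tissue`), orthologous groups (group id, comma-separated
`taxid.gene` member tokens), scored channels (gene, tissue id, tissue name,
channel, raw, confidence, stars). Ontologies use a minimal OBO 1.2 subset
(`id`/`name`/`is_a`/`is_obsolete`); only the is_a DAG is used. Sigmoid fits
and calibration functions are flat JSON.

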