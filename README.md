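# emtspectrum

Quantification of the epithelial–mesenchymal continuum in single-cell
expression data.

Epithelial-to-mesenchymal transition (EMT) in carcinomas — pancreatic
ductal adenocarcinoma in particular — is not a binary switch but a plastic
continuum of partial-EMT (pEMT) states between an epithelial and a
mesenchymal pole. `emtspectrum` is a toolkit for placing cancer cells on
that continuum from a counts matrix and an EMT gene signature, and for two
companion measurements used alongside it: a weighted histopathology score
for specimen composition tables, and Ripley L-function statistics for
T-cell infiltration around cancer cells in multiplexed-imaging coordinate
tables. It is aimed at computational biologists analysing tumor scRNA-seq
together with histology and multiplexed imaging readouts.

## The method

Starting from a cells × genes count matrix:

1. **QC** — keep cells detecting between 200 and 5000 genes (configurable
   within the usual 4000–7000 upper range) and at most 10% mitochondrial
   counts (cells strictly above 10% are removed).
2. **Normalise and scale** — depth-normalise, log1p, then z-score each gene
   ("scaled data").
3. **Select cancer cells** — by mean scaled expression of epithelial
   markers and/or a lineage label (e.g. YFP tracing), OR-combined.
4. **Diffusion smoothing** — a MAGIC-style Markov imputation on the
   signature genes: adaptive-kernel kNN affinities
   A_ij = exp(−(d_ij/σ_i)^α) with σ_i the k-th-neighbour distance,
   symmetrised, row-normalised to a transition matrix T, and applied as
   T^t X (defaults k = 15, α = 2, t = 3).
5. **Cluster** — shared-nearest-neighbour graph + Leiden modularity
   communities on the smoothed signature expression; the resolution can be
   chosen from a grid by within-cluster expression consistency.
6. **E/M score** — per cluster,

       score = log2(EPI / MES)

   where EPI and MES are the fractions of strictly positive scaled-
   expression entries over the cluster's cells for the epithelial and
   mesenchymal signature arms. Clusters with score ≥ 1.5 are epithelial,
   ≤ −1.5 mesenchymal, and in between partial-EMT; clusters are relabelled
   1..K from the epithelial to the mesenchymal end, and cell-weighted
   phenotype proportions are reported overall, per sample, and per sample
   classification (pooled score by default).

The EMT signature (e.g. the ~315-gene universal signature with epithelial
and mesenchymal arms) is user-supplied as a two-column TSV and can be
mapped between species by an ortholog table or a title-casing rule.

A fully synthetic data generator produces count matrices with known
ground truth (latent EMT coordinate and class per cell), histology
composition tables, and marked point patterns with tunable
attraction/exclusion between phenotypes, so the entire pipeline is
testable without external data.

## Worked example

The bundled demo simulates 3000 cancer cells at a (40, 35, 25)% mixture of
epithelial / partial-EMT / mesenchymal states and runs the full pipeline:

```bash
emtspectrum run --config examples/demo_config.yaml --out-dir demo_out
```

prints

```
8 clusters | EPI=40.80% PEMT=34.33% MES=24.87%
```

i.e. the recovered phenotype percentages match the simulated mixture to
within a point. `demo_out/em_scores.csv` holds the per-cluster table,
ordered from the most epithelial cluster to the most mesenchymal:

```
cluster,epi_fraction,mes_fraction,score,em_class,n_cells
1,0.957,0.012,6.33,EPI,561
...
4,0.585,0.486,0.27,PEMT,422
...
8,0.007,0.972,-7.22,MES,344
```

Cluster 1 has 96% of its epithelial-arm entries positive and almost no
mesenchymal signal (score 6.3 → epithelial); cluster 4 expresses both arms
at comparable rates (score 0.27 → partial-EMT). `proportions.json` carries
the overall and per-sample percentages, and `samples.csv` the per-sample
classification (all four simulated samples share the mixture, so all are
called pEMT).

The other two instruments are one-liners:

```bash
emtspectrum pathology histology.csv        # weighted pathology score per specimen
emtspectrum spatial points.csv --r-max 20  # L-function AUC of T-cell infiltration
```

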