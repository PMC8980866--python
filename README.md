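# ripeomics

Integrative transcriptome–proteome analysis of a staged time course
(fruit-ripening style), exercised end-to-end on synthetic paired
multi-omics data with planted ground truth.

The package implements:

- **io_formats** — TSV expression matrices with stage/replicate metadata,
  GMT gene sets, gene↔protein ID maps, gene lengths; FPKM computation and
  the expressed-gene filter (max FPKM > 0.3).
- **synthetic_data** — a paired simulator: negative-binomial counts and
  log-normal protein intensities driven by six temporal templates, with a
  stage-decaying mRNA–protein coupling schedule ρ_s, planted gene sets
  (template-aligned, decoupled, random background) and a full truth record
  for recovery testing.
- **differential** — median-of-ratios size factors, Welch-t differential
  expression (padj < 0.05 & |log2FC| > 1) and abundance
  (p < 0.05 & FC > 1.3 or < 1/1.3) calling, three-set Venn region counts.
- **enrichment** — two-tailed Fisher over-representation (minimum-likelihood
  convention), BH correction, and −log10(p)/z enrichment-matrix clustering
  (UPGMA on Euclidean distances).
- **clustering** — fuzzy c-means on standardized stage profiles with a
  membership threshold, Ward "ward.D" hierarchical clustering, PCA scores,
  Pearson sample-correlation matrices.
- **integration** — mRNA–protein pairing, per-stage and per-gene Pearson
  correlations, correlation-ranked GSEA (weighted KS running sum, gene-set
  permutation null), per-set mean log2FC summaries.
- **pipeline / CLI** — one-config orchestration with derived seeds, TSV/JSON
  outputs and a checksummed run manifest (bit-identical reruns).

## CLI

```sh
# simulate a paired dataset with planted truth
ripeomics simulate --seed 1 --outdir data/

# differential calls for one contrast
ripeomics de --omics rna --matrix data/counts.tsv --samples data/samples_rna.tsv \
    --contrast 18DAP:10DAP --out deg.tsv

# over-representation, clustering, integration
ripeomics enrich --de de_ids.txt --background bg_ids.txt --gmt data/gene_sets.gmt --out enr.tsv
ripeomics cluster fcm --matrix data/proteins.tsv --samples data/samples_protein.tsv -c 6 --outdir fcm/
ripeomics integrate genecor --rna data/counts.tsv --rna-samples data/samples_rna.tsv \
    --protein data/proteins.tsv --protein-samples data/samples_protein.tsv \
    --idmap data/id_map.tsv --out genecor.tsv

# full pipeline from a YAML config
ripeomics run --config config.yaml
```

A minimal `config.yaml`:

```yaml
outdir: run1
seed: 1
gsea_n_perm: 1000
simulate: {}          # default: 2000 genes, 600 proteins, 4 stages x 3 reps
```

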