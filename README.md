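# magscope

Reference-independent identification, recovery, and refinement of
population-level genomes (MAGs) from multi-sample metagenomic assemblies.

Two complementary routes are implemented end to end:

1. **Automated co-abundance binning with inspection** (`canopy_refine`) —
   genes are filtered (length ≥ 100 nt, fold-coverage ≥ 2× in ≥ 1 sample),
   their per-sample abundance profiles are canopy-clustered under a Pearson
   distance (thresholds 0.1 / 0.4 / 0.1 / 0.005, stop fraction 1), clusters
   with ≥ 700 genes become metagenomic species (MGS), and each MGS is
   inspected in a 2D k-mer-signature embedding of its best sample's contigs,
   selected by polygon, and refined.
2. **Targeted marker-gene ("beacon contig") recovery** (`targeted`) —
   taxon-annotated marker genes (confidence ≥ 75%) with complete
   predictions are grouped at 95% identity over 50% of the shorter
   sequence; the contigs carrying group members are highlighted as beacons
   in the embedding; the surrounding cluster is selected and refined.

Both routes share: contig chunking (fragments < 1,000 nt dropped, 5,000 nt
chunks), canonical k-mer signatures with a centered log-ratio transform,
Barnes–Hut t-SNE embedding, point-in-polygon bin selection, single-copy
marker-family completeness/contamination scoring (107 families), %GC
diagnostics, and single-pass coverage-outlier refinement (|modified
Z-score| > 3.5, strict).

A first-class synthetic-community simulator (`magscope.synthetic_community`)
generates ground-truthed genomes, contigs, genes, co-abundant coverages,
planted marker families, near-duplicate sequences, and taxon annotations so
every stage is testable without external data.

## Test

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(canopy partition recovery, both end-to-end routes scored against planted
truth, outlier refinement vs a brute-force oracle, greedy-clustering oracle
equivalence, chunking/signature invariants, QC counting, determinism).

## CLI

```
magscope simulate     --config spec.json --out community/
magscope canopy       --coverages gene_coverage.tsv --min-genes 700 --out canopies/
magscope embed        --fasta contigs.fasta --seed 42 --coverage cov.tsv --out points.tsv
magscope cluster-seqs --fasta genes.fasta -c 0.95 --aS 0.5 --out clusters/
magscope target       --annotations tax.tsv --target-taxon Cyanobacteria \
                      --genes genes.fasta --coverages gene_coverage.tsv --out clsg/
magscope refine       --points points.tsv --chunk-map points.chunkmap.tsv \
                      --polygon bin1.json --fasta contigs.fasta \
                      --coverage depth.tsv --out bin1/
magscope run          --config run.yaml           # full pipeline, either approach
```

A `run` config (JSON or YAML) names the input directory (in the layout
written by `magscope simulate`), the approach, the seed, and any stage
parameters; unknown keys are rejected and every run writes a manifest with
parameters, input hashes, and the package version. Polygon files
(`{"vertices": [[x, y], ...]}`) replace the interactive selection step; when
none are given, a scaffolding helper selects the cluster automatically
(convex hull of labelled points for approach 1, density cluster around the
beacon for approach 2).

## Layout

```
src/magscope/
  synthetic_community.py   ground-truthed community simulator + I/O
  signature_embedding.py   chunking, canonical k-mer signatures, CLR, t-SNE
  canopy_mgs.py            co-abundance canopy clustering, MGS calling
  sequence_clustering.py   greedy identity clustering (dereplication, CLSGs)
  bin_qc_refine.py         polygon selection, essential-gene QC, %GC,
                           modified-Z coverage refinement
  targeted_recovery.py     marker selection, CLSG groups, sample ranking,
                           beacon contigs
  pipeline.py              end-to-end orchestration, config, manifests
  cli.py                   click command-line interface
```

## Notes and assumptions

- k = 5 canonical (reverse-complement merged) k-mers and the embedding
  hyperparameters (PCA to 50 dims, perplexity 30, 1,000 iterations) are
  configurable defaults; the upstream visualization tool does not pin them.
- The literal chunking rule can emit very short tail chunks; `--merge-tail`
  (default in the pipeline, opt-in in `magscope embed`) folds tails shorter
  than the minimum length into the preceding chunk.
- Identity in sequence clustering is computed against the shorter sequence
  (local alignment: match +2, mismatch −3, gap open −5, gap extend −2).
- Embedding coordinates are run-specific; polygons are only valid against
  the embedding run that produced them (run id recorded with each bin).
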