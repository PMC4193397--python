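# aggprop

Sequence-only prediction of protein **aggregation propensity** and **GroEL
dependence**, plus the comparative-genomics layer that relates the predicted
proteome fractions (fAg, fC3) to genomic GC content with phylogenetically
aware statistics.

The package contains:

- `aggprop.core_io` — FASTA / newick / TSV readers and writers, sequence
  sanitization (non-canonical residues B/Z/X/U/O/* are dropped with a
  warning), GC content.
- `aggprop.features` — deterministic descriptor engine: residue composition,
  gapped residue-pair composition, pseudo amino acid composition,
  Moreau-Broto / Moran / Geary property autocorrelation, CTD
  (composition/transition/distribution), quasi-sequence-order, foldability
  segment statistics, positive-charge distribution; plus the shipped
  24-feature classification spec. Property scales live in
  `src/aggprop/data/property_scales.tsv`.
- `aggprop.curation` — solubility thresholding (>70% soluble, <30%
  aggregation-prone), multi-study substrate-label merging, greedy redundancy
  reduction at 30% global-alignment identity.
- `aggprop.model` — confusion-matrix metrics (Acc/Sn/Sp/MCC), ROC/AUC, mRMR
  feature selection, RBF-SVM training under stratified 5-fold CV with pooled
  metrics, sigmoid-calibrated scored prediction, JSON model serialization.
- `aggprop.genome_scan` — proteome-wide application of both classifiers:
  fAg = predicted aggregation-prone fraction, fC3 = GroEL-obligate fraction
  (the obligate classifier is applied within the predicted aggregation-prone
  subset; both denominators are reported), groEL-copy-number stratification
  with Mann-Whitney tests.
- `aggprop.phylo_stats` — Kendall tau-b, Felsenstein independent contrasts,
  through-origin contrast correlation, ANCOVA (`y ~ gc * habitat`, Type-II
  F-tests), Mann-Whitney U (exact and tie-corrected normal approximation).
- `aggprop.synthetic_data` — seeded generators: codon-model GC-biased
  proteomes, planted-signal labeled sets, Yule trees with correlated
  Brownian traits, per-genome summary tables.

## CLI

All functionality is reachable through one entry point; each run writes a
`*.manifest.json` provenance record next to its output.

```bash
# synthetic fixture bundle (proteome FASTAs, training set, tree, metadata)
aggprop synth --seed 0 --n-organisms 20 --proteome-size 50 --out-dir demo/

# feature matrix for a FASTA
aggprop features demo/org0000.fasta --out demo/features.tsv

# curate a training set from a solubility table + substrate lists
aggprop curate --solubility sol.tsv --substrates groel.txt --substrates dnak.txt \
    --sequences all.fasta --out-prefix curated

# train (use --balanced for the imbalanced GroEL-obligate task)
aggprop train --fasta demo/train.fasta --labels demo/train.labels.tsv \
    --seed 0 --out demo/model.json

# predict single proteins
aggprop predict --model demo/model.json --fasta query.fasta --out calls.tsv

# proteome-wide scan (repeat --proteome per organism)
aggprop scan --proteome demo/org0000.fasta --proteome demo/org0001.fasta \
    --agg-model demo/model.json --c3-model demo/model.json \
    --metadata demo/metadata.tsv --out demo/summary.tsv

# comparative statistics (Kendall; PIC if a newick tree is given; ANCOVA if
# the metadata has >= 2 habitat levels)
aggprop stats --summary demo/summary.tsv --tree demo/tree.nwk --out demo/stats.json
```

### TSV schemas

- solubility table: header + `id<TAB>solubility` (percent in [0,100]).
- substrate lists: one protein id per line.
- metadata: header + `organism_id`, optional `gc`, `groel_copies`, `habitat`.
- scan summary: `organism_id, n_proteins, n_excluded, fAg, fC3,
  fC3_within_agg, gc, groel_copies, habitat`.
- prediction output: `id, class, confidence` (confidence in (0,1); a
  decision value of 0 maps to exactly 0.5).

## Notes

- Feature extraction is total over the curated length policy: sequences
  shorter than a feature's lag/gap yield 0 with a warning (strict mode
  available); proteome scans exclude proteins shorter than 31 residues.
- Models are plain JSON containers; the RBF decision function is recomputed
  from stored arrays at predict time, and the feature-spec digest is checked
  before prediction.
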