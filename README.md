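# its2vec

Alignment-free classification of fungal DNA barcodes (ITS region) to the
species level, for metabarcoding and reference-database work where BLAST-style
alignment against every reference is too slow and 4^k k-mer frequency vectors
(65,536 features at k = 8) are too large.

## Method

Reference sets in the UNITE tradition group ITS sequences into species-level
operational taxonomic units called **species hypotheses (SHs)**; the SH is the
class label. The pipeline has three stages:

1. **Reference-set construction.** Records whose genus or species rank is
   missing, `unidentified`, or `uncultured` are discarded; SHs with a single
   sequence are dropped; SHs with more than 10 sequences are randomly capped
   at 10. The result is partitioned into *m*-regular subsets
   `ITSset_m` (m = 2…10), each holding the species represented by exactly *m*
   sequences.

2. **Sequence embedding.** Each sequence of length *N* is tokenized into its
   *N* − *k* + 1 overlapping k-mers (default *k* = 9). A skip-gram word
   embedding with negative sampling is trained on the k-mer corpus
   (window 4, 100 dimensions, 5 epochs, `min_count` 1), and a sequence is
   represented as the elementwise **mean of its k-mer vectors** — a dense
   100-dimensional vector regardless of sequence length.

3. **Classification and evaluation.** A random forest (100 trees, 2 candidate
   features per split, Gini impurity, unlimited depth) maps sequence vectors
   to SH labels. `ITSset_m` is evaluated by *m*-fold cross-validation in
   which every fold contains exactly one sequence of every SH; `ITSset_10` is
   first subsampled to 5 sequences per SH and gets 5-fold CV. Reported
   metrics are accuracy, support-weighted precision and recall, and the
   multi-class Matthews correlation coefficient (MCC); for two classes the
   MCC reduces to

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A bundled synthetic-barcode generator (per-species random ancestors,
Jukes–Cantor-like within-species substitutions, UNITE-style headers) lets the
whole stack run and be tested without downloading any database.

## Worked example

Simulate 20 species with 5 sequences each at a 5 % within-species
substitution rate, then cross-validate the full pipeline:

```sh
its2vec simulate --species 20 --per-species 5 --sub-rate 0.05 --seed 42 --out mid.fasta
its2vec cv --input mid.fasta -k 9 --window 4 --n-estimators 100 --max-features 2 \
           --seed 42 --report mid_report.tsv
```

which logs `cv: ITSset_5 mean accuracy 97.00%, MCC 0.970` and writes:

```
m	fold	accuracy	precision	recall	mcc
5	0	95.000000	92.500000	95.000000	0.949871
5	1	100.000000	100.000000	100.000000	1.000000
5	2	95.000000	92.500000	95.000000	0.949871
5	3	100.000000	100.000000	100.000000	1.000000
5	4	95.000000	92.500000	95.000000	0.949871
5	mean	97.000000	95.500000	97.000000	0.969923
5	std	2.738613	4.107919	2.738613	0.027457
```

Each row is one held-out fold (20 sequences, one per species); the `mean` and
`std` rows aggregate across folds (sample standard deviation). Support-
weighted recall coincides with accuracy by construction in single-label
multi-class evaluation, which is why those two columns are identical;
precision is lower because classes that are never predicted contribute zero
at their support weight. At a 1 % substitution rate the same pipeline scores
100 %; at 12 % (approaching between-species divergence in 9-mer space)
accuracy drops to 45 %.

Other subcommands: `build-dataset` (filter/cap/partition a reference FASTA,
with a stage-count report), `train-embedding` (persist the k-mer vectors in a
text key-vector format), `train` / `predict` (fit and apply the forest), and
`grid rf` / `grid embedding` (hyperparameter grids, long-format TSV). Run any
subcommand with `--help` for its options.

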