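# Methods

## Problem and model

The task is single-label, multi-class assignment of fungal ITS barcode
sequences to species hypotheses (SHs) — the species-level OTUs used by
UNITE-style reference databases. The pipeline composes three models:

1. a lexical model of a DNA sequence as the ordered set of its overlapping
   k-mers (a length-*N* sequence yields *N* − *k* + 1 tokens);
2. a distributional model of k-mers — skip-gram with negative sampling — in
   which a k-mer's vector is learned by predicting the k-mers that co-occur
   with it inside a symmetric context window, and a sequence is the mean of
   its k-mers' vectors;
3. a random-forest classifier from sequence vectors to SH labels.

The embedding is trained **unsupervised on the full corpus before any
cross-validation split**. This mirrors how such embeddings are used against
reference databases (the token vocabulary is a property of the corpus, not of
a training fold), but it does mean the representation — not the classifier —
has seen the held-out sequences; `evaluate_records` callers who need strictly
leakage-free protocols can train the embedding on any record subset they
choose and pass the model into `run_cv` explicitly.

## Skip-gram trainer

No off-the-shelf word-embedding library is part of this package's dependency
set; the trainer (`its2vec._sgns`) is a compact, numba-compiled
implementation of the canonical skip-gram objective, and its defaults are the
canonical ones:

| parameter | default | meaning |
|---|---|---|
| `k` | 9 | k-mer length; 9 is the sweet spot for ITS-scale barcodes (8–10 behave similarly, larger k fragments the vocabulary) |
| `window` | 4 | maximal context half-width; the effective window per center token is drawn uniformly from 1..window (reduced-window rule) |
| `dim` | 100 | embedding dimensionality; also the classifier's feature count |
| `epochs` | 5 | corpus passes |
| `min_count` | 1 | no vocabulary pruning — every corpus k-mer gets a vector |
| `negative_samples` | 5 | noise tokens per positive pair, drawn from unigram^0.75 |
| `alpha` / `min_alpha` | 0.025 / 1e-4 | linear learning-rate decay over tokens processed |
| `subsample` | 1e-3 | frequent-token down-sampling threshold (rarely triggers on k-mer corpora, where most tokens are near-unique) |

Numerical details: gradients are clipped via the ±6 logit cutoff; updates are
float32; input vectors are initialized uniform in (−0.5/dim, 0.5/dim) and
output (context) vectors at zero. Training is always single-threaded, so a
fixed seed gives bitwise-identical vectors; the `deterministic` flag is kept
in `EmbeddingParams` to document that contract.

Out-of-vocabulary k-mers at inference are skipped in the averaging (this
preserves the mean semantics); a sequence with no in-vocabulary k-mer, or
shorter than k, maps to the zero vector and is flagged rather than rejected,
since a classifier input must exist for every query. Tokens containing IUPAC
ambiguity letters are ordinary vocabulary entries — with `min_count=1` and an
open vocabulary there is no principled reason to special-case them.

## Reference-set construction

"Unclear taxonomy" is operationalized as: empty genus or species rank, or a
rank containing `unidentified` / `uncultured` case-insensitively (substring
match, so `uncultured_fungus` is caught). Removals are logged per reason so
the filter can be audited. Singleton SHs are dropped (a class must appear in
both a training and a validation fold), over-represented SHs are capped at 10
by uniform random selection, and the result is partitioned into m-regular
subsets. Capping cannot create singletons and singleton-dropping cannot push
an SH over the cap, so those two stages commute; the fixed order
filter → drop-singletons → cap → partition is for determinism, and the whole
pipeline is idempotent.

Class labels are dense 0-based integers assigned in sorted-SH order, so label
assignment is stable across runs and record orders.

**Seeding.** One master seed expands into named per-stage streams via
SHA-256; per-SH draws (capping, subsampling, fold assignment) are seeded by
(seed, sh_code) and applied over accession-sorted members, so the outcome for
one SH is independent of every other SH and of record order in the file.

## Cross-validation protocol

`ITSset_m` is evaluated with m-fold CV in which each fold contains exactly
one sequence of every SH — the m members of each SH are spread over the m
folds by a seeded permutation. Every class is therefore present in every
training split, and every held-out fold is a complete one-sequence-per-species
query set. The fully-capped subset (`ITSset_10`) is first subsampled to 5
sequences per SH and evaluated with 5-fold CV, keeping the largest subset's
forest training tractable. Per-fold metrics are computed on the held-out fold
only; the headline value is the across-fold mean with the sample (n−1)
standard deviation.

## Metrics

Accuracy is the fraction correct. Precision and recall are support-weighted
one-vs-rest aggregates of the binary confusion-count forms; under
single-label multi-class evaluation the support-weighted recall is
algebraically identical to accuracy (each class's recall is its correct
count over its support, and the weights are the supports), which is a useful
internal consistency check and is asserted in the tests. Micro-averaging
would have forced precision to equal accuracy as well; the support-weighted
convention is chosen precisely because it keeps precision informative
(classes never predicted contribute 0 at their weight). MCC is the
multi-class generalization computed from the full confusion matrix and
reduces to the binary formula for two classes; a degenerate denominator (a
zero row or column factor) yields MCC = 0.

## Random forest

Standard Gini / bootstrap / unlimited-depth forest (scikit-learn).
`max_features` is an **absolute count** of candidate features per split, not
a fraction — the tuning grid 2..10 against a 100-dimensional embedding only
makes sense as counts, with √100 = 10 as the conventional default ceiling.
The tuned operating point (2 features, 100 trees) favors highly decorrelated
trees, which suits many-class problems with few training rows per class. No
class weighting is applied: the m-regular subsets are balanced by
construction.

## Synthetic data generator

The generator emulates the *structure* that makes SH classification
well-posed: per-species ancestor sequences drawn i.i.d. over {A,C,G,T}
(configurable GC content; lengths uniform on 450–900, bracketing the ~700 bp
typical of ITS barcodes), with members derived by i.i.d. point substitutions
at a configurable rate. Substitutions resample uniformly (Jukes–Cantor-like),
so the effective per-base change rate is 0.75× the nominal rate — the tests'
binomial oracles account for this. A fraction of species can be labeled
`g__unidentified`/`s__uncultured` to exercise the filter, and an optional
two-level mode derives species from genus ancestors at a stated divergence
for harder benchmarks.

What it does **not** emulate: ITS secondary structure and conserved 5.8S
blocks, length/GC heterogeneity across clades, chimeras, sequencing error
profiles, or ragged amplicon boundaries. Independent random ancestors share
almost no 9-mers, so species are near-orthogonal in token space; passing the
recovery tests therefore demonstrates that the pipeline's machinery is
correct and that accuracy degrades as within-species variation approaches
between-species divergence — it does not predict absolute accuracy on real
reference databases, where related species share most of their sequence.

## Problem sizes

The bundled tests and the acceptance script run at desk scale by design:
recovery tests use 50 species × 5 sequences (lengths 450–900, the default
generator conditions), other tests use 5–20 species with shorter sequences,
and the acceptance script's embedding measurement uses a 10-sequence corpus.
These sizes exercise every code path; database-scale runs (10^5 sequences,
10^4 classes) use the same entry points unchanged.

## Known limitations

- The full-corpus embedding protocol leaks unlabeled test sequences into the
  representation (discussed above); the strictly clean alternative is
  available but not the default.
- The FASTA header dialect registry ships two layouts
  (`accession|SH|lineage` and the four-field `sh_general` style); real UNITE
  releases drift, and new layouts must be registered by the caller.
- MCC = 0 for degenerate confusion matrices is a convention, not a limit.
- The skip-gram trainer is single-threaded; at database scale it trades
  wall-clock time for exact reproducibility.
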