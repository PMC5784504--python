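# Methods

## Problem

Given entity-annotated biomedical text (mutations, genes, drugs, diseases,
cell lines), decide which (mutation, gene) and (mutation, drug) pairs stand
in a real relation — a mutation belonging to a gene, or predicting response
or resistance to a drug.  The package works at two granularities:

* **document level** — with *m* unique mutations and *n* unique partner
  entities in a document, all *m × n* pairs are candidates; a candidate is
  true if the relation is asserted anywhere in the document (the
  any-sentence rule);
* **sentence level** — a candidate is a (mutation, partner) mention pair
  co-occurring in one sentence, true iff that sentence expresses the
  relation.

Mutation-gene relations are 1:1 (one mutation belongs to one gene) while
mutation-drug relations are frequently 1:n, which is the structural reason
the drug task is harder — frequency/distance features that reward the
nearest or most frequent partner mislead the classifier when several
partners are genuinely related.

## Background-knowledge features from a co-occurrence index

A local inverted index over a background corpus stands in for a
PubMed-scale biomedical entity search engine.  Retrieval is boolean
(conjunction of required terms, optional OR group); ranking of the
target-kind entities found in the retrieved documents uses a transparent
tf-idf-style score

```
score(e) = Σ_{d ∈ docs} count(d, e) · log(1 + N / df(e))
```

with `N` the corpus size and `df` the entity's document frequency.  Only
relative magnitudes matter downstream, so the particular idf dampening is
not critical; this form is monotone in co-occurrence count and discounts
ubiquitous entities.

Four query strategies convert the index into features for a candidate pair,
using the entities around the mutation as context.  Entities of the *same
kind as the target* are excluded from the context first (a second drug in
the sentence distorts a mutation-drug query rather than informing it), and
the mutation itself is dropped from its own context:

| feature | query |
|---|---|
| BSSM | mutation only |
| BSSA | mutation AND every context entity |
| BSSO | mutation required; context entities as an OR group |
| BSSAO | mean over context entities c of (mutation AND c) |

BSSAO uses the mean rather than the sum so its scale does not grow with
context size.  With an empty context, BSSA and BSSO degenerate to BSSM and
BSSAO is 0.  Sentence-level features use the sentence's mentions as
context; document-level features use all non-mutation document mentions.
Other mutations are excluded from the context at both levels: a conjunctive
query containing two rare mutations almost always retrieves nothing and
would zero the multi-entity strategies.

## Distance/frequency features and the residue filter

Per document-level candidate: NTDS (number of sentences where mutation and
partner co-occur), TDFS (partner mention count), ODFS (mention count of the
most frequent same-kind rival), and DMCS (binary: some mutation mention's
nearest same-kind mention — span-midpoint distance, ties to the left — is
the partner, in the same sentence).  NTDS is counted at sentence
granularity; DMCS is evaluated per candidate so that candidates sharing a
mutation can differ.

SEQ_Filter is the wild-type residue check: mutation `XnY` is compatible
with a gene only if the gene's protein carries residue `X` at 1-based
position `n`.  It applies to amino-acid-level substitutions only; DNA-level
mentions (`c.1799T>A`) are passed through unparsed and excluded from
gene-pair datasets.  Mutation mentions are normalized to one-letter HGVS
protein form (``Val600Glu``/``p.V600E`` → ``V600E``) before any of this.

## Distant supervision

Sentence datasets are labelled by joining a curated relation table to the
corpus: a sentence is positive when it contains a co-occurring pair the
table asserts for that document (gene pairs must additionally pass
SEQ_Filter); negative when it contains a co-occurring pair absent from the
table and the known-relation set (gene pairs must additionally *fail*
SEQ_Filter — an unconfirmed pair that passes the residue check is too risky
as a negative and is skipped).  A sentence enters each labelled set at most
once, even with several qualifying pairs, to avoid duplicated training
signal.

## Classifiers

**Document level.** scikit-learn CART decision tree and random forest with
library-default hyper-parameters, seeded.  Candidate sets are heavily
imbalanced, so negatives are down-sampled to the positive count; evaluation
is stratified 10-fold cross-validation with *both* the training and test
portion of each fold balanced (folds are assigned first, then balanced —
stratification keeps both classes present in every fold of small sets).

**Sentence level.** A convolutional network in the Kim
sentence-classification style, implemented directly in numpy (forward,
backprop, Adam); the model is small enough that a framework would outweigh
the computation.  Per token: 300-d word embedding ⊕ 10-d entity-type
embedding (target mutation / target gene / target drug / other-kind /
plain) ⊕ two 10-d position embeddings indexed by the clipped relative
offset from each target mention.  Convolutions of widths 3/4/5 with 100
maps each, ReLU, max-over-time pooling; the pooled 300-d vector is
concatenated with the standardized scalar block (the four search scores,
or any ordered feature list — the fusion point is after pooling, before
the affine output layer), dropout 0.5, affine + softmax.  Entity mentions
are collapsed to single tokens before encoding so the type and position
channels stay token-aligned; over-long sentences are truncated to a window
centred between the two targets.

Defaults kept at the Kim conventions: widths 3/4/5, 100 maps, dropout keep
0.5, batch 50.  Choices the architecture leaves open are config fields with
logged defaults: optimizer Adam at 1e-3 (SGD available), max sentence
length 30 tokens (the synthetic sentences are short; raise it for real
abstracts), epoch count per run (3–6 in the shipped tests), best-epoch
selection by dev-set F1.  Scalar standardization uses train-split moments
only, which also makes predictions invariant to uniform translation of the
scalar inputs.  Word embeddings initialize from pre-trained vectors where
the vocabulary overlaps, uniform ±0.25 elsewhere; everything is fine-tuned.
All randomness flows from the config seed; training is reproducible
run-to-run on a single compute thread.

**Word vectors.** Skip-gram with negative sampling (5 negatives,
unigram^0.75 noise, window 5, linear learning-rate decay), implemented in
numpy, with multi-word entity phrases merged to single tokens
(``non-small cell lung cancer`` → ``non-small_cell_lung_cancer``) and
words of corpus frequency < 5 dropped.  Readers/writers for the word2vec
text and binary interchange formats are included.

## Evaluation protocols

Precision/recall/F1 with zero-division defined as 0 so fold averaging is
total.  Document-level models use balanced 10-fold CV; the network uses
repeated random sub-sampling (per repetition: a balanced held-out test
draw, balanced training on the remainder, a fresh model), since re-training
a network ten times per configuration is the protocol's cost driver.  Test
draws are independent across repetitions.  The no-learning baseline
classifies every co-occurring candidate positive: recall 1 by construction,
F1 exactly 2/3 on balanced sets — the floor any trained model must clear.
Relation-table export emits predicted-positive sentence pairs sorted by
probability (dedup keeps the best row per (document, mutation, partner)
triple), and gold-list comparison partitions a gold set into found /
never-co-occurring-at-sentence-level / missed-otherwise.

## Synthetic study conditions

The generator plants the structure every stage assumes.  Defaults: 15
genes, 15 drugs, 30 mutations, 120 documents × 5 sentences, positive rate
0.45, SEQ_Filter violation rate 0.9 among decoy gene pairs (a random
residue matches by chance only 1/20, so most erroneous pairings fail the
check; the engineered remainder models plausible-but-wrong pairings),
co-occurrence boost 4 (true pairs appear in ~5× more background documents
than decoy pairs), template noise 0.1 (that fraction of positives is
phrased neutrally — the label noise distant supervision actually has,
and the cases only the search-score features can rescue).

Proteins are uniform random 200–400-residue sequences; each mutation's
wild type is read off its gene's sequence, so every true pair passes the
residue check by construction.  Positive sentences use trigger templates
("conferred resistance to", "activating mutation of", …) and carry
distractor entities (an unrelated gene, a second drug, a disease) so
bag-of-entities evidence is insufficient; negatives co-mention pairs with
neutral templates.  Document-level truth follows from sentence plants by
the any-sentence rule.

What the generator does **not** emulate: real lexical/syntactic diversity
(a closed template family), discourse-level relations spanning sentences,
NER errors, and realistic entity frequency distributions.  Passing the
shipped benchmarks therefore demonstrates that the pipeline's machinery is
correct and that its features carry the intended signal under controlled
conditions — not that these F1 levels transfer to PubMed-scale text.

## Benchmark sizes and expected numbers

The shipped tests and `scripts/acceptance.py` run at desk scale: the
document-level benchmark uses the default corpus (~430 balanced candidates
pooled over both tasks) with 5 seeds × 10 folds; the sentence-level
benchmark uses a 400-document corpus (~900 labelled sentences per task),
3–5 sub-sampling repetitions with 100+100 or 50+50 held-out sentences, and
3 training epochs.  Under those conditions the random forest reaches mean
F1 ≈ 0.98–0.99 (baseline features alone ≈ 0.87), the network ≈ 0.94–0.96
on both tasks, permuted labels fall to ≈ 0.5, and both models clear the
2/3 co-occurrence floor — the same ordering and directions (scores help,
the drug task is harder at the document level, pre-trained embeddings are
roughly neutral on synthetic text) that motivate the method.

## Known limitations

* The index's ranking formula is a stand-in; absolute scores are not
  comparable to any external engine's.
* Only protein substitution nomenclature is parsed; indels, frameshifts
  and DNA/RNA-level HGVS are out of scope.
* The rule-based sentence splitter is deterministic but simplistic
  (punctuation + capitalization with an abbreviation list).
* The network is CPU-bound numpy; it is sized for datasets of thousands,
  not millions, of sentences.
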