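# Methods

## Problem and model

The package treats biocuration triage as binary probabilistic
classification of articles. An article is "considered" (label 1) when
curators judged it to contain at least one gene with statistically
supported relevance to the phenotype; otherwise "not considered"
(label 0). Three classifier families — logistic regression, random
forests, and a multilayer perceptron — map a sparse feature vector per
article to a probability of being considered. The families are treated
symmetrically behind one contract (`train` / `predict_proba`), so the
evaluation layer is classifier-blind.

The scientific content is less in the classifiers than in (a) the
annotation-derived feature sets and (b) the gene-centric operating
point. Both are described below.

## Feature generation

All co-occurrence features are scoped to sentences. Sentence
segmentation is deliberately simple and deterministic: the title is one
sentence; the abstract splits at sentence-final punctuation followed by
whitespace and an uppercase letter or digit (so "e.g. value" stays
intact). A fixed rule keeps feature goldens stable across runs; no
trained sentence model is involved.

Per-article feature sets (keys are plain strings; matrices are sparse
nonnegative counts or indicators over a vocabulary learned on training
articles only and frozen thereafter — unseen test keys are dropped):

* **BOW** — lowercased unigrams, split on non-alphanumerics, tokens of
  length 1 and pure numbers dropped, standard English stopwords
  (articles, prepositions, pronouns included) removed, suffixed by zone
  (`tnfTITLE`, `tnfABSTRACT`). Frequencies.
* **MeSH** — one indicator per heading (`Premature Birth-No`, by the
  major-topic flag) and one per heading–subheading pair
  (`Premature Birth-Genetics-Yes`). The heading indicator is emitted
  whether or not qualifiers are present.
* **GeneSubjectPredicate** — counts of predications whose subject and
  object semantic groups are (GENE, DISO) or (DISO, GENE), keyed as
  `GENE-ASSOCIATED_WITH-DISO`. Keys are (group, predicate, group)
  triples, not CUI-level triples: CUI-level keys would number in the
  thousands, while group-level keys stay in the dozens and generalise
  across genes.
* **GeneSignificance** — two per-sentence key families: for each
  Quantitative Concept (semtype `qnco`), `cui-G1|G0` by gene-concept
  co-occurrence in that sentence; for each configured significance CUI,
  `cui-G1|G0-N1|N0`, where N1 marks a negation CUI ("Negative",
  "Negation", "Unchanged") in the same sentence. The negation bit keeps
  "was not statistically significant" sentences from counting as
  positive evidence. A concept that is both significant and
  quantitative emits both key families.
* **GeneCount** — a fixed six-key numeric vocabulary from PubTator GENE
  mentions: unique gene identifiers in the title and in the abstract,
  the maximum mention count of any single gene in each zone, and the
  total mention count in each zone. The totals are this package's
  completion of a set whose canonical composition is underdetermined;
  they are documented here as a design choice.
* **SpeciesCheck** — per-sentence `cui-G1|G0` keys for every LIVB-group
  concept (the reference databases only accept human studies, so human
  vs. model-organism context is informative).
* **SemtypeCount** — per-sentence semantic-type *presence* (not mention
  count) with the same G1/G0 co-occurrence bit, accumulated over
  sentences. Typing rather than concept identity keeps this set small
  and generalisable.

"Gene presence" in a sentence means a MetaMap concept in the GENE
semantic group; a configuration switch widens this to the union with
PubTator gene mentions. PubTator mentions otherwise drive only
GeneCount.

Combination sets are exact column-wise concatenations with
member-prefixed keys: S1 = MeSH + GeneSignificance + SemtypeCount +
GeneSubjectPredicate + SpeciesCheck + GeneCount; S2 = S1 − MeSH;
S3 = S2 − GeneCount; S4 = S1 − GeneSubjectPredicate; S5 = S1 −
GeneCount; S6 = S1 − GeneSubjectPredicate − GeneCount. Concatenation is
tested as exact matrix equality against the member blocks.

The semantic-type → semantic-group table, the significance CUI list and
the negation CUI list ship as editable plain-text configuration. The
packaged CUI lists are deliberately short starting points: the canonical
lists are site-specific and should be grown from the UMLS Metathesaurus
for the phenotype at hand.

Vocabulary order is first-seen order over the fitting corpus: it is
deterministic for a fixed corpus and monotone under corpus growth, both
of which are property-tested.

## Offsets and format dialects

PubTator and MetaMap offsets are interpreted as 0-based, end-exclusive
positions over `title + " " + abstract` (the common dialect) and mapped
to sentences at ingest; a span crossing a sentence boundary belongs to
the sentence containing its start. The MetaMap reader accepts MMI-style
fielded lines; the SemRep reader accepts pipe-fielded predication lines
with `ti.k` / `ab.k` utterance ids. Both normalise into the same domain
types, so other dialects only need a reader, not new feature code.

The annotation store is a single-file SQLite database with the same
logical schema a server deployment would use (articles, sentences,
mesh, entities, concepts, predications, curated_genes). The benefit
claimed for the store is queryability, not the engine; tests require a
zero-service environment, and round-trip identity is property-tested.

## Training protocol

* **Split**: stratified 80/20 by label, per-class train count
  `round(0.8 · class size)`, seeded. Stratification mirrors the
  accepted/rejected ratio of the reference database in both partitions.
* **Class imbalance**: default is inverse-frequency class weights
  `w_c = N / (2 N_c)` (weighted class totals then balance exactly).
  Under-sampling, over-sampling (every original minority row kept) and
  a combined variant (majority down to the geometric mean of the class
  sizes, minority up to match) are available; on the reference corpora
  the strategies performed comparably and weights are the cheapest.
  The MLP implementation supports neither class nor sample weights, so
  for that family class weighting is realised by seeded weighted
  oversampling of training rows to the same effective ratio.
* **Hyper-parameters**: randomized search (default 1000 settings,
  3-fold stratified CV, scored by AUROC) over per-family distributions;
  finite grids smaller than the iteration budget are enumerated
  exhaustively with a warning. The search is run once on the
  SemtypeCount features and the winner reused across feature sets — the
  small, generic set makes tuning cheap and transfers adequately. The
  tuned values from the reference corpora ship as the `reference` preset:
  logistic `{max_iter 155, C 1.0, solver sag}`; random forest
  `{max_features 0.8, min_samples_split 3, min_impurity_decrease
  0.0066423, min_samples_leaf 4, criterion entropy}`; neural net
  `{alpha 0.0029, learning_rate_init 0.0139, hidden (60, 160),
  schedule invscaling}`. Two readings of the published hidden-layer
  size were possible (one layer of 60160 units vs. two of 60 and 160);
  the two-layer reading is adopted — a 60160-unit layer is implausible
  for corpora of ~2000 documents. The preset pins `solver="sgd"` for
  the MLP because a learning-rate schedule is meaningful only under
  SGD.

## Evaluation

Let TP/FP/TN/FN be the article-level confusion at threshold t
(predicted positive iff probability ≥ t). Reported metrics: recall,
precision, F1, and the gene-centric trio — gene recall
`|∪ genes of TP articles| / |∪ genes of TP∪FN articles|`, workload
saving `(TN+FN)/N`, and F-gene (harmonic mean of gene recall and
precision). Conventions: precision is 0 when nothing is predicted
positive; an empty union of curated genes is an error (it indicates a
bookkeeping bug, since threshold 0 must recover every gene), never a
0/0.

**Operating point.** Candidate thresholds are the distinct predicted
probabilities, scanned descending; the selected threshold is the
largest with gene recall ≥ 0.95. Because gene recall is non-decreasing
as the threshold drops, this maximises workload saving subject to the
constraint. The discrete scan typically overshoots the target slightly
(emitted gene recalls of 0.95–0.97 are normal). The rule is verified
against exhaustive scan on every random instance in the tests.

**Ranking metrics.** AUROC is computed in the Mann–Whitney rank form
(midranks for ties) and must agree with the trapezoidal area under the
empirical ROC curve to 1e-12 — two genuinely independent
implementations, both kept. AUCPR uses the continuous interpolated
estimator: between consecutive operating points TP and FP are
interpolated linearly and precision is integrated over recall in closed
form, matching the estimator family of the PRROC R package rather than
the step-function average precision. DeLong's paired test uses the
placement-value formulation with midranks; it is cross-checked in the
tests against the pROC R implementation and its p-values are verified
uniform under a permuted-label null. AUCPR confidence intervals come
from stratified 5-fold cross-validation, `mean ± 1.96·sd/√k` (a
t-quantile variant is available by flag).

## Synthetic corpus generator

The generator exists so that every stage — parsers included — is
testable without network access. Per article, a label is assigned by
exact stratification (`round(prevalence · n)` positives); conditional
on a positive label each of six channels plants its characteristic
evidence with probability equal to its strength: a disease MeSH heading
with a major "genetics" qualifier; a GENE–ASSOCIATED_WITH–DISO
predication; a significance CUI co-occurring with a gene concept; a
human LIVB concept co-occurring with a gene; a Genetic Function semtype
with a gene; elevated PubTator gene-mention counts. Negative articles
receive, at the same channel strength, the contrasting evidence
(negated-significance sentences, human or semtype concepts in
gene-free sentences), plus the same label-independent background
annotations both classes get. At strength 0 the two classes are
distributionally identical, so feature matrices carry no label
information — the null control.

Curated gene sets for positives are drawn Zipf-weighted from a
120-symbol vocabulary (union with the genes planted in that article's
channels), so genes recur across articles and gene recall genuinely
differs from article recall.

Default conditions mirror the preeclampsia reference corpus where a
value was published (prevalence 0.337) and otherwise use one fixed
realistic choice: 3–7 abstract sentences, 1–4 curated genes per
positive, channel strengths 0.9 for the strong-signal condition.

What the generator does *not* emulate: real lexical statistics (text is
template filler with planted surface forms), annotation-tool errors
(false or missed entity mentions), topic drift, or correlated channel
failures. Passing tests therefore demonstrate that the pipeline's
machinery — parsing, feature algebra, thresholding, metrics — is
correct and that the feature sets recover planted signal; they do not
certify classifier performance on real literature, which depends on
annotation quality and corpus heterogeneity.

With six independent evidence channels at strength 0.9 the synthetic
classes are nearly separable, so test AUROC saturates near 1.0; the
informative quantities on the strong-signal condition are the gene
recall (≈0.95, the constraint) and the workload saving (well above the
0.3 floor at prevalence 0.337).

## Problem sizes and runtime choices

The test suite and the reproduction script run the strong-signal
condition at n = 2000 articles and the null control at 10 replicates of
n = 400 — sizes chosen to put Monte-Carlo noise well inside the asserted
margins while keeping a full run in seconds on one core. Oracle suites
use 500–1000 random small instances. The DeLong null check uses 500
simulations at n = 200 against a Kolmogorov–Smirnov test at α = 0.01.

## Known limitations

* File-based ingestion only: no live PubMed/PubTator clients, and
  MetaMap/SemRep are consumed as output files, never executed.
* One reader dialect per annotation source; other MetaMap/SemRep output
  modes need a small reader addition.
* Unigram bag-of-words only; no TF-IDF, n-grams or embeddings — the
  baseline is deliberately the plain one the annotation-derived sets
  are compared against.
* No probability calibration; the threshold rule consumes ranks, not
  calibrated probabilities, so this is benign for the operating point
  but raw probabilities should not be read as frequencies.
* The packaged significance/negation CUI lists and the semantic-group
  table are starting points, not authoritative UMLS releases.
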