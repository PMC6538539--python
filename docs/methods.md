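# Methods

## Problem and data model

The package classifies the relation expressed between two biomedical entity
mentions in one sentence. Its input is not raw text but the tabular output
of a rule-based entity/relation extractor: a *feature record* with 15 fields
(identifiers; both entity mentions with semantic type and local context;
negation and tense of the relation; the relation verb; a reference relation
word; a context level; the verb phrase; the raw sentence). The label is
either coarse — *DirectedLink* when one entity directly causes an effect on
the other through the relation verb, *UndirectedLink* when they are only
indirectly associated — or fine-grained over ten classes, where causal
relations split into Cause/Increase/Decrease with Positive/Negative effect
direction (Increase/Decrease subclasses are signalled by an effect *trigger
word* such as "activation" or "reduction"), associations split into
Positive/Negative Correlation, and the two coarse classes remain as
fallbacks. The fine-grained class list is configurable because the taxonomy
itself enumerates eight leaf types; the default ten-class list appends the
two coarse fallbacks.

Records travel as UTF-8 TSV with a header. `"NA"` is the single missing
sentinel (trailing semicolons, an extractor artifact, are stripped on read).
Cleaning drops records whose entities or relation verb are empty/`NA` or
whose sentence is empty; the rules are explicit and configurable because
upstream discarding criteria are conventionally unstated.

## Feature groups

Five fixed field orderings are concatenated (single-space separator, `NA`
fields skipped) into one classifier input text, truncated to 256
*characters* after concatenation. The truncation unit is characters, not
tokens, matching the stated length cap of the input text; a token cap can be
imposed separately through the embedder's `fixed_len`. Skipping `NA` rather
than emitting it keeps sentinel tokens out of the embedding vocabulary.

## The convolutional classifier

Texts are lowercased and whitespace-tokenized (hyphens retained, so
`ubiquinone-9` is one token), then embedded with pre-trained word vectors
into an n×k matrix, zero-padded/truncated to a fixed n (default 64 tokens,
≈ 256 characters at ~4 characters/token). Out-of-vocabulary tokens map, by
default, to a per-token seeded uniform [−0.25, 0.25] vector cached for the
run; an all-zeros policy is available. Embeddings are static by default —
whether to fine-tune them is genuinely open, so a `trainable_embeddings`
flag exposes the alternative (gradients are scatter-added into the lookup
table; the padding row stays zero).

The architecture is the standard multi-width sentence-classification CNN:
three *parallel* convolution branches with region sizes 3/4/5 (not a stack
of three sequential layers — the parallel reading follows the architecture
family this design descends from), 300 feature maps each, ReLU by default
(leaky ReLU, sigmoid, tanh available), global max-over-time pooling, dropout
p = 0.5 on the pooled concatenation (hence "pooling dropout"; embeddings are
not dropped), and a softmax output layer trained with categorical
cross-entropy. The l2 term (default s = 10⁻⁴) is implemented as a weight
*penalty* on the softmax layer; a max-norm constraint is a recognized
alternative reading of "l2 constraint" and is intentionally out of the
default path. Optimizers: Adadelta (default, lr 1.0, ρ = 0.95, ε = 10⁻⁶),
AdaMax (lr 0.002, β₁ = 0.9, β₂ = 0.999) and plain SGD (lr 0.1), all
implemented alongside the backward pass in numpy. Mini-batch size 32, up to
500 epochs.

Early stopping watches validation loss with patience 10 (both configurable)
and restores the parameters of the best epoch; when no explicit validation
set is passed, a stratified 10 % split of the training data is held out.
Given equal parameters, data and seed, two fits produce identical histories
(one `numpy` generator drives initialization, shuffling and dropout), and
prediction is deterministic because dropout is inactive outside training.

Degenerate inputs: a single-class training set raises; a filter width
exceeding the fixed token length raises a shape error; softmax logits are
max-shifted before exponentiation, and the cross-entropy adds 10⁻¹² inside
the log.

## Baselines

Six conventional learners — linear-kernel SVM, SGD-trained linear model,
multinomial naive Bayes, logistic regression, random forest, k-nearest
neighbours — consume the *same group texts* as the CNN (how they were fed in
the original protocol is unstated; group texts keep the comparison on one
input), vectorized as TF-IDF unigrams with the package tokenizer (raw counts
and n-grams are options). Hyperparameters default to scikit-learn's
conventions; no search is run over baselines.

## Evaluation protocol

Stratified 5-fold cross-validation. Class imbalance is handled in the
*data*, not the loss: by default each training split is undersampled
(without replacement, seeded per fold) to its smallest class count.
Oversampling was deliberately not chosen as the default because it
duplicates minority texts and inflates apparent fold variance; it remains a
policy option in the design. Metrics are accuracy plus precision/recall/F1
averaged over classes with *equal* weights ("weighted (equally)
macro-average" is read as exactly that); support-weighted averaging is
computed side by side since the phrase admits both readings. A class with no
predicted (or no true) positives scores 0 for the undefined quantity, with a
logged warning — necessary in the fine-grained low-recall regime. Fold
results aggregate as Max/Ave/Min per metric. Micro-averaging and
significance testing are out of scope.

## Hyperparameter sweeps and search

One-dimensional sweeps cover dropout 0.1–0.9 (step 0.1), l2 ∈
{10⁻³…10⁻⁶}, feature maps ∈ {50, 100, 200, 400, 600, 1000} and batch size ∈
{32, 48, 64, 96, 128}, each trial differing from the base configuration in
exactly one value and sharing its seed, so sweep results are order-invariant.
The optimization space is learning rate {10⁻⁵, 10⁻³, 10⁻¹} × l2
{10⁻⁵, 10⁻³, 10⁻¹} × activation {ReLU, leaky ReLU, sigmoid, tanh} with the
AdaMax updater: grid search enumerates all 36 points; random search draws a
declared number of seeded uniform samples per dimension, with replacement
(the sampler is otherwise unspecified in the literature this follows).
Selection minimizes validation loss (the quantity the sweeps plot);
selecting on F1 is possible by reading the per-trial metrics. Trials are
appended to a JSON-lines log as they finish, so an interrupted search
resumes by skipping already-logged trials; every best trial is reproducible
from its recorded assignment and seed.

## Synthetic corpora

The labeled corpora this schema was designed around are not public, so the
generator builds corpora with the *structural* properties the pipeline
assumes, making every stage testable: four pairwise-disjoint verb families
(causal, associative, and one generic family per coarse fallback class), two
trigger families (increase/decrease), and a per-class signature
(verb family, trigger family or none, negation flag) that is unique across
the ten classes. With probability `signal` a record's class-identifying
features are drawn from its class signature, otherwise uniformly from the
union of lexicons; at `signal=1` a simple lookup rule (shipped as
`lexicon_lookup_rule`) classifies every record exactly, at `signal=0`
features are label-independent and any classifier sits at chance. The
`Negative*` classes are marked by the negation flag; note this is a modeling
convenience — in the source taxonomy "Negative" denotes a declining effect
direction rather than grammatical negation, and the flag is the generator's
structural stand-in for that distinction. Entity names are synthesized from
seeded syllables with hyphenated-numeral variants ("compound-9" style)
specifically to exercise tokenization. Sentences are templated
(`<entity_l> <verb> <trigger?> <entity_r> in <context>`); the generator does
not attempt linguistic realism, extraction noise, or real sentence-length
distributions — so green tests certify the pipeline's mechanics and
learnability behaviour, not performance on real abstracts.

The benchmark suite writes four fixtures: binary balanced (1 000 records,
50/50), binary imbalanced (1 000, 80/20 — the qualitative skew of real
corpora in this task), fine-grained (1 500, mildly skewed over ten classes)
and a 20-record smoke set, all at `signal=0.9` (smoke at 1.0): high coupling
with a noise floor, so models learn well but folds still vary.

## Problem sizes in the shipped analyses

The acceptance script and end-to-end tests run the network in a reduced
configuration — 50 feature maps, 32-token inputs, 50-dimensional seeded
random embeddings, 20–30 epochs, corpora of 200–2 000 records — chosen as
the smallest sizes at which the studied effects (learnability at the signal
extremes, fold spread, search accounting) are stable across seeds while the
full report recomputes in minutes on one CPU. The defaults on the estimator
itself remain the full-size architecture (300 maps, 200-dimensional vectors,
up to 500 epochs).

## Known limitations

- The numpy implementation is single-threaded BLAS-bound; it is meant for
  corpora of thousands, not millions, of records.
- Random search samples with replacement, so its trials are not guaranteed
  distinct.
- The grid-search tie-break (first minimum in enumeration order) matters
  only for exactly equal losses, which occur in practice only with fully
  saturated models.
- Weighted-by-support and equal-weight averaging coincide on balanced data;
  reports state which averaging they used.
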