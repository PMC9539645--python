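# Methods

## Model overview

`resdict` operationalizes resilience measurement in forum text as a
pipeline of four stages — preprocessing, two-layer ensemble NMF,
human-coded indicator annotation, and subsumption-taxonomy/dictionary
assembly. The statistical core is the two-layer factorization:

- Layer 1: for each quarterly window q, the nonnegative TF-IDF matrix
  A_q (n_q posts × m terms) is factorized A_q ≈ W_q H_q with k base
  topics. Rows of H_q are topic-term distributions; columns of W_q are
  per-post memberships.
- Layer 2: the stacked matrix B = [H_1; …; H_Q] ((Q·k) × m) is
  factorized B ≈ W′ H′ with k′ ensemble topics. A row of W′ says how a
  base topic decomposes over ensemble topics; a row of H′ is an
  ensemble topic's term distribution.
- Document projection: C stacks the W_q block-diagonally (a post lives
  in exactly one window, so its row is zero outside its own window's k
  columns), and D = C W′ gives every retained post a nonnegative
  membership over ensemble topics. The product C W′ is the unique
  dimensionally consistent projection given W′ of shape (Q·k) × k′.

Assumptions: topics are additive mixtures of nonnegative term weights
(the NMF premise); a quarter is a meaningful topical unit; a post's
dominant ensemble topic is a sufficient basis for indicator annotation;
indicator co-realization observed through dominant topics is evidence
of conceptual subsumption.

## Normalization conventions

After every NMF fit, each row of H (and H′) is scaled to unit sum with
the inverse scaling folded into the matching column of W (W H is
unchanged). Consequences: term weights are comparable across topics
(each topic's weights total 1, the convention the acceptance script
verifies), and windows contribute to B on a common scale regardless of
their TF-IDF mass. Rows with zero mass — which do not arise in
practice — are left untouched and logged.

Topic weights in the dictionary are the share of summed dominant-topic
membership mass per topic, expressed in percent; by construction the
weights over all topics total 100. This is the "relative importance"
reading of an average-topic-weight statistic: the alternative (a plain
per-post mean weight) does not produce a distribution over topics and
would not sum meaningfully.

## Numerical choices

- NMF solver: multiplicative updates under the Frobenius objective,
  eps = 1e-10 in denominators, iteration cap 500, stop when the
  per-sweep improvement relative to the initial error drops below 1e-6.
  The update rule guarantees a non-increasing error trace, which tests
  assert on the logged traces.
- Initialization: nonnegative double SVD with zero entries filled by
  small seeded uniform noise (the "ar" variant), so fits are both
  seed-deterministic and free of the zero-locking that plain NNDSVD
  causes under multiplicative updates.
- TF-IDF: raw term counts × smoothed idf ln((1+n)/(1+df)) + 1 with L2
  row normalization (the scikit-learn convention), idf computed within
  each window; the global vocabulary is the lexicographically sorted
  union over windows, so per-window matrices are column-aligned for
  stacking and rebuilds are bit-identical.
- Ties: top-term ranking breaks ties lexicographically; top-post
  ranking keeps corpus order; the dominant-topic argmax takes the
  lowest index and logs the tie; the taxonomy's parent choice among
  multiple subsumers takes the smallest post set (most specific
  subsumer), then name order.
- Degenerate inputs: empty corpora, empty windows, all-zero membership
  rows, k outside 1..min(n, m), non-finite matrix entries and
  unparseable timestamps are rejected with the offending window/post
  named; an all-zero D row yields a sentinel "no topic" annotation that
  stays in prevalence denominators but never in numerators.

## Word embedding

Coherence scoring and synonym expansion use a count-based embedding:
co-occurrence counts within a symmetric 5-token window → positive PMI →
truncated SVD (vectors U·√S, 100 dimensions by default, capped below
the vocabulary size), min term count 5. A count-based model was chosen
over a stochastically trained predictive one so that repeated pipeline
runs are bit-identical; on bag-of-words corpora of this size the two
families rank near-neighbours similarly. Neighbours are distributional,
not curated: antonym-like terms that share contexts can and do appear,
and are deliberately not filtered.

Topic coherence is the mean pairwise cosine similarity over a topic's
top-10 embeddable terms (out-of-vocabulary terms are skipped and
logged; fewer than two embeddable terms score 0 with a warning); the
mean over topics is the model-selection criterion, ties going to the
smaller k′.

## Parameter defaults

| Parameter | Default | Meaning |
|---|---|---|
| min_terms | 5 | posts with fewer lemmas are removed |
| k | 10 | base topics per quarterly window |
| k′ range | 10–20 | ensemble-topic candidates scored by coherence |
| N (mapping) | 15 | top terms shown to coders per topic |
| N (coherence) | 10 | top terms entering the coherence score |
| M | 20 | top posts shown to coders per topic |
| embedding | 100 dim, window 5, min count 5 | PPMI-SVD training |
| synonyms | 5 | nearest neighbours per dictionary term |
| subsumption | strict | exact subset containment; thresholded mode default t = 0.8 |

The `<5 terms` removal rule is applied strictly (`count < min_terms`
removed); the threshold is exposed in configuration.

## Subsumption taxonomy

x is an ancestor candidate of y iff containment(y in x) =
|posts(y) ∩ posts(x)| / |posts(y)| ≥ t and the reverse containment is
strictly smaller; strict mode fixes t = 1 (exact subset). The strict
relation is a strict partial order, so the output is always a forest;
the thresholded mode re-checks acyclicity and raises on the offending
pair. Equal post sets yield no edge (logged). Strict subsumption is
fragile on large noisy corpora — a single counterexample post breaks an
edge — which is why the thresholded Sanderson–Croft-style mode exists;
strict remains the default because it is the method's literal rule.

## Synthetic data: what it does and does not show

The generator plants: disjoint sparse topic supports (geometric
within-topic term weights), per-window topic frequencies (Dirichlet
draws), a nested topic → indicator design (social_capital topics ⊂
belonging topics, adaptive_capacity ⊂ learning, self_efficacy
disjoint), synonym pairs emitted adjacently in a background term
region, and an exact count of under-length posts. Pseudo-words pass
the linguistic stages unchanged; a 20-post hand-written English fixture
covers the lemmatizer/tagger path in tests.

Passing recovery tests on this corpus shows the pipeline's machinery is
correct — factorization recovers well-separated topics, projection and
annotation preserve planted proportions, subsumption recovers planted
nesting. It does not show that real forum posts have well-separated
topics, that dominant-topic annotation captures a post's meaning, or
that human coding is reliable; those are substantive assumptions of the
method, not properties the simulation can establish.

Problem sizes in the test and acceptance runs (4 quarterly windows,
500–2,000 posts per window, 400-term vocabulary, 5–6 topics) are the
package's desk-scale defaults: large enough that binomial noise in
prevalence stays under the tested 3-percentage-point band, small enough
to iterate on quickly.

## Interface design

The command line exposes three subcommands — `simulate`, `run` and
`run-config` — rather than one per phase. The phases share almost all
of their state (vocabulary, factor matrices, embedding), so a staged
CLI would mostly serialize and re-read intermediates; the single `run`
command instead materializes every intermediate artifact in the output
directory and halts at the one genuine break point, the human coding
step, resuming from the same command once a mapping file exists. All
stages remain individually callable as library functions.

## Known limitations

- The rule-based POS tagger and suffix lemmatizer are shallow (no
  context, no irregular-verb table beyond a small exception list);
  adequate for bag-of-words topic input, not for linguistic analysis.
- Deidentification only masks the post author's own identifier; it is
  not general PII scrubbing.
- Prevalence uses per-window denominators; indicators with
  multi-indicator topics can sum above 1 within a window by design.
- The human coding step is consumed as configuration; nothing validates
  its substantive quality.
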