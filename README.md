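# resdict

Semiautomatic construction of a **resilience dictionary** from a
time-stamped corpus of peer-support mental-health forum posts.

Peer-support forums (moderated spaces where people with lived experience
of mental illness share stories and advice) are believed to build
*resilience* — a strengths-based capability framework commonly broken
into five indicators: **social capital**, **belonging**, **learning**,
**adaptive capacity** and **self-efficacy**. `resdict` turns a raw
corpus of forum posts into a machine-readable dictionary that says which
discussion themes realize which indicators, how prevalent each indicator
is per calendar quarter, and which indicators subsume which others.

## The method

A 4-phase pipeline with one explicit human step:

1. **Preprocessing.** Posts are deidentified (author mentions replaced
   with a placeholder), sentence-split, POS-filtered to content words,
   stop-word-filtered and lemmatized; posts with fewer than 5 surviving
   terms are removed; each post is assigned to its calendar quarter.
2. **Two-layer ensemble NMF.** Per quarter *q*, a TF-IDF matrix
   A_q (posts × terms, shared global vocabulary) is factorized as
   A_q ≈ W_q H_q into *k* nonnegative **base topics**. The topic-term
   rows H_q of all Q quarters are stacked into B ((Q·k) × m), which is
   factorized again, B ≈ W′H′, into *k′* **ensemble topics** — themes
   that persist across quarters. Per-post ensemble memberships are
   D = C W′, where C is the block-structured stack of the W_q. The
   number of ensemble topics k′ is selected by **topic coherence**: the
   mean pairwise cosine similarity of each topic's top-10 terms in a
   word-embedding space, averaged over topics.
3. **Annotation (human-in-the-loop).** Without a mapping file the
   pipeline stops and emits a template with each topic's top-15 terms
   and top-20 posts; researchers code each topic to zero or more
   indicators. Each post then inherits the indicators of its *dominant*
   topic (argmax of its D row), and per-quarter **prevalence** (share of
   retained posts per indicator) is computed.
4. **Taxonomy and dictionary.** Indicator x *subsumes* y when the posts
   annotated with y are a subset of those annotated with x (a
   thresholded variant is available for noisy data). The dictionary
   lists, per indicator: its taxonomy parent, its topics, each topic's
   weight (share of summed dominant-topic mass, in %; all topics total
   100), top-10 terms, and each term's 5 nearest embedding neighbours.

Everything is seed-deterministic: NMF uses multiplicative updates with
nonnegative-double-SVD initialization, and the embedding is a
count-based PPMI + truncated-SVD model.

## Worked example

Because real forum corpora are private, the package ships a simulator
with planted ground truth (topics, indicator nesting, synonym pairs):

```sh
resdict simulate --out sim --windows 4 --docs-per-window 500 --seed 1
resdict run sim/corpus.csv --out demo --k 6 --k-prime-min 4 --k-prime-max 8 --seed 1
```

The run preprocesses 2,000 posts (1,400 retained, 70.00%; 600 removed,
30.00%), fits 6 base topics in each of 4 quarters, and selects k′ by
coherence; with six planted themes the report reads

```
{"scores": {"4": 0.529, "5": 0.557, "6": 0.618, "7": 0.591, "8": 0.576}, "chosen": 6}
```

i.e. mean topic coherence peaks at the planted topic count. Since no
mapping file was given, the run stops after Phase 2 and writes
`mapping_template.yaml`. After filling in the coding (topic → indicator
lists) and re-running with `--mapping`, the remaining artifacts appear:
`prevalence.csv` (tidy window/indicator/proportion rows, ready for a
streamgraph), `taxonomy.json`, e.g.

```
parents: {'social_capital': 'belonging', 'adaptive_capacity': 'learning',
          'belonging': None, 'learning': None, 'self_efficacy': None}
```

— the planted nesting (every social-capital post is also a belonging
post, etc.) recovered exactly — and `dictionary.json`, where e.g. the
topic coded "Gratitude" appears under *social_capital* (parent
*belonging*) with weight 17.0%, top words `w0012 w0013 w0014 ...` and,
for each top word, its 5 nearest neighbours (the planted co-occurrence
partners rank first).

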