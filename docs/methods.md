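# Methods

## Problem and model

`kbrelex` extracts gene/protein mentions and the directed semantic
relations between them (eight relation types such as `Binds_To`,
`Regulates_Expression`, `Is_Functionally_Equivalent_To`) from
standoff-annotated biomedical text, reinforcing a recurrent encoder with
curated knowledge: protein annotation records (names, function text) and
reaction models whose co-participating species define each entity's
"related entities".

A token window is embedded (200-dimensional word vectors; deterministic
pseudo-random vectors for out-of-vocabulary tokens) and encoded by a
bidirectional LSTM, giving hidden states h_t of 2 x 200 components (we read
"state size 200" as per-direction; the total-400 reading is the natural
alternative).  For the entity pair under consideration, the knowledge store
is queried for related entities of both arguments (their union, after name
expansion through all matching annotation records), each related name is
embedded as the mean of its token vectors, and at every time step the
hidden state attends over these vectors bilinearly:

    alpha_i ∝ exp(v_iᵀ U_v h_t),    s_t = Σ_i alpha_i v_i,    h'_t = h_t + P s_t .

`U_v` (200 x 400) is learned; because the v_i live in the 200-dimensional
embedding space while h_t has 400 components, the additive fusion
h_t + s_t needs the learned bridge `P` (400 x 200) — the minimal faithful
way to keep the update additive when the two spaces differ.  When an entity
has no knowledge-base neighbours, s_t = 0 and the fused state equals h_t
exactly, so the knowledge pathway degrades gracefully to the plain encoder.
Attention logits are max-subtracted before exponentiation, so adding a
constant to all logits cannot change the weights.

Fused states are merged into one sentence vector by attentive pooling with
a learned context vector u (scores u·tanh(h'_t), softmax over t, weighted
sum); the exact pooling operator is a design choice of this package — any
normalized convex combination preserves the contract that identical states
pool to themselves.  A softmax layer predicts the relation label; argmax
ties break to the lowest label index, with the label order fixed
(the eight relation types in a fixed order, then NONE).

Two further design choices are ours rather than forced by the
architecture:

* **Argument-role indicators.**  Two learned vectors are added to the
  embeddings of the arg1 and arg2 tokens.  Relations are directed and
  evaluated as exact (type, arg1, arg2) matches; without a role marker the
  windows for (a, b) and (b, a) are identical and the direction is
  unlearnable.
* **Input windows.**  Either the whole sentence or the span between the
  entities, expanded by two words on each side (clamped to the sentence) so
  adjacent pairs still carry context.  Candidate pairs never cross sentence
  boundaries.

## Entity extraction

Entity extraction is two-staged.  Stage 1 tags each token with one of four
position tags B/I/O/E (begin, inside, outside, end); a k-token entity is
`B I^(k-2) E`, and a single-token entity is a bare `B` — the four-tag
alphabet has no dedicated singleton tag, so the decoder treats a `B` not
followed by `I`/`E` as a closed singleton.  Decoding is lenient: an `I` or
`E` with no open span opens one at that token, and an unclosed `B..I` run
closes at its last token, so raw model output always yields spans.  The
tagger is the same BiLSTM (+ per-token knowledge attention) with a softmax
per token, or a linear-chain CRF with learned 4x4 transitions plus
start/stop scores, trained by forward-algorithm negative log-likelihood and
decoded by Viterbi (exact; verified against exhaustive enumeration).
Stage 2 classifies each decoded span's type (gene vs protein).  The entity
vector is the elementwise sum of the surface word vector (mean over the
entity's tokens), the type vector (the embedding of "gene"/"protein"), and
the annotation vector (the sum of token embeddings of all names and
function text of every matching record — records are merged, not ranked;
taxonomy is excluded as non-lexical).

## Knowledge store

The store is fully offline: annotation records (JSON) and reaction models
(SBML levels 2–3, `listOfReactions` subtree only; non-curated models are
refused).  Reaction participants are reactants ∪ products ∪ modifiers —
modifiers are included deliberately, since a catalyst interacts with the
species it modifies.  Name matching is exact after normalization
(case-fold, trim, collapse internal whitespace); no stemming or fuzzy
matching, so every lookup is auditable.  Related entities of a surface are
all participants of all reactions that intersect the surface's expanded
name set, minus that name set itself, in deterministic (model, reaction,
participant) order.

## Training

AdaDelta (rho 0.95, eps 1e-6) with learning-rate multiplier 1.0
(0.8/0.9/1.0 admissible), per-minibatch L2 strength 1e-5, minibatch size 10
(20 for corpora above ~2000 instances), dropout 0.3 on the BiLSTM inputs
during training only, cross-entropy (or CRF NLL) loss.  Candidate pairs
with no gold relation train as NONE; a flag can cap the negative:positive
ratio, but by default all negatives are kept.  Optional early stopping
monitors validation micro-F1 with patience 10 and restores the best
parameters; epoch count and split sizes are package defaults, chosen to
make the loop finite rather than dictated by the architecture.  All
parameter initialization, shuffling and dropout draw from generators seeded
by the run seed, so CPU runs are bit-reproducible.  Evaluation is
micro-averaged P/R/F1 with NONE excluded (NONE predictions are
abstentions, never false positives), matching shared-task convention.

The networks are implemented in numpy with a small reverse-mode autodiff
(float64 throughout); the attention, CRF and metric computations are each
validated against independent brute-force oracles in the test suite.

## Synthetic data

The generator emulates the three inputs — standoff corpus, knowledge
store, embedding file — as templated token streams: capitalized filler
words, one- or two-token entity mentions drawn from a 1000-name pool (even
indices genes, odd proteins), an optional label-specific trigger token
between the pair, and a terminal period.  75% of sentences carry a gold
relation; the relation label of a given ordered pair is a fixed
deterministic function of the two surfaces (relations between two specific
molecules are facts, so a recurring pair never carries contradictory
labels).  The knowledge side mirrors the corpus: each distinct surface
gets an annotation record with probability `kb_coverage` (default 0.75,
the coverage regime the method is designed for), and each gold pair is
planted, with probability `kb_signal`, into a reaction containing both
surfaces plus a label-specific marker species, so reaction
co-participation is predictive of the label.  Distractor reactions tie
random surfaces to label-free species.  Trigger and marker tokens get
mutually orthogonal axis-aligned embeddings; gene and protein name tokens
are offset in opposite directions along the last embedding coordinate so
entity types are learnable for unseen names.

What the generator does **not** emulate: natural biomedical syntax,
nested/discontinuous mentions, cross-sentence relations, class imbalance
beyond the NONE/relation split, and ambiguity of name normalization.
Passing tests therefore demonstrate that the machinery is correct and that
the knowledge pathway transports usable signal — not that any particular
F1 carries over to real corpora.

## The ablation experiment

The causal claim — knowledge attention helps beyond the text — is tested
by switching the two evidence channels independently on 500 synthetic
sentences with 4 relation labels and no lexical triggers, over 5 seeds,
training a KB-attentive and a text-only model under identical conditions
and comparing held-out micro-F1 (documents split 80/20).  With
`kb_signal = 1` only the KB pathway reaches the label; with
`kb_signal = 0` the two models see identical information and should tie.
The experiment runs at reduced widths (32-dimensional embeddings and LSTM
states, 15 epochs) — the planted structure is low-dimensional and the
comparison is paired, so production widths (200/200) would only add
runtime; those remain the package defaults.

## Numerical and degenerate-input choices

* Softmaxes are always max-subtracted; CRF partition functions use
  log-sum-exp.
* Empty knowledge sets short-circuit to s = 0 and bit-identical fused
  states; a model with `use_kb=False` and one fed empty memory produce
  bit-identical outputs.
* OOV vectors are Uniform(-0.25, 0.25) per component, seeded by a hash of
  (token, oov_seed) and cached — a common embedding-initialization scale,
  fixed for reproducibility.
* Duplicate embedding rows keep the first occurrence (warned); malformed
  rows are errors naming the line.
* Entities that cross sentence boundaries are dropped at load with a
  warning; discontinuous spans are rejected (assumed absent from the
  corpora this targets).
* Tokenization is rule-based (whitespace, peel surrounding punctuation,
  split internal `/`; hyphens and digits stay inside tokens so names like
  `14-3-3` survive); offsets are exact by construction, and externally
  produced POS/lemma fields can be carried on tokens but are never
  required.

## Known limitations

* The attention memory is a bag of related-entity vectors; reaction
  stoichiometry, directionality and kinetics are discarded.
* Pair-level memory is the union over both arguments; the model cannot
  tell which argument contributed a neighbour.
* The tokenizer is deliberately simple; text with unusual Unicode
  punctuation will tokenize coarsely (offsets remain exact).
* Training is single-threaded numpy; it is sized for corpora of thousands
  of sentences, not millions.
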