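# Methods

## Setting and model

`eventweave` follows the BioNLP Shared Task setting: named entities
(`.a1`, e.g. `Protein`) are given as input, and the system extracts typed
n-ary events — a trigger span plus (role, argument) pairs, where arguments
are entities or other events — together with `Negation` / `Speculation`
modifications (`.a2`).  Extraction is a pipeline of four classification
stages, each consuming the previous stage's predictions:

1. **Trigger/entity detection.** Candidates are tokens whose base form
   matches a per-type lexicon built from every annotated trigger/detected
   entity in the training corpora; each candidate is scored by per-type
   binary classifiers plus a NONE classifier, and the best label above
   threshold that beats NONE wins (lexicographic tie-break).  Tokens
   heading a given entity are not candidates: given entities are inputs,
   not prediction targets.
2. **Argument detection.** Candidates are same-sentence
   (trigger, annotation) pairs restricted to (trigger-type, argument-type)
   combinations attested in the pooled training data; labels are role
   types or NONE.
3. **Multiple-argument detection.** Candidates are subsets of a trigger's
   detected relations whose structure signature — (event type, multiset of
   (role, argument-type) pairs) — is attested in training; a structure is
   accepted when its resolved label equals the trigger's type.  Accepted
   structures that are proper subsets of another accepted structure on the
   same trigger are dropped.  Events are assembled bottom-up so that event
   arguments always reference built events; structures with cyclic or
   unresolvable arguments are discarded, keeping the output well-formed.
4. **Hedge detection.** Events are instances; labels are `Negation`,
   `Speculation` or NONE.

All stages use linear SVMs (scikit-learn `LinearSVC`, C = 1.0 by default,
no per-class weighting unless configured) over sparse features: character
2–4-grams of candidate surfaces, base-form context n-grams (window ±3,
lengths 1–3), endpoint/participant types, bags of between-tokens,
token-distance buckets, and shortest dependency paths when a parse layer
is attached.  These hyperparameters are declared package defaults exposed
in `FeatureConfig` / `TrainConfig`, not claims about any reference system.

Training chains stages on gold annotation (gold triggers feed the relation
stage, gold relations the structure stage); prediction chains on predicted
output.  Candidate construction is identical in training and prediction.

## Learning from partially overlapping corpora

The closed-world assumption — every unannotated candidate is a negative —
fails when corpora with different annotation scopes are pooled, because a
candidate may be unannotated only because its type was out of scope for
its source corpus.  The `multiple` strategy removes these spurious
negatives:

1. Pool positives `P_j` across all corpora for each type `T_j`.
2. Build a per-type filter `F_j` from `P_j`: surface base forms for the
   span stage; argument-type combinations and structure signatures,
   keyed by the owning event type, for the relation/structure stages.
3. Build per-corpus filters `F_i` as the union of `F_j` over the types
   annotated in corpus `C_i`.
4. From each corpus's closed-world negatives `N_i'` keep only those
   matching `F_i`, giving `N_i`.
5. Train a binary classifier per type on `P_j` versus
   `N_j = (union of N_i over T_j-annotated corpora) ∪ (P_m, m ≠ j)`.
6. Train the NONE classifier on all `N_i` (positive class) versus all
   `P_j` (negative class).

Prediction applies no filtering, so the single model extracts the union of
all annotated types.  Because the negative sets vary by type, training is
one-vs-rest per type rather than multi-class.  The hedge stage is never
filtered: every corpus annotates hedges on all of its events.  The
filtering is deliberately imperfect — some genuinely correct negatives are
also removed (e.g. an unannotated shared-type mention whose surface
happens to be attested) — and no attempt is made to rescue them.

Two indexing choices deserve note.  First, combination filters are keyed
by the *event type* that owns a combination, not by the role label being
predicted: a `(Methylation, Theme, Protein)` combination is admissible
evidence only in corpora annotating `Methylation`, even though `Theme`
itself is universal.  Second, candidate generation at every stage is
restricted to *globally* attested inventories (lexicon, type pairs,
signatures) identically under every strategy; this mirrors the span
stage's dictionary matching, bounds enumeration, and makes filtering a
strict no-op when all corpora share one scope — so `multiple` degenerates
exactly to `merge` on homogeneous corpus sets, and both degenerate to
`single` on one corpus.  The price is a recall ceiling: events whose
signature never occurs in training cannot be proposed.  Event types are
treated as mutually exclusive throughout.

The baselines: `merge` pools corpora closed-world; `single` trains per
corpus; `stacking` adds, to a target-corpus model, indicator features of
the labels predicted by models trained on each other corpus; `easyadapt`
duplicates every feature into a shared and a domain-specific copy (domain
= corpus, or corpus:subdomain where declared), trains one model on the
pooled augmented instances, and therefore requires a domain at
application time.  With a single domain the augmented space adds no
constraint beyond scaling.

An optional post-translational-modification collapse maps PTM event types
to one placeholder in the *structure classifier's label space* only; the
trigger detector keeps distinct types and assigns the final label.  The
collapse is a label-space operation and composes with the pooled
(merge-mode) strategies; combining it with per-type negative restriction
under `multiple` treats the placeholder as unannotated everywhere, a
known, logged limitation.

## Normalization and transferability

`NormalizationRules` unify label inventories before training: event/entity
type maps (e.g. `Catalysis → Positive_regulation`), role maps
(`toLoc → ToLoc`, `Theme1 → Theme`), rare-role removal (`fromLoc`,
`product`), and optional deletion of event structures whose signature
occurs exactly once in the training split (with cascade, so no dangling
event arguments remain).  Rules are idempotent.

An event *transfers* from one corpus to another when its type — and, in
the default recursive mode, every participant's type down through event
arguments — lies in the target's scope.  The recursive reading is the
default because an event with an out-of-scope participant cannot be
expressed in the target corpus at all; a type-only mode is available
behind a flag.  `transfer_matrix` tabulates pairwise counts with SUM and
RATIO (incoming transferable events over own events) summary rows.

## Evaluation

Scoring follows shared-task conventions.  An event matches a gold event
iff the types agree, the trigger spans match — strictly, or approximately
with the predicted span inside the gold span extended by one token on each
side (the tolerance is configurable) — and the argument sets match
role-wise, one-to-one, recursing through event arguments (exhaustive
permutation search per role; arities are small).  With the FULL criteria
the negation/speculation flags must also agree.  Matching is greedy and
one-to-one in document/id order; this rule is declared, not claimed
identical to any official implementation.  F1 = 2PR/(P+R), defined as 0
when both P and R are 0.  Before per-corpus evaluation, predictions are
scope-restricted: events whose type (or any recursive event argument's
type) lies outside the gold corpus's annotation scope are removed, with
cascade.

## Synthetic data

The generator emits multi-corpus scenarios in which every corpus's *text*
is drawn from one shared template language over the union of the
scenario's event types, while each corpus *annotates* only its declared
scope — so out-of-scope mentions are planted unannotated by construction,
and a naive merge manufactures spurious negatives exactly as in real
pooled corpora.  Sentences are templated subject–trigger–object clauses
(one per line) over a fixed protein vocabulary, with optional nested
regulation events, negation/speculation cues, site (`Entity`) arguments,
and a trigger word (`modification`) deliberately ambiguous between
`Phosphorylation` and `Methylation`, disambiguated only by a context
marker token.  The dependency layer is a deterministic head-chain per
clause — tests need stable path features, not linguistic fidelity.  Equal
seeds give byte-identical corpora.

What the generator does *not* emulate: natural lexical diversity, parser
noise, discontinuous or multi-token triggers, cross-sentence arguments,
annotation inconsistency between corpora sharing a type, and realistic
type distributions.  Passing tests on this data therefore demonstrate the
correctness and the qualitative behaviour of the training-set construction
and pipeline, not performance on real corpora.

Shipped scenarios: `identical-scopes` (degenerate-equivalence check),
`disjoint-plus-shared` (two corpora, one shared type, one specific type
each — the recall-recovery setting), `nested-regulation` (recursive
scoring) and `hedge-mix` (hedge detection).  Defaults: 4 sentences per
document, 70/10/20 train/devel/test split by document, 15% event-free
decoy sentences, 25% ambiguous-trigger rate and 20% site rate in the
disjoint scenario.  The headline comparison uses 150 documents per corpus
and 5 replicate seeds — large enough that per-seed F1 varies by under two
points while the whole experiment stays within seconds on one CPU.

## Numerical and design choices

* Offsets are 0-based, end-exclusive; discontinuous trigger spans are
  rejected with a clear error.  Equiv (`*`) records and unknown
  modification kinds are preserved verbatim and ignored downstream.
* Base forms come from a fixed rule (lowercase; strip `-ing`, `-ed`,
  `-es`, plural `-s`): deterministic and consistent across inflections of
  the same stem, with no claim of linguistic correctness.
* Multi-token annotations are anchored at their last overlapping token;
  predicted triggers are emitted as single tokens, absorbed by approximate
  span matching.
* Structure enumeration is capped (default 1000 candidates per trigger,
  smallest structures first, deterministic truncation with a warning).
* The random seed governs classifier fitting and instance shuffling only;
  candidate generation is fully deterministic, so equal seeds reproduce
  predictions bit-for-bit, including through model persistence.
* Types with no positive instances are excluded from the label space and
  logged; a type with no usable negatives receives a constant positive
  scorer rather than failing.

## Known limitations

Single-token trigger prediction; sentence-internal arguments only; the
attested-signature recall ceiling noted above; greedy (not optimal)
one-to-one matching in the scorer; no coreference handling; no external
lexical resources beyond optional user-supplied lexicon files; hedge
detection uses a fixed cue list plus context features rather than curated
meta-knowledge cues.
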