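# Methods

## Task and data model

A document is a clinical note's family-history text. Internally it is
split into sentences and tokens with 0-based half-open character spans;
every token's text equals the document substring at its span, and all
entity spans inherit that coordinate system. Three entity categories are
annotated — FamilyMember, Observation, LivingStatus — and two relation
types: family member–living status (score ∈ {0, 2, 4}) and family
member–observation (Negated / Non_Negated). Only first-degree (Mother,
Son, …) and second-degree (Grandparent, Aunt, Cousin, …) relatives are in
scope; spouse, nephew and other excluded kin are simply absent from the
lexicon. Family side (Paternal/Maternal) is only defined for second-degree
relatives; first-degree relatives always carry side NA.

Preprocessing (sentence splitting at terminal punctuation and newlines,
regex tokenization, Penn-Treebank POS tags from a closed-class lexicon
plus suffix and context rules) is deliberately small and deterministic:
family-history sections are short, line-oriented and lexically narrow, and
the only downstream POS consumer is the noun filter of the rule matcher.
A general-purpose tagger could be substituted behind `preprocess` without
touching anything else.

## Entity tagger

Per token the network sees the concatenation of

| input | dim | trained | notes |
|---|---|---|---|
| word lookup | 50 | yes | vocabulary from the training set, `<unk>` fallback |
| char-trigram hash | 20 | no | signed CRC32 hashing, L2-scaled; handles unseen words |
| concept channels | 10 each | yes | one embedding table per auxiliary BIO channel |

followed by forward and backward LSTM passes (32 hidden units per
direction by default), inverted dropout (rate 0.5) on the concatenated
state, and a softmax over the 7 BIO labels. Training: Nadam (lr 0.002,
β₁ 0.9, β₂ 0.999), 30 epochs, masked mean cross-entropy over padded
sentence batches. The network and its backpropagation are plain numpy;
the analytic gradients are checked against central finite differences in
the test suite. Hidden width, learning rate and batch size are package
defaults (the recipe they implement fixes only epochs, dropout and the
optimizer family); at the corpus sizes involved the model is insensitive
to the exact width. On very small corpora (≲ 20 documents) a smaller
batch (8) is the practical choice, since the update count, not the epoch
count, is what drives convergence.

Pretrained embedding files (word2vec text dialect) can be plugged in as
additional static providers but are never required. External concept
taggers are a pluggable interface; the shipped implementation is a
dictionary tagger over the generator's disease vocabulary, standing in
for license-restricted medical concept extractors. Its mentions pass
through the semantic-type filter: for each semantic type, the fraction of
its training-set mentions overlapping (≥ 1 shared character) a gold
observation is its mapping probability, and types with probability
strictly above 0.70 ("over 70%") are re-encoded as B-/I-Observation input
channels; all others become O.

## Voting ensemble

LSTM training is nondeterministic across seeds, so N taggers trained with
identical hyperparameters but different seeds (default seeds 1..N) vote:
a candidate is an exact (document, category, span) triple, kept when its
vote count reaches the threshold. The threshold semantics are **votes ≥
threshold**: a strict reading would make the maximum threshold (N of N)
unsatisfiable, which contradicts sweeping thresholds up to N. Overlapping
same-category survivors are resolved by (1) vote count, (2) the best rank
among each candidate's voters — models are ranked by their mean pairwise
span-F1 agreement with the other members, ties to the lower model index —
and (3) earlier span. Candidate identity is the exact span; cross-category
overlaps are left alone. The resolved set provably contains no two
overlapping same-category spans (asserted against an independent
conflict-recursion oracle on fuzzed inputs).

## Attribute heuristics

* **Normalization**: lowercase, strip numeric modifiers and determiners,
  look up the last kin word. A kin token directly preceding the mention in
  possessive position ("mother's sister") or a short have-construction
  ("mother has a sister") re-normalizes through a composition table
  ((Mother, Sister) → Aunt, (Father, Father) → Grandfather, …);
  coordination ("mother and father") does not compose. Compositions whose
  result leaves the annotated name set (e.g. sibling's son = nephew) are
  deliberately absent. Unknown kin words ("twin") return no name; the
  pipeline drops and logs such mentions rather than guessing.
  Normalization is idempotent on its own outputs.
* **Side**: first-degree → NA. Otherwise lowercase-substring cue search
  ("paternal", "mother's", "father had", …) in the mention text first,
  then the whole sentence, taking the cue nearest the mention; no cue →
  NA. The shipped cue lists are supersets of the handful of published
  examples, extended with symmetric and common clinical phrasings.
* **Living status**: not-alive cues ("deceased", "passed away", "no longer
  living") force score 0 and are checked first; otherwise healthy cues
  ("healthy", "alive and well", "good general health") give 4; otherwise
  2. Substring matching keeps the rule trivially auditable; its known
  cost is rare false hits inside longer words.
* **Negation**: ConText-style. Each trigger ("no", "denies", "not aware
  of", "no family history of", …) opens a forward scope to the sentence
  end, a termination conjunction (but/however/although), or 6 tokens,
  whichever comes first; an observation whose first token falls in any
  scope is Negated. The window and terminators are package defaults; the
  published description fixes only the trigger customization.

## Relation extraction

Candidate pairs are the full FM×LS and FM×OBS cross-products per document.
Pairs with a newline between the mentions are pruned; the published rule
prunes only training negatives, but this package applies it at inference
too so the train and test input distributions match (gold cross-line
relations are essentially nonexistent in FH sections, and a labeled
positive is never pruned). Features are binary indicators in eight
namespaces (mention words, 7-token windows each side of each mention,
between-words, and the count of family members strictly between the pair,
bucketed {0, 1, 2, 3+}), hashed to 2^18 dimensions. Each relation type
has its own logistic model trained by per-example online gradient
descent: learning rate 0.5/√t, 100 passes, seeded shuffling; prediction
is related ⇔ probability ≥ 0.5 (ties → related, forced by σ(0) = 0.5).
Scores and negation are attached afterwards by the rule components — each
related living-status mention is scored independently — and duplicate
(document, family-member tuple, mention-text, attribute) relations
collapse to one.

## Evaluation

Matching is document-level over unique tuples, which is what the
family-side and normalized-name matching semantics of the shared-task
metric imply; offset-level matching of tagger outputs is used internally
(ensemble voting, model ranking, parameter-recovery checks) but not for
task scores. Observations (and living-status surface forms in entity
scoring) match when the lowercase alphanumeric word sets share ≥ 1 word,
assigned greedily 1:1 in document order — the official assignment policy
is unpublished, and greedy assignment is the simplest order-deterministic
choice. Entity scoring does not compare living-status scores or negation
(the entity task does not define them); relation scoring does, unless a
`MatchSpec` ignores one attribute. Ignoring an attribute coarsens tuples,
so TP can only rise and FP/FN only fall — the ablation suite asserts this
monotonicity on randomly perturbed predictions. Percentages are reported
rounded to 2 decimals; zero denominators score 0. One naming wrinkle is
inherited from the task definition: published per-category entity tables
list a "Living status" row although the entity subtask is defined over
family members and observations; the category naming here follows the
task definition and the wrinkle is documented rather than resolved.

## Synthetic corpus

The generator emulates the annotated structure of FH corpora with
sentence templates: related FM–observation statements (plain, diagnosed,
died-of), living-status statements at all three scores, negated relations,
numeric kin ("three uncles"), nested kinship ("mother's sister" /
"mother has a sister"), side-modified second-degree kin, unrelated
observations ("No family history of X"), filler sentences, and newline
vs space sentence separators. All spans are exact by construction
(template assembly tracks offsets), a single seeded generator drives
every choice (same seed ⇒ byte-identical corpus), and gold attributes are
assigned from the same cue inventories the rules use, so the rule
components are consistent with gold by design. Default rates: 23% of
observation entities participate in no relation (matching the published
corpus profile of 978 observation entities vs 753 observation relations);
negation 12%, nested kinship 15%, numeric modifiers 12%, side cues on 50%
of second-degree kin, newline separators 30%. ~30 disease terms give the
taggers lexical variety.

What passing on this corpus shows — and does not. The generator is
template-based: its lexical variety, sentence lengths, annotation
ambiguity and noise are far below real clinical text, so near-perfect
parameter recovery (entity F1 ≥ 0.90 for a single tagger trained on 200
documents; end-to-end relation F1 ≥ 0.85) demonstrates that the learning
machinery, voting, features and plumbing are correct, not that real-corpus
scores (low-to-mid 80s entity F1, low 70s relation F1 for systems of this
family) would be reproduced. Real corpora are access-restricted and the
strongest published variants also depend on months of language-model
pretraining on restricted clinical text, both outside this package's
scope.

## Reproducibility and scale

Every stochastic component takes an explicit integer seed (tagger
initialization/shuffling, ensemble seed lists, relation-model shuffling,
corpus generation); two end-to-end runs with the same configuration are
byte-identical, and this is asserted in the tests. Test-suite problem
sizes (200 training documents for parameter recovery, 3 seeds; 15–30
documents for pipeline mechanics) run in a few minutes on one CPU; the
defaults scale linearly in documents × epochs.

## Known limitations

* Substring cue matching can fire inside longer words ("studied" contains
  "died"); irrelevant at the living-status phrase lengths involved, but a
  word-boundary mode would be the first upgrade for noisier text.
* Relations crossing a line break are unfindable by construction (the
  newline pruning rule).
* Coreference ("she", "this aunt") and cross-sentence attribute cues are
  out of scope.
* The POS tagger is domain-tuned; on text far from FH phrasing its noun
  filter will be the weakest link of the rule-based matcher.
* The negation scope model handles pre-scope triggers only (no "was ruled
  out" post-scope triggers, no uncertainty/experiencer dimensions).
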