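# Methods

This note documents the models and procedures implemented in `npmatch`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

Spontaneous adverse-event reporting systems record drug names as free
text. Mentions of natural products (botanical supplements) are especially
unstandardized: the same product appears as a common name ("Liquorice"),
misspellings ("Likorice"), a Latin binomial ("Glycyrrhiza glabra"), or a
long product-style string ("LICORICE ROOT EXTRACT CAPSULE"). `npmatch`
maps such strings onto a lexicon of disjoint *synonym groups*, each
holding one preferred term (PT), one Latin binomial, and known variants,
and mines candidate new names from strings that fail exact lookup.

## Text normalization and encoding

All matching operates on normalized strings: accented letters are
ASCII-folded, characters outside A–Z (after uppercasing) are removed
except whitespace, whitespace runs collapse to single spaces, and ends
are trimmed. Normalized names encode to fixed-length integer sequences:
A–Z → 1–26, space → 27, zero padding to 65 positions. Names longer than
65 characters cannot be encoded and are discarded by the pipeline (the
cutoff sits near the mean observed name length, ~30, plus one standard
deviation). Folding rather than deleting accented letters preserves
signal from Latin binomials; trailing (post-)padding keeps character
positions stable for the recurrent model.

## Classical matchers

**Gestalt pattern-matching (GPM).** Ratcliff/Obershelp similarity:
recursively find the longest common substring (the anchor), recurse on
the left flanks and right flanks, and score `2·Km/(|s1|+|s2|)` where `Km`
is the total matched length. Anchor ties resolve to the earliest start in
the first string, then the second — the same discipline as
`difflib.SequenceMatcher`, against which the implementation is tested.
No junk/popularity heuristic is applied, so scores do not depend on pool
composition. One documented consequence of deterministic tie-breaking:
the score is not exactly symmetric in its arguments on tie-heavy inputs
(reference implementations behave identically); rankings always use a
fixed argument order (query first), so retrieval is unaffected.

**Levenshtein edit distance (LED).** Classical unit-cost
insert/delete/substitute distance, no transpositions, computed by the
standard dynamic program (row-vectorized; the sequential pass handles the
deletion dependency). Ranking sorts on raw distance ascending.

`top_k` retrieval deduplicates the pool, sorts best-first with
lexicographic tie-breaks (so enlarging k extends rather than reorders the
list, and results are invariant under pool shuffling), and optionally
applies a similarity floor / distance ceiling cutoff; the default is no
cutoff, returning exactly k entries.

## Training-pair construction and balancing

Training instances are `(name_a, name_b, label)` with label 0 for
*matching* (same group) and 1 for *distant* (different groups) — note the
label is a distance target, not a similarity. Base matching pairs are all
within-group name combinations; each is augmented (default 5×) by
replacing one side with a random perturbation of 1–2 character edits
(substitution, insertion, deletion, adjacent transposition, drawn
uniformly — the classical typo operators). Distant pairs are sampled
uniformly across groups, one per matching pair by default. The heavy
augmentation factor reflects how such corpora are built in practice: the
raw name inventory is small, and nearly all of the training mass comes
from synthetic spelling variation.

Balancing runs in two rounds. Round one equalizes per-product
representation: each pair is attributed to the group of its first member
and every group is topped up to the maximum observed count (±1) by
synthesizing new unique matching pairs from perturbed names. Round two
equalizes the label totals to within 1% by synthesizing pairs of the
minority label (perturbed negatives keep the synthesized pool unique).
Balancing only ever adds pairs; existing pairs and labels are never
modified. When the retry budget cannot close a gap, a
`BalanceShortfallWarning` carries the achieved counts.

The split draws the holdout set first, then divides the remainder 70/30
into train/validation, eliminating any leakage path from holdout to model
selection. All randomness flows from explicit `numpy` generators, so the
whole dataset is reproducible byte-for-byte from two seeds.

## The Siamese distance model

Two weight-tied towers embed an encoded name pair; the model's output is
the cosine distance between the tower vectors. Each tower is:

1. per-character embedding into 30 dimensions;
2. two position-wise dense layers of width 130 (ReLU);
3. a bidirectional LSTM with 65 units per direction, over the character
   sequence, with padded positions masked (state carried through);
4. tower vector = concatenation of the two directions' final hidden
   states (130 dimensions).

Training minimizes the contrastive loss
`L(d, y) = (1−y)·d² + y·max(0, m−d)²` with margin `m = 1`, pulling
matching pairs toward distance 0 and pushing distant pairs beyond the
margin. Cosine distance ranges over [0, 2]; the model's *reported*
distance is clipped into [0, 1] to match the label range, while the
training loss uses the unclipped value so matching pairs beyond 1 still
receive a gradient (with `m = 1`, distant pairs beyond 1 have zero loss
either way, so the two views agree everywhere the loss is active).
Identical inputs produce identical tower vectors by weight tying, so
`distance(x, x) = 0` exactly.

The implementation is pure NumPy with hand-written backpropagation,
verified against float64 central differences to ~1e-9 relative error.
Because the embedding and the position-wise dense stack see only the 28
input symbols, their composition is evaluated once per optimizer step as
a 28-row table; sequences index into it, and the per-timestep input
projections of the LSTM likewise reduce to row lookups of a precomputed
`table @ W_x`. The recurrent products are then the only per-timestep
matrix work. Batches are length-bucketed (shuffled, then sorted by pair
length within chunks of 16 batches) so each batch truncates at its own
maximum sequence length.

Optimization: Adam (lr 2e-3 by default, β = 0.9/0.999), batch 256,
global-norm gradient clipping at 5, forget-gate bias initialized to 1,
Glorot-uniform weights from the config seed. The default learning rate
was chosen from the loss trajectories on the synthetic benchmark: 1e-3
reaches the same plateau but needs roughly twice the epochs. Validation
accuracy counts a pair correct when `(clipped distance > 0.5)` equals
`(label == 1)`; the 0.5 threshold is the midpoint of the label range and
is configurable. Early stopping monitors validation loss with patience
10 and a minimum meaningful improvement (`min_delta`, default 3e-3):
once gains below it persist for 10 consecutive epochs training stops,
and the weights of the lowest-validation-loss epoch are restored. After
4 such stalled epochs the learning rate is halved (reduce-on-plateau),
which settles the tail of training; without these two mechanisms the
late plateau's ~1e-4/epoch loss drift would postpone the stop almost
indefinitely. Checkpoints are a single `.npz` weights file with a
JSON config sidecar; reload is bit-exact.

## Evaluation metrics

**MRR.** For each query, the reciprocal of the rank of the first
qualifying candidate in the top-k (k = 20) list, 0 when absent — misses
are averaged in, not skipped. *Exact* mode accepts only the target
string; *equivalent* mode accepts any member of the target's synonym
group, so equivalent MRR dominates exact MRR on identical rankings. The
reported spread is the population standard deviation over per-query
reciprocal ranks (sample SD available via a flag). Only the first
qualifying hit is scored; a completeness companion (`recall_at_k`) is
provided separately.

**Cohen's kappa.** `(po − pe)/(1 − pe)` with chance agreement from the
marginal products; the degenerate all-agreeing-constant table returns 1.
Tested by enumeration of every 2×2 decision table with n ≤ 6 against
scikit-learn.

## Novelty mining pipeline

Unmapped strings are normalized, then filtered: over-length (> 65)
strings first, exact duplicates second (first occurrence kept, order
preserved) — the order matters for the intermediate counts and the
accounting identity `n_input = n_long + n_dup + n_pool` is an invariant.
The query set holds exactly two queries per product of interest (Latin
binomial and PT). Each query × method retrieves its top-20 pool strings.
Adjudication flags are advisory only: a genus-only result for a binomial
query, and blocklist collisions with other medical terms for common-name
queries (collision detection cannot be fully automated; the blocklist is
user-supplied). Two annotators' decisions are merged — agreement decides,
disagreement stays pending for adjudication — and kappa is computed on
the doubly-annotated subset. Accepted names are added to their groups
(cross-group conflicts are hard errors), and the capture delta counts
distinct report ids matched before vs after the update.

## Synthetic benchmark

`synth_lexicon` generates the entire study corpus so every stage is
testable without external data: pseudo-Latin binomials ("Genus species"
from syllable inventories), distinct common names, typo variants (1–3
edits, intensity scaled by `typo_rate`), and long-form product strings
(name + descriptor words) that give name lengths a mean near 30
characters with a heavy right tail, capped at 65. The unmapped pool
plants one or two recoverable perturbed variants per group (ground truth
recorded) among distractor strings.

The default benchmark configuration is 200 groups, 4 variants per group,
typo rate 0.2; with default pair construction this yields ≈38,000
balanced pairs (≈27,000 training), a deliberate desk-scale counterpart of
the full study corpus. On this corpus the trained model reaches best
validation accuracy ≥ 0.95 (observed ≈ 0.98, early-stopping after ≈ 33
epochs).

What the synthetic data does *not* emulate: brand names and
multi-ingredient product strings with no orthographic relation to the
canonical name, semantic (non-orthographic) synonymy beyond the planted
binomial↔common-name association, real-world misspelling biases (keyboard
adjacency, phonetics), and the extreme pool size of a real reporting
database. Passing the benchmark therefore demonstrates the correctness
and learnability of the machinery — not field performance on real
reports, which depends on curated lexicons and human review.

## Numerical and degenerate-input choices

- GPM of two empty strings is 1.0 (identical); the similarity of any
  string with itself is exactly 1.
- `cosine_distance` raises on zero vectors; inside the model, norms carry
  an epsilon (tower vectors are never exactly zero in practice).
- Ranking ties (equal scores) always break lexicographically on the
  candidate string.
- `perturb` retries up to 64 times to produce a distinct, valid,
  normalized output within the edit budget, then raises.
- Training raises on non-finite loss with the epoch index.
- An untrained model ranks pools without error but its rankings carry
  `trained=False`.

## Known limitations

- The NumPy trainer is single-device and unaccelerated; it is sized for
  desk-scale corpora (tens of thousands of pairs), not millions.
- GPM asymmetry under tie-breaking (above) is inherited from the
  algorithm's classical formulation.
- Balancing by synthesis can fall short on tiny lexicons with exhausted
  perturbation space; it warns rather than fails.
- The adjudication blocklist is user knowledge; the pipeline cannot
  decide medical-term collisions on its own.
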