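# Methods

## Problem and model

Each instance is one candidate drug pair in one sentence of the
DDIExtraction-2013 dialect.  The two target mentions are replaced by the
placeholders `DRUG1` / `DRUG2` (earlier offset first), all other drug
mentions by `DRUGOTHER`; the label is one of Mechanism, Effect, Advice,
Int, False.  The classifier fuses five feature blocks:

1. **Pooled sentence vector** — affine(tanh(·)) of the first-token
   (start marker) row of the encoder output `H^seq ∈ R^{n×d}`.
2. **Interaction feature** — `H^seq` rows are scaled by a fixed
   per-token weight vector that is high on the closed between-entity
   span `[j, k]` and low elsewhere; the span rows are averaged
   (divisor `k − j + 1`), squashed with tanh and mapped through an
   affine head.
3. **Entities feature** — a weighted sum `v · H^seq` with a fixed
   entity-centred weight vector (below), then tanh and an affine head.
4–5. **Molecular vectors** of the two drugs from a shared MGNN.

The concatenation (length `3d + 2·d_m`) feeds a 5-way softmax trained
with cross-entropy.  Disabled blocks (ablations) are replaced by zero
vectors of the same shape, keeping the classifier dimension constant.

## Interaction attention prior

High range `(h_w0, h_w1) = (0.9, 1.1)` and low range
`(l_w0, l_w1) = (0.3, 0.5)` are widened by an oscillation factor
`σ = 0.1` to `[0.8, 1.2]` and `[0.2, 0.6]`.  The widened intervals must
stay disjoint; this is enforced at construction.  Two modes realise the
"elastic" range: the default `midpoint` takes the interval midpoint
(deterministic, bit-stable), `sampled` draws a per-token uniform value
from the interval with a fixed seed.  Entity tokens `j` and `k` are
inside the high-weight span.  The vector is a structural prior, not
learned.

## Entities attention prior

Window masses `P(x) = CDF(x) − CDF(x − step)` are evaluated on the unit
grid `x = step·(rank+1)` and assigned high-to-low with increasing
distance from each entity: `⌈0.15·n⌉` tokens before the first entity
and `⌈0.25·n⌉` after it; the second entity is the mirror image
(`⌈0.25·n⌉` on its left, `⌈0.15·n⌉` on its right).  Fractions are of
the sentence length `n`.  All masses are scaled by their global
maximum, entity tokens are pinned to 1, overlapping windows resolve by
elementwise max, and uncovered tokens get a baseline weight 0.05 so
distant context is attenuated rather than erased.

Free parameters with no canonical value — the degrees of freedom and
step sizes — default to chi-square `k = 4`, Student-t `n = 5`,
`step = 1.0`; any such choice preserves the peaked-and-decaying shape,
and all are configurable.  Which distribution serves which entity is
likewise open; the default is chi-square for the first entity and
Student-t for the second.  The Student-t density uses the standard
exponent `−(n+1)/2` (the positive variant is not integrable).  Under
this construction, reversing the token order while swapping the two
entities *and* the two distribution specs exactly reverses the weight
vector; the fractions keep their roles.

## Molecular encoder

SMILES strings are parsed with RDKit; atoms are renumbered into RDKit's
canonical order so fingerprint assignment is reproducible.  Each heavy
atom receives an r-radius subgraph signature (r = 1 by default): its
element plus the sorted multiset of (bond type, neighbour signature)
pairs within r hops, with bond types collapsed to
single/double/triple/aromatic.  Signatures, not integer ids, are the
vocabulary contract; unknown signatures at inference map to a reserved
UNK id.  The MGNN update is additive,

    m_i^ℓ = m_i^{ℓ-1} + Σ_{j∈N_i} ReLU(W_hidden^{ℓ-1} m_j^{ℓ-1} + b),

with `L = 2` steps and `d_m = 64` by default, followed by sum pooling
and a ReLU-affine readout — a permutation-invariant composition.  One
encoder is shared by both drugs of a pair.  Drug names missing from the
name→SMILES table, or with unparsable SMILES, fall back to a dedicated
zero-initialised learnable unknown-structure vector; missing structures
are an expected condition, not an error.  Only 2-D connectivity is
used; stereochemistry and 3-D conformation are out of scope.

## Sentence encoders

The trainable desk-scale encoder is a small transformer (learned word
and position embeddings, 2 post-LN layers, 2 heads, `d = 32`) whose
vocabulary is built from the corpus; every word is one sub-token, and
the placeholders are atomic vocabulary items so span indices remap
exactly (word `w` → row `w + 1` past the start marker).  An adapter
class wraps any pretrained transformer exposing a tokenizer and a
last-hidden-state callable and performs first-subtoken span remapping;
it is exercised with a mock in the tests.  Sequences beyond the length
cap are truncated with a warning, and truncation that would drop an
entity placeholder is an error.

All trainable components run on a small reverse-mode automatic
differentiation core over float64 numpy arrays (`ddirel.nn`), verified
against central finite differences.

## Training and evaluation

Re-sampling is applied to the training split only: duplicate negatives
(identical masked token sequences — drug names are already erased by
masking) are reduced to their first occurrence, then each positive
class is grown by seeded sampling with replacement until it reaches
`oversample_ratio` (default 0.3) times the largest class count.
Optimisation is Adam (lr 1e-3, batch 16); epochs default to 8 and are
reduced in the test-suite experiments where fewer suffice (4–5 for the
planted-signal corpora).  All randomness — initialisation, shuffling,
sampling — derives from the `fit(seed)` argument, and the loss curve is
bit-reproducible given a seed.

Evaluation reports per-class precision, recall and F1 = 2PR/(P+R),
micro-averaged by pooling TP/FP/FN over the four positive classes with
False excluded (SemEval-2013 task 9.2 convention), plus macro averages,
since published DDI scores do not always state their averaging mode.

## Synthetic data

The generator emulates the corpus inputs without downloads: sentences
of 9–16 filler tokens with 2–3 drug mentions (positions at least two
tokens apart), one candidate pair per sentence, labels drawn from
priors (False 0.5, positives 0.125 each).  Under `trigger_between`, a
class-specific trigger token disjoint from all other vocabulary is
planted strictly between the target pair, mirroring the corpus
regularity that interaction evidence lies between the entities; under
`drug_identity` the label is a fixed digest of the unordered name pair
(molecular-only signal); `random` is the negative control.  One pair
per sentence is deliberate: with all pairs emitted, a trigger planted
between one pair can also fall between another pair labelled False,
corrupting the planted signal.

What passing on this generator shows — and does not.  The corpora are
separable by construction and tiny; recovering them demonstrates the
plumbing (span localisation, feature routing, optimisation) is correct,
not that the architecture reaches any particular score on the licensed
DDI-2013 corpus, whose class imbalance, lexical variety and annotation
noise the generator does not emulate.

## Numerical choices and degenerate inputs

- Chi-square/Student-t pdf and cdf values come from `scipy.stats`; the
  chi-square density is defined as 0 for `x ≤ 0`.
- Softmax and cross-entropy are max-shifted for overflow safety.
- Discontinuous entity mentions (";"-separated offsets) are skipped
  with a warning; corpus offsets are inclusive and converted to
  half-open at the parser boundary.
- Two-token sentences give the degenerate entities vector `[1, 1]`.
- A positive class absent from the training data is skipped by the
  over-sampler with a warning; a label with no positive instances
  yields NaN in the between-entity statistic.
- The between-entity statistic is parameterised by a trigger lexicon
  because the corpus-side criterion behind the published per-label
  fractions is not public; the statistic is a documented approximation
  and exact published fractions are not a target.

## Problem sizes used in the checked experiments

Planted-trigger recovery trains on 800 sentences and evaluates on 200
(micro-F1 > 0.95 required; observed 1.0); the ablation comparison uses
500/150 over 5 seeds; molecular-only identity recovery uses 400/150.
These sizes are the smallest at which the planted signals are learned
with comfortable margin, keeping the whole suite a few minutes on one
CPU core.

## Known limitations

- No fine-tuning recipes for pretrained encoders are included, and the
  adapter is validated against a mock rather than a real checkpoint.
- The linear classifier over concatenated molecular vectors cannot
  represent arbitrary pair→label maps (its drug-identity recovery is
  well above chance but far from perfect — consistent with a linear
  read-out of a pairwise function).
- Fingerprint ids depend on vocabulary insertion order; only signatures
  are stable across runs, which is what the contract guarantees.
- Oscillation sampling draws weights per token; per-sentence draws are
  not implemented.
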