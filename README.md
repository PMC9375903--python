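# ddirel

Relation extraction for drug–drug interactions (DDI): given a sentence
mentioning two or more drugs, classify each candidate drug pair into one
of the five DDIExtraction-2013 relation types — *Mechanism*, *Effect*,
*Advice*, *Int* or *False* (no interaction).

Sentences with several drug mentions typically carry several overlapping
candidate pairs, so per-pair features must localise to the target pair.
`ddirel` does this with two fixed positional attention priors applied to
the token embeddings of a sentence encoder, plus molecular structure
features of the two drugs:

- **Interaction attention** H<sup>int</sup>: tokens in the closed span
  [j, k] between the two target entities get weights from a high range
  [h<sub>w0</sub>−σ, h<sub>w1</sub>+σ] = [0.8, 1.2], all other tokens
  from a low range [0.2, 0.6] (defaults h<sub>w0</sub>=0.9,
  h<sub>w1</sub>=1.1, l<sub>w0</sub>=0.3, l<sub>w1</sub>=0.5, oscillation
  σ=0.1).  The weighted rows of H<sup>seq</sup> are averaged over the
  span, squashed and mapped through an affine head.
- **Entities attention** H<sup>ent</sup>: per-token weights built from
  windowed chi-square and Student-t probability masses
  P(x) = CDF(x) − CDF(x − step), assigned high-to-low moving away from
  each entity (15 % of the sentence length before an entity, 25 % after,
  mirrored for the second entity), pinning entity tokens to 1.
- **Molecular features** H<sup>mol</sup>: each drug name is resolved to
  SMILES, parsed into a heavy-atom graph, every atom assigned an
  r-radius subgraph fingerprint (r = 1), and encoded by an additive
  message-passing network
  m<sub>i</sub><sup>ℓ</sup> = m<sub>i</sub><sup>ℓ−1</sup> +
  Σ<sub>j∈N<sub>i</sub></sub> ReLU(W m<sub>j</sub><sup>ℓ−1</sup> + b),
  followed by sum pooling and a ReLU-affine readout.

The five blocks — pooled sentence vector, interaction feature, entities
feature, and the two molecular vectors — are concatenated and classified
with a softmax layer trained by cross-entropy.  Micro precision / recall
/ F1 = 2PR/(P+R) are pooled over the four positive classes (the
SemEval-2013 task 9.2 convention).

The package also ships corpus tooling for the DDI-2013 XML dialect
(entity masking with DRUG1/DRUG2/DRUGOTHER, duplicate-negative removal,
seeded positive over-sampling) and a synthetic-corpus generator that
plants recoverable signal, so the whole stack is testable offline.

## Worked example

```python
from ddirel import (DDIConfig, DDIModel, GeneratorSpec,
                    generate_corpus, generate_drug_table)

# synthetic corpus: the label is decided by a class-specific trigger
# token planted strictly between the target drug pair
_, train = generate_corpus(GeneratorSpec(n_sentences=800, seed=101))
_, test = generate_corpus(GeneratorSpec(n_sentences=200, seed=202))
table = generate_drug_table(12, seed=1)

model = DDIModel(train, drug_smiles=table, config=DDIConfig(epochs=4))
result = model.fit(seed=0)
print(result.summary(test))
```

prints

```
DDI relation classifier
============================================
feature blocks : pooled, interaction, entities, molecular
encoder        : tiny transformer (d=32, layers=2)
molecular      : MGNN (d_m=64, steps=2, r=1)
train instances: 864 (seed 0)
epochs         : 4, final loss 0.0052

class              P       R      F1     n
Mechanism      1.000   1.000   1.000    22
Effect         1.000   1.000   1.000    22
Advice         1.000   1.000   1.000    25
Int            1.000   1.000   1.000    29
micro          1.000   1.000   1.000    98
macro          1.000   1.000   1.000    98
```

The 800 training sentences grow to 864 after duplicate-negative
removal and positive over-sampling; held-out micro-F1 of 1.0 shows the
model recovers the planted between-entity trigger signal exactly.  A
`ddirel` command-line interface wraps the same pipeline
(`ddirel generate-corpus`, `ddirel preprocess`, `ddirel train`,
`ddirel encode-smiles`).

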