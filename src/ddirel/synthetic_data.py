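"""Synthetic corpora and drug tables with planted, recoverable signal.

Generates sentence-level candidate instances in the same XML dialect the
corpus reader parses, plus a name->SMILES table, entirely offline.  Each
sentence contains >= 2 drug mentions at random positions and exactly one
candidate pair (extra mentions act as DRUGOTHER distractors -- keeping
one gold pair per sentence prevents a trigger planted for one pair from
leaking into another pair's between-entity span).

Label rules
-----------
``trigger_between``
    The pair's label is drawn from the class priors; positive labels
    plant a class-specific trigger token strictly between the two target
    mentions.  Negative sentences contain no trigger.  Trigger tokens
    are disjoint from drug names and the filler vocabulary, so position
    and identity of the trigger carry the entire signal.
``trigger_anywhere``
    As above, but the trigger may land anywhere outside the mentions.
``drug_identity``
    The label is a fixed deterministic function of the (unordered) drug
    name pair; sentences carry no textual signal.
``random``
    Labels are drawn independently of everything (negative control).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .corpus_io import LABELS, POSITIVE_LABELS, EntityMention, mask_drugs

__all__ = [
    "GeneratorSpec",
    "SMILES_LIBRARY",
    "TRIGGER_TOKENS",
    "drug_lexicon",
    "generate_corpus",
    "generate_drug_table",
]

#: small valid molecules for the synthetic drug table
SMILES_LIBRARY = (
    "C", "CC", "CCO", "CCN", "CCC", "CC(C)O", "CC(=O)O", "CC(=O)N",
    "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "c1ccncc1",
    "c1ccc2ccccc2c1", "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1",
    "C1CCOC1", "C1CCNC1", "CC(=O)Oc1ccccc1C(=O)O", "CN1CCC1",
    "O=C(O)c1ccccc1", "CC(N)C(=O)O", "NCCO", "OCC(O)CO",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Clc1ccccc1", "FC(F)(F)c1ccccc1",
    "CCOC(=O)C",
)

#: class-specific trigger tokens, disjoint from fillers and drug names
TRIGGER_TOKENS = {
    "Mechanism": "trig_mechanism",
    "Effect": "trig_effect",
    "Advice": "trig_advice",
    "Int": "trig_int",
}


def drug_lexicon(n: int) -> list:
    """Deterministic synthetic drug names drug00, drug01, ..."""
    return [f"drug{i:02d}" for i in range(n)]


@dataclass(frozen=True)
class GeneratorSpec:
    n_sentences: int = 200
    vocab_size: int = 60
    sentence_len: tuple = (9, 16)
    n_drugs: tuple = (2, 3)
    n_drug_names: int = 12
    label_rule: str = "trigger_between"
    #: priors over (Mechanism, Effect, Advice, Int, False)
    class_priors: tuple = (0.125, 0.125, 0.125, 0.125, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.label_rule not in (
            "trigger_between", "trigger_anywhere", "drug_identity", "random"
        ):
            raise ValueError(f"unknown label rule {self.label_rule!r}")
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if self.sentence_len[0] < self.n_drugs[1] * 2 + 3:
            raise ValueError(
                "sentences too short for the requested number of drug "
                "mentions plus trigger placement"
            )


def _identity_label(name1: str, name2: str) -> str:
    """Fixed pair -> label map via a stable digest (order-insensitive)."""
    key = "|".join(sorted([name1, name2])).encode()
    digest = hashlib.sha256(key).digest()
    return LABELS[digest[0] % len(LABELS)]


def generate_corpus(spec: GeneratorSpec, xml_path=None):
    """Generate sentences with planted labels.

    Returns ``(xml_string, gold_instances)``; if ``xml_path`` is given the
    XML is also written there.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fillers = [f"word{i:03d}" for i in range(spec.vocab_size)]
    names = drug_lexicon(spec.n_drug_names)
    root = etree.Element("corpus")
    doc = etree.SubElement(root, "document", id="d0")
    gold = []
    for s in range(spec.n_sentences):
        length = int(rng.integers(spec.sentence_len[0], spec.sentence_len[1] + 1))
        n_drugs = int(rng.integers(spec.n_drugs[0], spec.n_drugs[1] + 1))
        tokens = [fillers[i] for i in rng.integers(0, len(fillers), size=length)]
        # drug positions: distinct, non-adjacent enough that the target
        # pair always has >= 1 token strictly between it
        while True:
            positions = np.sort(rng.choice(length, size=n_drugs, replace=False))
            if np.all(np.diff(positions) >= 2):
                break
        drug_names = [names[i] for i in rng.choice(len(names), size=n_drugs,
                                                   replace=False)]
        for pos, name in zip(positions, drug_names):
            tokens[pos] = name
        # target pair = the first two mentions
        p1, p2 = int(positions[0]), int(positions[1])
        name1, name2 = drug_names[0], drug_names[1]

        if spec.label_rule in ("trigger_between", "trigger_anywhere", "random"):
            label = LABELS[int(rng.choice(len(LABELS), p=spec.class_priors))]
        else:
            label = _identity_label(name1, name2)
        if spec.label_rule == "trigger_between" and label != "False":
            candidates = [
                i for i in range(p1 + 1, p2) if i not in set(positions.tolist())
            ]
            tokens[int(rng.choice(candidates))] = TRIGGER_TOKENS[label]
        elif spec.label_rule == "trigger_anywhere" and label != "False":
            candidates = [
                i for i in range(length) if i not in set(positions.tolist())
            ]
            tokens[int(rng.choice(candidates))] = TRIGGER_TOKENS[label]

        text = " ".join(tokens)
        sid = f"d0.s{s}"
        sent = etree.SubElement(doc, "sentence", id=sid, text=text)
        mentions = []
        offset = 0
        starts = []
        for tok in tokens:
            starts.append(offset)
            offset += len(tok) + 1
        for m, (pos, name) in enumerate(zip(positions, drug_names)):
            start = starts[pos]
            end = start + len(name) - 1  # inclusive, corpus dialect
            etree.SubElement(
                sent,
                "entity",
                id=f"{sid}.e{m}",
                charOffset=f"{start}-{end}",
                type="drug",
                text=name,
            )
            mentions.append(
                EntityMention(
                    id=f"{sid}.e{m}",
                    char_start=start,
                    char_end=end + 1,
                    text=name,
                    drug_name=name,
                )
            )
        pair_attrs = {
            "id": f"{sid}.p0",
            "e1": f"{sid}.e0",
            "e2": f"{sid}.e1",
            "ddi": "true" if label != "False" else "false",
        }
        if label != "False":
            pair_attrs["type"] = label.lower()
        etree.SubElement(sent, "pair", **pair_attrs)
        gold.append(mask_drugs(text, mentions, (mentions[0], mentions[1]), label))

    xml_bytes = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if xml_path is not None:
        with open(xml_path, "wb") as fh:
            fh.write(xml_bytes)
    return xml_bytes.decode("utf-8"), gold


def generate_drug_table(
    n_drugs: int,
    seed: int = 0,
    omit_frac: float = 0.0,
    tsv_path=None,
) -> dict:
    """Name -> SMILES table over the synthetic drug lexicon.

    A fraction ``omit_frac`` of names is left out of the table to
    exercise the unknown-structure path.  Returns the mapping; writes a
    two-column TSV if ``tsv_path`` is given.
    """
    if n_drugs < 1:
        raise ValueError("need n_drugs >= 1")
    rng = np.random.default_rng(seed)
    names = drug_lexicon(n_drugs)
    smiles_choices = [
        SMILES_LIBRARY[i % len(SMILES_LIBRARY)]
        for i in rng.permutation(max(n_drugs, len(SMILES_LIBRARY)))[:n_drugs]
    ]
    n_omit = int(round(omit_frac * n_drugs))
    omitted = set(rng.choice(n_drugs, size=n_omit, replace=False).tolist())
    table = {
        name: smi
        for i, (name, smi) in enumerate(zip(names, smiles_choices))
        if i not in omitted
    }
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("name\tsmiles\n")
            for name, smi in table.items():
                fh.write(f"{name}\t{smi}\n")
    return table
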