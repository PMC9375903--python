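"""Corpus handling for sentence-level drug-drug interaction candidates.

Reads the DDIExtraction-2013 XML dialect (documents > sentences > entity
mentions with character offsets > candidate pairs), masks the drug
mentions of each candidate pair (DRUG1 / DRUG2, remaining mentions
DRUGOTHER), and rebalances training sets by duplicate-negative removal
and seeded positive over-sampling.

Conventions
-----------
* Character offsets are 0-based half-open internally.  The corpus dialect
  stores inclusive offsets ("start-end"); the parser converts at the
  boundary.  Discontinuous mentions (";"-separated offsets) are rejected
  with a warning.
* Candidate pairs are unordered: DRUG1 is always the mention with the
  earlier offset.
* Tokenisation for span bookkeeping is whitespace-based on the masked
  sentence string; placeholders are padded with spaces so they always
  form standalone tokens.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "LABELS",
    "POSITIVE_LABELS",
    "EntityMention",
    "LabeledInstance",
    "SentenceRecord",
    "CorpusParseError",
    "CorpusValidationError",
    "parse_corpus",
    "corpus_to_instances",
    "mask_drugs",
    "undersample_negatives",
    "oversample_positives",
    "between_entity_statistic",
    "write_jsonl",
    "read_jsonl",
    "load_drug_table",
]

LABELS = ("Mechanism", "Effect", "Advice", "Int", "False")
POSITIVE_LABELS = ("Mechanism", "Effect", "Advice", "Int")

#: corpus `type` attribute -> canonical label (the shared task spells "advise")
_TYPE_MAP = {
    "mechanism": "Mechanism",
    "effect": "Effect",
    "advice": "Advice",
    "advise": "Advice",
    "int": "Int",
}

PLACEHOLDERS = ("DRUG1", "DRUG2", "DRUGOTHER")


class CorpusParseError(ValueError):
    """Malformed XML or missing required attributes."""


class CorpusValidationError(ValueError):
    """Structurally valid XML whose content violates corpus invariants."""


@dataclass(frozen=True)
class EntityMention:
    id: str
    char_start: int  # 0-based, inclusive
    char_end: int  # 0-based, exclusive
    text: str
    drug_name: str

    def validate(self, sentence_text: str, sentence_id: str = "?") -> None:
        if not (0 <= self.char_start < self.char_end <= len(sentence_text)):
            raise CorpusValidationError(
                f"entity {self.id}: offsets [{self.char_start},{self.char_end}) "
                f"outside sentence {sentence_id!r}"
            )
        got = sentence_text[self.char_start : self.char_end]
        if got != self.text:
            raise CorpusValidationError(
                f"entity {self.id} in sentence {sentence_id!r}: annotated text "
                f"{self.text!r} != sentence slice {got!r}"
            )


@dataclass(frozen=True)
class LabeledInstance:
    tokens: tuple
    j: int
    k: int
    label: str
    drug1_name: str
    drug2_name: str

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if not (0 <= self.j < self.k < len(self.tokens)):
            raise ValueError("need 0 <= j < k < len(tokens)")
        if self.tokens[self.j] != "DRUG1" or self.tokens[self.k] != "DRUG2":
            raise ValueError("tokens[j] must be DRUG1 and tokens[k] DRUG2")


@dataclass
class SentenceRecord:
    sentence_id: str
    text: str
    mentions: list = field(default_factory=list)
    #: (e1_id, e2_id, label) triples
    pairs: list = field(default_factory=list)


def _parse_offsets(raw: str) -> tuple[int, int]:
    start_s, _, end_s = raw.partition("-")
    return int(start_s), int(end_s) + 1  # inclusive -> half-open


def parse_corpus(xml_path) -> list[SentenceRecord]:
    """Parse a DDI-2013-dialect XML file into sentence records.

    Pairs with ``ddi="false"`` get label ``"False"``; typed pairs map
    through the shared-task type names.  Entity offsets are validated
    against the sentence text; a pair referencing an unknown entity id
    raises :class:`CorpusValidationError`.
    """
    try:
        tree = etree.parse(str(xml_path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML in {xml_path}: {exc}") from exc

    records = []
    for sent in tree.iter("sentence"):
        sid = sent.get("id", "?")
        text = sent.get("text", "")
        record = SentenceRecord(sentence_id=sid, text=text)
        known = {}
        for ent in sent.iter("entity"):
            raw_off = ent.get("charOffset", "")
            if ";" in raw_off:
                warnings.warn(
                    f"sentence {sid}: discontinuous mention {ent.get('id')} "
                    f"({raw_off!r}) skipped"
                )
                continue
            start, end = _parse_offsets(raw_off)
            mention = EntityMention(
                id=ent.get("id", ""),
                char_start=start,
                char_end=end,
                text=ent.get("text", ""),
                drug_name=ent.get("text", ""),
            )
            mention.validate(text, sid)
            known[mention.id] = mention
            record.mentions.append(mention)
        for pair in sent.iter("pair"):
            e1, e2 = pair.get("e1"), pair.get("e2")
            for eid in (e1, e2):
                if eid not in known:
                    raise CorpusValidationError(
                        f"sentence {sid}: pair {pair.get('id')} references "
                        f"unknown entity {eid!r}"
                    )
            if pair.get("ddi", "false").lower() == "true":
                raw_type = pair.get("type", "").lower()
                if raw_type not in _TYPE_MAP:
                    raise CorpusValidationError(
                        f"sentence {sid}: pair {pair.get('id')} has "
                        f"unknown interaction type {raw_type!r}"
                    )
                label = _TYPE_MAP[raw_type]
            else:
                label = "False"
            record.pairs.append((e1, e2, label))
        records.append(record)
    return records


def corpus_to_instances(records: Iterable[SentenceRecord]) -> list[LabeledInstance]:
    """Mask every candidate pair of every sentence into a LabeledInstance."""
    out = []
    for rec in records:
        by_id = {m.id: m for m in rec.mentions}
        for e1, e2, label in rec.pairs:
            out.append(
                mask_drugs(rec.text, rec.mentions, (by_id[e1], by_id[e2]), label)
            )
    return out


def mask_drugs(
    sentence_text: str,
    mentions: Sequence[EntityMention],
    target_pair: tuple,
    label: str = "False",
) -> LabeledInstance:
    """Replace the target pair by DRUG1/DRUG2 and other mentions by DRUGOTHER.

    DRUG1 is the target mention with the earlier character offset.  The
    masked string is whitespace-tokenised; placeholder positions j < k are
    recorded.  Overlapping mentions or a degenerate pair raise ValueError.
    """
    t1, t2 = target_pair
    if t1 == t2 or (t1.char_start, t1.char_end) == (t2.char_start, t2.char_end):
        raise ValueError("target pair must be two distinct mentions")
    for placeholder in PLACEHOLDERS:
        if placeholder in sentence_text.split():
            raise ValueError("sentence already contains mask placeholders")
    ordered = sorted(mentions, key=lambda m: (m.char_start, m.char_end))
    for a, b in zip(ordered, ordered[1:]):
        if b.char_start < a.char_end:
            raise CorpusValidationError(
                f"overlapping mentions {a.id} and {b.id}"
            )
    first, second = sorted([t1, t2], key=lambda m: m.char_start)

    pieces, cursor = [], 0
    for m in ordered:
        if m == first:
            repl = "DRUG1"
        elif m == second:
            repl = "DRUG2"
        else:
            repl = "DRUGOTHER"
        pieces.append(sentence_text[cursor : m.char_start])
        pieces.append(f" {repl} ")  # padding keeps placeholders atomic tokens
        cursor = m.char_end
    pieces.append(sentence_text[cursor:])
    tokens = "".join(pieces).split()
    j = tokens.index("DRUG1")
    k = tokens.index("DRUG2")
    return LabeledInstance(
        tokens=tuple(tokens),
        j=j,
        k=k,
        label=label,
        drug1_name=first.drug_name,
        drug2_name=second.drug_name,
    )


def undersample_negatives(instances: Sequence[LabeledInstance]) -> list[LabeledInstance]:
    """Drop duplicate negatives (identical masked token sequences).

    The first occurrence of each negative token sequence is kept; positives
    and relative order are untouched.  Idempotent.
    """
    seen = set()
    out = []
    for inst in instances:
        if inst.label == "False":
            if inst.tokens in seen:
                continue
            seen.add(inst.tokens)
        out.append(inst)
    return out


def oversample_positives(
    instances: Sequence[LabeledInstance],
    target_ratio: float,
    seed: int,
) -> list[LabeledInstance]:
    """Upsample sparse positive classes by seeded sampling with replacement.

    Each positive class is grown until its count reaches at least
    ``target_ratio`` times the count of the largest class (negatives
    included).  Originals keep their order; duplicates are appended.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    counts = {lab: 0 for lab in LABELS}
    for inst in instances:
        counts[inst.label] += 1
    largest = max(counts.values(), default=0)
    target = target_ratio * largest
    rng = np.random.default_rng(seed)
    out = list(instances)
    for lab in POSITIVE_LABELS:
        pool = [inst for inst in instances if inst.label == lab]
        if counts[lab] >= target:
            continue
        if not pool:
            warnings.warn(f"class {lab} has no instances; skipped in oversampling")
            continue
        need = int(np.ceil(target - counts[lab]))
        picks = rng.integers(0, len(pool), size=need)
        out.extend(pool[i] for i in picks)
    return out


def between_entity_statistic(
    instances: Sequence[LabeledInstance],
    trigger_lexicon: Iterable[str],
) -> dict:
    """Per positive label: fraction of instances whose trigger tokens all
    lie strictly between the entity pair.

    Instances with no trigger token anywhere count as satisfying the
    condition (vacuous truth).  Labels with no positive instances get NaN.
    """
    lexicon = set(trigger_lexicon)
    hits = {lab: 0 for lab in POSITIVE_LABELS}
    totals = {lab: 0 for lab in POSITIVE_LABELS}
    for inst in instances:
        if inst.label not in hits:
            continue
        totals[inst.label] += 1
        positions = [i for i, tok in enumerate(inst.tokens) if tok in lexicon]
        if all(inst.j < i < inst.k for i in positions):
            hits[inst.label] += 1
    out = {}
    for lab in POSITIVE_LABELS:
        if totals[lab] == 0:
            warnings.warn(f"no positive instances with label {lab}")
            out[lab] = float("nan")
        else:
            out[lab] = hits[lab] / totals[lab]
    return out


# ---------------------------------------------------------------------
# serialisation

def write_jsonl(instances: Iterable[LabeledInstance], path) -> None:
    with open(path, "w") as fh:
        for inst in instances:
            rec = asdict(inst)
            rec["tokens"] = list(rec["tokens"])
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> list[LabeledInstance]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(LabeledInstance(**json.loads(line)))
    return out


def load_drug_table(path) -> dict:
    """Read a two-column name->SMILES TSV with header ``name\\tsmiles``."""
    table = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "smiles"]:
            raise ValueError(f"unexpected drug-table header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, smiles = line.split("\t")[:2]
            table[name] = smiles
    return table
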