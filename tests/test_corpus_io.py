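"""Corpus parsing, drug masking, re-sampling and serialisation."""

import warnings

import numpy as np
import pytest

from ddirel import corpus_io as cio
from ddirel.corpus_io import EntityMention, LabeledInstance


def make_instance(tokens, label="False", d1="a", d2="b"):
    tokens = list(tokens)
    return LabeledInstance(
        tokens=tokens,
        j=tokens.index("DRUG1"),
        k=tokens.index("DRUG2"),
        label=label,
        drug1_name=d1,
        drug2_name=d2,
    )


# ---------------------------------------------------------------- parsing

def test_parse_toy_corpus_labels(toy_xml):
    records = cio.parse_corpus(toy_xml)
    assert len(records) == 1
    rec = records[0]
    assert len(rec.mentions) == 3
    assert [label for _, _, label in rec.pairs] == ["Effect", "False", "False"]
    instances = cio.corpus_to_instances(records)
    assert [inst.label for inst in instances] == ["Effect", "False", "False"]


def test_parse_missing_entity_reference(tmp_path, toy_xml):
    bad = toy_xml.read_text().replace('e2="d1.s0.e2"', 'e2="d1.s0.e9"')
    path = tmp_path / "bad.xml"
    path.write_text(bad)
    with pytest.raises(cio.CorpusValidationError, match="unknown entity"):
        cio.parse_corpus(path)


def test_parse_offset_mismatch_names_sentence(tmp_path, toy_xml):
    bad = toy_xml.read_text().replace('text="alosetron"', 'text="alosetran"')
    path = tmp_path / "bad.xml"
    path.write_text(bad)
    with pytest.raises(cio.CorpusValidationError, match="d1.s0"):
        cio.parse_corpus(path)


def test_parse_malformed_xml(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<corpus><document>")
    with pytest.raises(cio.CorpusParseError):
        cio.parse_corpus(path)


def test_parse_empty_document_list(tmp_path):
    path = tmp_path / "empty.xml"
    path.write_text("<corpus></corpus>")
    assert cio.parse_corpus(path) == []


def test_discontinuous_mention_skipped_with_warning(tmp_path, toy_xml):
    bad = toy_xml.read_text().replace('charOffset="19-27"', 'charOffset="19-22;24-27"')
    # drop the pair that references the now-skipped entity
    bad = "\n".join(line for line in bad.splitlines() if "p1" not in line and "p2" not in line)
    path = tmp_path / "disc.xml"
    path.write_text(bad)
    with pytest.warns(UserWarning, match="discontinuous"):
        records = cio.parse_corpus(path)
    assert len(records[0].mentions) == 2


# ---------------------------------------------------------------- masking

def test_mask_drugs_overlapping_relations_example(toy_xml):
    rec = cio.parse_corpus(toy_xml)[0]
    by_id = {m.id: m for m in rec.mentions}
    inst = cio.mask_drugs(
        rec.text, rec.mentions, (by_id["d1.s0.e0"], by_id["d1.s0.e2"]), "Effect"
    )
    assert list(inst.tokens) == ["DRUG1", "inhibits", "DRUGOTHER", "and", "DRUG2"]
    assert (inst.j, inst.k) == (0, 4)
    assert (inst.drug1_name, inst.drug2_name) == ("alosetron", "procainamide")


def test_mask_two_mentions_no_drugother():
    text = "aspirin boosts warfarin"
    m = [
        EntityMention("e0", 0, 7, "aspirin", "aspirin"),
        EntityMention("e1", 15, 23, "warfarin", "warfarin"),
    ]
    inst = cio.mask_drugs(text, m, (m[0], m[1]), "Mechanism")
    assert "DRUGOTHER" not in inst.tokens
    assert list(inst.tokens) == ["DRUG1", "boosts", "DRUG2"]


def test_mask_order_normalised_against_sorting_oracle():
    text = "aspirin boosts warfarin badly"
    m = [
        EntityMention("e0", 0, 7, "aspirin", "aspirin"),
        EntityMention("e1", 15, 23, "warfarin", "warfarin"),
    ]
    # target supplied in reverse offset order must give identical output
    fwd = cio.mask_drugs(text, m, (m[0], m[1]))
    rev = cio.mask_drugs(text, list(reversed(m)), (m[1], m[0]))
    assert fwd == rev
    assert fwd.tokens[fwd.j] == "DRUG1" and fwd.j < fwd.k


def test_mask_rejects_overlap_and_degenerate_pair():
    text = "aspirin boosts warfarin"
    a = EntityMention("e0", 0, 7, "aspirin", "aspirin")
    b = EntityMention("e1", 3, 10, "irin bo", "x")
    c = EntityMention("e2", 15, 23, "warfarin", "warfarin")
    with pytest.raises(cio.CorpusValidationError, match="overlap"):
        cio.mask_drugs(text, [a, b, c], (a, c))
    with pytest.raises(ValueError, match="distinct"):
        cio.mask_drugs(text, [a, c], (a, a))


def test_mask_is_not_applied_twice():
    text = "DRUG1 boosts DRUG2"
    m = [
        EntityMention("e0", 0, 5, "DRUG1", "a"),
        EntityMention("e1", 13, 18, "DRUG2", "b"),
    ]
    with pytest.raises(ValueError, match="placeholder"):
        cio.mask_drugs(text, m, (m[0], m[1]))


def test_mask_token_count_matches_whitespace_tokenisation():
    text = "x aspirin, boosts warfarin."
    m = [
        EntityMention("e0", 2, 9, "aspirin", "aspirin"),
        EntityMention("e1", 18, 26, "warfarin", "warfarin"),
    ]
    inst = cio.mask_drugs(text, m, (m[0], m[1]))
    # punctuation survives as separate-or-attached tokens; count equals
    # whitespace-token count of the masked string it was built from
    rebuilt = " ".join(inst.tokens)
    assert len(inst.tokens) == len(rebuilt.split())
    assert inst.tokens[inst.j] == "DRUG1" and inst.tokens[inst.k] == "DRUG2"


# ---------------------------------------------------------------- resampling

def test_undersample_brute_force_oracle():
    negs = [
        make_instance(["DRUG1", "x", "DRUG2"]),
        make_instance(["DRUG1", "y", "DRUG2"]),
        make_instance(["DRUG1", "x", "DRUG2"]),  # duplicate of first
        make_instance(["DRUG1", "z", "DRUG2"]),
    ]
    out = cio.undersample_negatives(negs)
    # oracle: first-occurrence dedupe on token tuples
    seen, expected = set(), []
    for inst in negs:
        if inst.tokens not in seen:
            seen.add(inst.tokens)
            expected.append(inst)
    assert out == expected
    assert len(out) == 3


def test_undersample_identity_on_positives_and_idempotent():
    pos = [make_instance(["DRUG1", "x", "DRUG2"], label="Effect")] * 3
    assert cio.undersample_negatives(pos) == pos
    mixed = pos + [make_instance(["DRUG1", "q", "DRUG2"])] * 2
    once = cio.undersample_negatives(mixed)
    assert cio.undersample_negatives(once) == once


def test_undersample_identity_defined_on_tokens_only():
    a = make_instance(["DRUG1", "x", "DRUG2"], d1="aspirin")
    b = make_instance(["DRUG1", "x", "DRUG2"], d1="warfarin")
    assert len(cio.undersample_negatives([a, b])) == 1


def test_oversample_count_oracle():
    insts = [make_instance(["DRUG1", f"a{i}", "DRUG2"], label="Effect") for i in range(10)]
    insts += [make_instance(["DRUG1", f"b{i}", "DRUG2"], label="Int") for i in range(2)]
    out = cio.oversample_positives(insts, 0.5, seed=3)
    counts = {lab: sum(1 for x in out if x.label == lab) for lab in ("Effect", "Int")}
    assert counts["Int"] >= 5
    assert counts["Effect"] == 10  # already above target
    # negatives untouched
    assert sum(1 for x in out if x.label == "False") == 0


def test_oversample_noop_when_target_met_and_deterministic():
    insts = [make_instance(["DRUG1", f"a{i}", "DRUG2"], label="Effect") for i in range(4)]
    insts += [make_instance(["DRUG1", f"b{i}", "DRUG2"], label="Int") for i in range(4)]
    assert cio.oversample_positives(insts, 0.1, seed=0) == insts
    grown1 = cio.oversample_positives(insts + [make_instance(["DRUG1", "z", "DRUG2"])] * 8, 0.9, seed=5)
    grown2 = cio.oversample_positives(insts + [make_instance(["DRUG1", "z", "DRUG2"])] * 8, 0.9, seed=5)
    assert grown1 == grown2


def test_oversample_never_touches_negatives_property():
    rng = np.random.default_rng(0)
    insts = []
    for i in range(30):
        lab = ["False", "Effect", "Int"][int(rng.integers(3))]
        insts.append(make_instance(["DRUG1", f"w{i}", "DRUG2"], label=lab))
    out = cio.oversample_positives(insts, 0.8, seed=1)
    assert [x for x in out if x.label == "False"] == [x for x in insts if x.label == "False"]


# ---------------------------------------------------------------- statistics

def test_between_statistic_hand_count():
    insts = [
        make_instance(["DRUG1", "trig", "DRUG2"], label="Effect"),
        make_instance(["trig", "DRUG1", "x", "DRUG2"], label="Effect"),
        make_instance(["DRUG1", "x", "DRUG2"], label="Mechanism"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = cio.between_entity_statistic(insts, {"trig"})
    assert stats["Effect"] == pytest.approx(0.5)
    assert stats["Mechanism"] == pytest.approx(1.0)  # vacuous: no trigger present
    assert np.isnan(stats["Advice"])


# ---------------------------------------------------------------- round-trip

def test_jsonl_round_trip(tmp_path, toy_xml):
    instances = cio.corpus_to_instances(cio.parse_corpus(toy_xml))
    path = tmp_path / "inst.jsonl"
    cio.write_jsonl(instances, path)
    back = cio.read_jsonl(path)
    assert back == instances


def test_drug_table_round_trip(tmp_path):
    path = tmp_path / "drugs.tsv"
    path.write_text("name\tsmiles\naspirin\tCC(=O)Oc1ccccc1C(=O)O\n")
    table = cio.load_drug_table(path)
    assert table == {"aspirin": "CC(=O)Oc1ccccc1C(=O)O"}
    (tmp_path / "bad.tsv").write_text("drug\tsmiles\n")
    with pytest.raises(ValueError, match="header"):
        cio.load_drug_table(tmp_path / "bad.tsv")
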