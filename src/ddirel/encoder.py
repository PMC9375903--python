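"""Sentence encoders: masked token sequence -> context matrix H^seq.

Two implementations of one contract:

* :class:`TinyTransformerEncoder` -- a small trainable transformer
  (learned word + position embeddings, post-LN multi-head self-attention
  blocks) whose vocabulary is built from the corpus.  Word-level tokens
  map one-to-one onto rows, so it trains end-to-end on a CPU in minutes.
* :class:`PretrainedEncoderAdapter` -- wraps any pretrained model
  exposing a huggingface-style ``tokenizer`` and last-hidden-state
  callable, mapping word positions to first-subtoken rows.

Both return an :class:`EncodedSentence`: an n-by-d matrix whose rows
include the start/end marker positions, the pooled first-token vector,
and a word -> first-subtoken-row map.  The entity placeholders DRUG1,
DRUG2 and DRUGOTHER are registered as atomic vocabulary items and are
never split, so span remapping is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import nn

__all__ = [
    "EncodedSentence",
    "TinyTransformerEncoder",
    "PretrainedEncoderAdapter",
    "remap_span",
]

CLS, SEP, UNK = "[CLS]", "[SEP]", "[UNK]"
SPECIALS = (CLS, SEP, UNK, "DRUG1", "DRUG2", "DRUGOTHER")


@dataclass
class EncodedSentence:
    h_seq: np.ndarray  # n_rows x d, rows 0 and n-1 are the markers
    pooled: np.ndarray  # first-token row
    subtoken_map: list  # word index -> first-subtoken row index
    input_ids: list

    @property
    def n_rows(self) -> int:
        return self.h_seq.shape[0]


def remap_span(subtoken_map: Sequence[int], j: int, k: int, n_rows: int):
    """Word-level span (j, k) -> sub-token row span (j', k').

    j' is the first sub-token row of word j; k' the last sub-token row of
    word k (i.e. the row before word k+1's first sub-token, or the row
    before the end marker for the final word).
    """
    if not (0 <= j <= k < len(subtoken_map)):
        raise IndexError(f"word span ({j}, {k}) outside map of {len(subtoken_map)} words")
    j_row = subtoken_map[j]
    k_row = subtoken_map[k + 1] - 1 if k + 1 < len(subtoken_map) else n_rows - 2
    if j_row >= n_rows - 1 or k_row >= n_rows - 1:
        raise ValueError("span words were truncated away")
    if j_row > k_row:
        raise ValueError("inconsistent sub-token map")
    return j_row, k_row


class TinyTransformerEncoder:
    """Desk-scale trainable transformer encoder (1 sub-token per word)."""

    def __init__(
        self,
        vocab: dict,
        d: int = 32,
        n_layers: int = 2,
        n_heads: int = 2,
        d_ff: int = 64,
        max_len: int = 256,
        seed: int = 0,
    ):
        if d % n_heads:
            raise ValueError("d must be divisible by n_heads")
        for special in SPECIALS:
            if special not in vocab:
                raise ValueError(f"vocabulary missing special token {special!r}")
        self.vocab = dict(vocab)
        self.d = d
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        self.tok_emb = nn.parameter(rng, (len(vocab), d), scale=0.1)
        self.pos_emb = nn.parameter(rng, (max_len, d), scale=0.1)
        self.layers = []
        for _ in range(n_layers):
            layer = {
                "wq": [nn.parameter(rng, (d, self.d_head)) for _ in range(n_heads)],
                "wk": [nn.parameter(rng, (d, self.d_head)) for _ in range(n_heads)],
                "wv": [nn.parameter(rng, (d, self.d_head)) for _ in range(n_heads)],
                "wo": nn.parameter(rng, (d, d)),
                "ln1_g": nn.Tensor(np.ones(d), requires_grad=True),
                "ln1_b": nn.zeros_param((d,)),
                "w1": nn.parameter(rng, (d, d_ff), scale=0.05),
                "b1": nn.zeros_param((d_ff,)),
                "w2": nn.parameter(rng, (d_ff, d), scale=0.05),
                "b2": nn.zeros_param((d,)),
                "ln2_g": nn.Tensor(np.ones(d), requires_grad=True),
                "ln2_b": nn.zeros_param((d,)),
            }
            self.layers.append(layer)

    @classmethod
    def from_corpus(cls, instances: Iterable, **kwargs) -> "TinyTransformerEncoder":
        vocab = {tok: i for i, tok in enumerate(SPECIALS)}
        for inst in instances:
            for tok in inst.tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        return cls(vocab, **kwargs)

    @property
    def params(self) -> list:
        out = [self.tok_emb, self.pos_emb]
        for layer in self.layers:
            out.extend(layer["wq"] + layer["wk"] + layer["wv"])
            out.extend(
                layer[key]
                for key in ("wo", "ln1_g", "ln1_b", "w1", "b1", "w2", "b2",
                            "ln2_g", "ln2_b")
            )
        return out

    # -- tokenisation --------------------------------------------------
    def input_ids(self, tokens: Sequence[str]):
        if len(tokens) == 0:
            raise ValueError("empty token sequence")
        words = list(tokens)
        if len(words) + 2 > self.max_len:
            kept = self.max_len - 2
            dropped = set(words[kept:])
            if "DRUG1" in dropped or "DRUG2" in dropped:
                if "DRUG1" not in words[:kept] or "DRUG2" not in words[:kept]:
                    raise ValueError(
                        "truncation would drop an entity placeholder"
                    )
            warnings.warn(f"sequence truncated to {kept} words")
            words = words[:kept]
        unk = self.vocab[UNK]
        ids = [self.vocab[CLS]]
        subtoken_map = []
        for word in words:
            subtoken_map.append(len(ids))
            ids.append(self.vocab.get(word, unk))
        ids.append(self.vocab[SEP])
        return ids, subtoken_map

    # -- forward -------------------------------------------------------
    def forward(self, tokens: Sequence[str]):
        """Differentiable encoding: (H_seq tensor, subtoken_map, input_ids)."""
        ids, subtoken_map = self.input_ids(tokens)
        x = self.tok_emb.take(ids) + self.pos_emb.take(list(range(len(ids))))
        scale = 1.0 / np.sqrt(self.d_head)
        for layer in self.layers:
            heads = []
            for h in range(self.n_heads):
                q = x @ layer["wq"][h]
                k = x @ layer["wk"][h]
                v = x @ layer["wv"][h]
                att = nn.softmax((q @ k.T) * scale, axis=-1)
                heads.append(att @ v)
            attended = nn.concat(heads, axis=1) @ layer["wo"]
            x = nn.layer_norm(x + attended, layer["ln1_g"], layer["ln1_b"])
            ff = ((x @ layer["w1"] + layer["b1"]).relu()) @ layer["w2"] + layer["b2"]
            x = nn.layer_norm(x + ff, layer["ln2_g"], layer["ln2_b"])
        return x, subtoken_map, ids

    def encode(self, tokens: Sequence[str]) -> EncodedSentence:
        """Contract entry point: numpy snapshot of the current parameters."""
        h, subtoken_map, ids = self.forward(tokens)
        h_np = h.data.copy()
        return EncodedSentence(
            h_seq=h_np, pooled=h_np[0], subtoken_map=subtoken_map, input_ids=ids
        )


class PretrainedEncoderAdapter:
    """Adapter for a pretrained transformer (huggingface-style duck type).

    ``tokenizer`` must provide ``tokenize(word) -> list[str]`` and
    ``convert_tokens_to_ids(list[str]) -> list[int]`` plus
    ``cls_token``/``sep_token`` attributes; ``model`` must be a callable
    mapping a list of input ids to the last hidden state (n x d array).
    Placeholder words are registered as atomic: they are never passed to
    the sub-word tokenizer.
    """

    def __init__(self, tokenizer, model, max_len: int = 256):
        self.tokenizer = tokenizer
        self.model = model
        self.max_len = max_len

    def encode(self, tokens: Sequence[str]) -> EncodedSentence:
        if len(tokens) == 0:
            raise ValueError("empty token sequence")
        pieces = [self.tokenizer.cls_token]
        subtoken_map = []
        for word in tokens:
            subtoken_map.append(len(pieces))
            if word in ("DRUG1", "DRUG2", "DRUGOTHER"):
                pieces.append(word)
            else:
                pieces.extend(self.tokenizer.tokenize(word))
        pieces.append(self.tokenizer.sep_token)
        if len(pieces) > self.max_len:
            raise ValueError("sequence exceeds adapter maximum length")
        ids = self.tokenizer.convert_tokens_to_ids(pieces)
        h = np.asarray(self.model(ids), dtype=float)
        if h.shape[0] != len(ids):
            raise ValueError("model returned wrong number of rows")
        return EncodedSentence(
            h_seq=h, pooled=h[0], subtoken_map=subtoken_map, input_ids=ids
        )
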