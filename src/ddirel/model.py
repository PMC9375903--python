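"""Fused relation classifier for drug-drug interaction candidates.

:class:`DDIModel` is built from labelled instances (plus an optional
name->SMILES table) and :meth:`DDIModel.fit` trains the full stack --
tiny transformer encoder, fixed interaction/entities attention priors
with their affine heads, shared molecular MGNN encoder, and a softmax
classifier over the fused feature vector

    H = concat[H^pooled; H^interaction; H^entities; H^mol1; H^mol2]

with cross-entropy loss.  ``fit`` returns a :class:`DDIResults` object
carrying the trained parameters, the loss curve, prediction and
evaluation methods and a text ``summary()``.

Evaluation follows the SemEval-2013 task 9.2 convention: precision,
recall and F1 = 2PR/(P+R) per class, micro-averaged by pooling
TP/FP/FN over the four positive classes (False excluded); macro
averages are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .corpus_io import (
    LABELS,
    POSITIVE_LABELS,
    LabeledInstance,
    oversample_positives,
    undersample_negatives,
)
from .encoder import TinyTransformerEncoder, remap_span
from .entities_attention import (
    DEFAULT_LEFT,
    DEFAULT_RIGHT,
    DistributionSpec,
    build_entities_vector,
)
from .interaction_attention import WeightRanges, build_interaction_vector
from .molecular import FingerprintVocabulary, MGNNEncoder

__all__ = [
    "DDIConfig",
    "DDIModel",
    "DDIResults",
    "EvalReport",
    "fuse",
    "classify",
    "evaluate",
    "ablate",
    "kfold_indices",
]

_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


# ---------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DDIConfig:
    # encoder
    d: int = 32
    n_layers: int = 2
    n_heads: int = 2
    d_ff: int = 64
    max_len: int = 256
    # molecular
    d_m: int = 64
    mgnn_steps: int = 2
    fingerprint_radius: int = 1
    # attention priors
    ranges: WeightRanges = field(default_factory=WeightRanges)
    interaction_mode: str = "midpoint"
    interaction_seed: int = 13
    spec_left: DistributionSpec = DEFAULT_LEFT
    spec_right: DistributionSpec = DEFAULT_RIGHT
    before_frac: float = 0.15
    after_frac: float = 0.25
    baseline: float = 0.05
    # feature blocks
    use_pooled: bool = True
    use_interaction: bool = True
    use_entities: bool = True
    use_molecular: bool = True
    # optimisation
    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 8
    undersample: bool = True
    oversample_ratio: float = 0.3

    def __post_init__(self):
        if not (self.use_pooled or self.use_interaction or self.use_entities
                or self.use_molecular):
            raise ValueError("at least one feature block must be enabled")

    @property
    def fused_dim(self) -> int:
        return 3 * self.d + 2 * self.d_m


# ---------------------------------------------------------------------
# stateless operations

def fuse(pooled, interaction_feat, entities_feat, mol1, mol2) -> np.ndarray:
    """Concatenate the five feature blocks in their fixed order."""
    blocks = {
        "pooled": pooled,
        "interaction": interaction_feat,
        "entities": entities_feat,
        "mol1": mol1,
        "mol2": mol2,
    }
    arrays = []
    d = np.asarray(pooled).shape
    d_m = np.asarray(mol1).shape
    expected = {"pooled": d, "interaction": d, "entities": d,
                "mol1": d_m, "mol2": d_m}
    for name, block in blocks.items():
        arr = np.asarray(block, dtype=float)
        if arr.ndim != 1 or arr.shape != expected[name]:
            raise ValueError(f"feature block {name!r} has shape {arr.shape}")
        arrays.append(arr)
    return np.concatenate(arrays)


def classify(h: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stabilised softmax over the affine map W h + b (5 classes)."""
    logits = np.asarray(w, dtype=float) @ np.asarray(h, dtype=float) + np.asarray(b)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class ClassScores:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class EvalReport:
    per_class: dict
    micro: ClassScores
    macro: ClassScores

    def summary(self) -> str:
        lines = [f"{'class':<12}{'P':>8}{'R':>8}{'F1':>8}{'n':>6}"]
        for lab in POSITIVE_LABELS:
            s = self.per_class[lab]
            lines.append(
                f"{lab:<12}{s.precision:>8.3f}{s.recall:>8.3f}{s.f1:>8.3f}{s.support:>6d}"
            )
        lines.append(
            f"{'micro':<12}{self.micro.precision:>8.3f}{self.micro.recall:>8.3f}"
            f"{self.micro.f1:>8.3f}{self.micro.support:>6d}"
        )
        lines.append(
            f"{'macro':<12}{self.macro.precision:>8.3f}{self.macro.recall:>8.3f}"
            f"{self.macro.f1:>8.3f}{self.macro.support:>6d}"
        )
        return "\n".join(lines)


def _prf(tp: int, fp: int, fn: int) -> tuple:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate(predictions: Sequence[str], gold: Sequence[str]) -> EvalReport:
    """Per-class and pooled precision/recall/F1 over the positive classes."""
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    for lab in list(predictions) + list(gold):
        if lab not in _LABEL_INDEX:
            raise ValueError(f"unknown label {lab!r}")
    per_class = {}
    tp_sum = fp_sum = fn_sum = 0
    for lab in POSITIVE_LABELS:
        tp = sum(1 for p, g in zip(predictions, gold) if p == lab and g == lab)
        fp = sum(1 for p, g in zip(predictions, gold) if p == lab and g != lab)
        fn = sum(1 for p, g in zip(predictions, gold) if p != lab and g == lab)
        support = sum(1 for g in gold if g == lab)
        p, r, f1 = _prf(tp, fp, fn)
        per_class[lab] = ClassScores(p, r, f1, support)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
    p, r, f1 = _prf(tp_sum, fp_sum, fn_sum)
    micro = ClassScores(p, r, f1, sum(s.support for s in per_class.values()))
    macro = ClassScores(
        float(np.mean([s.precision for s in per_class.values()])),
        float(np.mean([s.recall for s in per_class.values()])),
        float(np.mean([s.f1 for s in per_class.values()])),
        micro.support,
    )
    return EvalReport(per_class=per_class, micro=micro, macro=macro)


def kfold_indices(n: int, k: int, seed: int) -> list:
    """Seeded k-fold split: list of (train_indices, test_indices)."""
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[jj] for jj in range(k) if jj != i]))
        out.append((train, test))
    return out


# ---------------------------------------------------------------------
# the model

class DDIModel:
    """Relation classifier over labelled DDI candidate instances.

    Parameters
    ----------
    instances : training split (already parsed and masked)
    drug_smiles : optional name -> SMILES mapping for the molecular block
    config : :class:`DDIConfig`
    """

    def __init__(
        self,
        instances: Sequence[LabeledInstance],
        drug_smiles: dict | None = None,
        config: DDIConfig | None = None,
    ):
        if len(instances) == 0:
            raise ValueError("empty training set")
        self.instances = list(instances)
        self.drug_smiles = dict(drug_smiles or {})
        self.config = config or DDIConfig()
        self.encoder: TinyTransformerEncoder | None = None
        self.mol_encoder: MGNNEncoder | None = None
        self.heads: dict = {}
        self._prior_cache: dict = {}

    # -- construction of trainable state -------------------------------
    def _initialise(self, seed: int):
        cfg = self.config
        self.encoder = TinyTransformerEncoder.from_corpus(
            self.instances,
            d=cfg.d,
            n_layers=cfg.n_layers,
            n_heads=cfg.n_heads,
            d_ff=cfg.d_ff,
            max_len=cfg.max_len,
            seed=seed,
        )
        vocab = FingerprintVocabulary(radius=cfg.fingerprint_radius)
        self.mol_encoder = MGNNEncoder(
            vocab,
            d_m=cfg.d_m,
            n_steps=cfg.mgnn_steps,
            seed=seed + 1,
        )
        # build the fingerprint vocabulary up front from the drug table
        for smiles in self.drug_smiles.values():
            try:
                self.mol_encoder._prepare(smiles, train=True)
            except ValueError:
                warnings.warn(f"unparsable SMILES in drug table: {smiles!r}")
        rng = np.random.default_rng(seed + 2)
        d, d_m = cfg.d, cfg.d_m
        self.heads = {
            "w_int": nn.parameter(rng, (d, d)),
            "b_int": nn.zeros_param((d,)),
            "w_0": nn.parameter(rng, (d, d)),
            "b_0": nn.zeros_param((d,)),
            "w_ent": nn.parameter(rng, (d, d)),
            "b_ent": nn.zeros_param((d,)),
            "w_cls": nn.parameter(rng, (len(LABELS), cfg.fused_dim)),
            "b_cls": nn.zeros_param((len(LABELS),)),
        }
        self._prior_cache = {}

    @property
    def params(self) -> list:
        out = list(self.encoder.params) + list(self.mol_encoder.params)
        out.extend(self.heads.values())
        return out

    def _priors(self, n_rows: int, j: int, k: int):
        """Fixed attention weight vectors for a (length, span) pair."""
        key = (n_rows, j, k)
        if key not in self._prior_cache:
            cfg = self.config
            inter = build_interaction_vector(
                n_rows, j, k, cfg.ranges, cfg.interaction_mode, cfg.interaction_seed
            ).weights
            ents = build_entities_vector(
                n_rows, j, k, cfg.spec_left, cfg.spec_right,
                cfg.before_frac, cfg.after_frac, cfg.baseline,
            ).weights
            self._prior_cache[key] = (inter, ents)
        return self._prior_cache[key]

    # -- forward pass ---------------------------------------------------
    def _forward(self, inst: LabeledInstance, train: bool = True) -> nn.Tensor:
        cfg = self.config
        zeros_d = nn.Tensor(np.zeros(cfg.d))
        zeros_dm = nn.Tensor(np.zeros(cfg.d_m))
        needs_text = cfg.use_pooled or cfg.use_interaction or cfg.use_entities
        if needs_text:
            h, submap, ids = self.encoder.forward(inst.tokens)
            n_rows = len(ids)
            j, k = remap_span(submap, inst.j, inst.k, n_rows)
            inter_w, ent_w = self._priors(n_rows, j, k)

        if cfg.use_pooled:
            pooled = self.heads["w_0"] @ h[0].tanh() + self.heads["b_0"]
        else:
            pooled = zeros_d
        if cfg.use_interaction:
            h_it = nn.Tensor(inter_w[:, None]) * h
            span_mean = h_it[j : k + 1].mean(axis=0)
            inter = self.heads["w_int"] @ span_mean.tanh() + self.heads["b_int"]
        else:
            inter = zeros_d
        if cfg.use_entities:
            pooled_e = nn.Tensor(ent_w) @ h
            ent = self.heads["w_ent"] @ pooled_e.tanh() + self.heads["b_ent"]
        else:
            ent = zeros_d
        if cfg.use_molecular:
            mol1 = self.mol_encoder.encode_drug(
                inst.drug1_name, self.drug_smiles, train=train
            )
            mol2 = self.mol_encoder.encode_drug(
                inst.drug2_name, self.drug_smiles, train=train
            )
        else:
            mol1 = mol2 = zeros_dm
        fused = nn.concat([pooled, inter, ent, mol1, mol2], axis=0)
        return self.heads["w_cls"] @ fused + self.heads["b_cls"]

    # -- training --------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        dev_instances: Sequence[LabeledInstance] | None = None,
        verbose: bool = False,
    ) -> "DDIResults":
        """Train all blocks with Adam on cross-entropy; returns results.

        Re-sampling (duplicate-negative removal, seeded positive
        over-sampling) is applied to the training split only.
        """
        cfg = self.config
        self._initialise(seed)
        train_set = list(self.instances)
        if cfg.undersample:
            train_set = undersample_negatives(train_set)
        if cfg.oversample_ratio > 0:
            train_set = oversample_positives(train_set, cfg.oversample_ratio, seed)
        if not train_set:
            raise ValueError("empty training set after re-sampling")

        optimiser = nn.Adam(self.params, lr=cfg.lr)
        rng = np.random.default_rng(seed + 3)
        loss_curve = []
        dev_curve = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train_set))
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
                losses = [
                    nn.cross_entropy_logits(
                        self._forward(inst, train=True), _LABEL_INDEX[inst.label]
                    )
                    for inst in batch
                ]
                loss = nn.concat([l.reshape(1) for l in losses]).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"divergent loss at epoch {epoch}: {loss.data}"
                    )
                optimiser.zero_grad()
                loss.backward()
                optimiser.step()
                epoch_loss += float(loss.data) * len(batch)
            loss_curve.append(epoch_loss / len(order))
            if dev_instances is not None:
                preds = self._predict_labels(dev_instances)
                dev_curve.append(
                    evaluate(preds, [i.label for i in dev_instances]).micro.f1
                )
            if verbose:
                msg = f"epoch {epoch}: loss {loss_curve[-1]:.4f}"
                if dev_curve:
                    msg += f", dev micro-F1 {dev_curve[-1]:.3f}"
                print(msg)
        return DDIResults(
            model=self,
            loss_curve=loss_curve,
            dev_curve=dev_curve,
            seed=seed,
            n_train=len(train_set),
        )

    # -- inference -------------------------------------------------------
    def predict_proba(self, instances: Iterable[LabeledInstance]) -> np.ndarray:
        if self.encoder is None:
            raise RuntimeError("model is not fitted")
        rows = []
        for inst in instances:
            logits = self._forward(inst, train=False).data
            z = logits - logits.max()
            e = np.exp(z)
            rows.append(e / e.sum())
        return np.asarray(rows)

    def _predict_labels(self, instances: Iterable[LabeledInstance]) -> list:
        probs = self.predict_proba(instances)
        return [LABELS[i] for i in probs.argmax(axis=1)]


@dataclass
class DDIResults:
    """Fit artefacts: trained model, loss curve, evaluation helpers."""

    model: DDIModel
    loss_curve: list
    dev_curve: list
    seed: int
    n_train: int

    def predict(self, instances: Sequence[LabeledInstance]) -> list:
        return self.model._predict_labels(instances)

    def predict_proba(self, instances: Sequence[LabeledInstance]) -> np.ndarray:
        return self.model.predict_proba(instances)

    def evaluate(self, instances: Sequence[LabeledInstance]) -> EvalReport:
        preds = self.predict(instances)
        return evaluate(preds, [inst.label for inst in instances])

    def summary(self, test_instances: Sequence[LabeledInstance] | None = None) -> str:
        cfg = self.model.config
        blocks = [
            name
            for name, on in [
                ("pooled", cfg.use_pooled),
                ("interaction", cfg.use_interaction),
                ("entities", cfg.use_entities),
                ("molecular", cfg.use_molecular),
            ]
            if on
        ]
        lines = [
            "DDI relation classifier",
            "=" * 44,
            f"feature blocks : {', '.join(blocks)}",
            f"encoder        : tiny transformer (d={cfg.d}, layers={cfg.n_layers})",
            f"molecular      : MGNN (d_m={cfg.d_m}, steps={cfg.mgnn_steps}, "
            f"r={cfg.fingerprint_radius})",
            f"train instances: {self.n_train} (seed {self.seed})",
            f"epochs         : {len(self.loss_curve)}, "
            f"final loss {self.loss_curve[-1]:.4f}",
        ]
        if test_instances is not None:
            lines.append("")
            lines.append(self.evaluate(test_instances).summary())
        return "\n".join(lines)


# ---------------------------------------------------------------------
# ablation

DEFAULT_VARIANTS = {
    "pooled_only": dict(use_interaction=False, use_entities=False,
                        use_molecular=False),
    "pooled+interaction": dict(use_entities=False, use_molecular=False),
    "pooled+interaction+entities": dict(use_molecular=False),
    "full": dict(),
}


def ablate(
    train_instances: Sequence[LabeledInstance],
    test_instances: Sequence[LabeledInstance],
    drug_smiles: dict | None = None,
    config: DDIConfig | None = None,
    variants: dict | None = None,
    seeds: Sequence[int] = (0,),
) -> dict:
    """Train/evaluate the model once per feature-block variant and seed.

    Disabled blocks are replaced by zero vectors of the right shape, so
    the classifier dimension is constant across variants.  Returns
    {variant: [EvalReport per seed]}.
    """
    config = config or DDIConfig()
    variants = variants if variants is not None else DEFAULT_VARIANTS
    out = {}
    for name, overrides in variants.items():
        cfg = dc_replace(config, **overrides)
        reports = []
        for seed in seeds:
            model = DDIModel(train_instances, drug_smiles=drug_smiles, config=cfg)
            result = model.fit(seed=seed)
            reports.append(result.evaluate(test_instances))
        out[name] = reports
    return out
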