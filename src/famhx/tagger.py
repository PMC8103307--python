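"""Trainable BIO entity tagger and the seed-varied ensemble around it.

The tagger assigns a BIO label over {FamilyMember, Observation,
LivingStatus} to every token.  Each training run is seeded: runs with
different seeds differ in weight initialization and data shuffling, which
is exactly the nondeterminism the voting ensemble exploits — an ensemble
is simply N trainings of the same configuration under N seeds.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import bilstm
from .bio import LABELS, decode_bio, encode_bio
from .concepts import ChannelProvider
from .embeddings import (CharHashEmbedding, EmbeddingProvider, LookupEmbedding,
                         default_providers)
from .model import Document, Entity

UNK = "<unk>"


@dataclass(frozen=True)
class TaggerConfig:
    epochs: int = 30
    recurrent_dropout: float = 0.5
    optimizer: str = "nadam"
    hidden_units: int = 32
    channel_embed_dim: int = 10
    seed: int = 1
    learning_rate: float = 0.002
    batch_size: int = 32
    lookup_dim: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.recurrent_dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedTagger:
    params: bilstm.Arrays
    config: TaggerConfig
    vocab: Dict[str, int]
    labels: Tuple[str, ...]
    providers: List[EmbeddingProvider]
    channel_providers: Sequence[ChannelProvider] = ()
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def label_index(self) -> Dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}


def _static_providers(providers: Sequence[EmbeddingProvider]):
    return [p for p in providers if not p.trainable]


def _lookup_dim(providers: Sequence[EmbeddingProvider], config: TaggerConfig) -> int:
    trainable = [p for p in providers if p.trainable]
    if len(trainable) > 1:
        raise ValueError("at most one trainable lookup provider is supported")
    return trainable[0].dim if trainable else config.lookup_dim


def _build_vocab(docs: Sequence[Document]) -> Dict[str, int]:
    vocab = {UNK: 0}
    for doc in docs:
        for sent in doc.sentences:
            for tok in sent.tokens:
                vocab.setdefault(tok.text.lower(), len(vocab))
    return vocab


def _sentence_batch(
    sentences,  # list of (doc, sentence, label_ids or None)
    vocab: Dict[str, int],
    providers: Sequence[EmbeddingProvider],
    channel_providers: Sequence[ChannelProvider],
    label_index: Dict[str, int],
) -> bilstm.Batch:
    statics = _static_providers(providers)
    static_dim = sum(p.dim for p in statics)
    B = len(sentences)
    T = max((len(s.tokens) for _, s, _ in sentences), default=0)
    T = max(T, 1)
    ids = np.zeros((T, B), dtype=np.intp)
    static = np.zeros((T, B, static_dim))
    channels = [np.zeros((T, B), dtype=np.intp) for _ in channel_providers]
    labels = np.zeros((T, B), dtype=np.intp)
    mask = np.zeros((T, B))
    for b, (doc, sent, lab) in enumerate(sentences):
        words = [t.text for t in sent.tokens]
        n = len(words)
        if n == 0:
            continue
        ids[:n, b] = [vocab.get(w.lower(), 0) for w in words]
        offset = 0
        for p in statics:
            static[:n, b, offset:offset + p.dim] = p.vectors(words)
            offset += p.dim
        for k, cp in enumerate(channel_providers):
            ch = cp.channel_for(doc, sent)
            channels[k][:n, b] = [label_index.get(t, 0) for t in ch.tags]
        if lab is not None:
            labels[:n, b] = lab
        mask[:n, b] = 1.0
    return bilstm.Batch(ids, static, channels, labels, mask)


def train_tagger(
    train_docs: Sequence[Document],
    gold_entities: Sequence[Entity],
    config: TaggerConfig = TaggerConfig(),
    providers: Optional[Sequence[EmbeddingProvider]] = None,
    channel_providers: Sequence[ChannelProvider] = (),
    loss_history: Optional[List[float]] = None,
) -> TrainedTagger:
    """Train one Bi-LSTM tagger on gold-annotated documents.

    Raises ``ValueError`` on an empty training set.  The returned model
    records its configuration verbatim in ``metadata`` alongside the seed
    and the per-epoch loss curve.
    """
    if not train_docs:
        raise ValueError("empty training set")
    providers = list(providers) if providers is not None else default_providers(
        config.lookup_dim)
    if not providers:
        raise ValueError("at least one embedding provider is required")
    label_index = {lab: i for i, lab in enumerate(LABELS)}
    by_doc: Dict[str, List[Entity]] = {}
    for e in gold_entities:
        by_doc.setdefault(e.doc_id, []).append(e)
    examples = []
    for doc in train_docs:
        ents = by_doc.get(doc.doc_id, [])
        for sent in doc.sentences:
            if not sent.tokens:
                continue
            tags = encode_bio(sent, ents)
            examples.append((doc, sent, [label_index[t] for t in tags]))
    if not examples:
        raise ValueError("training documents contain no tokenized sentences")

    vocab = _build_vocab(train_docs)
    rng = np.random.default_rng(config.seed)
    statics = _static_providers(providers)
    params = bilstm.init_params(
        rng,
        vocab_size=len(vocab),
        lookup_dim=_lookup_dim(providers, config),
        static_dim=sum(p.dim for p in statics),
        channel_sizes=[len(LABELS)] * len(channel_providers),
        channel_dim=config.channel_embed_dim,
        hidden=config.hidden_units,
        n_labels=len(LABELS),
    )
    opt = bilstm.Nadam(params, lr=config.learning_rate)
    order = np.arange(len(examples))
    epoch_losses: List[float] = []
    for _ in range(config.epochs):
        rng.shuffle(order)
        total, batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [examples[j] for j in order[i:i + config.batch_size]]
            batch = _sentence_batch(chunk, vocab, providers, channel_providers,
                                    label_index)
            loss, grads = bilstm.loss_and_grads(
                params, batch, config.hidden_units,
                dropout=config.recurrent_dropout, rng=rng)
            opt.step(params, grads)
            total += loss
            batches += 1
        epoch_losses.append(total / batches)
    if loss_history is not None:
        loss_history.extend(epoch_losses)
    return TrainedTagger(
        params=params,
        config=config,
        vocab=vocab,
        labels=LABELS,
        providers=providers,
        channel_providers=channel_providers,
        metadata={"config": asdict(config), "seed": config.seed,
                  "epoch_losses": epoch_losses},
    )


def predict_tags(tagger: TrainedTagger, doc: Document) -> List[List[str]]:
    """Per-sentence BIO label sequences; deterministic for fixed weights."""
    label_index = tagger.label_index
    out: List[List[str]] = []
    for sent in doc.sentences:
        if not sent.tokens:
            out.append([])
            continue
        batch = _sentence_batch([(doc, sent, None)], tagger.vocab,
                                tagger.providers, tagger.channel_providers,
                                label_index)
        pred = bilstm.predict_batch(tagger.params, batch,
                                    tagger.config.hidden_units)
        out.append([tagger.labels[pred[t, 0]] for t in range(len(sent.tokens))])
    return out


def predict_entities(tagger: TrainedTagger, doc: Document) -> List[Entity]:
    entities: List[Entity] = []
    for sent, tags in zip(doc.sentences, predict_tags(tagger, doc)):
        entities.extend(decode_bio(tags, sent, doc.doc_id))
    return entities


def train_ensemble(
    train_docs: Sequence[Document],
    gold_entities: Sequence[Entity],
    config: TaggerConfig = TaggerConfig(),
    n_models: int = 10,
    seeds: Optional[Sequence[int]] = None,
    providers_factory=None,
    channel_providers: Sequence[ChannelProvider] = (),
) -> List[TrainedTagger]:
    """Train ``n_models`` taggers identical except for their seeds.

    Seeds default to 1..n_models and are recorded in each model's
    metadata; a fixed seed list reruns to identical ensembles.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    seeds = list(seeds) if seeds is not None else list(range(1, n_models + 1))
    if len(seeds) != n_models:
        raise ValueError("need exactly one seed per model")
    models = []
    for seed in seeds:
        cfg = TaggerConfig(**{**asdict(config), "seed": seed})
        providers = providers_factory() if providers_factory else None
        models.append(train_tagger(train_docs, gold_entities, cfg,
                                   providers=providers,
                                   channel_providers=channel_providers))
    return models


def save_tagger(tagger: TrainedTagger, out_dir: str) -> None:
    """Persist weights (npz) + JSON metadata.  Static providers are
    re-created from their spec on load; channel providers are reattached
    by the caller (they depend on external concept taggers)."""
    os.makedirs(out_dir, exist_ok=True)
    np.savez(os.path.join(out_dir, "weights.npz"), **tagger.params)
    meta = {
        "config": asdict(tagger.config),
        "vocab": tagger.vocab,
        "labels": list(tagger.labels),
        "providers": [p.spec() for p in tagger.providers],
        "n_channels": len(tagger.channel_providers),
        "metadata": {k: v for k, v in tagger.metadata.items() if k != "config"},
    }
    with open(os.path.join(out_dir, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_tagger(model_dir: str,
                channel_providers: Sequence[ChannelProvider] = ()) -> TrainedTagger:
    weights_path = os.path.join(model_dir, "weights.npz")
    meta_path = os.path.join(model_dir, "meta.json")
    if not os.path.exists(weights_path) or not os.path.exists(meta_path):
        raise FileNotFoundError(
            f"model artifact incomplete: expected weights.npz and meta.json in {model_dir}")
    with np.load(weights_path) as data:
        params = {k: data[k] for k in data.files}
    meta = json.load(open(meta_path, encoding="utf-8"))
    providers: List[EmbeddingProvider] = []
    for spec in meta["providers"]:
        if spec["name"] == "lookup":
            providers.append(LookupEmbedding(spec["dim"]))
        elif spec["name"] == "charhash":
            providers.append(CharHashEmbedding(spec["dim"]))
        else:
            raise ValueError(f"cannot reconstruct provider {spec['name']!r}; "
                             "pass it explicitly")
    if meta["n_channels"] != len(channel_providers):
        raise ValueError(
            f"model was trained with {meta['n_channels']} aux channels, "
            f"got {len(channel_providers)}")
    return TrainedTagger(
        params=params,
        config=TaggerConfig(**meta["config"]),
        vocab=meta["vocab"],
        labels=tuple(meta["labels"]),
        providers=providers,
        channel_providers=channel_providers,
        metadata={"config": meta["config"], **meta["metadata"]},
    )
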