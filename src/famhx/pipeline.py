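"""End-to-end orchestration: notes in, entity and relation files out.

Stage order mirrors the extraction architecture: preprocessing, the tagger
ensemble (optionally with the rule-based family-member matcher overriding
the ensemble's family members), vote resolution, attribute heuristics,
candidate-pair generation, relation classification, attribute attachment,
and the annotation writers.  Every stage logs counts, and all randomness
is seeded through the configuration, so a rerun with the same config and
seeds produces byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotations import write_annotations
from .concepts import (ChannelProvider, DictionaryConceptTagger,
                       SemanticTypeMap, build_semantic_type_map)
from .model import (Category, Document, Entity, FamilyMemberAttrs,
                    LivingStatusAttrs, ObservationAttrs, Relation,
                    RelationType)
from .relations import (CandidatePair, LinearRelationModel, assemble_relations,
                        classify_pairs, extract_features,
                        generate_candidate_pairs, train_relation_model)
from .rules import (CueLexicon, FamilyLexicon, assign_family_side,
                    detect_negation, load_cue_lexicon, load_family_lexicon,
                    match_family_members, normalize_family_member,
                    score_living_status)
from .synthetic import DISEASES
from .tagger import (TaggerConfig, TrainedTagger, load_tagger, predict_entities,
                     save_tagger, train_ensemble)
from .voting import (EnsembleConfig, ModelRanking, collect_votes, rank_models,
                     resolve_entities)

logger = logging.getLogger("famhx.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    tagger: TaggerConfig = TaggerConfig()
    ensemble: EnsembleConfig = EnsembleConfig(threshold=5)
    n_models: int = 10
    relation_passes: int = 100
    relation_seed: int = 0
    use_rule_fm: bool = False   # rule-based family members + neural observations
    use_aux_channels: bool = True

    def tagger_seeds(self) -> List[int]:
        return [self.tagger.seed + i for i in range(self.n_models)]


@dataclass
class Artifacts:
    taggers: List[TrainedTagger]
    semantic_map: Optional[SemanticTypeMap]
    ls_model: LinearRelationModel
    obs_model: LinearRelationModel
    lexicon: FamilyLexicon
    cues: CueLexicon
    channel_providers: Sequence[ChannelProvider] = ()


def default_concept_taggers() -> Tuple[DictionaryConceptTagger, DictionaryConceptTagger]:
    """Dictionary mocks standing behind the two concept channels: a
    semantic-type tagger (UMLS-style) and a medical-problem tagger."""
    umls_like = DictionaryConceptTagger("umls_mock", DISEASES)
    problem_like = DictionaryConceptTagger(
        "problem_mock", {term: "problem" for term in DISEASES})
    return umls_like, problem_like


def build_channel_providers(
    train_docs: Sequence[Document],
    gold_entities: Sequence[Entity],
) -> Tuple[List[ChannelProvider], SemanticTypeMap]:
    umls_like, problem_like = default_concept_taggers()
    mentions = [m for doc in train_docs for m in umls_like.tag(doc)]
    gold_obs = [e for e in gold_entities if e.category is Category.OBSERVATION]
    smap = build_semantic_type_map(mentions, gold_obs)
    providers = [ChannelProvider(umls_like, semantic_map=smap),
                 ChannelProvider(problem_like, semantic_map=None)]
    return providers, smap


def _relation_examples(
    docs: Sequence[Document],
    entities: Sequence[Entity],
    relations: Sequence[Relation],
) -> Dict[RelationType, List[Tuple[List[str], bool]]]:
    by_doc: Dict[str, List[Entity]] = {}
    for e in entities:
        by_doc.setdefault(e.doc_id, []).append(e)
    examples: Dict[RelationType, List[Tuple[List[str], bool]]] = {
        RelationType.FM_LIVING_STATUS: [], RelationType.FM_OBSERVATION: []}
    for doc in docs:
        ents = by_doc.get(doc.doc_id, [])
        pairs = generate_candidate_pairs(ents, doc, mode="train",
                                         gold_relations=[r for r in relations
                                                         if r.doc_id == doc.doc_id])
        for pair in pairs:
            feats = extract_features(pair, doc, ents)
            examples[pair.type].append((feats, bool(pair.label)))
    return examples


def train_pipeline(
    train_docs: Sequence[Document],
    gold_entities: Sequence[Entity],
    gold_relations: Sequence[Relation],
    config: PipelineConfig = PipelineConfig(),
) -> Artifacts:
    """Train every learned component of the pipeline from gold data."""
    lexicon = load_family_lexicon()
    cues = load_cue_lexicon()
    channel_providers: List[ChannelProvider] = []
    smap: Optional[SemanticTypeMap] = None
    if config.use_aux_channels:
        channel_providers, smap = build_channel_providers(train_docs, gold_entities)
    logger.info("training %d taggers (seeds %s)", config.n_models,
                config.tagger_seeds())
    taggers = train_ensemble(train_docs, gold_entities, config.tagger,
                             n_models=config.n_models,
                             seeds=config.tagger_seeds(),
                             channel_providers=channel_providers)
    examples = _relation_examples(train_docs, gold_entities, gold_relations)
    ls_model = train_relation_model(examples[RelationType.FM_LIVING_STATUS],
                                    passes=config.relation_passes,
                                    seed=config.relation_seed)
    obs_model = train_relation_model(examples[RelationType.FM_OBSERVATION],
                                     passes=config.relation_passes,
                                     seed=config.relation_seed + 1)
    logger.info("relation training: %d LS examples, %d OBS examples",
                len(examples[RelationType.FM_LIVING_STATUS]),
                len(examples[RelationType.FM_OBSERVATION]))
    return Artifacts(taggers=taggers, semantic_map=smap, ls_model=ls_model,
                     obs_model=obs_model, lexicon=lexicon, cues=cues,
                     channel_providers=channel_providers)


def _attach_attributes(
    entities: Sequence[Entity],
    docs: Dict[str, Document],
    lexicon: FamilyLexicon,
    cues: CueLexicon,
) -> Tuple[List[Entity], int]:
    """Attribute heuristics stage; returns entities plus the count of
    family members dropped as unnormalizable."""
    out: List[Entity] = []
    dropped = 0
    for e in entities:
        doc = docs[e.doc_id]
        sent = doc.sentence_at(e.start) if e.start is not None else None
        if e.category is Category.FAMILY_MEMBER:
            norm = normalize_family_member(e.text, lexicon, sent, e.start)
            if norm is None:
                dropped += 1
                logger.info("dropping unnormalizable family member %r in %s",
                            e.text, e.doc_id)
                continue
            side = assign_family_side(e.text, norm, cues, sent, e.start)
            attrs = FamilyMemberAttrs(norm, side)
        elif e.category is Category.OBSERVATION:
            attrs = ObservationAttrs(detect_negation(sent, e, cues)
                                     if sent is not None else "Non_Negated")
        else:
            attrs = LivingStatusAttrs(score_living_status(e.text, cues))
        out.append(Entity(e.doc_id, e.category, e.text, e.start, e.end,
                          attrs=attrs))
    return out, dropped


def predict_pipeline(
    docs: Sequence[Document],
    artifacts: Artifacts,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[List[Entity], List[Relation], Dict[str, int]]:
    """Run the trained pipeline over documents.

    Returns attribute-bearing entities, relations, and per-stage counts.
    """
    doc_map = {d.doc_id: d for d in docs}
    predictions = [[e for d in docs for e in predict_entities(t, d)]
                   for t in artifacts.taggers]
    votes = collect_votes(predictions)
    if len(predictions) >= 2:
        ranking = rank_models(predictions)
    else:
        ranking = ModelRanking(pairwise_f1=((0.0,),), mean_agreement=(0.0,),
                               rank=(0,))
    resolved = resolve_entities(votes, ranking, config.ensemble)
    log = {"documents": len(docs),
           "vote_candidates": len(votes.candidates),
           "resolved_entities": len(resolved)}
    if config.use_rule_fm:
        rule_fms = [e for d in docs
                    for e in match_family_members(d, artifacts.lexicon)]
        resolved = ([e for e in resolved
                     if e.category is not Category.FAMILY_MEMBER] + rule_fms)
        log["rule_family_members"] = len(rule_fms)
    entities, dropped = _attach_attributes(resolved, doc_map,
                                           artifacts.lexicon, artifacts.cues)
    log["attributed_entities"] = len(entities)
    log["unnormalizable_dropped"] = dropped
    positives: List[CandidatePair] = []
    n_pairs = 0
    by_doc: Dict[str, List[Entity]] = {}
    for e in entities:
        by_doc.setdefault(e.doc_id, []).append(e)
    for doc in docs:
        ents = by_doc.get(doc.doc_id, [])
        pairs = generate_candidate_pairs(ents, doc, mode="test")
        n_pairs += len(pairs)
        for rtype, model in ((RelationType.FM_LIVING_STATUS, artifacts.ls_model),
                             (RelationType.FM_OBSERVATION, artifacts.obs_model)):
            typed = [p for p in pairs if p.type is rtype]
            feats = [extract_features(p, doc, ents) for p in typed]
            positives.extend(p for p, related, _ in
                             classify_pairs(model, typed, feats) if related)
    relations = assemble_relations(positives, doc_map, artifacts.cues)
    log["candidate_pairs"] = n_pairs
    log["positive_pairs"] = len(positives)
    log["relations"] = len(relations)
    for stage, count in log.items():
        logger.info("stage %s: %d", stage, count)
    return entities, relations, log


def run_end_to_end(
    docs: Sequence[Document],
    artifacts: Artifacts,
    out_dir: str,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[str, str, str]:
    """Predict and write entity/relation files plus a JSON run log."""
    entities, relations, log = predict_pipeline(docs, artifacts, config)
    epath, rpath = write_annotations(entities, relations, out_dir)
    log_path = os.path.join(out_dir, "run_log.json")
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump({"config": _config_dict(config), "stages": log}, fh,
                  indent=1, sort_keys=True)
    return epath, rpath, log_path


def _config_dict(config: PipelineConfig) -> Dict[str, object]:
    return {"tagger": asdict(config.tagger),
            "ensemble": {"threshold": config.ensemble.threshold},
            "n_models": config.n_models,
            "relation_passes": config.relation_passes,
            "relation_seed": config.relation_seed,
            "use_rule_fm": config.use_rule_fm,
            "use_aux_channels": config.use_aux_channels}


def save_artifacts(artifacts: Artifacts, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for i, tagger in enumerate(artifacts.taggers):
        save_tagger(tagger, os.path.join(out_dir, f"tagger_{i}"))
    for name, model in (("ls_model", artifacts.ls_model),
                        ("obs_model", artifacts.obs_model)):
        np.savez(os.path.join(out_dir, f"{name}.npz"),
                 weights=model.weights, bias=np.array([model.bias]))
        with open(os.path.join(out_dir, f"{name}.json"), "w") as fh:
            json.dump({"passes": model.passes, "seed": model.seed,
                       "learning_rate": model.learning_rate}, fh)
    meta = {"n_taggers": len(artifacts.taggers),
            "semantic_map": (artifacts.semantic_map.to_dict()
                             if artifacts.semantic_map else None)}
    with open(os.path.join(out_dir, "artifacts.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def load_artifacts(model_dir: str) -> Artifacts:
    meta_path = os.path.join(model_dir, "artifacts.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(
            f"missing artifact {meta_path}; run training first")
    meta = json.load(open(meta_path, encoding="utf-8"))
    smap = (SemanticTypeMap.from_dict(meta["semantic_map"])
            if meta["semantic_map"] else None)
    channel_providers: List[ChannelProvider] = []
    if smap is not None:
        umls_like, problem_like = default_concept_taggers()
        channel_providers = [ChannelProvider(umls_like, semantic_map=smap),
                             ChannelProvider(problem_like, semantic_map=None)]
    taggers = [load_tagger(os.path.join(model_dir, f"tagger_{i}"),
                           channel_providers=channel_providers)
               for i in range(meta["n_taggers"])]
    models = {}
    for name in ("ls_model", "obs_model"):
        with np.load(os.path.join(model_dir, f"{name}.npz")) as data:
            weights, bias = data["weights"], float(data["bias"][0])
        info = json.load(open(os.path.join(model_dir, f"{name}.json")))
        models[name] = LinearRelationModel(weights=weights, bias=bias, **info)
    return Artifacts(taggers=taggers, semantic_map=smap,
                     ls_model=models["ls_model"], obs_model=models["obs_model"],
                     lexicon=load_family_lexicon(), cues=load_cue_lexicon(),
                     channel_providers=channel_providers)
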