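"""End-to-end pipeline orchestration.

Runs corpus → NER → extraction → species tagging → aggregation →
evaluation behind one declarative configuration, writing one artifact per
stage plus a run manifest (config hash, input digests, per-stage record
counts).  Re-running with identical inputs reproduces identical stage
artifacts; the manifest records their digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from connmine import __version__
from connmine.aggregate import build_db, query_region
from connmine.corpus_io import read_corpus
from connmine.evaluation import evaluate_overall, evaluate_seed, load_gold_lists, write_report
from connmine.lexicon import build_lexicon
from connmine.ner import TaggerModel, annotate_document, write_mentions
from connmine.relations import (
    ExtractorConfig,
    KernelModel,
    candidate_pairs,
    extract_filter,
    extract_kernel,
    extract_rules,
    load_rules,
    write_connection_mentions,
)
from connmine.species import load_species_dict, tag_corpus, write_species_tags

logger = logging.getLogger("connmine")

NER_MODES = ("lexical", "statistical", "both")


@dataclass
class PipelineConfig:
    corpus_path: str
    corpus_format: str = "jsonl"
    lexicon_sources: list[str] = field(default_factory=list)
    ner_mode: str = "lexical"
    extractors: list[str] = field(default_factory=lambda: ["filter", "rules"])
    patterns_path: str | None = None
    confidences: dict[str, float] | None = None
    conjunction_filter: bool = True
    list_filter: bool = True
    negation_filter: bool = True
    species_dict_path: str | None = None
    gold_path: str | None = None
    out_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ner_mode not in NER_MODES:
            raise ValueError(f"NER mode must be one of {NER_MODES}, got {self.ner_mode!r}")
        for ex in self.extractors:
            if ex not in ("filter", "rules", "kernel"):
                raise ValueError(f"unknown extractor {ex!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    kernel_model: KernelModel | None = None,
    tagger_model: TaggerModel | None = None,
) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    *kernel_model* / *tagger_model* supply the trained models when the
    kernel extractor or a statistical NER mode is configured.
    """
    # -- pre-flight: every referenced input must exist before any stage runs
    inputs = [cfg.corpus_path, *cfg.lexicon_sources]
    for opt in (cfg.patterns_path, cfg.species_dict_path, cfg.gold_path):
        if opt is not None:
            inputs.append(opt)
    missing = [p for p in inputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"pre-flight check failed, missing inputs: {missing}")
    if not cfg.lexicon_sources:
        raise ValueError("pre-flight check failed: no lexicon sources configured")
    if "kernel" in cfg.extractors and kernel_model is None:
        raise ValueError("pre-flight check failed: kernel extractor configured without a trained model")
    if cfg.ner_mode in ("statistical", "both") and tagger_model is None:
        raise ValueError("pre-flight check failed: statistical NER configured without a trained tagger")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    durations: dict[str, float] = {}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(n: int) -> None:
            counts[name] = n
            durations[name] = round(time.perf_counter() - t0, 3)
            logger.info("stage=%s count=%d duration=%.3fs", name, n, durations[name])

        return done

    try:
        done = stage("corpus")
        docs = list(read_corpus(cfg.corpus_path, format=cfg.corpus_format))
        done(len(docs))
    except Exception as exc:
        raise RuntimeError(f"stage corpus failed: {exc}") from exc

    try:
        done = stage("lexicon")
        lex = build_lexicon(list(cfg.lexicon_sources))
        lex.save(out / "lexicon.json")
        done(len(lex))
    except Exception as exc:
        raise RuntimeError(f"stage lexicon failed: {exc}") from exc

    try:
        done = stage("ner")
        annotated = {
            doc.doc_id: annotate_document(doc, lex, mode=cfg.ner_mode, model=tagger_model) for doc in docs
        }
        all_mentions = [m for per_doc in annotated.values() for _, ms in per_doc for m in ms]
        write_mentions(all_mentions, out / "mentions.jsonl")
        done(len(all_mentions))
    except Exception as exc:
        raise RuntimeError(f"stage ner failed: {exc}") from exc

    try:
        done = stage("extract")
        ex_cfg = ExtractorConfig(
            conjunction_filter=cfg.conjunction_filter,
            list_filter=cfg.list_filter,
            negation_filter=cfg.negation_filter,
        )
        if cfg.confidences:
            ex_cfg.confidences.update(cfg.confidences)
        rules = load_rules(cfg.patterns_path)
        conn = []
        for doc in docs:
            for sent, mentions in annotated[doc.doc_id]:
                pairs = candidate_pairs(sent, mentions)
                if not pairs:
                    continue
                if "filter" in cfg.extractors:
                    conn.extend(extract_filter(sent, pairs, ex_cfg))
                if "rules" in cfg.extractors:
                    conn.extend(extract_rules(sent, pairs, ex_cfg, rules=rules))
                if "kernel" in cfg.extractors:
                    conn.extend(extract_kernel(sent, pairs, kernel_model, ex_cfg))
        write_connection_mentions(conn, out / "connections.jsonl")
        done(len(conn))
    except Exception as exc:
        raise RuntimeError(f"stage extract failed: {exc}") from exc

    try:
        done = stage("species")
        sdict = load_species_dict(cfg.species_dict_path)
        tags = tag_corpus(docs, sdict)
        write_species_tags(tags, out / "species.jsonl")
        done(sum(len(v) for v in tags.values()))
    except Exception as exc:
        raise RuntimeError(f"stage species failed: {exc}") from exc

    try:
        done = stage("aggregate")
        db = build_db(
            conn,
            lex,
            species_tags=tags,
            provenance={
                "corpus": cfg.corpus_path,
                "n_documents": len(docs),
                "extractors": list(cfg.extractors),
                "ner_mode": cfg.ner_mode,
                "seed": cfg.seed,
            },
        )
        db.save(out / "db.json")
        db.to_edge_list(out / "edges.csv")
        done(len(db.records))
    except Exception as exc:
        raise RuntimeError(f"stage aggregate failed: {exc}") from exc

    eval_rows = []
    if cfg.gold_path is not None:
        try:
            done = stage("evaluate")
            gold_lists = load_gold_lists(cfg.gold_path)
            for seed_label, gold in sorted(gold_lists.items()):
                seed_id = lex.resolve(seed_label) or lex.resolve(gold.seed)
                if seed_id is None:
                    raise ValueError(f"gold seed {seed_label!r} does not resolve in the lexicon")
                proposed = query_region(db, seed_id, lex)
                eval_rows.append(evaluate_seed(gold, proposed, lex))
            if eval_rows:
                eval_rows.append(evaluate_overall(eval_rows))
            write_report(eval_rows, out / "eval.csv")
            done(len(eval_rows))
        except Exception as exc:
            raise RuntimeError(f"stage evaluate failed: {exc}") from exc

    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json" and p.is_file())
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "input_digests": {p: _sha256(Path(p)) for p in inputs},
        "counts": counts,
        "durations_s": durations,
        "artifact_digests": {name: _sha256(out / name) for name in artifacts},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
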