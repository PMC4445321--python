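"""Sentence-level connection extraction.

Given the resolved region mentions of a sentence, three extractor models
decide which co-mentioned region pairs are asserted to be connected:

* FILTER — co-occurrence of every candidate pair, minus pairs removed by
  switchable filters (coordinating-conjunction pattern, long list context,
  negation before a connective).
* RULES — nine hand-crafted surface templates over a connective lexicon
  ("projection from A to B", "A innervates B", ...), with conjunction
  distribution in the region slots.
* KERNEL — a supervised pair classifier over lexical/positional features.

Extracted relations are undirected: directional syntax in the rule
templates is used for matching only, and pair keys order the two region
ids lexicographically.  Each extractor stamps its mentions with a fixed
confidence (defaults 0.45 / 0.60 / 0.72 — the measured precision of each
extractor, used downstream as the per-mention weight).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from connmine.corpus_io import Sentence, Token, tokenize
from connmine.ner import Mention

#: tokens allowed to appear freely between rule-pattern elements
FILLER = frozenset({"the", "a", "an", "its", "their", "region", "regions", "ipsilateral", "contralateral", "bilateral"})

_CONJ = frozenset({"and", "or"})
_NEGATION = frozenset({"no", "not", "neither", "nor", "never", "absence", "without"})

DEFAULT_CONFIDENCES = {"FILTER": 0.45, "KERNEL": 0.60, "RULES": 0.72}


def _load_packaged(name: str) -> str:
    return resources.files("connmine.data").joinpath(name).read_text(encoding="utf-8")


def load_connectives(path: str | Path | None = None) -> frozenset[str]:
    """Load the connective lexicon (packaged default or a user file)."""
    text = Path(path).read_text(encoding="utf-8") if path is not None else _load_packaged("connectives.txt")
    return frozenset(
        line.strip().lower() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class CandidatePair:
    """An unordered pair of resolved, non-overlapping mentions in one sentence."""

    doc_id: str
    sentence_index: int
    mention_a: Mention
    mention_b: Mention

    def __post_init__(self) -> None:
        if self.mention_a.region_id is None or self.mention_b.region_id is None:
            raise ValueError("candidate pairs require resolved mentions")
        if self.mention_a.region_id == self.mention_b.region_id:
            raise ValueError("candidate pairs require distinct region ids")

    @property
    def pair_key(self) -> tuple[str, str]:
        a, b = self.mention_a.region_id, self.mention_b.region_id
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ConnectionMention:
    """One sentence-level evidence item for an unordered region pair."""

    region_a: str
    region_b: str
    doc_id: str
    sentence_index: int
    evidence_text: str
    extractor: str  # FILTER | KERNEL | RULES
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.region_a > self.region_b:
            raise ValueError("pair key must be lexicographically ordered")

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.region_a, self.region_b)

    @property
    def sentence_key(self) -> tuple[str, int, tuple[str, str]]:
        return (self.doc_id, self.sentence_index, self.pair_key)


@dataclass
class ExtractorConfig:
    """Switches, lexicons and per-extractor confidence constants."""

    conjunction_filter: bool = True  # f1
    list_filter: bool = True  # f2
    negation_filter: bool = True  # f3
    list_threshold: int = 4
    connectives: frozenset[str] = field(default_factory=load_connectives)
    confidences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONFIDENCES))

    def __post_init__(self) -> None:
        for name, c in self.confidences.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"confidence for {name} outside [0, 1]: {c}")


def candidate_pairs(sentence: Sentence, mentions: Sequence[Mention]) -> list[CandidatePair]:
    """All unordered pairs of resolved mentions with distinct region ids."""
    resolved = [m for m in mentions if m.region_id is not None]
    pairs: list[CandidatePair] = []
    for i in range(len(resolved)):
        for j in range(i + 1, len(resolved)):
            a, b = resolved[i], resolved[j]
            if a.region_id != b.region_id:
                pairs.append(
                    CandidatePair(doc_id=sentence.doc_id, sentence_index=sentence.index, mention_a=a, mention_b=b)
                )
    return pairs


def _emit(pair: CandidatePair, sentence: Sentence, extractor: str, confidence: float) -> ConnectionMention:
    a, b = pair.pair_key
    return ConnectionMention(
        region_a=a,
        region_b=b,
        doc_id=sentence.doc_id,
        sentence_index=sentence.index,
        evidence_text=sentence.text,
        extractor=extractor,
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# FILTER


def extract_filter(
    sentence: Sentence,
    pairs: Sequence[CandidatePair],
    cfg: ExtractorConfig,
    tokens: Sequence[Token] | None = None,
) -> list[ConnectionMention]:
    """Co-occurrence extraction with unlikely pairs filtered out.

    Filters (each individually switchable):

    f1 (conjunction) — the two mentions are joined by a coordinating
    conjunction ("A and B", "both A and B", "A or B") and no connective
    appears anywhere in the sentence: regions listed, not connected.

    f2 (list context) — the sentence mentions ``list_threshold``-or-more
    distinct regions and no connective.

    f3 (negation) — a negation token within 3 tokens before a connective.
    """
    if not pairs:
        return []
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    lower = [t.text.lower() for t in toks]
    has_connective = any(w in cfg.connectives for w in lower)

    n_mentions = len({(m.start, m.end) for p in pairs for m in (p.mention_a, p.mention_b)})
    if cfg.list_filter and n_mentions >= cfg.list_threshold and not has_connective:
        return []
    if cfg.negation_filter and has_connective:
        for i, w in enumerate(lower):
            if w in cfg.connectives and any(x in _NEGATION for x in lower[max(0, i - 3) : i]):
                return []

    out: list[ConnectionMention] = []
    for pair in pairs:
        if cfg.conjunction_filter and not has_connective:
            lo = min(pair.mention_a.end, pair.mention_b.end)
            hi = max(pair.mention_a.start, pair.mention_b.start)
            between = [t.text.lower() for t in toks if lo <= t.start and t.end <= hi]
            if any(w in _CONJ for w in between):
                continue
        out.append(_emit(pair, sentence, "FILTER", cfg.confidences["FILTER"]))
    return out


# ---------------------------------------------------------------------------
# RULES


@dataclass(frozen=True)
class _Lit:
    alts: frozenset[str]
    optional: bool = False


@dataclass(frozen=True)
class _Slot:
    name: str  # "A" | "B"


@dataclass(frozen=True)
class Rule:
    rule_id: str
    elements: tuple


def parse_rule_line(line: str) -> Rule:
    rule_id, pattern = line.split("\t", 1)
    elements: list = []
    for tok in pattern.split():
        if tok in ("{A}", "{B}"):
            elements.append(_Slot(tok[1]))
        elif tok.startswith("[") and tok.endswith("]"):
            elements.append(_Lit(frozenset(tok[1:-1].lower().split("|")), optional=True))
        else:
            elements.append(_Lit(frozenset(tok.lower().split("|"))))
    return Rule(rule_id=rule_id.strip(), elements=tuple(elements))


def load_rules(path: str | Path | None = None) -> list[Rule]:
    """Load rule templates (packaged default file or a user pattern file)."""
    text = Path(path).read_text(encoding="utf-8") if path is not None else _load_packaged("rules.txt")
    rules = []
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            rules.append(parse_rule_line(line))
    return rules


def _sentence_items(sentence: Sentence, mentions: Sequence[Mention], tokens: Sequence[Token]):
    """Collapse each resolved mention into a single entity item.

    Returns a list of ("W", lowercased word) and ("E", mention) items in
    sentence order.
    """
    resolved = sorted((m for m in mentions if m.region_id is not None), key=lambda m: m.start)
    items: list[tuple[str, object]] = []
    mi = 0
    for t in tokens:
        while mi < len(resolved) and resolved[mi].end <= t.start:
            mi += 1
        if mi < len(resolved) and resolved[mi].start <= t.start and t.end <= resolved[mi].end:
            if not items or items[-1] != ("E", resolved[mi]):
                items.append(("E", resolved[mi]))
        else:
            items.append(("W", t.text.lower()))
    return items


_MAX_FILLER_SKIP = 3


def _match_rule(rule: Rule, items: list) -> list[dict[str, list[Mention]]]:
    """All bindings of a rule's slots to entity items, anywhere in the sentence."""
    results: list[dict[str, list[Mention]]] = []

    def skip_filler(pos: int) -> list[int]:
        positions = [pos]
        p = pos
        for _ in range(_MAX_FILLER_SKIP):
            if p < len(items) and items[p][0] == "W" and items[p][1] in FILLER:
                p += 1
                positions.append(p)
            else:
                break
        return positions

    def conjunct_chains(pos: int) -> list[tuple[list[Mention], int]]:
        """Extensions "and/or/, E" after a slot; longest chains first."""
        chains: list[tuple[list[Mention], int]] = [([], pos)]
        collected: list[Mention] = []
        p = pos
        while True:
            q = p
            if q < len(items) and items[q][0] == "W" and items[q][1] == ",":
                q += 1
            sep = q < len(items) and items[q][0] == "W" and items[q][1] in ("and", "or")
            if sep:
                q += 1
            elif q == p:
                break
            hit = None
            for fp in skip_filler(q):
                if fp < len(items) and items[fp][0] == "E":
                    hit = fp
                    break
            if hit is None:
                break
            collected = collected + [items[hit][1]]
            p = hit + 1
            chains.append((list(collected), p))
        chains.sort(key=lambda c: -len(c[0]))
        return chains

    def match(e_idx: int, pos: int, bindings: dict[str, list[Mention]]) -> None:
        if e_idx == len(rule.elements):
            results.append({k: list(v) for k, v in bindings.items()})
            return
        elem = rule.elements[e_idx]
        for p in skip_filler(pos):
            if isinstance(elem, _Lit):
                if elem.optional:
                    match(e_idx + 1, p, bindings)
                if p < len(items) and items[p][0] == "W" and items[p][1] in elem.alts:
                    match(e_idx + 1, p + 1, bindings)
                if elem.optional:
                    break  # optional: non-consuming branch already explored once
            else:  # slot
                if p < len(items) and items[p][0] == "E":
                    head: Mention = items[p][1]
                    for conjuncts, after in conjunct_chains(p + 1):
                        bindings[elem.name] = [head] + conjuncts
                        match(e_idx + 1, after, bindings)
                        del bindings[elem.name]

    for start in range(len(items)):
        match(0, start, {})
    return results


def extract_rules(
    sentence: Sentence,
    pairs: Sequence[CandidatePair],
    cfg: ExtractorConfig,
    rules: Sequence[Rule] | None = None,
    tokens: Sequence[Token] | None = None,
) -> list[ConnectionMention]:
    """Apply the surface rule templates; conjunct slots distribute.

    Only pairs present among the candidate pairs are emitted (rules never
    invent pairs), each once, with the RULES confidence.
    """
    if not pairs:
        return []
    if rules is None:
        rules = load_rules()
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    mentions = []
    seen_spans = set()
    for p in pairs:
        for m in (p.mention_a, p.mention_b):
            if (m.start, m.end) not in seen_spans:
                seen_spans.add((m.start, m.end))
                mentions.append(m)
    items = _sentence_items(sentence, mentions, toks)
    candidate_keys = {p.pair_key for p in pairs}
    matched: set[tuple[str, str]] = set()
    for rule in rules:
        for binding in _match_rule(rule, items):
            if "A" not in binding or "B" not in binding:
                continue
            for ma in binding["A"]:
                for mb in binding["B"]:
                    if ma.region_id == mb.region_id:
                        continue
                    key = tuple(sorted((ma.region_id, mb.region_id)))
                    if key in candidate_keys:
                        matched.add(key)  # type: ignore[arg-type]
    by_key = {}
    for p in pairs:
        by_key.setdefault(p.pair_key, p)
    return [
        _emit(by_key[key], sentence, "RULES", cfg.confidences["RULES"]) for key in sorted(matched)
    ]


# ---------------------------------------------------------------------------
# KERNEL


def pair_features(
    sentence: Sentence,
    pair: CandidatePair,
    cfg: ExtractorConfig,
    tokens: Sequence[Token] | None = None,
) -> dict[str, float]:
    """Feature map for the supervised pair classifier."""
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    left, right = sorted((pair.mention_a, pair.mention_b), key=lambda m: m.start)
    feats: dict[str, float] = {"bias": 1.0}
    between = [t for t in toks if left.end <= t.start and t.end <= right.start]
    for t in between:
        feats[f"bow={t.text.lower()}"] = 1.0
    # 2-token windows around each mention
    lpos = [i for i, t in enumerate(toks) if t.end <= left.start]
    rpos = [i for i, t in enumerate(toks) if t.start >= right.end]
    for off, i in enumerate(lpos[-2:][::-1], start=1):
        feats[f"wl-{off}={toks[i].text.lower()}"] = 1.0
    for off, i in enumerate(rpos[:2], start=1):
        feats[f"wr+{off}={toks[i].text.lower()}"] = 1.0
    feats[f"dist={min(len(between) // 3, 4)}"] = 1.0
    feats["has_connective"] = float(any(t.text.lower() in cfg.connectives for t in toks))
    feats["connective_between"] = float(any(t.text.lower() in cfg.connectives for t in between))
    feats["conj_between"] = float(any(t.text.lower() in _CONJ for t in between))
    return feats


@dataclass
class KernelModel:
    """Probabilistic pair classifier (regularized logistic model)."""

    vectorizer: DictVectorizer
    clf: LogisticRegression
    meta: dict


def train_kernel(labeled: Sequence[tuple[dict[str, float], int]], seed: int = 0) -> KernelModel:
    """Fit the pair classifier on (feature-map, 0/1 label) examples."""
    if not labeled:
        raise ValueError("empty training set")
    y = [int(lab) for _, lab in labeled]
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    vec = DictVectorizer()
    X = vec.fit_transform([f for f, _ in labeled])
    clf = LogisticRegression(max_iter=500, C=10.0, random_state=seed)
    clf.fit(X, y)
    return KernelModel(vectorizer=vec, clf=clf, meta={"n_examples": len(labeled), "seed": seed})


def extract_kernel(
    sentence: Sentence,
    pairs: Sequence[CandidatePair],
    model: KernelModel,
    cfg: ExtractorConfig,
    tokens: Sequence[Token] | None = None,
) -> list[ConnectionMention]:
    """Emit pairs the classifier scores at probability ≥ 0.5."""
    if model is None:
        raise ValueError("extract_kernel requires a trained model")
    if not pairs:
        return []
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    X = model.vectorizer.transform([pair_features(sentence, p, cfg, tokens=toks) for p in pairs])
    pos_col = list(model.clf.classes_).index(1)
    proba = model.clf.predict_proba(X)[:, pos_col]
    return [
        _emit(p, sentence, "KERNEL", cfg.confidences["KERNEL"])
        for p, pr in zip(pairs, proba)
        if pr >= 0.5
    ]


# ---------------------------------------------------------------------------
# I/O


def write_connection_mentions(items: Iterable[ConnectionMention], path: str | Path) -> int:
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for cm in items:
            fh.write(
                json.dumps(
                    {
                        "region_a": cm.region_a,
                        "region_b": cm.region_b,
                        "doc_id": cm.doc_id,
                        "sentence_index": cm.sentence_index,
                        "extractor": cm.extractor,
                        "confidence": cm.confidence,
                        "evidence_text": cm.evidence_text,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
            n += 1
    return n


def read_connection_mentions(path: str | Path) -> list[ConnectionMention]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(ConnectionMention(**json.loads(line)))
    return out
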