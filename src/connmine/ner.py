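"""Brain-region named-entity recognition.

Two complementary recognizers over tokenized sentences:

* :func:`match_lexical` — dictionary longest-match against a
  :class:`~connmine.lexicon.RegionLexicon`, scanning token subsequences up
  to a maximum phrase length and keeping maximal non-overlapping matches
  with leftmost-longest priority.  Document-local abbreviations introduced
  by the pattern ``long form (ABBR)`` are honored for the rest of the
  document.

* :func:`tag_statistical` — a trainable BIO sequence tagger (regularized
  log-linear token model with a transition-constrained Viterbi decode) that
  can mark complex region names absent from the lexicon.

:func:`merge_mentions` unions the two streams; on span overlap the lexical
mention wins because it carries a canonical region id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from connmine.corpus_io import Document, Sentence, Token, segment_sentences, tokenize
from connmine.lexicon import RegionLexicon, normalize_name

MAX_PHRASE_TOKENS = 8

_LABELS = ("O", "B", "I")

_LEAD_ARTICLES = frozenset({"the", "a", "an"})


def _wordlike(tok: Token) -> bool:
    return any(c.isalnum() for c in tok.text)


@dataclass(frozen=True)
class Mention:
    """A located brain-region mention in one sentence."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    region_id: str | None
    source: str  # "lexical" | "statistical"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class AbbreviationRegistry:
    """Document-local abbreviation → region id bindings.

    Bindings are created by :func:`register_abbreviations` from the pattern
    ``⟨lexical mention⟩ ( ⟨UPPERCASE⟩ )`` and consulted by
    :func:`match_lexical` before the lexicon, so a document-local binding
    shadows a colliding lexicon surface within its document.
    """

    def __init__(self) -> None:
        self._bindings: dict[str, str] = {}

    def bind(self, abbrev: str, region_id: str) -> None:
        self._bindings[normalize_name(abbrev)] = region_id

    def resolve(self, surface: str) -> str | None:
        return self._bindings.get(normalize_name(surface))

    def __len__(self) -> int:
        return len(self._bindings)


def match_lexical(
    sentence: Sentence,
    lex: RegionLexicon,
    tokens: Sequence[Token] | None = None,
    abbreviations: AbbreviationRegistry | None = None,
    max_len: int = MAX_PHRASE_TOKENS,
) -> list[Mention]:
    """Dictionary longest-match over token subsequences.

    Scans left to right; at each token takes the longest subsequence (up to
    *max_len* tokens) whose surface resolves in the abbreviation registry or
    the lexicon, then continues after it — i.e. maximal non-overlapping
    matches with leftmost-longest priority.
    """
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    mentions: list[Mention] = []
    i = 0
    n = len(toks)
    while i < n:
        # a mention cannot start at an article or a punctuation token, nor
        # end at one: normalization would erase them and inflate the span
        if not _wordlike(toks[i]) or toks[i].text.lower() in _LEAD_ARTICLES:
            i += 1
            continue
        best: tuple[int, str] | None = None  # (j_exclusive, region_id)
        for j in range(min(n, i + max_len), i, -1):
            if not _wordlike(toks[j - 1]):
                continue
            surface = sentence.text[toks[i].start : toks[j - 1].end]
            rid = abbreviations.resolve(surface) if abbreviations is not None else None
            if rid is None:
                rid = lex.resolve(surface)
            if rid is not None:
                best = (j, rid)
                break
        if best is None:
            i += 1
            continue
        j, rid = best
        start, end = toks[i].start, toks[j - 1].end
        mentions.append(
            Mention(
                doc_id=sentence.doc_id,
                sentence_index=sentence.index,
                start=start,
                end=end,
                surface=sentence.text[start:end],
                region_id=rid,
                source="lexical",
            )
        )
        i = j
    return mentions


def register_abbreviations(
    sentence: Sentence,
    mentions: Iterable[Mention],
    registry: AbbreviationRegistry,
    tokens: Sequence[Token] | None = None,
) -> AbbreviationRegistry:
    """Bind parenthesized uppercase abbreviations following lexical mentions.

    The pattern ``⟨mention⟩ ( ABBR )`` with a single all-uppercase token of
    length ≥ 2 binds ABBR to the mention's region id for the remainder of
    the document.
    """
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    end_to_pos = {t.end: k for k, t in enumerate(toks)}
    for m in mentions:
        if m.region_id is None:
            continue
        k = end_to_pos.get(m.end)
        if k is None or k + 3 >= len(toks):
            continue
        t_open, t_abbr, t_close = toks[k + 1], toks[k + 2], toks[k + 3]
        if (
            t_open.text == "("
            and t_close.text == ")"
            and len(t_abbr.text) >= 2
            and t_abbr.text.isalpha()
            and t_abbr.text.isupper()
        ):
            registry.bind(t_abbr.text, m.region_id)
    return registry


def merge_mentions(lexical: Sequence[Mention], statistical: Sequence[Mention]) -> list[Mention]:
    """Union of both streams; on span overlap the lexical mention wins."""
    merged = list(lexical)
    for sm in statistical:
        if any(sm.start < lm.end and lm.start < sm.end for lm in lexical):
            continue
        merged.append(sm)
    return sorted(merged, key=lambda m: (m.start, m.end))


# ---------------------------------------------------------------------------
# statistical tagger


def _shape(tok: str) -> str:
    out = []
    for c in tok:
        if c.isupper():
            out.append("X")
        elif c.islower():
            out.append("x")
        elif c.isdigit():
            out.append("d")
        else:
            out.append(c)
    s = "".join(out)
    # collapse runs to keep the shape vocabulary small
    collapsed = []
    for c in s:
        if not collapsed or collapsed[-1] != c:
            collapsed.append(c)
    return "".join(collapsed)


def _token_features(tokens: Sequence[Token], i: int, lex: RegionLexicon | None) -> dict[str, float | str]:
    feats: dict[str, float | str] = {
        "bias": 1.0,
        "lower": tokens[i].text.lower(),
        "shape": _shape(tokens[i].text),
        "pos_bucket": str(min(i // 5, 3)),
    }
    for off in (-2, -1, 1, 2):
        j = i + off
        feats[f"ctx{off}"] = tokens[j].text.lower() if 0 <= j < len(tokens) else "<pad>"
    if lex is not None:
        feats["in_lex"] = 1.0 if lex.lookup(tokens[i].text) else 0.0
    return feats


@dataclass
class TaggerModel:
    """Discriminative BIO tagger: log-linear token scores + Viterbi decode.

    Transition constraints forbid I after O or at sentence start, so decoded
    sequences are always valid BIO.
    """

    vectorizer: DictVectorizer
    clf: LogisticRegression
    lexicon_features: bool
    meta: dict

    def predict_labels(self, tokens: Sequence[Token], lex: RegionLexicon | None = None) -> list[str]:
        if not tokens:
            return []
        feats = [_token_features(tokens, i, lex if self.lexicon_features else None) for i in range(len(tokens))]
        X = self.vectorizer.transform(feats)
        logp = self.clf.predict_log_proba(X)
        order = list(self.clf.classes_)
        col = {lab: order.index(lab) for lab in _LABELS if lab in order}
        n = len(tokens)
        NEG = -1e9
        # viterbi over O/B/I with BIO validity constraints
        score = {lab: (logp[0][col[lab]] if lab in col else NEG) for lab in _LABELS}
        score["I"] = NEG  # no I at start
        back: list[dict[str, str]] = []
        for t in range(1, n):
            emit = {lab: (logp[t][col[lab]] if lab in col else NEG) for lab in _LABELS}
            new_score: dict[str, float] = {}
            bp: dict[str, str] = {}
            for lab in _LABELS:
                allowed = _LABELS if lab != "I" else ("B", "I")
                prev = max(allowed, key=lambda p: score[p])
                new_score[lab] = score[prev] + emit[lab]
                bp[lab] = prev
            score, back_t = new_score, bp
            back.append(back_t)
        lab = max(_LABELS, key=lambda l: score[l])
        labels = [lab]
        for bp in reversed(back):
            lab = bp[lab]
            labels.append(lab)
        return labels[::-1]


def train_tagger(
    annotated: Sequence[tuple[Sentence, Sequence[str]]],
    seed: int = 0,
    lex: RegionLexicon | None = None,
) -> TaggerModel:
    """Fit the BIO tagger on (sentence, label-sequence) pairs.

    Labels must align one-to-one with the sentence's tokens.  Training is
    deterministic given *seed*.
    """
    if not annotated:
        raise ValueError("empty training set")
    feats: list[dict] = []
    labels: list[str] = []
    for sent, labs in annotated:
        toks = tokenize(sent)
        if len(toks) != len(labs):
            raise ValueError(
                f"label/token misalignment in doc {sent.doc_id!r} sentence {sent.index}: "
                f"{len(labs)} labels for {len(toks)} tokens"
            )
        bad = [l for l in labs if l not in _LABELS]
        if bad:
            raise ValueError(f"invalid BIO label(s) {bad[:3]}")
        for i in range(len(toks)):
            feats.append(_token_features(toks, i, lex))
            labels.append(labs[i])
    vec = DictVectorizer()
    X = vec.fit_transform(feats)
    clf = LogisticRegression(max_iter=500, C=10.0, random_state=seed)
    clf.fit(X, labels)
    return TaggerModel(
        vectorizer=vec,
        clf=clf,
        lexicon_features=lex is not None,
        meta={"n_sentences": len(annotated), "n_tokens": len(labels), "seed": seed},
    )


def tag_statistical(
    sentence: Sentence,
    model: TaggerModel,
    lex: RegionLexicon | None = None,
    tokens: Sequence[Token] | None = None,
) -> list[Mention]:
    """Decode BIO labels and emit one mention per maximal B/I run.

    A region id is attached when the normalized surface resolves in the
    lexicon unambiguously; otherwise the mention stays unresolved.
    """
    toks = list(tokens) if tokens is not None else tokenize(sentence)
    labels = model.predict_labels(toks, lex)
    mentions: list[Mention] = []
    i = 0
    while i < len(toks):
        if labels[i] == "B":
            j = i + 1
            while j < len(toks) and labels[j] == "I":
                j += 1
            start, end = toks[i].start, toks[j - 1].end
            surface = sentence.text[start:end]
            rid = None
            if lex is not None:
                cands = lex.lookup(surface)
                if len(cands) == 1:
                    rid = next(iter(cands))
            mentions.append(
                Mention(
                    doc_id=sentence.doc_id,
                    sentence_index=sentence.index,
                    start=start,
                    end=end,
                    surface=surface,
                    region_id=rid,
                    source="statistical",
                )
            )
            i = j
        else:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# document-level driver and I/O


def annotate_document(
    doc: Document,
    lex: RegionLexicon,
    mode: str = "lexical",
    model: TaggerModel | None = None,
) -> list[tuple[Sentence, list[Mention]]]:
    """Run NER over a document sentence by sentence.

    *mode* is ``lexical``, ``statistical`` or ``both``.  Abbreviation
    bindings registered in earlier sentences apply to later ones.
    """
    if mode not in {"lexical", "statistical", "both"}:
        raise ValueError(f"unknown NER mode {mode!r}")
    if mode in {"statistical", "both"} and model is None:
        raise ValueError(f"NER mode {mode!r} requires a trained tagger model")
    registry = AbbreviationRegistry()
    out: list[tuple[Sentence, list[Mention]]] = []
    for sent in segment_sentences(doc):
        toks = tokenize(sent)
        lexical: list[Mention] = []
        statistical: list[Mention] = []
        if mode in {"lexical", "both"}:
            lexical = match_lexical(sent, lex, tokens=toks, abbreviations=registry)
            register_abbreviations(sent, lexical, registry, tokens=toks)
        if mode in {"statistical", "both"}:
            statistical = tag_statistical(sent, model, lex, tokens=toks)
        out.append((sent, merge_mentions(lexical, statistical)))
    return out


def write_mentions(items: Iterable[Mention], path: str | Path) -> int:
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for m in items:
            fh.write(
                json.dumps(
                    {
                        "doc_id": m.doc_id,
                        "sentence_index": m.sentence_index,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                        "region_id": m.region_id,
                        "source": m.source,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
            n += 1
    return n


def read_mentions(path: str | Path) -> list[Mention]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(Mention(**json.loads(line)))
    return out
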