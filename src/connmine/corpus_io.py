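"""Corpus reading/writing, sentence segmentation and tokenization.

Documents are the unit of input (one per publication: identifier plus
title/abstract or full text).  Sentences and tokens carry character spans
(0-based, half-open, counted in Unicode code points) back into their parent
text so that every downstream annotation can be re-sliced exactly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

SOURCES = ("abstracts", "fulltext", "synthetic")

#: Abbreviations that must not terminate a sentence even when followed by
#: whitespace and an uppercase letter.
ABBREV_GUARD = frozenset(
    {
        "e.g.",
        "i.e.",
        "et al.",
        "al.",
        "etc.",
        "cf.",
        "vs.",
        "ca.",
        "approx.",
        "fig.",
        "figs.",
        "no.",
        "dr.",
        "st.",
        "resp.",
    }
)


@dataclass(frozen=True)
class Document:
    """One publication record."""

    doc_id: str
    text: str
    source: str = "abstracts"
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.text:
            raise ValueError(f"document {self.doc_id!r}: text must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"document {self.doc_id!r}: unknown source {self.source!r}")


@dataclass(frozen=True)
class Sentence:
    """A sentence located inside a document by character span."""

    doc_id: str
    index: int
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Token:
    """A token located inside a sentence by character span."""

    text: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# corpus I/O


def read_corpus(path: str | Path, format: str = "jsonl") -> Iterator[Document]:
    """Yield :class:`Document` records from *path* in input order.

    Supported formats: ``jsonl`` (one JSON object per line with keys
    ``doc_id``, ``text``, ``source``, ``meta``), ``text_dir`` (a directory of
    ``*.txt`` files, file stem as doc_id), and ``pubmed_xml`` (PubMed-style
    article sets; title + abstract only).  Duplicate document identifiers
    raise :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "jsonl":
        gen = _read_jsonl(path)
    elif format == "text_dir":
        gen = _read_text_dir(path)
    elif format == "pubmed_xml":
        gen = _read_pubmed_xml(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for doc in gen:
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        yield doc


def _read_jsonl(path: Path) -> Iterator[Document]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                yield Document(
                    doc_id=str(rec["doc_id"]),
                    text=rec["text"],
                    source=rec.get("source", "abstracts"),
                    meta={str(k): str(v) for k, v in rec.get("meta", {}).items()},
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed corpus record at line {lineno} of {path}: {exc}") from exc


def _read_text_dir(path: Path) -> Iterator[Document]:
    if not path.is_dir():
        raise ValueError(f"{path} is not a directory")
    for fp in sorted(path.glob("*.txt")):
        text = fp.read_text(encoding="utf-8")
        yield Document(doc_id=fp.stem, text=text, source="fulltext")


def _read_pubmed_xml(path: Path) -> Iterator[Document]:
    """Extract PMID + title + abstract from PubMed-style XML."""
    tree = etree.parse(str(path))
    articles = tree.findall(".//PubmedArticle")
    if not articles:
        articles = tree.findall(".//Article")
    for i, art in enumerate(articles, start=1):
        pmid_el = art.find(".//PMID")
        title_el = art.find(".//ArticleTitle")
        abstract_parts = ["".join(t.itertext()) for t in art.findall(".//AbstractText")]
        if pmid_el is None or pmid_el.text is None:
            raise ValueError(f"malformed PubMed record number {i}: missing PMID")
        title = "".join(title_el.itertext()) if title_el is not None else ""
        text = " ".join(p for p in [title] + abstract_parts if p).strip()
        if not text:
            raise ValueError(f"malformed PubMed record number {i}: no title or abstract text")
        yield Document(doc_id=pmid_el.text.strip(), text=text, source="abstracts")


def write_corpus(docs: Iterable[Document], path: str | Path, format: str = "jsonl") -> int:
    """Write documents as JSON-lines; returns the number of records written."""
    if format != "jsonl":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {"doc_id": doc.doc_id, "text": doc.text, "source": doc.source, "meta": doc.meta}
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# sentence segmentation

_TERMINATOR_RE = re.compile(r"[.?!]+(?=\s+[\"'(]?[A-Z0-9])")


def segment_sentences(doc: Document) -> list[Sentence]:
    """Rule-based sentence segmentation with a fixed abbreviation guard.

    A period/question/exclamation mark followed by whitespace and an
    uppercase letter or digit ends a sentence unless the preceding word is a
    guarded abbreviation (``e.g.``, ``et al.``, ``Fig.`` ...).  Returned
    sentences are trimmed of surrounding whitespace; spans index the
    document text.
    """
    text = doc.text
    boundaries: list[int] = []
    for m in _TERMINATOR_RE.finditer(text):
        end = m.end()
        # word containing the terminator, e.g. "al." in "et al."
        wstart = end
        while wstart > 0 and not text[wstart - 1].isspace():
            wstart -= 1
        word = text[wstart:end].lower()
        prev_word = ""
        pend = wstart
        while pend > 0 and text[pend - 1].isspace():
            pend -= 1
        pstart = pend
        while pstart > 0 and not text[pstart - 1].isspace():
            pstart -= 1
        prev_word = text[pstart:pend].lower()
        if word in ABBREV_GUARD or f"{prev_word} {word}" in ABBREV_GUARD:
            continue
        boundaries.append(end)
    boundaries.append(len(text))

    sentences: list[Sentence] = []
    cursor = 0
    for b in boundaries:
        start, end = cursor, b
        while start < end and text[start].isspace():
            start += 1
        while end > start and text[end - 1].isspace():
            end -= 1
        if start < end:
            sentences.append(
                Sentence(doc_id=doc.doc_id, index=len(sentences), start=start, end=end, text=text[start:end])
            )
        cursor = b
    return sentences


# ---------------------------------------------------------------------------
# tokenization

_PUNCT = ".,;:!?()[]{}\"'`“”‘’«»"


def tokenize(sentence: Sentence | str) -> list[Token]:
    """Whitespace tokenization with leading/trailing punctuation split off.

    Hyphenated words stay single tokens; internal punctuation (e.g. the
    period in "3.5") is preserved.  Token spans index the sentence text.
    """
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, cstart = m.group(), m.start()
        lead = 0
        while lead < len(chunk) and chunk[lead] in _PUNCT:
            lead += 1
        trail = len(chunk)
        while trail > lead and chunk[trail - 1] in _PUNCT:
            trail -= 1
        for i in range(lead):
            tokens.append(Token(chunk[i], cstart + i, cstart + i + 1))
        if lead < trail:
            tokens.append(Token(chunk[lead:trail], cstart + lead, cstart + trail))
        for i in range(trail, len(chunk)):
            tokens.append(Token(chunk[i], cstart + i, cstart + i + 1))
    return tokens
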