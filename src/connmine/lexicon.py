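"""Canonical brain-region lexicon with synonym merging and hierarchy.

A lexicon is assembled from one or more vocabulary TSVs (columns
``region_id``, ``preferred_name``, ``synonyms`` pipe-separated,
``parent_id``, ``source``).  The first-listed source is the atlas of
record: it defines canonical identifiers and the hierarchy; later sources
attach additional synonyms, merged by id or by exact normalized
preferred-name match.  A normalized surface mapping to more than one region
is kept and reported as ambiguous; resolution order is the rank of the best
source attached to each candidate entry, ties broken by lexicographic id.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

_ARTICLE_RE = re.compile(r"^(?:the\s+)+")
_WS_RE = re.compile(r"\s+")
# keep word characters, spaces and hyphens; hyphens surrounded by word chars survive
_PUNCT_RE = re.compile(r"[^\w\s-]|_")
_DANGLING_HYPHEN_RE = re.compile(r"(?<![^\W\d_])-|-(?![^\W\d_])", re.UNICODE)


def normalize_name(surface: str) -> str:
    """Normalize a region surface form for dictionary matching.

    Case-folds, applies Unicode compatibility (NFKD) normalization and
    strips diacritics, removes punctuation except internal hyphens,
    collapses whitespace and drops a leading article.  Idempotent.
    """
    s = unicodedata.normalize("NFKD", surface)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.casefold()
    s = _PUNCT_RE.sub(" ", s)
    s = _DANGLING_HYPHEN_RE.sub(" ", s)
    s = _WS_RE.sub(" ", s).strip()
    s = _ARTICLE_RE.sub("", s)
    return s


@dataclass
class RegionEntry:
    """One canonical brain region with its synonym set."""

    region_id: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    parent_id: str | None = None
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.synonyms.add(self.preferred_name)


class RegionLexicon:
    """Map of region entries plus a normalized-surface index."""

    def __init__(self, entries: Iterable[RegionEntry], source_order: list[str] | None = None):
        self.entries: dict[str, RegionEntry] = {}
        for e in entries:
            if e.region_id in self.entries:
                raise ValueError(f"duplicate region_id {e.region_id!r}")
            self.entries[e.region_id] = e
        self.source_order: list[str] = list(source_order or [])
        for e in self.entries.values():
            if e.parent_id is not None and e.parent_id not in self.entries:
                raise ValueError(f"entry {e.region_id!r}: unknown parent_id {e.parent_id!r}")
        self._check_no_cycles()
        self.index: dict[str, set[str]] = {}
        for e in self.entries.values():
            for syn in e.synonyms:
                norm = normalize_name(syn)
                if norm:
                    self.index.setdefault(norm, set()).add(e.region_id)

    def _check_no_cycles(self) -> None:
        for rid in self.entries:
            seen = {rid}
            cur = self.entries[rid].parent_id
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"parent cycle involving {rid!r}")
                seen.add(cur)
                cur = self.entries[cur].parent_id

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.entries

    def __getitem__(self, region_id: str) -> RegionEntry:
        return self.entries[region_id]

    # -- lookup -------------------------------------------------------------

    def lookup(self, surface: str) -> set[str]:
        """Region ids whose synonym set contains the normalized surface."""
        return set(self.index.get(normalize_name(surface), set()))

    def _source_rank(self, entry: RegionEntry) -> int:
        ranks = [self.source_order.index(s) for s in entry.sources if s in self.source_order]
        return min(ranks) if ranks else len(self.source_order)

    def resolve(self, surface: str) -> str | None:
        """Deterministically resolve a surface to a single region id.

        Ambiguous surfaces resolve to the candidate whose best-ranked source
        comes first in the source order, ties by lexicographic region id.
        """
        cands = self.lookup(surface)
        if not cands:
            return None
        return min(cands, key=lambda rid: (self._source_rank(self.entries[rid]), rid))

    def ambiguities(self) -> dict[str, set[str]]:
        """Normalized surfaces mapping to more than one region id."""
        return {s: set(ids) for s, ids in self.index.items() if len(ids) > 1}

    # -- hierarchy ----------------------------------------------------------

    def ancestors(self, region_id: str) -> list[str]:
        if region_id not in self.entries:
            raise KeyError(region_id)
        chain: list[str] = []
        cur = self.entries[region_id].parent_id
        while cur is not None:
            chain.append(cur)
            cur = self.entries[cur].parent_id
        return chain

    def related(self, a: str, b: str) -> str:
        """Relation of *a* to *b*: 'same', 'ancestor', 'descendant' or 'unrelated'."""
        if a not in self.entries:
            raise KeyError(a)
        if b not in self.entries:
            raise KeyError(b)
        if a == b:
            return "same"
        if a in self.ancestors(b):
            return "ancestor"
        if b in self.ancestors(a):
            return "descendant"
        return "unrelated"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source_order": self.source_order,
            "entries": [
                {
                    "region_id": e.region_id,
                    "preferred_name": e.preferred_name,
                    "synonyms": sorted(e.synonyms),
                    "parent_id": e.parent_id,
                    "sources": sorted(e.sources),
                }
                for e in sorted(self.entries.values(), key=lambda e: e.region_id)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "RegionLexicon":
        entries = [
            RegionEntry(
                region_id=r["region_id"],
                preferred_name=r["preferred_name"],
                synonyms=set(r["synonyms"]),
                parent_id=r.get("parent_id"),
                sources=set(r.get("sources", [])),
            )
            for r in d["entries"]
        ]
        return cls(entries, source_order=d.get("source_order", []))

    @classmethod
    def load(cls, path: str | Path) -> "RegionLexicon":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def read_vocabulary(path: str | Path) -> list[dict]:
    """Read one vocabulary TSV into row dicts; validates names are present."""
    path = Path(path)
    rows: list[dict] = []
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):  # header is line 1
            rid = (row.get("region_id") or "").strip()
            name = (row.get("preferred_name") or "").strip()
            if not rid:
                raise ValueError(f"{path} row {i}: missing region_id")
            if not name:
                raise ValueError(f"{path} row {i}: missing preferred_name")
            syns = [s.strip() for s in (row.get("synonyms") or "").split("|") if s.strip()]
            rows.append(
                {
                    "region_id": rid,
                    "preferred_name": name,
                    "synonyms": syns,
                    "parent_id": (row.get("parent_id") or "").strip() or None,
                    "source": (row.get("source") or "").strip() or path.stem,
                }
            )
    return rows


def build_lexicon(sources: list[str | Path]) -> RegionLexicon:
    """Build a merged lexicon from vocabulary files.

    The first file is the source of record (canonical ids and hierarchy).
    Rows of later files merge into an existing entry when their region_id
    matches, else when their normalized preferred name equals that of an
    existing entry; otherwise they create a new entry.  Synonym sets are
    unioned.  Merging is order-independent in content up to the canonical
    id chosen for name-merged rows.
    """
    if not sources:
        raise ValueError("at least one vocabulary source is required")
    all_rows = [(Path(p), read_vocabulary(p)) for p in sources]
    source_order: list[str] = []
    for _, rows in all_rows:
        for row in rows:
            if row["source"] not in source_order:
                source_order.append(row["source"])

    entries: dict[str, RegionEntry] = {}
    by_norm_name: dict[str, str] = {}
    for _, rows in all_rows:
        for row in rows:
            target: RegionEntry | None = None
            if row["region_id"] in entries:
                target = entries[row["region_id"]]
            else:
                norm = normalize_name(row["preferred_name"])
                if norm in by_norm_name:
                    target = entries[by_norm_name[norm]]
            if target is None:
                target = RegionEntry(
                    region_id=row["region_id"],
                    preferred_name=row["preferred_name"],
                    synonyms=set(row["synonyms"]),
                    parent_id=row["parent_id"],
                    sources={row["source"]},
                )
                entries[target.region_id] = target
                by_norm_name.setdefault(normalize_name(target.preferred_name), target.region_id)
            else:
                target.synonyms.update(row["synonyms"])
                target.synonyms.add(row["preferred_name"])
                target.sources.add(row["source"])
                if target.parent_id is None and row["parent_id"] in entries:
                    target.parent_id = row["parent_id"]

    # drop parent links pointing outside the merged id space
    for e in entries.values():
        if e.parent_id is not None and e.parent_id not in entries:
            e.parent_id = None
    return RegionLexicon(entries.values(), source_order=source_order)
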