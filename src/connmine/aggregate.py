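"""Corpus-wide aggregation of connection mentions into a scored database.

Each unordered region pair accumulates its evidence sentences; the mention
unit is a (document, sentence, pair) triple, deduplicated across extractors
by keeping the highest-confidence one.  A pair's score is the rounded
(half away from zero) sum of the deduplicated confidences — the number of
connection mentions normalized by the confidence that each was extracted
correctly.  High scores mean many supporting articles, not a physiologically
strong connection.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from connmine.lexicon import RegionLexicon
from connmine.relations import ConnectionMention

_EXTRACTOR_TIEBREAK = {"RULES": 0, "KERNEL": 1, "FILTER": 2}


def dedup(mentions: Sequence[ConnectionMention]) -> list[ConnectionMention]:
    """Keep one item per (doc, sentence, pair): highest confidence wins.

    Confidence ties break by extractor preference RULES > KERNEL > FILTER.
    Output preserves first-seen order of the surviving keys.
    """
    best: dict[tuple, ConnectionMention] = {}
    order: list[tuple] = []
    for cm in mentions:
        key = cm.sentence_key
        if key not in best:
            best[key] = cm
            order.append(key)
        else:
            cur = best[key]
            if (-cm.confidence, _EXTRACTOR_TIEBREAK.get(cm.extractor, 9)) < (
                -cur.confidence,
                _EXTRACTOR_TIEBREAK.get(cur.extractor, 9),
            ):
                best[key] = cm
    return [best[k] for k in order]


def score(dedup_mentions: Sequence[ConnectionMention]) -> int:
    """Round-half-away-from-zero sum of confidences for one pair."""
    keys = {cm.pair_key for cm in dedup_mentions}
    if len(keys) > 1:
        raise ValueError(f"score() expects mentions of a single pair, got {sorted(keys)}")
    total = sum(cm.confidence for cm in dedup_mentions)
    return int(math.floor(total + 0.5))


@dataclass
class ConnectionRecord:
    """Aggregated evidence for one unordered region pair."""

    region_a: str
    region_b: str
    n_mentions: int
    score: int
    evidence: list[ConnectionMention]
    species_counts: dict[str, int] = field(default_factory=dict)

    @property
    def pair_key(self) -> tuple[str, str]:
        return (self.region_a, self.region_b)

    @property
    def doc_ids(self) -> set[str]:
        return {cm.doc_id for cm in self.evidence}


@dataclass
class ConnectivityDB:
    """Scored region-pair records plus provenance."""

    records: dict[tuple[str, str], ConnectionRecord]
    provenance: dict = field(default_factory=dict)

    def regions(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.records:
            out.add(a)
            out.add(b)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "records": {
                f"{a}|{b}": {
                    "region_a": r.region_a,
                    "region_b": r.region_b,
                    "n_mentions": r.n_mentions,
                    "score": r.score,
                    "species_counts": dict(sorted(r.species_counts.items())),
                    "evidence": [
                        {
                            "doc_id": cm.doc_id,
                            "sentence_index": cm.sentence_index,
                            "extractor": cm.extractor,
                            "confidence": cm.confidence,
                            "evidence_text": cm.evidence_text,
                        }
                        for cm in r.evidence
                    ],
                }
                for (a, b), r in sorted(self.records.items())
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityDB":
        records = {}
        for key, r in d["records"].items():
            a, b = key.split("|")
            records[(a, b)] = ConnectionRecord(
                region_a=r["region_a"],
                region_b=r["region_b"],
                n_mentions=r["n_mentions"],
                score=r["score"],
                species_counts=dict(r.get("species_counts", {})),
                evidence=[
                    ConnectionMention(
                        region_a=a,
                        region_b=b,
                        doc_id=e["doc_id"],
                        sentence_index=e["sentence_index"],
                        extractor=e["extractor"],
                        confidence=e["confidence"],
                        evidence_text=e["evidence_text"],
                    )
                    for e in r["evidence"]
                ],
            )
        return cls(records=records, provenance=d.get("provenance", {}))

    @classmethod
    def load(cls, path: str | Path) -> "ConnectivityDB":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_edge_list(self, path: str | Path) -> int:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region_a", "region_b", "n_mentions", "score"])
            n = 0
            for (a, b), r in sorted(self.records.items()):
                w.writerow([a, b, r.n_mentions, r.score])
                n += 1
        return n


def build_db(
    mentions: Iterable[ConnectionMention],
    lex: RegionLexicon,
    species_tags: Mapping[str, Sequence] | None = None,
    provenance: dict | None = None,
) -> ConnectivityDB:
    """Group deduplicated mentions by pair and fill counts, scores and species.

    *species_tags* maps doc_id → iterable of :class:`~connmine.species.SpeciesTag`
    (or any object with ``taxon_label``); each taxon counts a document once
    per pair.
    """
    deduped = dedup(list(mentions))
    for cm in deduped:
        for rid in cm.pair_key:
            if rid not in lex:
                raise ValueError(f"connection mention references unknown region id {rid!r}")
    groups: dict[tuple[str, str], list[ConnectionMention]] = {}
    for cm in deduped:
        groups.setdefault(cm.pair_key, []).append(cm)
    records: dict[tuple[str, str], ConnectionRecord] = {}
    for key in sorted(groups):
        ev = groups[key]
        sp_counts: dict[str, int] = {}
        if species_tags is not None:
            for doc_id in sorted({cm.doc_id for cm in ev}):
                for tag in species_tags.get(doc_id, []):
                    label = getattr(tag, "taxon_label", str(tag))
                    sp_counts[label] = sp_counts.get(label, 0) + 1
        records[key] = ConnectionRecord(
            region_a=key[0],
            region_b=key[1],
            n_mentions=len(ev),
            score=score(ev),
            evidence=ev,
            species_counts=sp_counts,
        )
    return ConnectivityDB(records=records, provenance=provenance or {})


def query_region(db: ConnectivityDB, region_id: str, lex: RegionLexicon) -> list[tuple[str, int]]:
    """Ranked proposed targets for a seed region.

    All partners of *region_id*, sorted by descending score, ties by
    ascending preferred name.  This list is what gets evaluated against a
    curated gold target list.
    """
    if region_id not in lex:
        raise KeyError(f"unknown region id {region_id!r}")
    partners: list[tuple[str, int]] = []
    for (a, b), rec in db.records.items():
        if region_id == a:
            partners.append((b, rec.score))
        elif region_id == b:
            partners.append((a, rec.score))
    partners.sort(key=lambda t: (-t[1], lex[t[0]].preferred_name if t[0] in lex else t[0]))
    return partners


def matrix(db: ConnectivityDB, top_n: int) -> pd.DataFrame:
    """Symmetric score matrix over the top-*top_n* regions by total score mass."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mass: dict[str, int] = {}
    for (a, b), rec in db.records.items():
        mass[a] = mass.get(a, 0) + rec.score
        mass[b] = mass.get(b, 0) + rec.score
    top = sorted(mass, key=lambda r: (-mass[r], r))[:top_n]
    df = pd.DataFrame(0, index=top, columns=top, dtype=int)
    for (a, b), rec in db.records.items():
        if a in df.index and b in df.index:
            df.loc[a, b] = rec.score
            df.loc[b, a] = rec.score
    return df
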