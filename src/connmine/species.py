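"""Species tagging of documents and per-seed species breakdowns.

A deterministic dictionary tagger resolves species mentions (common and
Latin names) to taxa; the packaged dictionary covers the taxa that dominate
connectivity reports (Rattus, Mus, Homo Sapiens, Simiiformes, Chordata,
Felidae, Canis).  Documents with no match are reported downstream under
"No species found".  Matching is longest-match over tokens, with the same
surface normalization used for region NER.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from connmine.corpus_io import Document, tokenize
from connmine.lexicon import normalize_name

NO_SPECIES = "No species found"

_MAX_VARIANT_TOKENS = 3


@dataclass(frozen=True)
class SpeciesTag:
    """One taxon attributed to a document, with the surfaces that matched."""

    doc_id: str
    taxon_id: str
    taxon_label: str
    matched_surfaces: tuple[str, ...]


@dataclass
class SpeciesDict:
    """taxon_id → (label, normalized-variant set)."""

    entries: dict[str, tuple[str, set[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (label, variants) in self.entries.items():
            if not variants:
                raise ValueError(f"taxon {tid!r} ({label}) has no name variants")

    @property
    def index(self) -> dict[str, str]:
        idx: dict[str, str] = {}
        for tid in sorted(self.entries):
            _, variants = self.entries[tid]
            for v in variants:
                idx.setdefault(v, tid)
        return idx

    def ambiguities(self) -> dict[str, set[str]]:
        by_variant: dict[str, set[str]] = {}
        for tid, (_, variants) in self.entries.items():
            for v in variants:
                by_variant.setdefault(v, set()).add(tid)
        return {v: tids for v, tids in by_variant.items() if len(tids) > 1}


def load_species_dict(path: str | Path | None = None) -> SpeciesDict:
    """Load the species dictionary TSV (packaged default or a user file)."""
    if path is None:
        text = resources.files("connmine.data").joinpath("species.tsv").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    entries: dict[str, tuple[str, set[str]]] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        tid = row["taxon_id"].strip()
        label = row["label"].strip()
        variants = {normalize_name(v) for v in row["variants"].split("|") if v.strip()}
        variants.add(normalize_name(label))
        entries[tid] = (label, variants)
    return SpeciesDict(entries=entries)


def tag_species(doc: Document, sdict: SpeciesDict) -> list[SpeciesTag]:
    """Dictionary longest-match over the whole document text.

    Returns one tag per distinct taxon, in order of first occurrence; an
    unmatched document yields an empty list.
    """
    idx = sdict.index
    toks = tokenize(doc.text)
    found: dict[str, list[str]] = {}
    order: list[str] = []
    i = 0
    while i < len(toks):
        hit = None
        if not any(c.isalnum() for c in toks[i].text):
            i += 1
            continue
        for j in range(min(len(toks), i + _MAX_VARIANT_TOKENS), i, -1):
            if not any(c.isalnum() for c in toks[j - 1].text):
                continue
            surface = doc.text[toks[i].start : toks[j - 1].end]
            tid = idx.get(normalize_name(surface))
            if tid is not None:
                hit = (j, tid, surface)
                break
        if hit is None:
            i += 1
            continue
        j, tid, surface = hit
        if tid not in found:
            found[tid] = []
            order.append(tid)
        found[tid].append(surface)
        i = j
    return [
        SpeciesTag(doc_id=doc.doc_id, taxon_id=tid, taxon_label=sdict.entries[tid][0], matched_surfaces=tuple(found[tid]))
        for tid in order
    ]


def tag_corpus(docs: Iterable[Document], sdict: SpeciesDict) -> dict[str, list[SpeciesTag]]:
    """Tag every document; the result maps doc_id → tags (possibly empty)."""
    return {doc.doc_id: tag_species(doc, sdict) for doc in docs}


def species_breakdown(
    db,
    seed_region: str,
    tags: Mapping[str, Sequence[SpeciesTag]],
) -> pd.DataFrame:
    """Per-species publication counts for a seed region's evidence.

    Counts distinct documents contributing evidence for any pair containing
    the seed, grouped by taxon; untagged documents fall under
    ``"No species found"``.  Percentages are over the seed's documents,
    reported to one decimal.  A document tagged with several taxa counts
    once per taxon, so percentages can sum above 100 in that case.
    """
    if seed_region not in db.regions():
        raise KeyError(f"seed region {seed_region!r} has no records in the database")
    docs: set[str] = set()
    for (a, b), rec in db.records.items():
        if seed_region in (a, b):
            docs.update(rec.doc_ids)
    total = len(docs)
    counts: dict[str, int] = {}
    for doc_id in sorted(docs):
        doc_tags = list(tags.get(doc_id, []))
        if not doc_tags:
            counts[NO_SPECIES] = counts.get(NO_SPECIES, 0) + 1
        else:
            for t in {t.taxon_label for t in doc_tags}:
                counts[t] = counts.get(t, 0) + 1
    rows = [
        {"taxon": taxon, "n_documents": n, "percentage": round(100.0 * n / total, 1)}
        for taxon, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_documents", "percentage"])


def write_species_tags(tags: Mapping[str, Sequence[SpeciesTag]], path: str | Path) -> int:
    n = 0
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc_id in sorted(tags):
            for t in tags[doc_id]:
                fh.write(
                    json.dumps(
                        {
                            "doc_id": t.doc_id,
                            "taxon_id": t.taxon_id,
                            "taxon_label": t.taxon_label,
                            "matched_surfaces": list(t.matched_surfaces),
                        },
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )
                n += 1
    return n


def read_species_tags(path: str | Path) -> dict[str, list[SpeciesTag]]:
    out: dict[str, list[SpeciesTag]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                tag = SpeciesTag(
                    doc_id=d["doc_id"],
                    taxon_id=d["taxon_id"],
                    taxon_label=d["taxon_label"],
                    matched_surfaces=tuple(d["matched_surfaces"]),
                )
                out.setdefault(tag.doc_id, []).append(tag)
    return out
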