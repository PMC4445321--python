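"""Precision/recall evaluation of proposed targets against gold lists.

For each seed region, the ranked target list from the connectivity
database is compared with a manually curated gold target list.  A gold
target counts as found when a proposed region's synonym set contains its
normalized name, or — hierarchical credit — when the gold name resolves in
the lexicon to a region on the same parent chain as a proposed region (a
proposal of "thalamus" gets credit for the gold target "ventral thalamic
nuclei" and vice versa).  Seeds are pooled by summing counts before
computing the overall precision and recall (micro-averaging); that is the
only averaging scheme under which pooled metrics follow from per-seed
counts.

Afferent and efferent gold entries are merged into one undirected target
set per seed, since extraction does not recover direction.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from connmine.lexicon import RegionLexicon, normalize_name

RELATIONS = ("afferent", "efferent", "either")


@dataclass(frozen=True)
class GoldTarget:
    name: str
    relation: str = "either"


@dataclass
class GoldTargetList:
    """Curated connectivity targets for one seed region."""

    seed: str
    targets: list[GoldTarget]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.targets:
            if not t.name:
                raise ValueError(f"seed {self.seed!r}: empty target name")
            norm = normalize_name(t.name)
            if norm in seen:
                raise ValueError(f"seed {self.seed!r}: duplicate target {t.name!r}")
            seen.add(norm)

    def __len__(self) -> int:
        return len(self.targets)


def load_gold_lists(path: str | Path | None = None) -> dict[str, GoldTargetList]:
    """Read gold CSV (columns seed, target_name, relation) into per-seed lists.

    Rows repeating a target for the same seed under both directions merge
    into a single undirected entry (relation "either").
    """
    if path is None:
        text = resources.files("connmine.data").joinpath("gold_targets.csv").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    per_seed: dict[str, dict[str, GoldTarget]] = {}
    for row in csv.DictReader(text.splitlines()):
        seed = row["seed"].strip()
        name = row["target_name"].strip()
        rel = (row.get("relation") or "either").strip() or "either"
        if rel not in RELATIONS:
            raise ValueError(f"unknown relation {rel!r} for {seed}/{name}")
        norm = normalize_name(name)
        bucket = per_seed.setdefault(seed, {})
        if norm in bucket and bucket[norm].relation != rel:
            bucket[norm] = GoldTarget(name=bucket[norm].name, relation="either")
        else:
            bucket.setdefault(norm, GoldTarget(name=name, relation=rel))
    return {seed: GoldTargetList(seed=seed, targets=list(b.values())) for seed, b in per_seed.items()}


@dataclass(frozen=True)
class EvalCounts:
    """One evaluation row: counts and derived precision/recall for a seed."""

    seed: str
    gold_n: int
    proposed_n: int
    missed_n: int

    def __post_init__(self) -> None:
        if not (0 <= self.missed_n <= self.gold_n):
            raise ValueError(f"missed_n {self.missed_n} outside [0, gold_n={self.gold_n}]")

    @property
    def tp(self) -> int:
        return self.gold_n - self.missed_n

    @property
    def precision(self) -> float | None:
        """Exact fraction tp / proposed_n (None when nothing was proposed)."""
        return self.tp / self.proposed_n if self.proposed_n else None

    @property
    def recall(self) -> float:
        return self.tp / self.gold_n if self.gold_n else 0.0

    @staticmethod
    def _round2(x: float | None) -> float | None:
        if x is None:
            return None
        return math.floor(x * 100 + 0.5) / 100

    @property
    def precision_2dp(self) -> float | None:
        return self._round2(self.precision)

    @property
    def recall_2dp(self) -> float:
        return self._round2(self.recall)


def match_target(
    gold_name: str,
    proposed: Iterable[str],
    lex: RegionLexicon,
) -> tuple[bool, str | None, str]:
    """Decide whether a gold target is covered by the proposed regions.

    Returns ``(found, matched_region_id, how)`` with ``how`` one of
    ``"exact"`` (synonym match), ``"hierarchy"`` (ancestor/descendant
    credit) or ``"none"``.  Exact/synonym matches are preferred.
    """
    norm = normalize_name(gold_name)
    proposed = list(proposed)
    for rid in proposed:
        if rid in lex and any(normalize_name(s) == norm for s in lex[rid].synonyms):
            return True, rid, "exact"
    gold_ids = lex.lookup(gold_name)
    for gid in sorted(gold_ids):
        for rid in proposed:
            if rid in lex and lex.related(gid, rid) in {"same", "ancestor", "descendant"}:
                return True, rid, "hierarchy"
    return False, None, "none"


def evaluate_seed(
    gold: GoldTargetList,
    proposed: Sequence[tuple[str, int]] | Sequence[str],
    lex: RegionLexicon,
) -> EvalCounts:
    """Count gold targets missed by the proposed (ranked) target list."""
    if len(gold) == 0:
        raise ValueError(f"empty gold list for seed {gold.seed!r}: recall undefined")
    proposed_ids = [p[0] if isinstance(p, tuple) else p for p in proposed]
    missed = 0
    for target in gold.targets:
        found, _, _ = match_target(target.name, proposed_ids, lex)
        if not found:
            missed += 1
    return EvalCounts(seed=gold.seed, gold_n=len(gold), proposed_n=len(proposed_ids), missed_n=missed)


def evaluate_overall(per_seed: Sequence[EvalCounts]) -> EvalCounts:
    """Micro-average: pool counts across seeds, then derive the metrics."""
    if not per_seed:
        raise ValueError("no per-seed counts to pool")
    return EvalCounts(
        seed="Overall",
        gold_n=sum(e.gold_n for e in per_seed),
        proposed_n=sum(e.proposed_n for e in per_seed),
        missed_n=sum(e.missed_n for e in per_seed),
    )


def write_report(rows: Sequence[EvalCounts], path: str | Path) -> None:
    """CSV report with the counts and 2-decimal metrics, one row per seed."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["seed", "gold_n", "proposed_n", "missed_n", "tp", "precision", "recall"])
        for e in rows:
            w.writerow(
                [
                    e.seed,
                    e.gold_n,
                    e.proposed_n,
                    e.missed_n,
                    e.tp,
                    "" if e.precision_2dp is None else f"{e.precision_2dp:.2f}",
                    f"{e.recall_2dp:.2f}",
                ]
            )
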