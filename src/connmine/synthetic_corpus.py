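"""Deterministic synthetic corpora with full ground truth.

Generates abstract-like documents containing templated connectivity
statements (instantiations of the nine surface rule templates plus one
held-out connective phrasing that the rules do not cover), coordinating-
conjunction distractors ("both A and B were examined" — co-mentioned but
not connected), region-free prose, species mentions, and document-local
abbreviation definitions.  Every emitted sentence carries machine-readable
ground truth (mention spans, BIO labels, true connection pairs, document
species), so each pipeline stage can be tested against construction.

The generator is integer-seeded and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import random

from connmine.corpus_io import Document, Sentence, tokenize
from connmine.lexicon import RegionEntry, RegionLexicon
from connmine.evaluation import GoldTarget, GoldTargetList
from connmine.ner import match_lexical
from connmine.relations import ExtractorConfig, candidate_pairs, pair_features

# ---------------------------------------------------------------------------
# toy lexicon

_MODIFIERS = ["medial", "lateral", "ventral", "dorsal", "anterior", "posterior", "central", "rostral"]
_HEADS = [
    "tegmental nucleus",
    "pallidal complex",
    "striatal field",
    "thalamic area",
    "habenular nucleus",
    "cerebellar field",
    "olfactory area",
    "reticular core",
]
_PARENTS = ["telencephalon", "diencephalon", "mesencephalon", "rhombencephalon"]


def toy_lexicon(n_regions: int = 24, ambiguous_abbrevs: bool = True) -> RegionLexicon:
    """A small deterministic region lexicon with synonyms and a hierarchy.

    Region names are modifier + head combinations ("medial tegmental
    nucleus"); each region gets an initials abbreviation as a synonym, and
    with *ambiguous_abbrevs* some abbreviations collide across regions to
    exercise ambiguity reporting and resolution.
    """
    entries: list[RegionEntry] = [
        RegionEntry(region_id=f"P{k}", preferred_name=name, sources={"toy"})
        for k, name in enumerate(_PARENTS)
    ]
    names = [(m, h) for h in _HEADS for m in _MODIFIERS]
    if n_regions > len(names):
        raise ValueError(f"at most {len(names)} toy regions available")
    for i, (mod, head) in enumerate(names[:n_regions]):
        name = f"{mod} {head}"
        abbr = "".join(w[0].upper() for w in name.split())
        synonyms = {name, abbr}
        if ambiguous_abbrevs:
            # head-only initials ("TN" for every "... tegmental nucleus")
            # are shared across regions: controlled ambiguity
            synonyms.add("".join(w[0].upper() for w in head.split()))
        entries.append(
            RegionEntry(
                region_id=f"R{i:02d}",
                preferred_name=name,
                synonyms=synonyms,
                parent_id=f"P{i % len(_PARENTS)}",
                sources={"toy"},
            )
        )
    return RegionLexicon(entries, source_order=["toy"])


# ---------------------------------------------------------------------------
# sentence templates

#: positive templates keyed by the rule family they instantiate; "{A}"/"{B}"
#: are replaced by region surfaces.
POSITIVE_TEMPLATES = {
    "r1": "A dense projection from the {A} to the {B} was traced.",
    "r2": "The {A} projects to the {B}.",
    "r3": "The {B} receives afferents from the {A}.",
    "r4": "The {A} innervates the {B}.",
    "r5": "Efferents from the {A} terminate in the {B}.",
    "r6": "Afferents to the {B} originate in the {A}.",
    "r7": "The {A} sends axons to the {B}.",
    "r8": "A connection between the {A} and the {B} was demonstrated.",
    "r9": "The {A} is reciprocally connected with the {B}.",
}

#: a connective phrasing deliberately absent from the rule file, so the
#: supervised pair classifier has coverage the rules lack
HELDOUT_TEMPLATES = {
    "heldout": "The {A} was found to be strongly linked with the {B}.",
}

CONJUNCTION_TEMPLATES = [
    "Both the {A} and the {B} were examined.",
    "Responses of the {A} and the {B} were recorded.",
    "The {A} and the {B} were studied in detail.",
]

PLAIN_SENTENCES = [
    "The experimental procedures were approved by the local committee.",
    "Histological sections were processed according to standard protocols.",
    "Electrophysiological recordings were obtained under anesthesia.",
    "Behavioral performance was monitored throughout the sessions.",
]

SPECIES_SURFACES = {
    "Rattus": "rats",
    "Mus": "mice",
    "Homo Sapiens": "humans",
    "Simiiformes": "monkeys",
    "Felidae": "cats",
    "Canis": "dogs",
    "Chordata": "ferrets",
}


@dataclass(frozen=True)
class PlantedConnection:
    region_a: str
    region_b: str
    n_statements: int = 3
    family: str = "mixed"  # a POSITIVE_TEMPLATES key, "heldout", or "mixed"

    @property
    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.region_a, self.region_b)))  # type: ignore[return-value]


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus."""

    seed: int = 0
    n_documents: int = 100
    n_regions: int = 24
    planted_connections: list[PlantedConnection] | None = None
    n_planted: int = 10
    statements_per_connection: int = 3
    conjunction_rate: float = 0.0
    plain_rate: float = 0.3
    abbreviation_rate: float = 0.1
    species_mix: dict[str, float] = field(
        default_factory=lambda: {"Rattus": 0.45, "Mus": 0.05, "Homo Sapiens": 0.05, "Felidae": 0.1}
    )
    out_of_lexicon_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("conjunction_rate", "plain_rate", "abbreviation_rate", "out_of_lexicon_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if sum(self.species_mix.values()) > 1.0 + 1e-9:
            raise ValueError("species_mix fractions must sum to at most 1")
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")


@dataclass(frozen=True)
class SentenceTruth:
    doc_id: str
    sentence_index: int
    text: str
    kind: str  # template family, "conjunction", "plain", "species", "abbrev_def"
    mention_spans: tuple[tuple[int, int, str], ...]  # (start, end, region_id)
    true_pairs: tuple[tuple[str, str], ...]

    def bio_labels(self) -> list[str]:
        toks = tokenize(self.text)
        labels = ["O"] * len(toks)
        for start, end, _ in self.mention_spans:
            inside = False
            for i, t in enumerate(toks):
                if t.start >= start and t.end <= end:
                    labels[i] = "I" if inside else "B"
                    inside = True
        return labels


@dataclass
class GroundTruth:
    sentences: list[SentenceTruth]
    true_pairs: set[tuple[str, str]]
    doc_species: dict[str, list[str]]
    n_conjunction_sentences: int
    planted: list[PlantedConnection]


def _render(template: str, substitutions: dict[str, tuple[str, str]]) -> tuple[str, list[tuple[int, int, str]]]:
    """Fill {A}/{B} slots; returns text and the char spans of the fills."""
    spans: list[tuple[int, int, str]] = []
    out: list[str] = []
    cursor = 0
    pos = 0
    while pos < len(template):
        nxt = template.find("{", pos)
        if nxt == -1:
            out.append(template[pos:])
            break
        out.append(template[pos:nxt])
        cursor += nxt - pos
        close = template.index("}", nxt)
        slot = template[nxt + 1 : close]
        surface, region_id = substitutions[slot]
        out.append(surface)
        spans.append((cursor, cursor + len(surface), region_id))
        cursor += len(surface)
        pos = close + 1
    return "".join(out), spans


def _default_planted(lex: RegionLexicon, cfg: SimConfig, rng: random.Random) -> list[PlantedConnection]:
    region_ids = sorted(rid for rid in lex.entries if rid.startswith("R"))
    pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(pairs) < cfg.n_planted and attempts < 10_000:
        a, b = rng.sample(region_ids, 2)
        pairs.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
        attempts += 1
    return [
        PlantedConnection(a, b, n_statements=cfg.statements_per_connection, family="mixed")
        for a, b in sorted(pairs)
    ]


def generate(
    cfg: SimConfig, lex: RegionLexicon | None = None
) -> tuple[list[Document], GroundTruth, dict[str, GoldTargetList]]:
    """Generate (corpus, ground truth, per-seed gold lists).

    Gold lists are complete by construction: for every region involved in a
    planted connection, its gold targets are exactly its planted partners'
    preferred names.
    """
    rng = random.Random(cfg.seed)
    if lex is None:
        lex = toy_lexicon(cfg.n_regions)
    planted = cfg.planted_connections
    if planted is None:
        planted = _default_planted(lex, cfg, rng)
    for pc in planted:
        for rid in (pc.region_a, pc.region_b):
            if rid not in lex:
                raise ValueError(f"planted connection uses unknown region {rid!r}")

    families = sorted(POSITIVE_TEMPLATES)
    # queue of statement sentences to distribute over documents
    statements: list[tuple[PlantedConnection, str]] = []
    for pc in planted:
        for _ in range(pc.n_statements):
            if pc.family == "mixed":
                fam = rng.choice(families + ["heldout"])
            else:
                fam = pc.family
            statements.append((pc, fam))
    rng.shuffle(statements)

    species_labels = sorted(cfg.species_mix)
    docs: list[Document] = []
    truths: list[SentenceTruth] = []
    doc_species: dict[str, list[str]] = {}
    n_conj = 0

    per_doc: list[list[tuple[PlantedConnection, str]]] = [[] for _ in range(cfg.n_documents)]
    for k, st in enumerate(statements):
        per_doc[k % cfg.n_documents].append(st)

    for d in range(cfg.n_documents):
        doc_id = f"SYN{d:05d}"
        sentences: list[tuple[str, str, list[tuple[int, int, str]], list[tuple[str, str]]]] = []

        # species sentence (drives the document's taxon ground truth)
        taxa: list[str] = []
        u = rng.random()
        acc = 0.0
        for lab in species_labels:
            acc += cfg.species_mix[lab]
            if u < acc:
                taxa = [lab]
                break
        if taxa:
            sentences.append(
                (f"Experiments were performed in adult {SPECIES_SURFACES[taxa[0]]}.", "species", [], [])
            )

        for pc, fam in per_doc[d]:
            a_id, b_id = pc.region_a, pc.region_b
            a_name, b_name = lex[a_id].preferred_name, lex[b_id].preferred_name
            template = HELDOUT_TEMPLATES.get(fam) or POSITIVE_TEMPLATES[fam]
            if rng.random() < cfg.abbreviation_rate:
                # define a document-local abbreviation, then use it
                abbr = "Q" + "".join(w[0].upper() for w in a_name.split())
                def_text, def_spans = _render(
                    "The {A} ({ABBRLIT}) was examined in detail.",
                    {"A": (a_name, a_id), "ABBRLIT": (abbr, a_id)},
                )
                def_spans = [def_spans[0]]  # only the long form is a mention
                sentences.append((def_text, "abbrev_def", def_spans, []))
                text, spans = _render(template, {"A": (abbr, a_id), "B": (b_name, b_id)})
            else:
                text, spans = _render(template, {"A": (a_name, a_id), "B": (b_name, b_id)})
            sentences.append((text, fam, spans, [pc.pair_key]))

        if rng.random() < cfg.conjunction_rate:
            region_ids = sorted(rid for rid in lex.entries if rid.startswith("R"))
            a, b = rng.sample(region_ids, 2)
            text, spans = _render(
                rng.choice(CONJUNCTION_TEMPLATES),
                {"A": (lex[a].preferred_name, a), "B": (lex[b].preferred_name, b)},
            )
            sentences.append((text, "conjunction", spans, []))
            n_conj += 1
        if rng.random() < cfg.plain_rate or not sentences:
            sentences.append((rng.choice(PLAIN_SENTENCES), "plain", [], []))

        # order is kept as built: abbreviation definitions must precede use
        offset = 0
        parts: list[str] = []
        for idx, (text, kind, spans, pairs) in enumerate(sentences):
            parts.append(text)
            truths.append(
                SentenceTruth(
                    doc_id=doc_id,
                    sentence_index=idx,
                    text=text,
                    kind=kind,
                    mention_spans=tuple(spans),
                    true_pairs=tuple(pairs),
                )
            )
            offset += len(text) + 1
        docs.append(Document(doc_id=doc_id, text=" ".join(parts), source="synthetic"))
        doc_species[doc_id] = taxa

    true_pairs = {pc.pair_key for pc in planted}
    truth = GroundTruth(
        sentences=truths,
        true_pairs=true_pairs,
        doc_species=doc_species,
        n_conjunction_sentences=n_conj,
        planted=list(planted),
    )

    # complete gold lists per seed
    partners: dict[str, set[str]] = {}
    for a, b in true_pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    gold = {
        seed: GoldTargetList(
            seed=lex[seed].preferred_name,
            targets=[GoldTarget(name=lex[t].preferred_name) for t in sorted(ts)],
        )
        for seed, ts in partners.items()
    }
    return docs, truth, gold


# ---------------------------------------------------------------------------
# training-data generators


def generate_tagger_training(
    cfg: SimConfig, lex: RegionLexicon | None = None, n_sentences: int = 200
) -> list[tuple[Sentence, list[str]]]:
    """BIO-annotated sentences for tagger training/evaluation.

    At the configured rate, planted region names are novel compounds absent
    from the toy lexicon (extra modifier + known head noun), exercising the
    tagger's ability to mark names a dictionary cannot.
    """
    rng = random.Random(cfg.seed + 104729)
    if lex is None:
        lex = toy_lexicon(cfg.n_regions)
    region_ids = sorted(rid for rid in lex.entries if rid.startswith("R"))
    novel_mods = ["accessory", "paracentral", "intermediate", "superficial"]
    out: list[tuple[Sentence, list[str]]] = []
    families = sorted(POSITIVE_TEMPLATES) + ["heldout"]
    for i in range(n_sentences):
        def surface() -> tuple[str, str]:
            if rng.random() < cfg.out_of_lexicon_rate:
                name = f"{rng.choice(novel_mods)} {rng.choice(_HEADS)}"
                return name, "OOL"
            rid = rng.choice(region_ids)
            return lex[rid].preferred_name, rid

        fam = families[i % len(families)]
        template = HELDOUT_TEMPLATES.get(fam) or POSITIVE_TEMPLATES[fam]
        (a_name, _), (b_name, _) = surface(), surface()
        if rng.random() < 0.25:
            template = rng.choice(CONJUNCTION_TEMPLATES)
        text, spans = _render(template, {"A": (a_name, "A"), "B": (b_name, "B")})
        sent = Sentence(doc_id="train", index=i, start=0, end=len(text), text=text)
        st = SentenceTruth(
            doc_id="train",
            sentence_index=i,
            text=text,
            kind=fam,
            mention_spans=tuple((s, e, r) for s, e, r in spans),
            true_pairs=(),
        )
        out.append((sent, st.bio_labels()))
    return out


def generate_kernel_training(
    cfg: SimConfig,
    lex: RegionLexicon | None = None,
    n_positive: int = 500,
    n_negative: int = 500,
    extractor_cfg: ExtractorConfig | None = None,
) -> list[tuple[dict[str, float], int]]:
    """Labeled candidate-pair feature maps for the pair classifier.

    Positives are rule-template (and held-out-template) statements;
    negatives are coordinating-conjunction distractors.
    """
    rng = random.Random(cfg.seed + 7919)
    if lex is None:
        lex = toy_lexicon(cfg.n_regions)
    if extractor_cfg is None:
        extractor_cfg = ExtractorConfig()
    region_ids = sorted(rid for rid in lex.entries if rid.startswith("R"))
    families = sorted(POSITIVE_TEMPLATES) + ["heldout"]
    labeled: list[tuple[dict[str, float], int]] = []
    specs = [(1, n_positive), (0, n_negative)]
    for label, n in specs:
        for i in range(n):
            a, b = rng.sample(region_ids, 2)
            if label == 1:
                fam = families[i % len(families)]
                template = HELDOUT_TEMPLATES.get(fam) or POSITIVE_TEMPLATES[fam]
            else:
                template = rng.choice(CONJUNCTION_TEMPLATES)
            text, _ = _render(
                template, {"A": (lex[a].preferred_name, a), "B": (lex[b].preferred_name, b)}
            )
            sent = Sentence(doc_id=f"k{label}{i}", index=0, start=0, end=len(text), text=text)
            mentions = match_lexical(sent, lex)
            for pair in candidate_pairs(sent, mentions):
                labeled.append((pair_features(sent, pair, extractor_cfg), label))
    return labeled
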