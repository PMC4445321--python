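# Methods

## The pipeline model

`connmine` treats connectivity mining as three sequential decisions, all
made at sentence granularity:

1. *Which token spans name brain regions?* (NER)
2. *Which co-mentioned region pairs are asserted to be connected?*
   (relation extraction)
3. *How much corpus-wide evidence supports each pair?* (aggregation)

The unit of evidence is a (document, sentence, unordered region pair)
triple. Relations are undirected throughout: rule templates use
directional syntax ("projection from A to B") only for matching, and pair
keys order region ids lexicographically. No cross-sentence inference is
attempted, and the system does not distinguish asserted facts from
hypotheses — a sentence that phrases a connection is evidence for it.

## Text plumbing

Character offsets are 0-based, half-open, counted in Unicode code points.
Sentence segmentation is rule-based: a run of `.?!` followed by whitespace
and an uppercase letter or digit terminates a sentence unless the
preceding word is on a fixed abbreviation guard list ("e.g.", "et al.",
"Fig.", …). Tokenization splits on whitespace, then detaches leading and
trailing punctuation; hyphenated words stay single tokens. Both are
deterministic and dependency-free, which keeps spans stable across runs
and platforms; neither attempts linguistic adequacy beyond abstracts and
templated prose.

## Region lexicon

The lexicon merges one or more vocabulary TSVs. The first source is the
atlas of record: it defines canonical identifiers and the single-parent
hierarchy; later sources attach synonyms, merged by shared id or by exact
normalized preferred-name equality. Surface normalization case-folds,
applies NFKD with diacritic folding, removes punctuation except internal
hyphens, collapses whitespace and strips leading articles; it is
idempotent, and the lookup index is keyed by its fixed points.

Synonym collisions across vocabularies are real (e.g. "GP"), so ambiguous
surfaces are retained and reported rather than dropped. Resolution, when a
single id is needed, is deterministic: the candidate whose best-ranked
source appears first in the source order wins, ties broken by
lexicographic id. Content-wise the merge is order-independent; the
canonical id attached to a name-merged row necessarily follows the
atlas-of-record, which is the one order-dependent element of the design.

## NER

**Dictionary matcher.** Scans token subsequences up to 8 tokens (the
longest atlas-style names fit) and keeps maximal non-overlapping matches
with leftmost-longest priority. A mention may not start at an article or a
punctuation-only token, nor end at one: normalization erases those tokens,
so admitting them would inflate spans and corrupt the conjunction test in
the extraction stage. The matcher is verified against a brute-force oracle
that enumerates every admissible subsequence and applies the same
selection rule.

**Abbreviations.** The pattern ⟨lexical mention⟩ "(" ⟨uppercase token,
length ≥ 2⟩ ")" binds the abbreviation to the mention's region id for the
remainder of the document; a document-local binding shadows a colliding
lexicon surface, since an author's explicit definition outranks a global
synonym list.

**Statistical tagger.** A discriminative BIO tagger for complex region
names absent from any lexicon: per-token log-linear scores (features:
lowercased token, collapsed word shape, ±2-token context, lexicon
membership flag, position bucket) decoded by Viterbi under transition
constraints that forbid I after O or at sentence start, so every decoded
sequence is valid BIO. Training is deterministic given the seed. A
statistical mention receives a region id only when its normalized surface
resolves unambiguously; otherwise it stays unresolved and cannot enter
candidate pairs (but is preserved for curation). When both recognizers
fire on overlapping spans, the lexical mention wins because it carries a
canonical id.

## Relation extraction

All three extractors consume the same candidate set: every unordered pair
of resolved, non-overlapping mentions with distinct region ids.

**FILTER** retains a candidate unless a filter fires; each filter is
individually switchable:

- *f1, coordinating conjunction*: the two mentions are joined by
  "and"/"or" (including "both … and") and no connective-lexicon term
  appears anywhere in the sentence — the regions are listed, not
  connected.
- *f2, list context*: the sentence mentions ≥ 4 distinct regions and no
  connective.
- *f3, negation*: a negation token within 3 tokens before a connective.

**RULES** applies nine surface templates over the connective lexicon
("projection(s) from A to B", "A projects to B", "B receives afferents
from A", "A innervates B", "efferents/axons from A terminate in B",
"afferents to B originate in A", "A sends axons to B", "connection between
A and B", "A is reciprocally connected with B"). Templates live in an
editable pattern file (`data/rules.txt`) with `{A}`/`{B}` slots,
alternatives and optional tokens; articles and "region(s)"-type fillers
may intervene. A region slot followed by "and/or/," plus another region
distributes over the conjuncts, so "projection from A to C and D" yields
(A,C) and (A,D). Matching is recursive with backtracking, so a template's
own literal "and" (rule 8) is never consumed by conjunct collection.
Rules never invent pairs: emitted pairs are always a subset of the
candidates.

**KERNEL** is a logistic pair classifier over bag-of-words between the
mentions, ±2-token windows around each mention, a token-distance bucket,
and connective/conjunction indicator features; pairs at predicted
probability ≥ 0.5 are emitted. It exists to cover connective phrasings the
rule file does not enumerate.

Each extractor stamps a fixed confidence: FILTER 0.45, KERNEL 0.60, RULES
0.72 — the measured precision of each extractor, interpreted as the
probability that one of its extractions is correct. The mapping of
extractor precision to per-mention confidence is a declared modeling
choice and the constants are configurable.

## Aggregation and scoring

Within one (document, sentence, pair) key, the maximum-confidence
extraction survives (ties: RULES > KERNEL > FILTER). A pair's score is the
sum of its deduplicated confidences, rounded half away from zero. The
score is an integer "effective mention count": it is monotone in evidence,
bounded above by the raw mention count, and a single low-confidence
co-occurrence (0.45) rounds to 0 — one unsupported co-mention is not worth
a reported connection, but it is retained in the database with its
evidence sentence. Ranked target lists sort by descending score with ties
broken by preferred name; the score matrix over the top-N regions by score
mass is symmetric with a zero diagonal.

## Species

A deterministic dictionary tagger (same normalization and longest-match
discipline as region NER) maps common and Latin species names to taxa; the
packaged dictionary covers the taxa that dominate the connectivity
literature (Rattus, Mus, Homo Sapiens, Simiiformes, Chordata, Felidae,
Canis). Per-seed breakdowns count distinct documents contributing evidence
to any pair containing the seed, grouped by taxon, with untagged documents
reported as "No species found". A document may carry several taxa; each
counts it once, so percentages sum to 100 exactly only for single-species
documents.

## Evaluation

A gold target counts as found if (preferred) a proposed region's synonym
set contains the target's normalized name, or (hierarchical credit) the
gold name resolves in the lexicon to a region that is the same as, an
ancestor of, or a descendant of a proposed region — proposing "thalamus"
earns credit for the gold target "ventral thalamic nuclei" and vice
versa. Per seed: `tp = gold − missed`, `precision = tp / proposed`,
`recall = tp / gold`. Seeds pool by micro-averaging (summing counts before
dividing); this is the only averaging scheme under which pooled metrics
follow from per-seed counts. Display rounding is half-away-from-zero to
two decimals; exports keep exact fractions. Gold lists merge afferent and
efferent panels into one undirected set, deduplicating targets listed
under both directions.

## Synthetic corpus

The generator emulates exactly the corpus properties the extractors
assume, with defaults chosen as plausible for abstract corpora:

- planted connectivity statements drawn from the nine rule templates plus
  one held-out connective phrasing ("was found to be strongly linked
  with") that the rule file deliberately does not cover, giving the pair
  classifier coverage the rules lack (default 10 planted pairs × 3
  statements);
- coordinating-conjunction distractors ("Both A and B were examined";
  default rate 0, set per experiment) — co-mentions that are not
  connections;
- region-free prose (rate 0.3) and species sentences (mix dominated by
  rat, as in the connectivity literature);
- document-local abbreviation definitions at rate 0.1, always emitted
  before first use;
- a toy lexicon of modifier+head region names with initials synonyms and
  shared head-only abbreviations for controlled ambiguity, under a
  four-root hierarchy.

Everything derives from one integer seed through a single generator; the
corpus, ground truth (mention spans, BIO labels, true pairs, document
species) and complete per-seed gold lists are deterministic and mutually
consistent by construction.

What passing on this corpus shows — and does not show: template
instantiations are separable by construction, so perfect recovery,
held-out tagger F1 and classifier accuracy demonstrate correctness of the
pipeline mechanics (matching, filtering, distribution, deduplication,
scoring, evaluation bookkeeping), not performance on real prose, whose
phrasing diversity, hedging and parenthetical structure the generator
intentionally does not model.

## Numerical and procedural choices

- Rounding is half away from zero wherever a rounded value is exported
  (scores, display metrics).
- All model fits (tagger, pair classifier) are seeded and deterministic;
  the pipeline funnels every source of randomness through one seed.
- Degenerate inputs fail loudly: empty training sets, single-class
  labels, unknown region ids, mixed pair keys in scoring, empty gold
  lists, parent cycles and duplicate document ids all raise with the
  offending record named.
- Problem sizes used by the verification script — 500 documents, 50
  planted pairs, 200 training / 100 held-out tagger sentences, 1000
  classifier pairs — are compact study conditions that the statistics
  stabilize at; the script reruns everything from scratch at each seed.

## Known limitations

- Direction of projections is not extracted; reciprocal and one-way
  connections are indistinguishable in the database.
- Facts are not separated from hypotheses or negated-by-context claims
  beyond the local negation filter.
- The rule inventory and connective lexicon are surface-level English;
  no parsing, so long-range constructions evade RULES (by design the
  co-occurrence and classifier paths are the safety net).
- Cross-atlas hierarchy reconciliation is out of scope: hierarchy queries
  follow the atlas-of-record's single-parent tree.
- The species tagger is a dictionary: it cannot disambiguate genus
  abbreviations or strain names outside its variant list.
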