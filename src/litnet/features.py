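"""Co-occurrence indexing and the nine-feature vector per gene pair.

Co-occurrence is tracked at three text levels: *abstract* (same document),
*sentence* (same sentence) and *semantic* (same sentence with an interaction
cue phrase — "binds with", "and", ... — strictly between the two mentions).
A gene pair (g1, g2) is described by nine unitless ratios:

=======  ==========================  ========
feature  entities                    level
=======  ==========================  ========
W1-W3    g1 and g2                   abstract / sentence / semantic
W4-W6    g1 and the GO terms of g2   abstract / sentence / semantic
W7-W9    g2 and the GO terms of g1   abstract / sentence / semantic
=======  ==========================  ========

Each ratio is the number of co-occurrence units over the entities' individual
appearances; the default normalization is the Jaccard form c/(n_a+n_b-c),
which is bounded in [0, 1] and symmetric.  A gene's GO terms act as one
composite entity: the composite occurs in a unit iff at least one of the
gene's GO terms occurs there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import AbstractRecord, GOAnnotationMap, Mention, abstract_text, _token_seq

__all__ = [
    "DEFAULT_CUES",
    "CueLexicon",
    "OccurrenceIndex",
    "PairFeatures",
    "FEATURE_NAMES",
    "load_cue_lexicon",
    "build_occurrence_index",
    "level_counts",
    "pair_features",
    "all_pair_features",
    "features_to_frame",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_NAMES = tuple(f"W{i}" for i in range(1, 10))

DEFAULT_CUES = (
    "binds with",
    "interacts with",
    "interact with",
    "binds to",
    "associated with",
    "and",
    "or",
)

LEVELS = ("abstract", "sentence", "semantic")


@dataclass
class CueLexicon:
    """Ordered lowercase phrases that signal an interaction between entities."""

    phrases: tuple[str, ...] = DEFAULT_CUES

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("cue lexicon must be non-empty")
        self.phrases = tuple(p.lower() for p in self.phrases)


def load_cue_lexicon(path: str | Path) -> CueLexicon:
    """One cue phrase per line."""
    with open(path, encoding="utf-8") as fh:
        phrases = tuple(line.strip().lower() for line in fh if line.strip())
    return CueLexicon(phrases=phrases)


@dataclass
class OccurrenceIndex:
    """Per-entity occurrence sets at the three text levels.

    ``semantic_links`` maps an unordered entity-id pair (sorted tuple) to the
    set of (abstract id, sentence index) units where a cue phrase links them;
    it is always a subset of the pair's shared sentence units.
    """

    abstract_sets: dict[str, set[str]] = field(default_factory=dict)
    sentence_sets: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    semantic_links: dict[tuple[str, str], set[tuple[str, int]]] = field(default_factory=dict)

    def link_units(self, a: str, b: str) -> set[tuple[str, int]]:
        return self.semantic_links.get(_pair_key(a, b), set())


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _cue_spans(sentence_text: str, cues: CueLexicon) -> list[tuple[int, int]]:
    """Character spans of cue-phrase occurrences, matched on token boundaries.

    Single-word cues ("and", "or") must be standalone tokens; multiword cues
    match as consecutive token runs.  Comparison is case-insensitive.
    """
    toks = _token_seq(sentence_text)
    lowered = [t.lower() for t, _, _ in toks]
    spans: list[tuple[int, int]] = []
    for cue in cues.phrases:
        cue_toks = cue.split()
        k = len(cue_toks)
        for i in range(len(toks) - k + 1):
            if lowered[i : i + k] == cue_toks:
                spans.append((toks[i][1], toks[i + k - 1][2]))
    return spans


def build_occurrence_index(
    records: Sequence[AbstractRecord],
    mentions: Iterable[Mention],
    cues: CueLexicon | None = None,
) -> OccurrenceIndex:
    """Aggregate mentions into abstract/sentence sets and semantic links.

    A semantic link is recorded for an entity pair iff both entities are
    mentioned in one sentence and a cue phrase occurs strictly between the
    two mention spans (checked over every ordering of mention pairs).  The
    cue must join the mentions directly: if a third entity mention lies
    between the two, the outer pair is not linked (in "A was studied; B and
    C rose" the cue "and" links B-C but not A-C).
    """
    cues = cues or CueLexicon()
    texts = {rec.id: abstract_text(rec) for rec in records}
    index = OccurrenceIndex()
    by_sentence: dict[tuple[str, int], list[Mention]] = {}
    for m in mentions:
        index.abstract_sets.setdefault(m.entity_id, set()).add(m.abstract_id)
        unit = (m.abstract_id, m.sentence_index)
        index.sentence_sets.setdefault(m.entity_id, set()).add(unit)
        by_sentence.setdefault(unit, []).append(m)

    for unit, ms in by_sentence.items():
        if len(ms) < 2:
            continue
        abstract_id, _ = unit
        # cue spans are relative to the full abstract text so they compare
        # directly with mention char_spans
        text = texts.get(abstract_id)
        if text is None:
            continue
        spans = _cue_spans(text, cues)
        if not spans:
            continue
        for ma, mb in combinations(ms, 2):
            if ma.entity_id == mb.entity_id:
                continue
            lo = min(ma.char_span[1], mb.char_span[1])
            hi = max(ma.char_span[0], mb.char_span[0])
            if hi <= lo:
                continue
            blocked = any(
                other is not ma and other is not mb
                and lo <= other.char_span[0] and other.char_span[1] <= hi
                for other in ms
            )
            if blocked:
                continue
            if any(lo <= cs and ce <= hi for cs, ce in spans):
                index.semantic_links.setdefault(
                    _pair_key(ma.entity_id, mb.entity_id), set()
                ).add(unit)
    return index


# ---------------------------------------------------------------------------
# counting

def _entity_sets(index: OccurrenceIndex, entity: str | frozenset[str]):
    """(abstract set, sentence set) of a single entity or a GO composite."""
    if isinstance(entity, (set, frozenset)):
        abs_set: set[str] = set()
        sent_set: set[tuple[str, int]] = set()
        for t in entity:
            abs_set |= index.abstract_sets.get(t, set())
            sent_set |= index.sentence_sets.get(t, set())
        return abs_set, sent_set
    return (
        index.abstract_sets.get(entity, set()),
        index.sentence_sets.get(entity, set()),
    )


def _composite_links(index: OccurrenceIndex, gene: str, terms: frozenset[str]):
    units: set[tuple[str, int]] = set()
    for t in terms:
        units |= index.link_units(gene, t)
    return units


def level_counts(
    index: OccurrenceIndex,
    a: str | frozenset[str],
    b: str | frozenset[str],
    level: str,
) -> tuple[int, int, int]:
    """(joint count c, n_a, n_b) for two entities at a text level.

    Counts use set semantics over units: abstract ids at the abstract level,
    (abstract, sentence) pairs at the sentence level.  The semantic level
    counts cue-linked sentence units; its individual counts are the
    sentence-level ones, since semantic links are a subset of shared
    sentences.  Unknown entities count 0.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level: {level!r}")
    a_abs, a_sent = _entity_sets(index, a)
    b_abs, b_sent = _entity_sets(index, b)
    if level == "abstract":
        return len(a_abs & b_abs), len(a_abs), len(b_abs)
    if level == "sentence":
        return len(a_sent & b_sent), len(a_sent), len(b_sent)
    # semantic
    if isinstance(a, (set, frozenset)) and isinstance(b, (set, frozenset)):
        raise ValueError("semantic counts need at least one plain entity")
    if isinstance(a, (set, frozenset)):
        c = len(_composite_links(index, b, frozenset(a)))  # type: ignore[arg-type]
    elif isinstance(b, (set, frozenset)):
        c = len(_composite_links(index, a, frozenset(b)))
    else:
        c = len(index.link_units(a, b))
    return c, len(a_sent), len(b_sent)


def _normalize(c: int, n_a: int, n_b: int, how: str) -> float:
    if how == "jaccard":
        denom = n_a + n_b - c
    elif how == "min":
        denom = min(n_a, n_b)
    elif how == "product":
        denom = n_a * n_b
    else:
        raise ValueError(f"unknown feature normalization: {how!r}")
    return c / denom if denom > 0 else 0.0


@dataclass(frozen=True)
class PairFeatures:
    """The nine-feature vector for an unordered gene pair, g1 < g2."""

    g1: str
    g2: str
    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) != 9:
            raise ValueError("expected 9 features")


def _features_ordered(
    index: OccurrenceIndex,
    g1: str,
    g2: str,
    go: GOAnnotationMap,
    normalization: str = "jaccard",
) -> tuple[float, ...]:
    """Nine features respecting the (g1, g2) argument order."""
    go1 = frozenset(go.terms_of(g1))
    go2 = frozenset(go.terms_of(g2))
    for gene, terms in ((g1, go1), (g2, go2)):
        if not terms:
            raise ValueError(f"gene {gene!r} has no GO annotation")
    entity_pairs = ((g1, g2), (g1, go2), (g2, go1))
    w = []
    for a, b in entity_pairs:
        for level in LEVELS:
            c, n_a, n_b = level_counts(index, a, b, level)
            w.append(_normalize(c, n_a, n_b, normalization))
    return tuple(w)


def pair_features(
    index: OccurrenceIndex,
    g1: str,
    g2: str,
    go: GOAnnotationMap,
    normalization: str = "jaccard",
) -> PairFeatures:
    """Feature vector for an unordered pair (canonicalized so g1 < g2).

    Swapping the arguments exchanges the (W4, W5, W6) and (W7, W8, W9)
    blocks, so the canonical form is order-independent.
    """
    if g1 == g2:
        raise ValueError("pair must consist of two distinct genes")
    a, b = _pair_key(g1, g2)
    return PairFeatures(g1=a, g2=b, w=_features_ordered(index, a, b, go, normalization))


def _candidate_pairs(
    index: OccurrenceIndex, genes: Sequence[str], go: GOAnnotationMap
) -> set[tuple[str, str]]:
    """Pairs that can have a nonzero feature: some abstract holds g1 together
    with g2 or with a GO term of g2 (or vice versa)."""
    eligible = set(genes)
    gene_in: dict[str, set[str]] = {}
    goterm_in: dict[str, set[str]] = {}
    for g in eligible:
        for aid in index.abstract_sets.get(g, set()):
            gene_in.setdefault(aid, set()).add(g)
        for t in go.terms_of(g):
            for aid in index.abstract_sets.get(t, set()):
                goterm_in.setdefault(aid, set()).add(g)
    pairs: set[tuple[str, str]] = set()
    for aid, gs in gene_in.items():
        for a, b in combinations(sorted(gs), 2):
            pairs.add((a, b))
        for a in gs:
            for b in goterm_in.get(aid, set()):
                if a != b:
                    pairs.add(_pair_key(a, b))
    return pairs


def all_pair_features(
    index: OccurrenceIndex,
    genes: Sequence[str],
    go: GOAnnotationMap,
    normalization: str = "jaccard",
    drop_zero: bool = True,
) -> list[PairFeatures]:
    """Feature rows for unordered pairs of eligible genes.

    With ``drop_zero`` (default) only pairs with at least one nonzero feature
    are kept; otherwise every pair is emitted.  Rows are ordered by
    (g1, g2) lexicographically.
    """
    if drop_zero:
        pairs = sorted(_candidate_pairs(index, genes, go))
    else:
        pairs = list(combinations(sorted(set(genes)), 2))
    rows = []
    for a, b in pairs:
        pf = pair_features(index, a, b, go, normalization)
        if drop_zero and not any(pf.w):
            continue
        rows.append(pf)
    return rows


# ---------------------------------------------------------------------------
# tabular I/O

def features_to_frame(rows: Sequence[PairFeatures]) -> pd.DataFrame:
    data = {
        "g1": [r.g1 for r in rows],
        "g2": [r.g2 for r in rows],
    }
    for i, name in enumerate(FEATURE_NAMES):
        data[name] = [r.w[i] for r in rows]
    return pd.DataFrame(data)


def write_feature_table(rows: Sequence[PairFeatures], path: str | Path) -> None:
    features_to_frame(rows).to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"g1": str, "g2": str})
    missing = [c for c in ("g1", "g2", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df
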