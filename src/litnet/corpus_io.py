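"""Corpus, lexicon and annotation I/O plus dictionary-based entity mention finding.

Abstracts are plain text records (id, title, body).  Gene symbols are matched
case-sensitively as whole tokens; Gene Ontology terms are matched by their
term name (case-insensitive) or by a literal ``GO:nnnnnnn`` id.  All character
coordinates are 0-based half-open offsets into ``title + " " + body``, with
the title counted as sentence 0.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AbstractRecord",
    "SentenceSpan",
    "GeneLexicon",
    "GOAnnotationMap",
    "Mention",
    "DEFAULT_ABBREVIATIONS",
    "load_abstracts",
    "write_abstracts_tsv",
    "load_gene_lexicon",
    "load_go_annotations",
    "eligible_genes",
    "abstract_text",
    "split_sentences",
    "sentence_spans",
    "find_mentions",
    "find_corpus_mentions",
]

#: separator inserted between title and body when forming the abstract text
TITLE_SEP = " "

#: tokens (with trailing period) that never end a sentence
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.", "al.", "vs.", "cf.", "fig.", "figs.", "dr.", "no.", "ca.",
     "approx.", "st.", "sp.", "spp.", "i.e.", "e.g."}
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class AbstractRecord:
    """One corpus document: an opaque id (e.g. a PubMed id), title and body."""

    id: str
    title: str
    body: str = ""


@dataclass(frozen=True)
class SentenceSpan:
    """A sentence located inside the combined title+body text."""

    index: int
    start: int
    end: int


@dataclass
class GeneLexicon:
    """Official gene symbols and the surface strings that match each symbol.

    By default a symbol matches only itself; synonym support is an extension
    point (populate ``match_forms`` with extra surfaces).
    """

    symbols: set[str]
    match_forms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym in self.symbols:
            self.match_forms.setdefault(sym, {sym})

    def surfaces(self) -> Iterable[tuple[str, str]]:
        """Yield (surface string, symbol) pairs."""
        for sym in sorted(self.symbols):
            for form in sorted(self.match_forms.get(sym, {sym})):
                yield form, sym


@dataclass
class GOAnnotationMap:
    """gene symbol -> set of GO ids, plus GO id -> term name."""

    annotations: dict[str, set[str]]
    names: dict[str, str]

    def terms_of(self, gene: str) -> set[str]:
        return self.annotations.get(gene, set())


@dataclass(frozen=True)
class Mention:
    """A located occurrence of a gene symbol or GO term in an abstract."""

    entity_kind: str  # "gene" | "go_term"
    entity_id: str
    abstract_id: str
    sentence_index: int
    char_span: tuple[int, int]


# ---------------------------------------------------------------------------
# loading / writing

def load_abstracts(path: str | Path, format: str = "tsv") -> list[AbstractRecord]:
    """Read a corpus file into records, preserving input order.

    ``tsv`` expects three UTF-8 tab-separated columns (id, title, body), no
    header; ``medline-text`` expects blank-line-separated blocks with
    ``PMID-``, ``TI  -`` and ``AB  -`` prefixed lines (continuations indented).
    Duplicate ids and malformed rows raise ``ValueError``.
    """
    path = Path(path)
    if format == "tsv":
        records = _load_tsv(path)
    elif format == "medline-text":
        records = _load_medline(path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise ValueError("empty abstract id")
        if rec.id in seen:
            raise ValueError(f"duplicate abstract id: {rec.id!r}")
        seen.add(rec.id)
    return records


def _load_tsv(path: Path) -> list[AbstractRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            records.append(AbstractRecord(id=parts[0], title=parts[1], body=parts[2]))
    return records


def _load_medline(path: Path) -> list[AbstractRecord]:
    records = []
    fields: dict[str, str] = {}
    current: str | None = None

    def flush() -> None:
        nonlocal fields, current
        if fields:
            records.append(
                AbstractRecord(
                    id=fields.get("PMID", "").strip(),
                    title=fields.get("TI", "").strip(),
                    body=fields.get("AB", "").strip(),
                )
            )
        fields, current = {}, None

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            m = re.match(r"^([A-Z]+)\s*-\s?(.*)$", line)
            if m:
                current = m.group(1)
                fields[current] = (fields.get(current, "") + " " + m.group(2)).strip()
            elif line.startswith(" ") and current:
                fields[current] = fields[current] + " " + line.strip()
            else:
                raise ValueError(f"{path}: malformed MEDLINE line: {line!r}")
    flush()
    return records


def write_abstracts_tsv(records: Sequence[AbstractRecord], path: str | Path) -> None:
    """Write records back to the 3-column TSV dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            for part in (rec.title, rec.body):
                if "\t" in part or "\n" in part:
                    raise ValueError("title/body may not contain tabs or newlines")
            fh.write(f"{rec.id}\t{rec.title}\t{rec.body}\n")


def load_gene_lexicon(path: str | Path) -> GeneLexicon:
    """Read one gene symbol per line (blank lines ignored)."""
    symbols = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.add(sym)
    return GeneLexicon(symbols=symbols)


def load_go_annotations(path: str | Path, genes: GeneLexicon | None = None) -> GOAnnotationMap:
    """Read ``gene<TAB>GO_id<TAB>term_name`` rows.

    Rows naming a gene absent from ``genes`` (when given) are skipped with a
    warning rather than silently accepted.
    """
    annotations: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            gene, go_id, name = (p.strip() for p in parts)
            if genes is not None and gene not in genes.symbols:
                warnings.warn(
                    f"{path}:{lineno}: annotation for unknown gene {gene!r} skipped"
                )
                continue
            annotations.setdefault(gene, set()).add(go_id)
            names[go_id] = name
    return GOAnnotationMap(annotations=annotations, names=names)


def eligible_genes(genes: GeneLexicon, go: GOAnnotationMap) -> tuple[list[str], list[str]]:
    """Split the lexicon into (annotated, unannotated) gene symbol lists.

    Genes with no GO annotation are excluded from feature extraction; the
    second list reports them.
    """
    annotated = sorted(g for g in genes.symbols if go.terms_of(g))
    unannotated = sorted(g for g in genes.symbols if not go.terms_of(g))
    return annotated, unannotated


# ---------------------------------------------------------------------------
# sentences

def abstract_text(record: AbstractRecord) -> str:
    """Combined title + separator + body text that all offsets refer to."""
    return record.title + TITLE_SEP + record.body


def split_sentences(
    text: str,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[SentenceSpan]:
    """Segment ``text`` into sentence spans.

    A boundary is a run of ``. ! ?`` followed by whitespace and an uppercase
    letter or digit, unless the word ending at the terminator (with its
    period) is in the abbreviation guard list.  Spans are trimmed of
    surrounding whitespace and cover all non-whitespace text.
    """
    guards = {a.lower() for a in abbreviations}
    breaks: list[int] = []
    for m in re.finditer(r"[.!?]+(?=\s+[A-Z0-9])", text):
        end = m.end()
        # word ending at the terminator, including it, e.g. "al."
        wstart = end - 1
        while wstart > 0 and not text[wstart - 1].isspace():
            wstart -= 1
        if text[wstart:end].lower() in guards:
            continue
        breaks.append(end)
    spans: list[SentenceSpan] = []
    cursor = 0
    for brk in breaks + [len(text)]:
        chunk = text[cursor:brk]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        start, end = cursor + lead, brk - trail
        if end > start:
            spans.append(SentenceSpan(index=len(spans), start=start, end=end))
        cursor = brk
    return spans


def sentence_spans(
    record: AbstractRecord,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[SentenceSpan]:
    """Sentence spans of a record, with the title guaranteed to be sentence 0.

    Title and body are segmented separately (so a title lacking a terminator
    still forms its own sentence) and reported in coordinates of
    ``abstract_text(record)``.
    """
    spans: list[SentenceSpan] = []
    if record.title.strip():
        for s in split_sentences(record.title, abbreviations):
            spans.append(SentenceSpan(index=len(spans), start=s.start, end=s.end))
    offset = len(record.title) + len(TITLE_SEP)
    for s in split_sentences(record.body, abbreviations):
        spans.append(SentenceSpan(index=len(spans), start=s.start + offset, end=s.end + offset))
    return spans


# ---------------------------------------------------------------------------
# mention finding

def _token_seq(text: str) -> list[tuple[str, int, int]]:
    """Alphanumeric tokens with their character spans."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _build_matchers(
    genes: GeneLexicon, go: GOAnnotationMap
) -> tuple[dict[tuple[str, ...], str], dict[tuple[str, ...], str], int]:
    """Token-sequence matchers: exact-case gene sequences, casefolded GO sequences."""
    gene_seqs: dict[tuple[str, ...], str] = {}
    for surface, sym in genes.surfaces():
        toks = tuple(t for t, _, _ in _token_seq(surface))
        if toks:
            gene_seqs[toks] = sym
    go_seqs: dict[tuple[str, ...], str] = {}
    for go_id, name in go.names.items():
        toks = tuple(t.lower() for t, _, _ in _token_seq(name))
        if toks:
            go_seqs[toks] = go_id
        # the literal "GO:0001234" form tokenizes as ("go", "0001234")
        id_toks = tuple(t.lower() for t, _, _ in _token_seq(go_id))
        if id_toks:
            go_seqs[id_toks] = go_id
    max_len = max(
        [len(k) for k in gene_seqs] + [len(k) for k in go_seqs] + [1]
    )
    return gene_seqs, go_seqs, max_len


def _scan_record(
    record: AbstractRecord,
    matchers: tuple[dict[tuple[str, ...], str], dict[tuple[str, ...], str], int],
    abbreviations: frozenset[str] | set[str],
) -> list[Mention]:
    text = abstract_text(record)
    spans = sentence_spans(record, abbreviations)
    gene_seqs, go_seqs, max_len = matchers
    mentions: list[Mention] = []
    for span in spans:
        toks = _token_seq(text[span.start : span.end])
        i = 0
        while i < len(toks):
            hit = None
            for length in range(min(max_len, len(toks) - i), 0, -1):
                window = tuple(t for t, _, _ in toks[i : i + length])
                if window in gene_seqs:
                    hit = ("gene", gene_seqs[window], length)
                    break
                lowered = tuple(t.lower() for t in window)
                if lowered in go_seqs:
                    hit = ("go_term", go_seqs[lowered], length)
                    break
            if hit is None:
                i += 1
                continue
            kind, entity_id, length = hit
            start = span.start + toks[i][1]
            end = span.start + toks[i + length - 1][2]
            mentions.append(
                Mention(
                    entity_kind=kind,
                    entity_id=entity_id,
                    abstract_id=record.id,
                    sentence_index=span.index,
                    char_span=(start, end),
                )
            )
            i += length
    return mentions


def find_mentions(
    record: AbstractRecord,
    genes: GeneLexicon,
    go: GOAnnotationMap,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[Mention]:
    """Locate gene and GO-term mentions in a record by dictionary matching.

    Matching is over whole alphanumeric tokens: gene surfaces are compared
    case-sensitively, GO term names case-insensitively.  At each position the
    longest match wins (genes preferred on equal length) and the consumed
    tokens cannot take part in another mention, so overlaps resolve
    left-to-right, longest-first.  Results are deterministic and independent
    of lexicon iteration order.
    """
    return _scan_record(record, _build_matchers(genes, go), abbreviations)


def find_corpus_mentions(
    records: Sequence[AbstractRecord],
    genes: GeneLexicon,
    go: GOAnnotationMap,
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
) -> list[Mention]:
    """:func:`find_mentions` over a whole corpus, building the matchers once."""
    matchers = _build_matchers(genes, go)
    mentions: list[Mention] = []
    for rec in records:
        mentions.extend(_scan_record(rec, matchers, abbreviations))
    return mentions
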