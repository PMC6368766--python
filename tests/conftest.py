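import numpy as np
import pytest

from litnet.corpus_io import AbstractRecord, GeneLexicon, GOAnnotationMap, find_corpus_mentions
from litnet.features import CueLexicon, build_occurrence_index


@pytest.fixture
def tiny_lexicon():
    return GeneLexicon(symbols={"TP53", "BRCA2", "MDM2"})


@pytest.fixture
def tiny_go():
    return GOAnnotationMap(
        annotations={
            "TP53": {"GO:0000001"},
            "BRCA2": {"GO:0000002"},
            "MDM2": {"GO:0000003"},
        },
        names={
            "GO:0000001": "cell division",
            "GO:0000002": "dna repair",
            "GO:0000003": "protein binding",
        },
    )


def index_corpus(records, genes, go, cues=None):
    """Corpus records -> occurrence index (shared helper, not the oracle)."""
    mentions = find_corpus_mentions(records, genes, go)
    return build_occurrence_index(records, mentions, cues or CueLexicon()), mentions


def random_tiny_corpus(rng: np.random.Generator, n_abstracts=4):
    """A random corpus of <= 5 abstracts over 3 genes with GO names in prose."""
    genes = GeneLexicon(symbols={"AAA1", "BBB2", "CCC3"})
    go = GOAnnotationMap(
        annotations={"AAA1": {"GO:0000010"}, "BBB2": {"GO:0000020"}, "CCC3": {"GO:0000030"}},
        names={
            "GO:0000010": "alpha process",
            "GO:0000020": "beta process",
            "GO:0000030": "gamma process",
        },
    )
    words = ["AAA1", "BBB2", "CCC3", "alpha process", "beta process",
             "gamma process", "binds with", "and", "rose", "fell", "slowly"]
    records = []
    for i in range(n_abstracts):
        n_sent = int(rng.integers(1, 4))
        sentences = []
        for _ in range(n_sent):
            k = int(rng.integers(1, 5))
            picks = [words[int(rng.integers(len(words)))] for _ in range(k)]
            s = " ".join(picks) + "."
            sentences.append(s[0].upper() + s[1:])
        records.append(
            AbstractRecord(id=f"R{i}", title=f"Report {i}.", body=" ".join(sentences))
        )
    return records, genes, go
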