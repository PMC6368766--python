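"""Bundled reference tables: curated cancer seed-gene lists and the worked
breast-cancer top-30 prediction example.

The seed lists (18 prostate, 23 breast, 16 lung genes) are the curated
disease-gene sets that anchor subnetwork extraction.  The breast-cancer
top-30 table carries a validation status per predicted gene:

* ``YES`` — validated against the MalaCards / NCI-GDC benchmarks;
* ``YES+Seed`` — validated and also one of the curated seed genes;
* ``Seed`` — a seed gene not counted as benchmark-validated;
* ``candidate`` — not validated (a novel candidate).

``comparison_top30`` is the top-30 list of a previously published
breast-cancer text-mining ranking, used only for overlap comparison.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .network import SeedList

__all__ = [
    "DISEASES",
    "load_seed_genes",
    "load_breast_top30",
    "load_comparison_top30",
    "validated_fraction",
    "seed_fraction",
    "overlap_genes",
]

DISEASES = ("prostate", "breast", "lung")

VALIDATED_STATUSES = frozenset({"YES", "YES+Seed"})
SEED_STATUSES = frozenset({"Seed", "YES+Seed"})


def _data_path(name: str):
    return resources.files("litnet.data").joinpath(name)


def load_seed_genes(disease: str) -> SeedList:
    """Curated seed genes for one of the three studied cancer types."""
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}; choose from {DISEASES}")
    text = _data_path(f"seeds_{disease}.txt").read_text(encoding="utf-8")
    symbols = [line.strip() for line in text.splitlines() if line.strip()]
    return SeedList(disease=disease, symbols=symbols)


def load_breast_top30() -> pd.DataFrame:
    """Top-30 predicted breast-cancer genes with validation status."""
    with resources.as_file(_data_path("breast_top30.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_comparison_top30() -> list[str]:
    """Top-30 list of the comparison breast-cancer ranking."""
    text = _data_path("comparison_top30.txt").read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def validated_fraction(table: pd.DataFrame) -> float:
    """Fraction of rows benchmark-validated (YES or YES+Seed).

    Bare ``Seed`` and ``candidate`` rows do not count as validated.
    """
    return float(table["status"].isin(VALIDATED_STATUSES).mean())


def seed_fraction(table: pd.DataFrame) -> float:
    """Fraction of rows that are seed genes (Seed or YES+Seed)."""
    return float(table["status"].isin(SEED_STATUSES).mean())


def overlap_genes(table: pd.DataFrame, other: list[str]) -> list[str]:
    """Genes shared between the predicted list and a comparison list."""
    return sorted(set(table["gene"]) & set(other))
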