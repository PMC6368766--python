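"""Scoring of pair predictions and gene rankings.

Pair classifiers are scored by ROC/AUC and precision-recall curves computed
from raw probabilities.  Gene rankings are scored by precision@n against
curated benchmark gene sets, and networks by seed recall (the fraction of a
disease's seed genes present as nodes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import InteractionNetwork, SeedList

__all__ = [
    "BenchmarkSet",
    "RankingEvaluation",
    "load_benchmark",
    "union_benchmarks",
    "precision_at_n",
    "seed_recall",
    "roc_curve",
    "auc",
    "pr_curve",
]


@dataclass
class BenchmarkSet:
    """A named set of known disease genes (e.g. disease + source database)."""

    name: str
    symbols: set[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("benchmark set is empty")


def load_benchmark(path: str | Path, name: str | None = None) -> BenchmarkSet:
    path = Path(path)
    symbols = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym:
                symbols.add(sym)
    return BenchmarkSet(name=name or path.stem, symbols=symbols)


def union_benchmarks(*benchmarks: BenchmarkSet, name: str = "union") -> BenchmarkSet:
    symbols: set[str] = set()
    for b in benchmarks:
        symbols |= b.symbols
    return BenchmarkSet(name=name, symbols=symbols)


@dataclass
class RankingEvaluation:
    measure: str
    n: int
    precision: float
    hits: list[tuple[str, bool]]


def precision_at_n(
    ranked: list[str], benchmark: BenchmarkSet, n: int, measure: str = ""
) -> RankingEvaluation:
    """Fraction of the first n ranked genes present in the benchmark.

    Symbol matching is exact and case-sensitive after whitespace trimming.
    ``n`` may not exceed the ranking length (no padding).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        raise ValueError(f"n={n} exceeds ranking length {len(ranked)}")
    bench = {s.strip() for s in benchmark.symbols}
    hits = [(g, g.strip() in bench) for g in ranked[:n]]
    precision = sum(flag for _, flag in hits) / n
    return RankingEvaluation(measure=measure, n=n, precision=precision, hits=hits)


def seed_recall(net: InteractionNetwork, seeds: SeedList) -> float:
    """|seeds present as network nodes| / |seeds|."""
    if not seeds.symbols:
        raise ValueError("seed list is empty")
    present = set(seeds.symbols) & set(net.graph.nodes)
    return len(present) / len(seeds.symbols)


# ---------------------------------------------------------------------------
# threshold sweeps

def _check_scores(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y).astype(int)
    if p.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return p, y


def roc_curve(p: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) points swept over all distinct score thresholds.

    A pair is predicted positive when its score strictly exceeds the
    threshold; the endpoints (0, 0) and (1, 1) are always included.
    """
    p, y = _check_scores(p, y)
    pos = int(y.sum())
    neg = len(y) - pos
    points = [(0.0, 0.0)]
    for t in sorted(set(p), reverse=True):
        pred = p > t
        tpr = float((pred & (y == 1)).sum()) / pos
        fpr = float((pred & (y == 0)).sum()) / neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal area under an (x, y) curve sorted by x."""
    pts = sorted(points)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return float(area)


def pr_curve(p: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """(recall, precision) points over the same strict threshold sweep.

    Precision at zero predictions is defined as 1 by convention, so the
    curve starts at (0, 1) and ends at (1, prevalence).
    """
    p, y = _check_scores(p, y)
    pos = int(y.sum())
    points = [(0.0, 1.0)]
    for t in sorted(set(p), reverse=True):
        pred = p > t
        npred = int(pred.sum())
        tp = int((pred & (y == 1)).sum())
        precision = tp / npred if npred else 1.0
        recall = tp / pos
        points.append((recall, precision))
    all_positive = (1.0, pos / len(y))
    if points[-1] != all_positive:
        points.append(all_positive)
    return points
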