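"""End-to-end convenience: corpus -> features -> classifier -> network.

Glues the stage modules together for the common case of running the whole
pipeline on one corpus (real or simulated).  Each stage remains usable on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus_io import eligible_genes, find_corpus_mentions
from .features import (
    CueLexicon,
    all_pair_features,
    build_occurrence_index,
    features_to_frame,
)
from .models import (
    LabeledPairTable,
    WLRModel,
    WKLRModel,
    classify,
    compute_weights,
    fit_wlr,
    fit_wklr,
    predict_proba,
)
from .network import InteractionNetwork, build_network
from .synthetic_data import SimulatedCorpus

__all__ = ["PipelineResult", "extract_features", "run_synthetic_pipeline", "edge_f1"]


def extract_features(records, genes, go, cues: CueLexicon | None = None) -> pd.DataFrame:
    """Corpus records -> g1/g2/W1..W9 feature frame over annotated genes."""
    mentions = find_corpus_mentions(records, genes, go)
    index = build_occurrence_index(records, mentions, cues or CueLexicon())
    annotated, _ = eligible_genes(genes, go)
    rows = all_pair_features(index, annotated, go)
    return features_to_frame(rows)


@dataclass
class PipelineResult:
    features: pd.DataFrame
    table: LabeledPairTable
    model: WLRModel | WKLRModel
    probabilities: np.ndarray
    predicted_edges: set[tuple[str, str]]
    network: InteractionNetwork


def run_synthetic_pipeline(
    sim: SimulatedCorpus,
    model: str = "wlr",
    lam: float = 1e-2,
    sigma: float = 0.5,
    tau: float | None = None,
    threshold: float = 0.5,
) -> PipelineResult:
    """Features from a simulated corpus, labels from its true edge set, a
    fitted rare-event classifier, and the predicted interaction network."""
    feats = extract_features(sim.records, sim.genes, sim.go)
    labels = pd.DataFrame(
        {
            "g1": feats["g1"],
            "g2": feats["g2"],
            "label": [
                int((a, b) in sim.true_edges) for a, b in zip(feats["g1"], feats["g2"])
            ],
        }
    )
    table = LabeledPairTable.from_frames(feats, labels)
    w = compute_weights(table.y, tau=tau)
    if model == "wlr":
        fitted: WLRModel | WKLRModel = fit_wlr(table, w, lam)
    elif model == "wklr":
        fitted = fit_wklr(table, w, lam, sigma)
    else:
        raise ValueError(f"unknown model {model!r}")
    p = predict_proba(fitted, table.X)
    yhat = classify(p, threshold)
    edges = {
        pair for pair, pred, prob in zip(table.pairs, yhat, p) if pred == 1
    }
    net = build_network(
        [(a, b, float(prob)) for (a, b), prob in zip(table.pairs, p) if (a, b) in edges]
    )
    return PipelineResult(
        features=feats,
        table=table,
        model=fitted,
        probabilities=p,
        predicted_edges=edges,
        network=net,
    )


def edge_f1(predicted: set[tuple[str, str]], truth: set[tuple[str, str]]) -> float:
    """F1 of a predicted edge set against the ground-truth edge set."""
    tp = len(predicted & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)
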