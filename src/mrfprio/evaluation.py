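"""Decision scores, leave-one-out validation and ROC/AUC.

Posteriors are converted to rank-percentile decision scores within each
run so that a single threshold is meaningful across disease classes of
very different sizes. Validation masks one known positive at a time,
rebuilds its prior as if it were unknown (no leakage), re-runs the
sampler and records the held-out gene's decision score; known genes of
other classes serve as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import sklearn.metrics

from .core import PriorVector
from .data import NetworkCollection
from .errors import EvaluationError
from .inference import SamplerConfig, run_deng, run_imrf1, run_imrf2


def decision_scores(posterior: np.ndarray) -> np.ndarray:
    """Fractional-rank percentile of each posterior (ties get the average
    rank), mapping the scores onto (0, 1]."""
    from scipy.stats import rankdata

    posterior = np.asarray(posterior, dtype=float)
    if len(posterior) == 0:
        raise EvaluationError("need at least one gene to score")
    return rankdata(posterior, method="average") / len(posterior)


@dataclass
class RocResult:
    """ROC curve and its trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(table: pd.DataFrame) -> RocResult:
    """ROC curve / AUC from a labelled score table (columns: label, score).

    Equal scores are grouped at a single threshold; the AUC is the
    trapezoidal area, which for a step-free sweep equals the normalized
    Mann-Whitney U statistic.
    """
    labels = np.asarray(table["label"], dtype=int)
    scores = np.asarray(table["score"], dtype=float)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC needs both positive and negative labels")
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


_RUNNERS: dict[str, Callable] = {
    "imrf1": run_imrf1,
    "imrf2": run_imrf2,
}


def _run_mode(mode, collection, known, priors, config, negatives=None):
    if mode == "deng":
        return run_deng(collection, known, negatives or [], priors, config)
    try:
        runner = _RUNNERS[mode]
    except KeyError:
        raise EvaluationError(f"unknown mode: {mode!r}") from None
    return runner(collection, known, priors, config)


def leave_one_out(
    collection: NetworkCollection,
    class_genes,
    other_class_genes,
    priors_builder: Callable[[frozenset, frozenset], PriorVector],
    config: SamplerConfig,
    mode: str = "imrf2",
) -> pd.DataFrame:
    """Leave-one-out score table for a disease class.

    ``priors_builder(class_genes, all_disease_genes)`` must return the
    prior vector for a given set of known class genes, so that the
    held-out gene's prior can be rebuilt without its own label. Positives
    with no edge in any network are excluded from testing. Negative
    controls (known genes of other classes) are never clamped by any run,
    so their scores come from the base run with all class genes known.

    Returns a DataFrame with columns (gene, label, score).
    """
    class_genes = frozenset(class_genes)
    other = frozenset(other_class_genes) - class_genes
    if not class_genes:
        raise EvaluationError("class_genes must be non-empty")
    degrees = collection.degrees().sum(axis=0)
    eligible = sorted(g for g in class_genes if degrees[g] >= 1)
    if not eligible:
        raise EvaluationError(
            "no class gene has an annotated interaction partner in any network"
        )
    rows = []
    # negatives: scored in the base run, where they are unclamped
    base_priors = priors_builder(class_genes, class_genes | other)
    base = _run_mode(mode, collection, sorted(class_genes), base_priors, config,
                     negatives=sorted(other))
    base_scores = base.decision_scores()
    for g in sorted(other):
        rows.append({"gene": int(g), "label": 0, "score": float(base_scores[g])})
    for g in eligible:
        held_class = class_genes - {g}
        if not held_class:
            raise EvaluationError(
                "cannot hold out the only known gene of the class"
            )
        priors = priors_builder(held_class, (held_class | other))
        res = _run_mode(mode, collection, sorted(held_class), priors, config,
                        negatives=sorted(other))
        rows.append({"gene": int(g), "label": 1,
                     "score": float(res.decision_scores()[g])})
    return pd.DataFrame(rows, columns=["gene", "label", "score"])
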