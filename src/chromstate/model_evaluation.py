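"""Model-size diagnostics and mark-subset evaluation.

Two questions from the study design: how many states are enough (emission-row
correlation of smaller models against a large reference model), and how much
does a group of marks contribute (segmentation agreement when those marks are
hidden from the emission term).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import BinaryTrackSet
from .hmm import ChromatinModel, marginal_segment, segment
from .state_comparison import build_confusion, comparison_stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelCorrelation",
    "SubsetEvaluation",
    "compare_models",
    "state_number_diagnostics",
    "eval_subset",
]


@dataclass
class ModelCorrelation:
    reference_K: int
    compared_K: int
    matrix: np.ndarray  # K_ref × K_cmp Pearson correlations of emission rows
    max_per_reference_state: np.ndarray


@dataclass
class SubsetEvaluation:
    mark_mask: np.ndarray
    confusion: np.ndarray
    jaccard: np.ndarray  # per-state diagonal Jaccard, full vs subset segmentation


def _row_correlations(R: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of R and every row of C.

    Constant rows (zero variance) get correlation 0 by convention, with a warning.
    """
    Rc = R - R.mean(axis=1, keepdims=True)
    Cc = C - C.mean(axis=1, keepdims=True)
    rs = np.sqrt((Rc**2).sum(axis=1))
    cs = np.sqrt((Cc**2).sum(axis=1))
    if (rs == 0).any() or (cs == 0).any():
        logger.warning("constant emission rows: correlation defined as 0")
    denom = np.outer(rs, cs)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Rc @ Cc.T) / denom
    corr[~np.isfinite(corr)] = 0.0
    return np.clip(corr, -1.0, 1.0)


def compare_models(reference: ChromatinModel, other: ChromatinModel) -> ModelCorrelation:
    """Correlate every reference-state emission vector with every other-state vector."""
    if set(reference.marks) != set(other.marks):
        raise ValueError(
            f"mark sets differ: {sorted(set(reference.marks) ^ set(other.marks))}"
        )
    order = [other.marks.index(m) for m in reference.marks]
    corr = _row_correlations(reference.E, other.E[:, order])
    return ModelCorrelation(reference.K, other.K, corr, corr.max(axis=1))


def state_number_diagnostics(
    models: list[ChromatinModel], drop_threshold: float = 0.9
) -> tuple[pd.DataFrame, int | None]:
    """Per-K summary of max correlation against the largest model.

    Returns the table and the smallest K at which no reference state falls
    below ``drop_threshold`` — a diagnostic, not an automatic choice of K.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    models = sorted(models, key=lambda m: m.K)
    reference = models[-1]
    rows = []
    for m in models[:-1]:
        mc = compare_models(reference, m)
        rows.append(
            {
                "K": m.K,
                "min_max_corr": mc.max_per_reference_state.min(),
                "mean_max_corr": mc.max_per_reference_state.mean(),
                "n_states_below_threshold": int(
                    (mc.max_per_reference_state < drop_threshold).sum()
                ),
            }
        )
    table = pd.DataFrame(rows).sort_values("K").reset_index(drop=True)
    ok = table[table["n_states_below_threshold"] == 0]
    flagged = int(ok["K"].iloc[0]) if len(ok) else None
    return table, flagged


def eval_subset(
    model: ChromatinModel, tracks: BinaryTrackSet, mark_mask: np.ndarray
) -> SubsetEvaluation:
    """Segmentation agreement between the full model and a mark-subset evaluation.

    The confusion matrix crosses the all-marks segmentation with the
    marginalized segmentation; its diagonal, expressed as per-state Jaccard
    indices, quantifies how much the hidden marks define each state.
    """
    mark_mask = np.asarray(mark_mask, dtype=bool)
    full = segment(model, tracks)
    sub = marginal_segment(model, tracks, mark_mask)
    conf = build_confusion(full, sub)
    stats = comparison_stats(conf)
    jacc = np.nan_to_num(stats.jaccard.to_numpy(), nan=1.0)  # empty states trivially agree
    return SubsetEvaluation(mark_mask, conf.B, jacc)
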