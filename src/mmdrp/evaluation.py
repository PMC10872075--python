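"""Range-resolved and subgroup evaluation of combined validation predictions.

A single score over the whole AAC range is dominated by the low-AAC bulk and
hides how a model does on the clinically interesting, strong-response tail.
Two complementary views are provided: a trailing moving-average MAE along the
sorted AAC range, and RMSE over explicit subgroups (targeted vs untargeted
drugs, AAC windows, splitting scheme). Note that the RMSE of a single
prediction equals its MAE.

The repurposing screen flags (drug, noncognate cell line) pairs where the
measured response exceeds every cognate (approved-lineage) response by a
margin and the model predicted that response accurately on a first-seen cell
line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import DrugRecord, ResponseRecord
from .model import PredictionRecord

logger = logging.getLogger("mmdrp")

__all__ = [
    "MovingMAECurve", "RepurposingCandidate", "moving_average_mae",
    "subgroup_rmse", "repurposing_screen",
]


@dataclass
class MovingMAECurve:
    """Trailing-window MAE along the true-AAC-sorted predictions."""

    aac: np.ndarray        # true AAC at each window's end
    mae: np.ndarray        # trailing mean absolute error
    window: int


@dataclass(frozen=True)
class RepurposingCandidate:
    drug: str
    cell_line: str
    lineage: str
    noncognate_aac: float
    max_cognate_aac: float
    predicted_aac: float
    mae: float


def _sorted_errors(predictions: list[PredictionRecord]):
    # stable sort by true AAC; ties keep input (record id) order
    order = sorted(range(len(predictions)),
                   key=lambda i: predictions[i].true_aac)
    true = np.array([predictions[i].true_aac for i in order])
    err = np.array([abs(predictions[i].pred_aac - predictions[i].true_aac)
                    for i in order])
    return true, err


def moving_average_mae(predictions: list[PredictionRecord],
                       window: int = 500) -> MovingMAECurve:
    """Trailing moving average of absolute error over ``window`` samples,
    sweeping the predictions in ascending true-AAC order."""
    if not predictions:
        raise ValueError("no predictions")
    window = max(1, min(window, len(predictions)))
    true, err = _sorted_errors(predictions)
    kernel = np.ones(window) / window
    mae = np.convolve(err, kernel, mode="valid")
    return MovingMAECurve(aac=true[window - 1:], mae=mae, window=window)


def subgroup_rmse(predictions: list[PredictionRecord],
                  catalog: list[DrugRecord] | None = None,
                  targeted: bool | None = None,
                  aac_range: tuple[float, float] | None = None,
                  scheme: str | None = None) -> dict:
    """Unweighted RMSE over the filtered subgroup, with its size.

    ``aac_range`` filters on true AAC as a half-open check ``lo <= aac``
    (and ``aac <= hi``). An empty subgroup returns ``{"empty": True}``
    rather than a misleading zero.
    """
    subset = predictions
    if scheme is not None:
        subset = [p for p in subset if p.scheme == scheme]
    if aac_range is not None:
        lo, hi = aac_range
        subset = [p for p in subset if lo <= p.true_aac <= hi]
    if targeted is not None:
        if catalog is None:
            raise ValueError("targeted filter needs the drug catalog")
        flag = {d.name: d.targeted for d in catalog}
        subset = [p for p in subset if flag.get(p.drug, False) == targeted]
    if not subset:
        return {"empty": True, "n": 0, "rmse": None}
    err = np.array([p.pred_aac - p.true_aac for p in subset])
    return {"empty": False, "n": len(subset),
            "rmse": float(np.sqrt(np.mean(err ** 2)))}


def repurposing_screen(responses: list[ResponseRecord],
                       predictions: list[PredictionRecord],
                       catalog: list[DrugRecord],
                       margin: float = 0.2,
                       mae_threshold: float = 0.2
                       ) -> list[RepurposingCandidate]:
    """Flag drugs whose measured response in a noncognate cell line beats
    every cognate response by ``margin``, where the model also predicted
    that response with MAE <= ``mae_threshold``.

    Cognate = cell line whose lineage is in the drug's approved lineages;
    drugs with no approved lineages are skipped with a warning.
    Predictions should come from a scheme in which the flagged cell line was
    unseen during training (e.g. split by cell line).
    """
    pred_by_pair = {(p.cell_line, p.drug): p for p in predictions}
    candidates: list[RepurposingCandidate] = []
    for drug in catalog:
        if not drug.approved_lineages:
            logger.warning("repurposing screen: %s has no approved lineages; skipped",
                           drug.name)
            continue
        rows = [r for r in responses if r.drug == drug.name]
        cognate = [r.aac for r in rows if r.lineage in drug.approved_lineages]
        if not cognate:
            logger.warning("repurposing screen: %s has no cognate cell lines; skipped",
                           drug.name)
            continue
        max_cognate = max(cognate)
        for r in rows:
            if r.lineage in drug.approved_lineages:
                continue
            if r.aac - max_cognate < margin:
                continue
            pred = pred_by_pair.get((r.cell_line, r.drug))
            if pred is None:
                continue
            mae = abs(pred.pred_aac - r.aac)
            if mae <= mae_threshold:
                candidates.append(RepurposingCandidate(
                    drug.name, r.cell_line, r.lineage, r.aac,
                    max_cognate, pred.pred_aac, mae))
    candidates.sort(key=lambda c: (-(c.noncognate_aac - c.max_cognate_aac),
                                   c.drug, c.cell_line))
    return candidates
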