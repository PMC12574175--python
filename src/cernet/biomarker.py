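"""Single-feature two-class discrimination scored by ROC AUC.

The AUC equals the probability that a randomly chosen positive-class
value exceeds a randomly chosen negative-class value, with ties counted
half — i.e. the Mann–Whitney U statistic divided by n_pos·n_neg.  Since
a biomarker lower in cases is as informative as one higher, the
orientation-corrected ``reported_auc = max(auc, 1 − auc)`` is emitted
alongside the raw value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)


class BiomarkerError(ValueError):
    pass


@dataclass(frozen=True)
class ROCResult:
    feature_id: str
    auc: float
    n_pos: int
    n_neg: int

    @property
    def orientation(self) -> str:
        return "higher_in_pos" if self.auc >= 0.5 else "higher_in_neg"

    @property
    def reported_auc(self) -> float:
        return max(self.auc, 1.0 - self.auc)


def roc_auc(pos: np.ndarray, neg: np.ndarray, feature_id: str = "") -> ROCResult:
    """Tie-aware AUC: [#(p>n) + ½·#(p=n)] / (n_pos·n_neg), via rank sums."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise BiomarkerError("both classes must be non-empty")
    u1 = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").statistic
    return ROCResult(feature_id, float(u1) / (pos.size * neg.size), pos.size, neg.size)


def evaluate_biomarkers(
    m: ExpressionMatrix,
    design: SampleDesign,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """AUC per feature for the design's alternative (positive) class.

    Masked cells are excluded per sample; absent features yield NA rows.
    Columns: auc, reported_auc, orientation, n_pos, n_neg.
    """
    design.check_covers(m)
    vals = m.unmasked()
    neg_cols = design.samples_in(design.reference)
    pos_cols = design.samples_in(design.alternative)
    if not neg_cols or not pos_cols:
        raise BiomarkerError("both classes must have samples")
    features = list(features) if features is not None else m.feature_ids
    rows = {}
    for fid in features:
        if fid not in m.values.index:
            logger.info("evaluate_biomarkers: feature %r absent; NA row", fid)
            rows[fid] = (np.nan, np.nan, "", 0, 0)
            continue
        pos = vals.loc[fid, pos_cols].dropna().to_numpy()
        neg = vals.loc[fid, neg_cols].dropna().to_numpy()
        if pos.size == 0 or neg.size == 0:
            rows[fid] = (np.nan, np.nan, "", pos.size, neg.size)
            continue
        r = roc_auc(pos, neg, fid)
        rows[fid] = (r.auc, r.reported_auc, r.orientation, r.n_pos, r.n_neg)
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["auc", "reported_auc", "orientation", "n_pos", "n_neg"],
    )
    table.index.name = "feature"
    return table
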