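"""CCP-score adjustment of competing signatures.

To ask whether a published prognostic signature carries information beyond
proliferation, each of its genes is replaced by the residuals of a
least-squares regression on the CCP score, attenuating any CCP-correlated
signal; the negative control subtracts a constant (the gene's mean) instead,
which leaves every proportional-hazards p-value untouched.  A signature that
is prognostic (p < 0.05) under the control but not after CCP adjustment has
"lost" its predictive ability; prognostic under both, it is "retained".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import GeneMatrix
from .prognostics import ClinicalTable, PrognosticsError, test_continuous
from .scoring import ScoreVector, Signature, ScoringError, signature_score

log = logging.getLogger(__name__)

LOST, RETAINED, NOT_PROGNOSTIC = "lost", "retained", "not_prognostic"


@dataclass
class AdjustmentOutcome:
    signature_name: str
    cohort_id: str
    control_p: float
    adjusted_p: float
    category: str

    def __post_init__(self) -> None:
        expected = classify(self.control_p, self.adjusted_p)
        if self.category != expected:
            raise ValueError(f"category {self.category!r} inconsistent with p-values")


def classify(control_p: float, adjusted_p: float, alpha: float = 0.05) -> str:
    if control_p >= alpha:
        return NOT_PROGNOSTIC
    return LOST if adjusted_p >= alpha else RETAINED


def adjust_for_score(m: GeneMatrix, score: ScoreVector,
                     genes: Sequence[str]) -> GeneMatrix:
    """Replace each listed gene row by its residuals from a least-squares fit
    on (intercept, score); other rows pass through unchanged."""
    s = score.to_series().reindex(m.values.columns)
    if s.isna().any():
        raise PrognosticsError("score does not cover all matrix samples")
    sv = s.to_numpy(dtype=float)
    if np.std(sv) == 0:
        raise PrognosticsError("constant score")
    target = [g for g in genes if g in m.values.index]
    out = m.values.copy()
    Y = out.loc[target].to_numpy(dtype=float)
    sc = sv - sv.mean()
    slope = (Y @ sc) / (sc @ sc)
    resid = Y - Y.mean(axis=1, keepdims=True) - slope[:, None] * sc
    out.loc[target] = resid
    # rows stay mean-zero; the normalized flag is kept so the residual rows
    # can be re-scored as unweighted means (unit variance is not re-imposed)
    return replace(m, values=out)


def adjust_control(m: GeneMatrix, genes: Sequence[str]) -> GeneMatrix:
    """Negative control: subtract each listed gene row's mean (intercept-only
    adjustment); preserves all prognostic signal up to centering."""
    target = [g for g in genes if g in m.values.index]
    out = m.values.copy()
    Y = out.loc[target].to_numpy(dtype=float)
    out.loc[target] = Y - Y.mean(axis=1, keepdims=True)
    return replace(m, values=out)


@dataclass
class AdjustmentSummary:
    outcomes: list[AdjustmentOutcome]
    heatmap: pd.DataFrame        # signatures x cohorts, cells in {lost,retained,none,absent}
    loss_percentages: pd.Series  # per signature; NaN when never prognostic


def run_adjustment_analysis(signatures: Sequence[Signature],
                            cohorts: Sequence[tuple[str, GeneMatrix, ClinicalTable]],
                            ccp: Signature,
                            alpha: float = 0.05) -> AdjustmentSummary:
    """For each (signature, cohort): score the CCP signature from all its
    genes on the platform, build control- and CCP-adjusted matrices
    restricted to the signature's genes, re-score, re-test against the
    cohort's endpoint, and classify lost/retained/not-prognostic."""
    if not signatures or not cohorts:
        raise ValueError("need at least one signature and one cohort")
    outcomes: list[AdjustmentOutcome] = []
    cells: dict[str, dict[str, str]] = {s.name: {} for s in signatures}
    for cohort_id, m, clin in cohorts:
        try:
            ccp_score = signature_score(m, ccp)
        except ScoringError as exc:
            log.warning("cohort %s: %s; skipped", cohort_id, exc)
            for s in signatures:
                cells[s.name][cohort_id] = "absent"
            continue
        for sig in signatures:
            present = [g for g in sig.genes if g in m.values.index]
            if not present:
                log.info("signature %s absent from cohort %s platform",
                         sig.name, cohort_id)
                cells[sig.name][cohort_id] = "absent"
                continue
            control_m = adjust_control(m, present)
            adjusted_m = adjust_for_score(m, ccp_score, present)
            control_p = test_continuous(signature_score(control_m, sig), clin).p
            adj_score = signature_score(adjusted_m, sig)
            if np.std(adj_score.score) < 1e-10:
                # self-adjustment: residualizing a signature on its own score
                # leaves no variance, hence no prognostic information
                adjusted_p = 1.0
            else:
                adjusted_p = test_continuous(adj_score, clin).p
            cat = classify(control_p, adjusted_p, alpha=alpha)
            outcomes.append(AdjustmentOutcome(sig.name, cohort_id,
                                              float(control_p), float(adjusted_p), cat))
            cells[sig.name][cohort_id] = cat if cat != NOT_PROGNOSTIC else "none"
    heatmap = pd.DataFrame(cells).T.reindex([s.name for s in signatures])
    heatmap = heatmap[[c for c, *_ in cohorts]]
    per_sig = {s.name: [o for o in outcomes if o.signature_name == s.name]
               for s in signatures}
    loss = pd.Series({
        name: loss_percentage(outs) if outs else float("nan")
        for name, outs in per_sig.items()}, name="loss_pct")
    return AdjustmentSummary(outcomes=outcomes, heatmap=heatmap,
                             loss_percentages=loss)


def loss_percentage(outcomes: Sequence[AdjustmentOutcome]) -> float:
    """100 * lost / (lost + retained) over the cohorts where the signature was
    prognostic under the control; NaN (not applicable) when none were."""
    if not outcomes:
        raise ValueError("loss_percentage needs at least one outcome")
    lost = sum(o.category == LOST for o in outcomes)
    retained = sum(o.category == RETAINED for o in outcomes)
    if lost + retained == 0:
        return float("nan")
    return 100.0 * lost / (lost + retained)
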