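"""Signature scoring: the average of normalized expression over a gene set.

The cell-cycle proliferation (CCP) score of a sample is the unweighted mean
of the z-normalized expression of the signature genes measured on the
platform.  Genes absent from the platform are dropped and the achieved
coverage is reported so callers can gate on it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import GeneMatrix

log = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class Signature:
    """A named gene set. ``genes`` keeps first-seen order, duplicates removed."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        deduped = tuple(dict.fromkeys(self.genes))
        if not deduped:
            raise ScoringError("signature must contain at least one gene")
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def subset(self, genes, name: str | None = None) -> "Signature":
        keep = tuple(g for g in self.genes if g in set(genes))
        return Signature(name or self.name, keep)


#: The refined cell-cycle signature as printed in its source ("CCP-12");
#: note the published list contains 11 symbols under that name.
CCP12 = Signature("CCP-12", (
    "BIRC5", "BUB1B", "CDC20", "CDCA8", "CENPF", "FOXM1",
    "KIF11", "NUSAP1", "PTTG1", "TK1", "TOP2A",
))


@dataclass
class ScoreVector:
    """Per-sample signature score plus how much of the signature was used."""

    sample_ids: pd.Index
    score: np.ndarray
    n_genes_used: int
    coverage: float
    name: str = "score"

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name=self.name)

    def __len__(self) -> int:
        return len(self.score)


def signature_score(m: GeneMatrix, sig: Signature,
                    coverage_warn: float = 0.5) -> ScoreVector:
    """Score ``sig`` on a normalized gene matrix: per-sample unweighted mean
    over the signature genes present on the platform.

    Raises if the matrix is not flagged normalized or no signature gene is
    present; warns when coverage falls below ``coverage_warn``.
    """
    if not m.normalized:
        raise ScoringError("signature_score requires a normalized matrix")
    present = [g for g in sig.genes if g in m.values.index]
    if not present:
        raise ScoringError(f"signature {sig.name!r} absent from platform")
    coverage = len(present) / len(sig.genes)
    if coverage < coverage_warn:
        log.warning("signature %s: coverage %.2f below %.2f (%d/%d genes)",
                    sig.name, coverage, coverage_warn, len(present), len(sig.genes))
    sub = m.values.loc[present].to_numpy(dtype=float)
    score = np.nanmean(sub, axis=0)
    return ScoreVector(sample_ids=m.values.columns, score=score,
                       n_genes_used=len(present), coverage=coverage,
                       name=sig.name)


def write_scores(sv: ScoreVector, path) -> None:
    """Two-column TSV: sample_id, score."""
    from .io import FLOAT_FMT
    sv.to_series().to_frame("score").to_csv(
        path, sep="\t", index_label="sample_id", float_format=FLOAT_FMT)
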