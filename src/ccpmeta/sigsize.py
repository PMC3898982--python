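"""Signature-size resampling, cross-cohort gene consistency, refined
signatures, and the nested full-vs-refined evaluation.

Because cell-cycle genes are highly correlated, a random subset of the full
signature often scores nearly as well as the whole.  The resampling
experiment draws up to ``max_reps`` distinct gene subsets at each size,
scores each, tests each against the cohort endpoint, and records the
proportion significant at p < 0.05.  Refined signatures (CCP-k) take the
top-k genes by how many cohorts each gene is individually prognostic in,
and the nested test asks whether the full score still adds information to a
model holding the refined score and a clinical risk covariate.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import GeneMatrix
from .prognostics import (ClinicalTable, PrognosticResult, added_value_test,
                          auc_screen, cox_score_test)
from .scoring import ScoreVector, Signature

log = logging.getLogger(__name__)

#: the size grid "1, 2, 4, ... 30, 31": even steps plus both endpoints
DEFAULT_SIZES = (1, *range(2, 31, 2), 31)
REFINED_PRESETS = (4, 7, 10, 12)


@dataclass
class SizeCurve:
    cohort_id: str
    sizes: tuple[int, ...]
    prop_significant: tuple[float, ...]
    p_distributions: dict[int, np.ndarray]
    n_reps_per_size: dict[int, int]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cohort_id": self.cohort_id,
            "size": self.sizes,
            "n_reps": [self.n_reps_per_size[s] for s in self.sizes],
            "prop_significant": self.prop_significant,
        })


@dataclass
class GeneConsistency:
    gene: str
    n_cohorts_tested: int
    n_cohorts_significant: int
    mean_p: float

    def __post_init__(self) -> None:
        if self.n_cohorts_significant > self.n_cohorts_tested:
            raise ValueError("significant count exceeds tested count")


def _distinct_subsets(genes: Sequence[str], size: int, max_reps: int,
                      rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Up to max_reps distinct index subsets of the given size; exhaustive
    when the subset space is no larger than max_reps."""
    G = len(genes)
    total = math.comb(G, size)
    if total <= max_reps:
        return list(combinations(range(G), size))
    seen: set[tuple[int, ...]] = set()
    while len(seen) < max_reps:
        seen.add(tuple(sorted(rng.choice(G, size=size, replace=False).tolist())))
    return sorted(seen)


def _subset_pvalues(m: GeneMatrix, clin: ClinicalTable, genes: list[str],
                    subsets: list[tuple[int, ...]]) -> np.ndarray:
    """p-value of the subset-mean score for every subset, vectorised."""
    common = m.values.columns.intersection(clin.sample_ids)
    Z = m.values.loc[genes, common].to_numpy(dtype=float)   # G x n
    ind = np.zeros((len(subsets), len(genes)))
    for r, sub in enumerate(subsets):
        ind[r, list(sub)] = 1.0 / len(sub)
    scores = ind @ Z                                        # reps x n
    cdata = clin.data.loc[common]
    if clin.is_binary:
        _, p, _ = auc_screen(cdata["label"].to_numpy(dtype=int), scores.T)
    else:
        _, p, _, _ = cox_score_test(cdata["time"].to_numpy(dtype=float),
                                    cdata["event"].to_numpy(dtype=float), scores.T)
    return p


def random_signature_curves(ccp_genes: Sequence[str],
                            cohorts: Sequence[tuple[str, GeneMatrix, ClinicalTable]],
                            sizes: Sequence[int] = DEFAULT_SIZES,
                            max_reps: int = 10000,
                            alpha: float = 0.05,
                            seed: int = 0) -> list[SizeCurve]:
    """Per cohort and signature size, the proportion of random gene subsets
    whose score is prognostic (p < alpha).  Sizes are truncated per cohort to
    the number of signature genes on its platform; sampling is without
    replacement within a size and deterministic under the seed."""
    curves = []
    for ci, (cohort_id, m, clin) in enumerate(cohorts):
        avail = [g for g in ccp_genes if g in m.values.index]
        G = len(avail)
        used_sizes, props = [], []
        pdist: dict[int, np.ndarray] = {}
        nreps: dict[int, int] = {}
        for size in sizes:
            if size > G:
                log.warning("cohort %s: size %d exceeds %d available genes; skipped",
                            cohort_id, size, G)
                continue
            rng = np.random.default_rng([seed, ci, size])
            subsets = _distinct_subsets(avail, size, max_reps, rng)
            p = _subset_pvalues(m, clin, avail, subsets)
            used_sizes.append(size)
            props.append(float(np.mean(p < alpha)))
            pdist[size] = p
            nreps[size] = len(subsets)
        curves.append(SizeCurve(cohort_id=cohort_id, sizes=tuple(used_sizes),
                                prop_significant=tuple(props),
                                p_distributions=pdist, n_reps_per_size=nreps,
                                seed=seed))
    return curves


def plateau_size(curve: SizeCurve, frac: float = 0.95) -> int | None:
    """Smallest size whose proportion-significant reaches ``frac`` of the
    full-size (largest available) proportion; None when every proportion is
    zero (not applicable)."""
    if not curve.sizes:
        raise ValueError("empty size curve")
    full = curve.prop_significant[-1]
    if all(p == 0 for p in curve.prop_significant):
        return None
    target = frac * full
    for s, p in zip(curve.sizes, curve.prop_significant):
        if p >= target:
            return s
    return curve.sizes[-1]


def curve_is_monotone(curve: SizeCurve, n_sd: float = 3.0,
                      skip_last: bool = True) -> bool:
    """Whether the proportion-significant curve is non-decreasing within a
    binomial Monte-Carlo tolerance of ``n_sd`` standard errors per step.

    The final (full-size) point is a 0/1 indicator from a single subset and
    is excluded by default.
    """
    sizes = curve.sizes[:-1] if skip_last and len(curve.sizes) > 1 else curve.sizes
    props = curve.prop_significant[:len(sizes)]
    for i in range(len(sizes) - 1):
        p = 0.5 * (props[i] + props[i + 1])
        se = math.sqrt(max(p * (1 - p), 1e-6)
                       * (1 / curve.n_reps_per_size[sizes[i]]
                          + 1 / curve.n_reps_per_size[sizes[i + 1]]))
        if props[i + 1] < props[i] - n_sd * se - 1e-12:
            return False
    return True


def rank_genes_by_consistency(cohorts: Sequence[tuple[str, GeneMatrix, ClinicalTable]],
                              genes: Sequence[str],
                              alpha: float = 0.05) -> list[GeneConsistency]:
    """Rank genes by the number of cohorts where they are individually
    prognostic (p < alpha), ties broken by mean p then symbol."""
    records = {g: {"tested": 0, "sig": 0, "ps": []} for g in genes}
    any_present = False
    for cohort_id, m, clin in cohorts:
        present = [g for g in genes if g in m.values.index]
        if not present:
            continue
        any_present = True
        common = m.values.columns.intersection(clin.sample_ids)
        X = m.values.loc[present, common].to_numpy(dtype=float).T
        cdata = clin.data.loc[common]
        if clin.is_binary:
            _, p, _ = auc_screen(cdata["label"].to_numpy(dtype=int), X)
        else:
            _, p, _, _ = cox_score_test(cdata["time"].to_numpy(dtype=float),
                                        cdata["event"].to_numpy(dtype=float), X)
        for g, pv in zip(present, p):
            if np.isnan(pv):
                continue
            rec = records[g]
            rec["tested"] += 1
            rec["sig"] += int(pv < alpha)
            rec["ps"].append(float(pv))
    if not any_present:
        raise ValueError("no listed gene present in any cohort")
    out = [GeneConsistency(gene=g, n_cohorts_tested=r["tested"],
                           n_cohorts_significant=r["sig"],
                           mean_p=float(np.mean(r["ps"])) if r["ps"] else 1.0)
           for g, r in records.items()]
    out.sort(key=lambda c: (-c.n_cohorts_significant, c.mean_p, c.gene))
    return out


def refine_signature(consistency: Sequence[GeneConsistency], k: int,
                     name: str | None = None) -> Signature:
    """Top-k genes of the consistency ranking as a refined signature."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(consistency):
        raise ValueError(f"k={k} exceeds ranking length {len(consistency)}")
    return Signature(name or f"CCP-{k}", tuple(c.gene for c in consistency[:k]))


def full_vs_refined_test(clin: ClinicalTable, full_score: ScoreVector,
                         refined_score: ScoreVector,
                         risk_covariate: pd.Series) -> PrognosticResult:
    """Does the full signature add predictive value to a model already
    holding the refined score and a clinical risk covariate?  Nested LRT."""
    base = pd.DataFrame({
        "refined": refined_score.to_series(),
        str(risk_covariate.name or "risk"): risk_covariate,
    })
    return added_value_test(clin, base, full_score.to_series().rename("full"))
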