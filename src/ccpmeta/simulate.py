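"""Synthetic multi-cohort expression/survival data with known ground truth.

Each cohort has a latent per-sample proliferation factor P and an
independent factor Q, both standard normal.  A block of "cell-cycle" genes
loads on P (expression = baseline + lambda*P + noise), an independent
prognostic block loads on Q, and the remaining genes are pure noise.
Outcomes follow a proportional-hazards model with log-hazard
beta_prolif*P + beta_indep*Q (exponential baseline by default, Weibull shape
exposed) under uniform non-informative censoring, or a Bernoulli label
through a logistic link on P.  Platform differences are emulated by
class-stratified gene dropout and duplicated, noisier probes.

All randomness flows from one counter-based (Philox) generator per cohort,
so identical specs and seeds regenerate bit-identical cohorts.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix
from .prognostics import ClinicalTable
from .scoring import Signature

CCP_CLASS, INDEP_CLASS, NULL_CLASS = "ccp", "indep_prognostic", "null"

#: baseline (probe-efficiency) offset of a duplicated probe; the duplicate
#: sits lower on average so max-mean collapsing has a deterministic winner
DUP_BASELINE_OFFSET = -0.5
DUP_NOISE_FACTOR = 1.5


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Defaults mirror a mid-sized microarray cohort with a 31-gene correlated
    cell-cycle block of moderate effect (log-hazard 0.7 per unit latent
    factor) and a low-event endpoint (~9% of patients progress within the
    follow-up window), the regime where signature composition and size
    genuinely matter for prognostic power.
    """

    n_samples: int = 150
    n_genes: int = 2000
    n_ccp_genes: int = 31
    n_indep_prognostic_genes: int = 20
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.7
    beta_prolif: float = 0.7
    beta_indep: float = 0.7
    baseline_hazard: float = 0.025
    censor_max: float = 6.0
    weibull_shape: float = 1.0
    endpoint_kind: str = "OS"      # DSS | OS | RFS | PFS | binary
    binary_intercept: float = -1.0
    binary_slope: float = 1.0
    gene_dropout_frac: float = 0.0
    probe_dup_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise SimulationError("n_samples must be >= 2")
        if self.n_ccp_genes + self.n_indep_prognostic_genes > self.n_genes:
            raise SimulationError(
                "n_ccp_genes + n_indep_prognostic_genes exceeds n_genes")
        lo, hi = self.loading_range
        if lo > hi:
            raise SimulationError("loading_range low exceeds high")
        if not self.noise_sd > 0:
            raise SimulationError("noise_sd must be positive")
        if not self.baseline_hazard > 0:
            raise SimulationError("baseline_hazard must be positive")
        if not self.censor_max > 0:
            raise SimulationError("censor_max must be positive")
        if not self.weibull_shape > 0:
            raise SimulationError("weibull_shape must be positive")
        for name in ("gene_dropout_frac", "probe_dup_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.endpoint_kind not in ("DSS", "OS", "RFS", "PFS", "binary"):
            raise SimulationError(f"unknown endpoint_kind {self.endpoint_kind!r}")


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    latent_prolif: np.ndarray            # per sample
    latent_indep: np.ndarray             # per sample
    gene_class: pd.Series                # per generated gene (pre-dropout universe)
    true_loading: pd.Series              # per generated gene
    measured_genes: tuple[str, ...]      # genes surviving dropout
    spec: CohortSpec

    def genes_of_class(self, cls: str, measured_only: bool = True) -> list[str]:
        genes = list(self.gene_class[self.gene_class == cls].index)
        if measured_only:
            measured = set(self.measured_genes)
            genes = [g for g in genes if g in measured]
        return genes


@dataclass
class SyntheticCohort:
    cohort_id: str
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: TruthRecord

    def __post_init__(self) -> None:
        if list(self.expression.sample_ids) != list(self.clinical.sample_ids):
            raise SimulationError("expression and clinical sample IDs differ")


def gene_universe(spec: CohortSpec) -> tuple[list[str], pd.Series]:
    """Deterministic shared gene naming: CCPG### / INDG### / NULG###, so
    signatures transfer across cohorts generated from compatible specs."""
    names, classes = [], []
    for i in range(spec.n_ccp_genes):
        names.append(f"CCPG{i + 1:03d}")
        classes.append(CCP_CLASS)
    for i in range(spec.n_indep_prognostic_genes):
        names.append(f"INDG{i + 1:03d}")
        classes.append(INDEP_CLASS)
    for i in range(spec.n_genes - spec.n_ccp_genes - spec.n_indep_prognostic_genes):
        names.append(f"NULG{i + 1:04d}")
        classes.append(NULL_CLASS)
    return names, pd.Series(classes, index=names, name="gene_class")


def ccp_signature(spec: CohortSpec, name: str = "CCP-true") -> Signature:
    """The true cell-cycle gene set of the generator, as a Signature."""
    return Signature(name, tuple(f"CCPG{i + 1:03d}" for i in range(spec.n_ccp_genes)))


def _stratified_dropout(classes: pd.Series, frac: float,
                        rng: np.random.Generator) -> list[str]:
    """Drop round(frac * class size) genes within each class; returns kept
    gene names in original order."""
    if frac == 0.0:
        return list(classes.index)
    dropped: set[str] = set()
    for cls in (CCP_CLASS, INDEP_CLASS, NULL_CLASS):
        members = list(classes[classes == cls].index)
        k = round(frac * len(members))
        if k:
            dropped.update(rng.choice(members, size=k, replace=False))
    return [g for g in classes.index if g not in dropped]


def generate_cohort(spec: CohortSpec, cohort_id: str | None = None) -> SyntheticCohort:
    """Generate one cohort per the spec; same spec + seed is bit-identical."""
    spec.validate()
    rng = np.random.Generator(np.random.Philox(spec.seed))
    n = spec.n_samples
    names, classes = gene_universe(spec)

    P = rng.standard_normal(n)
    Q = rng.standard_normal(n)
    lo, hi = spec.loading_range
    loadings = np.zeros(len(names))
    is_ccp = (classes == CCP_CLASS).to_numpy()
    is_ind = (classes == INDEP_CLASS).to_numpy()
    loadings[is_ccp] = rng.uniform(lo, hi, size=is_ccp.sum())
    loadings[is_ind] = rng.uniform(lo, hi, size=is_ind.sum())
    baselines = rng.uniform(6.0, 10.0, size=len(names))

    factor = np.zeros((len(names), n))
    factor[is_ccp] = loadings[is_ccp, None] * P[None, :]
    factor[is_ind] = loadings[is_ind, None] * Q[None, :]
    expr = baselines[:, None] + factor + rng.normal(0.0, spec.noise_sd,
                                                    size=(len(names), n))

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    # clinical covariates: age, gender, and coarsened correlates of P
    age = rng.normal(65.0, 10.0, size=n)
    gender = rng.integers(0, 2, size=n)
    stage = (P + rng.normal(0.0, 1.0, size=n) > 0.8).astype(int)
    grade = (P + rng.normal(0.0, 1.2, size=n) > 0.5).astype(int)
    clin = pd.DataFrame({"age": age, "gender": gender,
                         "stage": stage, "grade": grade},
                        index=pd.Index(sample_ids, name="sample_id"))
    clin.insert(0, "endpoint_kind", spec.endpoint_kind)
    if spec.endpoint_kind == "binary":
        prob = 1.0 / (1.0 + np.exp(-(spec.binary_intercept
                                     + spec.binary_slope * P)))
        clin.insert(1, "label", (rng.uniform(size=n) < prob).astype(int))
    else:
        rate = spec.baseline_hazard * np.exp(spec.beta_prolif * P
                                             + spec.beta_indep * Q)
        raw = rng.exponential(1.0, size=n) / rate
        T = raw ** (1.0 / spec.weibull_shape)
        C = rng.uniform(0.0, spec.censor_max, size=n)
        clin.insert(1, "time", np.minimum(T, C))
        clin.insert(2, "event", (T <= C).astype(int))

    kept = _stratified_dropout(classes, spec.gene_dropout_frac, rng)

    # probe table: every kept gene gets one probe; a fraction get a second,
    # noisier and lower-baseline probe mapped to the same symbol
    gene_pos = {g: i for i, g in enumerate(names)}
    n_dup = round(spec.probe_dup_frac * len(kept))
    dup_genes = set(rng.choice(kept, size=n_dup, replace=False)) if n_dup else set()
    probe_ids, probe_gene, rows = [], [], []
    for g in kept:
        i = gene_pos[g]
        probe_ids.append(f"{g}_p1")
        probe_gene.append(g)
        rows.append(expr[i])
        if g in dup_genes:
            dup = (baselines[i] + DUP_BASELINE_OFFSET + factor[i]
                   + rng.normal(0.0, DUP_NOISE_FACTOR * spec.noise_sd, size=n))
            probe_ids.append(f"{g}_p2")
            probe_gene.append(g)
            rows.append(dup)
    values = pd.DataFrame(np.asarray(rows), index=pd.Index(probe_ids, name="probe"),
                          columns=sample_ids)
    expression = ExpressionMatrix(values, gene_map=dict(zip(probe_ids, probe_gene)))

    truth = TruthRecord(latent_prolif=P, latent_indep=Q, gene_class=classes,
                        true_loading=pd.Series(loadings, index=names,
                                               name="true_loading"),
                        measured_genes=tuple(kept), spec=spec)
    clinical = ClinicalTable(endpoint_kind=spec.endpoint_kind, data=clin.drop(
        columns=["endpoint_kind"]))
    return SyntheticCohort(cohort_id=cohort_id or f"cohort_seed{spec.seed}",
                           expression=expression, clinical=clinical, truth=truth)


def generate_multi_cohort(specs: Sequence[CohortSpec]) -> list[SyntheticCohort]:
    """Independent cohorts; cohort i reseeds at spec.seed + i so repeated
    specs still differ, while the gene-symbol universe is shared."""
    if not specs:
        raise SimulationError("generate_multi_cohort needs at least one spec")
    cohorts = []
    for i, spec in enumerate(specs):
        offset_spec = replace(spec, seed=spec.seed + i)
        cohorts.append(generate_cohort(offset_spec, cohort_id=f"cohort{i + 1:02d}"))
    return cohorts


def expected_gene_latent_correlation(loading: float, noise_sd: float) -> float:
    """Closed-form Pearson correlation between a generated gene and its latent
    factor: lambda / sqrt(lambda^2 + sigma^2)."""
    return loading / math.sqrt(loading ** 2 + noise_sd ** 2)


def write_cohort(cohort: SyntheticCohort, out_dir: str | os.PathLike) -> None:
    """Write expression/clinical/gene-map/truth TSVs and the true cell-cycle
    gene set as GMT into ``out_dir``."""
    from .io import write_clinical_tsv, write_expression_tsv, write_gene_map, write_gmt
    os.makedirs(out_dir, exist_ok=True)
    write_expression_tsv(cohort.expression.values,
                         os.path.join(out_dir, "expression.tsv"))
    clin = cohort.clinical.data.copy()
    clin.insert(0, "endpoint_kind", cohort.clinical.endpoint_kind)
    write_clinical_tsv(clin, os.path.join(out_dir, "clinical.tsv"))
    write_gene_map(cohort.expression.gene_map or {},
                   os.path.join(out_dir, "gene_map.tsv"))
    truth = pd.DataFrame({
        "gene_class": cohort.truth.gene_class,
        "true_loading": cohort.truth.true_loading,
        "measured": [g in set(cohort.truth.measured_genes)
                     for g in cohort.truth.gene_class.index],
    })
    truth.to_csv(os.path.join(out_dir, "truth_genes.tsv"), sep="\t",
                 index_label="gene", float_format="%.10g")
    latent = pd.DataFrame({"latent_prolif": cohort.truth.latent_prolif,
                           "latent_indep": cohort.truth.latent_indep},
                          index=cohort.expression.sample_ids)
    latent.to_csv(os.path.join(out_dir, "truth_latent.tsv"), sep="\t",
                  index_label="sample_id", float_format="%.10g")
    sig = ccp_signature(cohort.truth.spec)
    write_gmt({sig.name: sig.genes}, os.path.join(out_dir, "ccp_true.gmt"))
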