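"""End-to-end study orchestration over a directory of cohorts.

Stages: preprocess -> CCP scoring + prognostic table -> per-gene screen ->
module enrichment + cross-cohort ranking -> adjustment of competitor
signatures -> signature-size resampling -> consistency ranking + refined
signatures -> summary.  Every stage is a pure function of (inputs, config,
seed) and writes plain-text artifacts; reruns with the same seed are
byte-identical.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .adjustment import run_adjustment_analysis
from .enrichment import ModuleCatalog, overrepresentation, rank_modules, ranked_summary, top_hit
from .preprocess import ExpressionMatrix, GeneMatrix, collapse_probes, znormalize
from .prognostics import ClinicalTable, gene_screen, test_continuous
from .scoring import Signature, signature_score
from .sigsize import (REFINED_PRESETS, plateau_size, random_signature_curves,
                      rank_genes_by_consistency, refine_signature)

log = logging.getLogger(__name__)


class StudyError(RuntimeError):
    pass


@dataclass
class CohortEntry:
    cohort_id: str
    expression: str
    clinical: str
    gene_map: str | None = None
    role: str = ""                 # free-text disease-role tag
    endpoint_override: str | None = None


@dataclass
class StudyConfig:
    cohorts: list[CohortEntry]
    ccp_signature: str                       # path to gene list or GMT
    catalog: str | None = None               # GMT module catalog
    competitor_signatures: str | None = None  # GMT of published signatures
    screen_alpha: float = 0.01
    fdr_cut: float = 0.20
    sig_alpha: float = 0.05
    sizes: list[int] = field(default_factory=lambda: [1, *range(2, 31, 2), 31])
    reps: int = 10000
    refined_k: list[int] = field(default_factory=lambda: list(REFINED_PRESETS))
    seed: int = 0
    out_dir: str = "study_out"

    def __post_init__(self) -> None:
        for name in ("screen_alpha", "fdr_cut", "sig_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise StudyError(f"{name} must lie in (0, 1)")
        if not self.cohorts:
            raise StudyError("config lists no cohorts")

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohorts = [CohortEntry(**c) for c in raw.pop("cohorts")]
        return cls(cohorts=cohorts, **raw)


def load_cohort(entry: CohortEntry) -> tuple[str, GeneMatrix, ClinicalTable]:
    """Read one cohort from disk, collapse probes and z-normalize."""
    values = cio.read_expression_tsv(entry.expression)
    gene_map = cio.read_gene_map(entry.gene_map) if entry.gene_map else None
    m = znormalize(collapse_probes(ExpressionMatrix(values, gene_map=gene_map)))
    cdf = cio.read_clinical_tsv(entry.clinical)
    kind = entry.endpoint_override or str(cdf["endpoint_kind"].iloc[0])
    clin = ClinicalTable(endpoint_kind=kind, data=cdf.drop(columns=["endpoint_kind"]))
    return entry.cohort_id, m, clin


def _load_signature(path: str, default_name: str) -> Signature:
    if path.endswith(".gmt"):
        sets = cio.read_gmt(path)
        name, genes = next(iter(sets.items()))
        return Signature(name, genes)
    return Signature(default_name, cio.read_gene_list(path))


def run_study(cfg: StudyConfig) -> dict:
    """Execute every stage and write artifacts under ``cfg.out_dir``.

    Returns the summary dictionary (also written as summary.json).  Any
    stage failure aborts with the stage name and cohort id; artifacts from
    completed stages are retained.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "n_cohorts": len(cfg.cohorts)}
    stage = "load"
    try:
        cohorts = [load_cohort(e) for e in cfg.cohorts]
        ccp = _load_signature(cfg.ccp_signature, "CCP")

        # -- coverage of the CCP signature per cohort -----------------------
        stage = "coverage"
        cov_rows = []
        for cid, m, _ in cohorts:
            present = [g for g in ccp.genes if g in m.values.index]
            cov_rows.append((cid, len(present), len(ccp.genes),
                             len(present) / len(ccp.genes)))
        cov = pd.DataFrame(cov_rows, columns=["cohort_id", "n_present",
                                              "n_signature", "coverage"])
        cio.write_table(cov, os.path.join(out, "signature_coverage.tsv"))

        # -- CCP score prognostic table ------------------------------------
        stage = "score"
        rows = []
        for cid, m, clin in cohorts:
            sv = signature_score(m, ccp)
            res = test_continuous(sv, clin)
            rows.append((cid, clin.endpoint_kind, res.method, res.n,
                         res.estimate, res.ci_low, res.ci_high, res.p))
        prog = pd.DataFrame(rows, columns=["cohort_id", "endpoint", "method", "n",
                                           "estimate", "ci_low", "ci_high", "p"])
        cio.write_table(prog, os.path.join(out, "ccp_prognostic.tsv"))
        summary["ccp_significant_cohorts"] = int((prog["p"] < cfg.sig_alpha).sum())

        # -- per-gene screen -------------------------------------------------
        stage = "screen"
        os.makedirs(os.path.join(out, "screen"), exist_ok=True)
        screens = {}
        for cid, m, clin in cohorts:
            sr = gene_screen(m, clin, alpha=cfg.screen_alpha)
            screens[cid] = sr
            cio.write_table(sr.table.reset_index(names="gene"),
                            os.path.join(out, "screen", f"{cid}.tsv"))
        summary["screen_hits"] = {cid: len(sr.hits) for cid, sr in screens.items()}

        # -- enrichment ------------------------------------------------------
        if cfg.catalog:
            stage = "enrich"
            catalog = ModuleCatalog.from_gmt(cfg.catalog)
            os.makedirs(os.path.join(out, "enrichment"), exist_ok=True)
            tables = []
            for cid, m, clin in cohorts:
                universe = list(m.values.index)
                hits = [g for g in screens[cid].hits]
                tab = overrepresentation(hits, universe, catalog, cohort_id=cid)
                tables.append(tab)
                cio.write_table(tab.table, os.path.join(out, "enrichment", f"{cid}.tsv"))
            ranking = rank_modules(tables, fdr_cut=cfg.fdr_cut)
            cio.write_table(ranking, os.path.join(out, "module_ranking.tsv"))
            cio.write_table(ranked_summary(tables, fdr_cut=cfg.fdr_cut),
                            os.path.join(out, "module_summary.tsv"))
            hits_tab = pd.DataFrame(
                [(t.cohort_id, top_hit(tables, t.cohort_id, cfg.fdr_cut) or "none")
                 for t in tables], columns=["cohort_id", "top_hit"])
            cio.write_table(hits_tab, os.path.join(out, "top_hits.tsv"))
            summary["top_ranked_module"] = (str(ranking.iloc[0]["module_id"])
                                            if len(ranking) else None)

        # -- adjustment of competitor signatures ----------------------------
        if cfg.competitor_signatures:
            stage = "adjust"
            comp = [Signature(n, g) for n, g in
                    cio.read_gmt(cfg.competitor_signatures).items()]
            adj = run_adjustment_analysis(comp, cohorts, ccp, alpha=cfg.sig_alpha)
            adj.heatmap.reset_index(names="signature").to_csv(
                os.path.join(out, "adjustment_heatmap.tsv"), sep="\t", index=False)
            loss_tab = adj.loss_percentages.rename_axis("signature").reset_index()
            cio.write_table(loss_tab, os.path.join(out, "adjustment_loss.tsv"))
            summary["adjustment_loss_pct"] = {
                k: (None if pd.isna(v) else float(v))
                for k, v in adj.loss_percentages.items()}

        # -- signature-size resampling --------------------------------------
        stage = "sigsize"
        curves = random_signature_curves(ccp.genes, cohorts, sizes=cfg.sizes,
                                         max_reps=cfg.reps, alpha=cfg.sig_alpha,
                                         seed=cfg.seed)
        cio.write_table(pd.concat([c.to_frame() for c in curves],
                                  ignore_index=True),
                        os.path.join(out, "size_curves.tsv"))
        plateaus = pd.DataFrame(
            [(c.cohort_id, plateau_size(c) if plateau_size(c) is not None else -1)
             for c in curves], columns=["cohort_id", "plateau_size"])
        cio.write_table(plateaus, os.path.join(out, "plateau_sizes.tsv"))
        valid = plateaus.loc[plateaus["plateau_size"] > 0, "plateau_size"]
        summary["median_plateau_size"] = (float(valid.median())
                                          if len(valid) else None)

        # -- consistency ranking and refined signatures ---------------------
        stage = "refine"
        consistency = rank_genes_by_consistency(cohorts, ccp.genes,
                                                alpha=cfg.sig_alpha)
        cons_tab = pd.DataFrame([(c.gene, c.n_cohorts_tested,
                                  c.n_cohorts_significant, c.mean_p)
                                 for c in consistency],
                                columns=["gene", "n_cohorts_tested",
                                         "n_cohorts_significant", "mean_p"])
        cio.write_table(cons_tab, os.path.join(out, "gene_consistency.tsv"))
        refined = {}
        for k in cfg.refined_k:
            if k <= len(consistency):
                sig = refine_signature(consistency, k)
                refined[sig.name] = sig.genes
        cio.write_gmt(refined, os.path.join(out, "refined_signatures.gmt"))
        summary["refined_signatures"] = {n: len(g) for n, g in refined.items()}

        stage = "summary"
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_run_log(cfg, os.path.join(out, "run_log.txt"))
    except Exception as exc:
        raise StudyError(f"stage {stage!r} failed: {exc}") from exc
    return summary


def _write_run_log(cfg: StudyConfig, path: str) -> None:
    import lifelines
    import scipy
    import statsmodels
    lines = [
        "ccpmeta run log",
        f"seed: {cfg.seed}",
        f"cohorts: {[c.cohort_id for c in cfg.cohorts]}",
        f"thresholds: screen_alpha={cfg.screen_alpha} fdr_cut={cfg.fdr_cut} "
        f"sig_alpha={cfg.sig_alpha}",
        f"sizes: {list(cfg.sizes)} reps: {cfg.reps}",
        f"versions: numpy={np.__version__} scipy={scipy.__version__} "
        f"pandas={pd.__version__} lifelines={lifelines.__version__} "
        f"statsmodels={statsmodels.__version__}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
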