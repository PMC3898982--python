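"""Over-representation analysis of prognostic gene lists against a module
catalog (GO-term / KEGG-pathway style gene sets), with the cross-cohort
ranking rules used to call consistently prognostic modules.

Per module the one-sided hypergeometric tail probability P(X >= k) is
computed for the overlap k between the prognostic list and the module within
the measured-gene universe, with Benjamini-Hochberg FDR across the modules
of a table.  Modules are then ranked across cohorts first by the number of
cohorts significant at FDR < 20% and then by average p; a cohort's "top hit"
is its lowest-FDR module among those significant in at least two cohorts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class ModuleCatalog:
    """Named gene sets (modules) within one namespace (e.g. GO-BP, KEGG)."""

    modules: dict[str, tuple[str, ...]]
    namespace: str = "modules"

    def __post_init__(self) -> None:
        for mid, genes in self.modules.items():
            if not genes:
                raise EnrichmentError(f"module {mid!r} has an empty gene set")

    @classmethod
    def from_gmt(cls, path, namespace: str = "modules") -> "ModuleCatalog":
        from .io import read_gmt
        return cls(modules=dict(read_gmt(path)), namespace=namespace)


@dataclass
class EnrichmentTable:
    """Per-module overlap statistics for one cohort.

    ``table`` columns: module_id, k_overlap, K_module, n_list, N_universe,
    p, fdr -- sorted by p ascending.
    """

    cohort_id: str
    table: pd.DataFrame
    namespace: str = "modules"


def overrepresentation(gene_list: Iterable[str], universe: Iterable[str],
                       catalog: ModuleCatalog, cohort_id: str = "cohort",
                       ease: bool = False) -> EnrichmentTable:
    """One-sided hypergeometric over-representation of each catalog module in
    ``gene_list`` drawn from ``universe``.

    With ``ease=True`` the EASE-style conservative variant is used (one
    overlap gene removed from the tail).  Catalog genes outside the universe
    are clipped (logged); an empty gene list yields p = 1 rows.
    """
    universe_set = set(universe)
    genes = set(gene_list)
    outside = genes - universe_set
    if outside:
        raise EnrichmentError(
            f"{len(outside)} listed genes not in the universe (e.g. {sorted(outside)[0]!r})")
    N = len(universe_set)
    n = len(genes)
    if n == 0:
        log.warning("overrepresentation: empty gene list for %s", cohort_id)
    rows = []
    clipped = 0
    for mid in sorted(catalog.modules):
        module = set(catalog.modules[mid])
        clipped += len(module - universe_set)
        module &= universe_set
        K = len(module)
        if K == 0:
            continue
        k = len(module & genes)
        keff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(keff - 1, N, K, n)) if n else 1.0
        rows.append((mid, k, K, n, N, p))
    if clipped:
        log.info("overrepresentation: clipped %d catalog genes outside the universe", clipped)
    table = pd.DataFrame(rows, columns=["module_id", "k_overlap", "K_module",
                                        "n_list", "N_universe", "p"])
    if len(table):
        _, fdr, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["fdr"] = fdr
        table = table.sort_values(["p", "module_id"], kind="mergesort",
                                  ignore_index=True)
    else:
        table["fdr"] = pd.Series(dtype=float)
    return EnrichmentTable(cohort_id=cohort_id, table=table,
                           namespace=catalog.namespace)


def rank_modules(tables: Sequence[EnrichmentTable],
                 fdr_cut: float = 0.20) -> pd.DataFrame:
    """Rank modules across cohorts: number of cohorts with FDR below the cut
    (descending), then mean p over cohorts where tested (ascending), ties by
    module_id."""
    if not tables:
        raise EnrichmentError("rank_modules needs at least one table")
    cat = pd.concat(
        [t.table.assign(cohort_id=t.cohort_id) for t in tables], ignore_index=True)
    grouped = cat.groupby("module_id")
    out = pd.DataFrame({
        "n_cohorts_tested": grouped.size(),
        "n_cohorts_significant": grouped["fdr"].apply(lambda f: int((f < fdr_cut).sum())),
        "mean_p": grouped["p"].mean(),
    }).reset_index()
    out = out.sort_values(
        ["n_cohorts_significant", "mean_p", "module_id"],
        ascending=[False, True, True], kind="mergesort", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_hit(tables: Sequence[EnrichmentTable], cohort_id: str,
            fdr_cut: float = 0.20) -> str | None:
    """The cohort's lowest-FDR module among modules significant (FDR < cut)
    in at least two cohorts overall; None when no module qualifies."""
    ids = [t.cohort_id for t in tables]
    if cohort_id not in ids:
        raise EnrichmentError(f"unknown cohort_id {cohort_id!r}")
    cat = pd.concat(
        [t.table.assign(cohort_id=t.cohort_id) for t in tables], ignore_index=True)
    sig_counts = cat[cat["fdr"] < fdr_cut].groupby("module_id")["cohort_id"].nunique()
    qualifying = set(sig_counts[sig_counts >= 2].index)
    if not qualifying:
        return None
    here = cat[(cat["cohort_id"] == cohort_id) & cat["module_id"].isin(qualifying)]
    if here.empty:
        return None
    here = here.sort_values(["fdr", "module_id"], kind="mergesort")
    return str(here.iloc[0]["module_id"])


def ranked_summary(tables: Sequence[EnrichmentTable], n_top: int = 10,
                   fdr_cut: float = 0.20) -> pd.DataFrame:
    """The figure-style selection: the most consistently prognostic modules
    padded with each cohort's top hit, the latter marked with an asterisk."""
    ranking = rank_modules(tables, fdr_cut=fdr_cut)
    hits = {t.cohort_id: top_hit(tables, t.cohort_id, fdr_cut=fdr_cut)
            for t in tables}
    chosen = list(ranking["module_id"].head(n_top))
    for h in hits.values():
        if h is not None and h not in chosen:
            chosen.append(h)
    out = ranking[ranking["module_id"].isin(chosen)].copy()
    out["top_hit_for"] = out["module_id"].map(
        lambda m: ",".join(sorted(c for c, h in hits.items() if h == m)))
    out["asterisk"] = np.where(out["top_hit_for"] != "", "*", "")
    return out.reset_index(drop=True)
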