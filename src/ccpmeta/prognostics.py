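"""Survival and association machinery for expression scores and genes.

Time-to-event endpoints are analysed with Cox proportional-hazards models:
the reported p-value for a continuous score is the partial-likelihood score
test at beta = 0 (the continuous-covariate generalization of the log-rank
test), and the hazard ratio per 1-unit score with its Wald CI comes from the
fitted model.  Binary endpoints (progressor vs non-progressor, node+ vs
node-) are analysed by AUC with a Mann-Whitney p-value and a DeLong CI.

Also here: the endpoint hierarchy (DSS > OS > RFS; AUC only without
follow-up), the per-gene P<0.01 screen (vectorised score test), Kaplan-Meier
tertile stratification, forward-stepwise "final model" selection, and the
nested likelihood-ratio added-value test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .scoring import ScoreVector

log = logging.getLogger(__name__)

TIME_TO_EVENT_KINDS = ("DSS", "OS", "RFS", "PFS")
ENDPOINT_PRIORITY = ("DSS", "OS", "RFS", "PFS", "binary")
RESERVED_COLUMNS = ("endpoint_kind", "time", "event", "label")


class PrognosticsError(ValueError):
    pass


@dataclass
class ClinicalTable:
    """Per-sample endpoint and covariates.

    ``data`` is indexed by sample_id.  For time-to-event endpoint kinds it
    must carry ``time`` (>=0) and ``event`` (0/1); for the binary kind a 0/1
    ``label``.  All other columns are covariates (already numerically
    encoded; categorical contrasts are the caller's responsibility).
    """

    endpoint_kind: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.endpoint_kind not in ENDPOINT_PRIORITY:
            raise PrognosticsError(f"unknown endpoint_kind {self.endpoint_kind!r}")
        if self.is_binary:
            if "label" not in self.data.columns:
                raise PrognosticsError("binary endpoint requires a label column")
        else:
            missing = [c for c in ("time", "event") if c not in self.data.columns]
            if missing:
                raise PrognosticsError(f"time-to-event endpoint requires {missing}")
        if self.data.index.duplicated().any():
            raise PrognosticsError("duplicate sample_ids in clinical table")

    @property
    def is_binary(self) -> bool:
        return self.endpoint_kind == "binary"

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]


@dataclass
class PrognosticResult:
    """Universal result record: HR (per 1-unit predictor) or AUC, CI, p."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str  # cox_continuous | auc | logrank_groups | lrt
    p_lrt: float | None = None

    def __post_init__(self) -> None:
        if self.method in ("cox_continuous", "lrt") and not self.estimate > 0:
            raise PrognosticsError("hazard ratio must be positive")
        if self.method == "auc" and not (0.0 <= self.estimate <= 1.0):
            raise PrognosticsError("AUC must lie in [0, 1]")


@dataclass
class FittedModel:
    """A multivariate fit plus the forward-selection trace that built it."""

    terms: dict[str, float]
    loglik: float
    n_events: int
    selection_trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.terms


def select_endpoint(available: set[str] | list[str]) -> str:
    """Pick the analysis endpoint: DSS if available, else OS, else RFS (then
    PFS); a binary endpoint only when no time-to-event endpoint exists."""
    avail = set(available)
    if not avail:
        raise PrognosticsError("no endpoints available")
    unknown = avail - set(ENDPOINT_PRIORITY)
    if unknown:
        raise PrognosticsError(f"unknown endpoint kinds {sorted(unknown)}")
    for kind in ENDPOINT_PRIORITY:
        if kind in avail:
            return kind
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Cox score test (vectorised, Efron ties)

def cox_score_test(time, event, X):
    """Partial-likelihood score test at beta = 0 for each column of X.

    Efron handling of tied event times.  Returns (chi2, p, U, V) arrays of
    length X.shape[1].  Columns with zero information get p = NaN.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    order = np.argsort(time, kind="mergesort")
    t, e, Xs = time[order], event[order], X[order]

    # suffix (risk-set) sums of x and x^2
    S1 = np.cumsum(Xs[::-1], axis=0)[::-1]
    S2 = np.cumsum((Xs ** 2)[::-1], axis=0)[::-1]

    _, start = np.unique(t, return_index=True)
    d = np.add.reduceat(e, start)                      # events per tied group
    Ed1 = np.add.reduceat(e[:, None] * Xs, start, axis=0)
    Ed2 = np.add.reduceat(e[:, None] * Xs ** 2, start, axis=0)
    nR = (n - start).astype(float)

    has = d > 0
    if not has.any():
        raise PrognosticsError("no events")
    S1g, S2g = S1[start][has], S2[start][has]
    Ed1, Ed2 = Ed1[has], Ed2[has]
    dg, nRg = d[has], nR[has]

    U = Ed1.sum(axis=0)
    V = np.zeros(m)
    for l in range(int(dg.max())):
        act = dg > l
        frac = (l / dg[act])[:, None]
        denom = (nRg[act] - l)[:, None]
        m1 = (S1g[act] - frac * Ed1[act]) / denom
        m2 = (S2g[act] - frac * Ed2[act]) / denom
        U -= m1.sum(axis=0)
        V += (m2 - m1 ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U ** 2 / V, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p, U, V


# ---------------------------------------------------------------------------
# AUC machinery

def auc_mann_whitney(labels, scores):
    """AUC (probability a positive outranks a negative, ties count 1/2),
    two-sided Mann-Whitney p, and DeLong 95% CI."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise PrognosticsError("binary endpoint needs both classes present")
    auc = _auc_from_ranks(labels, scores)
    p = stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue
    lo, hi = _delong_ci(pos, neg, auc)
    return auc, float(p), lo, hi


def _auc_from_ranks(labels, scores):
    r = stats.rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    u1 = r[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u1 / (n1 * n0))


def _delong_ci(pos, neg, auc, level: float = 0.95):
    """DeLong variance via placement values."""
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / n for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / m for y in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1))


def auc_screen(labels, X):
    """Vectorised AUC + normal-approximation Mann-Whitney p per column of X."""
    labels = np.asarray(labels, dtype=int)
    X = np.asarray(X, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise PrognosticsError("binary endpoint needs both classes present")
    ranks = stats.rankdata(X, axis=0)
    u1 = ranks[labels == 1].sum(axis=0) - n1 * (n1 + 1) / 2
    auc = u1 / (n1 * n0)
    # tie-corrected normal approximation
    n = len(labels)
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts ** 3 - counts)
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u1 - n1 * n0 / 2) / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z))
    return auc, p, z


# ---------------------------------------------------------------------------

def _align(score: ScoreVector, clin: ClinicalTable) -> tuple[pd.Series, pd.DataFrame]:
    s = score.to_series()
    common = s.index.intersection(clin.sample_ids)
    dropped = len(s) - len(common)
    if dropped:
        log.info("dropping %d samples absent from the clinical table", dropped)
    if len(common) == 0:
        raise PrognosticsError("no overlapping samples between score and clinical table")
    return s.loc[common], clin.data.loc[common]


def _fit_cox(df: pd.DataFrame, duration_col="time", event_col="event") -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def test_continuous(score: ScoreVector, clin: ClinicalTable) -> PrognosticResult:
    """Univariate prognostic test of a continuous score.

    Time-to-event: Cox PH with the score as sole covariate; HR per 1-unit
    with Wald CI; p from the score test at beta=0 (log-rank family); the LRT
    p is kept alongside.  Binary: AUC with Mann-Whitney p and DeLong CI.
    """
    s, cdata = _align(score, clin)
    x = s.to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise PrognosticsError("constant score")
    if clin.is_binary:
        y = cdata["label"].to_numpy(dtype=int)
        auc, p, lo, hi = auc_mann_whitney(y, x)
        return PrognosticResult(auc, lo, hi, p, len(x), "auc")
    time = cdata["time"].to_numpy(dtype=float)
    event = cdata["event"].to_numpy(dtype=float)
    if event.sum() == 0:
        raise PrognosticsError("no events")
    _, pvec, _, _ = cox_score_test(time, event, x)
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    cph = _fit_cox(df)
    summ = cph.summary.loc["x"]
    return PrognosticResult(
        estimate=float(np.exp(summ["coef"])),
        ci_low=float(np.exp(summ["coef lower 95%"])),
        ci_high=float(np.exp(summ["coef upper 95%"])),
        p=float(pvec[0]),
        n=len(x),
        method="cox_continuous",
        p_lrt=float(cph.log_likelihood_ratio_test().p_value),
    )


@dataclass
class ScreenResult:
    """Per-gene univariate screen: result table plus the genes under alpha.

    ``table`` columns: p, statistic (signed z), estimate (one-step HR for
    time-to-event endpoints, AUC for binary ones), method.
    """

    table: pd.DataFrame
    alpha: float
    excluded: tuple[str, ...] = ()

    @property
    def hits(self) -> list[str]:
        t = self.table
        return list(t.index[t["p"] < self.alpha])


def gene_screen(m, clin: ClinicalTable, alpha: float = 0.01) -> ScreenResult:
    """Test every gene row of a normalized matrix against the endpoint.

    Time-to-event: vectorised Cox score test per gene; ``estimate`` is the
    one-step Newton HR exp(U/V).  Binary: vectorised AUC with a
    normal-approximation Mann-Whitney p.  Genes whose test is undefined
    (zero information) are excluded with a logged reason.
    """
    if not m.normalized:
        raise PrognosticsError("gene_screen requires a normalized matrix")
    common = m.values.columns.intersection(clin.sample_ids)
    if len(common) == 0:
        raise PrognosticsError("no overlapping samples")
    X = m.values[common].to_numpy(dtype=float).T  # samples x genes
    cdata = clin.data.loc[common]
    genes = m.values.index
    if clin.is_binary:
        y = cdata["label"].to_numpy(dtype=int)
        auc, p, z = auc_screen(y, X)
        table = pd.DataFrame({"p": p, "statistic": z, "estimate": auc,
                              "method": "auc"}, index=genes)
    else:
        time = cdata["time"].to_numpy(dtype=float)
        event = cdata["event"].to_numpy(dtype=float)
        if event.sum() == 0:
            raise PrognosticsError("no events")
        chi2, p, U, V = cox_score_test(time, event, X)
        with np.errstate(divide="ignore", invalid="ignore"):
            onestep = np.exp(np.where(V > 0, U / V, np.nan))
            z = np.sign(U) * np.sqrt(chi2)
        table = pd.DataFrame({"p": p, "statistic": z, "estimate": onestep,
                              "method": "cox_continuous"}, index=genes)
    bad = table["p"].isna()
    excluded = tuple(genes[bad])
    if excluded:
        log.info("gene_screen: excluded %d genes with undefined tests", len(excluded))
    return ScreenResult(table=table.loc[~bad.values], alpha=alpha, excluded=excluded)


# ---------------------------------------------------------------------------
# Kaplan-Meier tertiles

@dataclass
class KMTertiles:
    """KM curves for the lower/middle/upper 33% of the score distribution.

    The reported p is the continuous-score p from :func:`test_continuous`,
    not a 3-group log-rank.
    """

    thresholds: tuple[float, float]
    curves: dict[str, pd.DataFrame]     # stratum -> (time, survival, at_risk)
    counts: dict[str, int]
    result: PrognosticResult


def km_tertiles(score: ScoreVector, clin: ClinicalTable) -> KMTertiles:
    if clin.is_binary:
        raise PrognosticsError("km_tertiles requires a time-to-event endpoint")
    s, cdata = _align(score, clin)
    if len(s) < 6:
        raise PrognosticsError("km_tertiles requires n >= 6")
    x = s.to_numpy(dtype=float)
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    strata = {"lower": x <= q1, "middle": (x > q1) & (x <= q2), "upper": x > q2}
    for name, mask in strata.items():
        if not mask.any():
            q = "33.33%" if name != "upper" else "66.67%"
            raise PrognosticsError(f"empty {name} stratum (ties at the {q} quantile)")
    curves, counts = {}, {}
    for name, mask in strata.items():
        kmf = KaplanMeierFitter()
        kmf.fit(cdata["time"][mask], cdata["event"][mask])
        tab = kmf.event_table
        curves[name] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=float),
        })
        counts[name] = int(mask.sum())
    res = test_continuous(score, clin)
    return KMTertiles(thresholds=(float(q1), float(q2)), curves=curves,
                      counts=counts, result=res)


# ---------------------------------------------------------------------------
# Multivariate: forward stepwise and added-value LRT

def _fit_multivariate(cdata: pd.DataFrame, cols: list[str], binary: bool):
    """Fit Cox or logistic model on the named columns; return (fit, loglik,
    wald_p dict, coefs dict)."""
    if binary:
        import statsmodels.api as sm
        y = cdata["label"].to_numpy(dtype=int)
        if not cols:
            X0 = np.ones((len(y), 1))
            fit = sm.Logit(y, X0).fit(disp=0)
            return fit, float(fit.llf), {}, {}
        X = sm.add_constant(cdata[cols].to_numpy(dtype=float))
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        wald = {c: float(fit.pvalues[i + 1]) for i, c in enumerate(cols)}
        coefs = {c: float(fit.params[i + 1]) for i, c in enumerate(cols)}
        return fit, float(fit.llf), wald, coefs
    df = cdata[["time", "event", *cols]].astype(float)
    cph = _fit_cox(df)
    if not cols:
        raise AssertionError("Cox null fit handled separately")
    wald = {c: float(cph.summary.loc[c, "p"]) for c in cols}
    coefs = {c: float(cph.params_[c]) for c in cols}
    return cph, float(cph.log_likelihood_), wald, coefs


def _cox_null_loglik(cdata: pd.DataFrame, anchor_col: str) -> float:
    """Null partial log-likelihood via lifelines' own LRT on any single fit."""
    df = cdata[["time", "event", anchor_col]].astype(float)
    cph = _fit_cox(df)
    lrt = cph.log_likelihood_ratio_test()
    return float(cph.log_likelihood_ - lrt.test_statistic / 2.0)


def _endpoint_frame(clin: ClinicalTable, samples: pd.Index) -> pd.DataFrame:
    cols = ["label"] if clin.is_binary else ["time", "event"]
    return clin.data.loc[samples, cols]


def stepwise_final_model(clin: ClinicalTable, candidates: pd.DataFrame,
                         enter_p: float = 0.05) -> FittedModel:
    """Forward stepwise selection of the "final model".

    Starting from the empty model, at each step the candidate with the
    smallest Wald p enters if p < ``enter_p`` (ties broken by p then by
    term name); there is no removal step.  An empty final model is a valid,
    flagged outcome.
    """
    if candidates.shape[1] == 0:
        raise PrognosticsError("no candidates supplied")
    common = candidates.index.intersection(clin.sample_ids)
    cdata = _endpoint_frame(clin, common).join(candidates.loc[common])
    if not clin.is_binary:
        n_events = int(cdata["event"].sum())
        if n_events < 5:
            raise PrognosticsError("fewer than 5 events")
    else:
        n_events = int(cdata["label"].sum())
    selected: list[str] = []
    trace: list[tuple[str, float]] = []
    remaining = sorted(candidates.columns)
    while remaining:
        best: tuple[float, str] | None = None
        for cand in remaining:
            try:
                _, _, wald, _ = _fit_multivariate(cdata, selected + [cand],
                                                  clin.is_binary)
                p = wald[cand]
            except Exception as exc:  # non-convergent candidate: skip this step
                log.info("stepwise: candidate %s failed (%s)", cand, exc)
                continue
            if np.isnan(p):
                continue
            if best is None or (p, cand) < best:
                best = (p, cand)
        if best is None or best[0] >= enter_p:
            break
        p, cand = best
        selected.append(cand)
        trace.append((cand, float(p)))
        remaining.remove(cand)
    if not selected:
        log.warning("stepwise: no candidate entered the model")
        return FittedModel(terms={}, loglik=np.nan, n_events=n_events,
                           selection_trace=[])
    _, ll, _, coefs = _fit_multivariate(cdata, selected, clin.is_binary)
    return FittedModel(terms=coefs, loglik=ll, n_events=n_events,
                       selection_trace=trace)


def added_value_test(clin: ClinicalTable, base: pd.DataFrame | None,
                     addition: pd.Series) -> PrognosticResult:
    """Nested likelihood-ratio test: does ``addition`` improve the base model?

    Base and full models are fit on the same samples; the statistic is
    2*(ll_full - ll_base) on 1 df.  An addition collinear with the base
    contributes nothing by construction (stat 0, p 1).
    """
    name = addition.name or "addition"
    add = addition.rename(name)
    if base is None:
        base = pd.DataFrame(index=add.index)
    common = base.index.intersection(add.index).intersection(clin.sample_ids)
    if len(common) == 0:
        raise PrognosticsError("no overlapping samples")
    basec = base.loc[common]
    addc = add.loc[common].to_numpy(dtype=float)
    base_cols = [c for c in basec.columns if basec[c].std() > 0]
    # collinearity guard: addition explained exactly by base -> no information
    if base_cols:
        Xb = np.column_stack([np.ones(len(common)),
                              basec[base_cols].to_numpy(dtype=float)])
        resid = addc - Xb @ np.linalg.lstsq(Xb, addc, rcond=None)[0]
        denom = np.var(addc) if np.var(addc) > 0 else 1.0
        if np.var(resid) / denom < 1e-12:
            return PrognosticResult(1.0, 1.0, 1.0, 1.0, len(common), "lrt", p_lrt=1.0)
    elif np.std(addc) == 0:
        return PrognosticResult(1.0, 1.0, 1.0, 1.0, len(common), "lrt", p_lrt=1.0)
    cdata = _endpoint_frame(clin, common).join(basec[base_cols])
    cdata[name] = addc
    full_cols = base_cols + [name]
    try:
        fit_full, ll_full, _, _ = _fit_multivariate(cdata, full_cols, clin.is_binary)
        if base_cols:
            _, ll_base, _, _ = _fit_multivariate(cdata, base_cols, clin.is_binary)
        elif clin.is_binary:
            ll_base = float(fit_full.llnull)
        else:
            ll_base = _cox_null_loglik(cdata, name)
    except Exception as exc:
        raise PrognosticsError(f"added_value_test fit failed: {exc}") from exc
    stat = max(0.0, 2.0 * (ll_full - ll_base))
    p = float(stats.chi2.sf(stat, df=1))
    if clin.is_binary:
        i = full_cols.index(name) + 1  # constant first
        coef = float(fit_full.params[i])
        se = float(fit_full.bse[i])
    else:
        coef = float(fit_full.params_[name])
        se = float(fit_full.standard_errors_[name])
    est = float(np.exp(coef))
    lo, hi = float(np.exp(coef - 1.959963984540054 * se)), \
        float(np.exp(coef + 1.959963984540054 * se))
    return PrognosticResult(est, lo, hi, p, len(common), "lrt", p_lrt=p)
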