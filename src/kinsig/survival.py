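"""Survival evaluation of gene signatures.

A candidate gene set is scored against two endpoints of a patient cohort —
time-to-treatment (TTT) and overall survival (OS) — with Cox proportional
hazards models: h_i(t) = h_0(t) exp(beta_1 x_1 + ... + beta_p x_p). The
linear predictor sum(beta_g x_g) is the prognostic index (risk score);
ranking and splitting the cohort at its median yields two equal-sized risk
groups, whose hazard ratio (exponentiated Cox coefficient of the binary
group indicator, with Wald CI and log-rank p) summarizes the signature's
prognostic strength. Per-gene hazard ratios and leave-one-out contributions
to the combined HR identify the strongest markers; a multivariate model
adjusts a single gene for IGHV mutation status and 17p13 deletion.

Fitting uses the Efron tie correction throughout (month-resolution
survival times routinely contain ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalCohort",
    "CoxFit",
    "RiskStratification",
    "fit_cox",
    "prognostic_index",
    "dichotomize_median",
    "group_hazard_ratio",
    "km_estimate",
    "logrank_test",
    "single_gene_hr",
    "signature_hr",
    "leave_one_out_contributions",
    "top_k_by_individual_hr",
    "multivariate_cox",
    "four_way_emergence",
    "SignatureSurvivalModel",
    "SignatureSurvivalResults",
]

Endpoint = Literal["ttt", "os"]

CLINICAL_COLUMNS = [
    "sample_id", "ttt_months", "ttt_event", "os_months", "os_event",
    "ighv", "del17p",
]


@dataclass
class SurvivalCohort:
    """Per-sample gene expression plus two survival endpoints.

    `data` columns: sample_id, ttt_months, ttt_event, os_months, os_event,
    ighv (mutated/unmutated/unknown), del17p (0/1), then one column per
    gene (continuous expression, log2 scale).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        for ep in ("ttt", "os"):
            if (self.data[f"{ep}_months"] < 0).any():
                raise ValueError(f"negative {ep} times")
            if not self.data[f"{ep}_event"].isin([0, 1]).all():
                raise ValueError(f"{ep}_event must be 0/1")

    @property
    def genes(self) -> list[str]:
        return [c for c in self.data.columns if c not in CLINICAL_COLUMNS]

    @property
    def n(self) -> int:
        return len(self.data)

    def endpoint_columns(self, endpoint: Endpoint) -> tuple[str, str]:
        if endpoint not in ("ttt", "os"):
            raise ValueError(f"endpoint must be 'ttt' or 'os', got {endpoint!r}")
        return f"{endpoint}_months", f"{endpoint}_event"

    def expression(self, genes: Sequence[str]) -> pd.DataFrame:
        missing = [g for g in genes if g not in self.data.columns]
        if missing:
            raise KeyError(f"genes absent from cohort: {missing}")
        return self.data[list(genes)]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SurvivalCohort":
        return cls(pd.read_csv(path))


@dataclass
class CoxFit:
    """A fitted Cox proportional hazards model (Efron ties)."""

    covariates: list[str]
    betas: pd.Series
    se: pd.Series
    p_values: pd.Series
    log_likelihood: float
    converged: bool
    n_events: int
    n: int
    diagnostic: str = ""

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.betas)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "HR": np.exp(self.betas),
                "se": self.se,
                "p": self.p_values,
            }
        )


@dataclass
class RiskStratification:
    """Median-split risk groups with their hazard ratio.

    hr is the exponentiated Cox coefficient of the high-vs-low indicator;
    flagged marks degenerate fits (e.g. a group without events).
    """

    labels: pd.Series = field(repr=False)  # 'low'/'high' per sample
    hr: float
    hr_ci: tuple[float, float]
    logrank_p: float
    n_events: dict[str, int]
    prognostic_index: pd.Series | None = field(default=None, repr=False)
    fit: CoxFit | None = None
    flagged: bool = False
    diagnostic: str = ""


def _raise_constant(df: pd.DataFrame, covariates: Sequence[str]) -> None:
    constant = [c for c in covariates if df[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")


def fit_cox(
    cohort: SurvivalCohort,
    covariates: Sequence[str],
    endpoint: Endpoint,
    extra: pd.DataFrame | None = None,
) -> CoxFit:
    """Fit a Cox model on cohort covariates (gene columns and/or columns of
    `extra`, aligned on the cohort row order)."""
    tcol, ecol = cohort.endpoint_columns(endpoint)
    df = cohort.data[[tcol, ecol]].copy()
    for cov in covariates:
        if extra is not None and cov in extra.columns:
            df[cov] = np.asarray(extra[cov], dtype=float)
        elif cov in cohort.data.columns:
            df[cov] = np.asarray(cohort.data[cov], dtype=float)
        else:
            raise KeyError(f"covariate {cov!r} absent from cohort")
    return _fit_cox_frame(df, list(covariates), tcol, ecol)


def _fit_cox_frame(
    df: pd.DataFrame, covariates: list[str], tcol: str, ecol: str
) -> CoxFit:
    n_events = int(df[ecol].sum())
    if n_events == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    _raise_constant(df, covariates)
    cph = CoxPHFitter(penalizer=0.0)
    converged, diagnostic = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col=tcol, event_col=ecol)
        except ConvergenceError as exc:
            return CoxFit(
                covariates=covariates,
                betas=pd.Series(np.nan, index=covariates),
                se=pd.Series(np.nan, index=covariates),
                p_values=pd.Series(np.nan, index=covariates),
                log_likelihood=np.nan,
                converged=False,
                n_events=n_events,
                n=len(df),
                diagnostic=f"convergence failure: {exc}",
            )
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            diagnostic = str(w.message)
    return CoxFit(
        covariates=covariates,
        betas=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        p_values=cph.summary["p"].copy(),
        log_likelihood=float(cph.log_likelihood_),
        converged=converged,
        n_events=n_events,
        n=len(df),
        diagnostic=diagnostic,
    )


def prognostic_index(fit: CoxFit, cohort: SurvivalCohort) -> pd.Series:
    """PI_i = sum_g beta_g x_ig, indexed by sample_id."""
    missing = [c for c in fit.covariates if c not in cohort.data.columns]
    if missing:
        raise KeyError(f"cohort lacks fit covariate(s): {missing}")
    X = cohort.data[fit.covariates].to_numpy(dtype=float)
    pi = X @ fit.betas.loc[fit.covariates].to_numpy()
    return pd.Series(pi, index=cohort.data["sample_id"], name="prognostic_index")


def dichotomize_median(values: Sequence[float], ids: Sequence | None = None) -> pd.Series:
    """Rank-based median split into equal-sized groups (+-1 for odd n).

    Samples are stably sorted by (value, id); the first ceil(n/2) are
    labelled 'low', the rest 'high'. All-identical values are rejected —
    no informative split exists.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need >= 2 values to dichotomize")
    if np.isnan(v).any():
        raise ValueError("NaN in values to dichotomize")
    if np.all(v == v[0]):
        raise ValueError("all values identical: no informative median split")
    if ids is None:
        ids = np.arange(len(v))
    ids = np.asarray(ids)
    order = np.lexsort((ids, v))  # value primary, id secondary, stable
    n_low = int(np.ceil(len(v) / 2))
    labels = np.empty(len(v), dtype=object)
    labels[order[:n_low]] = "low"
    labels[order[n_low:]] = "high"
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="risk_group")


def group_hazard_ratio(
    cohort: SurvivalCohort, labels: Sequence[str], endpoint: Endpoint
) -> RiskStratification:
    """HR of high vs low risk group: exp of the Cox coefficient of the
    group indicator, with Wald 95% CI and the log-rank p attached."""
    tcol, ecol = cohort.endpoint_columns(endpoint)
    lab = np.asarray(labels)
    if set(lab) - {"low", "high"}:
        raise ValueError("labels must be 'low'/'high'")
    times = cohort.data[tcol].to_numpy(dtype=float)
    events = cohort.data[ecol].to_numpy(dtype=int)
    n_events = {
        g: int(events[lab == g].sum()) for g in ("low", "high")
    }
    stat, logrank_p = logrank_test(times, events, lab)
    label_series = pd.Series(lab, index=cohort.data["sample_id"], name="risk_group")

    if min((lab == "low").sum(), (lab == "high").sum()) == 0:
        raise ValueError("one risk group is empty")
    if n_events["low"] == 0 or n_events["high"] == 0:
        hr = np.inf if n_events["low"] == 0 else 0.0
        return RiskStratification(
            labels=label_series, hr=hr, hr_ci=(np.nan, np.nan),
            logrank_p=logrank_p, n_events=n_events, flagged=True,
            diagnostic="a risk group has zero events; HR degenerate",
        )
    df = cohort.data[[tcol, ecol]].copy()
    df["high_risk"] = (lab == "high").astype(float)
    fit = _fit_cox_frame(df, ["high_risk"], tcol, ecol)
    beta = float(fit.betas["high_risk"])
    se = float(fit.se["high_risk"])
    ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
    return RiskStratification(
        labels=label_series,
        hr=float(np.exp(beta)),
        hr_ci=ci,
        logrank_p=logrank_p,
        n_events=n_events,
        fit=fit,
        flagged=not fit.converged,
        diagnostic=fit.diagnostic,
    )


def km_estimate(
    times: Sequence[float], events: Sequence[int], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Product-limit survival estimate, tidy per group.

    Returns columns (group, time, survival, at_risk); the time grid is the
    set of observed times per group, always including t=0 with S=1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if labels is None:
        labels = np.repeat("all", len(times))
    labels = np.asarray(labels)
    out = []
    for g in pd.unique(labels):
        mask = labels == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        for t in table.index:
            out.append(
                {
                    "group": g,
                    "time": float(t),
                    "survival": float(surv.loc[t]),
                    "at_risk": int(table.loc[t, "at_risk"]),
                }
            )
    return pd.DataFrame(out)


def logrank_test(
    times: Sequence[float], events: Sequence[int], labels: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(groups)}")
    m0, m1 = labels == groups[0], labels == groups[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("one group is empty")
    res = _ll_logrank(times[m0], times[m1], events[m0], events[m1])
    return float(res.test_statistic), float(res.p_value)


def single_gene_hr(
    cohort: SurvivalCohort, gene: str, endpoint: Endpoint
) -> RiskStratification:
    """Median split on one gene's expression, then the group HR."""
    expr = cohort.expression([gene])[gene]
    labels = dichotomize_median(expr.to_numpy(), ids=cohort.data["sample_id"])
    return group_hazard_ratio(cohort, labels.to_numpy(), endpoint)


def signature_hr(
    cohort: SurvivalCohort, genes: Sequence[str], endpoint: Endpoint
) -> RiskStratification:
    """Combined-signature HR: Cox fit on all genes -> prognostic index ->
    median split -> group HR."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene signature")
    fit = fit_cox(cohort, genes, endpoint)
    if not np.isfinite(fit.betas).all():
        return RiskStratification(
            labels=pd.Series(dtype=object), hr=np.nan, hr_ci=(np.nan, np.nan),
            logrank_p=np.nan, n_events={}, fit=fit, flagged=True,
            diagnostic=fit.diagnostic or "signature Cox fit did not converge",
        )
    pi = prognostic_index(fit, cohort)
    labels = dichotomize_median(pi.to_numpy(), ids=cohort.data["sample_id"])
    strat = group_hazard_ratio(cohort, labels.to_numpy(), endpoint)
    strat.prognostic_index = pi
    strat.fit = fit
    strat.flagged = strat.flagged or not fit.converged
    return strat


def leave_one_out_contributions(
    cohort: SurvivalCohort, genes: Sequence[str], endpoint: Endpoint, k: int | None = None
) -> pd.DataFrame:
    """Contribution of each gene to the combined HR.

    For each gene g the signature HR is recomputed on genes \\ {g};
    contribution = HR_full - HR_without. Returns a frame sorted by
    contribution descending (ties by gene name) with columns
    (gene, hr_without, contribution); `k` truncates to the top k.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for leave-one-out analysis")
    if k is not None and k > len(genes):
        raise ValueError(f"k={k} exceeds pool size {len(genes)}")
    hr_full = signature_hr(cohort, genes, endpoint).hr
    rows = []
    for g in genes:
        rest = [x for x in genes if x != g]
        hr_wo = signature_hr(cohort, rest, endpoint).hr
        rows.append({"gene": g, "hr_without": hr_wo, "contribution": hr_full - hr_wo})
    out = pd.DataFrame(rows).sort_values(
        ["contribution", "gene"], ascending=[False, True], ignore_index=True
    )
    out.attrs["hr_full"] = hr_full
    return out if k is None else out.head(k).reset_index(drop=True)


def top_k_by_individual_hr(
    cohort: SurvivalCohort, genes: Sequence[str], endpoint: Endpoint, k: int = 8
) -> tuple[pd.DataFrame, RiskStratification]:
    """Rank genes by individual median-split HR; refit a k-gene signature
    on the top k and return (ranking frame, combined stratification)."""
    genes = list(genes)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds pool size {len(genes)}")
    rows = []
    for g in genes:
        strat = single_gene_hr(cohort, g, endpoint)
        rows.append({"gene": g, "hr": strat.hr, "logrank_p": strat.logrank_p})
    ranking = pd.DataFrame(rows).sort_values(
        ["hr", "gene"], ascending=[False, True], ignore_index=True
    )
    top = ranking["gene"].head(k).tolist()
    return ranking, signature_hr(cohort, top, endpoint)


def multivariate_cox(
    cohort: SurvivalCohort, endpoint: Endpoint, gene: str = "DNPEP"
) -> dict:
    """Gene high/low adjusted for IGHV status and del17p.

    IGHV 'unknown' samples are excluded listwise. Returns univariate and
    multivariate CoxFits plus Wald p-values per covariate.
    """
    expr = cohort.expression([gene])[gene]
    labels = dichotomize_median(expr.to_numpy(), ids=cohort.data["sample_id"])
    keep = cohort.data["ighv"].isin(["mutated", "unmutated"]).to_numpy()
    if keep.sum() < 2:
        raise ValueError("too few samples with known IGHV status")
    sub = cohort.data.loc[keep].reset_index(drop=True)
    covs = pd.DataFrame(
        {
            f"{gene}_high": (labels.to_numpy() == "high").astype(float)[keep],
            "ighv_unmutated": (sub["ighv"] == "unmutated").astype(float),
            "del17p": sub["del17p"].astype(float),
        }
    )
    subcohort = SurvivalCohort(sub)
    names = list(covs.columns)
    _raise_constant(covs, names)
    multi = fit_cox(subcohort, names, endpoint, extra=covs)
    uni = {
        c: fit_cox(subcohort, [c], endpoint, extra=covs) for c in names
    }
    return {
        "multivariate": multi,
        "univariate": uni,
        "p_values": multi.p_values.to_dict(),
        "n": int(keep.sum()),
    }


def four_way_emergence(
    cohort: SurvivalCohort, genes: Sequence[str], k: int | None = None
) -> dict:
    """The four top-k lists (individual-HR and leave-one-out, per endpoint)
    and their intersection — the 'emerges across all analyses' criterion.

    With k=None the list length is effect-driven per endpoint: the number
    of genes whose individual-HR Wald CI lies above 1 (at least 1) — the
    analog of cutting at 'HR above the baseline marker' rather than at a
    fixed quantile of the pool.
    """
    genes = list(genes)
    lists: dict[str, list[str]] = {}
    ks: dict[str, int] = {}
    for ep in ("ttt", "os"):
        rows = []
        for g in genes:
            strat = single_gene_hr(cohort, g, ep)
            rows.append(
                {"gene": g, "hr": strat.hr, "ci_low": strat.hr_ci[0]}
            )
        ranking = pd.DataFrame(rows).sort_values(
            ["hr", "gene"], ascending=[False, True], ignore_index=True
        )
        k_ep = k if k is not None else max(int((ranking["ci_low"] > 1).sum()), 1)
        k_ep = min(k_ep, len(genes))
        ks[ep] = k_ep
        lists[f"individual_{ep}"] = ranking["gene"].head(k_ep).tolist()
        loo = leave_one_out_contributions(cohort, genes, ep, k=k_ep)
        lists[f"loo_{ep}"] = loo["gene"].tolist()
    common = set(lists["individual_ttt"])
    for key in ("individual_os", "loo_ttt", "loo_os"):
        common &= set(lists[key])
    return {**lists, "k": ks, "common": sorted(common)}


class SignatureSurvivalModel:
    """Signature-vs-survival model in the statsmodels Model/Results idiom.

    Parameters
    ----------
    cohort : SurvivalCohort
    genes : sequence of str
        Signature gene pool evaluated against the endpoint.
    endpoint : {'ttt', 'os'}
    """

    def __init__(self, cohort: SurvivalCohort, genes: Sequence[str], endpoint: Endpoint):
        self.cohort = cohort
        self.genes = list(genes)
        self.endpoint = endpoint

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, genes: Sequence[str], endpoint: Endpoint
    ) -> "SignatureSurvivalModel":
        return cls(SurvivalCohort(data), genes, endpoint)

    def fit(self, k: int = 8, leave_one_out: bool = True) -> "SignatureSurvivalResults":
        strat = signature_hr(self.cohort, self.genes, self.endpoint)
        individual = pd.DataFrame(
            [
                {
                    "gene": g,
                    "hr": single_gene_hr(self.cohort, g, self.endpoint).hr,
                }
                for g in self.genes
            ]
        ).sort_values(["hr", "gene"], ascending=[False, True], ignore_index=True)
        loo = (
            leave_one_out_contributions(self.cohort, self.genes, self.endpoint)
            if leave_one_out and len(self.genes) >= 2
            else None
        )
        return SignatureSurvivalResults(
            model=self, stratification=strat, individual_hr=individual,
            contributions=loo, k=k,
        )


@dataclass
class SignatureSurvivalResults:
    """Fit results: combined stratification, per-gene HRs, contributions."""

    model: SignatureSurvivalModel
    stratification: RiskStratification
    individual_hr: pd.DataFrame = field(repr=False)
    contributions: pd.DataFrame | None = field(repr=False, default=None)
    k: int = 8

    @property
    def hr(self) -> float:
        return self.stratification.hr

    def top_genes(self) -> list[str]:
        return self.individual_hr["gene"].head(self.k).tolist()

    def summary(self) -> str:
        s = self.stratification
        lines = [
            f"Signature survival analysis — endpoint {self.model.endpoint}",
            f"  genes: {len(self.model.genes)}, samples: {self.model.cohort.n}",
            f"  combined HR (high vs low): {s.hr:.3f} "
            f"[{s.hr_ci[0]:.3f}, {s.hr_ci[1]:.3f}], log-rank p = {s.logrank_p:.3g}",
            f"  events: low {s.n_events.get('low')}, high {s.n_events.get('high')}",
            "  top genes by individual HR: "
            + ", ".join(
                f"{r.gene} ({r.hr:.2f})"
                for r in self.individual_hr.head(self.k).itertuples()
            ),
        ]
        if self.contributions is not None:
            top = self.contributions.head(self.k)
            lines.append(
                "  strongest leave-one-out contributors: "
                + ", ".join(
                    f"{r.gene} ({r.contribution:+.2f})" for r in top.itertuples()
                )
            )
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan–Meier curves of the two risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tcol, ecol = self.model.cohort.endpoint_columns(self.model.endpoint)
        data = self.model.cohort.data
        lab = self.stratification.labels.to_numpy()
        for grp in ("low", "high"):
            mask = lab == grp
            kmf = KaplanMeierFitter()
            kmf.fit(data.loc[mask, tcol], data.loc[mask, ecol], label=f"{grp} risk")
            kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        return ax
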