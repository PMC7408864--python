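"""Synthetic inputs with planted ground truth for the full pipeline.

Every input the analysis consumes can be generated here: a multi-study
collection of log2 expression matrices with genes planted to co-express
with a kinase panel, a survival cohort drawn from a proportional-hazards
model, a qPCR Ct table with stage-dependent expression, and median-effect
dose-response curves with known Loewe-additivity (or planted synergy).

Co-expression model: each dataset has a per-sample latent "BcR activity"
factor f; panel kinase j is lambda*f + sqrt(1-lambda^2)*e_j (so kinases are
mutually correlated at lambda^2, as co-regulated pathway members are), and
a planted positive gene is rho*u + sqrt(1-rho^2)*eps against the
standardized mean u of its target-kinase set, in each of its support
datasets. Background genes are independent noise. All values are affinely
rescaled to a log2-microarray-like scale. A gene cannot correlate at
rho > 1/sqrt(s) with s mutually independent kinases, which is why the
shared factor is part of the model, not an option.

Each generator draws from its own child stream of the master seed, so
adding or reordering generators never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionDataset
from .survival import SurvivalCohort

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "generate_expression_collection",
    "generate_survival_cohort",
    "generate_qpcr_table",
    "generate_dose_response",
    "generate_kinetic_trace",
]

_DEFAULT_PANEL = ("ZAP70", "AKT1", "AKT2", "BTK", "MAPK1", "MAPK3", "PIK3CD")

# stream indices spawned from the master seed, one per generator
_STREAMS = {"expression": 0, "survival": 1, "qpcr": 2, "dose": 3, "kinetic": 4}


def _default_betas_ttt() -> dict[str, float]:
    return {
        "DNPEP": 1.0,
        "SIG_T1": 0.8, "SIG_T2": 0.8, "SIG_T3": 0.8, "SIG_T4": 0.8,
    }


def _default_betas_os() -> dict[str, float]:
    return {
        "DNPEP": 1.0,
        "SIG_O1": 0.8, "SIG_O2": 0.8, "SIG_O3": 0.8, "SIG_O4": 0.8,
    }


def _default_stage_effect() -> dict[str, float]:
    # log2 expression shift per Rai risk stratum
    return {"0": 0.0, "I-II": 1.0, "III-IV": 2.0}


def _default_drugs() -> dict[str, tuple[float, float]]:
    # (m, Dm): slopes and median-effect doses, concentrations in uM
    return {"DI93293": (1.5, 1.4), "ABT737": (2.0, 0.3)}


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, fully determined by `seed`."""

    seed: int = 0
    # expression collection
    n_datasets: int = 14
    samples_per_dataset: tuple[int, int] = (30, 200)
    n_genes: int = 2000
    kinase_panel: tuple[str, ...] = _DEFAULT_PANEL
    planted_positive_genes: int = 100
    rho: float = 0.85
    planted_dataset_support: int = 6
    kinases_per_positive: int = 3
    kinase_loading: float = 0.9  # lambda of the shared BcR-activity factor
    outlier_fraction: float = 0.0
    # survival cohort
    cohort_n: int = 107
    true_betas_ttt: dict[str, float] = field(default_factory=_default_betas_ttt)
    true_betas_os: dict[str, float] = field(default_factory=_default_betas_os)
    cohort_noise_genes: int = 3
    baseline_hazard_ttt: float = 1.0 / 40.0   # events per month
    baseline_hazard_os: float = 1.0 / 120.0
    censor_window_ttt: float = 120.0          # months
    censor_window_os: float = 150.0
    ighv_unmutated_prevalence: float = 0.45
    ighv_unknown_prevalence: float = 0.07
    del17p_prevalence: float = 0.08
    beta_ighv: float = 0.8
    beta_del17p: float = 0.9
    # qPCR
    qpcr_n: int = 34
    rai_sizes: tuple[int, int, int] = (20, 10, 4)   # stage 0 / I-II / III-IV
    stage_effect: dict[str, float] = field(default_factory=_default_stage_effect)
    qpcr_sigma: float = 0.5     # cycles, per-sample biological + technical
    reference_ct_mean: float = 25.0
    qpcr_target: str = "DNPEP"
    qpcr_reference: str = "ABL1"
    # dose-response
    drugs: dict[str, tuple[float, float]] = field(default_factory=_default_drugs)
    doses_per_curve: int = 8
    synergy_factor: float = 1.0   # 1 = Loewe-additive combinations
    dose_noise: float = 0.0       # sd of logit-scale noise on fa

    def __post_init__(self) -> None:
        for name in ("n_datasets", "n_genes", "cohort_n", "qpcr_n",
                     "planted_dataset_support", "doses_per_curve"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")
        if not (0.0 <= self.outlier_fraction <= 0.3):
            raise ValueError("outlier_fraction must be in [0, 0.3]")
        if self.planted_dataset_support > self.n_datasets:
            raise ValueError("planted_dataset_support exceeds n_datasets")
        if self.kinases_per_positive > len(self.kinase_panel):
            raise ValueError("kinases_per_positive exceeds panel size")
        if not (self.rho <= 1.0) or self.kinase_loading <= 0 or self.kinase_loading > 1:
            raise ValueError("kinase_loading must be in (0, 1]")
        if sum(self.rai_sizes) != self.qpcr_n:
            raise ValueError("rai_sizes must sum to qpcr_n")
        if self.qpcr_sigma < 0:
            raise ValueError("qpcr_sigma must be >= 0")
        if self.baseline_hazard_ttt <= 0 or self.baseline_hazard_os <= 0:
            raise ValueError("baseline hazards must be positive")
        for drug, (m, dm) in self.drugs.items():
            if m <= 0 or dm <= 0:
                raise ValueError(f"drug {drug!r}: m and Dm must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators."""

    positive_genes: dict[str, dict] = field(default_factory=dict)
    true_betas: dict[str, dict[str, float]] = field(default_factory=dict)
    true_median_effect: dict[str, tuple[float, float]] = field(default_factory=dict)
    synergy_factor: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


def _background_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_expression_collection(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], PlantedTruth]:
    """The multi-study expression collection with planted positives."""
    rng = config.rng("expression")
    panel = list(config.kinase_panel)
    background = _background_names(config.n_genes)
    if set(panel) & set(background):
        raise ValueError("kinase panel collides with background gene names")

    n_pos = config.planted_positive_genes
    if n_pos > config.n_genes:
        raise ValueError("more planted positives than genes")
    pos_idx = rng.choice(config.n_genes, size=n_pos, replace=False)
    pos_genes = sorted(background[i] for i in pos_idx)

    lam = config.kinase_loading
    anchor = panel[0]
    truth = PlantedTruth()
    plan: dict[str, dict] = {}
    for g in pos_genes:
        others = [k for k in panel if k != anchor]
        extra = rng.choice(
            len(others), size=config.kinases_per_positive - 1, replace=False
        )
        kinases = [anchor] + sorted(others[i] for i in extra)
        ds_support = sorted(
            rng.choice(config.n_datasets, size=config.planted_dataset_support,
                       replace=False).tolist()
        )
        plan[g] = {"kinases": kinases, "datasets": ds_support}
    truth.positive_genes = plan

    gene_means = {g: 8.0 + rng.normal(0, 1.0) for g in background + panel}
    scale = 1.2  # log2-intensity spread

    datasets: list[ExpressionDataset] = []
    lo, hi = config.samples_per_dataset
    for d in range(config.n_datasets):
        ds_id = f"DS{d + 1:02d}"
        n = int(rng.integers(lo, hi + 1))
        f = rng.standard_normal(n)
        kin_z = {
            k: lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            for k in panel
        }
        Z = np.empty((len(background), n))
        for i, g in enumerate(background):
            Z[i] = rng.standard_normal(n)
        idx = {g: i for i, g in enumerate(background)}
        for g, info in plan.items():
            eps = rng.standard_normal(n)
            if d in info["datasets"]:
                u = np.sum([kin_z[k] for k in info["kinases"]], axis=0)
                u = (u - u.mean()) / u.std()
                Z[idx[g]] = config.rho * u + np.sqrt(1 - config.rho**2) * eps
            else:
                Z[idx[g]] = eps
        all_genes = background + panel
        M = np.vstack([Z, np.array([kin_z[k] for k in panel])])
        if config.outlier_fraction > 0:
            n_out = int(np.floor(config.outlier_fraction * n))
            if n_out:
                cols = rng.choice(n, size=n_out, replace=False)
                M[:, cols] = 10.0 * rng.standard_normal((M.shape[0], n_out))
        means = np.array([gene_means[g] for g in all_genes])[:, None]
        data = pd.DataFrame(
            means + scale * M,
            index=pd.Index(all_genes, name="gene_id"),
            columns=[f"{ds_id}_S{j + 1:03d}" for j in range(n)],
        )
        datasets.append(ExpressionDataset(dataset_id=ds_id, data=data))
    return datasets, truth


def generate_survival_cohort(
    config: SyntheticConfig,
) -> tuple[SurvivalCohort, PlantedTruth]:
    """A proportional-hazards cohort with two endpoints.

    Event times are exponential with rate h0 * exp(PI) per endpoint;
    censoring is independent uniform on (0, censor_window). Both endpoints
    share covariates (gene expression, IGHV, del17p) but have independent
    event-time noise.
    """
    rng = config.rng("survival")
    genes = sorted(set(config.true_betas_ttt) | set(config.true_betas_os))
    genes += [f"NOISE{i + 1:02d}" for i in range(config.cohort_noise_genes)]
    n = config.cohort_n

    X = pd.DataFrame(
        rng.standard_normal((n, len(genes))), columns=genes
    )
    p_unk = config.ighv_unknown_prevalence
    p_unm = config.ighv_unmutated_prevalence
    u = rng.random(n)
    ighv = np.where(u < p_unm, "unmutated",
                    np.where(u < p_unm + p_unk, "unknown", "mutated"))
    del17p = (rng.random(n) < config.del17p_prevalence).astype(int)

    cols = {"sample_id": [f"P{i + 1:03d}" for i in range(n)]}
    truth = PlantedTruth()
    for ep, betas, h0, window in (
        ("ttt", config.true_betas_ttt, config.baseline_hazard_ttt,
         config.censor_window_ttt),
        ("os", config.true_betas_os, config.baseline_hazard_os,
         config.censor_window_os),
    ):
        lp = np.zeros(n)
        for g, b in betas.items():
            lp += b * X[g].to_numpy()
        lp += config.beta_ighv * (ighv == "unmutated")
        lp += config.beta_del17p * del17p
        t_event = rng.exponential(1.0, size=n) / (h0 * np.exp(lp))
        c = rng.uniform(0.0, window, size=n) if window > 0 else np.zeros(n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
        if window == 0:
            event[:] = 0
        cols[f"{ep}_months"] = time
        cols[f"{ep}_event"] = event
        truth.true_betas[ep] = dict(betas)
    frame = pd.DataFrame(cols)
    frame["ighv"] = ighv
    frame["del17p"] = del17p
    frame = pd.concat([frame, X], axis=1)
    return SurvivalCohort(frame), truth


def generate_qpcr_table(config: SyntheticConfig) -> pd.DataFrame:
    """Ct table (sample_id, gene, ct, rai, binet) with stage-planted shifts.

    Reference-gene Ct ~ N(mu_ref, sigma); target Ct = ct_ref - log2(expr)
    + noise where log2(expr) = stage_effect[stratum] + N(0, sigma).
    Rai strata sizes default to 20/10/4; Binet is derived (Rai 0 -> A,
    III-IV -> C, I-II mostly A) so that A vs B+C is 29 vs 5 at defaults.
    """
    rng = config.rng("qpcr")
    n0, n1, n2 = config.rai_sizes
    rai = ["0"] * n0 + ["I-II"] * n1 + ["III-IV"] * n2
    binet = ["A"] * n0 + ["A"] * max(n1 - 1, 0) + ["B"] * min(n1, 1) + ["C"] * n2
    rows = []
    for i in range(config.qpcr_n):
        sid = f"Q{i + 1:03d}"
        ct_ref = config.reference_ct_mean + config.qpcr_sigma * rng.standard_normal()
        log2_expr = (
            config.stage_effect[rai[i]]
            + config.qpcr_sigma * rng.standard_normal()
        )
        ct_target = (
            ct_ref - log2_expr + config.qpcr_sigma * rng.standard_normal()
        )
        rows.append((sid, config.qpcr_reference, ct_ref, rai[i], binet[i]))
        rows.append((sid, config.qpcr_target, ct_target, rai[i], binet[i]))
    df = pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "rai", "binet"])
    if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
        raise ValueError("generated Ct outside (0, 45); check config scale")
    return df


def _dx(fa: float, m: float, dm: float) -> float:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def generate_dose_response(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Single-agent and combination dose-response tables.

    Single agents follow the median-effect equation
    fa = D^m / (D^m + Dm^m). Combination points (first drug varied, second
    fixed near its Dm, a non-constant-ratio design) are constructed so that
    d1/Dx1(fa) + d2/Dx2(fa) = synergy_factor — i.e. the true combination
    index equals `synergy_factor` at every point (1 = Loewe additivity).
    Optional noise perturbs fa on the logit scale.
    """
    rng = config.rng("dose")
    truth = PlantedTruth(
        true_median_effect=dict(config.drugs), synergy_factor=config.synergy_factor
    )
    single_rows = []
    for drug, (m, dm) in config.drugs.items():
        k = config.doses_per_curve
        doses = dm * np.logspace(-1.2, 1.2, k, base=10.0)
        for d in doses:
            if d <= 0:
                raise ValueError("doses must be positive")
            fa = d**m / (d**m + dm**m)
            if config.dose_noise > 0:
                logit = np.log(fa / (1 - fa)) + config.dose_noise * rng.standard_normal()
                fa = 1.0 / (1.0 + np.exp(-logit))
            single_rows.append((drug, d, fa))
    single = pd.DataFrame(single_rows, columns=["drug", "dose", "fa"])

    names = list(config.drugs)
    combo_rows = []
    if len(names) >= 2:
        d1_name, d2_name = names[0], names[1]
        m1, dm1 = config.drugs[d1_name]
        m2, dm2 = config.drugs[d2_name]
        d2 = dm2  # fixed second agent, paper-style design
        s = config.synergy_factor
        for d1 in dm1 * np.logspace(-0.9, 0.9, 6, base=10.0):
            def gap(fa: float) -> float:
                return d1 / _dx(fa, m1, dm1) + d2 / _dx(fa, m2, dm2) - s

            fa = brentq(gap, 1e-12, 1 - 1e-12)
            if config.dose_noise > 0:
                logit = np.log(fa / (1 - fa)) + config.dose_noise * rng.standard_normal()
                fa = 1.0 / (1.0 + np.exp(-logit))
            combo_rows.append((d1_name, d1, d2_name, d2, fa))
    combos = pd.DataFrame(
        combo_rows, columns=["drug1", "dose1", "drug2", "dose2", "fa"]
    )
    return single, combos, truth


def generate_kinetic_trace(
    config: SyntheticConfig,
    slopes: Mapping[str, float] | None = None,
    noise: float = 0.0,
    n_points: int = 30,
    saturate_after: float | None = None,
) -> pd.DataFrame:
    """Kinetic fluorescence traces (time_s, rfu, condition).

    One trace per condition; fluorescence rises linearly at the given
    slope (RFU/min, defaults untreated 100, inhibitor 12, zinc_blocked 5)
    with optional Gaussian noise, plateauing after `saturate_after`
    seconds if set.
    """
    rng = config.rng("kinetic")
    if slopes is None:
        slopes = {"untreated": 100.0, "inhibitor": 12.0, "zinc_blocked": 5.0}
    t = np.arange(n_points, dtype=float) * 60.0
    rows = []
    for cond, slope in slopes.items():
        eff_t = t if saturate_after is None else np.minimum(t, saturate_after)
        rfu = 50.0 + slope * eff_t / 60.0
        if noise > 0:
            rfu = rfu + noise * rng.standard_normal(n_points)
        for ti, yi in zip(t, rfu):
            rows.append((ti, yi, cond))
    return pd.DataFrame(rows, columns=["time_s", "rfu", "condition"])
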