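"""Enzyme-activity scoring and Chou-Talalay combination indices.

Kinetic aminopeptidase assays are reduced to a rate of fluorescence
increase (RFI, fluorescence units per minute) over the most linear
window of the trace; the inhibitor effect is
activity score = (RFI_inhibitor - RFI_untreated) / (RFI_untreated -
RFI_zinc_blocked) * 100%, where the zinc-blocked reaction defines zero
activity. Negative scores mean inhibition; the magnitude is also reported.

Dose-response curves follow the median-effect equation
fa/fu = (D/Dm)^m, fitted by linear regression of log(fa/(1-fa)) on
log D. The combination index at an observed combination point is
CI = d1/Dx1 + d2/Dx2 with Dx = Dm (fa/(1-fa))^(1/m) (mutually-exclusive,
non-constant-ratio form): CI < 1 synergy, = 1 additivity, > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "kinetic_slope",
    "activity_score",
    "MedianEffectFit",
    "median_effect_fit",
    "combination_index",
    "ci_label",
    "combination_table",
    "MedianEffectModel",
    "MedianEffectResults",
]


def kinetic_slope(
    timestamps: Sequence[float],
    fluorescence: Sequence[float],
    window_points: int = 10,
) -> tuple[float, float]:
    """OLS slope (per minute) over the contiguous window maximizing R^2.

    The "linear portion" of a saturating kinetic trace is found by sliding
    a window of `window_points` samples and keeping the window with the
    best linear fit (ties resolved towards the earliest window). Returns
    (slope_per_minute, r2); an all-constant trace returns slope 0 with
    r2 = nan (degenerate flag).
    """
    t = np.asarray(timestamps, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("timestamps and fluorescence must be equal-length vectors")
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if window_points < 2 or window_points > len(t):
        raise ValueError("window_points must be in [2, len(trace)]")
    if np.allclose(y, y[0]):
        return 0.0, float("nan")
    best = None
    for start in range(len(t) - window_points + 1):
        sl = slice(start, start + window_points)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat window -> r = nan
            res = stats.linregress(t[sl], y[sl])
        r2 = res.rvalue**2 if np.isfinite(res.rvalue) else -np.inf
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, res.slope)
    r2, slope_per_s = best
    return float(slope_per_s * 60.0), float(r2)


def activity_score(rfi_di: float, rfi_u: float, rfi_zn: float) -> float:
    """((RFI_inhibited - RFI_untreated) / (RFI_untreated - RFI_blocked)) * 100.

    0% means no effect of the inhibitor; -100% means full block down to
    the zinc-inhibited baseline. Report abs() as the inhibition magnitude.
    """
    if rfi_u == rfi_zn:
        raise ValueError(
            "no dynamic range: untreated and zinc-blocked rates are equal"
        )
    return (rfi_di - rfi_u) / (rfi_u - rfi_zn) * 100.0


@dataclass
class MedianEffectFit:
    """Median-effect parameters of one drug: fa/fu = (D/Dm)^m."""

    drug: str
    m: float
    dm: float
    r2: float
    n_points: int

    def fa(self, dose: float) -> float:
        """Predicted fraction affected at a dose."""
        return dose**self.m / (dose**self.m + self.dm**self.m)

    def dx(self, fa: float) -> float:
        """Dose required for a given fraction affected."""
        if not (0.0 < fa < 1.0):
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def median_effect_fit(
    doses: Sequence[float], fa: Sequence[float], drug: str = ""
) -> MedianEffectFit:
    """Fit (m, Dm) by the log-linear median-effect plot.

    Regresses log10(fa/(1-fa)) on log10(D); m is the slope and
    Dm = 10^(-intercept/m). Points with fa at exactly 0 or 1 carry no
    information on the log-odds scale and are excluded with a warning.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if d.shape != f.shape or d.ndim != 1:
        raise ValueError("doses and fa must be equal-length vectors")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    valid = (f > 0.0) & (f < 1.0)
    if (~valid).any():
        warnings.warn(
            f"excluding {int((~valid).sum())} point(s) with fa at 0 or 1",
            stacklevel=2,
        )
    if valid.sum() < 3:
        raise ValueError("need >= 3 dose points with fa strictly in (0, 1)")
    x = np.log10(d[valid])
    y = np.log10(f[valid] / (1.0 - f[valid]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError(f"non-positive median-effect slope ({m:.3g})")
    dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        drug=drug, m=m, dm=dm, r2=float(res.rvalue**2), n_points=int(valid.sum())
    )


def combination_index(
    d1: float, d2: float, fa: float, fit1: MedianEffectFit, fit2: MedianEffectFit
) -> float:
    """CI = d1/Dx1(fa) + d2/Dx2(fa) at the observed fraction affected."""
    if not (0.0 < fa < 1.0):
        raise ValueError("fa must lie strictly in (0, 1)")
    return d1 / fit1.dx(fa) + d2 / fit2.dx(fa)


def ci_label(ci: float, tol: float = 0.05) -> str:
    if ci < 1.0 - tol:
        return "synergy"
    if ci > 1.0 + tol:
        return "antagonism"
    return "additivity"


def combination_table(
    combos: pd.DataFrame, fits: dict[str, MedianEffectFit]
) -> pd.DataFrame:
    """Per-point CI for a combination table (drug1, dose1, drug2, dose2, fa)."""
    rows = []
    for rec in combos.itertuples():
        fit1, fit2 = fits[rec.drug1], fits[rec.drug2]
        ci = combination_index(rec.dose1, rec.dose2, rec.fa, fit1, fit2)
        rows.append(
            {
                "drug1": rec.drug1, "dose1": rec.dose1,
                "drug2": rec.drug2, "dose2": rec.dose2,
                "fa": rec.fa, "ci": ci, "call": ci_label(ci),
            }
        )
    return pd.DataFrame(rows)


class MedianEffectModel:
    """Median-effect dose-response model, Model/Results style.

    Parameters
    ----------
    data : DataFrame with columns (drug, dose, fa)
        Single-agent viability data, one row per dose point.
    """

    def __init__(self, data: pd.DataFrame):
        for col in ("drug", "dose", "fa"):
            if col not in data.columns:
                raise ValueError(f"dose table missing column {col!r}")
        self.data = data

    def fit(self) -> "MedianEffectResults":
        fits = {
            drug: median_effect_fit(sub["dose"], sub["fa"], drug=drug)
            for drug, sub in self.data.groupby("drug", sort=True)
        }
        return MedianEffectResults(model=self, fits=fits)


@dataclass
class MedianEffectResults:
    model: MedianEffectModel
    fits: dict[str, MedianEffectFit]

    def combination_indices(self, combos: pd.DataFrame) -> pd.DataFrame:
        return combination_table(combos, self.fits)

    def summary(self) -> str:
        lines = ["Median-effect fits (fa/fu = (D/Dm)^m)"]
        for drug, fit in self.fits.items():
            lines.append(
                f"  {drug}: m = {fit.m:.4f}, Dm = {fit.dm:.4g}, "
                f"r2 = {fit.r2:.4f} ({fit.n_points} points)"
            )
        return "\n".join(lines)
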