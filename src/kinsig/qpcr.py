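"""qPCR relative expression and stage-group comparisons.

Relative expression follows the single-delta doubling-efficiency model,
2^(Ct_ref - Ct_target), against a housekeeping reference gene (ABL1 by
default; no calibrator sample is involved, so the delta-delta-Ct form is
not used). Stage contrasts compare relative-expression means between
clinical CLL strata with Welch's two-sample t-test: Rai 0 vs III-IV and
I-II vs III-IV, and Binet A vs B+C.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "welch_t_test",
    "stage_comparison",
    "RAI_CONTRASTS",
    "BINET_CONTRASTS",
]

RAI_CONTRASTS = [("0", "III-IV"), ("I-II", "III-IV")]
BINET_CONTRASTS = [("A", "B+C")]


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^(Ct_ref - Ct_target): expression of the target relative to the
    reference gene under 100% amplification efficiency."""
    ct_target = float(ct_target)
    ct_reference = float(ct_reference)
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("non-finite Ct value")
    return 2.0 ** (ct_reference - ct_target)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _per_sample_expression(
    records: pd.DataFrame, target: str, reference: str
) -> pd.DataFrame:
    for col in ("sample_id", "gene", "ct"):
        if col not in records.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if ((records["ct"] <= 0) | (records["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")
    wide = records.pivot_table(index="sample_id", columns="gene", values="ct")
    for g in (target, reference):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"gene {g!r} missing for some samples")
    meta = records.drop_duplicates("sample_id").set_index("sample_id")
    out = pd.DataFrame(
        {
            "rel_expr": 2.0 ** (wide[reference] - wide[target]),
        }
    )
    for col in ("rai", "binet"):
        if col in meta.columns:
            out[col] = meta[col]
    return out.reset_index()


def stage_comparison(
    records: pd.DataFrame,
    staging: str = "rai",
    target: str = "DNPEP",
    reference: str = "ABL1",
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Welch tests of relative expression between clinical stage groups.

    Rai contrasts: 0 vs III-IV and I-II vs III-IV; Binet: A vs B+C.
    Returns one row per contrast with group means, sizes, t, df and p.
    Relative expression is compared untransformed by default
    (`log2_transform` switches to the log scale).
    """
    if staging not in ("rai", "binet"):
        raise ValueError("staging must be 'rai' or 'binet'")
    expr = _per_sample_expression(records, target, reference)
    if staging not in expr.columns:
        raise ValueError(f"Ct table has no {staging!r} stage column")
    values = expr["rel_expr"].to_numpy()
    if log2_transform:
        values = np.log2(values)
    stages = expr[staging].astype(str)

    def group(label: str) -> np.ndarray:
        if label == "B+C":
            mask = stages.isin(["B", "C"])
        else:
            mask = stages == label
        return values[mask.to_numpy()]

    contrasts = RAI_CONTRASTS if staging == "rai" else BINET_CONTRASTS
    rows = []
    for g1, g2 in contrasts:
        a, b = group(g1), group(g2)
        if len(a) == 0 or len(b) == 0:
            empty = [g for g, v in ((g1, a), (g2, b)) if len(v) == 0]
            raise ValueError(f"empty stage stratum/strata: {empty}")
        t, df, p = welch_t_test(a, b)
        rows.append(
            {
                "staging": staging,
                "contrast": f"{g1} vs {g2}",
                "mean_1": float(np.mean(a)),
                "mean_2": float(np.mean(b)),
                "n_1": len(a),
                "n_2": len(b),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
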