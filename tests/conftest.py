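import numpy as np
import pandas as pd
import pytest

from kinsig.survival import SurvivalCohort


def make_cohort(
    rng: np.random.Generator,
    n: int,
    betas_ttt: dict[str, float],
    betas_os: dict[str, float] | None = None,
    extra_genes: list[str] | None = None,
    h0_ttt: float = 1 / 40,
    h0_os: float = 1 / 120,
    censor_ttt: float = 120.0,
    censor_os: float = 150.0,
) -> SurvivalCohort:
    """Minimal proportional-hazards cohort for op-level simulations."""
    betas_os = betas_os if betas_os is not None else {}
    genes = sorted(set(betas_ttt) | set(betas_os) | set(extra_genes or []))
    X = pd.DataFrame(rng.standard_normal((n, len(genes))), columns=genes)
    frame = {"sample_id": [f"S{i}" for i in range(n)]}
    for ep, betas, h0, window in (
        ("ttt", betas_ttt, h0_ttt, censor_ttt),
        ("os", betas_os, h0_os, censor_os),
    ):
        lp = np.zeros(n)
        for g, b in betas.items():
            lp += b * X[g].to_numpy()
        t_event = rng.exponential(1.0, size=n) / (h0 * np.exp(lp))
        c = rng.uniform(0, window, size=n)
        frame[f"{ep}_months"] = np.minimum(t_event, c)
        frame[f"{ep}_event"] = (t_event <= c).astype(int)
    df = pd.DataFrame(frame)
    df["ighv"] = "mutated"
    df["del17p"] = 0
    return SurvivalCohort(pd.concat([df, X], axis=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
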