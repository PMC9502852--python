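import numpy as np
import pandas as pd
import pytest

from micromr import CohortConfig, InstrumentConfig, simulate_two_sample
from micromr.assoc_screen import outcome_summary_stats
from micromr.instruments import harmonize_all


@pytest.fixture
def three_insts() -> pd.DataFrame:
    """Tiny hand-checkable instrument set."""
    return pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3"],
            "beta_x": [0.2, 0.3, 0.5],
            "se_x": [0.01, 0.01, 0.01],
            "beta_y": [0.4, 0.9, 1.0],
            "se_y": [0.1, 0.1, 0.2],
        }
    )


def make_two_sample(theta: float, seed: int, **inst_kw):
    """Simulate, estimate outcome associations, and harmonize."""
    cfg = InstrumentConfig(theta_true=theta, **inst_kw)
    exposure, cohort, truth = simulate_two_sample(cfg, CohortConfig(), seed=seed)
    outcome = outcome_summary_stats(cohort)
    insts, _ = harmonize_all(exposure, outcome)
    return insts, truth, cohort


@pytest.fixture(scope="session")
def harmonized_nine():
    """Nine harmonized instruments with a known causal effect of -25."""
    cfg = InstrumentConfig(theta_true=-25.0)
    exposure, cohort, truth = simulate_two_sample(cfg, CohortConfig(), seed=20240917)
    outcome = outcome_summary_stats(cohort)
    insts, _ = harmonize_all(exposure, outcome)
    assert len(insts) == 9
    return insts, truth


def seeds_from(base: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(base).spawn(n)]
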