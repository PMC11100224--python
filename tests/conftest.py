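import math

import pandas as pd
import pytest

from poemediate import (
    SimulationParams,
    compute_cc_weights,
    sample_case_control,
    simulate_population,
)

# Outcome coefficients with theta2 = ln(2)/0.46 exactly, so the true
# maternal PNIE odds ratio is exactly 2.0 given beta1m = 0.46.
EFFECT_THETA = (None, 1.96, 1.21, math.log(2) / 0.46, -2.2, 0.0, 1.0)
NULL_BETA = (0.0, 0.0, 0.0, 0.0)
NULL_THETA = (None, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def effect_params() -> SimulationParams:
    return SimulationParams(n_population=12_000, theta_true=EFFECT_THETA, seed=11)


@pytest.fixture(scope="session")
def null_params() -> SimulationParams:
    return SimulationParams(
        n_population=12_000, beta_true=NULL_BETA, theta_true=NULL_THETA, seed=12
    )


def latent_summaries(subjects: pd.DataFrame) -> pd.DataFrame:
    """Use the ground-truth subject latent methylation as the mediator summary."""
    return subjects[["subject_id", "latent_m"]].rename(
        columns={"latent_m": "summary_m"}
    ).assign(cpg_id="cg_latent", n_visits=1)


@pytest.fixture(scope="session")
def cc_sample(effect_params):
    """A 500/500 nested case-control sample with latent-mean summaries."""
    pop = simulate_population(effect_params)
    sample = sample_case_control(pop, 500, 500, match_vars=(), seed=21)
    return {
        "sample": sample,
        "summaries": latent_summaries(sample.subjects),
        "weights": compute_cc_weights(effect_params.incidence_pi, 0.5),
    }
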