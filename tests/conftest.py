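import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def k4_design():
    from sfsc.oacd import preset_design

    return preset_design(4)


@pytest.fixture()
def two_drug_unit_landscape():
    """Two drugs with emax=1, h=1, ec50=1 and no interaction or noise."""
    from sfsc.synthetic_data import TrueLandscape

    return TrueLandscape(
        drugs=("D01", "D02"),
        emax=np.ones(2),
        hill=np.ones(2),
        ec50=np.ones(2),
        gamma=np.zeros((2, 2)),
        hormesis=np.zeros(2),
        noise_sd=0.0,
        seed=0,
    )


def noise_response(design, sd, seed, replicates=3, mean=1.0):
    """Stacked pure-noise response table over a design."""
    from sfsc.synthetic_data import RUN_ID, VIABILITY

    rng = np.random.default_rng(seed)
    rid = np.tile(np.arange(design.n_runs), replicates)
    return pd.DataFrame(
        {RUN_ID: rid, VIABILITY: mean + rng.normal(0.0, sd, len(rid))}
    )


def polynomial_response(design, coef, sd=0.0, seed=0, replicates=3):
    """Response generated exactly from a quadratic polynomial on coded levels."""
    from sfsc.oacd import model_matrix, quadratic_terms
    from sfsc.synthetic_data import RUN_ID, VIABILITY

    terms = quadratic_terms(design.factors)
    beta = np.array([coef.get(t, 0.0) for t in terms])
    clean = model_matrix(design.coded, terms).to_numpy() @ beta
    rng = np.random.default_rng(seed)
    rid = np.tile(np.arange(design.n_runs), replicates)
    y = clean[rid] + (rng.normal(0.0, sd, len(rid)) if sd > 0 else 0.0)
    return pd.DataFrame({RUN_ID: rid, VIABILITY: y})
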