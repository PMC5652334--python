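import numpy as np
import pytest
from hypothesis import settings

import receptorcall as rc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def er_model():
    """Published ER ExMax parameter set as a model."""
    return rc.preset("ER", "ExMax").model


@pytest.fixture(scope="session")
def exmax_models():
    """Published ExMax parameter sets for all three receptors."""
    return {rec: rc.preset(rec, "ExMax").model for rec in ("ER", "PGR", "HER2")}


@pytest.fixture(scope="session")
def er_cohort():
    """One seeded cohort drawn from the ER ExMax regime at the crisp-IHC size."""
    cfg = rc.with_options(rc.preset("ER", "ExMax"), n_samples=2269, seed=20_001)
    return rc.simulate_cohort(cfg)


def make_expr(values, probe_id="test_at"):
    values = np.asarray(values, dtype=float)
    return rc.ExpressionVector(
        sample_ids=[f"s{i}" for i in range(len(values))], values=values, probe_id=probe_id
    )


def make_labels(neg, pos, missing=0):
    return (
        [rc.IHCStatus.NEGATIVE] * neg
        + [rc.IHCStatus.POSITIVE] * pos
        + [rc.IHCStatus.MISSING] * missing
    )
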