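import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tgsmdr import GenotypeRecord, load_published_frequencies

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published_table():
    return load_published_frequencies()


def make_record(sample_id="S1", group="athlete", **calls):
    """Record with full 'perfect literature profile' defaults, overridable."""
    base = {
        "ANKK1": "GG",
        "APOE_rs429358": "TT",
        "APOE_rs7412": "CC",
        "APOE_rs405509": "GG",
        "BDNF_AS": "CC",
        "COMT": "AA",
        "MAPT": "CC",
        "NOS3": "TT",
    }
    base.update(calls)
    from tgsmdr.panel import panel_by_name

    by_name = panel_by_name()
    canonical = {
        k: by_name[k].canonical_genotype(v) if v is not None else None
        for k, v in base.items()
    }
    return GenotypeRecord(sample_id, group, canonical)


@pytest.fixture
def perfect_record():
    return make_record()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
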