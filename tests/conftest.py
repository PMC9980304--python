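import numpy as np
import pytest

from evmap.fcs_io import AcquisitionMeta, ChannelSchema, EventTable, qc_filter
from evmap.synthetic import CohortSpec, default_populations, simulate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schema():
    return ChannelSchema(
        names=("LALS", "PSMA", "Ghrelin"),
        roles={"scatter": "LALS", "marker1": "PSMA", "marker2": "Ghrelin"},
    )


@pytest.fixture
def meta():
    return AcquisitionMeta(
        flow_rate_ul_min=3.01,
        duration_s=120.0,
        dilution_factor=100.0,
        patient_id="PX",
    )


def make_table(rng, schema, meta, n=1000):
    return EventTable(
        intensities=rng.uniform(1.0, 1e4, size=(n, 3)), schema=schema, meta=meta
    )


def fast_cohort_spec(n_per_class=6, seed=0, multiplier=3.0, **kw):
    """Small, QC-passing cohort for unit tests: 6000 events over 10 s."""
    return CohortSpec(
        n_per_class=(n_per_class, n_per_class),
        populations=tuple(default_populations(planted_multiplier=multiplier)),
        events_per_replicate=6000,
        duration_s=10.0,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_planted_cohort():
    """Session-shared small planted cohort: (SampleSet after QC, clinical, y)."""
    samples, clinical, y = simulate_samples(fast_cohort_spec(n_per_class=6, seed=42))
    return qc_filter(samples), clinical, y
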