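import numpy as np
import pytest

from airway_turnover.core_data import SubjectSeries, TaxonCountTable
from airway_turnover.synthetic_cohort import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def small_table() -> TaxonCountTable:
    return TaxonCountTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["A", "B"],
        counts=np.array([[30, 70], [5, 0], [1, 3]]),
    )


@pytest.fixture
def tiny_cohort():
    """A quickly generated cohort: 8 subjects per group, default structure."""
    cfg = SyntheticCohortConfig(
        seed=7, n_subjects_per_group={"mild": 8, "moderate": 8, "severe": 8}
    )
    table, meta, truth = generate_cohort(cfg)
    return cfg, table, meta, truth


def make_series(counts, days=None, group="g", subject="s", taxa=None) -> SubjectSeries:
    counts = np.asarray(counts)
    if days is None:
        days = np.arange(1, counts.shape[0] + 1)
    if taxa is None:
        taxa = [f"t{k}" for k in range(counts.shape[1])]
    return SubjectSeries(subject, group, np.asarray(days), counts, list(taxa))
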