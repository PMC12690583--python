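import pandas as pd
import pytest

from cpidebias import SynthConfig
from cpidebias.synthetic_data import generate_activity_table, generate_compounds


def make_interactions(rows):
    """Build an interaction table from (compound, target, label[, extras]) tuples."""
    records = []
    for row in rows:
        rec = {
            "compound_id": row[0],
            "target_id": row[1],
            "label": row[2],
            "provenance": "measured",
            "year": 2010,
            "family": "Kinase",
            "cluster_id": 0,
        }
        rec.update(row[3] if len(row) > 3 else {})
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        seed=11,
        n_targets=30,
        n_compounds=600,
        n_clusters=4,
        fingerprint_len=96,
        records_per_target=(15, 40),
        year_range=(2005, 2020),
    )


@pytest.fixture(scope="session")
def small_compounds(small_config):
    return generate_compounds(small_config)


@pytest.fixture(scope="session")
def small_activity(small_config, small_compounds):
    return generate_activity_table(small_config, small_compounds)
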