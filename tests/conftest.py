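import networkx as nx
import pytest

from cadnet.records import Cohort, MedicalRecord
from cadnet.simulate import generate_cohort, reference_cohort_config


def make_record(rid, sex="male", dia=(), com=(), age=60, year=2015):
    return MedicalRecord(
        record_id=rid, sex=sex, age=age, admission_year=year,
        diagnoses=dia, comorbidities=com,
    )


@pytest.fixture
def toy_cohort():
    """Three records with hand-enumerable co-occurrence counts:
    r1 {A,B}, r2 {A,B}, r3 {A,C} (diagnoses); comorbidities X,Y in r1, X in r2."""
    return Cohort([
        make_record("r1", "male", dia=["A", "B"], com=["X", "Y"]),
        make_record("r2", "male", dia=["A", "B"], com=["X"]),
        make_record("r3", "female", dia=["A", "C"], com=[]),
    ])


@pytest.fixture
def bridge_graph():
    """Two unit-weight triangles joined by one edge; optimal Q = 5/14."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")],
        weight=1,
    )
    return g


@pytest.fixture(scope="session")
def reference_config():
    return reference_cohort_config(seed=11)


@pytest.fixture(scope="session")
def reference_cohort_small(reference_config):
    """195-record synthetic cohort drawn from the calibrated config."""
    return generate_cohort(reference_config)


@pytest.fixture(scope="session")
def reference_cohort_1k():
    from dataclasses import replace

    cfg = replace(reference_cohort_config(seed=7), n_patients=1000)
    return generate_cohort(cfg)
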