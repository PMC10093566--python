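import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petln.cohort import (
    CohortTable,
    NodeRecord,
    PatientRecord,
    ReferenceUptake,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_patient(pid="P1", primary=9.0, liver=3.1, brainstem=7.2, lung=0.45, **kw):
    defaults = dict(
        age_years=68, sex="m", glucose_mmol_per_l=5.5, uptake_time_min=56.0,
        injected_activity_mbq=236.0, body_weight_kg=78.0, histology_subtype="AC",
    )
    defaults.update(kw)
    return PatientRecord(
        patient_id=pid,
        reference=ReferenceUptake(primary, liver, brainstem, lung),
        **defaults,
    )


def make_node(pid="P1", nid="N1", suvmax=6.3, histology="malignant", **kw):
    defaults = dict(station=7, short_axis_mm=12.0,
                    suvmean=suvmax * 0.7, suvpeak=suvmax * 0.9)
    defaults.update(kw)
    return NodeRecord(patient_id=pid, node_id=nid, suvmax=suvmax,
                      histology=histology, **defaults)


@pytest.fixture
def demo_cohort():
    """10 nodes over 4 patients with hand-checkable features."""
    patients = [
        make_patient("P1", primary=9.0, liver=3.0, brainstem=7.0, lung=0.5),
        make_patient("P2", primary=12.0, liver=2.5, brainstem=6.0, lung=0.8, sex="f"),
        make_patient("P3", primary=7.5, liver=3.5, brainstem=8.0, lung=0.6,
                     histology_subtype="SCC"),
        make_patient("P4", primary=10.0, liver=2.8, brainstem=6.5, lung=0.4),
    ]
    nodes = [
        make_node("P1", "P1-N1", suvmax=11.0, histology="malignant"),
        make_node("P1", "P1-N2", suvmax=2.8, histology="benign", station=4),
        make_node("P1", "P1-N3", suvmax=3.6, histology="benign", station=10),
        make_node("P2", "P2-N1", suvmax=14.5, histology="malignant", station=2),
        make_node("P2", "P2-N2", suvmax=4.1, histology="benign", station=11),
        make_node("P3", "P3-N1", suvmax=8.2, histology="malignant", station=5),
        make_node("P3", "P3-N2", suvmax=2.2, histology="benign", station=12),
        make_node("P4", "P4-N1", suvmax=3.3, histology="benign", station=6),
        make_node("P4", "P4-N2", suvmax=9.7, histology="malignant"),
        make_node("P4", "P4-N3", suvmax=5.0, histology="benign", station=4),
    ]
    return CohortTable(patients=patients, nodes=nodes)


@pytest.fixture
def rng():
    return np.random.default_rng(20230327)
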