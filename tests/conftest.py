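import datetime as dt

import pytest

from pvsignal.contingency import DrugSet
from pvsignal.report_io import CaseReport, EventDefinition, StudyWindow
from pvsignal.synthetic import AML_PT, AML_PT_CODE, MDS_PT, MDS_PT_CODE, default_config, generate

PARP_DRUGS = ("olaparib", "niraparib", "rucaparib", "talazoparib")


def make_report(report_id="R1", drug="olaparib", events=(("Nausea", None),), **kw):
    """CaseReport factory with innocuous defaults."""
    defaults = dict(
        report_id=report_id,
        primary_suspect_drug=drug,
        event_pts=frozenset(events),
        receipt_date=dt.date(2018, 6, 1),
    )
    defaults.update(kw)
    return CaseReport(**defaults)


@pytest.fixture
def mds_event():
    return EventDefinition("MDS", pt_codes=frozenset([MDS_PT_CODE]),
                           pt_names=frozenset([MDS_PT]))


@pytest.fixture
def aml_event():
    return EventDefinition("AML", pt_codes=frozenset([AML_PT_CODE]),
                           pt_names=frozenset([AML_PT]))


@pytest.fixture
def parp_drug_sets():
    singles = [DrugSet.of(d, d) for d in PARP_DRUGS]
    return [DrugSet.of("PARP class", *PARP_DRUGS)] + singles


@pytest.fixture
def study_window():
    return StudyWindow(dt.date(2014, 10, 1), dt.date(2021, 9, 30))


@pytest.fixture(scope="session")
def small_db():
    """A 2,000-report synthetic database shared by read-only tests."""
    return generate(default_config(seed=11, n_reports=2000))
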