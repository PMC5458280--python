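import math

import pytest

from pvsignal.contingency import StratumTable
from pvsignal.disproportionality import EffectEstimate
from pvsignal.reports import CohortSpec, SafetyReport


def make_report(rid, year=2010, drugs=(), indications=("NON-SMALL CELL LUNG CANCER",),
                reactions=()):
    return SafetyReport(
        report_id=rid, year=year, drugs=frozenset(drugs),
        indications=frozenset(indications), reactions=frozenset(reactions),
    )


def make_estimate(stratum, y, v, level=0.95):
    """EffectEstimate straight from (y, v), bypassing a table."""
    z = 1.959963984540054 if level == 0.95 else None
    assert z is not None
    half = z * math.sqrt(v)
    return EffectEstimate(
        stratum=str(stratum), y=y, v=v, ror=math.exp(y),
        ci_low=math.exp(y - half), ci_high=math.exp(y + half), level=level,
    )


@pytest.fixture
def nsclc_spec():
    return CohortSpec(
        indication_term="NON-SMALL CELL LUNG CANCER",
        drug_term="CARBOPLATIN",
        event_term="ANAEMIA",
        years=tuple(range(2004, 2016)),
    )


@pytest.fixture
def toy_cohort():
    """Six 2010 reports: 2 exposed-with-event, 1 exposed-without,
    1 unexposed-with, 2 unexposed-without."""
    mk = lambda rid, exposed, event: make_report(  # noqa: E731
        rid,
        drugs=("CARBOPLATIN", "PACLITAXEL") if exposed else ("PACLITAXEL",),
        reactions=("ANAEMIA", "NAUSEA") if event else ("NAUSEA",),
    )
    return [mk("r1", 1, 1), mk("r2", 1, 1), mk("r3", 1, 0),
            mk("r4", 0, 1), mk("r5", 0, 0), mk("r6", 0, 0)]


@pytest.fixture
def table_2112():
    return StratumTable(stratum="2010", a=2, b=1, c=1, d=2)
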