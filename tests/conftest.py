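"""Shared fixtures: independent oracles and a hand-built 10-subject cohort."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycovar.config import SimConfig
from glycovar.synthdata import RawTables, simulate_cohort


# ---------------------------------------------------------------------------
# independent oracles (deliberately written from the closed forms, not by
# importing the package implementations)
# ---------------------------------------------------------------------------


def oracle_egfr(scr: float, age: float, female: bool) -> float:
    """Literal CKD-EPI 2009 evaluation, race coefficient 1."""
    kappa = 0.7 if female else 0.9
    alpha = -0.329 if female else -0.411
    r = scr / kappa
    val = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age
    return val * 1.018 if female else val


def oracle_ols_slope(t, y) -> float:
    """Closed-form OLS slope sum((t-tbar)(y-ybar)) / sum((t-tbar)^2)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tb, yb = t.mean(), y.mean()
    return float(((t - tb) * (y - yb)).sum() / ((t - tb) ** 2).sum())


@pytest.fixture(scope="session")
def oracle_egfr_fn():
    return oracle_egfr


# ---------------------------------------------------------------------------
# hand-built 10-subject fixture with known eligibility outcomes
# ---------------------------------------------------------------------------

D0 = pd.Timestamp("2015-01-06")  # index day 0 for every fixture subject
ADULT_BIRTH = pd.Timestamp("1960-01-01")  # age ~55.0 at D0
CHILD_BIRTH = pd.Timestamp("2000-06-01")  # age ~14.6 at D0


def _d(day: int) -> pd.Timestamp:
    return D0 + pd.Timedelta(days=day)


#: expected eligibility outcome per fixture subject (worked by hand)
FIXTURE_EXPECTED = {
    "S01": "included",  # HVS 50 -> category 3, rapid decliner
    "S02": "min_visits",  # only 4 visits
    "S03": "min_span",  # 5 visits over 328 days (0.90 y)
    "S04": "min_scr",  # only 2 creatinine measures
    "S05": "low_baseline_egfr",  # Scr 5.0 mg/dL -> eGFR ~12 < 15
    "S06": "no_index",  # no HbA1c at all
    "S07": "no_baseline_egfr",  # creatinine only on days 400/450/500
    "S08": "underage",  # age ~14.6 at index
    "S09": "included",  # constant HbA1c -> HVS 0, category 1
    "S10": "included",  # every change >= 0.5 -> HVS 100, category 5
}

#: hand-computed HVS / category / rapid status of the included subjects
FIXTURE_INCLUDED = {
    "S01": {"hvs": 50.0, "category": 3, "rapid": True},
    "S09": {"hvs": 0.0, "category": 1, "rapid": False},
    "S10": {"hvs": 100.0, "category": 5, "rapid": True},
}

#: raw series of the included subjects, for slope oracle checks (all male)
FIXTURE_SCR = {
    "S01": ([0, 200, 400], [1.0, 1.1, 1.2]),
    "S09": ([0, 180, 450], [0.9, 0.9, 0.9]),
    "S10": ([0, 200, 400], [1.0, 1.3, 1.6]),
}


def build_fixture_tables() -> RawTables:
    subjects, visits, labs, meds, dx = [], [], [], [], []

    def add(sid, birth, visit_days, hba1c, scr, med=None, code=None):
        subjects.append((sid, "M", birth))
        for d in visit_days:
            visits.append((sid, _d(d)))
        for d, v in hba1c:
            labs.append((sid, _d(d), "HBA1C", v, "%"))
        for d, v in scr:
            labs.append((sid, _d(d), "SCR", v, "mg/dL"))
        if med:
            meds.append((sid, _d(med[0]), med[1]))
        if code:
            dx.append((sid, _d(code[0]), code[1]))

    five = [0, 100, 200, 300, 400]
    add(
        "S01", ADULT_BIRTH, five,
        hba1c=list(zip(five, [7.0, 7.6, 7.5, 8.2, 8.1])),
        scr=list(zip(*FIXTURE_SCR["S01"])),
        med=(100, "INSULIN"), code=(0, "I10"),
    )
    add(
        "S02", ADULT_BIRTH, [0, 100, 200, 300],
        hba1c=[(0, 7.0), (300, 7.2)], scr=[(0, 1.0), (100, 1.0), (200, 1.0)],
    )
    add(
        "S03", ADULT_BIRTH, [0, 80, 160, 240, 328],
        hba1c=[(0, 7.0)], scr=[(0, 1.0), (160, 1.0), (328, 1.0)],
    )
    add(
        "S04", ADULT_BIRTH, five,
        hba1c=[(0, 7.0), (400, 7.0)], scr=[(0, 1.0), (200, 1.0)],
    )
    add(
        "S05", ADULT_BIRTH, five,
        hba1c=[(0, 7.0), (400, 7.0)],
        scr=[(0, 5.0), (200, 5.0), (400, 5.0)],
    )
    add(
        "S06", ADULT_BIRTH, five,
        hba1c=[], scr=[(0, 1.0), (200, 1.0), (400, 1.0)],
    )
    add(
        "S07", ADULT_BIRTH, [0, 100, 200, 300, 400, 500],
        hba1c=[(0, 7.0), (500, 7.4)],
        scr=[(400, 1.0), (450, 1.0), (500, 1.0)],
    )
    add(
        "S08", CHILD_BIRTH, five,
        hba1c=list(zip(five, [7.0, 7.6, 7.5, 8.2, 8.1])),
        scr=[(0, 1.0), (200, 1.0), (400, 1.0)],
    )
    add(
        "S09", ADULT_BIRTH, [0, 90, 180, 270, 365, 450],
        hba1c=[(d, 7.0) for d in [0, 90, 180, 270, 450]],
        scr=list(zip(*FIXTURE_SCR["S09"])),
        med=(90, "STATIN"),
    )
    add(
        "S10", ADULT_BIRTH, five,
        hba1c=list(zip(five, [7.0, 7.6, 7.0, 7.8, 7.2])),
        scr=list(zip(*FIXTURE_SCR["S10"])),
        code=(0, "I25.1"),
    )

    return RawTables(
        subjects=pd.DataFrame(subjects, columns=["subject_id", "sex", "birth_date"]),
        visits=pd.DataFrame(visits, columns=["subject_id", "visit_date"]),
        labs=pd.DataFrame(labs, columns=["subject_id", "date", "analyte", "value", "unit"]),
        meds=pd.DataFrame(meds, columns=["subject_id", "date", "drug_class"]),
        diagnoses=pd.DataFrame(dx, columns=["subject_id", "date", "icd10_code"]),
    ).validate()


@pytest.fixture(scope="session")
def fixture_tables() -> RawTables:
    return build_fixture_tables()


@pytest.fixture(scope="session")
def small_sim_raw() -> RawTables:
    """A moderately sized simulated cohort shared across tests."""
    return simulate_cohort(SimConfig(n_subjects=800, seed=42))


@pytest.fixture(scope="session")
def small_sim_cohort(small_sim_raw):
    from glycovar.cohort import build_cohort

    cohort, long_egfr, log = build_cohort(small_sim_raw)
    return cohort, long_egfr, log
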