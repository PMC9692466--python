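"""Cohort construction: eligibility, analysis window, baseline capture.

The entry point is :func:`build_cohort`, which turns the raw tables into a
per-subject analysis table (one :class:`CohortRow` per included subject), a
long eGFR-measurement table for the mixed model, and an exclusion log in
which every excluded subject appears under exactly one reason.

Eligibility reasons are evaluated in a fixed priority order so the log is
deterministic:

``no_index`` -> ``underage`` -> ``min_visits`` -> ``min_span`` ->
``min_scr`` -> ``min_hba1c`` -> ``no_baseline_egfr`` -> ``low_baseline_egfr``
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CODE_PREFIXES, EligibilityConfig
from .errors import ConfigError, EligibilityError
from .measures import creatinine_to_mgdl, egfr_ckdepi, hvs_category, rapid_decline
from .synthdata import RawTables

__all__ = [
    "SubjectRecord",
    "build_cohort",
    "apply_eligibility",
    "index_and_end",
    "capture_baseline",
    "adherence",
    "flag_comorbidity",
    "EXCLUSION_ORDER",
]

DAYS_PER_YEAR = 365.25

EXCLUSION_ORDER = (
    "no_index",
    "underage",
    "min_visits",
    "min_span",
    "min_scr",
    "min_hba1c",
    "no_baseline_egfr",
    "low_baseline_egfr",
)


@dataclass
class SubjectRecord:
    """One person's raw longitudinal stream, for per-subject operations."""

    subject_id: str
    sex: str
    birth_date: pd.Timestamp
    visit_dates: pd.DatetimeIndex
    hba1c: pd.DataFrame  # date, value (%)
    scr: pd.DataFrame  # date, value (mg/dL)
    med_classes: Tuple[str, ...] = ()
    icd10_codes: Tuple[str, ...] = ()

    @classmethod
    def from_tables(cls, raw: RawTables, subject_id: str) -> "SubjectRecord":
        sub = raw.subjects.loc[raw.subjects["subject_id"] == subject_id]
        if sub.empty:
            raise EligibilityError(f"unknown subject {subject_id}")
        labs = _normalised_labs(raw.labs)
        labs = labs[labs["subject_id"] == subject_id]
        return cls(
            subject_id=subject_id,
            sex=str(sub["sex"].iloc[0]),
            birth_date=pd.Timestamp(sub["birth_date"].iloc[0]),
            visit_dates=pd.DatetimeIndex(
                raw.visits.loc[raw.visits["subject_id"] == subject_id, "visit_date"]
            ).sort_values(),
            hba1c=labs[labs["analyte"] == "HBA1C"][["date", "value"]].reset_index(drop=True),
            scr=labs[labs["analyte"] == "SCR"][["date", "value"]].reset_index(drop=True),
            med_classes=tuple(
                raw.meds.loc[raw.meds["subject_id"] == subject_id, "drug_class"].unique()
            ),
            icd10_codes=tuple(
                raw.diagnoses.loc[raw.diagnoses["subject_id"] == subject_id, "icd10_code"]
            ),
        )


def _normalised_labs(labs: pd.DataFrame) -> pd.DataFrame:
    """Unit-normalise creatinine to mg/dL and average same-day duplicates."""
    out = labs.copy()
    if "unit" in out.columns:
        scr = out["analyte"] == "SCR"
        umol = scr & out["unit"].str.strip().str.lower().str.replace("µ", "u").isin(
            ("umol/l", "umoll")
        )
        out.loc[umol, "value"] = creatinine_to_mgdl(out.loc[umol, "value"].to_numpy(), "umol/L")
    out = (
        out.groupby(["subject_id", "analyte", "date"], as_index=False)["value"]
        .mean()
        .sort_values(["subject_id", "analyte", "date"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def index_and_end(subject: SubjectRecord) -> Tuple[pd.Timestamp, pd.Timestamp]:
    """Index date = first HbA1c; end = last HbA1c-or-creatinine date."""
    if subject.hba1c.empty:
        raise EligibilityError(f"no index: subject {subject.subject_id} has no HbA1c")
    index = subject.hba1c["date"].min()
    end = subject.hba1c["date"].max()
    if not subject.scr.empty:
        end = max(end, subject.scr["date"].max())
    return pd.Timestamp(index), pd.Timestamp(end)


def capture_baseline(
    subject: SubjectRecord,
    index_date: pd.Timestamp,
    window_days: Tuple[int, int] = (-30, 365),
) -> Dict[str, Optional[float]]:
    """Nearest-to-index in-window baseline creatinine and HbA1c.

    Ties in absolute distance resolve to the earlier measurement.  Returns
    a dict with ``baseline_scr``, ``baseline_egfr``, ``baseline_hba1c``
    (None when nothing qualifies).
    """
    lo, hi = window_days
    out: Dict[str, Optional[float]] = {
        "baseline_scr": None,
        "baseline_egfr": None,
        "baseline_hba1c": None,
    }
    age_at_index = (index_date - subject.birth_date).days / DAYS_PER_YEAR

    def nearest(df: pd.DataFrame) -> Optional[Tuple[float, float]]:
        if df.empty:
            return None
        delta = (df["date"] - index_date).dt.days
        ok = (delta >= lo) & (delta <= hi)
        if not ok.any():
            return None
        cand = df.loc[ok].assign(_delta=delta[ok])
        cand = cand.assign(_absd=cand["_delta"].abs()).sort_values(
            ["_absd", "_delta"], kind="mergesort"
        )
        row = cand.iloc[0]
        return float(row["value"]), float(row["_delta"])

    got = nearest(subject.scr)
    if got is not None:
        scr, delta = got
        out["baseline_scr"] = scr
        out["baseline_egfr"] = egfr_ckdepi(
            scr, age_at_index + delta / DAYS_PER_YEAR, subject.sex
        )
    got = nearest(subject.hba1c)
    if got is not None:
        out["baseline_hba1c"] = got[0]
    return out


def adherence(
    subject: SubjectRecord, index_date: pd.Timestamp, end_date: pd.Timestamp
) -> float:
    """Outpatient visits per year over [index, end]."""
    follow_up = (end_date - index_date).days / DAYS_PER_YEAR
    if follow_up <= 0:
        raise EligibilityError("adherence undefined: zero follow-up")
    n = int(((subject.visit_dates >= index_date) & (subject.visit_dates <= end_date)).sum())
    return n / follow_up


def _norm_code(code: str) -> str:
    return str(code).upper().replace(".", "").strip()


def flag_comorbidity(
    icd10_codes: Sequence[str],
    code_prefixes: Mapping[str, Sequence[str]] = DEFAULT_CODE_PREFIXES,
) -> Tuple[bool, bool]:
    """(hypertension, ascvd) flags from configurable ICD-10 prefix lists.

    Matching is case-insensitive and ignores dots.
    """
    for key in ("hypertension", "ascvd"):
        if not code_prefixes.get(key):
            raise ConfigError(f"code prefix list {key!r} must be nonempty")
    codes = [_norm_code(c) for c in icd10_codes]

    def hit(prefixes: Sequence[str]) -> bool:
        normed = tuple(_norm_code(p) for p in prefixes)
        return any(c.startswith(normed) for c in codes)

    return hit(code_prefixes["hypertension"]), hit(code_prefixes["ascvd"])


def _first_reason(flags: Dict[str, pd.Series]) -> pd.Series:
    """Combine boolean exclusion columns into one reason per subject."""
    reason = pd.Series(pd.NA, index=next(iter(flags.values())).index, dtype=object)
    for name in EXCLUSION_ORDER:
        if name in flags:
            mask = flags[name].fillna(False).astype(bool) & reason.isna()
            reason[mask] = name
    return reason


def build_cohort(
    raw: RawTables,
    elig: Optional[EligibilityConfig] = None,
    code_prefixes: Mapping[str, Sequence[str]] = DEFAULT_CODE_PREFIXES,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, List[str]]]:
    """Construct the analysis cohort from raw tables.

    Returns ``(cohort, long_egfr, exclusion_log)`` where ``cohort`` has one
    row per included subject (see module docstring for derivations),
    ``long_egfr`` holds every in-window eGFR measurement as
    ``(subject_id, time_years, egfr)`` for included subjects, and
    ``exclusion_log`` maps each exclusion reason to the excluded ids.
    """
    cfg = (elig or EligibilityConfig()).validate()
    subs = raw.subjects.set_index("subject_id")
    labs = _normalised_labs(raw.labs)
    hb = labs[labs["analyte"] == "HBA1C"]
    scr = labs[labs["analyte"] == "SCR"]

    base = pd.DataFrame(index=subs.index)
    base["sex"] = subs["sex"]
    base["birth_date"] = pd.to_datetime(subs["birth_date"])

    # index / end dates
    base["index_date"] = hb.groupby("subject_id")["date"].min()
    last_hb = hb.groupby("subject_id")["date"].max()
    last_scr = scr.groupby("subject_id")["date"].max()
    base["last_hba1c_date"] = last_hb
    base["last_scr_date"] = last_scr
    base["end_date"] = pd.concat([last_hb, last_scr], axis=1).max(axis=1)
    base["age_at_index"] = (base["index_date"] - base["birth_date"]).dt.days / DAYS_PER_YEAR

    # visits within [index, end]
    v = raw.visits.merge(
        base[["index_date", "end_date"]], left_on="subject_id", right_index=True, how="inner"
    )
    v = v[(v["visit_date"] >= v["index_date"]) & (v["visit_date"] <= v["end_date"])]
    base["n_visits"] = v.groupby("subject_id")["visit_date"].count().reindex(base.index).fillna(0)
    base["span_years"] = (
        (v.groupby("subject_id")["visit_date"].max() - base["index_date"]).dt.days
        / DAYS_PER_YEAR
    )

    # in-study lab series (index..end), times in years since index
    def in_window(df: pd.DataFrame) -> pd.DataFrame:
        m = df.merge(
            base[["index_date", "end_date", "birth_date", "sex", "age_at_index"]],
            left_on="subject_id",
            right_index=True,
            how="inner",
        )
        m = m[(m["date"] >= m["index_date"]) & (m["date"] <= m["end_date"])].copy()
        m["t"] = (m["date"] - m["index_date"]).dt.days / DAYS_PER_YEAR
        return m.sort_values(["subject_id", "date"], kind="mergesort")

    hb_w = in_window(hb)
    scr_w = in_window(scr)
    base["n_hba1c"] = hb_w.groupby("subject_id")["value"].size().reindex(base.index).fillna(0)
    # creatinine measures counted from the baseline-window start to the end
    scr_cnt = scr.merge(
        base[["index_date", "end_date"]], left_on="subject_id", right_index=True, how="inner"
    )
    lo_days = pd.to_timedelta(cfg.baseline_window_days[0], unit="D")
    scr_cnt = scr_cnt[
        (scr_cnt["date"] >= scr_cnt["index_date"] + lo_days)
        & (scr_cnt["date"] <= scr_cnt["end_date"])
    ]
    base["n_scr"] = scr_cnt.groupby("subject_id")["value"].size().reindex(base.index).fillna(0)

    # baseline capture: nearest in-window measurement, ties -> earlier
    def baseline_pick(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
        m = df.merge(
            base[["index_date", "age_at_index", "sex"]],
            left_on="subject_id",
            right_index=True,
            how="inner",
        )
        delta = (m["date"] - m["index_date"]).dt.days
        m = m.assign(_delta=delta)
        m = m[(m["_delta"] >= cfg.baseline_window_days[0]) & (m["_delta"] <= cfg.baseline_window_days[1])]
        m = m.assign(_absd=m["_delta"].abs()).sort_values(
            ["subject_id", "_absd", "_delta"], kind="mergesort"
        )
        first = m.groupby("subject_id").first()
        return first.rename(columns={"value": value_col})

    b_scr = baseline_pick(scr, "baseline_scr")
    # underage subjects are excluded later; the adult CKD-EPI formula is
    # not evaluated for them (age at measurement floored at 18 otherwise)
    b_scr = b_scr[b_scr["age_at_index"] >= cfg.min_age] if len(b_scr) else b_scr
    if len(b_scr):
        b_scr["baseline_egfr"] = egfr_ckdepi(
            b_scr["baseline_scr"].to_numpy(),
            np.maximum(
                (b_scr["age_at_index"] + b_scr["_delta"] / DAYS_PER_YEAR).to_numpy(), 18.0
            ),
            b_scr["sex"].to_numpy(),
        )
        base["baseline_scr"] = b_scr["baseline_scr"]
        base["baseline_egfr"] = b_scr["baseline_egfr"]
    else:
        base["baseline_scr"] = np.nan
        base["baseline_egfr"] = np.nan
    b_hb = baseline_pick(hb, "baseline_hba1c")
    base["baseline_hba1c"] = b_hb["baseline_hba1c"] if len(b_hb) else np.nan

    # eligibility, one primary reason each, in fixed order
    flags = {
        "no_index": base["index_date"].isna(),
        "underage": base["age_at_index"] < cfg.min_age,
        "min_visits": base["n_visits"] < cfg.min_visits,
        "min_span": base["span_years"].fillna(0) < cfg.min_span_years,
        "min_scr": base["n_scr"] < cfg.min_creatinine_measures,
        "min_hba1c": base["n_hba1c"] < cfg.min_hba1c_measures,
        "no_baseline_egfr": base["baseline_egfr"].isna(),
        "low_baseline_egfr": base["baseline_egfr"] < cfg.min_baseline_egfr,
    }
    reason = _first_reason(flags)
    excluded = reason.dropna()
    log: Dict[str, List[str]] = {
        r: sorted(excluded.index[excluded == r]) for r in EXCLUSION_ORDER if (excluded == r).any()
    }
    keep = reason.isna()
    cohort = base.loc[keep].copy()

    # derived measures on included subjects (vectorised over successive
    # within-subject pairs; hb_k is sorted by subject then date)
    hb_k = hb_w[hb_w["subject_id"].isin(cohort.index)]
    sid_arr = hb_k["subject_id"].to_numpy()
    t_arr = hb_k["t"].to_numpy(dtype=float)
    v_arr = hb_k["value"].to_numpy(dtype=float)
    pair = sid_arr[:-1] == sid_arr[1:]
    pairs = pd.DataFrame(
        {
            "subject_id": sid_arr[:-1][pair],
            "jump": (np.abs(np.diff(v_arr)) >= 0.5 - 1e-9)[pair],
            "area": (0.5 * (v_arr[:-1] + v_arr[1:]) * np.diff(t_arr))[pair],
        }
    )
    agg = pairs.groupby("subject_id").agg(
        n_pairs=("jump", "size"), n_jumps=("jump", "sum"), area=("area", "sum")
    )
    cohort["hvs"] = 100.0 * agg["n_jumps"] / agg["n_pairs"]
    cohort["hvs_category"] = hvs_category(cohort["hvs"].to_numpy())
    g_t = hb_k.groupby("subject_id")["t"]
    span = g_t.max() - g_t.min()
    cohort["twa_hba1c"] = agg["area"] / span
    cohort["follow_up_years"] = (
        (cohort["end_date"] - cohort["index_date"]).dt.days / DAYS_PER_YEAR
    )
    cohort["adherence"] = cohort["n_visits"] / cohort["follow_up_years"]

    # eGFR long table and per-subject OLS slope (closed form, grouped)
    scr_k = scr_w[scr_w["subject_id"].isin(cohort.index)].copy()
    scr_k["egfr"] = egfr_ckdepi(
        scr_k["value"].to_numpy(),
        (scr_k["age_at_index"] + scr_k["t"]).to_numpy(),
        scr_k["sex"].to_numpy(),
    )
    long_egfr = scr_k[["subject_id", "t", "egfr"]].rename(columns={"t": "time_years"})
    long_egfr = long_egfr.reset_index(drop=True)
    g = scr_k.assign(
        t2=scr_k["t"] ** 2, ty=scr_k["t"] * scr_k["egfr"]
    ).groupby("subject_id")[["t", "t2", "ty", "egfr"]]
    s = g.sum()
    n_pts = scr_k.groupby("subject_id").size()
    denom = n_pts * s["t2"] - s["t"] ** 2
    cohort["mean_slope"] = (n_pts * s["ty"] - s["t"] * s["egfr"]) / denom
    cohort["rapid_decliner"] = rapid_decline(cohort["mean_slope"].to_numpy())

    # covariate flags
    cohort["female"] = (cohort["sex"] == "F").astype(int)
    cohort["baseline_egfr_lt60"] = (cohort["baseline_egfr"] < 60).astype(int)
    dx = raw.diagnoses.merge(
        base[["index_date"]], left_on="subject_id", right_index=True, how="inner"
    )
    dx = dx[
        dx["date"] <= dx["index_date"] + pd.to_timedelta(cfg.baseline_window_days[1], unit="D")
    ]
    dx["code"] = dx["icd10_code"].map(_norm_code)
    htn_pref = tuple(_norm_code(p) for p in code_prefixes["hypertension"])
    asc_pref = tuple(_norm_code(p) for p in code_prefixes["ascvd"])
    htn_ids = set(dx.loc[dx["code"].str.startswith(htn_pref), "subject_id"])
    asc_ids = set(dx.loc[dx["code"].str.startswith(asc_pref), "subject_id"])
    cohort["hypertension"] = cohort.index.isin(htn_ids).astype(int)
    cohort["ascvd"] = cohort.index.isin(asc_ids).astype(int)
    cohort["htn_or_ascvd"] = ((cohort["hypertension"] + cohort["ascvd"]) > 0).astype(int)

    meds = raw.meds.merge(
        base[["index_date", "end_date"]], left_on="subject_id", right_index=True, how="inner"
    )
    meds = meds[(meds["date"] >= meds["index_date"]) & (meds["date"] <= meds["end_date"])]
    for flag, classes in (
        ("ever_insulin", ("INSULIN",)),
        ("ever_statin", ("STATIN",)),
        ("ever_arb_acei", ("ARB_ACEI",)),
        ("ever_ccb", ("CCB",)),
        ("ever_sglt2_glp1", ("SGLT2I", "GLP1RA")),
    ):
        ids = set(meds.loc[meds["drug_class"].isin(classes), "subject_id"])
        cohort[flag] = cohort.index.isin(ids).astype(int)

    cohort["n_hba1c"] = cohort["n_hba1c"].astype(int)
    cohort["n_scr"] = cohort["n_scr"].astype(int)
    cohort["n_visits"] = cohort["n_visits"].astype(int)
    cohort = cohort.reset_index().rename(columns={"index": "subject_id"})
    long_egfr = long_egfr[long_egfr["subject_id"].isin(cohort["subject_id"])]
    return cohort, long_egfr.reset_index(drop=True), log


def apply_eligibility(
    raw: RawTables, cfg: Optional[EligibilityConfig] = None
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Included subject ids and the exclusion log (reason -> ids)."""
    cohort, _, log = build_cohort(raw, cfg)
    return sorted(cohort["subject_id"]), log
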