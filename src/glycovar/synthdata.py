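"""Synthetic longitudinal EMR tables with the structure the analysis assumes.

The generator emits the five raw tables (subjects, visits, labs, meds,
diagnoses) from a :class:`~glycovar.config.SimConfig`.  Each subject is
assigned a latent variability band; the HbA1c series is built so that the
probability of a successive change of >= 0.5% equals the band's jump
probability, and the creatinine series is induced from a subject-level true
eGFR slope by inverting the CKD-EPI equation at the attained age.  Binary
covariates carry band-dependent prevalences so downstream balancing is
exercised on genuinely confounded data.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import N_CATEGORIES, SimConfig, config_hash
from .errors import ConfigError
from .measures import creatinine_from_egfr, hvs, hvs_category

logger = logging.getLogger(__name__)

__all__ = [
    "RawTables",
    "simulate_hba1c_series",
    "simulate_creatinine_series",
    "simulate_cohort",
    "simulate_rapid_flags",
    "write_tables",
    "read_tables",
]

TABLE_NAMES = ("subjects", "visits", "labs", "meds", "diagnoses")

#: latent eGFR trajectories are floored here before CKD-EPI inversion
EGFR_FLOOR = 1.0

# jump-magnitude distribution: sub-threshold changes uniform on [0, 0.48),
# qualifying changes 0.51 + |half-normal(sigma)|.  The margins around the
# 0.5% threshold keep the jump/no-jump split intact when values are
# emitted rounded to 2 decimals.
_JUMP_SIGMA = 0.4
_SUB_THRESHOLD_HI = 0.48
_JUMP_BASE = 0.51

_MED_CLASSES = {
    "insulin": "INSULIN",
    "statin": "STATIN",
    "arb_acei": "ARB_ACEI",
    "ccb": "CCB",
    "sglt2_glp1": "SGLT2I",
}
_DX_CODES = {"hypertension": "I10", "ascvd": "I25.1"}


@dataclass
class RawTables:
    """The five raw EMR-style tables, dates as datetime64 columns."""

    subjects: pd.DataFrame  # subject_id, sex, birth_date
    visits: pd.DataFrame  # subject_id, visit_date
    labs: pd.DataFrame  # subject_id, date, analyte, value, unit
    meds: pd.DataFrame  # subject_id, date, drug_class
    diagnoses: pd.DataFrame  # subject_id, date, icd10_code

    def validate(self) -> "RawTables":
        ids = set(self.subjects["subject_id"])
        for name in ("visits", "labs", "meds", "diagnoses"):
            tab = getattr(self, name)
            if len(tab) and not set(tab["subject_id"]).issubset(ids):
                raise ConfigError(f"{name} references unknown subject ids")
        if len(self.labs) and not (self.labs["value"] > 0).all():
            raise ConfigError("labs values must be strictly positive")
        return self


def simulate_hba1c_series(
    level_mean: float,
    jump_prob: float,
    n_visits: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate an ordered HbA1c series (NGSP %) of length ``n_visits``.

    At each successive pair, with probability ``jump_prob`` the absolute
    change is drawn at/above the 0.5% threshold, otherwise strictly below
    it, so the expected variability score of the series is
    ``100 * jump_prob``.  The walk mean-reverts to ``level_mean`` (the step
    direction is biased toward the level, and forced toward it beyond a
    +-3% excursion, which also keeps values positive).
    """
    if n_visits < 2:
        raise ConfigError("n_visits must be >= 2 (HVS undefined otherwise)")
    if not 0.0 <= jump_prob <= 1.0:
        raise ConfigError("jump_prob must lie in [0, 1]")
    values = np.empty(n_visits)
    values[0] = level_mean + rng.normal(0.0, 0.3)
    jump = rng.random(n_visits - 1) < jump_prob
    mags = np.where(
        jump,
        _JUMP_BASE + np.abs(rng.normal(0.0, _JUMP_SIGMA, n_visits - 1)),
        rng.uniform(0.0, _SUB_THRESHOLD_HI, n_visits - 1),
    )
    toward_u = rng.random(n_visits - 1)
    tie_sign = rng.choice((-1.0, 1.0), n_visits - 1)
    for k in range(1, n_visits):
        dev = values[k - 1] - level_mean
        if dev == 0.0:
            sign = tie_sign[k - 1]
        elif abs(dev) > 3.0:
            sign = -np.sign(dev)
        else:
            p_toward = 0.5 + 0.4 * min(abs(dev) / 2.0, 1.0)
            sign = -np.sign(dev) if toward_u[k - 1] < p_toward else np.sign(dev)
        values[k] = values[k - 1] + sign * mags[k - 1]
    return values


def simulate_creatinine_series(
    baseline_egfr: float,
    true_slope: float,
    times: Sequence[float],
    noise_sd: float,
    age: float,
    sex: str,
    rng: np.random.Generator,
    subject_id: str = "?",
) -> np.ndarray:
    """Creatinine (mg/dL) at ``times`` (years) from a linear latent eGFR.

    latent eGFR(t) = baseline + slope*t + N(0, noise_sd), floored at
    :data:`EGFR_FLOOR`, then inverted through CKD-EPI at age ``age + t``.
    """
    t = np.asarray(times, dtype=float)
    if baseline_egfr <= 0:
        raise ConfigError("baseline_egfr must be > 0")
    if np.any(np.diff(t) < 0):
        raise ConfigError("times must be non-decreasing")
    latent = baseline_egfr + true_slope * t + (
        rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0
    )
    if np.any(latent < EGFR_FLOOR):
        logger.warning(
            "subject %s: eGFR trajectory floored at %.1f for %d measurement(s)",
            subject_id, EGFR_FLOOR, int(np.sum(latent < EGFR_FLOOR)),
        )
        latent = np.maximum(latent, EGFR_FLOOR)
    return creatinine_from_egfr(latent, age + t, np.repeat(sex, t.size))


def simulate_rapid_flags(
    categories: Sequence[int],
    p_reference: float,
    odds_ratio_by_category: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli rapid-decline indicators with planted category odds ratios.

    ``odds_ratio_by_category`` has 5 entries (the first must be 1.0); the
    log-odds of the outcome in category g is logit(p_reference) +
    log(OR_g).
    """
    ors = np.asarray(odds_ratio_by_category, dtype=float)
    if ors.shape != (5,) or abs(ors[0] - 1.0) > 1e-12 or np.any(ors <= 0):
        raise ConfigError("odds_ratio_by_category must be 5 positive values, first = 1")
    if not 0 < p_reference < 1:
        raise ConfigError("p_reference must lie in (0, 1)")
    cats = np.asarray(categories, dtype=int)
    logit = np.log(p_reference / (1 - p_reference)) + np.log(ors)[cats - 1]
    p = 1.0 / (1.0 + np.exp(-logit))
    return rng.random(cats.size) < p


def _visit_times(cfg: SimConfig, follow_up: float, rng: np.random.Generator) -> np.ndarray:
    if cfg.visit_process == "regular":
        times = np.arange(0.0, follow_up + 1e-9, 1.0 / cfg.visit_rate)
    else:
        n_max = int(follow_up * cfg.visit_rate * 4 + 20)
        gaps = rng.exponential(1.0 / cfg.visit_rate, n_max)
        times = np.concatenate(([0.0], np.cumsum(gaps)))
        times = times[times <= follow_up]
    return times


def simulate_cohort(config: SimConfig) -> RawTables:
    """Generate the five raw tables for a full synthetic cohort.

    Deterministic given ``config.seed``.  Each subject receives a latent
    variability band drawn from ``category_probs``; slopes are assigned by
    that latent band, or — when ``slope_assignment="realized"`` — by the
    band of the variability score actually realised by the generated HbA1c
    series (useful for planted-truth recovery experiments).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    start0 = pd.Timestamp(cfg.start_date)

    cat = rng.choice(N_CATEGORIES, size=n, p=np.asarray(cfg.category_probs)) + 1
    age = np.clip(rng.normal(np.asarray(cfg.age_mean_by_category)[cat - 1], cfg.age_sd), 21.0, 90.0)
    female = rng.random(n) < np.asarray(cfg.female_frac_by_category)[cat - 1]
    sex = np.where(female, "F", "M")
    follow_up = cfg.follow_up_years * np.exp(rng.normal(0.0, cfg.follow_up_log_sd, n))
    follow_up = np.clip(follow_up, 0.3, 12.0)
    enrol_offset = rng.integers(0, max(int(cfg.enrol_span_years * 365.25), 1), n)
    baseline_egfr = np.clip(
        rng.normal(cfg.baseline_egfr_mean, cfg.baseline_egfr_sd, n), 20.0, 150.0
    )
    flags = {
        cov: rng.random(n) < np.asarray(prev)[cat - 1]
        for cov, prev in cfg.covariate_prevalence.items()
    }
    lagged = rng.random(n) < cfg.p_last_scr_lag

    jump_probs = np.asarray(cfg.jump_prob_by_category)
    levels = np.asarray(cfg.hba1c_level_mean_by_category)
    slopes_by_cat = np.asarray(cfg.true_slope_by_category)

    sids = np.array([f"S{i + 1:06d}" for i in range(n)])
    index_day = enrol_offset.astype(int)  # days since start0, per subject

    # accumulators: (subject row index, day offset from that subject's index)
    v_idx, v_day = [], []
    hb_idx, hb_day, hb_val = [], [], []
    scr_idx, scr_day, scr_val = [], [], []
    med_rows, dx_rows = [], []

    for i in range(n):
        times = _visit_times(cfg, follow_up[i], rng)
        days = np.unique(np.round(times * 365.25).astype(int))
        nv = days.size
        v_idx.append(np.full(nv, i))
        v_day.append(days)

        # HbA1c: index visit always measured, later visits may be missing
        has_hb = np.ones(nv, bool)
        if cfg.p_missing_hba1c > 0 and nv > 1:
            has_hb[1:] = rng.random(nv - 1) >= cfg.p_missing_hba1c
        n_hb = int(has_hb.sum())
        band = int(cat[i])
        if n_hb >= 2:
            hb_vals = np.round(
                simulate_hba1c_series(levels[band - 1], jump_probs[band - 1], n_hb, rng), 2
            )
            realized_band = int(hvs_category(hvs(hb_vals)))
        else:
            hb_vals = np.round(levels[band - 1] + rng.normal(0.0, 0.3, n_hb), 2)
            realized_band = band
        hb_idx.append(np.full(n_hb, i))
        hb_day.append(days[has_hb])
        hb_val.append(hb_vals)

        # creatinine, from the planted eGFR trajectory
        slope_band = realized_band if cfg.slope_assignment == "realized" else band
        true_slope = slopes_by_cat[slope_band - 1] + (
            rng.normal(0.0, cfg.slope_sd) if cfg.slope_sd > 0 else 0.0
        )
        has_scr = rng.random(nv) >= cfg.p_missing_scr
        has_scr[0] = True
        scr_days = days[has_scr]
        if lagged[i] and cfg.last_scr_lag_days > 0:
            scr_days = np.append(scr_days, days[-1] + cfg.last_scr_lag_days)
        scr = simulate_creatinine_series(
            baseline_egfr[i], true_slope, scr_days / 365.25, cfg.egfr_noise_sd,
            age[i], str(sex[i]), rng, subject_id=sids[i],
        )
        scr_idx.append(np.full(scr_days.size, i))
        scr_day.append(scr_days)
        scr_val.append(np.round(scr, 4))

        med_day = int(days[rng.integers(0, nv)])
        for cov, cls in _MED_CLASSES.items():
            if flags.get(cov, np.zeros(n, bool))[i]:
                med_rows.append((i, med_day, cls))
        for cov, code in _DX_CODES.items():
            if flags.get(cov, np.zeros(n, bool))[i]:
                dx_rows.append((i, 0, code))

    base = np.datetime64(start0, "D")
    index_np = base + index_day.astype("timedelta64[D]")

    def dates_for(idx: np.ndarray, day: np.ndarray) -> pd.Series:
        return pd.Series(index_np[idx] + day.astype("timedelta64[D]")).astype(
            "datetime64[ns]"
        )

    v_idx = np.concatenate(v_idx)
    v_day = np.concatenate(v_day)
    hb_idx, hb_day = np.concatenate(hb_idx), np.concatenate(hb_day)
    scr_idx, scr_day = np.concatenate(scr_idx), np.concatenate(scr_day)
    lab_idx = np.concatenate([hb_idx, scr_idx])
    lab_day = np.concatenate([hb_day, scr_day])

    birth_np = index_np - np.round(age * 365.25).astype("timedelta64[D]")
    subjects = pd.DataFrame(
        {
            "subject_id": sids,
            "sex": sex,
            "birth_date": pd.Series(birth_np).astype("datetime64[ns]"),
        }
    )
    visits = pd.DataFrame(
        {"subject_id": sids[v_idx], "visit_date": dates_for(v_idx, v_day)}
    )
    labs = pd.DataFrame(
        {
            "subject_id": sids[lab_idx],
            "date": dates_for(lab_idx, lab_day),
            "analyte": np.concatenate(
                [np.full(hb_idx.size, "HBA1C"), np.full(scr_idx.size, "SCR")]
            ),
            "value": np.concatenate([np.concatenate(hb_val), np.concatenate(scr_val)]),
            "unit": np.concatenate(
                [np.full(hb_idx.size, "%"), np.full(scr_idx.size, "mg/dL")]
            ),
        }
    )
    if med_rows:
        m_idx = np.array([r[0] for r in med_rows])
        m_day = np.array([r[1] for r in med_rows])
        meds = pd.DataFrame(
            {
                "subject_id": sids[m_idx],
                "date": dates_for(m_idx, m_day),
                "drug_class": [r[2] for r in med_rows],
            }
        )
    else:
        meds = pd.DataFrame(columns=["subject_id", "date", "drug_class"])
        meds["date"] = meds["date"].astype("datetime64[ns]")
    if dx_rows:
        d_idx = np.array([r[0] for r in dx_rows])
        d_day = np.array([r[1] for r in dx_rows])
        diagnoses = pd.DataFrame(
            {
                "subject_id": sids[d_idx],
                "date": dates_for(d_idx, d_day),
                "icd10_code": [r[2] for r in dx_rows],
            }
        )
    else:
        diagnoses = pd.DataFrame(columns=["subject_id", "date", "icd10_code"])
        diagnoses["date"] = diagnoses["date"].astype("datetime64[ns]")

    raw = RawTables(
        subjects=subjects, visits=visits, labs=labs, meds=meds, diagnoses=diagnoses
    )
    return raw.validate()


def write_tables(raw: RawTables, out_dir, config: Optional[SimConfig] = None) -> None:
    """Write the five tables as UTF-8 CSV with ISO-8601 dates, plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in TABLE_NAMES:
        df = getattr(raw, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {"tables": list(TABLE_NAMES)}
    if config is not None:
        manifest["seed"] = config.seed
        manifest["config_hash"] = config_hash(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


_DATE_COLS = {
    "subjects": ["birth_date"],
    "visits": ["visit_date"],
    "labs": ["date"],
    "meds": ["date"],
    "diagnoses": ["date"],
}


def read_tables(in_dir) -> RawTables:
    """Read the five CSV tables written by :func:`write_tables`."""
    src = Path(in_dir)
    frames = {}
    for name in TABLE_NAMES:
        df = pd.read_csv(src / f"{name}.csv")
        for col in _DATE_COLS[name]:
            df[col] = pd.to_datetime(df[col])
        frames[name] = df
    return RawTables(**frames).validate()
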