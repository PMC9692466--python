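"""Configuration objects for simulation, eligibility, balancing and models.

Every config is a plain dataclass with a ``validate()`` method that raises
:class:`~glycovar.errors.ConfigError` naming the offending field, plus YAML
round-tripping for the CLI.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import yaml

from .errors import ConfigError

N_CATEGORIES = 5

# Marginal band-membership proportions of the simulated cohort
# (506, 585, 661, 444, 201 of 2397).
DEFAULT_CATEGORY_PROBS = (
    506 / 2397,
    585 / 2397,
    661 / 2397,
    444 / 2397,
    201 / 2397,
)

# Per-category prevalence of binary covariates; gradients deliberately
# confound band membership so that balancing has real work to do.
DEFAULT_COVARIATE_PREVALENCE: Dict[str, Tuple[float, ...]] = {
    "hypertension": (0.686, 0.759, 0.691, 0.658, 0.602),
    "ascvd": (0.435, 0.463, 0.380, 0.347, 0.289),
    "insulin": (0.206, 0.354, 0.461, 0.536, 0.552),
    "statin": (0.646, 0.697, 0.667, 0.694, 0.697),
    "arb_acei": (0.421, 0.468, 0.446, 0.385, 0.428),
    "ccb": (0.342, 0.364, 0.357, 0.306, 0.289),
    "sglt2_glp1": (0.05, 0.05, 0.05, 0.05, 0.05),
}


@dataclass
class SimConfig:
    """Generative specification of a synthetic outpatient diabetes cohort."""

    n_subjects: int = 1000
    follow_up_years: float = 4.7  # target median
    follow_up_log_sd: float = 0.30  # lognormal spread around the median
    visit_rate: float = 1.9  # visits per year
    visit_process: str = "poisson"  # "poisson" | "regular"
    category_probs: Tuple[float, ...] = DEFAULT_CATEGORY_PROBS
    jump_prob_by_category: Tuple[float, ...] = (0.08, 0.30, 0.50, 0.70, 0.92)
    hba1c_level_mean_by_category: Tuple[float, ...] = (6.8, 7.1, 7.4, 7.8, 8.6)
    true_slope_by_category: Tuple[float, ...] = (-0.33, -0.55, -0.75, -1.26, -2.16)
    slope_sd: float = 2.0  # between-subject slope spread within a band
    slope_assignment: str = "latent"  # "latent" | "realized"
    baseline_egfr_mean: float = 90.0
    baseline_egfr_sd: float = 15.0
    egfr_noise_sd: float = 4.0
    covariate_prevalence: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    age_mean_by_category: Tuple[float, ...] = (60.3, 61.2, 57.5, 54.9, 53.4)
    age_sd: float = 10.0
    female_frac_by_category: Tuple[float, ...] = (0.468, 0.407, 0.384, 0.396, 0.368)
    p_missing_hba1c: float = 0.0  # chance a non-index visit lacks HbA1c
    p_missing_scr: float = 0.0  # chance a visit lacks creatinine
    last_scr_lag_days: int = 0  # extra creatinine-only tail after last visit
    p_last_scr_lag: float = 0.0  # fraction of subjects receiving that tail
    start_date: str = "2012-01-01"
    enrol_span_years: float = 3.0  # index dates spread uniformly over this span
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.follow_up_years <= 0:
            raise ConfigError("follow_up_years must be > 0")
        if self.visit_rate <= 0:
            raise ConfigError("visit_rate must be > 0")
        if self.visit_process not in ("poisson", "regular"):
            raise ConfigError("visit_process must be 'poisson' or 'regular'")
        if self.slope_assignment not in ("latent", "realized"):
            raise ConfigError("slope_assignment must be 'latent' or 'realized'")
        probs = tuple(self.category_probs)
        if len(probs) != N_CATEGORIES:
            raise ConfigError("category_probs must have 5 entries")
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError("category_probs entries must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError("category_probs must sum to 1 within 1e-12")
        for name in (
            "jump_prob_by_category",
            "hba1c_level_mean_by_category",
            "true_slope_by_category",
            "age_mean_by_category",
            "female_frac_by_category",
        ):
            vals = tuple(getattr(self, name))
            if len(vals) != N_CATEGORIES:
                raise ConfigError(f"{name} must have 5 entries")
        if any(p < 0 or p > 1 for p in self.jump_prob_by_category):
            raise ConfigError("jump_prob_by_category entries must lie in [0, 1]")
        if any(f < 0 or f > 1 for f in self.female_frac_by_category):
            raise ConfigError("female_frac_by_category entries must lie in [0, 1]")
        for name in ("follow_up_log_sd", "slope_sd", "baseline_egfr_sd", "egfr_noise_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_missing_hba1c", "p_missing_scr", "p_last_scr_lag"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.baseline_egfr_mean <= 0:
            raise ConfigError("baseline_egfr_mean must be > 0")
        for cov, prev in self.covariate_prevalence.items():
            if len(tuple(prev)) != N_CATEGORIES:
                raise ConfigError(f"covariate_prevalence[{cov!r}] must have 5 entries")
            if any(p < 0 or p > 1 for p in prev):
                raise ConfigError(f"covariate_prevalence[{cov!r}] entries must lie in [0, 1]")
        return self


@dataclass
class EligibilityConfig:
    """Thresholds of the cohort eligibility rules."""

    min_visits: int = 5
    min_span_years: float = 1.0
    min_creatinine_measures: int = 3
    min_hba1c_measures: int = 2  # HVS needs one successive pair
    min_baseline_egfr: float = 15.0
    min_age: float = 18.0
    baseline_window_days: Tuple[int, int] = (-30, 365)

    def validate(self) -> "EligibilityConfig":
        for name in ("min_visits", "min_span_years", "min_creatinine_measures",
                     "min_hba1c_measures", "min_baseline_egfr", "min_age"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.baseline_window_days
        if not lo < hi:
            raise ConfigError("baseline_window_days start must precede end")
        return self


#: covariates balanced across HVS categories, in model order
DEFAULT_BALANCE_COVARIATES = (
    "age_at_index",
    "female",
    "baseline_egfr_lt60",
    "htn_or_ascvd",
    "ever_insulin",
    "ever_statin",
    "ever_arb_acei",
    "twa_hba1c",
    "adherence",
)


@dataclass
class BalanceSpec:
    """What entropy balancing must equalise, and how hard to try."""

    covariates: Tuple[str, ...] = DEFAULT_BALANCE_COVARIATES
    moment_order: int = 1
    target: str = "pooled"  # "pooled" | "reference"
    tolerance: float = 1e-8
    max_iter: int = 200

    def validate(self) -> "BalanceSpec":
        if not self.covariates:
            raise ConfigError("covariates must be nonempty")
        if self.moment_order not in (1, 2):
            raise ConfigError("moment_order must be 1 or 2")
        if self.target not in ("pooled", "reference"):
            raise ConfigError("target must be 'pooled' or 'reference'")
        if self.tolerance <= 0:
            raise ConfigError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        return self


@dataclass
class ModelConfig:
    """Shared settings of the outcome models."""

    mid: float = 0.75  # minimal important slope difference, mL/min/1.73m2/yr
    reference_category: int = 1
    ci_level: float = 0.95
    logistic_variance: str = "sandwich"  # "sandwich" | "model"
    min_stratum_size: int = 50

    def validate(self) -> "ModelConfig":
        if self.mid <= 0:
            raise ConfigError("mid must be > 0")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.reference_category != 1:
            raise ConfigError("reference_category must be 1")
        if self.logistic_variance not in ("sandwich", "model"):
            raise ConfigError("logistic_variance must be 'sandwich' or 'model'")
        return self


# ICD-10 prefixes used to flag comorbidity from the diagnosis table; the
# study-specific code lists are configurable, these are pragmatic defaults.
DEFAULT_CODE_PREFIXES: Dict[str, Tuple[str, ...]] = {
    "hypertension": ("I10", "I11", "I12", "I13", "I15"),
    "ascvd": ("I20", "I21", "I22", "I23", "I24", "I25", "I63", "I65", "I66", "I70"),
}


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def config_to_yaml(cfg) -> str:
    """Serialise any config dataclass to a YAML document."""
    return yaml.safe_dump(_as_plain(cfg), sort_keys=True)


def config_hash(cfg) -> str:
    """Stable short hash of a config, for run manifests."""
    canon = json.dumps(_as_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


_TUPLE_FIELDS = {
    "category_probs",
    "jump_prob_by_category",
    "hba1c_level_mean_by_category",
    "true_slope_by_category",
    "age_mean_by_category",
    "female_frac_by_category",
    "baseline_window_days",
    "covariates",
}


def _coerce(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} field(s): {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(val)
        if key == "covariate_prevalence" and isinstance(val, dict):
            val = {k: tuple(v) for k, v in val.items()}
        kwargs[key] = val
    return cls(**kwargs).validate()


def sim_config_from_yaml(text: str) -> SimConfig:
    return _coerce(SimConfig, yaml.safe_load(text) or {})


def load_sim_config(path) -> SimConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return sim_config_from_yaml(fh.read())
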