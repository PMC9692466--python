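"""Weighted outcome models, subgroup analyses, and the sensitivity suite.

Two primary models:

* :func:`fit_weighted_logistic` — logistic regression of the rapid-decline
  flag on category indicators with entropy-balancing weights treated as
  probability weights (robust sandwich CIs by default).
* :func:`fit_weighted_mixed_slopes` — a linear mixed model of eGFR on
  category, time, and category-by-time fixed effects with a random
  intercept and random slope per subject, estimated by maximum likelihood
  with each subject's log-likelihood contribution multiplied by its
  weight.  The category-by-time interaction coefficients are the slope
  differences vs the reference band; Wald CIs; estimates are compared
  against the minimal important difference (default 0.75).

The mixed model is written directly (profiled weighted deviance over the
random-effects Cholesky factor, Woodbury identities per subject) because no
pre-installed library fits subject-weighted mixed models; the log-likelihood
it maximises is checked against independent oracles in the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from scipy import stats

from .config import BalanceSpec, ModelConfig
from .balancing import entropy_balance
from .errors import BalanceError, ModelError

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "MixedSlopesFit",
    "fit_weighted_logistic",
    "fit_weighted_mixed_slopes",
    "subgroup_suite",
    "sensitivity_suite",
]

N_CAT = 5


@dataclass
class EffectEstimate:
    """One model term: estimate with CI on its reporting scale."""

    term: str
    scale: str  # "odds_ratio" | "slope_difference" | "slope"
    estimate: float
    se: float  # on the estimation scale (log-odds for odds ratios)
    ci_low: float
    ci_high: float
    n_used: int
    exceeds_mid: Optional[bool] = None

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "scale": self.scale,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_used": self.n_used,
            "exceeds_mid": self.exceeds_mid,
        }


def _category_design(categories: np.ndarray) -> Tuple[np.ndarray, List[int]]:
    """Intercept + indicator columns for the observed non-reference categories."""
    present = sorted(int(g) for g in np.unique(categories))
    if 1 not in present:
        raise ModelError("reference category (1) is absent")
    non_ref = [g for g in present if g != 1]
    cols = [np.ones(categories.size)]
    for g in non_ref:
        cols.append((categories == g).astype(float))
    return np.column_stack(cols), non_ref


def fit_weighted_logistic(
    rapid: Sequence[bool],
    categories: Sequence[int],
    weights: Sequence[float],
    cfg: Optional[ModelConfig] = None,
) -> List[EffectEstimate]:
    """Odds ratios of rapid decline for categories 2-5 vs the reference.

    Maximises the weighted Bernoulli log-likelihood of a saturated
    category-indicator model; CIs use the probability-weight sandwich
    variance unless ``cfg.logistic_variance == "model"``.
    """
    cfg = (cfg or ModelConfig()).validate()
    y = np.asarray(rapid, dtype=float)
    cats = np.asarray(categories, dtype=int)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ModelError("weights must be strictly positive")
    for g in np.unique(cats):
        cls = np.unique(y[cats == g])
        if cls.size < 2:
            raise ModelError(f"category {g}: outcome has a single class ({cls[0]:.0f})")
    X, non_ref = _category_design(cats)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    cov_type = "HC0" if cfg.logistic_variance == "sandwich" else "nonrobust"
    try:
        res = model.fit(cov_type=cov_type)
    except Exception as exc:  # statsmodels raises various separation errors
        raise ModelError(f"weighted logistic failed: {exc}") from exc
    if np.any(np.abs(res.params) > 30):
        g = int(np.argmax(np.abs(res.params)))
        raise ModelError(f"perfect separation suspected (coefficient {g} diverged)")
    z = stats.norm.ppf(0.5 + cfg.ci_level / 2)
    out = []
    for j, g in enumerate(non_ref, start=1):
        b, se = float(res.params[j]), float(res.bse[j])
        out.append(
            EffectEstimate(
                term=f"category_{g}_vs_1",
                scale="odds_ratio",
                estimate=float(np.exp(b)),
                se=se,
                ci_low=float(np.exp(b - z * se)),
                ci_high=float(np.exp(b + z * se)),
                n_used=int(y.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# weighted linear mixed model with random intercept + slope
# ---------------------------------------------------------------------------


@dataclass
class MixedSlopesFit:
    """Full result of the weighted mixed-slopes model."""

    reference_slope: EffectEstimate
    differences: List[EffectEstimate]
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    re_covariance: np.ndarray  # 2x2, intercept/slope
    converged: bool
    diagonal_refit: bool
    n_subjects: int
    n_obs: int


def _subject_blocks(
    subject_ids: np.ndarray, t: np.ndarray, y: np.ndarray, X: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject cross-product blocks S_i = U_i'U_i, U_i = [Z_i X_i y_i]."""
    order = np.argsort(subject_ids, kind="mergesort")
    sid, t, y, X = subject_ids[order], t[order], y[order], X[order]
    _, starts, counts = np.unique(sid, return_index=True, return_counts=True)
    U = np.column_stack([np.ones_like(t), t, X, y])
    outer = U[:, :, None] * U[:, None, :]
    S = np.add.reduceat(outer, starts, axis=0)
    return S, counts, starts


def _profiled_deviance(
    theta: np.ndarray,
    S: np.ndarray,
    counts: np.ndarray,
    w: np.ndarray,
    p: int,
    want_beta: bool = False,
):
    """-2 * weighted profile log-likelihood at relative-covariance factor theta.

    theta parameterises Lambda = [[t0, 0], [t1, t2]] with
    G = sigma^2 * Lambda Lambda'.  beta and sigma^2 are profiled out.
    """
    L = np.array([[theta[0], 0.0], [theta[1], theta[2]]])
    ZtZ = S[:, :2, :2]
    ZtX = S[:, :2, 2 : 2 + p]
    Zty = S[:, :2, -1]
    XtX = S[:, 2 : 2 + p, 2 : 2 + p]
    Xty = S[:, 2 : 2 + p, -1]
    yty = S[:, -1, -1]

    A = np.eye(2) + L.T @ ZtZ @ L  # (m, 2, 2)
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    if np.any(det <= 0):
        return np.inf if not want_beta else (np.inf, None, None, None, None)
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1]
    Ainv[:, 1, 1] = A[:, 0, 0]
    Ainv[:, 0, 1] = -A[:, 0, 1]
    Ainv[:, 1, 0] = -A[:, 1, 0]
    Ainv /= det[:, None, None]
    P = L @ Ainv @ L.T  # (m, 2, 2)

    LZtX = np.swapaxes(ZtX, 1, 2)  # (m, p, 2)
    XtVX = XtX - LZtX @ P @ ZtX
    XtVy = Xty - np.einsum("mpz,mzk,mk->mp", LZtX, P, Zty)
    ytVy = yty - np.einsum("mz,mzk,mk->m", Zty, P, Zty)

    Gb = np.einsum("m,mpq->pq", w, XtVX)
    gy = np.einsum("m,mp->p", w, XtVy)
    try:
        beta = np.linalg.solve(Gb, gy)
    except np.linalg.LinAlgError:
        return np.inf if not want_beta else (np.inf, None, None, None, None)
    rss = float(w @ ytVy - beta @ gy)
    Nw = float(w @ counts)
    sigma2 = max(rss / Nw, 1e-12)
    dev = float(w @ np.log(det)) + Nw * (np.log(2 * np.pi * sigma2) + 1.0)
    if not want_beta:
        return dev
    return dev, beta, sigma2, Gb, L


def fit_weighted_mixed_slopes(
    long: pd.DataFrame,
    categories: Union[pd.Series, Dict[str, int]],
    weights: Union[pd.Series, Dict[str, float]],
    cfg: Optional[ModelConfig] = None,
) -> MixedSlopesFit:
    """Weighted ML fit of eGFR on category, time and category-by-time.

    ``long`` needs columns ``subject_id``, ``time_years``, ``egfr``;
    ``categories`` and ``weights`` map subject_id -> band / weight.
    Returns the reference-band mean slope (the fixed time coefficient) and
    the four interaction contrasts with Wald CIs.
    """
    cfg = (cfg or ModelConfig()).validate()
    cat_map = dict(categories) if not isinstance(categories, dict) else categories
    w_map = dict(weights) if not isinstance(weights, dict) else weights
    df = long[["subject_id", "time_years", "egfr"]].copy()
    counts_per = df.groupby("subject_id").size()
    if (counts_per < 3).any():
        bad = counts_per[counts_per < 3].index.tolist()[:3]
        raise ModelError(f"subjects with <3 eGFR measures: {bad} ...")
    sid = df["subject_id"].to_numpy()
    t = df["time_years"].to_numpy(dtype=float)
    y = df["egfr"].to_numpy(dtype=float)
    cats_row = np.array([cat_map[s] for s in sid], dtype=int)

    # fixed effects: 1, category indicators, t, category x t
    D, non_ref = _category_design(cats_row)
    X = np.column_stack([D, t[:, None] * D])
    p = X.shape[1]
    k = D.shape[1]  # index of the time main effect

    S, counts, starts = _subject_blocks(sid, t, y, X)
    order = np.argsort(sid, kind="mergesort")
    uniq = sid[order][starts]
    w = np.array([w_map[s] for s in uniq], dtype=float)
    if np.any(w <= 0):
        raise ModelError("weights must be strictly positive")

    def objective(theta):
        return _profiled_deviance(theta, S, counts, w, p)

    x0 = np.array([1.0, 0.0, 1.0])
    res = scipy.optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
    )
    diagonal_refit = False
    theta = res.x
    if not res.success or not np.isfinite(res.fun):
        # fall back to a diagonal random-effects covariance
        diagonal_refit = True
        logger.warning("mixed model: full covariance fit failed, refitting diagonal")

        def objective_diag(th2):
            return _profiled_deviance(np.array([th2[0], 0.0, th2[1]]), S, counts, w, p)

        res = scipy.optimize.minimize(
            objective_diag, np.array([1.0, 1.0]), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if not res.success or not np.isfinite(res.fun):
            raise ModelError(f"mixed model did not converge: {res.message}")
        theta = np.array([res.x[0], 0.0, res.x[1]])

    dev, beta, sigma2, Gb, L = _profiled_deviance(theta, S, counts, w, p, want_beta=True)
    if beta is None:
        raise ModelError("mixed model produced a singular fixed-effects system")
    cov_beta = sigma2 * np.linalg.inv(Gb)
    G = sigma2 * (L @ L.T)

    z = stats.norm.ppf(0.5 + cfg.ci_level / 2)
    n_sub = int(counts.size)
    n_obs = int(counts.sum())

    def eff(idx: int, term: str, scale: str, with_mid: bool) -> EffectEstimate:
        b = float(beta[idx])
        se = float(np.sqrt(cov_beta[idx, idx]))
        return EffectEstimate(
            term=term, scale=scale, estimate=b, se=se,
            ci_low=b - z * se, ci_high=b + z * se, n_used=n_sub,
            exceeds_mid=(abs(b) > cfg.mid) if with_mid else None,
        )

    reference = eff(k, "time_reference", "slope", with_mid=False)
    diffs = [
        eff(k + j, f"category_{g}_x_time", "slope_difference", with_mid=True)
        for j, g in enumerate(non_ref, start=1)
    ]
    return MixedSlopesFit(
        reference_slope=reference,
        differences=diffs,
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        re_covariance=G,
        converged=True,
        diagonal_refit=diagonal_refit,
        n_subjects=n_sub,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# orchestration: fit both primary models on a (sub)cohort
# ---------------------------------------------------------------------------


def _fit_both(
    cohort: pd.DataFrame,
    long_egfr: pd.DataFrame,
    balance_spec: BalanceSpec,
    cfg: ModelConfig,
) -> Dict[str, object]:
    bal = entropy_balance(cohort, cohort["hvs_category"].to_numpy(), balance_spec)
    weights = pd.Series(bal.weights, index=cohort["subject_id"])
    cats = pd.Series(cohort["hvs_category"].to_numpy(), index=cohort["subject_id"])
    logistic = fit_weighted_logistic(
        cohort["rapid_decliner"].to_numpy(),
        cohort["hvs_category"].to_numpy(),
        bal.weights,
        cfg,
    )
    sub_long = long_egfr[long_egfr["subject_id"].isin(cohort["subject_id"])]
    mixed = fit_weighted_mixed_slopes(sub_long, cats, weights, cfg)
    return {
        "n": int(len(cohort)),
        "balance": bal,
        "logistic": logistic,
        "mixed": mixed,
    }


SUBGROUPS = {
    "sex": ("female", {1: "female", 0: "male"}),
    "age": ("age_ge60", {1: "age>=60", 0: "age<60"}),
    "insulin": ("ever_insulin", {1: "insulin", 0: "no_insulin"}),
    "baseline_egfr": ("baseline_egfr_lt60", {1: "egfr<60", 0: "egfr>=60"}),
}


def subgroup_suite(
    cohort: pd.DataFrame,
    long_egfr: pd.DataFrame,
    balance_spec: Optional[BalanceSpec] = None,
    cfg: Optional[ModelConfig] = None,
) -> Dict[Tuple[str, str], Dict[str, object]]:
    """Refit both primary models within each stratum of the four subgroups.

    Balancing weights are re-estimated within every stratum.  Strata below
    ``cfg.min_stratum_size`` or failing model preconditions are skipped
    with a logged reason (an entry ``{"skipped": reason}``).
    """
    balance_spec = balance_spec or BalanceSpec()
    cfg = (cfg or ModelConfig()).validate()
    work = cohort.copy()
    work["age_ge60"] = (work["age_at_index"] >= 60).astype(int)
    out: Dict[Tuple[str, str], Dict[str, object]] = {}
    for name, (col, labels) in SUBGROUPS.items():
        for val, label in labels.items():
            key = (name, label)
            stratum = work[work[col] == val]
            if len(stratum) < cfg.min_stratum_size:
                out[key] = {"skipped": f"stratum size {len(stratum)} < {cfg.min_stratum_size}"}
                continue
            try:
                out[key] = _fit_both(stratum, long_egfr, balance_spec, cfg)
            except Exception as exc:
                logger.warning("subgroup %s/%s skipped: %s", name, label, exc)
                out[key] = {"skipped": str(exc)}
    return out


DEFAULT_SCENARIOS = (
    "window_2y",
    "window_3y",
    "window_4y",
    "window_5y",
    "unparallel_90d",
    "baseline_hba1c_weights",
    "exclude_egfr_lt30",
    "exclude_sglt2_glp1",
)


def _windowed_scenario(
    cohort: pd.DataFrame, long_egfr: pd.DataFrame, window: float
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    sub = long_egfr[long_egfr["time_years"] <= window + 1e-9]
    counts = sub.groupby("subject_id").size()
    keep = set(counts[counts >= 3].index)
    dropped = int(len(cohort) - len(keep))
    sub = sub[sub["subject_id"].isin(keep)]
    coh = cohort[cohort["subject_id"].isin(keep)].copy()
    # windowed per-subject OLS slope and rapid flag
    g = sub.assign(ty=sub["time_years"] * sub["egfr"], t2=sub["time_years"] ** 2).groupby(
        "subject_id"
    )
    s = g[["time_years", "t2", "ty", "egfr"]].sum()
    n = g.size()
    slope = (n * s["ty"] - s["time_years"] * s["egfr"]) / (n * s["t2"] - s["time_years"] ** 2)
    coh["mean_slope"] = coh["subject_id"].map(slope)
    coh["rapid_decliner"] = coh["mean_slope"] <= -5.0 + 1e-9
    return coh, sub, dropped


def sensitivity_suite(
    cohort: pd.DataFrame,
    long_egfr: pd.DataFrame,
    balance_spec: Optional[BalanceSpec] = None,
    cfg: Optional[ModelConfig] = None,
    scenarios: Sequence[str] = DEFAULT_SCENARIOS,
) -> Dict[str, Dict[str, object]]:
    """Re-run balancing and both models under each sensitivity scenario.

    Scenarios: slopes restricted to 2/3/4/5-year windows; exclusion of
    subjects whose last HbA1c and creatinine are >= 90 days apart;
    balancing on baseline instead of time-weighted HbA1c; exclusion of
    baseline eGFR < 30; exclusion of SGLT2i/GLP-1RA users.  A scenario
    that leaves a category empty (or otherwise unfittable) is marked
    infeasible rather than fatal.
    """
    balance_spec = balance_spec or BalanceSpec()
    cfg = (cfg or ModelConfig()).validate()
    out: Dict[str, Dict[str, object]] = {}
    for name in scenarios:
        coh, sub_long, spec, dropped = cohort, long_egfr, balance_spec, 0
        try:
            if name.startswith("window_"):
                window = float(name.split("_")[1].rstrip("y"))
                coh, sub_long, dropped = _windowed_scenario(cohort, long_egfr, window)
            elif name == "unparallel_90d":
                gap = (cohort["last_hba1c_date"] - cohort["last_scr_date"]).abs()
                keep = gap < pd.Timedelta(days=90)
                dropped = int((~keep).sum())
                coh = cohort[keep]
            elif name == "baseline_hba1c_weights":
                covs = tuple(
                    "baseline_hba1c" if c == "twa_hba1c" else c
                    for c in balance_spec.covariates
                )
                spec = BalanceSpec(
                    covariates=covs,
                    moment_order=balance_spec.moment_order,
                    target=balance_spec.target,
                    tolerance=balance_spec.tolerance,
                    max_iter=balance_spec.max_iter,
                )
            elif name == "exclude_egfr_lt30":
                keep = cohort["baseline_egfr"] >= 30
                dropped = int((~keep).sum())
                coh = cohort[keep]
            elif name == "exclude_sglt2_glp1":
                keep = cohort["ever_sglt2_glp1"] == 0
                dropped = int((~keep).sum())
                coh = cohort[keep]
            else:
                raise ModelError(f"unknown scenario {name!r}")
            if set(coh["hvs_category"].unique()) != set(cohort["hvs_category"].unique()):
                out[name] = {"infeasible": "a category is empty", "dropped": dropped}
                continue
            result = _fit_both(coh, sub_long, spec, cfg)
            result["dropped"] = dropped
            out[name] = result
        except (ModelError, BalanceError) as exc:
            out[name] = {"infeasible": str(exc), "dropped": dropped}
        logger.info("sensitivity scenario %s: dropped %d subjects", name, dropped)
    return out
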