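"""Entropy balancing: exponential-tilting weights with exact moment balance.

For each category g the weights solve

    min  sum_i w_i log(w_i)      over w_i > 0, mean_g(w) = 1
    s.t. weighted covariate moments of g  =  target moments

whose dual is the strictly convex problem

    min_lambda  log mean_{i in g} exp(lambda . (c_i - m))

solved by damped Newton iterations; the primal solution is
``w_i = n_g * softmax(lambda . c_i)``.  Targets are the pooled (full-sample)
moments by default, so every category — including the reference — is
reweighted toward the common margin.

Covariates are standardised internally for conditioning only; the solution
is invariant to affine rescaling of any covariate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .config import BalanceSpec
from .errors import BalanceError

__all__ = ["BalanceResult", "entropy_balance", "balance_diagnostics"]

_RIDGE = 1e-10


@dataclass
class BalanceResult:
    """Per-subject weights plus dual parameters and balance diagnostics."""

    weights: np.ndarray  # positive, mean 1 within each category
    lambdas: Dict[int, np.ndarray]  # dual coefficients per category (raw scale)
    smd_before: pd.DataFrame  # covariate x category
    smd_after: pd.DataFrame
    converged: bool
    iterations: Dict[int, int] = field(default_factory=dict)

    @property
    def max_abs_smd_after(self) -> float:
        return float(self.smd_after.abs().to_numpy().max())


def _expand_moments(X: np.ndarray, order: int) -> np.ndarray:
    if order == 1:
        return X
    return np.hstack([X, X**2])


def _solve_category(
    C: np.ndarray, tolerance: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Damped Newton on the dual for one category.

    ``C`` holds standardised covariate deviations from the target.  Returns
    (weights summing to n_g, lambda, iterations); raises on failure.
    """
    n, k = C.shape
    lam = np.zeros(k)

    def dual(l: np.ndarray) -> float:
        eta = C @ l
        m = eta.max()
        return m + np.log(np.mean(np.exp(eta - m)))

    f = dual(lam)
    for it in range(1, max_iter + 1):
        eta = C @ lam
        eta -= eta.max()
        w = np.exp(eta)
        w /= w.sum()
        grad = w @ C
        if np.max(np.abs(grad)) < tolerance:
            return w * n, lam, it - 1
        if np.linalg.norm(lam) > 1e4:
            j = int(np.argmax(np.abs(grad)))
            raise BalanceError(
                "infeasible: dual diverging, target likely outside the convex "
                f"hull (worst covariate index {j}, gradient {grad[j]:.3e})"
            )
        H = (C * w[:, None]).T @ C - np.outer(grad, grad)
        try:
            step = np.linalg.solve(H + _RIDGE * np.eye(k), grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge guards this
            raise BalanceError(f"singular dual Hessian: {exc}") from exc
        # step-halving: the dual objective must not increase
        alpha = 1.0
        for _ in range(40):
            trial = lam - alpha * step
            f_trial = dual(trial)
            if f_trial <= f + 1e-12:
                lam, f = trial, f_trial
                break
            alpha *= 0.5
        else:
            raise BalanceError(
                f"line search failed; gradient norm {np.max(np.abs(grad)):.3e}"
            )
    eta = C @ lam
    eta -= eta.max()
    w = np.exp(eta)
    w /= w.sum()
    grad = w @ C
    raise BalanceError(
        f"no convergence in {max_iter} iterations; final gradient norm "
        f"{np.max(np.abs(grad)):.3e}"
    )


def entropy_balance(
    covariates: pd.DataFrame,
    categories: Sequence[int],
    spec: Optional[BalanceSpec] = None,
) -> BalanceResult:
    """Estimate entropy-balancing weights across the five categories.

    ``covariates`` must contain the columns named in ``spec.covariates``;
    ``categories`` are integer labels 1-5.  Weighted first moments (and
    second, if ``moment_order=2``) of every covariate equal the target
    moments within ``spec.tolerance`` on the standardised scale.
    """
    spec = (spec or BalanceSpec()).validate()
    missing = [c for c in spec.covariates if c not in covariates.columns]
    if missing:
        raise BalanceError(f"missing covariate column(s): {missing}")
    X = covariates[list(spec.covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise BalanceError("covariates must be finite")
    cats = np.asarray(categories, dtype=int)
    if cats.shape[0] != X.shape[0]:
        raise BalanceError("categories length must match covariate rows")
    labels = np.unique(cats)

    M = _expand_moments(X, spec.moment_order)
    if spec.target == "pooled":
        target = M.mean(axis=0)
    else:
        ref = M[cats == labels.min()]
        if ref.size == 0:
            raise BalanceError("reference category is empty")
        target = ref.mean(axis=0)
    scale = M.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0

    names = list(spec.covariates)
    if spec.moment_order == 2:
        names = names + [f"{c}^2" for c in spec.covariates]

    weights = np.ones(X.shape[0])
    lambdas: Dict[int, np.ndarray] = {}
    iterations: Dict[int, int] = {}
    for g in labels:
        idx = np.flatnonzero(cats == g)
        Cg = (M[idx] - target) / scale
        if idx.size <= Cg.shape[1]:
            raise BalanceError(
                f"category {g}: {idx.size} subjects cannot carry "
                f"{Cg.shape[1]} moment constraints"
            )
        # a constant covariate whose value differs from the target is infeasible
        const = Cg.std(axis=0) <= 1e-12
        off = const & (np.abs(Cg.mean(axis=0)) > max(spec.tolerance, 1e-10))
        if np.any(off):
            bad = [names[j] for j in np.flatnonzero(off)]
            raise BalanceError(
                f"infeasible: covariate(s) {bad} constant in category {g} "
                "but off target"
            )
        try:
            w, lam, it = _solve_category(Cg, spec.tolerance, spec.max_iter)
        except BalanceError as exc:
            raise BalanceError(f"category {g}: {exc}") from exc
        weights[idx] = w
        lambdas[int(g)] = lam / scale
        iterations[int(g)] = it

    smd_before = balance_diagnostics(covariates, cats, np.ones_like(weights), spec)
    smd_after = balance_diagnostics(covariates, cats, weights, spec)
    return BalanceResult(
        weights=weights,
        lambdas=lambdas,
        smd_before=smd_before,
        smd_after=smd_after,
        converged=True,
        iterations=iterations,
    )


def balance_diagnostics(
    covariates: pd.DataFrame,
    categories: Sequence[int],
    weights: np.ndarray,
    spec: Optional[BalanceSpec] = None,
) -> pd.DataFrame:
    """Standardised mean differences vs the target, per covariate x category.

    SMD = (weighted category mean - target mean) / pooled SD.  A zero
    pooled SD yields SMD 0 when the means agree and raises otherwise.
    """
    spec = (spec or BalanceSpec()).validate()
    X = covariates[list(spec.covariates)].to_numpy(dtype=float)
    cats = np.asarray(categories, dtype=int)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise BalanceError("weights must be strictly positive")
    if spec.target == "pooled":
        target = X.mean(axis=0)
    else:
        target = X[cats == cats.min()].mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    rows = {}
    for g in np.unique(cats):
        idx = cats == g
        wm = np.average(X[idx], axis=0, weights=w[idx])
        diff = wm - target
        smd = np.zeros_like(diff)
        nz = sd > 0
        smd[nz] = diff[nz] / sd[nz]
        if np.any(~nz & (np.abs(diff) > 1e-10)):
            raise BalanceError("zero pooled SD with unequal means")
        rows[int(g)] = smd
    return pd.DataFrame(rows, index=list(spec.covariates)).rename_axis("covariate")
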