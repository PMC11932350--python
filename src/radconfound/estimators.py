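"""Regression arms: Cox on individual data, Poisson on the person-years table.

Both arms are fit with and without the smoking covariate ("adjusted"
and "unadjusted" analyses); the quantity of interest is always the dose
coefficient — a log hazard ratio per Gy — with its standard error from
the inverse observed information and a 95% Wald interval.

The Cox arm uses a vectorized Newton–Raphson maximizer of the partial
likelihood with Efron handling of tied event times.  Simulated times
are continuous, so ties have measure zero and Efron's correction only
engages on exact float collisions; with no ties it coincides with the
exact partial likelihood.  The Poisson arm fits cell event counts with
a log link and log person-years offset via statsmodels GLM, with an
intercept and linear/quadratic attained-age terms standing in for the
baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import Cohort
from .person_years import PersonYearsTable

__all__ = ["AnalysisSpec", "FitResult", "cox_fit", "poisson_fit", "wald_ci"]

Z975 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class AnalysisSpec:
    """Which regression model to fit and with which covariates.

    ``covariates`` must include ``"dose"``; the smoking-adjusted
    analysis adds ``"smk"``.  ``age_terms`` (Poisson only) controls the
    linear + quadratic attained-age baseline terms.
    """

    model: str = "cox"  # "cox" | "poisson"
    covariates: tuple[str, ...] = ("dose", "smk")
    age_terms: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("cox", "poisson"):
            raise ValueError("model must be 'cox' or 'poisson'")
        if "dose" not in self.covariates:
            raise ValueError("covariates must include 'dose'")

    @property
    def adjusted(self) -> bool:
        return "smk" in self.covariates


@dataclass(frozen=True)
class FitResult:
    """Dose-coefficient estimate from one regression fit."""

    beta_r_hat: float
    se: float
    ci95: tuple[float, float]
    converged: bool
    beta_s_hat: float | None = None
    nuisance: dict = field(default_factory=dict)
    n_events: int = 0


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-theory interval ``beta ∓ z * se``."""
    if not se > 0:
        raise ValueError("se must be positive")
    z = float(norm.ppf(0.5 + level / 2.0))
    return (beta - z * se, beta + z * se)


def _failed(n_events: int = 0) -> FitResult:
    return FitResult(
        beta_r_hat=np.nan, se=np.nan, ci95=(np.nan, np.nan), converged=False, n_events=n_events
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties), vectorized Newton–Raphson
# ---------------------------------------------------------------------------


def _cox_newton(time: np.ndarray, event: np.ndarray, X: np.ndarray,
                max_iter: int = 50, tol: float = 1e-10):
    """Maximize the Efron partial likelihood; return (beta, cov, converged).

    Subjects are sorted by descending time so each event's risk set is a
    prefix; cumulative sums give the risk-set aggregates S0, S1, S2 and
    tied-death sums are removed in Efron fractions l/D.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    t, d, x = time[order], event[order].astype(bool), X[order]
    n_ev = int(d.sum())
    if n_ev == 0:
        raise ValueError("at least one event is required")

    pos = np.nonzero(d)[0]
    xe = x[pos]
    et = t[pos]
    # group tied event times (descending order keeps groups contiguous)
    _, inv, counts = np.unique(-et, return_inverse=True, return_counts=True)
    first = np.r_[0, np.cumsum(counts)[:-1]]
    l_rank = np.arange(n_ev) - first[inv]
    D = counts[inv].astype(float)
    frac = l_rank / D
    # prefix end: last sorted index with time >= each event time
    prefix_end = np.searchsorted(-t, -et, side="right") - 1

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = x @ beta
        eta -= eta.max()  # guard exp overflow; partial likelihood is shift-invariant
        w = np.exp(eta)
        xw = x * w[:, None]
        xxw = x[:, :, None] * x[:, None, :] * w[:, None, None]
        S0 = np.cumsum(w)[prefix_end]
        S1 = np.cumsum(xw, axis=0)[prefix_end]
        S2 = np.cumsum(xxw, axis=0)[prefix_end]
        we, xwe, xxwe = w[pos], xw[pos], xxw[pos]
        s0 = np.bincount(inv, we)[inv]
        s1 = np.column_stack([np.bincount(inv, xwe[:, j]) for j in range(p)])[inv]
        s2 = np.stack(
            [np.bincount(inv, xxwe[:, j, k]) for j in range(p) for k in range(p)], axis=1
        ).reshape(-1, p, p)[inv]
        d0 = S0 - frac * s0
        d1 = S1 - frac[:, None] * s1
        d2 = S2 - frac[:, None, None] * s2
        grad = xe.sum(axis=0) - (d1 / d0[:, None]).sum(axis=0)
        r = d1 / d0[:, None]
        info = (d2 / d0[:, None, None]).sum(axis=0) - r.T @ r  # observed information
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + delta
        if not np.all(np.isfinite(beta)):
            return beta, None, False
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        return beta, None, False
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return beta, None, False
    if np.any(np.diag(cov) <= 0):
        return beta, None, False
    return beta, cov, True


def cox_fit(cohort: Cohort, spec: AnalysisSpec) -> FitResult:
    """Fit the Cox model on individual data; dose coefficient and Wald CI."""
    if spec.model != "cox":
        raise ValueError("spec.model must be 'cox'")
    n_events = cohort.n_events
    if n_events < 1:
        return _failed(0)
    cols = {"dose": cohort.dose, "smk": cohort.smk}
    X = np.column_stack([np.asarray(cols[c], dtype=float) for c in spec.covariates])
    # constant columns carry no information in a partial likelihood
    # (it is invariant to covariate shifts); drop them rather than let
    # the information matrix go singular
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    kept_names = [spec.covariates[j] for j in keep]
    if "dose" not in kept_names:
        return _failed(n_events)
    beta, cov, ok = _cox_newton(
        np.asarray(cohort.time, dtype=float), np.asarray(cohort.event), X[:, keep]
    )
    if not ok:
        return _failed(n_events)
    i_dose = kept_names.index("dose")
    b = float(beta[i_dose])
    se = float(np.sqrt(cov[i_dose, i_dose]))
    beta_s = None
    if spec.adjusted:
        beta_s = float(beta[kept_names.index("smk")]) if "smk" in kept_names else float("nan")
    return FitResult(
        beta_r_hat=b,
        se=se,
        ci95=(b - Z975 * se, b + Z975 * se),
        converged=True,
        beta_s_hat=beta_s,
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Grouped Poisson regression with person-years offset
# ---------------------------------------------------------------------------


def poisson_fit(pyt: PersonYearsTable, spec: AnalysisSpec) -> FitResult:
    """Fit the grouped Poisson model on a person-years table.

    Cell counts are Poisson with mean ``PY * exp(b0 + b1*t + b2*t^2 +
    br*dose [+ bs*smk])`` using the person-year-weighted representative
    covariate values; ``log(PY)`` enters as the offset.
    """
    if spec.model != "poisson":
        raise ValueError("spec.model must be 'poisson'")
    tab = pyt.table
    n_events = int(tab["events"].sum())
    if n_events < 1:
        return _failed(0)
    design_cols = [np.ones(len(tab))]
    names = ["const"]
    if spec.age_terms:
        design_cols += [tab["mean_t"].to_numpy(), tab["mean_t2"].to_numpy()]
        names += ["t", "t2"]
    for c in spec.covariates:
        design_cols.append(tab["mean_dose"].to_numpy() if c == "dose" else tab[c].to_numpy().astype(float))
        names.append(c)
    X = np.column_stack(design_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _failed(n_events)
    offset = np.log(tab["person_years"].to_numpy())
    try:
        res = sm.GLM(tab["events"].to_numpy(), X, family=sm.families.Poisson(), offset=offset).fit()
    except Exception:
        return _failed(n_events)
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        return _failed(n_events)
    i_dose = names.index("dose")
    b = float(res.params[i_dose])
    se = float(res.bse[i_dose])
    if not se > 0:
        return _failed(n_events)
    beta_s = float(res.params[names.index("smk")]) if spec.adjusted else None
    nuisance = {nm: float(v) for nm, v in zip(names, res.params) if nm in ("const", "t", "t2")}
    return FitResult(
        beta_r_hat=b,
        se=se,
        ci95=(b - Z975 * se, b + Z975 * se),
        converged=bool(res.converged),
        beta_s_hat=beta_s,
        nuisance=nuisance,
        n_events=n_events,
    )
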