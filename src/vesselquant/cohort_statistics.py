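"""Cohort-level statistics: dichotomization, rank tests, Kaplan–Meier /
log-rank, and Cox proportional-hazards regression.

Continuous tissue metrics are dichotomized at the cohort median into
"low (0–50%)" and "high (> 50%)" groups (ties at the median go low, so
the low group includes the 50th percentile).  Survival association is
assessed by Kaplan–Meier curves with the log-rank test and by cause-
specific Cox regression (univariable and multivariable) with Wald tests
per term.

The Cox fitter is a Newton–Raphson maximizer of the partial likelihood
with Breslow tie handling by default (Efron selectable), convergence at
|Δ log-likelihood| < 1e-9, and explicit diagnostics on monotone
likelihood (complete separation) instead of a silently huge coefficient.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class NotEstimableError(RuntimeError):
    """A statistic cannot be computed for this input (flagged, not silent)."""


class CoxConvergenceError(RuntimeError):
    """Partial-likelihood maximization failed (separation or divergence)."""


# ---------------------------------------------------------------------------
# dichotomization & rank statistics
# ---------------------------------------------------------------------------

def dichotomize(values) -> pd.Series:
    """Median split: low iff value <= cohort median, high otherwise.

    Missing values stay missing.  The median is computed on non-missing
    values only.
    """
    s = pd.Series(values, dtype=float)
    valid = s.dropna()
    if len(valid) < 2:
        raise ValueError("need >= 2 non-missing values to dichotomize")
    cutoff = float(valid.median())
    out = pd.Series(
        np.where(s <= cutoff, "low", "high"), index=s.index, dtype=object
    )
    out[s.isna()] = np.nan
    return out


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration.

    Enumerates all n! pairings of the y-ranks against the x-ranks
    (midranks for ties); feasible for the n <= 10 regime it is used in.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry_c)
    if denom == 0:
        return float("nan")
    obs = abs(rx_c @ ry_c / denom)
    n = len(x)
    count = total = 0
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 40320 or total + len(chunk) == math.factorial(n):
            idx = np.array(chunk)
            rhos = (ry_c[idx] @ rx_c) / denom
            count += int(np.sum(np.abs(rhos) >= obs - 1e-12))
            total += len(chunk)
            chunk = []
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p value.

    Midranks for ties; p from the t approximation for n > 10 and from
    exact permutation enumeration for n <= 10.  Constant input yields
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 4:
        raise ValueError("need >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if len(x) <= 10:
        p = _exact_spearman_p(x, y)
    else:
        p = float(res.pvalue)
    return rho, p


def group_tests(values, groups) -> float:
    """Two-sided p for a distributional difference across groups.

    Mann–Whitney U for two groups, Kruskal–Wallis for more; both
    tie-corrected.  An empty group is an error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if len(samples) == 2:
        return float(stats.mannwhitneyu(*samples, alternative="two-sided").pvalue)
    return float(stats.kruskal(*samples).pvalue)


# ---------------------------------------------------------------------------
# Kaplan–Meier + log-rank
# ---------------------------------------------------------------------------

def km_logrank(time, event, group) -> dict:
    """Product-limit curves per group and the log-rank test across groups.

    Returns ``{"curves": DataFrame(group, time, survival), "chi2": float,
    "p": float, "n": int, "n_events": int}``.  Raises
    :class:`NotEstimableError` when no events occurred at all.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise NotEstimableError("no events: log-rank undefined")
    frames = []
    for g in pd.unique(group):
        sel = group == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", g)
        frames.append(sf)
    lr = multivariate_logrank_test(time, group, event)
    return {
        "curves": pd.concat(frames, ignore_index=True),
        "chi2": float(lr.test_statistic),
        "p": float(lr.p_value),
        "n": int(len(time)),
        "n_events": int(event.sum()),
    }


# ---------------------------------------------------------------------------
# Cox proportional hazards (partial likelihood, Newton–Raphson)
# ---------------------------------------------------------------------------

def cox_partial_loglik(
    beta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Log partial likelihood at ``beta`` (Breslow or Efron ties)."""
    ll, _, _ = _cox_ll_grad_hess(beta, time, event, x, ties)
    return ll


def _cox_ll_grad_hess(beta, time, event, x, ties):
    n, p = x.shape
    order = np.argsort(-time, kind="stable")  # descending: risk sets by cumsum
    t = time[order]
    d = event[order]
    xs = x[order]
    eta = xs @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * xs, axis=0)
    s2 = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        # subjects j+1..i share this time; risk set = indices 0..i
        tied = [k for k in range(j + 1, i + 1) if d[k] == 1]
        m = len(tied)
        if m:
            xsum = xs[tied].sum(axis=0)
            ll += float(eta[tied].sum())
            grad += xsum
            S0, S1, S2 = s0[i], s1[i], s2[i]
            if ties == "breslow" or m == 1:
                ll -= m * math.log(S0)
                grad -= m * S1 / S0
                hess -= m * (S2 / S0 - np.outer(S1, S1) / S0**2)
            elif ties == "efron":
                w_t = w[tied].sum()
                s1_t = (w[tied, None] * xs[tied]).sum(axis=0)
                s2_t = (
                    w[tied, None, None]
                    * (xs[tied][:, :, None] * xs[tied][:, None, :])
                ).sum(axis=0)
                for l in range(m):
                    f = l / m
                    d0 = S0 - f * w_t
                    d1 = S1 - f * s1_t
                    d2 = S2 - f * s2_t
                    ll -= math.log(d0)
                    grad -= d1 / d0
                    hess -= d2 / d0 - np.outer(d1, d1) / d0**2
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, grad, hess


@dataclass
class SurvivalResult:
    """Fitted Cox model: per-term hazard ratios with Wald inference."""

    table: pd.DataFrame  # term, coef, se, hr, ci_low, ci_high, z, p
    loglik: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    model: str = "cox"
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    reference_levels: dict = field(default_factory=dict)

    def hr(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "hr"])


def cox_fit(
    time,
    event,
    covariates: pd.DataFrame,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> SurvivalResult:
    """Cox proportional-hazards fit by Newton–Raphson with step halving.

    ``covariates`` must already be numerically coded (see
    :func:`design_matrix` for categorical coding with explicit reference
    levels).  HR = exp(coef); 95% CI = exp(coef ± 1.96·se); p per term
    from the Wald z statistic.  Convergence is declared when the log
    partial likelihood changes by less than ``tol``; monotone likelihood
    (complete separation) raises :class:`CoxConvergenceError`.
    """
    x = np.asarray(covariates, dtype=float)
    terms = list(covariates.columns)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if x.ndim != 2 or len(time) != len(event) or len(time) != x.shape[0]:
        raise ValueError("time, event and covariates must align")
    if event.sum() < 1:
        raise NotEstimableError("no events: Cox model not estimable")
    if np.isnan(x).any():
        raise ValueError("covariates contain missing values; drop or impute first")
    # center covariates for numerical stability (coefficients unaffected)
    x_mean = x.mean(axis=0)
    xc = x - x_mean

    beta = np.zeros(x.shape[1])
    ll, grad, hess = _cox_ll_grad_hess(beta, time, event, xc, ties)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_ll_grad_hess(new_beta, time, event, xc, ties)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_ll_grad_hess(
                new_beta, time, event, xc, ties
            )
            halvings += 1
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > 20):
            raise CoxConvergenceError(
                "monotone partial likelihood (complete separation): "
                f"|coef| exploding for terms {terms}"
            )
        if abs(delta) < tol:
            break
    else:
        raise CoxConvergenceError(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)):
        raise CoxConvergenceError("non-finite standard errors")
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": terms,
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "z": z,
            "p": p,
        }
    )
    return SurvivalResult(
        table=table,
        loglik=float(ll),
        n=len(time),
        n_events=int(event.sum()),
        ties=ties,
        n_iter=n_iter,
    )


def design_matrix(
    df: pd.DataFrame, terms: dict[str, str | None]
) -> tuple[pd.DataFrame, dict]:
    """Numeric design matrix with explicit reference levels.

    ``terms`` maps column names to the reference level for categorical
    columns (dummy-coded against that level) or ``None`` for columns
    used as numeric.  Rows with missing values in any term are dropped
    (complete-case analysis); the returned frame preserves the surviving
    index so time/event can be aligned.
    """
    cols = {}
    refs = {}
    sub = df[list(terms)].dropna()
    for col, ref in terms.items():
        s = sub[col]
        if ref is None:
            cols[col] = s.astype(float)
        else:
            levels = [l for l in pd.unique(s) if l != ref]
            if ref not in set(pd.unique(s)):
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            refs[col] = ref
            for level in sorted(map(str, levels)):
                cols[f"{col}[{level}]"] = (s.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=sub.index), refs


def subgroup_forest(
    df: pd.DataFrame,
    group_col: str,
    time_col: str = "time",
    event_col: str = "event",
    subgroups: dict[str, pd.Series] | None = None,
    ties: str = "breslow",
) -> pd.DataFrame:
    """Univariable Cox HR of ``group_col`` (high vs low) per subgroup.

    ``subgroups`` maps subgroup names to boolean masks over ``df``; the
    default is the whole cohort.  Subgroups with fewer than 2 cases, a
    single group level, or no events are reported with
    ``estimable=False`` rather than fitted.
    """
    if subgroups is None:
        subgroups = {"all": pd.Series(True, index=df.index)}
    rows = []
    for name, mask in subgroups.items():
        sub = df[mask.reindex(df.index, fill_value=False)]
        sub = sub.dropna(subset=[group_col, time_col, event_col])
        x = (sub[group_col].astype(str) == "high").astype(float).to_frame("high")
        row = {
            "subgroup": name,
            "n": len(sub),
            "n_events": int(sub[event_col].sum()) if len(sub) else 0,
            "estimable": False,
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
        }
        if len(sub) >= 2 and row["n_events"] >= 1 and x["high"].nunique() == 2:
            try:
                res = cox_fit(sub[time_col], sub[event_col], x, ties=ties)
                t = res.table.iloc[0]
                row.update(
                    estimable=True,
                    hr=t["hr"],
                    ci_low=t["ci_low"],
                    ci_high=t["ci_high"],
                    p=t["p"],
                )
            except (CoxConvergenceError, NotEstimableError):
                pass
        rows.append(row)
    return pd.DataFrame(rows)
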