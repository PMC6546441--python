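"""Inference stack for the behavioral assays and pigmentation scores.

Cohorts of 20 same-sex butterflies are photographed 15 times at 4-minute
intervals in a cage tiled with brown and green patches.  Two binomial
"two-vector" responses are built per cohort x time point:

* preference — (arrivals to brown, arrivals to green),
* activity   — (relocated, stationary).

Both are modelled with binomial-logit mixed models (cohort and time point
as crossed random intercepts); pigmentation scores use gaussian models.
Minimum adequate models come from BIC backward elimination; p-values from
likelihood-ratio tests and from a parametric bootstrap; post-hoc pairwise
comparisons use Tukey-style familywise adjustment with a compact letter
display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    BinomialMixedModel,
    FitError,
    GaussianMixedModel,
    MixedModelResults,
    MixedModelSpec,
    build_design,
    FACTOR_LEVELS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "build_preference_response",
    "build_activity_response",
    "fit_glmm",
    "fit_lmm",
    "lmm_term_ftests",
    "lrt",
    "parametric_bootstrap_p",
    "backward_select_bic",
    "posthoc_pairwise",
    "test_vs_even",
]

COHORT_COLUMNS = [
    "cohort_id",
    "sex",
    "Td",
    "Ta",
    "timepoint",
    "on_brown",
    "on_green",
    "arrivals_brown",
    "arrivals_green",
    "stationary",
    "relocated",
]

# full starting model: all main effects and two-way interactions
FULL_FIXED = (
    ("Td",),
    ("Ta",),
    ("Sex",),
    ("Td", "Ta"),
    ("Td", "Sex"),
    ("Ta", "Sex"),
)


@dataclass
class TestResult:
    statistic: float
    df: int
    p_lrt: float
    p_boot: float | None = None
    nsim: int | None = None
    n_failed: int = 0


def _validate_cohort_table(obs: pd.DataFrame, cohort_size: int = 20) -> None:
    missing = set(COHORT_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    later = obs[obs["timepoint"] > 1]
    counts = later[["on_brown", "on_green", "arrivals_brown", "arrivals_green", "stationary", "relocated"]]
    bad = (
        (counts < 0).any(axis=1)
        | (later["on_brown"] + later["on_green"] > cohort_size)
        | (later["arrivals_brown"] + later["arrivals_green"] > later["relocated"])
    )
    if bad.any():
        rows = later.index[bad].tolist()
        raise ValueError(f"cohort-table invariant violated at rows {rows[:20]}")


def _two_vector(obs: pd.DataFrame, success_col: str, failure_col: str, role: str) -> pd.DataFrame:
    """One (successes, failures) row per cohort x timepoint, t >= 2."""
    _validate_cohort_table(obs)
    out = obs[obs["timepoint"] > 1].copy()
    out = out.rename(columns={"cohort_id": "cohort", "sex": "Sex"})
    out["successes"] = out[success_col].astype(float)
    out["failures"] = out[failure_col].astype(float)
    trials = out["successes"] + out["failures"]
    n_zero = int((trials == 0).sum())
    if n_zero:
        logger.info("%s response: dropping %d zero-trial rows", role, n_zero)
    out = out[trials > 0]
    cols = ["cohort", "timepoint", "Td", "Ta", "Sex", "successes", "failures"]
    out = out[cols].reset_index(drop=True)
    out.attrs["role"] = role
    out.attrs["n_zero_trial_dropped"] = n_zero
    return out


def build_preference_response(obs: pd.DataFrame) -> pd.DataFrame:
    """Arrivals-to-brown vs arrivals-to-green, per cohort and time point."""
    return _two_vector(obs, "arrivals_brown", "arrivals_green", "preference")


def build_activity_response(obs: pd.DataFrame) -> pd.DataFrame:
    """Relocated vs stationary individuals, per cohort and time point."""
    return _two_vector(obs, "relocated", "stationary", "activity")


def fit_glmm(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelResults:
    return BinomialMixedModel.from_spec(data, spec).fit()


def fit_lmm(data: pd.DataFrame, spec: MixedModelSpec) -> MixedModelResults:
    return GaussianMixedModel.from_spec(data, spec).fit()


def lmm_term_ftests(data: pd.DataFrame, spec: MixedModelSpec) -> pd.DataFrame:
    """Model-comparison F tests for each removable fixed term of a gaussian model.

    For the default no-random-term model this is the classical ANOVA
    partial F with residual degrees of freedom; the df convention is
    isolated here so an alternative (e.g. Satterthwaite) can be swapped in.
    """
    full = GaussianMixedModel.from_spec(data, spec)
    X_full, _ = build_design(data, spec.fixed)
    y = np.asarray(data[spec.response], dtype=float)
    n, p_full = X_full.shape
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    ssr_full = float(np.sum((y - X_full @ beta) ** 2))
    df_resid = n - p_full
    rows = []
    for term in spec.removable_terms():
        reduced = spec.drop(term)
        X_red, _ = build_design(data, reduced.fixed)
        beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        ssr_red = float(np.sum((y - X_red @ beta_r) ** 2))
        ddf = p_full - X_red.shape[1]
        degenerate = ssr_full <= 1e-12 * max(float(np.sum(y * y)), 1e-30)
        if degenerate or df_resid <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat = ((ssr_red - ssr_full) / ddf) / (ssr_full / df_resid)
            p = float(stats.f.sf(f_stat, ddf, df_resid))
        rows.append({"term": ":".join(term), "F": f_stat, "df1": ddf, "df2": df_resid, "p": p})
    del full  # design validation only
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# likelihood-ratio machinery
# ---------------------------------------------------------------------------


def lrt(fit_full: MixedModelResults, fit_reduced: MixedModelResults) -> TestResult:
    """Likelihood-ratio test of nested fits (chi-square reference)."""
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValueError("reduced spec is not nested in the full spec")
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("fits use different numbers of rows")
    statistic = max(2.0 * (fit_full.llf - fit_reduced.llf), 0.0)
    df = fit_full.df_model - fit_reduced.df_model
    if df <= 0:
        return TestResult(statistic=statistic, df=0, p_lrt=1.0)
    return TestResult(statistic=statistic, df=df, p_lrt=float(stats.chi2.sf(statistic, df)))


def parametric_bootstrap_p(
    fit_full: MixedModelResults,
    fit_reduced: MixedModelResults,
    nsim: int = 999,
    seed: int = 0,
) -> TestResult:
    """Parametric-bootstrap p-value for a nested model comparison.

    Response tables are simulated from the fitted reduced model (with fresh
    random-intercept draws), both models are refitted on each, and the
    add-one p-value ``(1 + #{sim >= obs}) / (nsim + 1)`` is returned.
    Simulation refits that fail are dropped and counted; more than 10%
    failures is an error.
    """
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    base = lrt(fit_full, fit_reduced)
    rng = np.random.default_rng(seed)
    model_red: BinomialMixedModel = fit_reduced.model
    model_full: BinomialMixedModel = fit_full.model
    n_exceed = 0
    n_failed = 0
    n_done = 0
    for _ in range(nsim):
        y_sim = model_red.simulate(fit_reduced, rng)
        try:
            sim_red = model_red.refit_like(y_sim).fit(
                start_sigma=list(fit_reduced.vc.values()) or None
            )
            sim_full = model_full.refit_like(y_sim).fit(
                start_sigma=list(fit_full.vc.values()) or None
            )
        except (FitError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        stat_sim = max(2.0 * (sim_full.llf - sim_red.llf), 0.0)
        n_done += 1
        if stat_sim >= base.statistic:
            n_exceed += 1
    if n_failed > 0.1 * nsim:
        raise FitError(f"parametric bootstrap: {n_failed}/{nsim} simulation refits failed")
    p_boot = (1.0 + n_exceed) / (n_done + 1.0)
    return TestResult(
        statistic=base.statistic,
        df=base.df,
        p_lrt=base.p_lrt,
        p_boot=p_boot,
        nsim=n_done,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# BIC backward elimination
# ---------------------------------------------------------------------------


def _term_sort_key(term):
    # higher-order terms first, then alphabetical
    return (-len(term), ":".join(term))


def backward_select_bic(data: pd.DataFrame, full: MixedModelSpec, fitter=None):
    """Backward elimination from the full model by BIC.

    At each step the single removable term (marginality respected:
    interactions go before their main effects) whose removal lowers BIC
    most is dropped; elimination stops when no removal lowers BIC.
    Ties break toward the higher-order term, then alphabetically.
    Returns ``(selected_results, trace)`` where the trace records each
    step's candidate BICs.
    """
    if fitter is None:
        fitter = fit_glmm if full.family == "binomial" else fit_lmm
    current_spec = full
    current_fit = fitter(data, current_spec)
    trace = [{"action": "start", "fixed": current_spec.fixed, "bic": current_fit.bic}]
    while True:
        candidates = sorted(current_spec.removable_terms(), key=_term_sort_key)
        best = None
        for term in candidates:
            reduced = current_spec.drop(term)
            try:
                fit_r = fitter(data, reduced)
            except FitError:
                trace.append({"action": "fit-failed", "term": term})
                raise
            if fit_r.bic < current_fit.bic - 1e-9 and (best is None or fit_r.bic < best[2].bic - 1e-9):
                best = (term, reduced, fit_r)
        if best is None:
            break
        term, current_spec, current_fit = best
        trace.append({"action": "drop", "term": term, "fixed": current_spec.fixed, "bic": current_fit.bic})
    return current_fit, trace


# ---------------------------------------------------------------------------
# post-hoc pairwise comparisons (Tukey-style) and letter display
# ---------------------------------------------------------------------------


def _cell_design_rows(fit: MixedModelResults, factors):
    """Averaged design rows (marginal means) for each grouping-factor cell."""
    spec = fit.spec
    model_factors = sorted({f for t in spec.fixed for f in t})
    for f in factors:
        if f not in model_factors:
            raise ValueError(f"factor {f!r} is not in the fitted model")
    other = [f for f in model_factors if f not in factors]
    cells = []
    from itertools import product

    for levels in product(*[FACTOR_LEVELS[f] for f in factors]):
        grid = pd.DataFrame(
            list(product(*[FACTOR_LEVELS[f] for f in other])) or [()],
            columns=other,
        )
        for f, lev in zip(factors, levels):
            grid[f] = lev
        X, _ = build_design(grid, spec.fixed)
        cells.append(("|".join(f"{f}={l}" for f, l in zip(factors, levels)), X.mean(axis=0)))
    return cells


def _compact_letters(names, significant_pairs):
    """Insert-and-absorb compact letter display: groups sharing a letter
    are not significantly different."""
    groups = [set(names)]
    for a, b in significant_pairs:
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: min(names.index(n) for n in g))
    letters = {n: "" for n in names}
    for i, g in enumerate(groups):
        for n in names:
            if n in g:
                letters[n] += chr(ord("a") + i)
    return letters


def posthoc_pairwise(
    fit: MixedModelResults,
    factors,
    alpha: float = 0.05,
    n_mc: int = 40000,
    seed: int = 20190410,
) -> pd.DataFrame:
    """All pairwise contrasts of estimated marginal means on the link scale.

    Familywise adjustment follows the Tukey idea: each contrast's z
    statistic is referred to the distribution of the maximum absolute
    component of a multivariate normal with the contrasts' correlation
    structure (evaluated by a seeded quasi-deterministic Monte Carlo, so
    the adjustment is reproducible).  A compact letter display at ``alpha``
    is attached: cells sharing a letter are not significantly different.
    """
    cells = _cell_design_rows(fit, factors)
    names = [c[0] for c in cells]
    L = np.array([c[1] for c in cells])
    beta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    pairs = [(i, j) for i in range(len(cells)) for j in range(i + 1, len(cells))]
    K = np.array([L[i] - L[j] for i, j in pairs])
    est = K @ beta
    var = np.einsum("ij,jk,ik->i", K, V, K)
    se = np.sqrt(np.maximum(var, 1e-300))
    z = est / se
    p_unadj = 2.0 * stats.norm.sf(np.abs(z))
    if len(pairs) == 1:
        p_adj = p_unadj.copy()
    else:
        cov_z = (K @ V @ K.T) / np.outer(se, se)
        cov_z = (cov_z + cov_z.T) / 2 + 1e-10 * np.eye(len(pairs))
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(np.zeros(len(pairs)), cov_z, size=n_mc, method="cholesky")
        max_abs = np.max(np.abs(draws), axis=1)
        # shared draws make the adjusted p monotone in |z| and >= unadjusted
        p_adj = np.array([np.mean(max_abs >= abs(zi)) for zi in z])
        p_adj = np.maximum(p_adj, p_unadj)
    sig = [(names[i], names[j]) for (i, j), p in zip(pairs, p_adj) if p < alpha]
    letters = _compact_letters(names, sig)
    out = pd.DataFrame(
        {
            "contrast": [f"{names[i]} - {names[j]}" for i, j in pairs],
            "estimate": est,
            "se": se,
            "z": z,
            "p_unadj": p_unadj,
            "p_adj": p_adj,
        }
    )
    out.attrs["letters"] = letters
    out.attrs["emmeans"] = pd.Series(L @ beta, index=names)
    return out


def test_vs_even(successes: int, failures: int) -> float:
    """Exact two-sided binomial test of a 1:1 ratio on aggregated counts."""
    n = successes + failures
    if n < 1:
        raise ValueError("need at least one trial")
    return float(stats.binomtest(int(successes), int(n), 0.5).pvalue)
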