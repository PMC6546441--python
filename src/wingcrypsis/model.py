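"""Mixed models for cohort behavior and wing pigmentation.

Two model classes in the statsmodels mould:

* :class:`BinomialMixedModel` — binomial responses (successes, failures)
  with a logit link, fixed treatment effects and crossed random intercepts
  (cohort, time point).  Fitted by maximum likelihood with a Laplace
  approximation to the random-intercept integrals.
* :class:`GaussianMixedModel` — gaussian responses (pigmentation scores);
  the same machinery, for which the Laplace approximation is exact.  With
  no random term it reduces to ordinary least squares.

Both use the "spherical" parametrisation: random intercepts are written
``u_f = sigma_f * b_f`` with ``b_f ~ N(0, I)``, so the linear predictor is
``eta = X beta + sum_f sigma_f Z_f b_f`` and the boundary ``sigma_f = 0``
is an ordinary point of the profiled likelihood.  The inner problem
(mode of ``beta, b`` given the sigmas) is solved by penalised Newton
iterations; the per-observation Hessian has at most a handful of dense
columns plus one large diagonal random-factor block, which is eliminated
by a Schur complement so each step costs O(n) regardless of the number of
cohorts.  The outer problem (the sigmas, plus the residual variance in the
gaussian case) is a bounded quasi-Newton search on the Laplace objective.

Estimation is ML throughout (never REML) so that likelihood-ratio tests
and BIC comparisons across fixed-effect structures are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

__all__ = [
    "MixedModelSpec",
    "BinomialMixedModel",
    "GaussianMixedModel",
    "MixedModelResults",
    "FitError",
]

# canonical order of the experimental factors and their non-reference levels
FACTOR_LEVELS = {"Td": ("27", "19"), "Ta": ("27", "19"), "Sex": ("M", "F")}
_FACTOR_ORDER = ("Td", "Ta", "Sex")


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification and design building
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedModelSpec:
    """Which terms enter the model.

    ``fixed`` is a tuple of terms, each term a tuple of factor names, e.g.
    ``(("Td",), ("Ta",), ("Sex",), ("Ta", "Sex"))``.  Marginality is
    enforced: an interaction may appear only if both main effects do.
    ``random`` names the random-intercept grouping columns.
    """

    response: str = "y"
    fixed: tuple = ()
    random: tuple = ()
    family: str = "binomial"

    def __post_init__(self):
        fixed = tuple(tuple(t) for t in self.fixed)
        object.__setattr__(self, "fixed", fixed)
        object.__setattr__(self, "random", tuple(self.random))
        if self.family not in ("binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        mains = {t[0] for t in fixed if len(t) == 1}
        for term in fixed:
            if len(term) > 2:
                raise ValueError("only main effects and two-way interactions are supported")
            if len(term) == 2 and not set(term) <= mains:
                raise ValueError(
                    f"marginality violation: interaction {term} without both main effects"
                )

    def drop(self, term) -> "MixedModelSpec":
        term = tuple(term)
        if term not in self.fixed:
            raise ValueError(f"term {term} not in spec")
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))

    def removable_terms(self):
        """Fixed terms whose removal respects marginality."""
        in_interaction = set()
        for t in self.fixed:
            if len(t) == 2:
                in_interaction.update(t)
        return [t for t in self.fixed if len(t) == 2 or t[0] not in in_interaction]

    def is_nested_in(self, other: "MixedModelSpec") -> bool:
        return (
            set(self.fixed) <= set(other.fixed)
            and set(self.random) <= set(other.random)
            and self.family == other.family
        )


def _canonical_term(term):
    return tuple(sorted(term, key=_FACTOR_ORDER.index))


def _indicator(data: pd.DataFrame, factor: str) -> np.ndarray:
    ref, alt = FACTOR_LEVELS[factor]
    col = data[factor].astype(str)
    bad = ~col.isin([ref, alt])
    if bad.any():
        raise ValueError(f"unknown {factor} levels: {sorted(col[bad].unique())}")
    return (col == alt).to_numpy(dtype=float)


def build_design(data: pd.DataFrame, fixed_terms) -> tuple:
    """Treatment-coded design matrix (reference cell Td=27, Ta=27, Sex=M)."""
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for term in (_canonical_term(t) for t in fixed_terms):
        ind = np.ones(len(data))
        for f in term:
            ind = ind * _indicator(data, f)
        alt_names = [f"{f}[{FACTOR_LEVELS[f][1]}]" for f in term]
        cols.append(ind)
        names.append(":".join(alt_names))
    X = np.column_stack(cols)
    return X, names


# ---------------------------------------------------------------------------
# inner (mode-finding) machinery, shared by both families
# ---------------------------------------------------------------------------


class _RandomStructure:
    """Integer codes and level counts for up to two crossed random factors.

    The factor with the most levels is the one eliminated diagonally in the
    Newton solve; any other factor's columns are carried densely alongside
    the fixed effects.
    """

    def __init__(self, data: pd.DataFrame, random_names):
        self.names = tuple(random_names)
        self.codes = []
        self.nlev = []
        self.levels = []
        for name in self.names:
            codes, levels = pd.factorize(data[name], sort=True)
            if len(levels) < 2:
                raise FitError(f"random factor {name!r} needs >= 2 levels")
            self.codes.append(np.asarray(codes))
            self.nlev.append(len(levels))
            self.levels.append(levels)
        if len(self.names) > 2:
            raise FitError("at most two crossed random factors are supported")
        # index of the 'big' (diagonally eliminated) factor
        self.big = int(np.argmax(self.nlev)) if self.names else None
        self.small = (1 - self.big) if len(self.names) == 2 else None


def _assemble(X, W, codes_s, qs, ss, codes_b, qb, sb):
    """Blocks of the penalised Hessian: top-dense B, coupling C, diagonal D."""
    p = X.shape[1]
    k = p + (qs or 0)
    B = np.zeros((k, k))
    XW = X * W[:, None]
    B[:p, :p] = XW.T @ X
    if qs:
        for j in range(p):
            B[j, p:] = ss * np.bincount(codes_s, weights=W * X[:, j], minlength=qs)
        B[p:, :p] = B[:p, p:].T
        B[p:, p:] = np.diag(ss * ss * np.bincount(codes_s, weights=W, minlength=qs) + 1.0)
    if codes_b is None:
        return B, None, None
    D = sb * sb * np.bincount(codes_b, weights=W, minlength=qb) + 1.0
    C = np.zeros((k, qb))
    for j in range(p):
        C[j] = sb * np.bincount(codes_b, weights=W * X[:, j], minlength=qb)
    if qs:
        cross = np.zeros((qs, qb))
        np.add.at(cross, (codes_s, codes_b), W)
        C[p:] = ss * sb * cross
    return B, C, D


def _schur_solve(B, C, D, g_top, g_big):
    """Solve [[B, C], [C', diag(D)]] [x; z] = [g_top; g_big]."""
    from scipy.linalg import cho_factor, cho_solve

    if C is None:
        cf = cho_factor(B)
        return cho_solve(cf, g_top), None, B
    Cd = C / D
    S = B - Cd @ C.T
    cf = cho_factor(S)
    x = cho_solve(cf, g_top - Cd @ g_big)
    z = (g_big - C.T @ x) / D
    return x, z, S


class _Family:
    constant = 0.0

    def mu_w(self, eta):  # (mean response, newton weights)
        raise NotImplementedError

    def loglik(self, eta):
        raise NotImplementedError

    def residual(self, eta):
        raise NotImplementedError


class _Binomial(_Family):
    def __init__(self, successes, trials):
        self.y = np.asarray(successes, dtype=float)
        self.m = np.asarray(trials, dtype=float)
        self.constant = float(
            np.sum(gammaln(self.m + 1) - gammaln(self.y + 1) - gammaln(self.m - self.y + 1))
        )

    def mu_w(self, eta):
        p = expit(eta)
        return self.m * p, np.maximum(self.m * p * (1.0 - p), 1e-10)

    def loglik(self, eta):
        # y*eta - m*log(1+e^eta), stable for large |eta|
        return float(np.sum(self.y * eta - self.m * np.logaddexp(0.0, eta)))

    def residual(self, eta):
        return self.y - self.m * expit(eta)


class _Gaussian(_Family):
    def __init__(self, y, variance):
        self.y = np.asarray(y, dtype=float)
        self.var = float(variance)

    def mu_w(self, eta):
        return eta, np.full(eta.shape, 1.0 / self.var)

    def loglik(self, eta):
        n = len(self.y)
        return float(
            -0.5 * np.sum((self.y - eta) ** 2) / self.var
            - 0.5 * n * np.log(2.0 * np.pi * self.var)
        )

    def residual(self, eta):
        return (self.y - eta) / self.var


def _inner_newton(family, X, rs: _RandomStructure, sigmas, beta, b_list, tol=1e-9, maxiter=100):
    """Penalised Newton for the joint mode of (beta, b) given the sigmas.

    Returns the mode, the conditional log-likelihood there, the log-det of
    the random-effect block of the penalised Hessian, and the Schur
    complement used for fixed-effect covariances.
    """
    p = X.shape[1]
    F = len(rs.names)
    ib, isml = rs.big, rs.small
    codes_b = rs.codes[ib] if F else None
    qb = rs.nlev[ib] if F else 0
    sb = sigmas[ib] if F else 0.0
    codes_s = rs.codes[isml] if isml is not None else None
    qs = rs.nlev[isml] if isml is not None else 0
    ss = sigmas[isml] if isml is not None else 0.0

    def eta_of(beta, b_list):
        eta = X @ beta
        for f in range(F):
            eta = eta + sigmas[f] * b_list[f][rs.codes[f]]
        return eta

    def penalty(b_list):
        return 0.5 * sum(float(b @ b) for b in b_list)

    eta = eta_of(beta, b_list)
    obj = family.loglik(eta) - penalty(b_list)
    converged = False
    S = None
    for _ in range(maxiter):
        r = family.residual(eta)
        _, W = family.mu_w(eta)
        g_top = np.empty(p + qs)
        g_top[:p] = X.T @ r
        if qs:
            g_top[p:] = ss * np.bincount(codes_s, weights=r, minlength=qs) - b_list[isml]
        g_big = (
            sb * np.bincount(codes_b, weights=r, minlength=qb) - b_list[ib]
            if F
            else None
        )
        gmax = np.max(np.abs(g_top))
        if F:
            gmax = max(gmax, np.max(np.abs(g_big)))
        B, C, D = _assemble(X, W, codes_s, qs, ss, codes_b, qb, sb)
        try:
            d_top, d_big, S = _schur_solve(B, C, D, g_top, g_big)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular penalised Hessian: {exc}") from exc
        if gmax < 1e-7:
            converged = True
            break
        # step halving on the penalised objective
        step = 1.0
        for _half in range(30):
            beta_new = beta + step * d_top[:p]
            b_new = [np.array(b) for b in b_list]
            if qs:
                b_new[isml] = b_list[isml] + step * d_top[p:]
            if F:
                b_new[ib] = b_list[ib] + step * d_big
            eta_new = eta_of(beta_new, b_new)
            obj_new = family.loglik(eta_new) - penalty(b_new)
            if obj_new >= obj - 1e-12:
                break
            step *= 0.5
        delta = max(np.max(np.abs(d_top)) * step, np.max(np.abs(d_big)) * step if F else 0.0)
        beta, b_list, eta, obj = beta_new, b_new, eta_new, obj_new
        if delta < 1e-9:
            converged = True
            break
    # log-determinant of the random-effect block only (fixed effects profiled)
    logdet = 0.0
    if F:
        _, W = family.mu_w(eta)
        Db = sb * sb * np.bincount(codes_b, weights=W, minlength=qb) + 1.0
        logdet = float(np.sum(np.log(Db)))
        if qs:
            Hss = np.diag(ss * ss * np.bincount(codes_s, weights=W, minlength=qs) + 1.0)
            cross = np.zeros((qs, qb))
            np.add.at(cross, (codes_s, codes_b), W)
            cross *= ss * sb
            Ssmall = Hss - (cross / Db) @ cross.T
            sign, ld = np.linalg.slogdet(Ssmall)
            if sign <= 0:
                raise FitError("indefinite random-effect Hessian")
            logdet += float(ld)
    llf_cond = family.loglik(eta) + family.constant
    return beta, b_list, eta, llf_cond, penalty(b_list), logdet, S, converged


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class MixedModelResults:
    """Fitted mixed model: estimates, uncertainties, diagnostics.

    ``params``/``bse`` are indexed by term name; ``vc`` maps each random
    factor to its fitted intercept standard deviation; ``llf`` is the
    (Laplace) maximised log-likelihood; ``df_model`` counts all free
    parameters (fixed coefficients + variance components), so
    ``bic = -2 llf + df_model * log(nobs)``.
    """

    model: object
    spec: MixedModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    vc: dict
    scale: float  # residual variance (gaussian) or 1.0
    llf: float
    nobs: int
    df_model: int
    converged: bool
    boundary: bool
    diverged: bool
    random_modes: dict = field(default_factory=dict)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.df_model * np.log(self.nobs)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} ({self.spec.family}, ML-Laplace)",
            f"nobs = {self.nobs}   llf = {self.llf:.4f}   BIC = {self.bic:.4f}",
            f"converged = {self.converged}   boundary = {self.boundary}"
            + ("   DIVERGED" if self.diverged else ""),
            "",
            f"{'term':<22}{'coef':>10}{'se':>10}{'z':>8}",
        ]
        for name in self.params.index:
            z = self.params[name] / self.bse[name] if self.bse[name] > 0 else np.nan
            lines.append(
                f"{name:<22}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}{z:>8.2f}"
            )
        if self.vc:
            lines.append("")
            for name, sd in self.vc.items():
                lines.append(f"random intercept sd({name}) = {sd:.4f}")
        if self.spec.family == "gaussian":
            lines.append(f"residual sd = {np.sqrt(self.scale):.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# binomial model
# ---------------------------------------------------------------------------


class BinomialMixedModel:
    """Binomial-logit mixed model for (successes, failures) count pairs."""

    def __init__(self, successes, failures, data, spec: MixedModelSpec):
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self.successes = np.asarray(successes, dtype=float)
        self.failures = np.asarray(failures, dtype=float)
        if np.any(self.successes < 0) or np.any(self.failures < 0):
            raise ValueError("counts must be non-negative")
        self.trials = self.successes + self.failures
        if np.any(self.trials <= 0):
            raise ValueError("rows with zero trials must be dropped before fitting")
        self.X, self.exog_names = build_design(self.data, spec.fixed)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise FitError(f"rank-deficient design: terms {self.exog_names} are aliased")
        self.rs = _RandomStructure(self.data, spec.random)

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: MixedModelSpec) -> "BinomialMixedModel":
        return cls(data["successes"], data["failures"], data, spec)

    # -- fitting ----------------------------------------------------------

    def _profiled(self, sigmas, state):
        fam = _Binomial(self.successes, self.trials)
        beta, b_list = state["beta"], [np.array(b) for b in state["b"]]
        out = _inner_newton(fam, self.X, self.rs, sigmas, beta, b_list)
        beta, b_list, eta, llf_cond, pen, logdet, S, conv = out
        state.update(beta=beta, b=b_list, S=S, eta=eta, conv=conv)
        return llf_cond - pen - 0.5 * logdet

    def fit(self, start_sigma=None, maxiter=200) -> MixedModelResults:
        F = len(self.rs.names)
        p = self.X.shape[1]
        state = {
            "beta": np.zeros(p),
            "b": [np.zeros(q) for q in self.rs.nlev],
            "S": None,
            "conv": False,
        }
        if F == 0:
            llf = self._profiled(np.zeros(0), state)
            sig_hat = np.zeros(0)
        else:
            x0 = np.full(F, 0.5) if start_sigma is None else np.asarray(start_sigma, float)

            def nll(s):
                return -self._profiled(np.abs(s), state)

            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, 15.0)] * F,
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7, "eps": 1e-5},
            )
            sig_hat = np.abs(res.x)
            llf = -nll(sig_hat)  # refresh state at the optimum
        S = state["S"]
        cov_top = np.linalg.inv(S)
        cov_beta = cov_top[:p, :p]
        eta = state["eta"]
        diverged = (not state["conv"]) or bool(np.max(np.abs(state["beta"])) > 15) or bool(
            np.max(np.abs(eta)) > 30
        )
        vc = {name: float(sig_hat[f]) for f, name in enumerate(self.rs.names)}
        boundary = any(sd < 1e-4 for sd in vc.values())
        params = pd.Series(state["beta"], index=self.exog_names)
        bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names)
        modes = {
            name: sig_hat[f] * state["b"][f] for f, name in enumerate(self.rs.names)
        }
        return MixedModelResults(
            model=self,
            spec=self.spec,
            params=params,
            bse=bse,
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            vc=vc,
            scale=1.0,
            llf=llf,
            nobs=len(self.successes),
            df_model=p + F,
            converged=bool(state["conv"]),
            boundary=boundary,
            diverged=diverged,
            random_modes=modes,
        )

    # -- simulation (for the parametric bootstrap) ------------------------

    def simulate(self, results: MixedModelResults, rng: np.random.Generator) -> np.ndarray:
        """Draw a new successes vector from the fitted model (new random effects)."""
        eta = self.X @ results.params.to_numpy()
        for f, name in enumerate(self.rs.names):
            u = rng.normal(0.0, results.vc[name], self.rs.nlev[f])
            eta = eta + u[self.rs.codes[f]]
        return rng.binomial(self.trials.astype(int), expit(eta)).astype(float)

    def refit_like(self, successes) -> "BinomialMixedModel":
        successes = np.asarray(successes, dtype=float)
        return BinomialMixedModel(successes, self.trials - successes, self.data, self.spec)


# ---------------------------------------------------------------------------
# gaussian model
# ---------------------------------------------------------------------------


class GaussianMixedModel:
    """Gaussian mixed model (ML). With no random term this is OLS."""

    def __init__(self, y, data, spec: MixedModelSpec):
        if spec.family != "gaussian":
            raise ValueError("GaussianMixedModel requires family='gaussian'")
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        self.X, self.exog_names = build_design(self.data, spec.fixed)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise FitError(f"rank-deficient design: terms {self.exog_names} are aliased")
        self.rs = _RandomStructure(self.data, spec.random)

    @classmethod
    def from_spec(cls, data: pd.DataFrame, spec: MixedModelSpec) -> "GaussianMixedModel":
        return cls(data[spec.response], data, spec)

    def _profiled(self, sigmas, var, state):
        fam = _Gaussian(self.y, var)
        out = _inner_newton(fam, self.X, self.rs, sigmas, state["beta"], state["b"])
        beta, b_list, eta, llf_cond, pen, logdet, S, conv = out
        state.update(beta=beta, b=b_list, S=S, eta=eta, conv=conv)
        return llf_cond - pen - 0.5 * logdet

    def fit(self) -> MixedModelResults:
        F = len(self.rs.names)
        p = self.X.shape[1]
        n = len(self.y)
        state = {"beta": np.zeros(p), "b": [np.zeros(q) for q in self.rs.nlev], "S": None}
        # OLS residual variance as the starting scale
        beta0, res0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        ssr0 = float(np.sum((self.y - self.X @ beta0) ** 2))
        var0 = max(ssr0 / n, 1e-12)
        if F == 0:
            llf = self._profiled(np.zeros(0), var0, state)
            sig_hat, var_hat = np.zeros(0), var0
        else:
            x0 = np.concatenate([np.full(F, np.sqrt(var0)), [np.log(var0)]])

            def nll(th):
                return -self._profiled(np.abs(th[:F]), np.exp(th[F]), state)

            res = optimize.minimize(
                nll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            sig_hat = np.abs(res.x[:F])
            var_hat = float(np.exp(res.x[F]))
            llf = -nll(res.x)
        S = state["S"]
        cov_beta = np.linalg.inv(S)[:p, :p]
        vc = {name: float(sig_hat[f]) for f, name in enumerate(self.rs.names)}
        params = pd.Series(state["beta"], index=self.exog_names)
        return MixedModelResults(
            model=self,
            spec=self.spec,
            params=params,
            bse=pd.Series(np.sqrt(np.diag(cov_beta)), index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            vc=vc,
            scale=var_hat,
            llf=llf,
            nobs=n,
            df_model=p + F + 1,
            converged=True,
            boundary=any(sd < 1e-4 for sd in vc.values()),
            diverged=False,
        )
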