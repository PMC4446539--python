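"""Two-level linear mixed models for gradient data.

The model for subject ``i`` with response vector ``y_i`` (one entry per
stimulus), fixed design ``X_i`` (polynomial terms in ``d``, the moderator
``u`` and cross-level interactions) and random design ``Z_i`` (subset of
``1, d, d^2``) is

    y_i = X_i beta + Z_i b_i + eps_i,
    b_i ~ N(0, Psi),   eps_i ~ N(0, sigma2 I),   independent,

so marginally ``y_i ~ N(X_i beta, V_i)`` with ``V_i = Z_i Psi Z_i' +
sigma2 I``.  Estimation maximizes the profiled Gaussian likelihood:
writing ``V_i = sigma2 (Z_i Lam Lam' Z_i' + I)`` with ``Lam`` the
Cholesky factor of the *relative* covariance ``Psi / sigma2``, both
``beta`` (by GLS) and ``sigma2`` (in closed form) are profiled out, and
only the free entries of ``Lam`` are optimized numerically.  The raw
Cholesky parameterization keeps ``Psi`` positive semi-definite by
construction and lets variances hit the zero boundary.

The optimizer is deterministic (Nelder-Mead from moment-based starting
values, tolerance 1e-8 on the deviance); there is no stochastic search.

Because the marginal covariance of every subject with the same stimulus
set is identical, subjects are grouped by random-design pattern and the
deviance is evaluated from pattern-level sufficient statistics, making
each evaluation O(k^3) rather than O(n k^3).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "LmmFit",
    "LrtResult",
    "LadderResult",
    "fit_lmm",
    "wald_tests",
    "lrt",
    "information_criteria",
    "predict_subjects",
    "model_ladder",
]

# canonical term ordering for fixed and random parts
FIXED_TERMS = ("1", "d", "d2", "u", "d:u", "d2:u")
RANDOM_TERMS = ("1", "d", "d2")
_REQUIRES = {"d2": {"d"}, "d:u": {"d", "u"}, "d2:u": {"d2", "d:u"}}


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the fixed and random parts, and how to estimate.

    Terms are named in a small formula language: ``1`` (intercept), ``d``,
    ``d2`` (quadratic in the stimulus dimension), ``u`` (subject
    covariate), ``d:u`` and ``d2:u`` (cross-level interactions).  Any
    higher-order term requires its lower-order parents.
    """

    fixed_terms: tuple = ("1", "d")
    random_terms: tuple = ("1",)
    estimation: str = "ML"

    def __post_init__(self):
        fixed = tuple(t for t in FIXED_TERMS if t in self.fixed_terms)
        rand = tuple(t for t in RANDOM_TERMS if t in self.random_terms)
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        unknown = set(self.random_terms) - set(RANDOM_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms {sorted(unknown)}")
        if fixed and "1" not in fixed:
            raise ValueError("the fixed part must include the intercept '1'")
        if rand and "1" not in rand:
            raise ValueError("a non-empty random part must include '1'")
        for t in fixed:
            missing = _REQUIRES.get(t, set()) - set(fixed)
            if missing:
                raise ValueError(
                    f"term {t!r} requires lower-order term(s) {sorted(missing)}")
        if "d2" in rand and "d" not in rand:
            raise ValueError("random 'd2' requires random 'd'")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        object.__setattr__(self, "fixed_terms", fixed)
        object.__setattr__(self, "random_terms", rand)

    @classmethod
    def from_formula(cls, fixed: str = "1+d", random: str = "1",
                     estimation: str = "ML") -> "ModelSpec":
        """Parse specs like ``fixed='1+d+u+d:u', random='1+d'``."""
        def parse(s):
            s = s.strip()
            if s in ("", "0"):
                return ()
            return tuple(t.strip() for t in s.split("+"))
        return cls(fixed_terms=parse(fixed), random_terms=parse(random),
                   estimation=estimation)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (set(self.fixed_terms) <= set(other.fixed_terms)
                and set(self.random_terms) <= set(other.random_terms))


def _columns(terms, d: np.ndarray, u: np.ndarray) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "1":
            cols.append(np.ones_like(d))
        elif t == "d":
            cols.append(d)
        elif t == "d2":
            cols.append(d ** 2)
        elif t == "u":
            cols.append(u)
        elif t == "d:u":
            cols.append(d * u)
        elif t == "d2:u":
            cols.append(d ** 2 * u)
    return np.column_stack(cols) if cols else np.empty((len(d), 0))


@dataclass
class LmmFit:
    """One fitted linear mixed model."""

    spec: ModelSpec
    fixed_names: tuple
    beta: np.ndarray            #: fixed-effect estimates, in fixed_names order
    se: np.ndarray              #: Wald standard errors
    z: np.ndarray               #: Wald statistics (standard-normal reference)
    p: np.ndarray               #: two-sided Wald p-values
    psi: np.ndarray             #: random-effects covariance, response scale
    sigma2: float               #: level-1 residual variance
    loglik: float
    deviance: float             #: -2 loglik (ML) / -2 restricted loglik (REML)
    n_obs: int
    n_clusters: int
    n_params: int               #: fixed + free (co)variance parameters
    converged: bool
    boundary: bool = False      #: a variance component collapsed to ~0
    subjects: np.ndarray = field(default=None, repr=False)  # ids seen at fit

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.deviance + self.n_params * math.log(self.n_obs)

    @property
    def fixed_estimates(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.fixed_names, "estimate": self.beta,
                             "se": self.se, "z": self.z, "p": self.p})

    def coef(self, term: str) -> float:
        return float(self.beta[self.fixed_names.index(term)])

    def coef_p(self, term: str) -> float:
        return float(self.p[self.fixed_names.index(term)])

    def vc_dict(self) -> dict:
        out = {"sigma2_e": self.sigma2}
        names = self.spec.random_terms
        for a, ta in enumerate(names):
            out[f"tau2_{a}"] = float(self.psi[a, a])
            for b in range(a):
                out[f"tau_{b}{a}"] = float(self.psi[b, a])
        return out


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio (deviance difference) test between nested ML fits."""

    delta_deviance: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# internal: grouped data and profiled deviance

class _Groups:
    """Per-pattern sufficient statistics for the profiled deviance.

    Subjects sharing the same random-design rows (same stimulus set)
    share the same relative covariance ``V* = Z Lam Lam' Z' + I``, so the
    quadratic forms entering the deviance can be accumulated per pattern:
    T1[k,l,p,q] = sum_i X_i[k,p] X_i[l,q], T2[k,l,p] = sum_i X_i[k,p] y_i[l],
    T3[k,l] = sum_i y_i[k] y_i[l].
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        subj, inv = np.unique(data["subject"].to_numpy(), return_inverse=True)
        order = np.argsort(inv, kind="stable")
        d = data["d"].to_numpy(dtype=float)[order]
        u = data["u"].to_numpy(dtype=float)[order]
        y = data["y"].to_numpy(dtype=float)[order]
        inv = inv[order]
        counts = np.bincount(inv)
        self.subjects = subj
        self.n_clusters = len(subj)
        self.n_obs = len(y)
        self.p = len(spec.fixed_terms)
        self.q = len(spec.random_terms)

        X = _columns(spec.fixed_terms, d, u)
        Z = _columns(spec.random_terms, d, u)

        starts = np.concatenate([[0], np.cumsum(counts)])
        keys = {}
        for i in range(self.n_clusters):
            sl = slice(starts[i], starts[i + 1])
            key = (counts[i], d[sl].tobytes())
            keys.setdefault(key, []).append(i)
        self.patterns = []
        for (ni, _), idx in keys.items():
            rows = np.concatenate([np.arange(starts[i], starts[i + 1])
                                   for i in idx])
            X3 = X[rows].reshape(len(idx), ni, self.p)
            Y2 = y[rows].reshape(len(idx), ni)
            Zu = Z[starts[idx[0]]:starts[idx[0]] + ni]
            self.patterns.append({
                "m": len(idx), "ni": ni, "Z": Zu, "idx": np.array(idx),
                "X3": X3, "Y2": Y2,
                "T1": np.einsum("mkp,mlq->klpq", X3, X3),
                "T2": np.einsum("mkp,ml->klp", X3, Y2),
                "T3": np.einsum("mk,ml->kl", Y2, Y2),
            })
        # retained for EB predictions / starting values
        self._X, self._Z, self._y = X, Z, y
        self._starts, self._counts = starts, counts

    def profiled(self, lam: np.ndarray):
        """Log|V*| sum, GLS beta, relative RSS and X'V*^-1 X for given Lam."""
        p = self.p
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        for pat in self.patterns:
            Zu = pat["Z"]
            if self.q:
                Vs = Zu @ (lam @ lam.T) @ Zu.T
                Vs[np.diag_indices_from(Vs)] += 1.0
            else:
                Vs = np.eye(pat["ni"])
            c, low = linalg.cho_factor(Vs, lower=True, check_finite=False)
            logdet += pat["m"] * 2.0 * np.sum(np.log(np.diag(c)))
            Vinv = linalg.cho_solve((c, low), np.eye(pat["ni"]),
                                    check_finite=False)
            XtViX += np.einsum("kl,klpq->pq", Vinv, pat["T1"])
            XtViy += np.einsum("kl,klp->p", Vinv, pat["T2"])
            ytViy += float(np.einsum("kl,kl->", Vinv, pat["T3"]))
        beta = np.linalg.solve(XtViX, XtViy)
        rss = ytViy - float(XtViy @ beta)
        return logdet, beta, max(rss, 1e-300), XtViX


def _vech_to_lower(theta: np.ndarray, q: int) -> np.ndarray:
    lam = np.zeros((q, q))
    lam[np.tril_indices(q)] = theta
    return lam


def _deviance(theta: np.ndarray, groups: _Groups, reml: bool) -> float:
    q = groups.q
    lam = _vech_to_lower(theta, q) if q else np.empty((0, 0))
    try:
        logdet, beta, rss, XtViX = groups.profiled(lam)
    except (np.linalg.LinAlgError, ValueError):
        return 1e12
    N, p = groups.n_obs, groups.p
    if reml:
        sign, ld_a = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        s2 = rss / (N - p)
        return logdet + ld_a + (N - p) * (1.0 + math.log(2 * math.pi * s2))
    s2 = rss / N
    return logdet + N * (1.0 + math.log(2 * math.pi * s2))


def _start_values(groups: _Groups) -> np.ndarray:
    """Moment-based start: per-subject OLS coefficient spread vs noise."""
    q = groups.q
    X, Z, y = groups._X, groups._Z, groups._y
    starts, counts = groups._starts, groups._counts
    # global OLS for a residual-variance baseline
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = float(resid @ resid) / max(len(y) - X.shape[1], 1)
    coefs = []
    for i in range(groups.n_clusters):
        sl = slice(starts[i], starts[i + 1])
        if counts[i] > q + 1:
            b, *_ = np.linalg.lstsq(Z[sl], y[sl], rcond=None)
            coefs.append(b)
    if len(coefs) > q + 1:
        B = np.array(coefs)
        psi0 = np.cov(B.T).reshape(q, q)
    else:
        psi0 = 0.5 * s2 * np.eye(q)
    rel = psi0 / s2
    w, v = np.linalg.eigh((rel + rel.T) / 2)
    rel = v @ np.diag(np.clip(w, 1e-3, None)) @ v.T
    lam0 = np.linalg.cholesky(rel)
    return lam0[np.tril_indices(q)]


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LmmFit:
    """Fit the mixed model by profiled ML or REML.

    ``data`` is a long-format gradient dataset (columns subject, d, u, y);
    unbalanced data (missing rows) is tolerated.  Non-convergence and
    boundary fits (a variance component at zero) are flagged on the
    result, never silently ignored.
    """
    groups = _Groups(data, spec)
    q = groups.q
    if groups.n_clusters < q + 1:
        raise ValueError(f"need at least {q + 1} subjects to estimate a "
                         f"{q}-dimensional random-effects covariance")
    reml = spec.estimation == "REML"

    if q == 0:
        dev = _deviance(np.empty(0), groups, reml)
        _, beta, rss, XtViX = groups.profiled(np.empty((0, 0)))
        s2 = rss / (groups.n_obs - groups.p if reml else groups.n_obs)
        lam = np.empty((0, 0))
        converged, boundary = True, False
    else:
        theta0 = _start_values(groups)
        res = optimize.minimize(
            _deviance, theta0, args=(groups, reml), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 200 * len(theta0) ** 2 + 400,
                     "maxfev": 10 ** 5})
        if not res.success:  # one deterministic restart from the best point
            res2 = optimize.minimize(
                _deviance, res.x, args=(groups, reml), method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-9,
                         "maxiter": 2000, "maxfev": 10 ** 5})
            res = res2 if res2.fun <= res.fun else res
        theta = res.x
        dev = float(res.fun)
        converged = bool(res.success) and dev < 1e11
        lam = _vech_to_lower(theta, q)
        _, beta, rss, XtViX = groups.profiled(lam)
        s2 = rss / (groups.n_obs - groups.p if reml else groups.n_obs)
        scale = max(np.max(np.abs(np.diag(lam))), 1.0)
        boundary = bool(np.min(np.abs(np.diag(lam))) < 1e-5 * scale)

    psi = s2 * (lam @ lam.T) if q else np.zeros((0, 0))
    cov_beta = s2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    n_vc = q * (q + 1) // 2 + 1      # free covariance entries + sigma2
    fit = LmmFit(
        spec=spec, fixed_names=tuple(spec.fixed_terms),
        beta=beta, se=se, z=z, p=pvals,
        psi=psi, sigma2=float(s2),
        loglik=-0.5 * dev, deviance=dev,
        n_obs=groups.n_obs, n_clusters=groups.n_clusters,
        n_params=groups.p + n_vc,
        converged=converged, boundary=boundary,
        subjects=groups.subjects,
    )
    if not converged:
        warnings.warn("mixed-model optimizer did not converge; estimates are "
                      "returned but flagged", stacklevel=2)
    return fit


def wald_tests(fit: LmmFit) -> pd.DataFrame:
    """Per-coefficient Wald tests against the standard normal.

    SEs come from the inverse GLS information sum(X' V^-1 X); no
    small-sample df correction is applied (the statistic is referred to
    N(0,1)).  Boundary or non-converged fits are flagged unreliable.
    """
    out = fit.fixed_estimates.copy()
    out["reliable"] = fit.converged and not fit.boundary
    return out


def lrt(fit_small: LmmFit, fit_big: LmmFit) -> LrtResult:
    """Deviance-difference test between two nested ML fits.

    The difference in deviance is referred to chi-square with df equal to
    the number of additional free parameters (covariances count).  Note
    that for variance components this naive reference is conservative at
    the boundary; that behavior is intentional and documented rather than
    corrected.
    """
    for f in (fit_small, fit_big):
        if f.spec.estimation != "ML":
            raise ValueError("deviance comparisons require ML fits (REML "
                             "deviances with different fixed parts are not "
                             "comparable)")
    if fit_small.n_obs != fit_big.n_obs or fit_small.n_clusters != fit_big.n_clusters:
        raise ValueError("fits must be on identical data")
    if not fit_small.spec.is_nested_in(fit_big.spec):
        raise ValueError("models are not nested")
    df = fit_big.n_params - fit_small.n_params
    if df <= 0:
        if fit_small.spec == fit_big.spec:
            return LrtResult(delta_deviance=abs(fit_small.deviance
                                                - fit_big.deviance),
                             df=0, p_value=1.0)
        raise ValueError("the larger model must add free parameters")
    delta = fit_small.deviance - fit_big.deviance
    if delta < -1e-3:
        warnings.warn(f"larger model fit worse by {-delta:.4g} deviance "
                      "units; optimizer trouble likely", stacklevel=2)
    delta = max(delta, 0.0)
    return LrtResult(delta_deviance=float(delta), df=df,
                     p_value=float(stats.chi2.sf(delta, df)))


def information_criteria(fit: LmmFit) -> tuple[float, float]:
    """(AIC, BIC) = deviance + 2p, deviance + p ln(N) with N the level-1 count."""
    if fit.spec.estimation != "ML":
        raise ValueError("information criteria are reported for ML fits")
    return fit.aic, fit.bic


def predict_subjects(fit: LmmFit, data: pd.DataFrame) -> pd.DataFrame:
    """Empirical-Bayes (BLUP) per-row conditional predictions.

    For subjects seen at fit time, b_i = Psi Z_i' V_i^-1 (y_i - X_i beta)
    shrinks the subject's own deviations toward zero, and the prediction
    is X_i beta + Z_i b_i.  Unseen subjects get the population curve with
    ``population_only=True``.
    """
    q = len(fit.spec.random_terms)
    rel = fit.psi / fit.sigma2 if q else np.zeros((0, 0))
    known = set(fit.subjects.tolist())
    out = np.empty(len(data))
    pop_only = np.zeros(len(data), dtype=bool)
    d = data["d"].to_numpy(dtype=float)
    u = data["u"].to_numpy(dtype=float)
    y = data["y"].to_numpy(dtype=float)
    X = _columns(fit.spec.fixed_terms, d, u)
    Z = _columns(fit.spec.random_terms, d, u)
    fixed_pred = X @ fit.beta
    for s, idx in data.groupby("subject").indices.items():
        if s not in known or q == 0:
            out[idx] = fixed_pred[idx]
            pop_only[idx] = s not in known
            continue
        Zi = Z[idx]
        Vs = Zi @ rel @ Zi.T + np.eye(len(idx))
        b = rel @ Zi.T @ np.linalg.solve(Vs, y[idx] - fixed_pred[idx])
        out[idx] = fixed_pred[idx] + Zi @ b
    res = data[["subject", "d"]].copy()
    res["y_hat"] = out
    res["population_only"] = pop_only
    return res


# ---------------------------------------------------------------------------
# the seven-model ladder

#: fixed / random parts of the canonical model sequence for gradient data
LADDER_SPECS = {
    1: ("1+d", "1"),
    2: ("1+d", "1+d"),
    3: ("1+d+u+d:u", "1+d"),
    4: ("1+d+d2", "1+d"),
    5: ("1+d+d2", "1+d+d2"),
    6: ("1+d+d2+u+d:u+d2:u", "1+d"),
    7: ("1+d+d2+u+d:u", "1+d"),
}
#: the nested comparisons run along the ladder: (label, smaller, larger)
LADDER_COMPARISONS = [
    ("random slope (2 vs 1)", 1, 2),
    ("moderator fixed effects (3 vs 2)", 2, 3),
    ("quadratic fixed effect (4 vs 2)", 2, 4),
    ("random quadratic (5 vs 4)", 4, 5),
    ("moderator with quadratic (6 vs 4)", 4, 6),
    ("drop d2:u (7 vs 6)", 7, 6),
]


@dataclass
class LadderResult:
    """All seven fits plus the nested deviance comparisons."""

    fits: dict
    comparisons: list  #: (label, small_idx, big_idx, LrtResult)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, fit in self.fits.items():
            row = {"model": i,
                   "fixed": "+".join(fit.fixed_names),
                   "random": "+".join(fit.spec.random_terms),
                   "deviance": fit.deviance, "AIC": fit.aic, "BIC": fit.bic,
                   "n_params": fit.n_params, "converged": fit.converged}
            rows.append(row)
        return pd.DataFrame(rows)


def model_ladder(data: pd.DataFrame, estimation: str = "ML") -> LadderResult:
    """Fit the canonical sequence of seven gradient models.

    The ladder grows from a random-intercept model with a linear
    gradient to a quadratic gradient with a moderator: random slope,
    moderator main effect and cross-level interaction, quadratic fixed
    term, random quadratic term, moderator-by-quadratic interaction, and
    the final model dropping that interaction.  Each extension is tested
    with a deviance-difference (LRT) against its parent.
    """
    fits = {}
    for i, (fx, rd) in LADDER_SPECS.items():
        fits[i] = fit_lmm(data, ModelSpec.from_formula(fx, rd, estimation))
    comps = []
    for label, a, b in LADDER_COMPARISONS:
        comps.append((label, a, b, lrt(fits[a], fits[b])))
    return LadderResult(fits=fits, comparisons=comps)
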