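"""Longitudinal inference: beta-binomial join-point mixed model and GEE.

Three pieces of machinery:

* ``fit_betabin_joinpoint`` — maximum marginal likelihood for the model

      y_ij | n_ij, b_i ~ BetaBinomial(n_ij, mu_ij, phi_g)
      logit(mu_ij)      = b0_g + b1_g * t_ij + b2_g * (t_ij - knot)_+ + b_i
      b_i               ~ Normal(0, sigma_b^2)

  where y_ij is the target-taxon count, n_ij the sequencing depth, t_ij
  days of age, g the subject's outcome group.  The beta-binomial is
  parameterised by mean mu and a single positive dispersion phi with
  shape parameters (mu/phi, (1-mu)/phi); phi -> 0 recovers the binomial.
  The join-point basis uses a truncated line (t - knot)_+ so b2 is the
  slope *change* at the knot and the curve is continuous there.  The
  scalar random intercept is integrated out by adaptive Gauss-Hermite
  quadrature (nodes recentred at each subject's posterior mode and
  rescaled by its curvature).  Standard errors come from the observed
  information; contrasts of the population-average relative abundance at
  a chosen day are Wald tests via the delta method.

* ``select_knot`` — the knot-placement heuristic: fit a cubic to the
  logit of day-pooled relative abundance (weighted by depth), set the
  first derivative to zero and solve, keeping the real root inside the
  observed day range closest to the median day.

* ``fit_gee_lognormal`` — marginal group comparisons of a positive
  outcome (pairwise Morisita-Horn, bacterial load) on the log scale with
  generalized estimating equations: exchangeable working correlation
  within subject, cluster-robust sandwich standard errors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from .core_data import SubjectSeries

__all__ = [
    "JoinPointSpec",
    "JoinPointFit",
    "GeeFit",
    "KnotSelection",
    "FitError",
    "betabinom_logpmf",
    "select_knot",
    "fit_betabin_joinpoint",
    "fit_gee_lognormal",
    "zero_inflation_check",
    "marginal_loglik_trapezoid",
]

logger = logging.getLogger(__name__)

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


class FitError(RuntimeError):
    """Optimizer failed to converge; carries diagnostic detail."""


# ---------------------------------------------------------------------------
# Beta-binomial primitives
# ---------------------------------------------------------------------------


def betabinom_logpmf(y, n, mu, phi):
    """Log pmf of the beta-binomial in mean/dispersion form.

    Shapes are (mu/phi, (1-mu)/phi); phi below 1e-8 is treated as the
    binomial limit.  Broadcasts over all arguments.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, 1 - 1e-12)
    phi = np.asarray(phi, dtype=float)
    comb = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    binom = comb + y * np.log(mu) + (n - y) * np.log1p(-mu)
    if np.all(phi < 1e-8):
        return binom
    a = mu / np.maximum(phi, 1e-12)
    b = (1 - mu) / np.maximum(phi, 1e-12)
    bb = (
        comb
        + _betaln(y + a, n - y + b)
        - _betaln(a, b)
    )
    return np.where(phi < 1e-8, binom, bb)


def _betaln(a, b):
    return gammaln(a) + gammaln(b) - gammaln(a + b)


# ---------------------------------------------------------------------------
# Knot selection
# ---------------------------------------------------------------------------


@dataclass
class KnotSelection:
    """Outcome of the cubic-derivative knot search."""

    knot_day: float
    roots: list[float]  # all real stationary points inside the day range
    cubic_coefs: np.ndarray  # np.polyfit order (highest power first)
    fallback: bool = False

    def __float__(self) -> float:
        return float(self.knot_day)


def select_knot(days, target_counts, totals, default: float = 10.0) -> KnotSelection:
    """Place the join-point knot where a cubic fit's derivative vanishes.

    Pools counts per distinct day across all subjects/groups, takes the
    logit of pooled relative abundance, fits a cubic in day weighted by
    the pooled depth, and solves d/dt = 0.  The real root inside the
    observed day range wins; with two in-range roots, the one closest to
    the median day (all roots are still reported).  No in-range real root
    falls back to ``default`` with a logged warning.
    """
    days = np.asarray(days, dtype=float)
    y = np.asarray(target_counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(np.unique(days)) < 4:
        raise ValueError("need >= 4 distinct day values to fit a cubic")
    uniq = np.unique(days)
    y_d = np.array([y[days == d].sum() for d in uniq])
    n_d = np.array([n[days == d].sum() for d in uniq])
    p = y_d / n_d
    # empirical-logit correction only where the plain logit is undefined
    boundary = (p <= 0) | (p >= 1)
    p = np.where(boundary, (y_d + 0.5) / (n_d + 1.0), p)
    logit_p = np.log(p / (1 - p))
    coefs = np.polyfit(uniq, logit_p, deg=3, w=np.sqrt(n_d))
    deriv = np.polyder(np.poly1d(coefs))
    roots = deriv.r
    # double roots surface numerically as conjugate pairs with tiny imaginary
    # parts, so realness is judged relative to the root's magnitude
    real = [float(r.real) for r in roots if abs(r.imag) <= 1e-3 * (1 + abs(r.real))]
    lo, hi = uniq.min(), uniq.max()
    in_range = [r for r in real if lo <= r <= hi]
    if not in_range:
        logger.warning(
            "no stationary point of the cubic inside [%g, %g]; "
            "falling back to knot = %g", lo, hi, default,
        )
        return KnotSelection(knot_day=default, roots=in_range, cubic_coefs=coefs, fallback=True)
    median_day = float(np.median(days))
    knot = min(in_range, key=lambda r: abs(r - median_day))
    return KnotSelection(knot_day=knot, roots=sorted(in_range), cubic_coefs=coefs)


# ---------------------------------------------------------------------------
# Beta-binomial join-point mixed model
# ---------------------------------------------------------------------------


@dataclass
class JoinPointSpec:
    """What to model: which taxon, where the knot sits, which groups."""

    taxon_id: str
    knot_day: float = 10.0
    groups: tuple[str, ...] = ()
    #: optional extra sample-level fixed effects, indexed by sample_id
    covariates: pd.DataFrame | None = None


@dataclass
class JoinPointFit:
    """Fitted join-point mixed model for one taxon."""

    taxon_id: str
    knot_day: float
    groups: tuple[str, ...]
    #: group -> (intercept, pre-knot slope, post-knot slope change), logit scale
    coef: dict[str, tuple[float, float, float]]
    sigma_b: float
    #: group -> beta-binomial dispersion
    phi: dict[str, float]
    covariate_coef: dict[str, float]
    loglik: float
    param_names: list[str]
    params: np.ndarray
    cov_params: np.ndarray  # observed-information covariance
    n_subjects: int
    n_obs: int
    converged: bool
    boundary_notes: list[str] = field(default_factory=list)

    def se(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.sqrt(np.diag(self.cov_params))))

    def mu_population(self, group: str, days) -> np.ndarray:
        """Population-average relative abundance curve (fraction scale).

        Marginalises expit(eta + b) over b ~ N(0, sigma_b^2) with
        Gauss-Hermite quadrature.
        """
        return _marginal_mu(np.asarray(days, dtype=float), self.coef[group],
                            self.knot_day, self.sigma_b)

    def contrast_at_day(self, day: float, group_a: str, group_b: str,
                        scale: str = "ra") -> dict:
        """Wald contrast of group mean abundance at ``day``.

        ``scale='ra'`` compares population-average relative abundance
        (delta method); ``scale='logit'`` compares linear predictors.
        """
        theta = self.params

        def value(th):
            f = _unpack(th, self.groups, len(self.covariate_coef))
            if scale == "ra":
                ma = _marginal_mu(np.array([day]), f["coef"][group_a], self.knot_day, f["sigma_b"])[0]
                mb = _marginal_mu(np.array([day]), f["coef"][group_b], self.knot_day, f["sigma_b"])[0]
                return ma - mb
            ea = _linpred(np.array([day]), f["coef"][group_a], self.knot_day)[0]
            eb = _linpred(np.array([day]), f["coef"][group_b], self.knot_day)[0]
            return ea - eb

        est = value(theta)
        grad = _num_grad(value, theta)
        var = float(grad @ self.cov_params @ grad)
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.inf
        return {
            "day": day,
            "groups": (group_a, group_b),
            "scale": scale,
            "estimate": float(est),
            "se": float(se),
            "z": float(z),
            "p": float(2 * norm.sf(abs(z))),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy parameter table: term, group, estimate, SE."""
        ses = np.sqrt(np.diag(self.cov_params))
        rows = []
        for name, est, se_ in zip(self.param_names, self.params, ses):
            term, _, group = name.partition(":")
            rows.append({"term": term, "group": group or "", "estimate": est, "se": se_})
        return pd.DataFrame(rows)


def _linpred(t, coef, knot):
    b0, b1, b2 = coef
    return b0 + b1 * t + b2 * np.clip(t - knot, 0.0, None)


def _marginal_mu(t, coef, knot, sigma_b):
    eta = _linpred(t, coef, knot)
    if sigma_b < 1e-8:
        return expit(eta)
    b = np.sqrt(2.0) * sigma_b * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    return expit(eta[:, None] + b[None, :]) @ w


def _num_grad(fun, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _unpack(theta, groups, n_cov):
    ng = len(groups)
    coef = {}
    for i, g in enumerate(groups):
        coef[g] = (theta[3 * i], theta[3 * i + 1], theta[3 * i + 2])
    pos = 3 * ng
    cov_coef = theta[pos:pos + n_cov]
    pos += n_cov
    sigma_b = theta[pos]
    phi = {g: theta[pos + 1 + i] for i, g in enumerate(groups)}
    return {"coef": coef, "cov_coef": cov_coef, "sigma_b": sigma_b, "phi": phi}


class _ModelData:
    """Flattened per-observation arrays, grouped by subject."""

    def __init__(self, series_list: list[SubjectSeries], spec: JoinPointSpec):
        groups = spec.groups or tuple(dict.fromkeys(s.group for s in series_list))
        gidx = {g: i for i, g in enumerate(groups)}
        taxon_pos = None
        y, n, t, subj, grp_obs, xcov = [], [], [], [], [], []
        subj_group = []
        for si, s in enumerate(series_list):
            if taxon_pos is None:
                if spec.taxon_id not in s.taxon_ids:
                    raise ValueError(f"taxon {spec.taxon_id!r} not in taxon index")
                taxon_pos = s.taxon_ids.index(spec.taxon_id)
            subj_group.append(gidx[s.group])
            tot = s.counts.sum(axis=1)
            for j in range(s.n_samples):
                y.append(s.counts[j, taxon_pos])
                n.append(tot[j])
                t.append(float(s.days[j]))
                subj.append(si)
                grp_obs.append(gidx[s.group])
                if spec.covariates is not None:
                    xcov.append(spec.covariates.loc[s.sample_ids[j]].to_numpy(dtype=float))
        self.groups = groups
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.t = np.asarray(t)
        self.tk = np.clip(self.t - spec.knot_day, 0.0, None)
        self.subj = np.asarray(subj)
        self.grp_obs = np.asarray(grp_obs)
        self.subj_group = np.asarray(subj_group)
        self.n_subjects = len(series_list)
        self.starts = np.searchsorted(self.subj, np.arange(self.n_subjects))
        self.xcov = np.asarray(xcov) if xcov else np.zeros((len(y), 0))
        self.n_cov = self.xcov.shape[1]
        self.cov_names = list(spec.covariates.columns) if spec.covariates is not None else []
        self._bhat_cache: np.ndarray | None = None  # warm start for the mode search

    def eta_fixed(self, theta):
        f = _unpack(theta, self.groups, self.n_cov)
        b0 = np.array([f["coef"][g][0] for g in self.groups])
        b1 = np.array([f["coef"][g][1] for g in self.groups])
        b2 = np.array([f["coef"][g][2] for g in self.groups])
        eta = b0[self.grp_obs] + b1[self.grp_obs] * self.t + b2[self.grp_obs] * self.tk
        if self.n_cov:
            eta = eta + self.xcov @ f["cov_coef"]
        phi_obs = np.array([f["phi"][g] for g in self.groups])[self.grp_obs]
        return eta, phi_obs, f["sigma_b"]

    def _subject_sums(self, logp_obs_rows):
        """Sum per-observation log probabilities by subject (rows kept)."""
        return np.add.reduceat(logp_obs_rows, self.starts, axis=-1)

    def loglik_subjects(self, theta, method: str = "agh", grid_width: float = 8.0,
                        grid_points: int = 2001):
        """Per-subject marginal log-likelihoods.

        ``agh``: adaptive Gauss-Hermite (15 nodes) recentred at each
        subject's posterior mode.  ``trapezoid``: dense brute-force
        trapezoidal integration over the random effect — the slow oracle.
        """
        eta, phi_obs, sigma = self.eta_fixed(theta)
        sigma = max(sigma, 0.0)

        def joint_logf(b_subj):
            # b_subj: (..., S) -> per-subject joint log density at b
            b_obs = np.take(b_subj, self.subj, axis=-1)
            lp = betabinom_logpmf(self.y, self.n, expit(eta + b_obs), phi_obs)
            out = self._subject_sums(lp)
            prior = -0.5 * (b_subj / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi))
            return out + prior

        if sigma < 1e-8:
            lp = betabinom_logpmf(self.y, self.n, expit(eta), phi_obs)
            return self._subject_sums(lp)

        if method == "trapezoid":
            grid = np.linspace(-grid_width * sigma, grid_width * sigma, grid_points)
            logf = joint_logf(grid[:, None] * np.ones(self.n_subjects))
            db = grid[1] - grid[0]
            # log of trapezoid rule via logsumexp with end-point half-weights
            logw = np.full(grid_points, np.log(db))
            logw[0] -= np.log(2)
            logw[-1] -= np.log(2)
            return logsumexp(logf + logw[:, None], axis=0)

        # --- adaptive GH: mode search (warm-started Newton), then rescale ---
        h = 1e-4
        if self._bhat_cache is None:
            coarse = np.linspace(-6 * sigma - 2, 6 * sigma + 2, 25)
            logf_grid = joint_logf(coarse[:, None] * np.ones(self.n_subjects))
            bhat = coarse[np.argmax(logf_grid, axis=0)]
        else:
            bhat = self._bhat_cache  # warm start from the previous evaluation
        # Newton to a tight tolerance so the likelihood is a deterministic
        # function of theta (the warm start must not leak into the value)
        for _ in range(40):
            f0, fp, fm = joint_logf(np.stack([bhat, bhat + h, bhat - h]))
            g1 = (fp - fm) / (2 * h)
            g2 = (fp - 2 * f0 + fm) / h**2
            # Newton in concave regions; plain gradient steps elsewhere
            step = np.clip(
                np.where(g2 < -1e-12, -g1 / np.where(g2 < -1e-12, g2, -1.0),
                         np.sign(g1) * 0.5),
                -2.0, 2.0,
            )
            bhat = bhat + step
            if np.max(np.abs(step)) < 2e-6:
                break
        bhat = bhat - step  # value consistent with the last curvature estimate
        self._bhat_cache = bhat
        scale = 1.0 / np.sqrt(np.maximum(-g2, 1e-8))
        nodes = bhat[None, :] + np.sqrt(2.0) * scale[None, :] * _GH_NODES[:, None]
        logf = joint_logf(nodes)
        logw = np.log(_GH_WEIGHTS)[:, None] + _GH_NODES[:, None] ** 2
        return logsumexp(logf + logw, axis=0) + np.log(np.sqrt(2.0) * scale)


def marginal_loglik_trapezoid(series_list, spec: JoinPointSpec, theta,
                              grid_points: int = 4001, grid_width: float = 10.0):
    """Brute-force marginal log-likelihood by dense trapezoid integration."""
    data = _ModelData(series_list, spec)
    return float(
        data.loglik_subjects(np.asarray(theta, dtype=float), method="trapezoid",
                             grid_points=grid_points, grid_width=grid_width).sum()
    )


def _start_values(data: _ModelData) -> np.ndarray:
    """Moment-style starts: per-group empirical-logit least squares."""
    theta = []
    for gi, g in enumerate(data.groups):
        m = data.grp_obs == gi
        p = (data.y[m] + 0.5) / (data.n[m] + 1.0)
        z = np.log(p / (1 - p))
        X = np.column_stack([np.ones(m.sum()), data.t[m], data.tk[m]])
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        theta.extend(beta)
    theta.extend([0.0] * data.n_cov)
    theta.append(0.5)  # sigma_b start
    theta.extend([0.05] * len(data.groups))  # phi starts
    return np.asarray(theta)


def fit_betabin_joinpoint(
    series_list: list[SubjectSeries],
    spec: JoinPointSpec,
    n_restarts: int = 3,
    seed: int = 0,
    maxiter: int = 300,
) -> JoinPointFit:
    """Maximum marginal likelihood for the beta-binomial join-point GLMM.

    The random intercept is integrated out by 15-node adaptive
    Gauss-Hermite quadrature; optimisation is L-BFGS-B with ``n_restarts``
    jittered starts (seeded) to guard against local optima.  Standard
    errors come from the numerically-differentiated observed information.
    A group whose target counts are all zero gets its dispersion pinned at
    the boundary with a warning rather than an error.
    """
    data = _ModelData(series_list, spec)
    groups = data.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for the group-specific model")
    notes = []
    for gi, g in enumerate(groups):
        if data.y[data.grp_obs == gi].sum() == 0:
            notes.append(f"group {g!r}: all-zero target counts; dispersion at boundary")
            logger.warning(notes[-1])

    ng = len(groups)
    n_par = 3 * ng + data.n_cov + 1 + ng
    bounds = (
        [(None, None)] * (3 * ng + data.n_cov)
        + [(1e-6, 10.0)]          # sigma_b
        + [(1e-8, 10.0)] * ng     # phi_g
    )

    def nll(theta):
        ll = data.loglik_subjects(theta).sum()
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(seed)
    base_start = _start_values(data)
    best = None
    for r in range(max(n_restarts, 1)):
        start = base_start.copy()
        if r > 0:
            start[: 3 * ng + data.n_cov] += rng.normal(0, 0.1, 3 * ng + data.n_cov)
            start[3 * ng + data.n_cov] = abs(start[3 * ng + data.n_cov] * rng.uniform(0.5, 2))
        start = np.clip(start, [b[0] if b[0] is not None else -np.inf for b in bounds],
                        [b[1] if b[1] is not None else np.inf for b in bounds])
        # eps well above the objective's numerical noise floor (~1e-6 for
        # cohort-sized data), else the FD gradient drowns near the optimum
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "maxfun": 15 * maxiter,
                                "eps": 1e-5})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("beta-binomial join-point fit failed: non-finite likelihood")
    if not best.success and "ABNORMAL" in str(best.message):
        raise FitError(
            f"optimizer did not converge: {best.message}; "
            f"|grad|={np.linalg.norm(best.jac):.3g}, nit={best.nit}"
        )

    theta = best.x
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(theta, nll, epsilon=1e-3)
    try:
        cov = np.linalg.inv(hess)
        if not np.all(np.diag(cov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        notes.append("observed information singular (boundary); pseudo-inverse SEs")

    f = _unpack(theta, groups, data.n_cov)
    names = []
    for g in groups:
        names += [f"intercept:{g}", f"slope_pre:{g}", f"slope_change:{g}"]
    names += [f"cov_{c}" for c in data.cov_names]
    names += ["sigma_b"] + [f"phi:{g}" for g in groups]
    return JoinPointFit(
        taxon_id=spec.taxon_id,
        knot_day=spec.knot_day,
        groups=groups,
        coef={g: tuple(map(float, f["coef"][g])) for g in groups},
        sigma_b=float(f["sigma_b"]),
        phi={g: float(f["phi"][g]) for g in groups},
        covariate_coef=dict(zip(data.cov_names, map(float, f["cov_coef"]))),
        loglik=float(-best.fun),
        param_names=names,
        params=theta,
        cov_params=cov,
        n_subjects=data.n_subjects,
        n_obs=len(data.y),
        converged=bool(best.success),
        boundary_notes=notes,
    )


# ---------------------------------------------------------------------------
# Log-normal GEE group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GeeFit:
    outcome: str
    groups: tuple[str, ...]
    #: group -> geometric mean on the original scale
    group_means: dict[str, float]
    params: pd.Series
    cov_params: pd.DataFrame
    #: rows: group_a, group_b, estimate (log scale), se, z, p
    contrasts: pd.DataFrame
    working_correlation: str
    #: (estimate, se, p) per unit time, when a time covariate was included
    time_slope: tuple[float, float, float] | None
    results: object  # underlying statsmodels results


def fit_gee_lognormal(
    values,
    subject_ids,
    groups,
    time=None,
    outcome_name: str = "outcome",
    adjust: str | None = None,
) -> GeeFit:
    """Compare a positive outcome across groups on the log scale with GEE.

    Exchangeable working correlation within subject, sandwich-robust
    standard errors, pairwise Wald contrasts between groups (unadjusted by
    default; ``adjust='holm'`` adds a ``p_adjusted`` column).  When every
    cluster is a singleton the fit reduces to ordinary least squares with
    heteroskedasticity-robust errors (logged note).
    """
    values = np.asarray(values, dtype=float)
    subject_ids = np.asarray(subject_ids)
    groups = np.asarray(groups)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        bad = np.flatnonzero(~(values > 0))[:5]
        raise ValueError(
            f"log-normal model needs positive values; offending records at {bad.tolist()}"
        )
    group_labels = tuple(dict.fromkeys(groups))
    if len(group_labels) < 2:
        raise ValueError("need at least 2 groups")
    logv = np.log(values)
    X = pd.DataFrame({"intercept": np.ones(len(values))})
    for g in group_labels[1:]:
        X[f"group_{g}"] = (groups == g).astype(float)
    if time is not None:
        X["time"] = np.asarray(time, dtype=float)

    singleton_only = pd.Series(subject_ids).value_counts().max() == 1
    if singleton_only:
        logger.info("all clusters are singletons; using OLS with robust (HC1) errors")
        res = sm.OLS(logv, X).fit(cov_type="HC1")
        corr_label = "independence (singleton clusters)"
    else:
        model = sm.GEE(
            logv, X, groups=subject_ids, family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        res = model.fit()
        corr_label = "exchangeable"

    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)

    # pairwise group contrasts on the log scale
    rows = []
    for i, ga in enumerate(group_labels):
        for gb in group_labels[i + 1:]:
            c = np.zeros(len(X.columns))
            if ga != group_labels[0]:
                c[X.columns.get_loc(f"group_{ga}")] += 1
            if gb != group_labels[0]:
                c[X.columns.get_loc(f"group_{gb}")] -= 1
            est = float(c @ params.to_numpy())
            se = float(np.sqrt(c @ cov.to_numpy() @ c))
            z = est / se if se > 0 else np.inf
            rows.append({"group_a": ga, "group_b": gb, "estimate": est,
                         "se": se, "z": z, "p": 2 * norm.sf(abs(z))})
    contrasts = pd.DataFrame(rows)
    if adjust is not None:
        if adjust != "holm":
            raise ValueError(f"unknown adjustment {adjust!r} (only 'holm')")
        from statsmodels.stats.multitest import multipletests

        contrasts["p_adjusted"] = multipletests(contrasts["p"], method="holm")[1]

    means = {}
    tbar = float(np.mean(np.asarray(time, dtype=float))) if time is not None else 0.0
    for g in group_labels:
        m = params["intercept"] + (params.get(f"group_{g}", 0.0))
        if time is not None:
            m += params["time"] * tbar
        means[g] = float(np.exp(m))

    slope = None
    if time is not None:
        s = float(params["time"])
        se = float(np.sqrt(cov.loc["time", "time"]))
        slope = (s, se, float(2 * norm.sf(abs(s / se))))

    return GeeFit(
        outcome=outcome_name,
        groups=group_labels,
        group_means=means,
        params=params,
        cov_params=cov,
        contrasts=contrasts,
        working_correlation=corr_label,
        time_slope=slope,
        results=res,
    )


# ---------------------------------------------------------------------------
# Zero-inflation diagnostic
# ---------------------------------------------------------------------------


def zero_inflation_check(
    fit: JoinPointFit,
    series_list: list[SubjectSeries],
    day_edges=(0, 7, 14, 30),
    z_tol: float = 3.0,
) -> pd.DataFrame:
    """Compare observed vs model-predicted zero fractions per group/day bin.

    The per-sample zero probability given the random intercept b is
    P0(b) = BB(0 | n, mu(t, b), phi_g); the bin's expected zero count and
    its model-based variance are accumulated per subject with b integrated
    out by Gauss-Hermite quadrature.  Zeros within a subject are correlated
    through the shared intercept, which the variance accounts for
    (law of total variance per subject, independence across subjects).
    A bin is flagged when the observed zero count deviates from its
    expectation by more than ``z_tol`` model standard deviations (with a
    half-count floor).  Empty bins are reported as skipped, never imputed.
    """
    taxon_pos = series_list[0].taxon_ids.index(fit.taxon_id)
    b_nodes = np.sqrt(2.0) * max(fit.sigma_b, 0.0) * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    edges = np.asarray(day_edges, dtype=float)
    nbins = len(edges) - 1
    # accumulators: observed count, expected count, variance, sample count
    acc = {(g, b): [0.0, 0.0, 0.0, 0] for g in fit.groups for b in range(nbins)}
    for s in series_list:
        tot = s.counts.sum(axis=1)
        t = s.days.astype(float)
        bin_idx = np.searchsorted(edges, t, side="right") - 1
        eta = _linpred(t, fit.coef[s.group], fit.knot_day)
        # P0 per (node, sample): zero probability conditional on b
        p0_b = np.exp(
            betabinom_logpmf(0.0, tot[None, :].astype(float),
                             expit(eta[None, :] + b_nodes[:, None]), fit.phi[s.group])
        )
        for b in set(bin_idx.tolist()):
            if b < 0 or b >= nbins:
                continue
            m = bin_idx == b
            cond_mean = p0_b[:, m].sum(axis=1)  # E[Z_s | b] at each node
            e_z = float(w @ cond_mean)
            var_cond = float(w @ (p0_b[:, m] * (1 - p0_b[:, m])).sum(axis=1))
            var_b = float(w @ cond_mean**2) - e_z**2
            a = acc[(s.group, b)]
            a[0] += float((s.counts[m, taxon_pos] == 0).sum())
            a[1] += e_z
            a[2] += var_cond + max(var_b, 0.0)
            a[3] += int(m.sum())
    rows = []
    for g in fit.groups:
        for b in range(nbins):
            obs, exp_, var, cnt = acc[(g, b)]
            label = f"[{edges[b]:g},{edges[b + 1]:g})"
            if cnt == 0:
                rows.append({"group": g, "day_bin": label, "n": 0,
                             "observed": np.nan, "predicted": np.nan,
                             "flagged": False, "skipped": True})
                continue
            sd = max(np.sqrt(var), 0.5)
            rows.append({"group": g, "day_bin": label, "n": cnt,
                         "observed": obs / cnt, "predicted": exp_ / cnt,
                         "flagged": bool(abs(obs - exp_) > z_tol * sd),
                         "skipped": False})
    return pd.DataFrame(rows)
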