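"""Drive-parameter estimation and hypothesis tests.

The drive parameter k is the proportion of successful gametes that
carried the Australian-origin allele; fair Mendelian segregation gives
k = 0.5.  Tests are run against a background transmission rate p0 —
by convention the pooled male-parent rate, which absorbs viability
effects shared by the sexes — via

* an exact binomial test (central, doubled-tail), and
* a binomial GLM with logit(p0) as an offset, whose intercept
  beta0 = logit(k) - logit(p0) has a closed-form MLE, so the Wald test
  is an analytic computation;
* binomial random-intercept GLMMs (marker or individual grouping) whose
  logit-normal marginal likelihood is maximised by adaptive
  Gauss-Hermite quadrature, with likelihood-ratio tests for the
  random-effect variance and Wald contrasts on an eight-level
  generation x position x sex fixed effect.

Power calculations use the arcsine-transform normal approximation
(h = 2 asin sqrt(k) - 2 asin sqrt(0.5)) cross-checked against exact
binomial power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

LOGIT = special.logit
EXPIT = special.expit


class EstimateError(ValueError):
    """Raised when an estimate is undefined (e.g. no informative data)."""


# ---------------------------------------------------------------------------
# exact binomial machinery
# ---------------------------------------------------------------------------

def binomial_p_two_sided(successes, n, p0, method: str = "central"):
    """Two-sided exact binomial p-value against success probability p0.

    ``central`` doubles the smaller tail (capped at 1), matching the
    symmetry of the offset-GLM Wald test; ``minlike`` sums all outcomes
    with probability mass <= the observed one (scipy's convention).
    Vectorised over ``successes``/``n``.
    """
    s = np.asarray(successes)
    n_arr = np.asarray(n)
    if method == "central":
        lower = stats.binom.cdf(s, n_arr, p0)
        upper = stats.binom.sf(s - 1, n_arr, p0)
        return np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    if method == "minlike":
        if s.ndim == 0:
            return stats.binomtest(int(s), int(n_arr), p0).pvalue
        return np.array(
            [stats.binomtest(int(si), int(ni), p0).pvalue for si, ni in zip(s, n_arr)]
        )
    raise ValueError(f"unknown method {method!r}")


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion."""
    z = stats.norm.ppf(0.5 + level / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


# ---------------------------------------------------------------------------
# k estimation and the offset GLM
# ---------------------------------------------------------------------------

@dataclass
class OffsetGLMFit:
    beta0: float
    se: float
    p_wald: float
    loglik: float
    boundary: bool = False
    ci95: tuple | None = None  # profile-likelihood CI at the boundary


@dataclass
class DriveEstimate:
    scope: str
    n: int
    successes: int
    k: float
    ci95: tuple
    p_binomial: float
    p_wald: float
    p0: float


def _offset_loglik(beta, s, n, p0):
    p = EXPIT(LOGIT(p0) + beta)
    return (
        special.gammaln(n + 1)
        - special.gammaln(s + 1)
        - special.gammaln(n - s + 1)
        + s * np.log(p)
        + (n - s) * np.log1p(-p)
    )


def glm_offset_fit(successes: int, n: int, p0: float) -> OffsetGLMFit:
    """Binomial GLM with intercept only and offset logit(p0).

    The MLE is analytic: beta0 = logit(s/n) - logit(p0) with
    SE = (n k (1-k))^(-1/2).  At the boundary (s in {0, n}) the Wald
    machinery degenerates; a profile-likelihood interval is reported
    instead and the p-value comes from the likelihood-ratio test of
    beta0 = 0.
    """
    if not 0 <= successes <= n or n < 1:
        raise EstimateError("need 0 <= successes <= n, n >= 1")
    if not 0 < p0 < 1:
        raise EstimateError("p0 must be in (0, 1)")
    if 0 < successes < n:
        k = successes / n
        beta0 = LOGIT(k) - LOGIT(p0)
        se = 1.0 / math.sqrt(n * k * (1 - k))
        z = beta0 / se
        p = 2 * stats.norm.sf(abs(z))
        ll = float(_offset_loglik(beta0, successes, n, p0))
        return OffsetGLMFit(beta0=beta0, se=se, p_wald=p, loglik=ll)
    # boundary: sup loglik approached as beta -> +-inf
    sign = 1.0 if successes == n else -1.0
    ll_sup = 0.0 + float(
        special.gammaln(n + 1) - special.gammaln(successes + 1)
        - special.gammaln(n - successes + 1)
    )
    crit = stats.chi2.ppf(0.95, 1) / 2

    def deficit(beta):
        return (ll_sup - float(_offset_loglik(beta, successes, n, p0))) - crit

    # inner bound of the one-sided profile interval
    lo, hi = 0.0, sign * 1.0
    while deficit(hi) > 0 and abs(hi) < 1e3:
        lo, hi = hi, hi * 2
    bound = optimize.brentq(deficit, min(lo, hi), max(lo, hi)) if abs(hi) < 1e3 else 0.0
    ci = (bound, math.inf) if sign > 0 else (-math.inf, bound)
    lr = 2 * (ll_sup - float(_offset_loglik(0.0, successes, n, p0)))
    p = stats.chi2.sf(lr, 1)
    return OffsetGLMFit(
        beta0=sign * math.inf, se=math.nan, p_wald=p, loglik=ll_sup,
        boundary=True, ci95=ci,
    )


def estimate_k(
    successes: int,
    n: int,
    p0: float = 0.5,
    scope: str = "pooled",
    method: str = "central",
) -> DriveEstimate:
    """Estimate k = successes/n with Wilson CI and tests against p0."""
    if n < 1:
        raise EstimateError("undefined estimate: n = 0")
    if not 0 <= successes <= n:
        raise EstimateError("successes outside [0, n]")
    k = successes / n
    ci = wilson_ci(successes, n)
    p_binom = float(binomial_p_two_sided(successes, n, p0, method=method))
    p_wald = glm_offset_fit(successes, n, p0).p_wald
    return DriveEstimate(
        scope=scope, n=n, successes=successes, k=k, ci95=ci,
        p_binomial=p_binom, p_wald=p_wald, p0=p0,
    )


def background_rate(
    records: pd.DataFrame, mode: str = "glmm", n_nodes: int = 20
) -> float:
    """Pooled male-parent transmission rate used as the null p0.

    mode="glmm" (default): population-level estimate from a binomial GLMM
    with marker identity as a random intercept.  mode="raw": the plain
    pooled proportion.  The two differ only when marker sample sizes are
    unbalanced and the among-marker variance is positive.
    """
    males = records[records["parent_sex"] == "M"]
    if not len(males):
        raise EstimateError(
            "no male-parent records; use p0 = 0.5 as the theoretical null"
        )
    if mode == "raw":
        return float(males["transmitted"].mean())
    if mode != "glmm":
        raise ValueError(f"unknown background mode {mode!r}")
    counts = (
        males.groupby("marker_id")["transmitted"].agg(["sum", "size"]).reset_index()
    )
    counts.columns = ["group", "successes", "n"]
    fit = glmm_fit(counts, p0=0.5, n_nodes=n_nodes)
    return float(EXPIT(LOGIT(0.5) + fit.beta[0]))


# ---------------------------------------------------------------------------
# binomial GLMM via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

@dataclass
class RandomInterceptFit:
    beta: np.ndarray  # fixed effects on the logit scale, relative to offset
    sigma: float
    loglik: float
    n_nodes: int
    converged: bool
    levels: list = field(default_factory=list)  # fixed-effect level names
    vcov: np.ndarray | None = None  # fixed-effect covariance (observed info)
    p0: float = 0.5
    group_sizes: np.ndarray | None = None
    level_n: np.ndarray | None = None  # total transmissions per fixed level
    loglik_sigma0: float = math.nan  # same data refit at sigma = 0 (offset GLM)
    message: str = ""

    @property
    def k_population(self):
        """Conditional-mode (u = 0) k per fixed-effect level."""
        return EXPIT(LOGIT(self.p0) + self.beta)


def _grouped_loglik_agq(eta, s, n, codes, n_groups, sigma, nodes, weights):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Rows (binomial counts with linear predictor ``eta`` = offset + fixed
    effects) sharing a group code share one random intercept
    u_g ~ N(0, sigma^2).  Returns the total log-likelihood.  For
    sigma ~ 0 the plain binomial log-likelihood is returned, so the fit
    degenerates exactly to the offset GLM.
    """
    base = float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(s + 1)
            - special.gammaln(n - s + 1)
        )
    )
    if sigma < 1e-10:
        p = EXPIT(eta)
        return base + float(np.sum(s * np.log(p) + (n - s) * np.log1p(-p)))

    inv_var = 1.0 / sigma**2
    u = np.zeros(n_groups)
    for _ in range(100):  # Newton to the mode of each group's integrand
        p = EXPIT(eta + u[codes])
        grad = np.bincount(codes, weights=s - n * p, minlength=n_groups) - u * inv_var
        hess = -np.bincount(codes, weights=n * p * (1 - p), minlength=n_groups) - inv_var
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = EXPIT(eta + u[codes])
    hess = -np.bincount(codes, weights=n * p * (1 - p), minlength=n_groups) - inv_var
    tau = 1.0 / np.sqrt(-hess)

    # int exp(g(u)) du ~ sqrt(2) tau sum_i w_i exp(x_i^2) exp(g(u_hat + sqrt(2) tau x_i))
    un = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    p_rk = EXPIT(eta[:, None] + un[codes])
    row_ll = s[:, None] * np.log(p_rk) + (n - s)[:, None] * np.log1p(-p_rk)
    g = np.zeros((n_groups, len(nodes)))
    np.add.at(g, codes, row_ll)
    g -= 0.5 * un * un * inv_var
    gmax = g.max(axis=1, keepdims=True)
    integral = np.sum(weights[None, :] * np.exp(g - gmax + nodes[None, :] ** 2), axis=1)
    log_integral = gmax[:, 0] + np.log(integral) + 0.5 * math.log(2.0) + np.log(tau)
    return base + float(
        np.sum(log_integral - 0.5 * math.log(2 * math.pi) - math.log(sigma))
    )


def _prepare_counts(counts: pd.DataFrame, fixed: str):
    s = counts["successes"].to_numpy(dtype=float)
    n = counts["n"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(counts["group"])
    if fixed == "intercept":
        design, levels = None, ["intercept"]
    elif fixed == "eight_level":
        if "level" not in counts.columns:
            raise ValueError("eight_level fit needs a 'level' column")
        levels = sorted(counts["level"].unique())
        design = np.zeros((len(counts), len(levels)))
        for j, lev in enumerate(levels):
            design[(counts["level"] == lev).to_numpy(), j] = 1.0
    else:
        raise ValueError(f"unknown fixed spec {fixed!r}")
    return s, n, codes.astype(int), len(uniques), design, levels


def glmm_marginal_loglik(
    beta, sigma, counts, p0, fixed: str = "intercept", n_nodes: int = 20
):
    """Marginal log-likelihood of the binomial random-intercept model.

    ``counts`` needs columns group, successes, n (and ``level`` for the
    eight-level fixed effect).  Exposed so independent integration
    oracles can check the quadrature directly.
    """
    s, n, codes, n_groups, design, _ = _prepare_counts(counts, fixed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = LOGIT(p0) + (np.full_like(s, beta[0]) if design is None else design @ beta)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    return _grouped_loglik_agq(eta, s, n, codes, n_groups, sigma, nodes, weights)


def glmm_fit(
    counts: pd.DataFrame,
    p0: float = 0.5,
    fixed: str = "intercept",
    n_nodes: int = 20,
) -> RandomInterceptFit:
    """Fit the binomial random-intercept GLMM by maximum likelihood.

    ``counts``: one row per group (or per group x fixed-effect cell) with
    columns ``group``, ``successes``, ``n`` and, for
    ``fixed="eight_level"``, a ``level`` column (cell-means coding: one
    coefficient per level, no global intercept).  The offset logit(p0)
    makes beta = 0 correspond to transmission at the background rate.
    The fit at sigma = 0 is always evaluated too; it equals the plain
    offset GLM and feeds the random-effect likelihood-ratio test.
    """
    counts = counts.reset_index(drop=True)
    if counts["group"].nunique() < 2:
        raise EstimateError("need >= 2 groups for a random intercept")
    s, n, codes, n_groups, design, levels = _prepare_counts(counts, fixed)
    n_beta = 1 if design is None else design.shape[1]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def eta_of(beta):
        beta = np.atleast_1d(beta)
        return LOGIT(p0) + (np.full_like(s, beta[0]) if design is None else design @ beta)

    def negll(theta):
        sigma = math.exp(theta[-1])
        return -_grouped_loglik_agq(
            eta_of(theta[:n_beta]), s, n, codes, n_groups, sigma, nodes, weights
        )

    pooled = np.clip(s.sum() / n.sum(), 1e-6, 1 - 1e-6)
    beta_start = np.full(n_beta, LOGIT(pooled) - LOGIT(p0))
    x0 = np.append(beta_start, math.log(0.2))
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 20000, "maxfev": 20000})
    converged = bool(res.success)
    beta_hat = np.atleast_1d(res.x[:n_beta])
    sigma_hat = math.exp(res.x[-1])
    ll_hat = -res.fun

    def negll_sigma0(beta):
        return -_grouped_loglik_agq(
            eta_of(beta), s, n, codes, n_groups, 0.0, nodes, weights
        )

    res0 = optimize.minimize(negll_sigma0, beta_start, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12,
                                      "maxiter": 20000, "maxfev": 20000})
    ll_sigma0 = -res0.fun
    # a vanishing variance plateaus in log-sigma; prefer the boundary fit
    if ll_sigma0 >= ll_hat - 1e-7:
        beta_hat = np.atleast_1d(res0.x)
        sigma_hat = 0.0
        ll_hat = ll_sigma0
        converged = converged or bool(res0.success)

    vcov = _beta_vcov(beta_hat, sigma_hat, s, n, codes, n_groups, p0, design,
                      nodes, weights)
    if design is not None:
        level_n = np.array([n[design[:, j] == 1.0].sum() for j in range(n_beta)])
    else:
        level_n = np.array([n.sum()])
    return RandomInterceptFit(
        beta=beta_hat,
        sigma=float(sigma_hat),
        loglik=float(ll_hat),
        n_nodes=n_nodes,
        converged=converged,
        levels=levels,
        vcov=vcov,
        p0=p0,
        group_sizes=n,
        level_n=level_n,
        loglik_sigma0=float(ll_sigma0),
        message=str(res.message),
    )


def _beta_vcov(beta, sigma, s, n, codes, n_groups, p0, design, nodes, weights):
    """Observed-information covariance of the fixed effects (sigma fixed
    at its estimate), by central finite differences of the log-likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    k = len(beta)

    def ll(b):
        eta = LOGIT(p0) + (np.full_like(s, b[0]) if design is None else design @ b)
        return _grouped_loglik_agq(eta, s, n, codes, n_groups, sigma, nodes, weights)

    h = 1e-4
    hess = np.zeros((k, k))
    f0 = ll(beta)
    for i in range(k):
        for j in range(i, k):
            bpp = beta.copy(); bpp[i] += h; bpp[j] += h
            bpm = beta.copy(); bpm[i] += h; bpm[j] -= h
            bmp = beta.copy(); bmp[i] -= h; bmp[j] += h
            bmm = beta.copy(); bmm[i] -= h; bmm[j] -= h
            if i == j:
                bp = beta.copy(); bp[i] += h
                bm = beta.copy(); bm[i] -= h
                hess[i, i] = (ll(bp) - 2 * f0 + ll(bm)) / h**2
            else:
                hess[i, j] = hess[j, i] = (
                    ll(bpp) - ll(bpm) - ll(bmp) + ll(bmm)
                ) / (4 * h**2)
    try:
        return np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return None


@dataclass
class LRTResult:
    lr: float
    p_nominal: float  # chi2 with 1 df (conventional software output)
    p_boundary: float  # 0.5 chi2_0 + 0.5 chi2_1 mixture


def lrt_random_effect(loglik_null: float, loglik_glmm: float) -> LRTResult:
    """LRT for the random-intercept variance (H0: sigma = 0).

    Reports the nominal chi-square(1) p-value alongside the
    boundary-corrected equal mixture of chi-square(0) and chi-square(1).
    """
    lr = 2.0 * (loglik_glmm - loglik_null)
    if lr < -1e-6:
        raise EstimateError(
            f"GLMM log-likelihood below the null's (LR = {lr:.3g}); "
            "optimisation failure"
        )
    lr = max(lr, 0.0)
    p_nom = float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    p_bound = 0.5 * float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    return LRTResult(lr=lr, p_nominal=p_nom, p_boundary=p_bound)


@dataclass
class ContrastResult:
    estimate: float
    se: float
    z: float
    p: float
    contrast: dict


def contrast_level(fit: RandomInterceptFit, focal_level: str) -> ContrastResult:
    """Wald test of one fixed-effect level against the weighted mean of the rest.

    The comparison value is the transmission-count-weighted mean of the
    other levels' coefficients; weights and the full contrast vector are
    returned so the definition is explicit in the output.
    """
    if focal_level not in fit.levels:
        raise EstimateError(
            f"level {focal_level!r} missing; available: {fit.levels}"
        )
    if fit.vcov is None:
        raise EstimateError("fit has no covariance matrix")
    if fit.level_n is None:
        raise EstimateError("fit carries no per-level transmission totals")
    idx = fit.levels.index(focal_level)
    c = np.zeros(len(fit.levels))
    others = [i for i in range(len(fit.levels)) if i != idx]
    w = np.asarray([fit.level_n[i] for i in others], dtype=float)
    w = w / w.sum()
    c[idx] = 1.0
    for i, wi in zip(others, w):
        c[i] = -wi
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.vcov @ c))
    z = est / se
    p = 2 * float(stats.norm.sf(abs(z)))
    return ContrastResult(
        estimate=est, se=se, z=z, p=p,
        contrast=dict(zip(fit.levels, c.round(6))),
    )


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    alpha: float
    target_power: float
    n: int
    k_bound: float
    note: str = "k and 1-k are equivalent by symmetry; k_bound > 0.5 by convention"


def _arcsine_power(k: float, n: int, alpha: float, p_null: float = 0.5) -> float:
    h = 2 * math.asin(math.sqrt(k)) - 2 * math.asin(math.sqrt(p_null))
    z = stats.norm.ppf(1 - alpha / 2)
    root_n = math.sqrt(n)
    return float(
        stats.norm.cdf(abs(h) * root_n - z) + stats.norm.cdf(-abs(h) * root_n - z)
    )


def exact_binomial_power(k: float, n: int, alpha: float, p_null: float = 0.5) -> float:
    """Power of the central exact binomial test at true proportion k."""
    s = np.arange(n + 1)
    pvals = binomial_p_two_sided(s, n, p_null, method="central")
    reject = pvals <= alpha
    return float(stats.binom.pmf(s[reject], n, k).sum())


def power_detectable_k(
    n: int, alpha: float = 0.05, target_power: float = 0.8, method: str = "arcsine"
) -> PowerSpec:
    """Smallest k > 0.5 detectable with the target power at level alpha."""
    if n < 1:
        raise EstimateError("n must be >= 1")
    if not 0 < alpha < 1 or not alpha < target_power < 1:
        raise EstimateError("need 0 < alpha < target_power < 1")
    if method == "arcsine":
        f = lambda k: _arcsine_power(k, n, alpha) - target_power
    elif method == "exact":
        f = lambda k: exact_binomial_power(k, n, alpha) - target_power
    else:
        raise ValueError(f"unknown method {method!r}")
    k_bound = optimize.brentq(f, 0.5 + 1e-9, 1 - 1e-9)
    return PowerSpec(alpha=alpha, target_power=target_power, n=n, k_bound=k_bound)


def required_n(k: float, alpha: float = 0.05, target_power: float = 0.8) -> int:
    """Transmissions needed to detect deviation k with the target power."""
    if abs(k - 0.5) < 1e-12:
        raise EstimateError("zero effect (k = 0.5) is undetectable at any n")
    h = abs(2 * math.asin(math.sqrt(k)) - 2 * math.asin(math.sqrt(0.5)))
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(target_power)
    return int(math.ceil(((z_a + z_b) / h) ** 2))


# ---------------------------------------------------------------------------
# multiplicity and sex ratio
# ---------------------------------------------------------------------------

def bonferroni_ledger(test_registry) -> dict:
    """Bonferroni arithmetic over the registry of tests actually run.

    ``test_registry`` is either a sequence of dimension sizes (m is their
    product) or a list of test descriptors (m is its length).  Returns m,
    the corrected alpha at nominal 0.05, and a correction function
    applied lazily via :func:`bonferroni_correct`.
    """
    if all(isinstance(x, (int, np.integer)) for x in test_registry):
        m = int(np.prod([int(x) for x in test_registry]))
    else:
        m = len(test_registry)
    return {"m": m, "alpha_corrected": 0.05 / m if m else math.nan}


def bonferroni_correct(p, m: int):
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)


@dataclass
class SexRatioResult:
    n_f: int
    n_m: int
    fmr: float
    se_interval: tuple  # fmr -/+ one delta-method SE (the reporting style
    # used for female-male ratios in pedigree studies)
    ci95: tuple
    p: float


def sex_ratio_test(n_f: int, n_m: int) -> SexRatioResult:
    """Female-male ratio with delta-method interval and exact binomial p."""
    n = n_f + n_m
    if n == 0:
        raise EstimateError("no sexed offspring")
    p = float(stats.binomtest(n_f, n, 0.5).pvalue)
    if n_f == 0 or n_m == 0:
        # exact fallback: transform a Clopper-Pearson interval on P(female)
        lo_p, hi_p = stats.binomtest(n_f, n, 0.5).proportion_ci(0.95, "exact")
        fmr = math.inf if n_m == 0 and n_f > 0 else 0.0
        ci = (lo_p / (1 - lo_p) if lo_p < 1 else math.inf,
              hi_p / (1 - hi_p) if hi_p < 1 else math.inf)
        return SexRatioResult(n_f, n_m, fmr, ci, ci, p)
    fmr = n_f / n_m
    se_log = math.sqrt(1 / n_f + 1 / n_m)
    se_iv = (fmr * math.exp(-se_log), fmr * math.exp(se_log))
    ci = (fmr * math.exp(-1.959964 * se_log), fmr * math.exp(1.959964 * se_log))
    return SexRatioResult(n_f, n_m, fmr, se_iv, ci, p)
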