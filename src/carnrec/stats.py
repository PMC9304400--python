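"""Statistical engine for the association and prevalence analyses.

Provides binomial logistic regression (IRLS via ``statsmodels``) with two
stepwise selectors (backwards-AIC; forward/backward likelihood-ratio),
chi-square goodness-of-fit with Monte Carlo p-values for small expected
counts, exact post-hoc binomial tests with Holm (sequential Bonferroni)
step-down adjustment, Fisher's exact test (enumeration for 2x2, fixed-margin
Monte Carlo for larger tables), and the Kruskal-Wallis test with Dunn's
rank-based post-hoc comparisons.

Every Monte Carlo procedure takes an explicit seed; nothing touches global
random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "GLMFit",
    "GOFResult",
    "PosthocTest",
    "fit_logistic",
    "stepwise_aic",
    "stepwise_lrt",
    "gof_chisq",
    "posthoc_binomial",
    "holm_adjust",
    "fisher_exact",
    "kruskal_wallis",
    "dunn_posthoc",
]

_Z90 = sps.norm.ppf(0.95)
_Z95 = sps.norm.ppf(0.975)


@dataclass
class GLMFit:
    """A fitted binomial logistic regression.

    Coefficients are log-odds per term; ``odds_ratios`` are their exponentials.
    Wald confidence intervals are reported at both 90% and 95% (the dual
    intervals used when plotting action/threat associations).
    """

    terms: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci95: np.ndarray  # (k, 2)
    ci90: np.ndarray  # (k, 2)
    log_likelihood: float
    aic: float
    converged: bool
    separation_flag: bool
    n_used: int
    exclusion: str = "none"

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci95_lo": self.ci95[:, 0],
                "ci95_hi": self.ci95[:, 1],
                "ci90_lo": self.ci90[:, 0],
                "ci90_hi": self.ci90[:, 1],
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "odds_ratios": self.odds_ratios.tolist(),
            "ci95": self.ci95.tolist(),
            "ci90": self.ci90.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "n_used": self.n_used,
            "exclusion": self.exclusion,
        }


@dataclass
class PosthocTest:
    category: str
    observed: int
    expected: float
    binomial_p_raw: float
    p_adjusted: float
    significant: bool


@dataclass
class GOFResult:
    """Chi-square goodness-of-fit outcome with optional post-hoc tests."""

    statistic: float
    df: int
    p_value: float
    method: str  # "asymptotic" or "monte_carlo"
    n_sim: int = 0
    posthoc: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "n_sim": self.n_sim,
            "posthoc": [vars(t) for t in self.posthoc],
        }


def _as_design(design) -> pd.DataFrame:
    if isinstance(design, pd.DataFrame):
        return design
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def fit_logistic(design, response, tol: float = 1e-8, max_iter: int = 100) -> GLMFit:
    """Fit a binomial logistic regression by IRLS with Wald 90/95% CIs.

    ``design`` holds the predictor columns (an intercept is added
    automatically).  Constant predictor columns are flagged with a warning
    but kept, mirroring how an attentive analyst would be told rather than
    silently corrected.  A zero-variance response is an error; quasi-complete
    separation is reported through ``separation_flag`` rather than penalized.
    """
    X = _as_design(design)
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"response length {len(y)} != design rows {len(X)}")
    if y.size == 0:
        raise ValueError("empty response")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("zero-variance response: all outcomes identical")

    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        warnings.warn(f"constant design column(s): {const_cols}", stacklevel=2)

    Xc = sm.add_constant(X, has_constant="add")
    terms = ["intercept"] + list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, np.asarray(Xc, dtype=float), family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=max_iter, tol=tol)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            res = model.fit(maxiter=max_iter, tol=tol, method="lbfgs")
            converged = False
        # statsmodels evaluates llf/bse lazily; keep them inside the guard so
        # separation-induced overflow warnings stay suppressed
        coefs = np.asarray(res.params, dtype=float)
        ses = np.asarray(res.bse, dtype=float)
        fitted = np.asarray(res.fittedvalues, dtype=float)
        llf = float(res.llf)
    if not converged:
        warnings.warn("logistic fit did not converge; partial results returned", stacklevel=2)
    separation = bool(
        ((fitted < 1e-6) | (fitted > 1 - 1e-6)).any() and np.abs(coefs).max() > 10
    )
    ci95 = np.column_stack([coefs - _Z95 * ses, coefs + _Z95 * ses])
    ci90 = np.column_stack([coefs - _Z90 * ses, coefs + _Z90 * ses])
    k = len(coefs)
    return GLMFit(
        terms=terms,
        coefficients=coefs,
        standard_errors=ses,
        ci95=ci95,
        ci90=ci90,
        log_likelihood=llf,
        aic=2 * k - 2 * llf,
        converged=converged,
        separation_flag=separation,
        n_used=len(y),
    )


def stepwise_aic(design, response, direction: str = "backward", **fit_kw) -> GLMFit:
    """Backwards stepwise selection minimising AIC.

    Starting from the full model, greedily remove the single term whose
    removal most decreases AIC; stop when no removal strictly decreases it.
    Candidate terms are examined in sorted-name order so ties break
    deterministically.
    """
    if direction != "backward":
        raise ValueError("only backward AIC selection is provided")
    X = _as_design(design)
    current = sorted(X.columns)
    best = fit_logistic(X[[c for c in X.columns if c in current]], response, **fit_kw)
    while current:
        candidates = []
        for term in sorted(current):
            reduced = [c for c in current if c != term]
            fit = fit_logistic(X[[c for c in X.columns if c in reduced]], response, **fit_kw)
            candidates.append((fit.aic, term, fit))
        best_aic, _, best_fit = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic < best.aic:
            drop = min(candidates, key=lambda t: (t[0], t[1]))[1]
            current = [c for c in current if c != drop]
            best = best_fit
        else:
            break
    return best


def _lrt_p(ll_full: float, ll_reduced: float, df: int) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(sps.chi2.sf(stat, df))


def stepwise_lrt(
    design,
    response,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    **fit_kw,
) -> GLMFit:
    """Forward/backward stepwise selection by likelihood-ratio testing.

    Alternates forward entry (smallest LRT p <= ``alpha_enter``) and backward
    removal (largest LRT p > ``alpha_remove``) until no move qualifies.
    Ties break by term-name order.
    """
    X = _as_design(design)
    included: list = []

    def _fit(cols):
        if cols:
            return fit_logistic(X[[c for c in X.columns if c in cols]], response, **fit_kw)
        return fit_logistic(pd.DataFrame(index=X.index), response, **fit_kw)

    current_fit = _fit(included)
    changed = True
    while changed:
        changed = False
        excluded = sorted(set(X.columns) - set(included))
        if excluded:
            trials = []
            for term in excluded:
                fit = _fit(sorted(included + [term]))
                p = _lrt_p(fit.log_likelihood, current_fit.log_likelihood, 1)
                trials.append((p, term, fit))
            p_best, term_best, fit_best = min(trials, key=lambda t: (t[0], t[1]))
            if p_best <= alpha_enter:
                included = sorted(included + [term_best])
                current_fit = fit_best
                changed = True
        if included:
            trials = []
            for term in sorted(included):
                reduced = [c for c in included if c != term]
                fit = _fit(reduced)
                p = _lrt_p(current_fit.log_likelihood, fit.log_likelihood, 1)
                trials.append((p, term, fit))
            p_worst, term_worst, fit_worst = max(trials, key=lambda t: (t[0], t[1]))
            if p_worst > alpha_remove:
                included = [c for c in included if c != term_worst]
                current_fit = fit_worst
                changed = True
    return current_fit


def _pearson_stat(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    return ((counts - expected) ** 2 / expected).sum(axis=-1)


def gof_chisq(
    observed_counts,
    expected_props,
    mc_threshold: float = 5.0,
    n_sim: int = 10000,
    seed: int | None = None,
) -> GOFResult:
    """Pearson chi-square goodness-of-fit against expected proportions.

    When any expected count falls below ``mc_threshold`` the p-value is
    simulated under the multinomial null with add-one correction
    ``p = (1 + #{simulated >= observed}) / (n_sim + 1)``; otherwise the
    asymptotic chi-square distribution is used.
    """
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if (obs < 0).any():
        raise ValueError("negative counts")
    if not np.isclose(props.sum(), 1.0, atol=1e-9):
        raise ValueError(f"expected proportions sum to {props.sum()}, not 1")
    n = obs.sum()
    if n == 0:
        raise ValueError("zero total count")
    expected = n * props
    if (expected == 0).any():
        raise ValueError("expected count of exactly zero; drop empty categories first")
    stat = float(_pearson_stat(obs, expected))
    df = len(obs) - 1
    if (expected < mc_threshold).any():
        if seed is None:
            raise ValueError("Monte Carlo p-value requires an explicit seed")
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(n), props, size=n_sim).astype(float)
        sim_stats = _pearson_stat(sims, expected)
        p = (1.0 + np.count_nonzero(sim_stats >= stat - 1e-12)) / (n_sim + 1.0)
        return GOFResult(stat, df, float(p), "monte_carlo", n_sim)
    p = float(sps.chi2.sf(stat, df))
    return GOFResult(stat, df, p, "asymptotic")


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down ("sequential Bonferroni") adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _binom_p(k: int, n: int, p0: float, rule: str) -> float:
    if rule == "min_likelihood":
        return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if rule == "doubling":
        lo = sps.binom.cdf(k, n, p0)
        hi = sps.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown two-sided rule: {rule}")


def posthoc_binomial(
    observed,
    n: int,
    expected_props,
    categories=None,
    alpha: float = 0.05,
    rule: str = "min_likelihood",
) -> list[PosthocTest]:
    """Per-category exact two-sided binomial tests with Holm adjustment.

    Each category's observed count is tested against its expected proportion
    of ``n``; Holm step-down controls family-wise error over the categories.
    Two-sided p-values use the minimum-likelihood inclusion rule by default
    (``rule="doubling"`` selects the doubled one-sided tail instead).
    """
    obs = np.asarray(observed, dtype=int)
    props = np.asarray(expected_props, dtype=float)
    if categories is None:
        categories = [f"cat{i}" for i in range(len(obs))]
    raw = np.array([_binom_p(int(k), int(n), float(p0), rule) for k, p0 in zip(obs, props)])
    adj = holm_adjust(raw)
    return [
        PosthocTest(
            category=str(c),
            observed=int(k),
            expected=float(n * p0),
            binomial_p_raw=float(pr),
            p_adjusted=float(pa),
            significant=bool(pa < alpha),
        )
        for c, k, p0, pr, pa in zip(categories, obs, props, raw, adj)
    ]


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given its margins."""
    t = np.asarray(table, dtype=float)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact(table, n_sim: int = 10000, seed: int | None = None) -> float:
    """Two-sided Fisher's exact test of independence.

    2x2 tables use exact hypergeometric enumeration with the
    minimum-likelihood inclusion rule.  Larger tables use Monte Carlo over
    tables with the observed margins (Patefield sampling), counting simulated
    tables whose conditional probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a non-negative 2-D integer array")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: all-zero row or column")
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    if seed is None:
        raise ValueError("Monte Carlo Fisher test requires an explicit seed")
    rng = np.random.default_rng(seed)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    sims = dist.rvs(n_sim, method="patefield", random_state=rng)
    obs_lp = _log_table_prob(t)
    sim_lps = np.array([_log_table_prob(s) for s in sims])
    hits = np.count_nonzero(sim_lps <= obs_lp + 1e-9)
    return float((1.0 + hits) / (n_sim + 1.0))


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = k - 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), df, float(p)


def dunn_posthoc(groups, labels=None, adjustment: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after Kruskal-Wallis.

    Returns one row per unordered pair with the z statistic, raw two-sided
    normal p, and multiplicity-adjusted p (Holm by default, ``"none"`` to
    skip adjustment).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    if adjustment == "holm":
        df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    elif adjustment == "none":
        df["p_adjusted"] = df["p_raw"]
    else:
        raise ValueError(f"unknown adjustment: {adjustment}")
    return df
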