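"""Bayesian linear-model group comparison via Gibbs sampling.

Group means and pairwise group differences are estimated from the normal
linear model y = X b + e, e ~ N(0, s2), with an improper flat prior on the
coefficients and an inverse-gamma(eps/2, eps/2) prior on the error variance
(eps = 0.001 by default — the vague conjugate default of the standard MCMC
regression routines used in ecology).  The sampler alternates the two
conjugate full conditionals,

    b  | s2, y  ~  N( (X'X)^-1 X'y,  s2 (X'X)^-1 )
    s2 | b,  y  ~  InvGamma( (eps + n)/2,  (eps + ||y - Xb||^2)/2 ),

discarding ``burnin`` iterations and retaining ``samples`` draws (defaults
1000 / 10000, i.e. iterations 1001:11000).  Group means use the
zero-intercept cell-means design (one indicator per level, each coefficient
a group mean); pairwise differences use a fitted-intercept treatment design
where the non-baseline coefficient is the pair difference.  A 95% credibility
interval of a difference that excludes zero is read, as in parametric
pairwise testing, as a credible difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BURNIN = 1000
DEFAULT_SAMPLES = 10000
DEFAULT_PRIOR_EPS = 0.001


@dataclass(frozen=True)
class PosteriorSummary:
    level_label: str
    mean: float
    ci_low: float
    ci_high: float
    n_obs: int

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValidationError("posterior mean must lie inside its CI")


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    diff_mean: float      # mean of (b - a)
    diff_ci_low: float
    diff_ci_high: float
    credible: bool

    def __post_init__(self):
        if not (self.diff_ci_low <= self.diff_mean <= self.diff_ci_high):
            raise ValidationError("difference mean must lie inside its CI")
        excludes0 = not (self.diff_ci_low <= 0.0 <= self.diff_ci_high)
        if self.credible != excludes0:
            raise ValidationError("credible flag must equal 'CI excludes 0'")


def gibbs_linear_regression(y, X, burnin: int = DEFAULT_BURNIN,
                            samples: int = DEFAULT_SAMPLES,
                            seed: int | np.random.Generator = 0,
                            prior_eps: float = DEFAULT_PRIOR_EPS) -> np.ndarray:
    """Posterior coefficient draws for the normal linear model.

    Returns an array of shape ``(samples, n_coefficients)``.  Reproducible
    for a fixed integer ``seed`` (or pass a Generator to continue a stream).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise DesignError(f"y has {len(y)} rows but X has {n}")
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} observations for {p} "
                              f"coefficients, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is rank deficient")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    XtX = X.T @ X
    Xty = X.T @ y
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ Xty
    chol = np.linalg.cholesky(XtX_inv)

    resid = y - X @ beta_hat
    sigma2 = float(resid @ resid) / max(n - p, 1)
    if sigma2 <= 0:
        sigma2 = 1e-12  # exactly collinear response; keep the chain proper

    a_post = 0.5 * (prior_eps + n)
    draws = np.empty((samples, p))
    total = burnin + samples
    for it in range(total):
        beta = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
        r = y - X @ beta
        b_post = 0.5 * (prior_eps + float(r @ r))
        # InvGamma(a, b) draw via 1 / Gamma(a, 1/b)
        sigma2 = b_post / rng.gamma(a_post)
        if it >= burnin:
            draws[it - burnin] = beta
    return draws


def mc_standard_error(draws: np.ndarray, n_batches: int = 50) -> np.ndarray:
    """Batch-means Monte-Carlo standard error of the posterior mean,
    one value per coefficient (robust to mild autocorrelation)."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 1:
        draws = draws.T
    n = draws.shape[0]
    b = max(2, n // n_batches)
    k = n // b
    batches = draws[:k * b].reshape(k, b, -1).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(k)


def _summaries_from_draws(draws: np.ndarray, labels, counts) -> list[PosteriorSummary]:
    means = draws.mean(axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return [PosteriorSummary(level_label=lab, mean=float(m),
                             ci_low=float(l), ci_high=float(h), n_obs=int(c))
            for lab, m, l, h, c in zip(labels, means, lo, hi, counts)]


def group_means(results: pd.DataFrame, value_col: str, by: list[str] | str,
                burnin: int = DEFAULT_BURNIN, samples: int = DEFAULT_SAMPLES,
                seed: int = 0, prior_eps: float = DEFAULT_PRIOR_EPS
                ) -> list[PosteriorSummary]:
    """Posterior mean and 95% CI for each level of ``by`` (a column or a
    column combination, e.g. ``["class", "lamp_type"]``) using the
    zero-intercept cell-means design.

    Levels with fewer than two observations are excluded with a warning.
    """
    if isinstance(by, str):
        by = [by]
    df = results.copy()
    df["_level"] = df[by].astype(str).agg(" x ".join, axis=1)

    counts = df["_level"].value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        logger.warning("excluding singleton levels from group means: %s", singletons)
        df = df[~df["_level"].isin(singletons)]
    if df.empty:
        raise ValidationError("no levels with >= 2 observations")

    levels = sorted(df["_level"].unique())
    y = df[value_col].to_numpy(dtype=float)
    X = np.column_stack([(df["_level"] == lev).to_numpy(float) for lev in levels])
    draws = gibbs_linear_regression(y, X, burnin=burnin, samples=samples,
                                    seed=seed, prior_eps=prior_eps)
    return _summaries_from_draws(draws, levels,
                                 [int(counts[lev]) for lev in levels])


def pairwise_differences(results: pd.DataFrame, value_col: str, factor: str,
                         within: str | None = None,
                         burnin: int = DEFAULT_BURNIN, samples: int = DEFAULT_SAMPLES,
                         seed: int = 0, prior_eps: float = DEFAULT_PRIOR_EPS
                         ) -> pd.DataFrame:
    """95% credibility intervals of pairwise level differences of ``factor``.

    Fits the fitted-intercept treatment-coded model with each level in turn
    as baseline; the coefficient of level B with baseline A is the B - A
    difference.  When ``within`` is given the comparison is repeated
    separately inside each level of that column (e.g. lamps compared within
    each class).  Returns a tidy frame, one row per (within-group, pair).
    """
    groups = [(None, results)] if within is None else list(results.groupby(within))

    records = []
    for gi, (group_label, df) in enumerate(groups):
        levels = sorted(df[factor].unique())
        if len(levels) < 2:
            logger.warning("group %s has < 2 levels of %s; skipped", group_label, factor)
            continue
        y = df[value_col].to_numpy(dtype=float)
        comps: dict[tuple[str, str], PairwiseComparison] = {}
        for bi, baseline in enumerate(levels[:-1]):
            others = [lev for lev in levels if lev != baseline]
            X = np.column_stack(
                [np.ones(len(df))] +
                [(df[factor] == lev).to_numpy(float) for lev in others])
            draws = gibbs_linear_regression(
                y, X, burnin=burnin, samples=samples,
                seed=(seed + 1009 * gi + 31 * bi) % (2 ** 31),
                prior_eps=prior_eps)
            for j, lev in enumerate(others, start=1):
                if (baseline, lev) in comps or (lev, baseline) in comps:
                    continue
                d = draws[:, j]
                lo, hi = np.percentile(d, [2.5, 97.5])
                comps[(baseline, lev)] = PairwiseComparison(
                    level_a=baseline, level_b=lev, diff_mean=float(d.mean()),
                    diff_ci_low=float(lo), diff_ci_high=float(hi),
                    credible=not (lo <= 0.0 <= hi))
        for (a, b), c in comps.items():
            records.append({
                "within": group_label, "level_a": a, "level_b": b,
                "diff_mean": c.diff_mean, "diff_ci_low": c.diff_ci_low,
                "diff_ci_high": c.diff_ci_high, "credible": c.credible})
    out = pd.DataFrame(records, columns=["within", "level_a", "level_b", "diff_mean",
                                         "diff_ci_low", "diff_ci_high", "credible"])
    if within is None:
        out = out.drop(columns=["within"])
    return out


def format_pairwise_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Lower-triangle presentation of pairwise differences: rows are the
    later level, columns the earlier, cells ``mean (lo, hi)`` with ``*``
    marking intervals excluding zero."""
    def cell(r):
        star = "*" if r.credible else ""
        return f"{r.diff_mean:.1f} ({r.diff_ci_low:.1f}, {r.diff_ci_high:.1f}){star}"

    df = pairs.copy()
    df["cell"] = df.apply(cell, axis=1)
    index_cols = ["within", "level_b"] if "within" in df.columns else ["level_b"]
    return df.pivot_table(index=index_cols, columns="level_a", values="cell",
                          aggfunc="first")
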