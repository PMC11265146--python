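"""Summary statistics for evaluation records.

Bootstrap confidence intervals for fold-level metrics, Kruskal-Wallis with
Dunn's post-hoc pairwise z tests (Holm-adjusted), and an OLS multivariable
summary of the experimental factors with estimated-marginal-means pairwise
contrasts — the standard reporting stack for a cross-validated benchmark
with several crossed design factors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "RegressionFit",
    "bootstrap_ci",
    "kruskal_wallis",
    "dunn_test",
    "holm_adjust",
    "ols_fit",
    "marginal_means_contrasts",
]


@dataclass
class StatResult:
    """A statistic with p-value(s), adjustment method, and optional CI."""

    statistic: float
    p_value: float | None = None
    adjusted_p: float | None = None
    method: str = ""
    ci: tuple[float, float, float] | None = None  # (lower, upper, level)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("CI lower bound exceeds upper bound")


def bootstrap_ci(
    values,
    B: int = 1000,
    level: float = 0.95,
    statistic: str = "mean",
    seed: int = 0,
) -> StatResult:
    """Percentile bootstrap CI for the mean of fold-level values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap_ci requires at least 2 values")
    if statistic != "mean":
        raise ValueError("only the mean statistic is supported")
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates is small; intervals will be noisy")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(B, len(values)))
    boot = values[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return StatResult(float(values.mean()), method=f"percentile bootstrap (B={B})", ci=(float(lo), float(hi), level))


def kruskal_wallis(groups: list) -> StatResult:
    """Kruskal-Wallis H with midrank tie correction; chi-squared p on g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis requires ≥2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatResult(0.0, 1.0, method="Kruskal-Wallis")
    H, p = sps.kruskal(*groups)
    return StatResult(float(H), float(p), method="Kruskal-Wallis")


def dunn_test(groups: list, names: list[str] | None = None) -> list[StatResult]:
    """Dunn's (1964) pairwise z tests on mean ranks, Holm-adjusted.

    Uses the pooled tie-corrected rank variance
    ``N(N+1)/12 - sum(t^3 - t) / (12(N-1))`` and two-sided normal p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("dunn_test requires ≥2 non-empty groups")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, ps = [], []
    for i, j in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(z)
        ps.append(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    adj = holm_adjust(ps)
    return [
        StatResult(float(z), float(p), float(a), method=f"Dunn: {names[i]} vs {names[j]}")
        for (i, j), z, p, a in zip(pairs, zs, ps, adj)
    ]


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjustment, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# regression + marginal means
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """An OLS fit over reference-coded categorical factors."""

    result: object  # statsmodels RegressionResults
    response: str
    terms: list[str]
    levels: dict[str, list[str]]
    reference: dict[str, str]
    table: pd.DataFrame = field(default=None)  # term, level, beta, ci, p

    @property
    def coefficients(self) -> pd.Series:
        return self.result.params


def ols_fit(
    records: pd.DataFrame,
    response: str = "balanced_accuracy",
    terms: list[str] | None = None,
    reference_levels: dict[str, str] | None = None,
) -> RegressionFit:
    """Least-squares fit of a fold metric on the crossed design factors.

    Each term is treatment (reference-level dummy) coded; the reference
    level is taken from ``reference_levels`` where given, else the first
    level in sorted order.  Classical (homoskedastic) standard errors.
    """
    if terms is None:
        terms = ["model", "direction", "condition", "fs_method"]
    reference_levels = dict(reference_levels or {})
    data = records.copy()
    levels: dict[str, list[str]] = {}
    if not terms:  # intercept-only model
        result = smf.ols(f"{response} ~ 1", data=data).fit()
        ci = result.conf_int(alpha=0.05)
        table = pd.DataFrame(
            [{"term": "Intercept", "level": "", "beta": result.params.iloc[0],
              "ci_low": ci.iloc[0, 0], "ci_high": ci.iloc[0, 1], "p_value": result.pvalues.iloc[0]}]
        )
        return RegressionFit(result, response, [], {}, {}, table)
    for t in terms:
        if t not in data.columns:
            raise ValueError(f"term '{t}' not found in records")
        lv = sorted(map(str, data[t].astype(str).unique()))
        if len(lv) < 2:
            raise ValueError(f"factor '{t}' has fewer than 2 observed levels")
        levels[t] = lv
        reference_levels.setdefault(t, lv[0])
        if reference_levels[t] not in lv:
            raise ValueError(f"reference level '{reference_levels[t]}' not observed for '{t}'")
        data[t] = data[t].astype(str)

    rhs = " + ".join(f"C({t}, Treatment(reference={reference_levels[t]!r}))" for t in terms)
    model = smf.ols(f"{response} ~ {rhs}", data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; aliased terms among {terms}")
    if len(data) <= model.exog.shape[1]:
        raise ValueError("more coefficients than observations")
    result = model.fit()

    ci = result.conf_int(alpha=0.05)
    rows = []
    for name in result.params.index:
        term, level = _parse_term(name, terms, reference_levels)
        rows.append(
            {
                "term": term,
                "level": level,
                "beta": result.params[name],
                "ci_low": ci.loc[name, 0],
                "ci_high": ci.loc[name, 1],
                "p_value": result.pvalues[name],
            }
        )
    table = pd.DataFrame(rows)
    return RegressionFit(result, response, terms, levels, reference_levels, table)


def _parse_term(name: str, terms: list[str], reference: dict[str, str]) -> tuple[str, str]:
    if name == "Intercept":
        return "Intercept", ""
    for t in terms:
        prefix = f"C({t}, Treatment(reference={reference[t]!r}))[T."
        if name.startswith(prefix):
            return t, name[len(prefix):-1]
    return name, ""


def marginal_means_contrasts(fit: RegressionFit, factor: str) -> list[StatResult]:
    """All pairwise contrasts of a factor's estimated marginal means.

    Marginal means average model predictions over the cartesian grid of
    the other factors' levels with equal weights.  Pairwise differences
    use Wald t tests on the coefficient covariance, Holm-adjusted.
    """
    if factor not in fit.terms:
        raise ValueError(f"factor '{factor}' is not in the fitted model")
    design_info = fit.result.model.data.design_info
    grid = pd.DataFrame(
        list(itertools.product(*[fit.levels[t] for t in fit.terms])), columns=fit.terms
    )
    (dmat,) = patsy.build_design_matrices([design_info], grid)
    dmat = np.asarray(dmat)

    L = {}
    for level in fit.levels[factor]:
        rows = dmat[(grid[factor] == level).to_numpy()]
        L[level] = rows.mean(axis=0)

    cov = fit.result.cov_params().to_numpy()
    beta = fit.result.params.to_numpy()
    df = fit.result.df_resid
    # scale below which an estimate/SE is numerically zero (guards the
    # saturated zero-residual fit, where cov_params is pure float noise)
    resp_scale = max(1.0, float(np.abs(fit.result.model.endog).max()))
    tiny = 1e-10 * resp_scale
    pairs = list(itertools.combinations(fit.levels[factor], 2))
    estimates, ps, ses = [], [], []
    for a, b in pairs:
        d = L[a] - L[b]
        est = float(d @ beta)
        se = float(np.sqrt(max(d @ cov @ d, 0.0)))
        if se < tiny:
            p = 1.0 if abs(est) < tiny else 0.0
        else:
            t = est / se
            p = min(1.0, 2.0 * sps.t.sf(abs(t), df))
        estimates.append(est)
        ses.append(se)
        ps.append(p)
    adj = holm_adjust(ps)
    out = []
    tcrit = sps.t.ppf(0.975, df)
    for (a, b), est, se, p, ap in zip(pairs, estimates, ses, ps, adj):
        out.append(
            StatResult(
                est,
                float(p),
                float(ap),
                method=f"emmeans {factor}: {a} - {b}",
                ci=(est - tcrit * se, est + tcrit * se, 0.95),
            )
        )
    return out
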