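"""Network-level statistics for imaging cohort tables.

Standardized general linear models per network-metric pair (outcome z-scored,
age/puberty z-scored, sex coded -0.5/+0.5 so its coefficient is a mean
contrast), AIC-based model selection among candidate formulas, a strict
p < alpha significance rule, and the single-measure two-way random-effects
absolute-agreement intraclass correlation ICC(2,1) for test-retest tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelFit",
    "ICCResult",
    "DegenerateFitError",
    "fit_age_model",
    "select_model_aic",
    "flag_significance",
    "icc_absolute_agreement",
    "fit_networks",
]


class DegenerateFitError(ValueError):
    """Outcome (or design) has no variance; the standardized fit is undefined."""


@dataclass(frozen=True)
class TermResult:
    term: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    significant: bool | None = None


@dataclass(frozen=True)
class ModelFit:
    metric: str
    network: str
    formula: tuple[str, ...]
    terms: tuple[TermResult, ...]
    r2_adj: float
    aic: float
    bic: float
    n: int

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    @property
    def n_params(self) -> int:
        return len(self.formula) + 1  # + intercept


@dataclass(frozen=True)
class ICCResult:
    icc: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    negative: bool

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.icc <= 1.0 + 1e-12):
            raise ValueError(f"ICC out of range: {self.icc}")


# term name -> column builder over a per-subject frame with z_age, sex_code, z_pds
_TERM_BUILDERS = {
    "age": lambda d: d["z_age"],
    "sex": lambda d: d["sex_code"],
    "pds": lambda d: d["z_pds"],
    "sex:pds": lambda d: d["sex_code"] * d["z_pds"],
    "age:sex": lambda d: d["z_age"] * d["sex_code"],
}


def _subject_frame(table: pd.DataFrame, metric: str, network: str) -> pd.DataFrame:
    rows = table[(table["metric"] == metric) & (table["network"] == network)]
    if rows.empty:
        raise ValueError(f"no rows for metric={metric!r}, network={network!r}")
    d = rows.drop_duplicates("subject_id").set_index("subject_id")
    if len(d) < 10:
        raise ValueError(f"need >= 10 subjects after filtering, got {len(d)}")
    out = pd.DataFrame(index=d.index)
    out["value"] = d["value"]
    out["z_age"] = (d["age"] - d["age"].mean()) / d["age"].std(ddof=1)
    out["sex_code"] = np.where(d["sex"] == "M", 0.5, -0.5)
    if "pds" in d:
        sd = d["pds"].std(ddof=1)
        out["z_pds"] = (d["pds"] - d["pds"].mean()) / (sd if sd > 0 else 1.0)
    return out


def fit_age_model(
    table: pd.DataFrame, metric: str, network: str,
    formula: Sequence[str] = ("age",),
) -> ModelFit:
    """OLS of the standardized outcome on standardized predictors.

    ``formula`` lists main-effect/interaction terms from
    {age, sex, pds, sex:pds, age:sex}; an intercept is always included.
    Coefficients are standardized betas with t-based 95% CIs.
    """
    d = _subject_frame(table, metric, network)
    sd_y = d["value"].std(ddof=1)
    if not np.isfinite(sd_y) or sd_y == 0:
        raise DegenerateFitError(f"constant outcome for {metric}/{network}")
    y = (d["value"] - d["value"].mean()) / sd_y
    X = pd.DataFrame({t: _TERM_BUILDERS[t](d) for t in formula}, index=d.index)
    X = sm.add_constant(X, prepend=True)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = tuple(
        TermResult(
            term=t, beta=float(res.params[t]),
            ci_low=float(ci.loc[t, 0]), ci_high=float(ci.loc[t, 1]),
            p=float(res.pvalues[t]),
        )
        for t in formula
    )
    return ModelFit(
        metric=metric, network=network, formula=tuple(formula), terms=terms,
        r2_adj=float(res.rsquared_adj), aic=float(res.aic), bic=float(res.bic),
        n=int(res.nobs),
    )


def select_model_aic(
    table: pd.DataFrame, metric: str, network: str,
    candidate_formulas: Sequence[Sequence[str]],
) -> tuple[tuple[str, ...], ModelFit]:
    """Fit every candidate on identical rows and return the lowest-AIC model.

    Ties (within 1e-9) break toward fewer parameters, then listed order.
    """
    if len(candidate_formulas) < 2:
        raise ValueError("need at least 2 candidate formulas")
    fits = [fit_age_model(table, metric, network, f) for f in candidate_formulas]
    if len({f.n for f in fits}) != 1:
        raise ValueError("candidates fitted on differing row sets; AIC incomparable")
    best = min(enumerate(fits), key=lambda kv: (round(kv[1].aic, 9), kv[1].n_params, kv[0]))
    return best[1].formula, best[1]


def flag_significance(fits: Sequence[ModelFit], alpha: float = 0.005) -> list[ModelFit]:
    """Annotate every term with a strict p < alpha significance flag."""
    out = []
    for f in fits:
        terms = tuple(
            TermResult(t.term, t.beta, t.ci_low, t.ci_high, t.p, significant=bool(t.p < alpha))
            for t in f.terms
        )
        out.append(ModelFit(f.metric, f.network, f.formula, terms, f.r2_adj, f.aic, f.bic, f.n))
    return out


def icc_absolute_agreement(table: pd.DataFrame, metric: str) -> ICCResult:
    """ICC(2,1): single-measure, two-way random effects, absolute agreement.

    Computed from the two-way ANOVA mean squares of the complete
    subject-by-session grid:
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Negative estimates are returned as computed and flagged.
    """
    rows = table[table["metric"] == metric]
    if rows.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    grid = rows.pivot(index="subject_id", columns="session", values="value")
    if grid.isna().any().any():
        raise ValueError("incomplete subject x session grid; ICC(2,1) requires complete data")
    x = grid.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC undefined for fewer than 2 subjects or 2 sessions")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:  # all values identical
        return ICCResult(icc=1.0, msr=msr, msc=msc, mse=mse, n=n, k=k, negative=False)
    icc = (msr - mse) / denom
    return ICCResult(icc=float(icc), msr=float(msr), msc=float(msc), mse=float(mse),
                     n=n, k=k, negative=bool(icc < 0))


def fit_networks(
    table: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    networks: Sequence[str] | None = None,
    formula: Sequence[str] = ("age",),
    alpha: float = 0.005,
) -> pd.DataFrame:
    """Fit the standardized age model for every network-metric pair.

    Returns a tidy results table (network, metric, term, beta, CI, p,
    r2_adj, aic, significant).
    """
    metrics = list(metrics) if metrics is not None else sorted(table["metric"].unique())
    networks = list(networks) if networks is not None else sorted(table["network"].unique())
    fits = [fit_age_model(table, m, nw, formula) for m in metrics for nw in networks]
    rows = []
    for f in flag_significance(fits, alpha=alpha):
        for t in f.terms:
            rows.append(
                {
                    "network": f.network, "metric": f.metric, "term": t.term,
                    "beta": t.beta, "ci_low": t.ci_low, "ci_high": t.ci_high,
                    "p": t.p, "r2_adj": f.r2_adj, "aic": f.aic, "bic": f.bic,
                    "n": f.n, "significant": t.significant,
                }
            )
    return pd.DataFrame(rows)
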