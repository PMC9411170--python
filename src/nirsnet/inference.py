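"""Brain-behavior inference chain.

Normality and variance-homogeneity screens, two-factor (skill x simulator)
between-subject effect tests with partial eta squared, Benjamini-Hochberg
FDR control, backward-elimination multiple regression, and recursive path
analysis reported as Estimate / S.E. / C.R. / P tables.

All models are ordinary least squares under the hood; the factorial model
uses effects (sum-to-zero) coding with Type-III sums of squares, the
convention of the point-and-click packages these analyses are usually run
in, so results are comparable across unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normality_screen",
    "variance_homogeneity",
    "factorial_effects",
    "estimated_marginal_means",
    "bh_adjust",
    "backward_regression",
    "RegressionResult",
    "PathModelSpec",
    "PathModel",
    "PathFitResult",
]


def normality_screen(data: pd.DataFrame, columns: Optional[Sequence[str]] = None,
                     by: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per dependent variable (optionally per
    design cell).  Advisory: results do not gate any downstream step.
    Constant samples are flagged with NaN statistics."""
    if columns is None:
        columns = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    groups = data.groupby(list(by)) if by else [((), data)]
    rows = []
    for key, g in groups:
        for col in columns:
            x = g[col].dropna().to_numpy()
            cell = dict(zip(by, key if isinstance(key, tuple) else (key,))) if by else {}
            if x.size < 3 or np.ptp(x) == 0:
                rows.append(dict(**cell, variable=col, W=np.nan, p=np.nan, flagged=True))
                continue
            W, p = stats.shapiro(x)
            rows.append(dict(**cell, variable=col, W=W, p=p, flagged=False))
    return pd.DataFrame(rows)


def variance_homogeneity(values, groups) -> tuple[float, float]:
    """Levene's test (center = mean) of equal variances across groups."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    stat, p = stats.levene(*samples, center="mean")
    return float(stat), float(p)


def _aggregate_trials(data: pd.DataFrame, dv: str, policy: str) -> pd.DataFrame:
    keys = ["subject", "skill", "simulator"]
    if policy == "trial-mean":
        return data.groupby(keys, as_index=False)[dv].mean()
    if policy == "trial-as-replicate":
        return data[keys + [dv]].copy()
    raise ValueError(f"unknown trial policy {policy!r}")


def factorial_effects(
    data: pd.DataFrame,
    dv: str,
    policy: str = "trial-mean",
) -> pd.DataFrame:
    """Two-factor between-subject effect tests for one dependent variable.

    ``data`` is tidy with columns subject, skill, simulator, ``dv`` (and
    optionally trial).  Repeated trials are reduced to subject-cell means by
    default (``policy='trial-mean'``) or kept as replicates.  The model is
    dv ~ skill * simulator with effects coding and Type-III sums of squares.

    Returns a table with one row per effect (skill, simulator,
    skill:simulator, Residual) carrying sum_sq, df, F, p and partial eta
    squared.
    """
    d = _aggregate_trials(data.dropna(subset=[dv]), dv, policy)
    counts = d.groupby(["skill", "simulator"])[dv].count()
    if len(counts) < 4 or (counts < 2).any():
        missing = counts[counts < 2].index.tolist() if len(counts) == 4 else "absent cells"
        raise ValueError(f"factorial design needs >=2 observations per cell; problem: {missing}")
    d = d.rename(columns={dv: "_dv"})
    model = smf.ols("_dv ~ C(skill, Sum) * C(simulator, Sum)", data=d).fit()
    an = sm.stats.anova_lm(model, typ=3)
    an = an.rename(index={
        "C(skill, Sum)": "skill",
        "C(simulator, Sum)": "simulator",
        "C(skill, Sum):C(simulator, Sum)": "skill:simulator",
    })
    an = an.loc[["skill", "simulator", "skill:simulator", "Residual"]]
    ss_err = an.loc["Residual", "sum_sq"]
    out = an.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    with np.errstate(invalid="ignore"):
        out["partial_eta_sq"] = out["SS"] / (out["SS"] + ss_err)
    # a constant response carries no effect: report F = 0, not 0/0 noise
    scale = max(float(len(d) * np.mean(np.abs(d["_dv"])) ** 2), float(out["SS"].sum()), 1e-300)
    degenerate = out["SS"].abs() < 1e-12 * scale
    out.loc[degenerate, ["F", "partial_eta_sq"]] = 0.0
    out.loc[degenerate, "p"] = 1.0
    out.loc["Residual", ["F", "p", "partial_eta_sq"]] = np.nan
    return out[["SS", "df", "F", "p", "partial_eta_sq"]]


def estimated_marginal_means(
    data: pd.DataFrame,
    dv: str,
    policy: str = "trial-mean",
) -> pd.DataFrame:
    """Model-based marginal means per factor level (and per cell), adjusted
    for the other factor by averaging predictions over its levels with equal
    weight; SEs from the fitted covariance of the coefficients."""
    d = _aggregate_trials(data.dropna(subset=[dv]), dv, policy).rename(columns={dv: "_dv"})
    model = smf.ols("_dv ~ C(skill, Sum) * C(simulator, Sum)", data=d).fit()
    skills = sorted(d["skill"].unique())
    sims = sorted(d["simulator"].unique())
    grid = pd.DataFrame(
        [(sk, si) for sk in skills for si in sims], columns=["skill", "simulator"]
    )
    from patsy import dmatrix

    mm = np.asarray(dmatrix(model.model.data.design_info, grid))
    cell_pred = mm @ model.params.to_numpy()
    covb = model.cov_params().to_numpy()
    rows = []
    for factor, levels in (("skill", skills), ("simulator", sims)):
        for lev in levels:
            w = (grid[factor] == lev).to_numpy(float)
            w /= w.sum()
            vec = w @ mm
            rows.append(dict(factor=factor, level=lev,
                             mean=float(vec @ model.params.to_numpy()),
                             se=float(np.sqrt(vec @ covb @ vec))))
    for k, (_, g) in enumerate(grid.iterrows()):
        vec = mm[k]
        rows.append(dict(factor="cell", level=f"{g['skill']}/{g['simulator']}",
                         mean=float(cell_pred[k]),
                         se=float(np.sqrt(vec @ covb @ vec))))
    return pd.DataFrame(rows)


def bh_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection flags at FDR level ``q``).
    """
    p = np.asarray(pvals, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adj, reject


@dataclass
class RegressionResult:
    """Final model of a backward-elimination regression."""

    retained: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fvalue: float
    df_model: float
    df_resid: float
    f_pvalue: float
    rsquared: float
    nobs: int
    trace: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Backward-elimination regression",
            "===============================",
            f"n = {self.nobs}   retained predictors: {', '.join(self.retained) or '(none)'}",
            f"F({self.df_model:.0f}, {self.df_resid:.0f}) = {self.fvalue:.3f},"
            f" p = {self.f_pvalue:.4g}, R^2 = {self.rsquared:.3f}",
            "",
            pd.DataFrame({"coef": self.params, "se": self.bse, "p": self.pvalues})
            .to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.trace:
            lines += ["", "Elimination trace:"] + [
                f"  step {s['step']}: removed {s['removed']} (p = {s['p']:.3f})"
                for s in self.trace
            ]
        return "\n".join(lines)


def backward_regression(
    y,
    X: pd.DataFrame,
    removal_p: float = 0.1,
) -> RegressionResult:
    """Backward elimination: refit OLS, drop the predictor with the largest
    partial-F p-value while it is >= ``removal_p``; stop when all retained
    predictors beat the threshold or none remain."""
    y = np.asarray(y, float)
    X = pd.DataFrame(X).copy()
    n, k = X.shape
    if n <= k + 2:
        raise ValueError(f"n = {n} too small for {k} predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()])) < k + 1:
        raise ValueError(f"rank-deficient design among predictors {list(X.columns)}")
    retained = list(X.columns)
    trace = []
    step = 0
    while True:
        exog = sm.add_constant(X[retained]) if retained else pd.DataFrame(
            {"const": np.ones(n)}, index=X.index
        )
        fit = sm.OLS(y, exog).fit()
        pvals = fit.pvalues.drop("const", errors="ignore")
        if pvals.empty or pvals.max() < removal_p:
            break
        worst = pvals.idxmax()
        step += 1
        trace.append(dict(step=step, removed=worst, p=float(pvals.max())))
        retained.remove(worst)
    fvalue = float(fit.fvalue) if retained else 0.0
    f_pvalue = float(fit.f_pvalue) if retained else 1.0
    return RegressionResult(
        retained=retained,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        fvalue=fvalue,
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
        f_pvalue=f_pvalue,
        rsquared=float(fit.rsquared) if retained else 0.0,
        nobs=int(fit.nobs),
        trace=trace,
    )


@dataclass
class PathModelSpec:
    """A recursive (acyclic) path model given as (independent -> dependent)
    arrows; exogenous variables are those never appearing as dependents."""

    arrows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.arrows = [tuple(a) for a in self.arrows]
        # cycle check by repeated removal of sink-free nodes
        deps: dict[str, set[str]] = {}
        nodes = set()
        for src, dst in self.arrows:
            deps.setdefault(dst, set()).add(src)
            nodes.update((src, dst))
        remaining = dict(deps)
        resolved = {n for n in nodes if n not in remaining}
        while remaining:
            free = [d for d, parents in remaining.items() if parents <= resolved]
            if not free:
                raise ValueError(f"path model is cyclic among {sorted(remaining)}")
            for d in free:
                resolved.add(d)
                del remaining[d]

    @property
    def endogenous(self) -> list[str]:
        seen: list[str] = []
        for _, dst in self.arrows:
            if dst not in seen:
                seen.append(dst)
        return seen

    def parents(self, dep: str) -> list[str]:
        return [src for src, dst in self.arrows if dst == dep]


@dataclass
class PathFitResult:
    """Per-arrow estimates of a recursive path model."""

    table: pd.DataFrame  # columns: dependent, independent, Estimate, S.E., C.R., P
    n: int
    estimator: str = "equation-wise OLS"
    degenerate: list[str] = field(default_factory=list)

    def summary(self) -> str:
        head = [
            "Recursive path analysis (equation-wise least squares)",
            "=====================================================",
            f"n = {self.n}   C.R. = Estimate / S.E.; P from the standard normal",
            "",
        ]
        tab = self.table.rename(columns={
            "dependent": "Dependent var.", "independent": "Independent variable",
            "Estimate": "Weight Estimate",
        })
        body = tab.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        tail = []
        if self.degenerate:
            tail = ["", "Degenerate equations (perfect fit): " + ", ".join(self.degenerate)]
        return "\n".join(head + [body] + tail)


class PathModel:
    """Recursive path model fitted equation-wise by least squares.

    Each endogenous variable is regressed on its parents; estimates are
    unstandardized coefficients with conventional OLS standard errors;
    critical ratios (C.R. = Estimate/S.E.) are referred to the standard
    normal, the convention of structural-equation software.
    """

    def __init__(self, spec: Union[PathModelSpec, list], data: pd.DataFrame):
        self.spec = spec if isinstance(spec, PathModelSpec) else PathModelSpec(spec)
        cols = {v for arrow in self.spec.arrows for v in arrow}
        missing = cols - set(data.columns)
        if missing:
            raise ValueError(f"data lacks path variables: {sorted(missing)}")
        self.data = data.dropna(subset=sorted(cols)).reset_index(drop=True)

    def fit(self) -> PathFitResult:
        n = len(self.data)
        rows = []
        degenerate = []
        for dep in self.spec.endogenous:
            parents = self.spec.parents(dep)
            if n < len(parents) + 2:
                raise ValueError(
                    f"n = {n} too small for equation {dep} ~ {' + '.join(parents)}"
                )
            X = sm.add_constant(self.data[parents])
            fit = sm.OLS(self.data[dep], X).fit()
            if fit.ssr <= 1e-12 * max(float(np.var(self.data[dep])) * n, 1e-300):
                degenerate.append(dep)
            for p in parents:
                est = float(fit.params[p])
                se = float(fit.bse[p])
                cr = est / se if se > 0 else np.inf
                pval = 2 * stats.norm.sf(abs(cr)) if np.isfinite(cr) else 0.0
                rows.append(dict(dependent=dep, independent=p, Estimate=est,
                                 **{"S.E.": se, "C.R.": cr, "P": pval}))
        return PathFitResult(pd.DataFrame(rows), n=n, degenerate=degenerate)
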