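"""Statistical layer: correlations, ANOVA + LSD letters, stepwise yield models.

The analysis mirrors the standard field-phenotyping workflow:

* Pearson correlations of every index and sensor variable against grain
  yield, with the usual significance stars (* < 0.05, ** < 0.01,
  *** < 0.001);
* agreement between ground-level and UAV-level indices (per-index Pearson
  r plus a one-way ANOVA for an observation-level effect);
* one-way ANOVA with Fisher's LSD multiple-range letters for yield-group
  comparisons (α = 0.05);
* forward/backward stepwise multiple regression of GY on a predictor
  menu, guided by the Akaike information criterion (Gaussian likelihood,
  k = 2), with an optional "simplified formula" reduction that drops
  non-significant terms and, among collinear pairs, keeps the predictor
  with the stronger marginal correlation to yield.

Fits are ordinary least squares via statsmodels on complete-case rows.
:class:`ModelFit` is a lightweight Results-style object: coefficients,
p-values, R², residual standard error, AIC, an equation string and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "correlate",
    "level_agreement",
    "anova_lsd",
    "stepwise_fit",
    "simplify_model",
    "ModelFit",
]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"


def correlate(
    data: pd.DataFrame, response: str = "gy", predictors: list[str] | None = None
) -> pd.DataFrame:
    """Pearson r and two-sided p of each variable against the response.

    Complete pairs only; needs ≥ 3 pairs per variable. A constant variable
    yields NaN r with a warning. Returns columns variable, r, p, stars, n.
    """
    if predictors is None:
        predictors = [
            c for c in data.columns
            if c != response and pd.api.types.is_numeric_dtype(data[c])
        ]
    rows = []
    y_all = data[response].astype(float)
    for var in predictors:
        pair = pd.concat([data[var].astype(float), y_all], axis=1).dropna()
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if len(pair) < 3:
            raise ValueError(f"{var}: fewer than 3 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"{var}: constant variable, correlation undefined",
                          stacklevel=2)
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(dict(variable=var, r=r, p=p, stars=_stars(p), n=len(pair)))
    return pd.DataFrame(rows)


def level_agreement(
    ground: pd.DataFrame, uav: pd.DataFrame, on: str = "plot_id",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Ground-vs-UAV agreement per index: Pearson r and ANOVA level effect.

    Both frames must cover the same plots (matched on ``on``). The ANOVA
    is a one-way test of observation level (ground vs aerial) on the
    pooled values of each index.
    """
    only_g = sorted(set(ground[on]) - set(uav[on]))
    only_u = sorted(set(uav[on]) - set(ground[on]))
    if only_g or only_u:
        raise ValueError(f"unmatched plots: ground-only={only_g}, uav-only={only_u}")
    merged = ground.merge(uav, on=on, suffixes=("_ground", "_uav"))
    if variables is None:
        variables = [
            c for c in ground.columns
            if c != on and pd.api.types.is_numeric_dtype(ground[c])
            and c in uav.columns
        ]
    rows = []
    for var in variables:
        pair = merged[[f"{var}_ground", f"{var}_uav"]].dropna()
        g, u = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
        if len(pair) < 3 or np.ptp(g) == 0 or np.ptp(u) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(g, u)
        if len(pair) >= 2:
            # clamp tiny negative F from floating error (identical groups)
            f_stat = max(float(stats.f_oneway(g, u).statistic), 0.0)
            f_p = float(stats.f.sf(f_stat, 1, 2 * len(pair) - 2))
        else:
            f_p = np.nan
        rows.append(dict(variable=var, r=r, p=p, stars=_stars(p),
                         anova_p=f_p, anova_stars=_stars(f_p), n=len(pair)))
    return pd.DataFrame(rows)


def anova_lsd(
    values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA with Fisher's LSD compact letter display.

    Groups sharing a letter are not significantly different at α. Pairwise
    tests use t = |m_i − m_j| / sqrt(MSE (1/n_i + 1/n_j)) on the ANOVA
    error degrees of freedom. Returns one row per group (descending mean)
    with n, mean and letters.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": np.asarray(groups)}).dropna()
    names = list(pd.unique(df["group"]))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = {g: df.loc[df["group"] == g, "value"].to_numpy() for g in names}
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("every group needs at least two values")

    n_total = len(df)
    k = len(names)
    grand = df["value"].mean()
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    df_err = n_total - k
    mse = ss_err / df_err
    tcrit = stats.t.ppf(1 - alpha / 2, df_err)

    means = {g: samples[g].mean() for g in names}
    order = sorted(names, key=lambda g: -means[g])

    def differ(a: str, b: str) -> bool:
        if mse == 0:
            return means[a] != means[b]
        lsd = tcrit * np.sqrt(mse * (1 / len(samples[a]) + 1 / len(samples[b])))
        return abs(means[a] - means[b]) > lsd

    # insert-and-absorb compact letter display on the descending-mean order
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(not differ(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            letters[g] += letter
    return pd.DataFrame(
        [dict(group=g, n=len(samples[g]), mean=means[g],
              letters="".join(sorted(letters[g]))) for g in order]
    )


@dataclass
class ModelFit:
    """A fitted multivariate yield model (Results-style container)."""

    response: str
    predictors: list[str]
    params: pd.Series
    pvalues: pd.Series
    r2: float
    rse: float
    aic: float
    nobs: int
    f_pvalue: float
    direction: str
    simplified: bool = False
    results: object = field(default=None, repr=False)

    def equation(self, digits: int = 3) -> str:
        """Human-readable equation string, e.g. ``gy = -0.53*asi + ... + 5.97``."""
        terms = [
            f"{self.params[p]:+.{digits}g}*{p}" for p in self.predictors
        ]
        terms.append(f"{self.params.get('const', 0.0):+.{digits}g}")
        rhs = " ".join(terms).replace("+", "+ ").replace("-", "- ").strip()
        return f"{self.response} = {rhs}"

    def summary(self) -> pd.DataFrame:
        """Coefficient table with p-values and fit statistics."""
        rows = [
            dict(term=t, coef=self.params[t], p=self.pvalues.get(t, np.nan),
                 stars=_stars(self.pvalues.get(t, np.nan)))
            for t in self.params.index
        ]
        tab = pd.DataFrame(rows)
        tab.attrs.update(r2=self.r2, rse=self.rse, aic=self.aic,
                         nobs=self.nobs, f_pvalue=self.f_pvalue,
                         direction=self.direction, simplified=self.simplified)
        return tab


def _ols(data: pd.DataFrame, response: str, predictors: list[str]):
    X = sm.add_constant(data[predictors].astype(float), has_constant="add") \
        if predictors else pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    return sm.OLS(data[response].astype(float), X).fit()


def _to_fit(res, response: str, predictors: list[str], direction: str,
            simplified: bool = False) -> ModelFit:
    rse = float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else np.nan
    return ModelFit(
        response=response,
        predictors=list(predictors),
        params=res.params,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        rse=rse,
        aic=float(res.aic),
        nobs=int(res.nobs),
        f_pvalue=float(res.f_pvalue) if predictors else np.nan,
        direction=direction,
        simplified=simplified,
        results=res,
    )


def stepwise_fit(
    data: pd.DataFrame,
    response: str = "gy",
    predictors: list[str] | None = None,
    direction: str = "forward",
) -> ModelFit:
    """AIC-guided stepwise OLS over a predictor menu.

    ``direction`` is ``forward`` (grow from the null model), ``backward``
    (prune from the full model) or ``both`` (forward passes with backward
    elimination after each addition). Complete-case rows only; candidate
    steps that fail to fit (singular design) are skipped with a log
    warning. Selection is deterministic for a fixed table: candidates are
    scanned in column order and a step is taken only when it strictly
    lowers AIC.
    """
    if predictors is None:
        predictors = [
            c for c in data.columns
            if c != response and pd.api.types.is_numeric_dtype(data[c])
        ]
    if direction not in ("forward", "backward", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    work = data[[response, *predictors]].dropna()
    if len(work) < len(predictors) + 10 and direction != "forward":
        warnings.warn("few complete rows relative to predictor count",
                      stacklevel=2)

    def aic_of(terms: list[str]) -> float:
        try:
            res = _ols(work, response, terms)
        except Exception:
            return np.inf
        if not np.all(np.isfinite(res.params)):
            return np.inf
        return res.aic

    current = list(predictors) if direction == "backward" else []
    best_aic = aic_of(current)

    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, str, str]] = []
        if direction in ("forward", "both"):
            for cand in predictors:
                if cand not in current:
                    moves.append((aic_of(current + [cand]), "add", cand))
        if direction in ("backward", "both"):
            for cand in current:
                moves.append((aic_of([t for t in current if t != cand]), "drop", cand))
        if not moves:
            break
        best = min(moves, key=lambda m: m[0])
        if best[0] < best_aic - 1e-10:
            best_aic = best[0]
            if best[1] == "add":
                current.append(best[2])
            else:
                current.remove(best[2])
            improved = True

    res = _ols(work, response, current)
    return _to_fit(res, response, current, direction)


def simplify_model(
    fit: ModelFit,
    data: pd.DataFrame,
    alpha: float = 0.05,
    collinearity_r: float = 0.70,
) -> ModelFit:
    """Reduce a fitted model to its "simplified formula".

    Iteratively: among predictor pairs whose pairwise |r| exceeds the
    collinearity threshold, drop the one with the weaker marginal
    correlation to the response; then drop the least significant
    predictor with p ≥ α; refit after each drop. If everything is
    dropped, the intercept-only model is returned with a warning.
    """
    response = fit.response
    current = list(fit.predictors)
    work = data[[response, *current]].dropna() if current else data[[response]]

    def marginal_r(p: str) -> float:
        x = work[p].to_numpy(float)
        if np.ptp(x) == 0:
            return 0.0
        return abs(stats.pearsonr(x, work[response].to_numpy(float))[0])

    while current:
        res = _ols(work, response, current)
        dropped = False
        # collinear pairs first: keep the stronger marginal correlate
        for a, b in itertools.combinations(sorted(current), 2):
            xa, xb = work[a].to_numpy(float), work[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            if abs(stats.pearsonr(xa, xb)[0]) >= collinearity_r:
                weaker = a if marginal_r(a) < marginal_r(b) else b
                current.remove(weaker)
                dropped = True
                break
        if dropped:
            continue
        pvals = res.pvalues.drop("const", errors="ignore")
        insignificant = pvals[pvals >= alpha]
        if insignificant.empty:
            break
        current.remove(insignificant.idxmax())
    if not current:
        warnings.warn("all predictors dropped; returning intercept-only model",
                      stacklevel=2)
    res = _ols(work, response, current)
    return _to_fit(res, response, current, fit.direction, simplified=True)
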