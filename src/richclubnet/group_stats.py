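"""Cognitive composites and covariate-adjusted group statistics.

Covers: z-score domain composites (executive / processing speed / memory),
the delayed-recall memory-status rule, Freedman–Lane covariate-adjusted
permutation tests with LSD-style pairwise follow-up, parametric ANCOVA with
LSD post hoc, HDRS-adjusted partial Pearson correlations, and stepwise
multiple regression with a forced covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._seeding import derive_rng
from .errors import DegenerateMetricError, ValidationError

__all__ = [
    "CognitiveComposites",
    "GroupTestResult",
    "DEFAULT_AVLT_NORMS",
    "cognitive_composites",
    "classify_memory_status",
    "adjusted_permutation_test",
    "ancova_lsd",
    "partial_correlation",
    "stepwise_regression",
]

#: Age-stratified AVLT delayed-recall cutoffs (score <= cutoff marks a memory
#: deficit). Ships with only the published 50-59y stratum; extend per local
#: norms before use on other ages.
DEFAULT_AVLT_NORMS = pd.DataFrame(
    [{"age_min": 50, "age_max": 59, "cutoff": 4}]
)

#: components of each cognitive domain: (expression, reverse?) where reverse
#: negates the z-score so that higher always means better.
_EXEC_COMPONENTS = (
    (lambda t: t["tmt_b"] - t["tmt_a"], True),
    (lambda t: t["stroop_c"] - t["stroop_a"], True),
    (lambda t: t["dst_backward"] - t["dst_forward"], False),
)
_SPEED_COMPONENTS = (
    (lambda t: t["stroop_a"], True),
    (lambda t: t["tmt_a"], True),
    (lambda t: t["sdmt"], False),
)
_MEMORY_COMPONENTS = (
    (lambda t: t[["avlt_n1", "avlt_n2", "avlt_n3", "avlt_n4", "avlt_n5"]].mean(axis=1),
     False),
    (lambda t: t["lmt"], False),
)


@dataclass
class CognitiveComposites:
    executive: np.ndarray
    speed: np.ndarray
    memory: np.ndarray

    def as_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {"executive": self.executive, "speed": self.speed, "memory": self.memory},
            index=index,
        )


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    n_perm: int = 0
    method: str = ""
    posthoc: dict = field(default_factory=dict)       # (ga, gb) -> p
    adjusted_means: dict = field(default_factory=dict)
    covariates_used: list = field(default_factory=list)


def _zscore(x: pd.Series, sample_mask: np.ndarray) -> pd.Series:
    ref = x[sample_mask].dropna()
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateMetricError("zero variance in a composite component")
    return (x - ref.mean()) / sd


def cognitive_composites(raw_tests: pd.DataFrame,
                         standardization_sample=None) -> CognitiveComposites:
    """Domain composites as unweighted means of z-scored components.

    Each component is z-scored over the standardization sample (default: all
    subjects); "reverse" components are sign-negated after z-scoring so higher
    is better on every axis. Missing raw scores propagate: a subject's
    composite is the mean of their available components.
    """
    t = raw_tests
    if standardization_sample is None:
        mask = np.ones(len(t), dtype=bool)
    else:
        mask = np.asarray(standardization_sample, dtype=bool)

    def build(components):
        cols = []
        for expr, reverse in components:
            z = _zscore(expr(t), mask)
            cols.append(-z if reverse else z)
        return pd.concat(cols, axis=1).mean(axis=1, skipna=True).to_numpy()

    return CognitiveComposites(
        executive=build(_EXEC_COMPONENTS),
        speed=build(_SPEED_COMPONENTS),
        memory=build(_MEMORY_COMPONENTS),
    )


def classify_memory_status(age: float, education: float, avlt_n5: float,
                           norm_table: pd.DataFrame | None = None) -> str:
    """"memory_deficit" iff the delayed-recall score is at or below the
    age-stratum cutoff, "intact" otherwise.

    ``education`` is part of the stratum signature in principle; the shipped
    default table stratifies by age only. A missing stratum is an error, never
    a silent default.
    """
    table = DEFAULT_AVLT_NORMS if norm_table is None else norm_table
    rows = table[(table["age_min"] <= age) & (age <= table["age_max"])]
    if len(rows) == 0:
        raise ValidationError(f"no AVLT norm stratum covers age {age}")
    cutoff = float(rows.iloc[0]["cutoff"])
    return "memory_deficit" if avlt_n5 <= cutoff else "intact"


# ---------------------------------------------------------------------------
# covariate-adjusted tests
# ---------------------------------------------------------------------------

def _design(groups, covariates) -> tuple[np.ndarray, np.ndarray, list]:
    """(reduced design [1, covs], group dummy block, group level list)."""
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    n = len(groups)
    if covariates is None:
        C = np.empty((n, 0))
        names: list = []
    else:
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            cov = covariates.copy()
            for c in names:
                if not np.issubdtype(cov[c].dtype, np.number):
                    cov[c] = pd.Categorical(cov[c]).codes  # binary indicator for e.g. gender
            C = cov.to_numpy(dtype=float)
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            names = [f"cov{i}" for i in range(C.shape[1])]
    X_red = np.column_stack([np.ones(n), C])
    G = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    if np.linalg.matrix_rank(X_red) < X_red.shape[1]:
        raise ValidationError("singular covariate design")
    return X_red, G, levels


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _group_f(y_rows: np.ndarray, M_red: np.ndarray, M_full: np.ndarray,
             df_g: int, df_e: int) -> np.ndarray:
    """Partial F for the group factor; vectorized over rows of y_rows."""
    rss_red = np.einsum("ij,ij->i", y_rows @ M_red, y_rows)
    rss_full = np.einsum("ij,ij->i", y_rows @ M_full, y_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        return ((rss_red - rss_full) / df_g) / (rss_full / df_e)


def _freedman_lane_p(y, X_red, X_full, df_g, df_e, n_perm, rng,
                     scheme: str = "freedman_lane") -> tuple[float, float]:
    """(F_obs, permutation p) under the chosen covariate-permutation scheme.

    freedman_lane: permute reduced-model residuals, re-add the covariate fit.
    residual: permute the residuals alone (simpler dialect).
    """
    n = len(y)
    M_red = np.eye(n) - _hat(X_red)
    M_full = np.eye(n) - _hat(X_full)
    f_obs = float(_group_f(y[None, :], M_red, M_full, df_g, df_e)[0])
    fitted_red = y - M_red @ y
    resid = M_red @ y
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    if scheme == "freedman_lane":
        y_star = fitted_red[None, :] + resid[perms]
    elif scheme == "residual":
        y_star = resid[perms]
    else:
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    f_null = _group_f(y_star, M_red, M_full, df_g, df_e)
    p = (1.0 + np.sum(f_null >= f_obs)) / (1.0 + n_perm)
    return f_obs, float(p)


def adjusted_permutation_test(values, groups, covariates=None, n_perm: int = 10000,
                              seed: int = 0, scheme: str = "freedman_lane",
                              posthoc: bool = True) -> GroupTestResult:
    """Omnibus covariate-adjusted permutation test on group means.

    Freedman–Lane: the outcome is regressed on covariates alone, the
    residuals are permuted and re-attached to the covariate fit, and the
    between-group partial F is recomputed on each reconstruction; the p-value
    is (1 + #{F* >= F_obs}) / (1 + n_perm). Pairwise follow-up runs the same
    scheme restricted to each pair of groups (LSD style: no multiplicity
    correction).
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    X_red, G, levels = _design(groups, covariates)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    for g in levels:
        if np.sum(groups == g) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 subjects")
    X_full = np.column_stack([X_red, G])
    df_g = G.shape[1]
    df_e = len(y) - X_full.shape[1]
    rng = derive_rng(seed, "adjusted_permutation_test")
    f_obs, p = _freedman_lane_p(y, X_red, X_full, df_g, df_e, n_perm, rng, scheme)
    result = GroupTestResult(statistic=f_obs, p_value=p, n_perm=n_perm,
                             method=f"permutation ({scheme})",
                             covariates_used=_cov_names(covariates))
    if posthoc and len(levels) > 2:
        for a_i, ga in enumerate(levels):
            for gb in levels[a_i + 1:]:
                sel = (groups == ga) | (groups == gb)
                sub_cov = _subset_cov(covariates, sel)
                Xr, Gp, _ = _design(groups[sel], sub_cov)
                Xf = np.column_stack([Xr, Gp])
                _, pp = _freedman_lane_p(
                    y[sel], Xr, Xf, 1, sel.sum() - Xf.shape[1], n_perm,
                    derive_rng(seed, "adjusted_permutation_test", ga, gb), scheme)
                result.posthoc[(ga, gb)] = pp
    return result


def _cov_names(covariates) -> list:
    if covariates is None:
        return []
    if isinstance(covariates, pd.DataFrame):
        return list(covariates.columns)
    return [f"cov{i}" for i in range(np.atleast_2d(np.asarray(covariates)).shape[-1])]


def _subset_cov(covariates, sel):
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        return covariates.loc[np.asarray(sel)].reset_index(drop=True)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        return C[sel]
    return C[sel] if C.shape[0] == len(sel) else C.T[sel]


def ancova_lsd(values, groups, covariates=None) -> GroupTestResult:
    """Parametric ANCOVA omnibus F for group plus LSD pairwise comparisons.

    The linear model is value ~ group indicators + covariates; adjusted group
    means are evaluated at the covariate grand means, and LSD post hoc tests
    are pairwise t tests on adjusted-mean contrasts using the full model's
    residual variance, uncorrected. With no covariates this reduces to
    one-way ANOVA.
    """
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    X_red, G, levels = _design(groups, covariates)
    X_full = np.column_stack([X_red, G])
    df_g = G.shape[1]
    df_e = len(y) - X_full.shape[1]
    if df_e < 1:
        raise ValidationError("not enough residual degrees of freedom")
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    rss_full = float(resid @ resid)
    M_red = np.eye(len(y)) - _hat(X_red)
    rss_red = float(y @ M_red @ y)
    f = ((rss_red - rss_full) / df_g) / (rss_full / df_e)
    p = float(stats.f.sf(f, df_g, df_e))
    mse = rss_full / df_e
    xtx_inv = np.linalg.pinv(X_full.T @ X_full)
    cov_means = X_red.mean(axis=0)  # [1, mean covariates]

    def contrast_row(level):
        row = np.zeros(X_full.shape[1])
        row[: X_red.shape[1]] = cov_means
        if level != levels[0]:
            row[X_red.shape[1] + levels[1:].index(level)] = 1.0
        return row

    adjusted = {g: float(contrast_row(g) @ beta) for g in levels}
    result = GroupTestResult(statistic=float(f), p_value=p, method="ancova",
                             adjusted_means=adjusted,
                             covariates_used=_cov_names(covariates))
    for a_i, ga in enumerate(levels):
        for gb in levels[a_i + 1:]:
            L = contrast_row(ga) - contrast_row(gb)
            se = float(np.sqrt(mse * L @ xtx_inv @ L))
            t = (adjusted[ga] - adjusted[gb]) / se
            result.posthoc[(ga, gb)] = float(2 * stats.t.sf(abs(t), df_e))
    return result


def partial_correlation(x, y, control) -> tuple[float, float]:
    """First-order partial Pearson correlation controlling one variable.

    r is the correlation of the residuals of x and y after regressing each on
    the control (with intercept); p comes from the t transform with n-3
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(x)
    if n < 4:
        raise ValidationError("partial correlation needs at least 4 subjects")
    Z = np.column_stack([np.ones(n), c])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DegenerateMetricError("zero residual variance in partial correlation")
    r = float(np.clip((rx @ ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2 * stats.t.sf(abs(t), df))


def stepwise_regression(response, candidates: dict, forced_covariate=None,
                        forced_name: str = "hrsd", p_enter: float = 0.05,
                        p_remove: float = 0.10) -> dict:
    """Forward/backward stepwise OLS with a covariate forced into every model.

    Candidates enter at p < ``p_enter`` and leave at p > ``p_remove``; the
    forced covariate is never removed. Reports standardized coefficients
    (beta) and p-values for the retained terms. Collinear candidates are
    dropped with a warning entry rather than crashing the selection.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    cand = {k: np.asarray(v, dtype=float) for k, v in candidates.items()}
    dropped = []
    kept_cand = {}
    base_cols = [np.ones(n)]
    if forced_covariate is not None:
        base_cols.append(np.asarray(forced_covariate, dtype=float))
    base = np.column_stack(base_cols)
    for name, v in cand.items():
        if np.linalg.matrix_rank(np.column_stack([base, v])) <= base.shape[1]:
            dropped.append(name)
        else:
            kept_cand[name] = v
    if n < len(kept_cand) + 3:
        raise ValidationError("too few subjects for stepwise selection")

    selected: list[str] = []

    def fit(names):
        X = base.copy()
        for nm in names:
            X = np.column_stack([X, kept_cand[nm]])
        return sm.OLS(y, X).fit()

    changed = True
    while changed:
        changed = False
        # forward step: best candidate below p_enter
        best_name, best_p = None, p_enter
        for nm in kept_cand:
            if nm in selected:
                continue
            res = fit(selected + [nm])
            p = res.pvalues[-1]
            if p < best_p:
                best_name, best_p = nm, p
        if best_name is not None:
            selected.append(best_name)
            changed = True
        # backward step: worst selected above p_remove
        if selected:
            res = fit(selected)
            ps = res.pvalues[base.shape[1]:]
            worst = int(np.argmax(ps))
            if ps[worst] > p_remove:
                selected.pop(worst)
                changed = True

    res = fit(selected)
    sy = y.std(ddof=1)
    out_terms = {}
    offset = base.shape[1]
    for k, nm in enumerate(selected):
        coef = res.params[offset + k]
        beta = coef * kept_cand[nm].std(ddof=1) / sy if sy > 0 else np.nan
        out_terms[nm] = {"coef": float(coef), "beta": float(beta),
                         "p": float(res.pvalues[offset + k])}
    forced = {}
    if forced_covariate is not None:
        fx = np.asarray(forced_covariate, dtype=float)
        forced = {"coef": float(res.params[1]),
                  "beta": float(res.params[1] * fx.std(ddof=1) / sy) if sy > 0 else np.nan,
                  "p": float(res.pvalues[1])}
    return {"selected": selected, "terms": out_terms,
            "forced": {forced_name: forced} if forced else {},
            "dropped_collinear": dropped, "r_squared": float(res.rsquared)}
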