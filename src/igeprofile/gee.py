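"""Family-aware GEE regression of asthma status on class-score factors.

Marginal (population-averaged) regression for clustered binary outcomes:
subjects nest in families, within-family dependence is modelled by an
exchangeable working correlation, and inference uses robust sandwich
standard errors, which stay valid even if the working correlation is
misspecified. Per-allergen class scores enter as categorical factors
with 4 non-reference levels — class 5, being rare, is merged into class
4, and class 0 is the reference — so each allergen contributes a global
4-df Wald test plus per-level odds ratios.

The analysis proceeds as in a screening-plus-selection design: a
univariate GEE per allergen (global Wald p < 0.05 keeps the allergen),
then forward selection into a multivariate model that always contains
age, sex and their interaction as covariates.

The default link is logit, so coefficients exponentiate to odds ratios;
a probit link is available via :class:`GEEConfig`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matrix import ReactivityMatrix

SEPARATION_COEF = 15.0


@dataclass
class GEEConfig:
    link: str = "logit"  # "logit" | "probit"
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.link not in ("logit", "probit"):
            raise ValueError("link must be 'logit' or 'probit'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class GEEFit:
    table: pd.DataFrame  # term, coefficient, robust_se, wald_chi2, df, p, or_, ci_low, ci_high
    alpha_hat: float  # estimated exchangeable correlation
    n_clusters: int
    converged: bool
    model_terms: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def encode_class_factor(scores: Sequence[float], prefix: str = "score") -> pd.DataFrame:
    """4 indicator columns for class-score levels 1–4 (5 merged into 4).

    Class 0 is the reference and carries no column. A constant input
    column yields all-zero indicators, which the fitters drop.
    """
    arr = np.asarray(scores, dtype=float)
    if ((arr < 0) | (arr > 5) | (arr != np.round(arr))).any():
        raise ValueError("class scores must be integers in 0..5")
    merged = np.minimum(arr.astype(int), 4)
    out = {f"{prefix}{level}": (merged == level).astype(float) for level in (1, 2, 3, 4)}
    return pd.DataFrame(out)


def wald_or_ci(coefficient: float, robust_se: float) -> dict[str, float]:
    """Wald χ² (1 df), p, OR and 95% CI from a coefficient and robust SE.

    OR = exp(β); CI = exp(β ± 1.96·SE); Wald = (β/SE)².
    """
    if robust_se <= 0:
        raise ValueError("robust SE must be positive")
    wald = (coefficient / robust_se) ** 2
    return {
        "wald_chi2": float(wald),
        "df": 1,
        "p": float(stats.chi2.sf(wald, df=1)),
        "or_": float(np.exp(coefficient)),
        "ci_low": float(np.exp(coefficient - 1.96 * robust_se)),
        "ci_high": float(np.exp(coefficient + 1.96 * robust_se)),
    }


def _drop_constant(design: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in design.columns if design[c].nunique() > 1]
    dropped = set(design.columns) - set(keep)
    if dropped:
        logging.getLogger("igeprofile").debug(
            "dropping constant design columns: %s", sorted(dropped))
    return design[keep]


def gee_fit(
    response: Sequence[int],
    design: pd.DataFrame,
    cluster_ids: Sequence[str],
    config: GEEConfig | None = None,
) -> GEEFit:
    """Fit a binary GEE with exchangeable working correlation.

    An intercept is added automatically; constant design columns are
    dropped. Robust (sandwich) covariance is always used. With every
    cluster a singleton the fit coincides with the ordinary GLM.
    """
    config = config or GEEConfig()
    y = np.asarray(response, dtype=float)
    groups = pd.Series(list(cluster_ids), name="family")
    if groups.nunique() < 2:
        raise ValueError("GEE needs at least 2 clusters")
    result, exog_columns = _fit_raw(y, design, groups.to_numpy(), config)
    if np.abs(result.params).max() > SEPARATION_COEF:
        warnings.warn("possible separation: |coefficient| > 15", stacklevel=2)
    rows = []
    for term, coef, se in zip(exog_columns, result.params, result.bse):
        if np.isfinite(se) and se > 0:
            cols = wald_or_ci(float(coef), float(se))
        else:  # separation or singular sandwich: inference undefined for this term
            cols = {"wald_chi2": np.nan, "df": 1, "p": np.nan,
                    "or_": float(np.exp(coef)), "ci_low": np.nan, "ci_high": np.nan}
        rows.append({"term": term, "coefficient": float(coef),
                     "robust_se": float(se), **cols})
    table = pd.DataFrame(rows)
    dep = getattr(result.cov_struct, "dep_params", 0.0)
    alpha_hat = float(dep) if np.ndim(dep) == 0 and dep is not None else 0.0
    return GEEFit(table, alpha_hat, int(groups.nunique()),
                  bool(getattr(result, "converged", True)),
                  model_terms=[c for c in exog_columns if c != "const"])


def _global_wald(result, exog_columns: list[str], term_names: Sequence[str]) -> tuple[float, int, float]:
    """Joint Wald χ² that all listed coefficients are zero (robust cov)."""
    idx = [exog_columns.index(t) for t in term_names if t in exog_columns]
    if not idx:
        return 0.0, 0, 1.0
    beta = np.asarray(result.params)[idx]
    cov = np.asarray(result.cov_params())[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        stat = float(beta @ np.linalg.pinv(cov) @ beta)
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def _fit_raw(
    y: np.ndarray, design: pd.DataFrame, groups: np.ndarray, config: GEEConfig
):
    """statsmodels fit plus the exog column list (for joint Wald tests).

    If the exchangeable-correlation iteration diverges (non-finite
    estimates), the model is refit under an independence working
    correlation — still a consistent GEE whose sandwich errors remain
    family-robust.
    """
    X = _drop_constant(design.reset_index(drop=True))
    exog = sm.add_constant(X, has_constant="add")
    link = sm.families.links.Logit() if config.link == "logit" else sm.families.links.Probit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cov_struct in (sm.cov_struct.Exchangeable(), sm.cov_struct.Independence()):
            model = sm.GEE(y, exog, groups=groups,
                           family=sm.families.Binomial(link=link),
                           cov_struct=cov_struct)
            result = model.fit(maxiter=config.max_iterations,
                               ctol=config.tolerance, cov_type="robust")
            params = np.asarray(result.params)
            if np.isfinite(params).all() and np.isfinite(np.asarray(result.bse)).all():
                return result, list(exog.columns)
            logging.getLogger("igeprofile").debug(
                "exchangeable GEE diverged; falling back to independence")
    raise ValueError("GEE estimation diverged under both working correlations")


def univariate_screen(
    matrix: ReactivityMatrix,
    asthma_status: Sequence[int],
    cluster_ids: Sequence[str],
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    config: GEEConfig | None = None,
) -> pd.DataFrame:
    """One GEE per allergen; global 4-df Wald test on its class factor.

    Returns a table (allergen_id, wald_chi2, df, p, retained); allergens
    whose fit fails to converge are logged and not retained.
    """
    config = config or GEEConfig()
    y = np.asarray(asthma_status, dtype=float)
    groups = np.asarray(list(cluster_ids))
    rows = []
    for j, allergen in enumerate(matrix.allergen_ids):
        factor = encode_class_factor(matrix.values[:, j], prefix=f"{allergen}_s")
        design = factor if covariates is None else pd.concat(
            [covariates.reset_index(drop=True), factor], axis=1)
        try:
            result, exog_cols = _fit_raw(y, design, groups, config)
            stat, df, p = _global_wald(result, exog_cols, list(factor.columns))
            rows.append((allergen, stat, df, p, p < alpha and df > 0))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"GEE failed for {allergen}: {exc}", stacklevel=2)
            rows.append((allergen, np.nan, 0, np.nan, False))
    return pd.DataFrame(rows, columns=["allergen_id", "wald_chi2", "df", "p", "retained"])


def _cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if min(table.shape) < 2:
        return 1.0 if np.array_equal(a, b) else 0.0
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))


def forward_select(
    matrix: ReactivityMatrix,
    candidates: Sequence[str],
    asthma_status: Sequence[int],
    cluster_ids: Sequence[str],
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    collinearity_v: float = 0.9,
    config: GEEConfig | None = None,
) -> tuple[GEEFit, list[str]]:
    """Forward selection of allergen factors over a covariate base model.

    Starting from covariates only (age, sex, age×sex), each step fits one
    extra candidate allergen at a time and admits the one with the
    smallest global-factor Wald p, provided p < α. Candidates whose raw
    scores have Cramér's V > ``collinearity_v`` with an already-selected
    allergen are screened out before entry. Covariates are never removed.
    """
    config = config or GEEConfig()
    y = np.asarray(asthma_status, dtype=float)
    groups = np.asarray(list(cluster_ids))
    col_of = {a: j for j, a in enumerate(matrix.allergen_ids)}
    selected: list[str] = []
    remaining = [a for a in candidates if a in col_of]

    def build_design(allergens: Sequence[str]) -> pd.DataFrame:
        parts = [covariates.reset_index(drop=True)]
        for a in allergens:
            parts.append(encode_class_factor(matrix.values[:, col_of[a]], prefix=f"{a}_s"))
        return pd.concat(parts, axis=1)

    while remaining:
        best_p, best_a = np.inf, None
        for a in list(remaining):
            if any(_cramers_v(matrix.values[:, col_of[a]],
                              matrix.values[:, col_of[s]]) > collinearity_v
                   for s in selected):
                remaining.remove(a)
                continue
            factor_cols = [f"{a}_s{lv}" for lv in (1, 2, 3, 4)]
            try:
                result, exog_cols = _fit_raw(y, build_design(selected + [a]),
                                             groups, config)
                if (np.abs(result.params).max() > SEPARATION_COEF
                        or not np.isfinite(np.asarray(result.bse)).all()):
                    remaining.remove(a)  # separation: unusable candidate
                    continue
                _, df, p = _global_wald(result, exog_cols, factor_cols)
            except (ValueError, np.linalg.LinAlgError):
                remaining.remove(a)
                continue
            if df > 0 and p < best_p:
                best_p, best_a = p, a
        if best_a is None or best_p >= alpha:
            break
        selected.append(best_a)
        remaining.remove(best_a)

    if not selected:
        warnings.warn("no candidate entered the forward model; "
                      "returning covariates-only fit", stacklevel=2)
    fit = gee_fit(y, build_design(selected), groups, config)
    return fit, selected


def classification_from_gee(
    fit: GEEFit,
    design: pd.DataFrame,
    response: Sequence[int],
    config: GEEConfig | None = None,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Threshold the fitted marginal probabilities into predicted status.

    Returns sensitivity, specificity, overall accuracy and the 2×2
    confusion counts.
    """
    config = config or GEEConfig()
    params = fit.table.set_index("term")["coefficient"]
    exog = sm.add_constant(design.reset_index(drop=True), has_constant="add")
    exog = exog[[c for c in exog.columns if c in params.index]]
    eta = exog.to_numpy() @ params.loc[exog.columns].to_numpy()
    proba = (1.0 / (1.0 + np.exp(-eta)) if config.link == "logit"
             else stats.norm.cdf(eta))
    pred = (proba > threshold).astype(int)
    true = np.asarray(response, dtype=int)
    pos, neg = true == 1, true == 0
    return {
        "sensitivity": float((pred[pos] == 1).mean()) if pos.any() else float("nan"),
        "specificity": float((pred[neg] == 0).mean()) if neg.any() else float("nan"),
        "accuracy": float((pred == true).mean()),
        "tp": int((pred[pos] == 1).sum()), "fn": int((pred[pos] == 0).sum()),
        "tn": int((pred[neg] == 0).sum()), "fp": int((pred[neg] == 1).sum()),
    }
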