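"""Individual-level association and causal analysis.

Outcome construction (PANSS percentage reductions, binary responder),
covariate-adjusted regressions of traits and efficacy on genetic scores,
trend tests, two-stage least-squares causal estimation, unit rescaling,
stratified/interaction models, mediation by conditioning, 2x2 factorial
allocation, and multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

WEAK_INSTRUMENT_F = 10.0
Z95 = 1.96


class SeparationError(RuntimeError):
    """Logistic fit shows (quasi-)complete separation; estimate withheld."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""


# ------------------------------------------------------------------ types


@dataclass
class EffectEstimate:
    """A regression effect with conventional and HC3-robust inference."""

    beta: float
    se: float
    se_hc3: float
    p: float
    p_hc3: float
    n: int
    model: str = ""
    family: str = "linear"
    p_fdr: float | None = None
    first_stage_f: float | None = None
    low_n: bool = False

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    @property
    def ci95_hc3(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se_hc3, self.beta + Z95 * self.se_hc3)

    @property
    def odds_ratio(self) -> float:
        if self.family != "logistic":
            raise AttributeError("odds_ratio defined for logistic family only")
        return float(np.exp(self.beta))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass
class CovariateSpec:
    """Ordered covariate set with automatic age-squared and categorical handling.

    ``age2`` is derived from ``age`` whenever ``age`` is present; the assigned
    drug class enters only when the outcome is a treatment-efficacy measure.
    """

    names: list[str] = field(default_factory=lambda: [
        "sex", "age", "age2", "center", "PC1", "PC2", "PC3", "PC4", "PC5",
        "course", "prev_medication",
    ])
    categorical: set[str] = field(default_factory=lambda: {"center"})

    @classmethod
    def default(cls, efficacy_outcome: bool) -> "CovariateSpec":
        spec = cls()
        if efficacy_outcome:
            spec.names = spec.names + ["drug_class"]
        return spec

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        for name in self.names:
            if name == "age2" and "age2" not in df.columns and "age" in df.columns:
                cols["age2"] = df["age"].to_numpy(dtype=float) ** 2
                continue
            if name in self.categorical:
                dummies = pd.get_dummies(df[name].astype(str), prefix=name, drop_first=True)
                for c in dummies.columns:
                    cols[c] = dummies[c].to_numpy(dtype=float)
            else:
                cols[name] = pd.to_numeric(df[name]).to_numpy(dtype=float)
        return pd.DataFrame(cols, index=df.index)


def _covariate_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=df.index)
    if isinstance(covariates, CovariateSpec):
        return covariates.design(df)
    return CovariateSpec(names=list(covariates),
                         categorical={c for c in covariates if df[c].dtype == object}).design(df)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, r = np.linalg.qr(mat)
        bad = [X.columns[j] for j in range(mat.shape[1])
               if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise CollinearityError(f"rank-deficient design; suspect columns: {bad}")


# ---------------------------------------------------------------- outcomes


def panss_reduction(baseline, endpoint, scale: str = "total"):
    """Percentage symptom reduction; positive values mean improvement.

    Totals use the conventional floor of 30 points:
    ``100 * (baseline - endpoint) / (baseline - 30)``. Subscale reductions
    omit the offset: ``100 * (baseline - endpoint) / baseline``.
    """
    baseline = np.asarray(baseline, dtype=float)
    endpoint = np.asarray(endpoint, dtype=float)
    if scale == "total":
        if np.any(baseline <= 30):
            raise ValueError("total-scale reduction undefined for baseline <= 30")
        out = 100.0 * (baseline - endpoint) / (baseline - 30.0)
    elif scale == "subscale":
        if np.any(baseline <= 0):
            raise ValueError("subscale reduction undefined for baseline <= 0")
        out = 100.0 * (baseline - endpoint) / baseline
    else:
        raise ValueError("scale must be 'total' or 'subscale'")
    return out if out.ndim else float(out)


def derive_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach reduction columns and the binary responder flag to a cohort table.

    Responder is 1 when the total reduction strictly exceeds the in-sample
    median (ties at the median are non-responders).
    """
    df = cohort.copy()
    df["reduction_total"] = panss_reduction(df["panss_base_total"], df["panss_end_total"], "total")
    for sub in ("positive", "negative", "general"):
        b, e = f"panss_base_{sub}", f"panss_end_{sub}"
        if b in df.columns:
            df[f"reduction_{sub}"] = panss_reduction(df[b], df[e], "subscale")
    med = df["reduction_total"].median()
    df["responder"] = (df["reduction_total"] > med).astype(int)
    return df


# ------------------------------------------------------------- regression


def _ols_with_hc3(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, X)
    res = model.fit()
    robust = res.get_robustcov_results(cov_type="HC3")
    return res, robust


def fit_adjusted(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates=None,
    family: str = "linear",
) -> EffectEstimate:
    """Covariate-adjusted regression of ``outcome`` on ``exposure``.

    Linear fits use OLS; logistic fits a binomial GLM and reports the
    log-odds coefficient (``odds_ratio`` exposes exp(beta)). Both
    conventional and HC3 sandwich inference are attached. Perfect separation
    raises :class:`SeparationError`; a rank-deficient design raises
    :class:`CollinearityError` naming the collinear columns.
    """
    W = _covariate_design(df, covariates)
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"),
         pd.to_numeric(df[exposure]).rename(exposure).astype(float), W],
        axis=1,
    )
    keep = X.notna().all(axis=1) & df[outcome].notna()
    X = X.loc[keep]
    y = pd.to_numeric(df.loc[keep, outcome]).to_numpy(dtype=float)
    n = len(y)
    if n <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the requested model")
    _check_rank(X)

    desc = f"{outcome} ~ {exposure} + {list(W.columns)} [{family}]"
    if family == "linear":
        res, robust = _ols_with_hc3(y, X)
        j = list(X.columns).index(exposure)
        return EffectEstimate(
            beta=float(res.params.iloc[j]), se=float(res.bse.iloc[j]),
            se_hc3=float(robust.bse[j]), p=float(res.pvalues.iloc[j]),
            p_hc3=float(robust.pvalues[j]), n=n, model=desc, family="linear",
        )
    if family != "logistic":
        raise ValueError("family must be 'linear' or 'logistic'")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = glm.fit()
            robust = glm.fit(cov_type="HC3")
        except Exception as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    sep = any("separat" in str(w.message).lower() for w in caught)
    if sep or np.any(np.abs(res.params) > 50):
        raise SeparationError("perfect or quasi-complete separation detected")
    j = list(X.columns).index(exposure)
    return EffectEstimate(
        beta=float(res.params.iloc[j]), se=float(res.bse.iloc[j]),
        se_hc3=float(robust.bse.iloc[j]), p=float(res.pvalues.iloc[j]),
        p_hc3=float(robust.pvalues.iloc[j]), n=n, model=desc, family="logistic",
    )


def trend_test(df: pd.DataFrame, characteristic: str, score: str) -> float:
    """p-for-trend of a baseline characteristic against the continuous score.

    Continuous characteristics use a linear model, binary ones a logistic
    model; unordered categoricals use the overall F test of score differences
    across levels. A constant characteristic is an error.
    """
    char = df[characteristic]
    s = pd.to_numeric(df[score]).to_numpy(dtype=float)
    if char.nunique(dropna=True) < 2:
        raise ValueError(f"{characteristic} has no variation")
    X = sm.add_constant(s)
    if char.dtype == object or isinstance(char.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(char.astype(str), drop_first=True).to_numpy(dtype=float)
        Xc = sm.add_constant(dummies)
        res = sm.OLS(s, Xc).fit()
        return float(res.f_pvalue)
    vals = pd.to_numeric(char).to_numpy(dtype=float)
    uniq = np.unique(vals[~np.isnan(vals)])
    if len(uniq) == 2:
        y01 = (vals == uniq.max()).astype(float)
        res = sm.GLM(y01, X, family=sm.families.Binomial()).fit()
        return float(res.pvalues[1])
    res = sm.OLS(vals, X).fit()
    return float(res.pvalues[1])


def two_stage_ls(
    df: pd.DataFrame,
    outcome: str,
    trait: str,
    score: str,
    covariates=None,
    covariates_in_first_stage: bool = True,
) -> EffectEstimate:
    """One-sample two-stage least squares: ``score`` instruments ``trait``.

    Stage 1 regresses the trait on the score (plus covariates by default);
    stage 2 regresses the outcome on the fitted trait plus covariates. The
    reported SE is the proper instrumental-variable variance computed from
    residuals about the *observed* trait, not the naive stage-2 OLS SE; the
    ``se_hc3`` slot carries the heteroskedasticity-robust sandwich analogue.
    A first-stage F below 10 triggers a weak-instrument warning.
    """
    W = _covariate_design(df, covariates)
    base = pd.concat([df[[outcome, trait, score]], W], axis=1).dropna()
    y = pd.to_numeric(base[outcome]).to_numpy(dtype=float)
    t = pd.to_numeric(base[trait]).to_numpy(dtype=float)
    s = pd.to_numeric(base[score]).to_numpy(dtype=float)
    Wm = base[list(W.columns)].to_numpy(dtype=float) if len(W.columns) else np.empty((len(y), 0))
    n = len(y)
    ones = np.ones((n, 1))

    Z1 = np.hstack([ones, s[:, None], Wm]) if covariates_in_first_stage else np.hstack([ones, s[:, None]])
    # first-stage F for the instrument
    fs = sm.OLS(t, Z1).fit()
    f_stat = float((fs.params[1] / fs.bse[1]) ** 2)
    if f_stat < WEAK_INSTRUMENT_F:
        warnings.warn(f"weak instrument: first-stage F = {f_stat:.2f} < 10", UserWarning)

    t_hat = Z1 @ np.linalg.lstsq(Z1, t, rcond=None)[0]
    X = np.hstack([ones, t[:, None], Wm])        # structural design (observed trait)
    Xh = np.hstack([ones, t_hat[:, None], Wm])   # instrumented design
    XtX = Xh.T @ Xh
    beta = np.linalg.solve(XtX, Xh.T @ y)
    e = y - X @ beta
    p_dim = X.shape[1]
    sigma2 = float(e @ e) / (n - p_dim)
    bread = np.linalg.inv(XtX)
    cov = sigma2 * bread
    meat = (Xh * (e**2)[:, None]).T @ Xh
    cov_r = bread @ meat @ bread * n / (n - p_dim)

    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    se_r = float(np.sqrt(cov_r[1, 1]))
    p = float(2 * sps.norm.sf(abs(b) / se))
    p_r = float(2 * sps.norm.sf(abs(b) / se_r))
    desc = f"{outcome} ~ [{trait} | {score}] + {list(W.columns)} [2SLS]"
    return EffectEstimate(beta=b, se=se, se_hc3=se_r, p=p, p_hc3=p_r, n=n,
                          model=desc, family="linear", first_stage_f=f_stat)


# ---------------------------------------------------------------- rescaling


@dataclass(frozen=True)
class RescaledEffect:
    multiplier: float  # rounded to 2 decimals, as reported
    beta: float
    ci95: tuple[float, float]


def rescale_per_trait_units(
    beta_per_sd_score: float,
    score_to_trait_beta: float,
    unit_step: float = 10.0,
    ci95: tuple[float, float] | None = None,
) -> RescaledEffect:
    """Convert a per-SD-of-score effect into an effect per ``unit_step`` of trait.

    The multiplier is ``unit_step / |score_to_trait_beta|`` rounded to two
    decimals; the effect (and CI, when given) is scaled by that multiplier.
    """
    if score_to_trait_beta == 0:
        raise ValueError("score_to_trait_beta must be nonzero")
    mult = round(unit_step / abs(score_to_trait_beta), 2)
    lo, hi = ci95 if ci95 is not None else (float("nan"), float("nan"))
    return RescaledEffect(multiplier=mult, beta=beta_per_sd_score * mult,
                          ci95=(lo * mult, hi * mult))


# ----------------------------------------------------------- stratification

HYPERLIPEMIA_TG = 151.0    # mg/dL, inclusive
HYPERLIPEMIA_HDL = 40.0    # mg/dL, inclusive
DYSGLYCEMIA_GLUCOSE = 100.8  # mg/dL, inclusive


def label_strata(df: pd.DataFrame, rule: str) -> pd.Series:
    """Binary stratum labels for the built-in rules (1 = exposed stratum).

    ``hyperlipemia``: TG >= 151 or HDL <= 40 (both inclusive);
    ``dysglycemia``: glucose >= 100.8; ``sex``/``drug_class``/any existing
    binary column pass through unchanged.
    """
    if rule == "hyperlipemia":
        return ((df["TG"] >= HYPERLIPEMIA_TG) | (df["HDL"] <= HYPERLIPEMIA_HDL)).astype(int)
    if rule == "dysglycemia":
        return (df["glucose"] >= DYSGLYCEMIA_GLUCOSE).astype(int)
    if rule in df.columns:
        return df[rule]
    raise ValueError(f"unknown stratum rule {rule!r}")


@dataclass
class StratifiedResult:
    per_stratum: dict
    p_interaction: float


def stratified_with_interaction(
    df: pd.DataFrame,
    outcome: str,
    score: str,
    stratum: str | pd.Series,
    covariates=None,
    family: str = "linear",
    min_n: int = 30,
) -> StratifiedResult:
    """Per-stratum effects plus an interaction p from the pooled product model.

    ``stratum`` is a built-in rule name or a label series. Strata with fewer
    than ``min_n`` samples are fitted but flagged ``low_n``. The pooled model
    adds stratum indicators and score-by-stratum products; ``p_interaction``
    is the (joint, for >2 levels) test of the product terms.
    """
    labels = label_strata(df, stratum) if isinstance(stratum, str) else stratum
    labels = pd.Series(labels, index=df.index)
    per: dict = {}
    for lev in sorted(labels.dropna().unique(), key=str):
        sub = df.loc[labels == lev]
        try:
            est = fit_adjusted(sub, outcome, score, covariates, family)
        except ValueError as exc:
            warnings.warn(f"stratum {lev!r} not estimable ({exc}); reported as None",
                          UserWarning)
            per[lev] = None
            continue
        est.low_n = len(sub) < min_n
        per[lev] = est

    W = _covariate_design(df, covariates)
    dummies = pd.get_dummies(labels.astype(str), prefix="stratum", drop_first=True).astype(float)
    s = pd.to_numeric(df[score]).astype(float)
    products = dummies.mul(s, axis=0)
    products.columns = [c.replace("stratum_", "scoreXstratum_") for c in dummies.columns]
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"), s.rename(score), dummies, products, W],
        axis=1,
    )
    keep = X.notna().all(axis=1) & df[outcome].notna()
    X = X.loc[keep]
    y = pd.to_numeric(df.loc[keep, outcome]).to_numpy(dtype=float)
    _check_rank(X)
    if family == "linear":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    prod_cols = [c for c in X.columns if c.startswith("scoreXstratum_")]
    if len(prod_cols) == 1:
        p_int = float(res.pvalues[prod_cols[0]])
    else:
        contrast = np.zeros((len(prod_cols), X.shape[1]))
        for r, c in enumerate(prod_cols):
            contrast[r, list(X.columns).index(c)] = 1.0
        p_int = float(np.squeeze(res.f_test(contrast).pvalue)) if family == "linear" \
            else float(np.squeeze(res.wald_test(contrast, scalar=True).pvalue))
    return StratifiedResult(per_stratum=per, p_interaction=p_int)


# ------------------------------------------------------------- mediation


@dataclass
class MediationResult:
    pqtl_effect: EffectEstimate
    trait_effect: EffectEstimate
    collinear: bool
    score_correlation: float


def mediation_condition(
    df: pd.DataFrame,
    outcome: str,
    pqtl_score: str,
    trait_score: str,
    covariates=None,
    pqtl_variant_ids: Sequence[str] | None = None,
    trait_variant_ids: Sequence[str] | None = None,
) -> MediationResult:
    """Joint model conditioning the pQTL score on the trait-weighted score.

    Both scores must be built on the identical variant set (enforced when the
    id lists are supplied), differing only in weights. Near-collinearity
    (|r| > 0.99) is flagged; each coefficient is reported conditioned on the
    other score.
    """
    if pqtl_variant_ids is not None and trait_variant_ids is not None:
        if set(pqtl_variant_ids) != set(trait_variant_ids):
            raise ValueError("mediation scores must share an identical variant set")
    r = float(np.corrcoef(pd.to_numeric(df[pqtl_score]), pd.to_numeric(df[trait_score]))[0, 1])
    collinear = abs(r) > 0.99

    W = _covariate_design(df, covariates)
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"),
         pd.to_numeric(df[pqtl_score]).rename(pqtl_score),
         pd.to_numeric(df[trait_score]).rename(trait_score), W],
        axis=1,
    )
    keep = X.notna().all(axis=1) & df[outcome].notna()
    X = X.loc[keep]
    y = pd.to_numeric(df.loc[keep, outcome]).to_numpy(dtype=float)
    if not collinear:
        _check_rank(X)
    res, robust = _ols_with_hc3(y, X)

    def _est(col: str) -> EffectEstimate:
        j = list(X.columns).index(col)
        return EffectEstimate(
            beta=float(res.params.iloc[j]), se=float(res.bse.iloc[j]),
            se_hc3=float(robust.bse[j]), p=float(res.pvalues.iloc[j]),
            p_hc3=float(robust.pvalues[j]), n=len(y),
            model=f"{outcome} ~ {pqtl_score} + {trait_score} (joint)",
        )

    return MediationResult(pqtl_effect=_est(pqtl_score), trait_effect=_est(trait_score),
                           collinear=collinear, score_correlation=r)


# -------------------------------------------------------------- factorial


def factorial_groups(score_a, score_b) -> np.ndarray:
    """2x2 allocation by median dichotomization of two scores.

    Values at or above the in-sample median count as "higher". Labels:
    0 = both lower (reference), 1 = a higher only, 2 = b higher only,
    3 = both higher.
    """
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    a_hi = a >= np.median(a)
    b_hi = b >= np.median(b)
    return (a_hi.astype(int) + 2 * b_hi.astype(int)).astype(int)


def bonferroni_threshold(alpha: float = 0.05, m: int = 4) -> float:
    """Per-test significance threshold alpha/m (0.05/4 = 0.0125 by default)."""
    return alpha / m


@dataclass
class FactorialResult:
    group_effects: dict[int, EffectEstimate]
    p_product_interaction: float
    threshold: float
    group_sizes: dict[int, int]


def factorial_effects(
    df: pd.DataFrame,
    outcome: str,
    score_a: str,
    score_b: str,
    covariates=None,
) -> FactorialResult:
    """Group-indicator regression plus the continuous product-term interaction.

    Groups 1-3 are contrasted against the both-lower reference; a separate
    model with the ``score_a * score_b`` product supplies the non-additivity
    p-value. The factorial significance threshold is Bonferroni 0.05/4.
    """
    a = pd.to_numeric(df[score_a]).to_numpy(dtype=float)
    b = pd.to_numeric(df[score_b]).to_numpy(dtype=float)
    groups = factorial_groups(a, b)
    sizes = {g: int(np.sum(groups == g)) for g in range(4)}
    if any(v == 0 for v in sizes.values()):
        raise ValueError(f"empty factorial group(s): {[g for g, v in sizes.items() if v == 0]}")

    W = _covariate_design(df, covariates)
    ind = pd.DataFrame({f"group_{g}": (groups == g).astype(float) for g in (1, 2, 3)},
                       index=df.index)
    X = pd.concat([pd.Series(1.0, index=df.index, name="const"), ind, W], axis=1)
    keep = X.notna().all(axis=1) & df[outcome].notna()
    X = X.loc[keep]
    y = pd.to_numeric(df.loc[keep, outcome]).to_numpy(dtype=float)
    _check_rank(X)
    res, robust = _ols_with_hc3(y, X)
    effects = {}
    for g in (1, 2, 3):
        j = list(X.columns).index(f"group_{g}")
        effects[g] = EffectEstimate(
            beta=float(res.params.iloc[j]), se=float(res.bse.iloc[j]),
            se_hc3=float(robust.bse[j]), p=float(res.pvalues.iloc[j]),
            p_hc3=float(robust.pvalues[j]), n=len(y),
            model=f"{outcome} ~ factorial group {g} vs reference",
        )

    Xp = pd.concat(
        [pd.Series(1.0, index=df.index, name="const"),
         pd.Series(a, index=df.index, name=score_a),
         pd.Series(b, index=df.index, name=score_b),
         pd.Series(a * b, index=df.index, name="product"), W],
        axis=1,
    ).loc[keep]
    resp = sm.OLS(y, Xp).fit()
    p_prod = float(resp.pvalues["product"])
    return FactorialResult(group_effects=effects, p_product_interaction=p_prod,
                           threshold=bonferroni_threshold(0.05, 4), group_sizes=sizes)


# ------------------------------------------------------------ multiplicity


def adjust_multiplicity(pvalues, method: str = "bh", m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m_eff = m if m is not None else len(p)
    if method == "bonferroni":
        return np.minimum(1.0, m_eff * p)
    if method != "bh":
        raise ValueError("method must be 'bh' or 'bonferroni'")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_eff / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
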