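"""Model-diagnostics protocol: heteroskedasticity, robust SEs, influence, VIF, stability.

Applied to every primary regression: Breusch-Pagan and White tests, HC3
sandwich standard errors, Cook's distance / studentized deleted residual
influence screening with refit-after-exclusion, variance inflation factors,
and the three-condition stable/sensitive classification of an estimate
against its sensitivity refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.diagnostic import het_breuschpagan, het_white
from statsmodels.stats.outliers_influence import OLSInfluence

from .onesample import EffectEstimate

COOKS_THRESHOLD = 0.5
STUDENTIZED_THRESHOLD = 4.0
VIF_THRESHOLD = 10.0


def breusch_pagan(res) -> float:
    """Breusch-Pagan LM test p-value (squared residuals on the regressors)."""
    return float(het_breuschpagan(res.resid, res.model.exog)[1])


def white_test(res) -> float:
    """White test p-value (adds squares and cross-products of regressors)."""
    return float(het_white(res.resid, res.model.exog)[1])


def hc3_se(res) -> np.ndarray:
    """HC3 sandwich standard errors for a fitted OLS or binomial GLM result."""
    if isinstance(res.model, sm.OLS):
        return np.asarray(res.get_robustcov_results(cov_type="HC3").bse)
    robust = res.model.fit(cov_type="HC3")
    return np.asarray(robust.bse)


@dataclass
class InfluenceResult:
    cooks_d: np.ndarray
    studentized_deleted: np.ndarray
    flagged: np.ndarray  # positional indices over the fitted observations


def influence(res, cooks_threshold: float = COOKS_THRESHOLD,
              studentized_threshold: float = STUDENTIZED_THRESHOLD) -> InfluenceResult:
    """Cook's distances and externally studentized residuals with flags.

    Linear models use the exact hat-matrix closed forms; logistic (GLM)
    models use the standard one-step approximations.
    """
    if isinstance(res.model, sm.OLS):
        n = int(res.nobs)
        scale_ref = 1.0 + float(np.var(res.model.endog))
        if res.ssr <= 1e-12 * n * scale_ref:  # numerically exact fit: 0/0 guard
            zeros = np.zeros(n)
            return InfluenceResult(cooks_d=zeros, studentized_deleted=zeros,
                                   flagged=np.array([], dtype=int))
        infl = OLSInfluence(res)
        cooks = np.asarray(infl.cooks_distance[0])
        student = np.asarray(infl.resid_studentized_external)
    else:
        infl = res.get_influence()
        cooks = np.asarray(infl.cooks_distance[0])
        student = np.asarray(infl.resid_studentized)
    flagged = np.nonzero((cooks > cooks_threshold)
                         | (np.abs(student) > studentized_threshold))[0]
    return InfluenceResult(cooks_d=cooks, studentized_deleted=student, flagged=flagged)


def vif(X) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 - R2_j).

    ``X`` holds the covariates only (no intercept column); each column is
    regressed on the others plus an intercept. A perfectly predictable
    column yields ``inf``.
    """
    X = pd.DataFrame(X)
    mat = X.to_numpy(dtype=float)
    n, m = mat.shape
    out = np.empty(m)
    for j in range(m):
        yj = mat[:, j]
        others = np.column_stack([np.ones(n), np.delete(mat, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def stability_classify(primary: EffectEstimate, sensitivity: EffectEstimate,
                       use_hc3_ci: bool = False) -> str:
    """"stable" iff direction, CI overlap, and 0.05-significance all agree.

    The three conditions: (i) same sign of the estimate, (ii) overlapping 95%
    CIs (conventional by default, HC3-based when ``use_hc3_ci``), (iii)
    concordant significance at alpha = 0.05. Any violation => "sensitive".
    """
    same_sign = np.sign(primary.beta) == np.sign(sensitivity.beta)
    ci_a = primary.ci95_hc3 if use_hc3_ci else primary.ci95
    ci_b = sensitivity.ci95_hc3 if use_hc3_ci else sensitivity.ci95
    overlap = ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]
    concordant = (primary.p < 0.05) == (sensitivity.p < 0.05)
    return "stable" if (same_sign and overlap and concordant) else "sensitive"


@dataclass
class DiagnosticsReport:
    bp_p: float
    white_p: float
    hc3_se: np.ndarray
    cooks_d: np.ndarray
    studentized_deleted: np.ndarray
    influential_idx: np.ndarray
    vif: pd.Series
    refit_beta: float | None
    stability: str

    def to_dict(self) -> dict:
        return {
            "bp_p": self.bp_p,
            "white_p": self.white_p,
            "n_influential": int(len(self.influential_idx)),
            "max_vif": float(self.vif.max()) if len(self.vif) else float("nan"),
            "refit_beta": self.refit_beta,
            "stability": self.stability,
        }


def diagnose_linear(y, X: pd.DataFrame, focus: str) -> DiagnosticsReport:
    """Run the full diagnostics protocol on one linear model.

    Fits OLS of ``y`` on ``X`` (which must contain an intercept column named
    ``const``), flags influential observations, refits without them, and
    classifies the focus coefficient as stable or sensitive.
    """
    y = np.asarray(y, dtype=float)
    res = sm.OLS(y, X).fit()
    robust_se = hc3_se(res)
    infl = influence(res)
    cols = list(X.columns)
    j = cols.index(focus)

    def _estimate(r, rob_se) -> EffectEstimate:
        b = float(np.asarray(r.params)[j])
        shc3 = float(rob_se[j])
        return EffectEstimate(
            beta=b, se=float(np.asarray(r.bse)[j]), se_hc3=shc3,
            p=float(np.asarray(r.pvalues)[j]),
            p_hc3=float(2 * norm.sf(abs(b) / shc3)) if shc3 > 0 else 1.0,
            n=int(r.nobs), model=f"~ {focus}",
        )

    primary = _estimate(res, robust_se)
    refit_beta = None
    if len(infl.flagged) and len(y) - len(infl.flagged) > X.shape[1] + 1:
        mask = np.ones(len(y), dtype=bool)
        mask[infl.flagged] = False
        res2 = sm.OLS(y[mask], X.loc[mask]).fit()
        sens = _estimate(res2, hc3_se(res2))
        refit_beta = sens.beta
        stability = stability_classify(primary, sens)
    else:
        stability = "stable"

    cov_cols = [c for c in cols if c != "const"]
    vifs = pd.Series(vif(X[cov_cols]), index=cov_cols) if cov_cols else pd.Series(dtype=float)
    return DiagnosticsReport(
        bp_p=breusch_pagan(res), white_p=white_test(res), hc3_se=robust_se,
        cooks_d=infl.cooks_d, studentized_deleted=infl.studentized_deleted,
        influential_idx=infl.flagged, vif=vifs, refit_beta=refit_beta,
        stability=stability,
    )
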