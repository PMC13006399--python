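"""Summary-statistics Mendelian randomization estimators and pleiotropy tests.

Implements inverse-variance-weighted (fixed and multiplicative random
effects), weighted-median, Egger regression with its intercept pleiotropy
test, Cochran's Q heterogeneity, and a PRESSO-style residual-sum-of-squares
outlier test, all from their defining formulas on harmonized per-variant
(beta_exposure, beta_outcome) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

Z95 = 1.96


@dataclass
class MRInput:
    """Harmonized per-variant effects of instruments on exposure and outcome."""

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        k = len(self.beta_exposure)
        if not (len(self.se_exposure) == len(self.beta_outcome) == len(self.se_outcome) == k):
            raise ValueError("all four arrays must share a length")
        if k < 1:
            raise ValueError("at least one instrument required")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        if self.ids is None:
            self.ids = [f"v{i + 1}" for i in range(k)]

    @property
    def k(self) -> int:
        return len(self.beta_exposure)

    @property
    def wald_ratios(self) -> np.ndarray:
        return self.beta_outcome / self.beta_exposure

    @property
    def ivw_weights(self) -> np.ndarray:
        """Second-order-free weights (beta_exposure / se_outcome)^2."""
        return (self.beta_exposure / self.se_outcome) ** 2

    def subset(self, mask: np.ndarray) -> "MRInput":
        mask = np.asarray(mask, dtype=bool)
        return MRInput(self.beta_exposure[mask], self.se_exposure[mask],
                       self.beta_outcome[mask], self.se_outcome[mask],
                       ids=[i for i, m in zip(self.ids, mask) if m])


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    p: float
    n_variants: int
    q_statistic: float | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    outliers_removed: list[str] = field(default_factory=list)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)


# ----------------------------------------------------------------------- IVW


def ivw(mri: MRInput, random_effects: str | bool = "auto") -> MRResult:
    """Inverse-variance-weighted meta-analysis of per-variant Wald ratios.

    Fixed-effects SE is (sum of weights)^-1/2; the multiplicative
    random-effects model inflates it by max(1, sqrt(Q/(k-1))).
    ``random_effects="auto"`` switches to random effects when the
    heterogeneity test has p < 0.05 (and k > 1).
    """
    w = mri.ivw_weights
    ratios = mri.wald_ratios
    est = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q, _, q_p = cochran_q(mri, est)

    if random_effects == "auto":
        use_random = mri.k > 1 and q_p < 0.05
    else:
        use_random = bool(random_effects) and mri.k > 1
    if use_random:
        scale = max(1.0, float(np.sqrt(q / (mri.k - 1))))
        se = se_fixed * scale
        method = "ivw_random"
    else:
        se = se_fixed
        method = "ivw_fixed"
    p = float(2 * sps.norm.sf(abs(est) / se)) if se > 0 else 1.0
    return MRResult(method=method, estimate=est, se=se, p=p,
                    n_variants=mri.k, q_statistic=q, q_p=q_p)


def cochran_q(mri: MRInput, estimate: float | None = None) -> tuple[float, int, float]:
    """Heterogeneity statistic Q = sum w_j (ratio_j - estimate)^2, df = k - 1."""
    if estimate is None:
        w0 = mri.ivw_weights
        estimate = float(np.sum(w0 * mri.wald_ratios) / np.sum(w0))
    w = mri.ivw_weights
    q = float(np.sum(w * (mri.wald_ratios - estimate) ** 2))
    df = mri.k - 1
    p = float(sps.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


# ------------------------------------------------------------ weighted median


def weighted_median(mri: MRInput, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator with seeded parametric-bootstrap SE.

    The estimate is the Wald ratio where the normalized cumulative
    inverse-variance weight crosses one half, linearly interpolated between
    the flanking order statistics.
    """
    if mri.k < 3:
        raise ValueError("weighted median requires at least 3 instruments")

    est = _wm_point(mri.wald_ratios, mri.ivw_weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(mri.beta_exposure, mri.se_exposure)
        by = rng.normal(mri.beta_outcome, mri.se_outcome)
        boots[b] = _wm_point(by / bx, (bx / mri.se_outcome) ** 2)
    se = float(np.std(boots, ddof=1))
    p = float(2 * sps.norm.sf(abs(est) / se)) if se > 0 else 1.0
    return MRResult(method="wm", estimate=est, se=se, p=p, n_variants=mri.k)


def _wm_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # cumulative weight evaluated at each ratio's "midpoint" mass
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5))
    frac = (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1]))


# --------------------------------------------------------------------- Egger


def egger(mri: MRInput) -> MRResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    Inputs are re-oriented so all exposure betas are positive, then a WLS fit
    with intercept and weights 1/se_outcome^2 provides the slope (causal
    estimate) and the intercept test for directional pleiotropy (t-based,
    k - 2 df, residual-scaled covariance).
    """
    if mri.k < 3:
        raise ValueError("Egger regression requires at least 3 instruments")
    sign = np.where(mri.beta_exposure < 0, -1.0, 1.0)
    bx = mri.beta_exposure * sign
    by = mri.beta_outcome * sign
    w = 1.0 / mri.se_outcome**2

    X = np.column_stack([np.ones(mri.k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = mri.k - 2
    scale = float(resid @ (w * resid)) / dof
    cov = scale * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):  # exact fits give se = 0
        tvals = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    return MRResult(
        method="egger", estimate=float(coef[1]), se=float(se[1]), p=float(pvals[1]),
        n_variants=mri.k, egger_intercept=float(coef[0]),
        egger_intercept_se=float(se[0]), egger_intercept_p=float(pvals[0]),
    )


# -------------------------------------------------------------------- PRESSO


@dataclass
class PressoResult:
    global_p: float
    outlier_p: np.ndarray  # Bonferroni-adjusted per-variant p
    outliers: list[str]
    filtered: MRInput
    global_rss: float


def _loo_ivw_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out slopes of weighted zero-intercept regression of by on bx."""
    num = w * bx * by
    den = w * bx * bx
    return (num.sum() - num) / (den.sum() - den)


def mr_presso(mri: MRInput, n_sim: int = 1000, seed: int = 0,
              significance: float = 0.05) -> PressoResult:
    """PRESSO-style global and per-variant outlier test.

    The observed weighted residual sum of squares of outcome betas about
    leave-one-out IVW fits is compared against ``n_sim`` parametric
    simulations from the no-pleiotropy model (effects resampled from their
    reported SEs around the leave-one-out predictions). Per-variant p-values
    come from the analogous single-variant comparison, Bonferroni-adjusted;
    variants below ``significance`` are removed from the returned input.
    """
    if mri.k < 4:
        raise ValueError("PRESSO needs at least 4 instruments for leave-one-out fits")
    rng = np.random.default_rng(seed)
    k = mri.k
    bx, by = mri.beta_exposure, mri.beta_outcome
    sx, sy = mri.se_exposure, mri.se_outcome
    w = 1.0 / sy**2

    slopes = _loo_ivw_slopes(bx, by, w)
    obs_contrib = w * (by - slopes * bx) ** 2
    obs_rss = float(obs_contrib.sum())

    sim_bx = rng.normal(bx, sx, size=(n_sim, k))
    sim_by = rng.normal(slopes * bx, sy, size=(n_sim, k))
    num = w * sim_bx * sim_by
    den = w * sim_bx * sim_bx
    sim_slopes = (num.sum(axis=1, keepdims=True) - num) / (den.sum(axis=1, keepdims=True) - den)
    sim_contrib = w * (sim_by - sim_slopes * sim_bx) ** 2
    sim_rss = sim_contrib.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (1 + n_sim))
    per_p = (1 + np.sum(sim_contrib >= obs_contrib, axis=0)) / (1 + n_sim)
    per_p_adj = np.minimum(1.0, per_p * k)
    outlier_mask = (per_p_adj < significance) & (global_p < significance)
    outliers = [mri.ids[i] for i in np.nonzero(outlier_mask)[0]]
    filtered = mri.subset(~outlier_mask) if outlier_mask.any() else mri
    return PressoResult(global_p=global_p, outlier_p=per_p_adj, outliers=outliers,
                        filtered=filtered, global_rss=obs_rss)


def run_all_estimators(mri: MRInput, n_boot: int = 1000, seed: int = 0) -> list[MRResult]:
    """IVW (auto fixed/random), weighted median and Egger on one input."""
    out = [ivw(mri)]
    if mri.k >= 3:
        out.append(weighted_median(mri, n_boot=n_boot, seed=seed))
        out.append(egger(mri))
    return out
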