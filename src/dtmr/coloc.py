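"""Bayesian colocalization of two association signals in one locus.

Per-variant approximate Bayes factors (Wakefield) feed the standard
five-hypothesis enumeration (H0: no association; H1/H2: one trait only;
H3: two distinct causal variants; H4: one shared causal variant). Loci are
LD-pruned beforehand with a sliding-window pairwise rule (500 kb, r2 0.8 by
default), and the variant with the highest per-SNP H4 posterior is reported
as the lead shared variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_PRIORS = {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5}
DEFAULT_PRIOR_SD = 0.15
PP_H4_THRESHOLD = 0.6  # decision threshold for a shared causal variant


@dataclass
class ColocInput:
    """Aligned per-variant summary pairs for two traits over one variant universe."""

    ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        k = len(self.ids)
        if not (len(self.beta1) == len(self.se1) == len(self.beta2) == len(self.se2) == k):
            raise ValueError("all arrays must match the id list length")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("standard errors must be positive")

    @classmethod
    def from_pvalues(cls, ids, p1, maf1, n1, p2, maf2, n2) -> "ColocInput":
        """Build from p-values + MAF + N when betas are unavailable.

        |z| is recovered from the p-value and the SE from the binomial
        variance approximation for a variance-1 trait,
        se = 1/sqrt(2 * MAF * (1-MAF) * (n + z^2)); the (unknown) sign is
        irrelevant to the Bayes factors.
        """
        b1, s1 = _z_to_beta_se(np.asarray(p1, float), np.asarray(maf1, float), np.asarray(n1, float))
        b2, s2 = _z_to_beta_se(np.asarray(p2, float), np.asarray(maf2, float), np.asarray(n2, float))
        return cls(ids=list(ids), beta1=b1, se1=s1, beta2=b2, se2=s2)


def _z_to_beta_se(p, maf, n):
    from scipy.stats import norm

    z = norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * (n + z**2))
    return z * se, se


@dataclass
class ColocResult:
    pp: dict[str, float]                # posterior for H0..H4, sums to 1
    priors: dict[str, float]
    snp_pp_h4: pd.Series                # per-variant posterior of being the shared SNP
    lead_variant: str
    lead_pp_h4: float
    n_variants: int


# ------------------------------------------------------------------ pruning


def ld_prune_region(
    variants: pd.DataFrame,
    ld,
    window_bp: int = 500_000,
    r2_max: float = 0.8,
) -> list[str]:
    """Sliding-window pairwise LD pruning.

    For every pair within ``window_bp`` of each other with r2 >= ``r2_max``,
    the variant with the larger p is dropped (tie: the later position).
    ``variants`` needs columns variant_id/pos/p; ``ld`` is a DataFrame or
    pair-keyed dict of r2 values.
    """
    df = variants.reset_index(drop=True)
    ids = df["variant_id"].astype(str).tolist()
    pos = df["pos"].to_numpy()
    pvals = df["p"].to_numpy(dtype=float)
    # priority: smaller p first, earlier position breaking ties
    priority = sorted(range(len(ids)), key=lambda i: (pvals[i], pos[i]))
    alive = [True] * len(ids)
    for i in priority:
        if not alive[i]:
            continue
        for j in range(len(ids)):
            if j == i or not alive[j]:
                continue
            if abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            if _pair_r2(ld, ids[i], ids[j]) >= r2_max:
                alive[j] = False
    return [ids[i] for i in range(len(ids)) if alive[i]]


def _pair_r2(ld, a: str, b: str) -> float:
    if isinstance(ld, pd.DataFrame):
        return float(ld.loc[a, b])
    if (a, b) in ld:
        return float(ld[(a, b)])
    if (b, a) in ld:
        return float(ld[(b, a)])
    return 0.0


# --------------------------------------------------------------------- ABF


def wakefield_log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor for one association.

    With z = beta/se and r = prior_sd^2 / (prior_sd^2 + se^2):
    log ABF = 0.5 * [log(1 - r) + r * z^2].
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return out if out.ndim else float(out)


# --------------------------------------------------------------- posteriors


def coloc_posteriors(
    inp: ColocInput,
    priors: dict[str, float] | None = None,
    prior_sd1: float = DEFAULT_PRIOR_SD,
    prior_sd2: float = DEFAULT_PRIOR_SD,
) -> ColocResult:
    """Enumerate the five colocalization hypotheses from per-variant ABFs.

    Priors: p1/p2 for a variant being causal for one trait only, p12 for a
    shared causal variant (defaults 1e-4, 1e-4, 1e-5). The per-variant H4
    posterior is the normalized product of the two traits' Bayes factors.
    """
    if len(inp.ids) < 2:
        raise ValueError("colocalization needs at least 2 variants")
    pr = dict(DEFAULT_PRIORS)
    if priors:
        pr.update(priors)
    l1 = wakefield_log_abf(inp.beta1, inp.se1, prior_sd1)
    l2 = wakefield_log_abf(inp.beta2, inp.se2, prior_sd2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    # sum over i != j of ABF1_i * ABF2_j = (sum ABF1)(sum ABF2) - sum ABF1*ABF2
    both = lsum1 + lsum2
    if both > lsum12:
        lcross = both + np.log1p(-np.exp(lsum12 - both))
    else:  # numerically everything on the diagonal
        lcross = -np.inf

    log_unnorm = {
        "H0": 0.0,
        "H1": np.log(pr["p1"]) + lsum1,
        "H2": np.log(pr["p2"]) + lsum2,
        "H3": np.log(pr["p1"]) + np.log(pr["p2"]) + lcross,
        "H4": (np.log(pr["p12"]) + lsum12) if pr["p12"] > 0 else -np.inf,
    }
    keys = list(log_unnorm)
    vals = np.array([log_unnorm[k] for k in keys])
    norm = logsumexp(vals[np.isfinite(vals)])
    pp = {k: (float(np.exp(v - norm)) if np.isfinite(v) else 0.0) for k, v in zip(keys, vals)}

    snp_log = l1 + l2
    snp_pp = np.exp(snp_log - logsumexp(snp_log))
    snp_series = pd.Series(snp_pp, index=inp.ids, name="snp_pp_h4")
    lead_idx = int(np.argmax(snp_pp))
    return ColocResult(
        pp=pp, priors=pr, snp_pp_h4=snp_series,
        lead_variant=inp.ids[lead_idx], lead_pp_h4=float(snp_pp[lead_idx]),
        n_variants=len(inp.ids),
    )


def result_to_dict(res: ColocResult) -> dict:
    """JSON-ready representation of a colocalization result."""
    return {
        "pp": res.pp,
        "priors": res.priors,
        "lead_variant": res.lead_variant,
        "lead_pp_h4": res.lead_pp_h4,
        "n_variants": res.n_variants,
        "snp_pp_h4": {k: float(v) for k, v in res.snp_pp_h4.items()},
    }
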