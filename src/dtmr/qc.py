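"""Variant- and sample-level genotype quality control with an auditable exclusion cascade.

Variant filters: missingness, minor allele frequency, and an exact
Hardy-Weinberg equilibrium test. Sample filters: missingness, heterozygosity
outliers, method-of-moments relatedness (PI-hat), and principal-component
outliers. All removals are recorded step by step in an
:class:`ExclusionLedger` whose arithmetic always balances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .panel import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; the defaults reproduce the study protocol.

    Variants are removed when missingness > ``variant_missing_max``, MAF
    strictly below ``variant_maf_min``, or exact HWE p < ``hwe_p_min``.
    Samples are removed for missingness > ``sample_missing_max``,
    heterozygosity beyond ``het_sd`` standard deviations, pairwise PI-hat
    >= ``ibd_max``, or any top-5 PC score beyond ``pc_outlier_sd`` SDs.
    """

    variant_missing_max: float = 0.02
    variant_maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.05
    het_sd: float = 3.0
    ibd_max: float = 0.2
    pc_outlier_sd: float = 6.0
    n_pcs: int = 5


@dataclass
class ExclusionLedger:
    """Ordered bookkeeping of sequential removals: (label, n_removed, n_remaining)."""

    n_start: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, label: str, n_removed: int) -> None:
        if n_removed < 0:
            raise ValueError("n_removed must be >= 0")
        self.rows.append((label, n_removed, self.n_remaining - n_removed))

    @property
    def n_remaining(self) -> int:
        return self.rows[-1][2] if self.rows else self.n_start

    def validate(self) -> None:
        prev = self.n_start
        for label, removed, remaining in self.rows:
            if remaining != prev - removed or remaining < 0:
                raise ValueError(f"ledger imbalance at step {label!r}")
            prev = remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "n_removed", "n_remaining"])


# --------------------------------------------------------------------- HWE


def hwe_test(n_hom_a: int, n_het: int, n_hom_b: int, method: str = "exact") -> float:
    """Two-sided Hardy-Weinberg equilibrium p-value from genotype counts.

    The default is the exact test conditional on the observed allele counts:
    the p-value is the total probability of all heterozygote configurations
    at most as probable as the observed one. Symmetric under allele
    relabeling. ``method="chisq"`` gives the 1-df goodness-of-fit test.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("HWE test undefined for all-zero counts")
    if method == "chisq":
        return _hwe_chisq(n_hom_a, n_het, n_hom_b)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    n_a = 2 * n_hom_a + n_het  # copies of allele a
    n_b = 2 * n_hom_b + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    # log P(h hets | n, rare) for every feasible h (same parity as rare)
    hs = np.arange(rare % 2, rare + 1, 2)
    hs = hs[(rare - hs) % 2 == 0]
    n_rr = (rare - hs) // 2
    n_cc = (n_a + n_b - rare - hs) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_rr + 1)
        - gammaln(hs + 1)
        - gammaln(n_cc + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = n_het
    obs_idx = np.nonzero(hs == obs)[0]
    if len(obs_idx) == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[obs_idx[0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _hwe_chisq(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    n = n_hom_a + n_het + n_hom_b
    p = (2 * n_hom_a + n_het) / (2.0 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_a, n_het, n_hom_b], dtype=float)
    mask = exp > 0
    stat = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    return float(chi2.sf(stat, df=1))


# --------------------------------------------------------------- variant QC


@dataclass
class VariantQCResult:
    kept: list[str]
    removed: dict[str, str]  # variant_id -> first failing rule
    ledger: ExclusionLedger


def variant_qc(panel: GenotypePanel, thresholds: QCThresholds = QCThresholds()) -> VariantQCResult:
    """Apply the variant filters in order: missingness, MAF, HWE.

    Each removed variant carries the first rule it failed. MAF removal is
    strict (< ``variant_maf_min``): a variant at exactly the threshold stays.
    """
    miss = panel.variant_missingness()
    maf = panel.minor_allele_frequency()
    removed: dict[str, str] = {}
    kept: list[str] = []
    for j, vid in enumerate(panel.variant_ids):
        if miss[j] > thresholds.variant_missing_max:
            removed[vid] = "missingness"
        elif np.isnan(maf[j]) or maf[j] < thresholds.variant_maf_min:
            removed[vid] = "maf"
        elif hwe_test(*panel.genotype_counts(j)) < thresholds.hwe_p_min:
            removed[vid] = "hwe"
        else:
            kept.append(vid)
    ledger = ExclusionLedger(n_start=panel.n_variants)
    for rule in ("missingness", "maf", "hwe"):
        ledger.record(rule, sum(1 for r in removed.values() if r == rule))
    ledger.validate()
    return VariantQCResult(kept=kept, removed=removed, ledger=ledger)


# ---------------------------------------------------------------- sample QC


@dataclass
class SampleQCResult:
    kept: list[str]
    removed: dict[str, str]
    ledger: ExclusionLedger
    pi_hat: pd.DataFrame | None = None


def _standardized(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls, then center/scale columns to unit variance."""
    x = dosages.copy()
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    x -= col_mean
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def pi_hat_matrix(panel: GenotypePanel) -> np.ndarray:
    """Method-of-moments relatedness from dosages (genomic-relationship form).

    Entry (i, j) estimates the expected allele-sharing proportion; ~1 for
    duplicates, ~0.5 for first-degree relatives, ~0 for unrelated pairs.
    """
    x = _standardized(panel.dosages)
    return (x @ x.T) / panel.n_variants


def principal_components(panel: GenotypePanel, n_pcs: int = 5) -> np.ndarray:
    x = _standardized(panel.dosages)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k]


def sample_qc(panel: GenotypePanel, thresholds: QCThresholds = QCThresholds()) -> SampleQCResult:
    """Sequential sample filters: missingness, heterozygosity, relatedness, PCs.

    Relatedness removes one member per flagged pair (the one with higher
    missingness; ties broken by lexicographic sample id). PCA is skipped with
    a warning when fewer than 3 samples survive the earlier steps.
    """
    ledger = ExclusionLedger(n_start=panel.n_samples)
    removed: dict[str, str] = {}
    alive = np.ones(panel.n_samples, dtype=bool)
    ids = panel.sample_ids

    miss = panel.sample_missingness()
    for i in np.nonzero(miss > thresholds.sample_missing_max)[0]:
        removed[ids[i]] = "missingness"
        alive[i] = False
    ledger.record("missingness", int((~alive).sum()))

    sub = panel.subset(sample_idx=np.nonzero(alive)[0])
    het_removed = 0
    if sub.n_samples >= 2:
        hard = np.rint(sub.dosages)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            het_rate = np.nanmean(hard == 1, axis=1)
        mu, sd = np.nanmean(het_rate), np.nanstd(het_rate)
        if sd > 0:
            for i in np.nonzero(np.abs(het_rate - mu) > thresholds.het_sd * sd)[0]:
                sid = sub.sample_ids[i]
                removed[sid] = "heterozygosity"
                alive[ids.index(sid)] = False
                het_removed += 1
    ledger.record("heterozygosity", het_removed)

    sub = panel.subset(sample_idx=np.nonzero(alive)[0])
    rel_removed = 0
    if sub.n_variants < 100:
        # PI-hat from few markers is pure noise (sd ~ 1/sqrt(m)); skip rather
        # than mass-flag unrelated pairs
        logger.warning("only %d variants; relatedness step skipped", sub.n_variants)
    elif sub.n_samples >= 2:
        pi = pi_hat_matrix(sub)
        sub_miss = sub.sample_missingness()
        order = np.argsort(sub.sample_ids)
        flagged: set[str] = set()
        iu, ju = np.triu_indices(sub.n_samples, k=1)
        for i, j in zip(iu, ju):
            if pi[i, j] < thresholds.ibd_max:
                continue
            si, sj = sub.sample_ids[i], sub.sample_ids[j]
            if si in flagged or sj in flagged:
                continue
            if sub_miss[i] > sub_miss[j]:
                drop = si
            elif sub_miss[j] > sub_miss[i]:
                drop = sj
            else:
                drop = max(si, sj)  # tie: keep lexicographically smaller id
            flagged.add(drop)
        for sid in sorted(flagged):
            removed[sid] = "relatedness"
            alive[ids.index(sid)] = False
            rel_removed += 1
    ledger.record("relatedness", rel_removed)

    sub = panel.subset(sample_idx=np.nonzero(alive)[0])
    pc_removed = 0
    if sub.n_samples < 3:
        logger.warning("fewer than 3 samples remain; PCA outlier step skipped")
    else:
        pcs = principal_components(sub, thresholds.n_pcs)
        mu = pcs.mean(axis=0)
        sd = pcs.std(axis=0)
        sd[sd == 0] = np.inf
        outlier = (np.abs(pcs - mu) > thresholds.pc_outlier_sd * sd).any(axis=1)
        for i in np.nonzero(outlier)[0]:
            sid = sub.sample_ids[i]
            removed[sid] = "pc_outlier"
            alive[ids.index(sid)] = False
            pc_removed += 1
    ledger.record("pc_outlier", pc_removed)

    ledger.validate()
    kept = [ids[i] for i in np.nonzero(alive)[0]]
    return SampleQCResult(kept=kept, removed=removed, ledger=ledger)


# --------------------------------------------------------------- cascades


def exclusion_cascade(
    initial_ids: Iterable[str],
    steps: Sequence[tuple[str, Iterable[str]]],
) -> tuple[ExclusionLedger, list[str]]:
    """Apply ordered removal steps to a starting id set.

    Removal is sequential: a later step only acts on survivors, so an id
    named by several steps is counted once, at its first removing step. Ids
    unknown to the current survivor set are ignored with a warning.
    """
    remaining = list(dict.fromkeys(str(i) for i in initial_ids))
    ledger = ExclusionLedger(n_start=len(remaining))
    alive = set(remaining)
    universe = set(remaining)
    for label, ids in steps:
        ids = {str(i) for i in ids}
        unknown = ids - universe
        if unknown:
            logger.warning("step %r names %d unknown ids; ignored", label, len(unknown))
        hit = ids & alive
        alive -= hit
        ledger.record(label, len(hit))
    ledger.validate()
    return ledger, [i for i in remaining if i in alive]


def exclusion_cascade_counts(n_start: int, steps: Sequence[tuple[str, int]]) -> ExclusionLedger:
    """Count-only convenience wrapper: disjoint removal steps of given sizes."""
    ledger = ExclusionLedger(n_start=n_start)
    for label, n_removed in steps:
        ledger.record(label, int(n_removed))
    ledger.validate()
    return ledger
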