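"""Instrument selection, direction harmonization, weighted scores, and strength statistics.

A drug-target score is built from summary-statistics records that survive a
region window, significance and frequency filters, and greedy LD clumping;
weights are the (harmonized) per-allele effect sizes. Instrument strength is
summarized by R-squared = sum(beta^2 * 2 * MAF * (1 - MAF)) and
F = [(N - K - 1)/K] * R2/(1 - R2), with F > 10 the conventional "strong" flag.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import SummaryStatRecord, TargetGeneRegion, filter_target_region, harmonize_pair
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

F_STRONG_THRESHOLD = 10.0


class NoInstrumentsError(ValueError):
    """Raised when a selection rule leaves no qualifying variant; names the filter."""


@dataclass(frozen=True)
class SelectionRule:
    """Filters applied in order: window, p-value, MAF, then LD clumping.

    Defaults match the drug-target rule (p < 5e-8, r2 < 0.1, MAF > 0.005,
    +/-100 kb window). :meth:`traditional` gives the genome-wide variant
    (r2 < 0.001, no region restriction); :meth:`pqtl` relaxes p to < 0.005.
    """

    p_max: float = 5e-8
    r2_max: float = 0.1
    maf_min: float = 0.005
    window_bp: int = 100_000
    source: str = "gwas"

    @classmethod
    def traditional(cls) -> "SelectionRule":
        return cls(p_max=5e-8, r2_max=0.001, maf_min=0.005, window_bp=0, source="gwas")

    @classmethod
    def pqtl(cls) -> "SelectionRule":
        return cls(p_max=0.005, r2_max=0.1, maf_min=0.005, window_bp=100_000, source="pqtl")


@dataclass
class InstrumentSet:
    """Selected, clumped variants with signed weights for one drug target.

    ``variants`` columns: variant_id, chrom, pos, ea, oa, eaf, weight, se, p.
    ``orientation`` is ``"raw"`` until :func:`orient_to_lowering` is applied.
    """

    variants: pd.DataFrame
    selection_rule: SelectionRule
    target: TargetGeneRegion | None = None
    orientation: str = "raw"
    r_squared: float | None = None
    f_statistic: float | None = None

    def __post_init__(self) -> None:
        if len(self.variants) < 1:
            raise ValueError("an InstrumentSet needs at least one variant")
        if not np.all(np.isfinite(self.variants["weight"])):
            raise ValueError("instrument weights must be finite")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def k(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def to_tsv(self, path) -> None:
        out = self.variants.copy()
        out["source"] = self.selection_rule.source
        out["orientation"] = self.orientation
        out.to_csv(path, sep="\t", index=False)


@dataclass
class ScoreVector:
    """Per-sample weighted allele sum with an attached standardized version."""

    raw: np.ndarray
    sample_ids: list[str]
    standardized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        sd = self.raw.std()
        if sd == 0:
            logger.warning("score has zero variance; standardized copy left at 0")
            self.standardized = np.zeros_like(self.raw)
        else:
            self.standardized = (self.raw - self.raw.mean()) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score_raw": self.raw, "score_std": self.standardized}
        )


# ----------------------------------------------------------------- clumping


def pairwise_r2(panel: GenotypePanel, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Squared Pearson correlation between dosage columns of a reference panel."""
    ids = variant_ids if variant_ids is not None else panel.variant_ids
    cols = [panel.column(v) for v in ids]
    x = panel.dosages[:, cols]
    mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x = x.copy()
    x[idx] = np.take(mean, idx[1])
    r = np.corrcoef(x, rowvar=False)
    if np.ndim(r) == 0:  # single variant
        r = np.array([[1.0]])
    return pd.DataFrame(r**2, index=ids, columns=ids)


def _r2_lookup(ld, a: str, b: str) -> float:
    if isinstance(ld, pd.DataFrame):
        if a in ld.index and b in ld.columns:
            return float(ld.loc[a, b])
    elif isinstance(ld, dict):
        if (a, b) in ld:
            return float(ld[(a, b)])
        if (b, a) in ld:
            return float(ld[(b, a)])
    else:
        raise TypeError("ld must be a DataFrame or dict keyed by id pairs")
    logger.warning("missing LD entry for (%s, %s); treated as r2=0", a, b)
    return 0.0


def ld_clump(candidates: pd.DataFrame, ld, r2_max: float) -> list[str]:
    """Greedy LD clumping of a candidate table.

    The lowest-p unprocessed variant becomes an index; every other candidate
    with r2 >= ``r2_max`` against it is discarded; repeat. Ties in p are
    broken by (chrom, pos). ``candidates`` needs columns
    variant_id/chrom/pos/p; ``ld`` is a DataFrame or pair-keyed dict of r2.
    """
    pending = candidates.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    retained: list[str] = []
    alive = dict.fromkeys(pending["variant_id"].astype(str), True)
    for vid in pending["variant_id"].astype(str):
        if not alive[vid]:
            continue
        retained.append(vid)
        alive[vid] = False
        for other, ok in alive.items():
            if ok and _r2_lookup(ld, vid, other) >= r2_max:
                alive[other] = False
    return retained


# ---------------------------------------------------------------- selection


def select_instruments(
    stats: list[SummaryStatRecord],
    region: TargetGeneRegion | None,
    rule: SelectionRule,
    ld,
) -> InstrumentSet:
    """Apply a selection rule and return the clumped instrument set.

    Filters run in order (region window when a region is given, then p-value,
    strict MAF > ``maf_min``, then clumping); an empty intermediate result
    raises :class:`NoInstrumentsError` naming the first filter that emptied
    the candidate list. Significance is strict (p < ``p_max``).
    """
    pool = list(stats)
    if not pool:
        raise NoInstrumentsError("no valid instruments: empty input")
    if region is not None:
        pool = filter_target_region(pool, region, rule.window_bp)
        if not pool:
            raise NoInstrumentsError("no valid instruments: region window filter")
    pool = [r for r in pool if r.p < rule.p_max]
    if not pool:
        raise NoInstrumentsError("no valid instruments: p-value filter")
    pool = [r for r in pool if r.maf > rule.maf_min]
    if not pool:
        raise NoInstrumentsError("no valid instruments: MAF filter")

    table = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in pool],
            "chrom": [r.chrom for r in pool],
            "pos": [r.pos for r in pool],
            "ea": [r.effect_allele for r in pool],
            "oa": [r.other_allele for r in pool],
            "eaf": [r.eaf for r in pool],
            "weight": [r.beta for r in pool],
            "se": [r.se for r in pool],
            "p": [r.p for r in pool],
        }
    )
    keep = ld_clump(table[["variant_id", "chrom", "pos", "p"]], ld, rule.r2_max)
    table = table[table["variant_id"].isin(keep)]
    return InstrumentSet(variants=table, selection_rule=rule, target=region)


# ------------------------------------------------------------- orientation


def orient_to_lowering(inst: InstrumentSet) -> InstrumentSet:
    """Re-express every variant so its weight reflects a trait *decrease*.

    Variants with positive weight have alleles swapped, weight negated and
    eaf complemented; zero-weight variants are dropped with a warning. The
    operation is idempotent.
    """
    v = inst.variants.copy()
    zero = v["weight"] == 0
    if zero.any():
        logger.warning("dropping %d zero-weight variants during orientation", int(zero.sum()))
        v = v[~zero]
        if v.empty:
            raise NoInstrumentsError("no valid instruments: all weights zero")
    flip = v["weight"] > 0
    v.loc[flip, ["ea", "oa"]] = v.loc[flip, ["oa", "ea"]].to_numpy()
    v.loc[flip, "eaf"] = 1.0 - v.loc[flip, "eaf"]
    v.loc[flip, "weight"] = -v.loc[flip, "weight"]
    return dataclasses.replace(inst, variants=v, orientation="lowering")


def apply_action_sign(inst: InstrumentSet, action: str) -> InstrumentSet:
    """Flip pQTL-score weights for inhibited targets; leave activated ones as-is."""
    if inst.selection_rule.source != "pqtl":
        raise ValueError("action sign applies to pQTL-based instrument sets only")
    if action == "activator":
        return inst
    if action == "inhibitor":
        v = inst.variants.copy()
        v["weight"] = -v["weight"]
        return dataclasses.replace(inst, variants=v)
    raise ValueError(f"unknown action {action!r}")


# ----------------------------------------------------------------- scoring


def compute_grs(panel: GenotypePanel, inst: InstrumentSet) -> ScoreVector:
    """Weighted allele sum per sample: sum_j dosage_ij * weight_j.

    Panel dosages are re-oriented to each instrument's effect allele (allele
    swap => dosage 2 - d; strand-complement labels accepted). Missing dosages
    are mean-imputed per variant. Instrument variants absent from the panel
    raise a single error listing them all.
    """
    missing = [v for v in inst.variant_ids if v not in set(panel.variant_ids)]
    if missing:
        raise KeyError(f"instrument variants absent from panel: {missing}")

    n = panel.n_samples
    raw = np.zeros(n)
    for row in inst.variants.itertuples(index=False):
        j = panel.column(row.variant_id)
        meta = panel.variants.iloc[j]
        panel_rec = SummaryStatRecord(
            variant_id=str(meta.variant_id), chrom=str(meta.chrom), pos=int(meta.pos),
            effect_allele=str(meta.ea), other_allele=str(meta.oa),
            eaf=float(np.clip(meta.eaf, 1e-9, 1 - 1e-9)), beta=0.0, se=1.0, p=1.0, n=n,
        )
        inst_rec = SummaryStatRecord(
            variant_id=str(row.variant_id), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.ea), other_allele=str(row.oa),
            eaf=float(np.clip(row.eaf, 1e-9, 1 - 1e-9)), beta=float(row.weight),
            se=float(row.se), p=float(np.clip(row.p, np.finfo(float).tiny, 1.0)), n=n,
        )
        harm = harmonize_pair(panel_rec, inst_rec)
        if not harm.ok:
            raise ValueError(f"cannot align {row.variant_id} to panel alleles: {harm.reason}")
        d = panel.dosages[:, j].copy()
        mean = np.nanmean(d)
        d[np.isnan(d)] = mean
        if harm.flipped:  # instrument counts the panel's other allele
            d = 2.0 - d
        raw += d * float(row.weight)
    return ScoreVector(raw=raw, sample_ids=list(panel.sample_ids))


def instrument_strength(inst: InstrumentSet, n_samples: int) -> tuple[float, float]:
    """(R2, F) instrument-strength statistics.

    R2 = sum(beta^2 * 2 * MAF * (1-MAF)) assumes per-allele betas on a
    variance-1 trait scale. F = [(N-K-1)/K] * R2/(1-R2). When any variant
    lacks allele-frequency information, F falls back to the mean squared
    Wald statistic (beta/se)^2 over variants and R2 is NaN.
    """
    k = inst.k
    if n_samples <= k + 1:
        raise ValueError("n_samples must exceed k + 1")
    v = inst.variants
    eaf = pd.to_numeric(v["eaf"], errors="coerce")
    if eaf.isna().any():
        f = float(np.mean((v["weight"] / v["se"]) ** 2))
        return float("nan"), f
    maf = np.minimum(eaf, 1.0 - eaf)
    r2 = float(np.sum(v["weight"] ** 2 * 2.0 * maf * (1.0 - maf)))
    if r2 >= 1.0:
        raise ValueError("R2 >= 1; weights are not on a variance-1 trait scale")
    f = (n_samples - k - 1) / k * r2 / (1.0 - r2)
    return r2, float(f)


def attach_strength(inst: InstrumentSet, n_samples: int) -> InstrumentSet:
    r2, f = instrument_strength(inst, n_samples)
    return dataclasses.replace(inst, r_squared=r2, f_statistic=f)
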