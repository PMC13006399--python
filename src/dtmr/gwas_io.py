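"""Reading, validation, harmonization, and windowing of GWAS/pQTL summary statistics.

Summary statistics are exchanged as tab-delimited files with the header
``variant_id  chrom  pos  ea  oa  eaf  beta  se  p  n`` (1-based positions,
``ea`` = effect allele). Target-gene definitions use
``gene  chrom  start  end  drug  action  modality``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: |eaf - 0.5| must exceed this for frequency-based resolution of palindromic pairs
PALINDROME_EAF_MARGIN = 0.08

SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
TARGET_COLUMNS = ["gene", "chrom", "start", "end", "drug", "action", "modality"]


class FormatError(ValueError):
    """The file as a whole cannot be interpreted (e.g. missing columns)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with a trait from GWAS or pQTL summary data."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def validate(self) -> None:
        """Raise ``ValueError`` if any field violates its invariant."""
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0 (got {self.se})")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_id}: p must be in (0, 1] (got {self.p})")
        if not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must be in (0, 1) (got {self.eaf})")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be 1-based positive")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, where strand cannot be resolved by alleles."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flipped(self) -> "SummaryStatRecord":
        """Return the record re-expressed with the other allele as effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )

    def complemented(self) -> "SummaryStatRecord":
        """Return the record with both alleles complemented (strand switch)."""
        return replace(
            self,
            effect_allele=_COMPLEMENT[self.effect_allele],
            other_allele=_COMPLEMENT[self.other_allele],
        )


@dataclass(frozen=True)
class TargetGeneRegion:
    """A drug-target gene with coordinates and its pharmacological action."""

    gene: str
    chrom: str
    start: int
    end: int
    drug: str
    action: str  # "inhibitor" | "activator"
    modality: str = ""  # "lipid" | "glucose"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.action not in ("inhibitor", "activator"):
            raise ValueError(f"{self.gene}: action must be inhibitor|activator, got {self.action!r}")


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass(frozen=True)
class Harmonization:
    """Outcome of aligning record ``b`` onto record ``a``'s allele orientation."""

    ok: bool
    b: SummaryStatRecord | None = None
    flipped: bool = False
    strand_flipped: bool = False
    reason: str | None = None


def read_summary_stats(path, errors: list[RowError] | None = None) -> list[SummaryStatRecord]:
    """Read a summary-statistics TSV into validated records.

    Rows violating record invariants are dropped, logged with their line number,
    and (if ``errors`` is a list) appended to it as :class:`RowError`.
    Missing columns raise :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message is informative
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    records: list[SummaryStatRecord] = []
    n_bad = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after header
        try:
            rec = SummaryStatRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.ea).upper(),
                other_allele=str(row.oa).upper(),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                p=float(row.p),
                n=int(row.n),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("%s line %d rejected: %s", path, line, exc)
            if errors is not None:
                errors.append(RowError(line=line, message=str(exc)))
            continue
        records.append(rec)
    if n_bad:
        logger.info("%s: rejected %d of %d rows", path, n_bad, len(df))
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path) -> None:
    rows = [
        (r.variant_id, r.chrom, r.pos, r.effect_allele, r.other_allele, r.eaf, r.beta, r.se, r.p, r.n)
        for r in records
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_target_genes(path) -> list[TargetGeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return [
        TargetGeneRegion(
            gene=str(r.gene),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            drug=str(r.drug),
            action=str(r.action),
            modality=str(r.modality),
        )
        for r in df.itertuples(index=False)
    ]


def write_target_genes(regions: Iterable[TargetGeneRegion], path) -> None:
    rows = [(g.gene, g.chrom, g.start, g.end, g.drug, g.action, g.modality) for g in regions]
    pd.DataFrame(rows, columns=TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def harmonize_pair(
    a: SummaryStatRecord,
    b: SummaryStatRecord,
    ambiguity_margin: float = PALINDROME_EAF_MARGIN,
) -> Harmonization:
    """Align record ``b`` to record ``a``'s effect-allele orientation.

    If ``b``'s effect allele equals ``a``'s other allele, ``b`` is flipped
    (beta negated, eaf complemented). Alleles reported on the opposite strand
    are complemented first. Palindromic variants (A/T, C/G) are resolved by
    allele frequency when both records' eaf lie farther than
    ``ambiguity_margin`` from 0.5, and rejected otherwise.
    """
    if a.variant_id != b.variant_id and (a.chrom, a.pos) != (b.chrom, b.pos):
        return Harmonization(ok=False, reason="different_variant")

    if a.is_palindromic():
        if b.alleles != a.alleles:
            return Harmonization(ok=False, reason="allele_mismatch")
        if abs(a.eaf - 0.5) <= ambiguity_margin or abs(b.eaf - 0.5) <= ambiguity_margin:
            return Harmonization(ok=False, reason="palindromic_ambiguous")
        cand = b if b.effect_allele == a.effect_allele else b.flipped()
        label_flip = cand is not b
        # allele labels cannot distinguish strands here; use frequency agreement
        if (a.eaf - 0.5) * (cand.eaf - 0.5) > 0:
            return Harmonization(ok=True, b=cand, flipped=label_flip)
        return Harmonization(ok=True, b=cand.flipped(), flipped=not label_flip, strand_flipped=True)

    strand_flipped = False
    if b.alleles == a.alleles:
        aligned = b
    else:
        comp = b.complemented() if b.alleles <= _COMPLEMENT.keys() else None
        if comp is not None and comp.alleles == a.alleles:
            aligned = comp
            strand_flipped = True
        else:
            return Harmonization(ok=False, reason="allele_mismatch")

    if aligned.effect_allele == a.effect_allele:
        return Harmonization(ok=True, b=aligned, strand_flipped=strand_flipped)
    return Harmonization(ok=True, b=aligned.flipped(), flipped=True, strand_flipped=strand_flipped)


def filter_target_region(
    stats: Sequence[SummaryStatRecord],
    region: TargetGeneRegion,
    window: int = 100_000,
) -> list[SummaryStatRecord]:
    """Records on the region's chromosome with pos in ``[start-window, end+window]``.

    Boundaries are inclusive at both ends; ``window`` must be non-negative.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    lo, hi = region.start - window, region.end + window
    return [r for r in stats if r.chrom == region.chrom and lo <= r.pos <= hi]
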