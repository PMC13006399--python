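"""Dosage-matrix container shared by the simulation, QC and scoring modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns of the per-variant metadata frame
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ea", "oa", "eaf"]


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix with per-variant metadata.

    ``dosages`` holds effect-allele counts in {0, 1, 2} as floats; ``NaN``
    marks a missing call. ``variants`` is indexed positionally, one row per
    dosage column, with columns :data:`VARIANT_COLUMNS` (``ea`` is the counted
    allele; ``eaf`` the frequency it was generated/observed at).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant table length does not match dosage columns")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    def column(self, variant_id: str) -> int:
        """Positional column index of a variant id."""
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return int(idx[0])

    def allele_frequency(self) -> np.ndarray:
        """Observed effect-allele frequency per variant, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def variant_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_hom_effect, n_het, n_hom_other) hard-call counts for column ``j``."""
        col = self.dosages[:, j]
        col = col[~np.isnan(col)]
        hard = np.rint(col)
        return int(np.sum(hard == 2)), int(np.sum(hard == 1)), int(np.sum(hard == 0))

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypePanel":
        """New panel restricted to the given positional sample/variant indices."""
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        v = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(s, v)],
            sample_ids=[self.sample_ids[i] for i in s],
            variants=self.variants.iloc[v].reset_index(drop=True),
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Write dosages as TSV: first column ``sample_id``, then one column per variant id."""
        df = pd.DataFrame(self.dosages, columns=self.variant_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    def variants_to_tsv(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, variants_path) -> "GenotypePanel":
        df = pd.read_csv(dosage_path, sep="\t", na_values=["NA"])
        meta = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        sample_ids = [str(s) for s in df["sample_id"]]
        mat = df.drop(columns=["sample_id"]).to_numpy(dtype=float)
        if list(df.columns[1:]) != [str(v) for v in meta["variant_id"]]:
            raise ValueError("dosage columns do not match variant metadata order")
        return cls(dosages=mat, sample_ids=sample_ids, variants=meta)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF 4.2 with GT (hard call) and DS (dosage) fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(self.sample_ids) + "\n")
            gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, row in self.variants.iterrows():
                fields = [str(row.chrom), str(row.pos), str(row.variant_id),
                          str(row.oa), str(row.ea), ".", "PASS", ".", "GT:DS"]
                for i in range(self.n_samples):
                    d = self.dosages[i, j]
                    if np.isnan(d):
                        fields.append("./.:.")
                    else:
                        fields.append(f"{gt_map[int(round(d))]}:{d:g}")
                fh.write("\t".join(fields) + "\n")
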