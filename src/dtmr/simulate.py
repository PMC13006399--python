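"""Synthetic cohort generator with known ground truth.

Produces genotype panels (HWE hard calls with block LD), covariates, metabolic
traits, PANSS-style outcomes, and matched external summary statistics so that
every downstream stage of the pipeline can be exercised and validated against
the parameters that generated the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import SummaryStatRecord, TargetGeneRegion, write_summary_stats, write_target_genes
from .panel import GenotypePanel, VARIANT_COLUMNS

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``grs_trait_beta`` is the trait shift (mg/dL) per SD of the genetic score;
    it is only used when the truth record does not pin a variance-explained
    target. ``trait_outcome_beta`` is the percent PANSS reduction per trait
    unit. ``pqtl_chain`` optionally interposes a protein layer
    (variant->protein beta, protein->trait beta).
    """

    n_samples: int = 2000
    n_variants: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.3
    grs_trait_beta: float = -6.0
    trait_outcome_beta: float = 0.0
    pqtl_chain: tuple[float, float] | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    trait_noise_sd: float = 20.0
    outcome_noise_sd: float = 20.0
    subscale_noise_sd: float = 5.0
    confounder_trait_beta: float = 0.0
    confounder_outcome_beta: float = 0.0
    trait_mean: float = 90.0
    outcome_mean: float = 50.0
    trait_name: str = "TG"
    n_centers: int = 5
    chrom: str = "1"
    variant_spacing: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise ConfigurationError("n_samples >= 2 and n_variants >= 1 required")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")


@dataclass
class TruthRecord:
    """Ground-truth effects used to generate phenotypes (the recovery oracle)."""

    causal_variant_ids: list[str]
    variant_trait_betas: dict[str, float]
    variant_protein_betas: dict[str, float] = field(default_factory=dict)
    protein_trait_beta: float = 0.0
    trait_outcome_beta: float = 0.0
    variance_explained_target: float | None = None

    def validate_against(self, panel: GenotypePanel) -> None:
        known = set(panel.variant_ids)
        missing = [v for v in self.causal_variant_ids if v not in known]
        if missing:
            raise ValueError(f"truth references variants absent from panel: {missing}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(**d)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_dosages(
    mafs: np.ndarray,
    block_size: int,
    rho: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-call dosages via two independent haplotype draws per sample.

    Each haplotype is a Gaussian-copula draw: within an LD block the latent
    normals are equicorrelated at ``rho``; the allele is carried when the
    latent falls below the MAF quantile. Independent haplotypes guarantee HWE
    at each variant's MAF by construction.
    """
    m = len(mafs)
    thresholds = sps.norm.ppf(mafs)
    dosage = np.zeros((n_samples, m))
    sq_rho, sq_ind = np.sqrt(rho), np.sqrt(1.0 - rho)
    for _hap in range(2):
        z = np.empty((n_samples, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            shared = rng.standard_normal((n_samples, 1))
            own = rng.standard_normal((n_samples, stop - start))
            z[:, start:stop] = sq_rho * shared + sq_ind * own
        dosage += (z < thresholds).astype(float)
    return dosage


def simulate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Generate a samples x variants panel of {0,1,2} dosages.

    Variants sit ``config.variant_spacing`` bp apart on ``config.chrom`` and
    form contiguous LD blocks of ``ld_block_size`` with within-block target
    correlation ``ld_rho``. Deterministic under ``config.seed``.
    """
    rng = _rng(config, 0)
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = _draw_dosages(mafs, config.ld_block_size, config.ld_rho, config.n_samples, rng)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    meta = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": config.chrom,
            "pos": [1 + config.variant_spacing * j for j in range(m)],
            "ea": [_ALLELE_PAIRS[k][0] for k in pair_idx],
            "oa": [_ALLELE_PAIRS[k][1] for k in pair_idx],
            "eaf": mafs,
        },
        columns=VARIANT_COLUMNS,
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    return GenotypePanel(dosages=dosages, sample_ids=sample_ids, variants=meta)


def default_truth(config: SimulationConfig, panel: GenotypePanel, n_causal: int = 1,
                  variance_explained: float | None = 0.05) -> TruthRecord:
    """Convenience truth: ``n_causal`` variants spread over blocks, equal betas.

    Within each chosen block the most informative variant (highest
    heterozygosity) becomes causal, so marginal GWAS power does not collapse
    for unlucky low-MAF draws. The per-variant trait beta defaults to
    ``grs_trait_beta / n_causal`` (sign preserved); the realized trait noise
    is later rescaled to hit ``variance_explained`` when it is not ``None``.
    """
    step = max(1, panel.n_variants // n_causal)
    het = panel.variants["eaf"].to_numpy() * (1.0 - panel.variants["eaf"].to_numpy())
    ids = []
    for j in range(n_causal):
        start = min(j * step, panel.n_variants - 1)
        stop = min(start + config.ld_block_size, panel.n_variants)
        best = start + int(np.argmax(het[start:stop]))
        ids.append(panel.variant_ids[best])
    beta = config.grs_trait_beta / n_causal
    rec = TruthRecord(
        causal_variant_ids=ids,
        variant_trait_betas={v: beta for v in ids},
        trait_outcome_beta=config.trait_outcome_beta,
        variance_explained_target=variance_explained,
    )
    if config.pqtl_chain is not None:
        vp, pt = config.pqtl_chain
        rec.variant_protein_betas = {v: vp for v in ids}
        rec.protein_trait_beta = pt
    rec.validate_against(panel)
    return rec


def _covariate_frame(n: int, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "age": rng.uniform(18, 45, size=n),
            "center": rng.integers(0, config.n_centers, size=n).astype(str),
            "course": rng.exponential(5.0, size=n),
            "prev_medication": rng.integers(0, 2, size=n),
            "drug_class": rng.integers(0, 2, size=n),
        }
    )
    df["age2"] = df["age"] ** 2
    for k in range(1, 6):
        df[f"PC{k}"] = rng.standard_normal(n)
    return df


def simulate_phenotypes(
    panel: GenotypePanel,
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the cohort table: covariates, trait, PANSS baselines/endpoints.

    The trait is a linear combination of causal dosages (optionally routed
    through a protein layer), covariate effects, an unobserved confounder,
    and Gaussian noise. When ``truth.variance_explained_target`` is set, the
    non-genetic variance is rescaled so the genetic component explains that
    fraction of the realized trait variance. The PANSS total endpoint is
    back-transformed from a percentage-reduction scale, so baseline totals
    always exceed 30.
    """
    truth.validate_against(panel)
    rng = _rng(config, 1) if rng is None else rng
    n = panel.n_samples
    df = _covariate_frame(n, config, rng)
    df.insert(0, "sample_id", panel.sample_ids)

    g = np.zeros(n)
    for vid, beta in truth.variant_trait_betas.items():
        g += np.nan_to_num(panel.dosages[:, panel.column(vid)]) * beta
    protein = np.zeros(n)
    if truth.variant_protein_betas:
        for vid, beta in truth.variant_protein_betas.items():
            protein += np.nan_to_num(panel.dosages[:, panel.column(vid)]) * beta
        protein += rng.standard_normal(n) * 0.5
        g = g + truth.protein_trait_beta * protein
        df["protein"] = protein

    cov_part = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        cov_part += beta * pd.to_numeric(df[name]).to_numpy()
    confounder = rng.standard_normal(n)
    cov_part = cov_part + config.confounder_trait_beta * confounder

    noise = rng.standard_normal(n)
    if truth.variance_explained_target is not None and truth.variance_explained_target > 0:
        var_g = float(np.var(g))
        target = truth.variance_explained_target
        resid_var = var_g * (1.0 / target - 1.0) - float(np.var(cov_part))
        sigma = float(np.sqrt(max(resid_var, 0.0)))
    else:
        sigma = config.trait_noise_sd
    trait = config.trait_mean + g - np.mean(g) + cov_part + sigma * noise
    df[config.trait_name] = trait

    # secondary metabolic baselines for stratified analyses
    df["HDL"] = 50.0 + 8.0 * rng.standard_normal(n)
    df["glucose"] = trait if config.trait_name == "glucose" else 86.0 + 9.0 * rng.standard_normal(n)

    reduction = (
        config.outcome_mean
        + truth.trait_outcome_beta * (trait - np.mean(trait))
        + config.confounder_outcome_beta * confounder
        + config.outcome_noise_sd * rng.standard_normal(n)
    )
    baseline_total = rng.integers(70, 121, size=n).astype(float)
    endpoint_total = baseline_total - reduction / 100.0 * (baseline_total - 30.0)
    df["panss_base_total"] = baseline_total
    df["panss_end_total"] = endpoint_total
    for sub in ("positive", "negative", "general"):
        base = rng.integers(15, 41, size=n).astype(float)
        red = reduction + config.subscale_noise_sd * rng.standard_normal(n)
        df[f"panss_base_{sub}"] = base
        df[f"panss_end_{sub}"] = base * (1.0 - red / 100.0)
    return df


def _marginal_stats(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-variant simple linear regression of ``y`` on dosage."""
    n = len(y)
    x = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", x, x)
    sxy = x.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    dof = n - 2
    sigma2 = np.maximum(syy - beta * sxy, 0.0) / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p


def simulate_summary_stats(
    panel: GenotypePanel,
    truth: TruthRecord,
    config: SimulationConfig,
    n_gwas: int = 10_000,
    gwas_noise_sd: float = 10.0,
    second_trait: str | None = None,
    second_causal_id: str | None = None,
    second_beta: float | None = None,
    second_causal_effect: float = 0.3,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord] | None]:
    """Marginal association statistics from an independent simulated panel.

    A fresh panel with the same variant metadata and LD structure is drawn at
    ``n_gwas`` samples, a trait is generated from the truth betas plus
    Gaussian noise, and each variant is tested marginally. ``second_trait``
    optionally produces statistics for a companion trait that shares the
    first causal variant (``"shared"``), has its own causal variant
    ``second_causal_id`` (``"distinct"``) — colocalization scenarios — or is
    causally downstream of trait 1 with slope ``second_causal_effect`` per SD
    (``"caused"``, a valid two-sample MR outcome).
    """
    rng = _rng(config, 2)
    mafs = panel.variants["eaf"].to_numpy()
    dosages = _draw_dosages(mafs, config.ld_block_size, config.ld_rho, n_gwas, rng)

    y = rng.standard_normal(n_gwas) * gwas_noise_sd
    col = {v: panel.column(v) for v in truth.variant_trait_betas}
    for vid, beta in truth.variant_trait_betas.items():
        y += dosages[:, col[vid]] * beta
    y = (y - y.mean()) / y.std()  # effects reported on a variance-1 trait scale
    beta1, se1, p1 = _marginal_stats(dosages, y)

    def _records(beta, se, p) -> list[SummaryStatRecord]:
        recs = []
        for j, row in panel.variants.iterrows():
            recs.append(
                SummaryStatRecord(
                    variant_id=str(row.variant_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.ea),
                    other_allele=str(row.oa),
                    eaf=float(np.mean(dosages[:, j]) / 2.0),
                    beta=float(beta[j]),
                    se=float(se[j]),
                    p=float(p[j]),
                    n=n_gwas,
                )
            )
        return recs

    stats1 = _records(beta1, se1, p1)
    if second_trait is None:
        return stats1, None
    if second_trait not in ("shared", "distinct", "caused"):
        raise ConfigurationError("second_trait must be None, 'shared', 'distinct' or 'caused'")
    if second_trait == "caused":
        ce = second_causal_effect
        y2 = ce * y + np.sqrt(max(1.0 - ce**2, 0.0)) * rng.standard_normal(n_gwas)
        beta2, se2, p2 = _marginal_stats(dosages, y2)
        return stats1, _records(beta2, se2, p2)
    if second_trait == "shared":
        causal2 = truth.causal_variant_ids[0]
    else:
        if second_causal_id is None:
            raise ConfigurationError("second_causal_id required for the 'distinct' scenario")
        causal2 = second_causal_id
    b2 = second_beta if second_beta is not None else next(iter(truth.variant_trait_betas.values()))
    y2 = rng.standard_normal(n_gwas) * gwas_noise_sd + dosages[:, panel.column(causal2)] * b2
    y2 = (y2 - y2.mean()) / y2.std()
    beta2, se2, p2 = _marginal_stats(dosages, y2)
    return stats1, _records(beta2, se2, p2)


def make_fixture_suite(config: SimulationConfig, outdir, n_causal: int = 1,
                       variance_explained: float | None = 0.05) -> dict[str, Path]:
    """Write a complete miniature study to ``outdir`` (plain-text formats only).

    Emits the dosage matrix (TSV + VCF), variant metadata, cohort table,
    trait summary statistics, a one-gene target table spanning the causal
    variant, and the truth ledger as JSON. Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_genotype_panel(config)
    truth = default_truth(config, panel, n_causal=n_causal, variance_explained=variance_explained)
    cohort = simulate_phenotypes(panel, truth, config)
    stats, _ = simulate_summary_stats(panel, truth, config)

    causal_pos = [int(panel.variants.loc[panel.column(v), "pos"]) for v in truth.causal_variant_ids]
    region = TargetGeneRegion(
        gene="GENE1",
        chrom=config.chrom,
        start=max(1, min(causal_pos) - 5_000),
        end=max(causal_pos) + 5_000,
        drug="drugA",
        action="inhibitor",
        modality="lipid",
    )

    paths = {
        "dosages": outdir / "dosages.tsv",
        "variants": outdir / "variants.tsv",
        "vcf": outdir / "genotypes.vcf",
        "cohort": outdir / "cohort.tsv",
        "sumstats": outdir / "sumstats.tsv",
        "targets": outdir / "targets.tsv",
        "truth": outdir / "truth.json",
    }
    panel.to_tsv(paths["dosages"])
    panel.variants_to_tsv(paths["variants"])
    panel.to_vcf(paths["vcf"])
    cohort.to_csv(paths["cohort"], sep="\t", index=False)
    write_summary_stats(stats, paths["sumstats"])
    write_target_genes([region], paths["targets"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
    return paths
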