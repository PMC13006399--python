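"""End-to-end orchestration: simulate -> QC -> scores -> associations -> factorial
-> two-sample MR -> colocalization -> diagnostics -> report.

All stages are pure functions of (config, seed); rerunning with the same
configuration reproduces byte-identical result tables. Artifacts are written
as plain-text TSV/JSON under the configured output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import diagnostics as diag_mod
from . import onesample, twosample
from .grs import (InstrumentSet, SelectionRule, attach_strength, compute_grs,
                  orient_to_lowering, pairwise_r2, select_instruments)
from .gwas_io import TargetGeneRegion
from .onesample import CovariateSpec
from .qc import QCThresholds, sample_qc, variant_qc
from .simulate import SimulationConfig, TruthRecord, default_truth, simulate_genotype_panel, \
    simulate_phenotypes, simulate_summary_stats

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "outdir", "simulation", "qc", "selection", "traditional_selection",
               "coloc_priors", "n_boot", "n_gwas", "variance_explained"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown YAML keys are rejected."""

    seed: int = 0
    outdir: str = "results"
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(n_variants=500))
    qc: QCThresholds = field(default_factory=QCThresholds)
    selection: SelectionRule = field(default_factory=SelectionRule)
    traditional_selection: SelectionRule = field(default_factory=SelectionRule.traditional)
    coloc_priors: dict = field(default_factory=lambda: dict(coloc_mod.DEFAULT_PRIORS))
    n_boot: int = 1000
    n_gwas: int = 10_000
    variance_explained: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if "maf_range" in sim:
                sim["maf_range"] = tuple(sim["maf_range"])
            if "pqtl_chain" in sim and sim["pqtl_chain"] is not None:
                sim["pqtl_chain"] = tuple(sim["pqtl_chain"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "selection" in kwargs:
            kwargs["selection"] = SelectionRule(**kwargs["selection"])
        if "traditional_selection" in kwargs:
            kwargs["traditional_selection"] = SelectionRule(**kwargs["traditional_selection"])
        return cls(**kwargs)


class Pipeline:
    """Stage-by-stage runner; later stages trigger the earlier ones they need."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}

    # ------------------------------------------------------------- stages

    def _timed(self, name: str, fn):
        t0 = time.perf_counter()
        out = fn()
        logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
        return out

    def stage_simulate(self) -> None:
        if "panel" in self.state:
            return
        cfg = self.config

        def _run():
            sim = cfg.simulation
            panel = simulate_genotype_panel(sim)
            truth = default_truth(sim, panel, n_causal=5,
                                  variance_explained=cfg.variance_explained)
            cohort = simulate_phenotypes(panel, truth, sim)
            stats1, stats2 = simulate_summary_stats(
                panel, truth, sim, n_gwas=cfg.n_gwas, second_trait="shared")
            _, stats_outcome = simulate_summary_stats(
                panel, truth, sim, n_gwas=cfg.n_gwas, second_trait="caused")
            regions = []
            for g, (vid, modality) in enumerate(
                    zip(truth.causal_variant_ids[:2], ("lipid", "glucose"))):
                pos = int(panel.variants.loc[panel.column(vid), "pos"])
                regions.append(TargetGeneRegion(
                    gene=f"GENE{g + 1}", chrom=sim.chrom,
                    start=max(1, pos - 5_000), end=pos + 5_000,
                    drug=f"drug{g + 1}", action="inhibitor", modality=modality))
            self.state.update(panel=panel, truth=truth, cohort=cohort,
                              stats1=stats1, stats2=stats2,
                              stats_outcome=stats_outcome, regions=regions)
            cohort.to_csv(self.outdir / "cohort.tsv", sep="\t", index=False)

        self._timed("simulate", _run)

    def stage_qc(self) -> None:
        if "panel_qc" in self.state:
            return
        self.stage_simulate()

        def _run():
            panel = self.state["panel"]
            vres = variant_qc(panel, self.config.qc)
            keep_v = [panel.column(v) for v in vres.kept]
            panel_v = panel.subset(variant_idx=keep_v)
            sres = sample_qc(panel_v, self.config.qc)
            keep_s = [panel_v.sample_ids.index(s) for s in sres.kept]
            panel_qc = panel_v.subset(sample_idx=keep_s)
            cohort = self.state["cohort"]
            cohort_qc = cohort[cohort["sample_id"].isin(sres.kept)].reset_index(drop=True)
            self.state.update(panel_qc=panel_qc, cohort_qc=cohort_qc,
                              variant_qc=vres, sample_qc=sres)
            vres.ledger.to_frame().to_csv(self.outdir / "variant_qc_ledger.tsv",
                                          sep="\t", index=False)
            sres.ledger.to_frame().to_csv(self.outdir / "sample_qc_ledger.tsv",
                                          sep="\t", index=False)

        self._timed("qc", _run)

    def stage_scores(self) -> None:
        if "scores" in self.state:
            return
        self.stage_qc()

        def _run():
            panel = self.state["panel_qc"]
            stats1 = [r for r in self.state["stats1"]
                      if r.variant_id in set(panel.variant_ids)]
            ld = pairwise_r2(panel)
            scores: dict[str, dict] = {}
            cohort = self.state["cohort_qc"].copy()
            for region in self.state["regions"]:
                inst = select_instruments(stats1, region, self.config.selection, ld)
                inst = orient_to_lowering(inst)
                inst = attach_strength(inst, panel.n_samples)
                vec = compute_grs(panel, inst)
                name = f"grs_{region.gene}"
                cohort[name] = vec.standardized
                scores[region.gene] = {"instruments": inst, "score": vec, "column": name}
                inst.to_tsv(self.outdir / f"instruments_{region.gene}.tsv")
            trad = select_instruments(stats1, None, self.config.traditional_selection, ld)
            trad = attach_strength(trad, panel.n_samples)
            vec = compute_grs(panel, trad)
            cohort["grs_traditional"] = vec.standardized
            scores["traditional"] = {"instruments": trad, "score": vec,
                                     "column": "grs_traditional"}
            self.state.update(scores=scores, cohort_scored=cohort)
            vec.to_frame().to_csv(self.outdir / "scores.tsv", sep="\t", index=False)

        self._timed("scores", _run)

    def stage_assoc(self) -> None:
        if "assoc" in self.state:
            return
        self.stage_scores()

        def _run():
            cfg = self.config
            cohort = onesample.derive_outcomes(self.state["cohort_scored"])
            self.state["cohort_scored"] = cohort
            trait = cfg.simulation.trait_name
            cov_trait = CovariateSpec.default(efficacy_outcome=False)
            cov_eff = CovariateSpec.default(efficacy_outcome=True)
            rows = []
            outcomes = ["reduction_total", "reduction_positive",
                        "reduction_negative", "reduction_general"]
            for gene, sc in self.state["scores"].items():
                col = sc["column"]
                rows.append(("trait", gene, trait,
                             onesample.fit_adjusted(cohort, trait, col, cov_trait)))
                for oc in outcomes:
                    rows.append(("efficacy", gene, oc,
                                 onesample.fit_adjusted(cohort, oc, col, cov_eff)))
                rows.append(("responder", gene, "responder",
                             onesample.fit_adjusted(cohort, "responder", col, cov_eff,
                                                    family="logistic")))
            # FDR within the efficacy family
            eff_idx = [i for i, r in enumerate(rows) if r[0] == "efficacy"]
            adj = onesample.adjust_multiplicity([rows[i][3].p for i in eff_idx], "bh")
            for i, a in zip(eff_idx, adj):
                rows[i][3].p_fdr = float(a)

            tsls = onesample.two_stage_ls(cohort, "reduction_total", trait,
                                          "grs_traditional", cov_eff)
            strat = onesample.stratified_with_interaction(
                cohort, "reduction_total", "grs_GENE1", "hyperlipemia", cov_eff)
            self.state.update(assoc=rows, tsls=tsls, stratified=strat)

            table = pd.DataFrame(
                [(fam, gene, oc, e.beta, e.se, e.se_hc3, *e.ci95, e.p, e.p_hc3,
                  e.p_fdr if e.p_fdr is not None else np.nan, e.n)
                 for fam, gene, oc, e in rows],
                columns=["family", "score", "outcome", "beta", "se", "se_hc3",
                         "ci_lo", "ci_hi", "p", "p_hc3", "p_fdr", "n"],
            )
            table.to_csv(self.outdir / "associations.tsv", sep="\t", index=False,
                         float_format="%.6g")

        self._timed("assoc", _run)

    def stage_factorial(self) -> None:
        if "factorial" in self.state:
            return
        self.stage_assoc()

        def _run():
            cohort = self.state["cohort_scored"]
            cov_eff = CovariateSpec.default(efficacy_outcome=True)
            res = onesample.factorial_effects(cohort, "reduction_total",
                                              "grs_GENE1", "grs_GENE2", cov_eff)
            self.state["factorial"] = res
            pd.DataFrame(
                [(g, e.beta, e.se, *e.ci95, e.p) for g, e in res.group_effects.items()],
                columns=["group", "beta", "se", "ci_lo", "ci_hi", "p"],
            ).to_csv(self.outdir / "factorial.tsv", sep="\t", index=False,
                     float_format="%.6g")

        self._timed("factorial", _run)

    def stage_mr2(self) -> None:
        if "mr2" in self.state:
            return
        self.stage_scores()

        def _run():
            inst = self.state["scores"]["traditional"]["instruments"]
            s1 = {r.variant_id: r for r in self.state["stats1"]}
            s2 = {r.variant_id: r for r in self.state["stats_outcome"]}
            ids = [v for v in inst.variant_ids if v in s1 and v in s2]
            mri = twosample.MRInput(
                beta_exposure=[s1[v].beta for v in ids],
                se_exposure=[s1[v].se for v in ids],
                beta_outcome=[s2[v].beta for v in ids],
                se_outcome=[s2[v].se for v in ids],
                ids=ids,
            )
            if mri.k >= 4:
                presso = twosample.mr_presso(mri, seed=self.config.seed)
                mri_used = presso.filtered
            else:
                presso = None
                mri_used = mri
            results = twosample.run_all_estimators(mri_used, n_boot=self.config.n_boot,
                                                   seed=self.config.seed)
            self.state.update(mr2=results, presso=presso)
            pd.DataFrame(
                [(r.method, r.estimate, r.se, *r.ci95, r.p, r.q_statistic, r.q_p,
                  r.egger_intercept, r.egger_intercept_p) for r in results],
                columns=["method", "estimate", "se", "ci_lo", "ci_hi", "p",
                         "q", "q_p", "egger_intercept", "egger_intercept_p"],
            ).to_csv(self.outdir / "mr2.tsv", sep="\t", index=False,
                     float_format="%.6g")

        self._timed("mr2", _run)

    def stage_coloc(self) -> None:
        if "coloc" in self.state:
            return
        self.stage_scores()

        def _run():
            panel = self.state["panel_qc"]
            region = self.state["regions"][0]
            s1 = {r.variant_id: r for r in self.state["stats1"]}
            s2 = {r.variant_id: r for r in self.state["stats2"]}
            lo, hi = region.start - 100_000, region.end + 100_000
            sub = panel.variants[(panel.variants["chrom"] == region.chrom)
                                 & panel.variants["pos"].between(lo, hi)]
            ids = [v for v in sub["variant_id"] if v in s1 and v in s2]
            table = pd.DataFrame({
                "variant_id": ids,
                "pos": [s1[v].pos for v in ids],
                "p": [s1[v].p for v in ids],
            })
            ld = pairwise_r2(panel, ids)
            kept = coloc_mod.ld_prune_region(table, ld)
            if len(kept) < 2:  # pruning left too little; fall back to unpruned set
                kept = ids
            cin = coloc_mod.ColocInput(
                ids=kept,
                beta1=[s1[v].beta for v in kept], se1=[s1[v].se for v in kept],
                beta2=[s2[v].beta for v in kept], se2=[s2[v].se for v in kept],
            )
            res = coloc_mod.coloc_posteriors(cin, self.config.coloc_priors)
            self.state["coloc"] = res
            with open(self.outdir / "coloc.json", "w") as fh:
                json.dump(coloc_mod.result_to_dict(res), fh, indent=2)

        self._timed("coloc", _run)

    def stage_diagnostics(self) -> None:
        if "diagnostics" in self.state:
            return
        self.stage_assoc()

        def _run():
            cohort = self.state["cohort_scored"]
            cov = CovariateSpec.default(efficacy_outcome=True)
            W = cov.design(cohort)
            X = pd.concat([pd.Series(1.0, index=cohort.index, name="const"),
                           cohort["grs_GENE1"].rename("grs_GENE1"), W], axis=1)
            rep = diag_mod.diagnose_linear(cohort["reduction_total"], X, "grs_GENE1")
            self.state["diagnostics"] = rep
            with open(self.outdir / "diagnostics.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=2)

        self._timed("diagnostics", _run)

    def stage_report(self) -> None:
        self.stage_factorial()
        self.stage_mr2()
        self.stage_coloc()
        self.stage_diagnostics()

        def _run():
            lines = ["pipeline report", "=" * 40]
            for gene, sc in self.state["scores"].items():
                inst = sc["instruments"]
                lines.append(f"score {gene}: k={inst.k} R2={inst.r_squared:.4f} "
                             f"F={inst.f_statistic:.1f}")
            tsls = self.state["tsls"]
            lines.append(f"2SLS trait->reduction: beta={tsls.beta:.3f} "
                         f"({tsls.ci95[0]:.3f}, {tsls.ci95[1]:.3f}) "
                         f"first-stage F={tsls.first_stage_f:.1f}")
            strat = self.state["stratified"]
            lines.append(f"stratified p_interaction={strat.p_interaction:.3f}")
            fac = self.state["factorial"]
            lines.append(f"factorial product p={fac.p_product_interaction:.3f} "
                         f"(threshold {fac.threshold})")
            for r in self.state["mr2"]:
                lines.append(f"MR {r.method}: {r.estimate:.3f} +/- {r.se:.3f} p={r.p:.2g}")
            cres = self.state["coloc"]
            lines.append(f"coloc PP.H4={cres.pp['H4']:.3f} lead={cres.lead_variant}")
            lines.append(f"diagnostics: {self.state['diagnostics'].stability}")
            (self.outdir / "report.txt").write_text("\n".join(lines) + "\n")

        self._timed("report", _run)


def run_pipeline(config: PipelineConfig) -> Pipeline:
    """Execute every stage and return the pipeline with its in-memory state."""
    pipe = Pipeline(config)
    pipe.stage_report()
    return pipe
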