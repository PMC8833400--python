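"""End-to-end model object: simulate/load -> harmonize -> phenotype -> evaluate.

`RadiomicSurvivalModel` is the statsmodels-style entry point: construct it
from cohort tables (or a simulation config), call :meth:`fit`, and receive
a :class:`RadiomicSurvivalResults` carrying the harmonization audit trail,
both phenotypes (ComBat-harmonized and merely z-scored features), the
univariate and multivariate evaluation tables with bootstrap CIs and LRT
p-values, and Kaplan-Meier curves; ``summary()`` prints the comparison the
analysis is built for.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, validate_cohort
from .combat import NestedHarmonizationResult, nested_combat, zscore_features
from .config import (EvaluationConfig, HarmonizationConfig, PipelineConfig,
                     SimulationConfig, substream)
from .phenotype import PhenotypeModel, associate_covariates
from .simulate import generate_cohort
from .survival import km_estimate, run_multivariate, run_univariate

__all__ = ["RadiomicSurvivalModel", "RadiomicSurvivalResults", "run_pipeline"]

COMBAT_LABEL = "Phenotype (ComBat)"
NONCOMBAT_LABEL = "Phenotype (non-ComBat)"


@dataclass
class RadiomicSurvivalResults:
    """Fitted pipeline results with artifact writing."""

    config: PipelineConfig
    cohort: Cohort
    harmonization: NestedHarmonizationResult
    phenotype_combat: PhenotypeModel
    phenotype_noncombat: PhenotypeModel
    associations: pd.DataFrame
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    seed: int
    manifest: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Radiomic phenotype survival analysis",
            "=" * 68,
            f"patients: {self.cohort.n_patients}   "
            f"events: {int(self.cohort.survival['event'].sum())} "
            f"({self.cohort.survival['event'].mean():.1%})",
            f"harmonization order: {' -> '.join(self.harmonization.applied_order)}",
            f"KS-flagged features pre -> post: "
            + ", ".join(
                f"{v}: {self.harmonization.pre_counts[v]} -> {self.harmonization.post_counts[v]}"
                for v in self.harmonization.pre_counts
            ),
            f"retained PCs (>= {self.phenotype_combat.variance_threshold:.0%} "
            f"variance): {self.phenotype_combat.pca.m}",
            f"cluster count k: {self.phenotype_combat.k}",
            "",
            "Univariate C-scores",
            "-" * 68,
        ]
        for _, r in self.univariate.iterrows():
            lines.append(f"{r['model']:<28s} C = {r['c_score']:.2f} "
                         f"({r['ci_low']:.2f}, {r['ci_high']:.2f})")
        lines += ["", "Multivariate models (LRT vs ECOG + Age baseline)", "-" * 68]
        for _, r in self.multivariate.iterrows():
            p = "--" if pd.isna(r["lrt_p"]) else f"p = {r['lrt_p']:.3f}"
            lines.append(f"{r['model']:<36s} C = {r['c_score']:.2f} "
                         f"({r['ci_low']:.2f}, {r['ci_high']:.2f})  {p}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict:
        """Write every stage artifact plus a manifest and return the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        artifacts = {}

        artifacts.update(self.cohort.write(outdir / "cohort"))
        harm_dir = outdir / "harmonization"
        harm_dir.mkdir(exist_ok=True)
        self.harmonization.final_features.to_csv(
            harm_dir / "features_harmonized.csv", index_label="patient_id")
        artifacts["features_harmonized"] = str(harm_dir / "features_harmonized.csv")
        with open(harm_dir / "audit.json", "w") as fh:
            json.dump(self.harmonization.to_dict(), fh, indent=2)
        artifacts["harmonization_audit"] = str(harm_dir / "audit.json")

        phen_dir = outdir / "phenotype"
        phen_dir.mkdir(exist_ok=True)
        labels = pd.DataFrame({
            "combat_cluster": self.phenotype_combat.labels,
            "combat_risk": self.phenotype_combat.risk_labels,
            "noncombat_cluster": self.phenotype_noncombat.labels,
            "noncombat_risk": self.phenotype_noncombat.risk_labels,
        })
        labels.to_csv(phen_dir / "labels.csv", index_label="patient_id")
        artifacts["phenotype_labels"] = str(phen_dir / "labels.csv")
        self.phenotype_combat.scores.to_csv(phen_dir / "pc_scores.csv",
                                            index_label="patient_id")
        artifacts["pc_scores"] = str(phen_dir / "pc_scores.csv")
        if self.phenotype_combat.consensus is not None:
            pac = pd.Series(self.phenotype_combat.consensus.pac_scores, name="pac")
            pac.to_csv(phen_dir / "pac_curve.csv", index_label="k")
            artifacts["pac_curve"] = str(phen_dir / "pac_curve.csv")
        with open(phen_dir / "audit.json", "w") as fh:
            json.dump(self.phenotype_combat.audit, fh, indent=2)
        artifacts["phenotype_audit"] = str(phen_dir / "audit.json")
        self.associations.to_csv(phen_dir / "associations.csv", index=False)
        artifacts["associations"] = str(phen_dir / "associations.csv")

        eval_dir = outdir / "evaluation"
        eval_dir.mkdir(exist_ok=True)
        self.univariate.to_csv(eval_dir / "univariate.csv", index=False)
        self.multivariate.to_csv(eval_dir / "multivariate.csv", index=False)
        artifacts["univariate"] = str(eval_dir / "univariate.csv")
        artifacts["multivariate"] = str(eval_dir / "multivariate.csv")
        for name, curve in self.km_curves.items():
            path = eval_dir / f"km_{name}.csv"
            curve.to_csv(path, index=False)
            artifacts[f"km_{name}"] = str(path)

        manifest = {
            "package": "radsurv",
            "version": __version__,
            "seed": self.seed,
            "stages": ["cohort", "harmonization", "phenotype", "evaluation", "km"],
            "parameters": {
                "harmonization": self.config.harmonization.to_dict(),
                "variance_threshold": self.config.variance_threshold,
                "evaluation": self.config.evaluation.to_dict(),
                "simulation": (self.config.simulation.to_dict()
                               if self.config.simulation else None),
            },
            "artifacts": artifacts,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        self.manifest = manifest
        return manifest

    def plot_km(self, ax=None):
        """Kaplan-Meier step plot of the two ComBat-phenotype risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, curve in self.km_curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=name)
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


class RadiomicSurvivalModel:
    """Harmonization + phenotype + Cox evaluation, fit on one cohort.

    Examples
    --------
    >>> from radsurv import RadiomicSurvivalModel, SimulationConfig
    >>> model = RadiomicSurvivalModel.from_simulation(SimulationConfig(), seed=7)
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, cohort: Cohort, config: PipelineConfig | None = None):
        if config is None:
            config = PipelineConfig(input_dir="<in-memory>",
                                    evaluation=EvaluationConfig(n_bootstrap=2000))
        self.config = config
        self.cohort = validate_cohort(cohort.features, cohort.batches,
                                      cohort.clinical, cohort.survival,
                                      cohort.latent_phenotype)

    @classmethod
    def from_simulation(cls, sim_config: SimulationConfig | None = None,
                        seed: int | None = None,
                        config: PipelineConfig | None = None) -> "RadiomicSurvivalModel":
        sim_config = sim_config or SimulationConfig()
        if seed is not None:
            sim_config.seed = int(seed)
        cohort = generate_cohort(sim_config)
        if config is None:
            config = PipelineConfig(simulation=sim_config,
                                    evaluation=EvaluationConfig(n_bootstrap=2000),
                                    seed=sim_config.seed)
        return cls(cohort, config)

    @classmethod
    def from_csv(cls, indir: str | Path,
                 config: PipelineConfig | None = None) -> "RadiomicSurvivalModel":
        cohort = read_cohort(indir)
        if config is None:
            config = PipelineConfig(input_dir=str(indir),
                                    evaluation=EvaluationConfig(n_bootstrap=2000))
        return cls(cohort, config)

    def fit(self, seed: int | None = None) -> RadiomicSurvivalResults:
        cfg = self.config
        master = cfg.seed if seed is None else int(seed)
        consensus_rng = substream(master, "consensus")
        bootstrap_rng = substream(master, "bootstrap")

        covariates = None
        protect = list(cfg.harmonization.protect_covariates)
        if protect:
            covariates = pd.get_dummies(self.cohort.clinical[protect],
                                        drop_first=True).astype(float)
        harmonization = nested_combat(self.cohort.features, self.cohort.batches,
                                      cfg.harmonization, covariates)

        def make_phenotype(features: pd.DataFrame) -> PhenotypeModel:
            return PhenotypeModel(
                variance_threshold=cfg.variance_threshold,
                k_range=cfg.consensus_k_range,
                n_resamples=cfg.consensus_resamples,
                subsample_fraction=cfg.consensus_subsample,
                fixed_k=cfg.fixed_k,
                outcome_aware=cfg.outcome_aware_orientation,
            ).fit(features, self.cohort.survival, consensus_rng)

        phen_combat = make_phenotype(harmonization.final_features)
        zscored, _ = zscore_features(self.cohort.features)
        phen_noncombat = make_phenotype(zscored)

        associations = associate_covariates(phen_combat.risk_labels,
                                            self.cohort.clinical,
                                            self.cohort.survival)
        phenotypes = {COMBAT_LABEL: phen_combat.risk_labels,
                      NONCOMBAT_LABEL: phen_noncombat.risk_labels}
        univariate = run_univariate(self.cohort, phenotypes, cfg.evaluation,
                                    bootstrap_rng)
        multivariate = run_multivariate(self.cohort, phenotypes,
                                        phen_combat.scores, cfg.evaluation,
                                        bootstrap_rng)
        km = km_estimate(self.cohort.survival, phen_combat.risk_labels)

        results = RadiomicSurvivalResults(
            config=cfg, cohort=self.cohort, harmonization=harmonization,
            phenotype_combat=phen_combat, phenotype_noncombat=phen_noncombat,
            associations=associations, univariate=univariate,
            multivariate=multivariate, km_curves=km, seed=master,
        )
        if cfg.outdir:
            results.save(cfg.outdir)
        return results


def run_pipeline(config: PipelineConfig) -> RadiomicSurvivalResults:
    """Run the full pipeline from a validated configuration."""
    config.validate()
    if config.simulation is not None:
        model = RadiomicSurvivalModel.from_simulation(config.simulation,
                                                      config=config)
    else:
        model = RadiomicSurvivalModel.from_csv(config.input_dir, config=config)
    return model.fit(config.seed)
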