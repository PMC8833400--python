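"""Configuration objects for simulation, harmonization and evaluation.

All stages draw their randomness from a single master seed through named
substreams (see :func:`substream`), so a pipeline run is reproducible from
one integer.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "HarmonizationConfig",
    "EvaluationConfig",
    "PipelineConfig",
    "substream",
]

# Named substreams hanging off the master seed.  The integer tags keep
# the streams disjoint and stable across releases.
_SUBSTREAMS = {"simulation": 11, "consensus": 23, "bootstrap": 37, "generic": 53}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a master seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_SUBSTREAMS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SUBSTREAMS[name]]))


def _default_batch_spec() -> dict[str, dict[str, float]]:
    # Cohort batch prevalences: contrast usage and CT scanner vendor.
    return {
        "contrast": {"non-contrast": 0.745, "contrast": 0.255},
        "vendor": {"Philips": 0.609, "Siemens": 0.327, "GE": 0.064},
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic chemoradiation cohort.

    Defaults emulate a 110-patient stage III NSCLC adenocarcinoma cohort:
    107 radiomic features, two acquisition batch variables (contrast agent
    with 2 levels, scanner vendor with 3), roughly half the patients dying
    during follow-up with a median overall survival of 30.6 months, and a
    latent two-group imaging phenotype that doubles the hazard of death.

    Parameters
    ----------
    gamma_sd
        Standard deviation of the additive per-batch per-feature location
        shifts, in z-score units.  Either a scalar applied to every batch
        variable or a mapping ``{batch_variable: sd}``.
    delta_range
        Uniform support of the multiplicative per-batch scale factors.
        Either a pair or a mapping ``{batch_variable: (lo, hi)}``.
    phenotype_separation
        Mean shift (z-units) added to the informative features of latent
        high-risk patients.
    log_hr_age
        Log hazard ratio per interquartile range of age (age enters the
        linear predictor as ``(age - 66) / 11``).
    censoring_floor
        Shortest possible follow-up as a fraction of the longest: patient
        entry is uniform over the accrual window, so censoring times are
        uniform on ``(floor * horizon, horizon)`` with the horizon scaled
        numerically to hit ``target_event_fraction``.
    """

    n_patients: int = 110
    n_features: int = 107
    batch_spec: dict[str, dict[str, float]] = field(default_factory=_default_batch_spec)
    gamma_sd: float | Mapping[str, float] = 1.0
    delta_range: tuple[float, float] | Mapping[str, tuple[float, float]] = (0.5, 2.0)
    phenotype_separation: float = 2.0
    n_informative: int = 20
    phenotype_prevalence: float = 0.5
    log_hr_phenotype: float = float(np.log(2.0))
    log_hr_age: float = 0.2
    log_hr_ecog: float = 0.3
    baseline_median_months: float = 30.6
    target_event_fraction: float = 0.509
    weibull_shape: float = 1.0  # 1.0 = exponential baseline hazard
    censoring_floor: float = 0.25
    batch_phenotype_confounding: float = 0.0  # log-odds tilt of batch levels by phenotype
    seed: int = 0

    def gamma_sd_for(self, variable: str) -> float:
        if isinstance(self.gamma_sd, Mapping):
            return float(self.gamma_sd.get(variable, 0.0))
        return float(self.gamma_sd)

    def delta_range_for(self, variable: str) -> tuple[float, float]:
        if isinstance(self.delta_range, Mapping):
            lo, hi = self.delta_range.get(variable, (1.0, 1.0))
        else:
            lo, hi = self.delta_range
        return float(lo), float(hi)

    def validate(self) -> "SimulationConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in (0, n_features]")
        for var, levels in self.batch_spec.items():
            total = sum(levels.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"prevalences for batch variable {var!r} sum to {total}, not 1")
        for var in self.batch_spec:
            lo, hi = self.delta_range_for(var)
            if lo <= 0 or hi < lo:
                raise ValueError(f"delta_range for {var!r} must satisfy 0 < lo <= hi")
        if not 0 < self.target_event_fraction < 1:
            raise ValueError("target_event_fraction must lie in (0, 1)")
        if not 0 < self.phenotype_prevalence < 1:
            raise ValueError("phenotype_prevalence must lie in (0, 1)")
        if not 0 <= self.censoring_floor < 1:
            raise ValueError("censoring_floor must lie in [0, 1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HarmonizationConfig:
    """Settings of the nested ComBat harmonization stage.

    ``alpha`` is the two-sided significance level of the two-sample
    Kolmogorov–Smirnov diagnostics that drive the nested ordering.
    ``eb_tol`` is the maximum relative change of the empirical-Bayes
    location/scale estimates at convergence (the convention of the
    reference ComBat implementations).
    """

    alpha: float = 0.05
    prior: str = "parametric"
    protect_covariates: Sequence[str] = ()
    eb_tol: float = 1e-6
    eb_max_iter: int = 1000
    min_batch_size: int = 2
    ks_mode: str = "asymp"  # "asymp" | "exact"
    # candidate scoring in the nested loop: flag count summed over all batch
    # variables ("all", the published procedure) or only the candidate's own
    # variable ("own")
    ks_scope: str = "all"

    def validate(self) -> "HarmonizationConfig":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.eb_tol <= 0:
            raise ValueError("eb_tol must be positive")
        if self.prior not in ("parametric", "nonparametric"):
            raise ValueError("prior must be 'parametric' or 'nonparametric'")
        if self.ks_mode not in ("asymp", "exact"):
            raise ValueError("ks_mode must be 'asymp' or 'exact'")
        if self.ks_scope not in ("all", "own"):
            raise ValueError("ks_scope must be 'all' or 'own'")
        if self.min_batch_size < 2:
            raise ValueError("min_batch_size must be >= 2")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protect_covariates"] = list(self.protect_covariates)
        return d


@dataclass
class EvaluationConfig:
    """Settings of the Cox-model evaluation stage.

    ``n_bootstrap = 50_000`` is the production default for the
    t-approximation confidence intervals of the C-score; pipelines and
    tests typically run with a reduced count.
    """

    n_bootstrap: int = 50_000
    ci_level: float = 0.95
    lrt_alpha: float = 0.05
    refit_phenotype: bool = False  # re-derive labels inside each bootstrap resample
    seed: int = 0

    def validate(self) -> "EvaluationConfig":
        if self.n_bootstrap < 2:
            raise ValueError("n_bootstrap must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``simulation`` (generate a synthetic cohort) or
    ``input_dir`` (load cohort CSVs) must be supplied.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    harmonization: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    variance_threshold: float = 0.85
    consensus_k_range: tuple[int, int] = (2, 6)
    consensus_resamples: int = 1000
    consensus_subsample: float = 0.8
    fixed_k: int | None = None  # skip consensus selection when set
    outcome_aware_orientation: bool = True
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation config or input_dir must be given")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.simulation is not None:
            self.simulation.validate()
        self.harmonization.validate()
        self.evaluation.validate()
        return self
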