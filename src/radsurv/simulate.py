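"""Synthetic chemoradiation-cohort generator.

Emulates the data structure the downstream analysis assumes: a
patient-by-feature radiomic table distorted by additive/multiplicative
per-batch effects, a latent two-group imaging phenotype carried by a subset
of informative features, clinical covariates matching the cohort summary
tables, and proportional-hazards survival with administrative censoring
calibrated to the observed event fraction.

The generative model for the features mirrors the location/scale model that
ComBat assumes: a base draw ``N(0, 1)`` per feature, a mean shift of
``phenotype_separation`` on the informative features for latent high-risk
patients, then for each batch variable ``v`` and assigned level ``b``

    x' = x * delta[b, g] + gamma[b, g],

with ``gamma ~ N(0, gamma_sd^2)`` and ``delta ~ Uniform(delta_range)``.

Survival times follow a Weibull (exponential by default) proportional
hazards model with linear predictor

    log_hr_phenotype * phenotype
    + log_hr_age * (age - 66) / 11
    + log_hr_ecog * ecog,

whose baseline scale is set so the reference patient (phenotype 0, median
age, ECOG 0) has the configured median survival.  Censoring is
administrative: entry is uniform over an accrual window, so censoring times
are uniform on ``(censoring_floor * H, H)`` with the horizon ``H`` solved
numerically so the expected event fraction matches the target.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort
from .config import SimulationConfig, substream

__all__ = ["generate_cohort", "generate_clinical"]

AGE_MEDIAN, AGE_IQR = 66.0, (60.0, 71.0)
BMI_MEDIAN, BMI_IQR = 26.5, (23.8, 29.9)
PACK_MEDIAN = 35.0
ECOG_LEVELS = ("0", "1", "2", "Unknown")
ECOG_PROBS = (0.455, 0.436, 0.091, 0.018)
SEX_LEVELS, SEX_PROBS = ("Female", "Male"), (0.618, 0.382)
RACE_LEVELS = ("White", "African American", "Asian", "Native American", "Other")
RACE_PROBS = (0.727, 0.200, 0.027, 0.009, 0.037)
NEVER_SMOKER_FRAC = 0.055

# Phi^{-1}(0.75): converts an interquartile range to a normal sd.
_Z75 = 0.6744897501960817


def _truncated_normal(rng, n, median, iqr, lo, hi):
    sd = (iqr[1] - iqr[0]) / (2 * _Z75)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(median, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


def generate_clinical(n: int, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n`` patients' clinical covariates from the cohort marginals.

    Age is truncated normal on [35, 90] with quantiles matched to median 66
    and IQR (60, 71); BMI analogously; pack-years are lognormal for smokers
    (median 35) and zero for the never-smoker fraction; ECOG, sex and race
    are multinomial with the cohort's prevalences.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, n, AGE_MEDIAN, AGE_IQR, 35.0, 90.0)
    bmi = _truncated_normal(rng, n, BMI_MEDIAN, BMI_IQR, 15.0, 55.0)
    # lognormal sigma from the geometric mean of the two one-sided IQR ratios
    sigma = 0.66
    pack = np.exp(rng.normal(np.log(PACK_MEDIAN), sigma, size=n))
    pack[rng.random(n) < NEVER_SMOKER_FRAC] = 0.0
    ecog = rng.choice(ECOG_LEVELS, size=n, p=ECOG_PROBS)
    sex = rng.choice(SEX_LEVELS, size=n, p=SEX_PROBS)
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    ids = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    return pd.DataFrame(
        {"age": age, "bmi": bmi, "pack_years": pack,
         "ecog": ecog, "sex": sex, "race": race},
        index=ids,
    )


def _assign_batches(rng, config: SimulationConfig, phenotype: np.ndarray) -> pd.DataFrame:
    n = config.n_patients
    cols = {}
    for var, spec in config.batch_spec.items():
        levels = list(spec)
        probs = np.array([spec[l] for l in levels], dtype=float)
        if config.batch_phenotype_confounding != 0.0:
            # tilt the log-odds of the first level for latent high-risk patients
            logits = np.log(probs)
            assign = np.empty(n, dtype=object)
            for z in (0, 1):
                lz = logits.copy()
                if z == 1:
                    lz[0] += config.batch_phenotype_confounding
                pz = np.exp(lz - lz.max())
                pz /= pz.sum()
                mask = phenotype == z
                assign[mask] = rng.choice(levels, size=mask.sum(), p=pz)
            cols[var] = assign
        else:
            cols[var] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols)


def _distort_features(rng, X: np.ndarray, batches: pd.DataFrame,
                      config: SimulationConfig) -> np.ndarray:
    p = X.shape[1]
    X = X.copy()
    for var in config.batch_spec:
        levels = list(config.batch_spec[var])
        gsd = config.gamma_sd_for(var)
        dlo, dhi = config.delta_range_for(var)
        gamma = rng.normal(0.0, gsd, size=(len(levels), p)) if gsd > 0 else np.zeros((len(levels), p))
        delta = rng.uniform(dlo, dhi, size=(len(levels), p))
        codes = pd.Categorical(batches[var], categories=levels).codes
        X = X * delta[codes] + gamma[codes]
    return X


def _ecog_numeric(ecog: pd.Series) -> np.ndarray:
    # latent hazard treats "Unknown" as the cohort's modal known status (1)
    mapping = {"0": 0.0, "1": 1.0, "2": 2.0, "Unknown": 1.0}
    return ecog.map(mapping).to_numpy()


def _calibrate_horizon(rates_scale: np.ndarray, shape: float, floor: float,
                       target: float) -> float:
    """Solve for the censoring horizon H giving the target event fraction.

    ``rates_scale`` holds each patient's Weibull scale b_i (time units), so
    F_i(t) = 1 - exp(-(t / b_i)^shape).  With censoring C ~ U(floor*H, H),
    the expected event fraction is mean_i E_U[F_i(H*U)], evaluated by
    quadrature over U.
    """
    u = np.linspace(floor, 1.0, 129)

    def event_fraction(h: float) -> float:
        t = h * u  # (grid,)
        F = 1.0 - np.exp(-np.power(t[None, :] / rates_scale[:, None], shape))
        return float(np.trapezoid(F, u, axis=1).mean() / (1.0 - floor))

    lo, hi = 1e-3, 1e3
    for _ in range(20):
        if event_fraction(hi) >= target:
            break
        hi *= 10
    else:
        raise ValueError(
            f"target_event_fraction={target} infeasible: censoring horizon "
            "cannot be extended enough under the administrative censoring model"
        )
    while event_fraction(lo) > target:
        lo /= 10
        if lo < 1e-12:
            raise ValueError(
                f"target_event_fraction={target} infeasible: even immediate "
                "censoring leaves a higher expected event fraction"
            )
    return brentq(lambda h: event_fraction(h) - target, lo, hi, xtol=1e-6)


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate a synthetic cohort under the configured study conditions.

    ``seed`` overrides ``config.seed`` when given.  Identical configuration
    and seed give a bit-identical cohort.
    """
    config = (config or SimulationConfig()).validate()
    master = config.seed if seed is None else int(seed)
    rng = substream(master, "simulation")

    n, p = config.n_patients, config.n_features
    phenotype = (rng.random(n) < config.phenotype_prevalence).astype(int)

    X = rng.normal(size=(n, p))
    X[:, : config.n_informative] += config.phenotype_separation * phenotype[:, None]

    batches = _assign_batches(rng, config, phenotype)
    X = _distort_features(rng, X, batches, config)

    clinical = generate_clinical(n, rng=rng)
    ids = clinical.index
    batches.index = ids

    lp = (
        config.log_hr_phenotype * phenotype
        + config.log_hr_age * (clinical["age"].to_numpy() - AGE_MEDIAN)
        / (AGE_IQR[1] - AGE_IQR[0])
        + config.log_hr_ecog * _ecog_numeric(clinical["ecog"])
    )
    k = config.weibull_shape
    # reference scale: median survival at lp = 0 equals baseline_median_months
    b0 = config.baseline_median_months / np.log(2.0) ** (1.0 / k)
    scales = b0 * np.exp(-lp / k)  # per-patient Weibull scale
    T = scales * rng.exponential(size=n) ** (1.0 / k)

    horizon = _calibrate_horizon(scales, k, config.censoring_floor,
                                 config.target_event_fraction)
    C = horizon * rng.uniform(config.censoring_floor, 1.0, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    time = np.maximum(time, 1e-8)  # guard against a zero observed time

    features = pd.DataFrame(X, index=ids,
                            columns=[f"feat_{g:03d}" for g in range(p)])
    survival = pd.DataFrame({"time": time, "event": event}, index=ids)
    latent = pd.Series(phenotype, index=ids, name="latent_phenotype")
    return Cohort(features=features, batches=batches, clinical=clinical,
                  survival=survival, latent_phenotype=latent)
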