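"""Cox models, Harrell's C, bootstrap-t confidence intervals, LRT, KM.

Model fitting goes through lifelines (Efron tie handling); the score
equation is additionally verified here by evaluating the Efron partial
log-likelihood gradient at the estimate, with a Newton polish when the
gradient max-norm exceeds the tolerance, so every returned fit satisfies
``max |grad| < 1e-6``.

Harrell's concordance index follows the usable-pair convention: a pair is
usable when the shorter observed time is an event (pairs tied in time with
both events are unusable; an event tied with a censoring is usable, the
event subject expected to carry the higher risk); tied risk scores
contribute 1/2.

Confidence intervals are bootstrap-t approximations: B patient-level
resamples with replacement, statistic recomputed per resample (Cox models
refit; phenotype labels held fixed as derived on the full cohort), and
CI = mean +/- t_{(1+level)/2, B-1} * sd of the replicate statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import EvaluationConfig

__all__ = [
    "CoxModel",
    "cox_fit",
    "cox_gradient",
    "concordance",
    "bootstrap_ci",
    "BootstrapCI",
    "likelihood_ratio_test",
    "km_estimate",
    "run_univariate",
    "run_multivariate",
    "encode_predictor",
]

GRADIENT_TOL = 1e-6


# ---------------------------------------------------------------------------
# Efron partial likelihood (used for the score-equation check and polish)

def _efron_quantities(beta, X, time, event, need_hess=False):
    order = np.lexsort((1 - event, time))
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wX = w[:, None] * X

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if need_hess else None

    # suffix sums over the risk set (times sorted ascending)
    S_R = np.cumsum(w[::-1])[::-1]
    G_R = np.cumsum(wX[::-1], axis=0)[::-1]
    if need_hess:
        wXX = wX[:, :, None] * X[:, None, :]
        H_R = np.cumsum(wXX[::-1], axis=0)[::-1]

    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        deaths = [idx for idx in range(i, j) if event[idx]]
        d = len(deaths)
        if d:
            sr = S_R[i]
            gr = G_R[i]
            sd_ = w[deaths].sum()
            gd = wX[deaths].sum(axis=0)
            if need_hess:
                hr = H_R[i]
                hd = wXX[deaths].sum(axis=0)
            ll += eta[deaths].sum()
            grad += X[deaths].sum(axis=0)
            for l in range(d):
                frac = l / d
                phi = sr - frac * sd_
                gl = (gr - frac * gd) / phi
                ll -= np.log(phi)
                grad -= gl
                if need_hess:
                    hess -= (hr - frac * hd) / phi - np.outer(gl, gl)
        i = j
    return ll, grad, hess


def cox_gradient(beta, X, time, event):
    """Gradient of the Efron partial log-likelihood at ``beta``."""
    _, grad, _ = _efron_quantities(np.asarray(beta, float), np.asarray(X, float),
                                   np.asarray(time, float), np.asarray(event, int))
    return grad


@dataclass
class CoxModel:
    """A fitted Cox proportional hazards model."""

    covariate_names: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    gradient_max_norm: float
    tie_method: str
    n: int
    n_events: int
    patient_index: pd.Index | None = None

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        return design[self.covariate_names].to_numpy(dtype=float) @ self.coefficients

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coefficients, "HR": self.hazard_ratios,
             "se": self.standard_errors, "p": self.p_values},
            index=self.covariate_names,
        )


def cox_fit(design: pd.DataFrame, survival: pd.DataFrame,
            tie_method: str = "efron") -> CoxModel:
    """Maximize the Cox partial likelihood (Efron ties) on a design matrix.

    ``design`` holds pre-expanded numeric covariate columns aligned with
    ``survival`` (columns ``time``/``event``).  Raises when there are no
    events, when the design is rank deficient, or on non-convergence.
    """
    if tie_method != "efron":
        raise NotImplementedError("only Efron tie handling is implemented")
    survival = survival.loc[design.index]
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with no observed events")
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (constant or collinear columns)")

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = design.copy()
    df["__T"], df["__E"] = time, event
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__T", event_col="__E")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    beta = cph.params_[design.columns].to_numpy(dtype=float)

    # verify the score equation; polish with Newton steps if needed
    ll, grad, hess = _efron_quantities(beta, X, time, event, need_hess=True)
    for _ in range(25):
        if np.abs(grad).max() < GRADIENT_TOL:
            break
        step = np.linalg.solve(hess, grad)
        new_beta = beta - step
        new_ll, new_grad, new_hess = _efron_quantities(new_beta, X, time, event,
                                                       need_hess=True)
        halvings = 0
        while new_ll < ll - 1e-10 * abs(ll) and halvings < 20:  # monotone step-halving
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _efron_quantities(new_beta, X, time, event,
                                                           need_hess=True)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    gmax = float(np.abs(grad).max())
    if gmax >= GRADIENT_TOL:
        raise RuntimeError(
            f"Cox fit did not reach score tolerance: max |grad| = {gmax:.2e}"
        )

    se = np.sqrt(np.diag(np.linalg.inv(-hess)))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return CoxModel(
        covariate_names=list(design.columns),
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        standard_errors=se,
        p_values=pvals,
        log_partial_likelihood=float(ll),
        gradient_max_norm=gmax,
        tie_method=tie_method,
        n=len(design),
        n_events=int(event.sum()),
        patient_index=design.index,
    )


# ---------------------------------------------------------------------------
# Concordance

def concordance(risk_scores, survival: pd.DataFrame | None = None,
                time=None, event=None) -> float:
    """Harrell's concordance index of risk scores against survival.

    Higher scores must predict earlier death.  See the module docstring
    for the usable-pair convention.
    """
    scores = np.asarray(risk_scores, dtype=float)
    if survival is not None:
        time = survival["time"].to_numpy(dtype=float)
        event = survival["event"].to_numpy(dtype=int)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("risk scores must be finite")

    t_i, t_j = time[:, None], time[None, :]
    e_i, e_j = event[:, None], event[None, :]
    usable = ((t_i < t_j) & (e_i == 1)) | ((t_i == t_j) & (e_i == 1) & (e_j == 0))
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    s_i, s_j = scores[:, None], scores[None, :]
    conc = (usable & (s_i > s_j)).sum() + 0.5 * (usable & (s_i == s_j)).sum()
    return float(conc / n_usable)


# ---------------------------------------------------------------------------
# Bootstrap-t confidence interval

@dataclass
class BootstrapCI:
    mean: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_failed: int


def bootstrap_ci(statistic, n: int, config: EvaluationConfig | None = None,
                 rng: np.random.Generator | int | None = None) -> BootstrapCI:
    """Bootstrap-t CI of a patient-level statistic.

    ``statistic`` is called with an integer index array (a with-replacement
    resample of ``range(n)``) and returns a real number; replicates that
    raise are dropped and counted, with an error when more than 10% fail.
    """
    config = (config or EvaluationConfig()).validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    B = config.n_bootstrap
    values = np.empty(B)
    failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = statistic(idx)
        except Exception:
            values[b] = np.nan
            failed += 1
    if failed > 0.10 * B:
        raise RuntimeError(
            f"{failed}/{B} bootstrap replicates failed to evaluate "
            "(model refit errors on resampled cohorts)"
        )
    vals = values[np.isfinite(values)]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    tcrit = stats.t.ppf(0.5 + config.ci_level / 2, df=max(len(vals) - 1, 1))
    half = tcrit * sd
    return BootstrapCI(mean, mean - half, mean + half, len(vals), failed)


# ---------------------------------------------------------------------------
# Likelihood ratio test

@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(nested: CoxModel, full: CoxModel) -> LRTResult:
    """Chi-squared LRT of nested Cox models fit on identical subjects."""
    if not set(nested.covariate_names) <= set(full.covariate_names):
        raise ValueError("models are not nested (covariate sets)")
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ValueError("models were not fit on identical subjects")
    df = len(full.covariate_names) - len(nested.covariate_names)
    stat = 2.0 * (full.log_partial_likelihood - nested.log_partial_likelihood)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(float(stat), df, p)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(survival: pd.DataFrame,
                groups: pd.Series | None = None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, overall or per group."""
    from lifelines import KaplanMeierFitter

    out = {}
    if groups is None:
        groups = pd.Series("all", index=survival.index)
    groups = groups.loc[survival.index]
    for g in pd.unique(groups):
        sub = survival.loc[groups == g]
        if len(sub) == 0:
            warnings.warn(f"empty group {g!r} skipped in KM estimate")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        curve = pd.DataFrame({
            "time": table.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
        })
        out[str(g)] = curve
    return out


# ---------------------------------------------------------------------------
# Predictor encoding and report tables

def encode_predictor(clinical: pd.DataFrame, name: str,
                     min_level_count: int = 5) -> pd.DataFrame:
    """Numeric design columns for one clinical predictor.

    Continuous covariates pass through; categoricals become indicator
    columns against the most frequent level, with levels rarer than
    ``min_level_count`` pooled into one bucket (rare indicators cause
    monotone-likelihood separation in Cox fits, especially under
    bootstrap resampling); ECOG is ordinal 0/1/2 with 'Unknown' mapped
    to NaN (callers drop those rows, complete-case).
    """
    if name == "ecog":
        col = clinical["ecog"].map({"0": 0.0, "1": 1.0, "2": 2.0, 0: 0.0,
                                    1: 1.0, 2: 2.0, "Unknown": np.nan})
        return col.to_frame("ecog")
    series = clinical[name].astype(str)
    if pd.api.types.is_numeric_dtype(clinical[name]):
        return clinical[name].astype(float).to_frame(name)
    counts = series.value_counts()
    rare = counts.index[counts < min_level_count]
    if len(rare) > 1:
        series = series.where(~series.isin(rare), other="pooled")
    ref = series.mode().iloc[0]
    levels = [l for l in pd.unique(series) if l != ref]
    return pd.DataFrame(
        {f"{name}[{lvl}]": (series == lvl).astype(float) for lvl in levels},
        index=series.index,
    )


def _phenotype_design(risk: pd.Series, name: str) -> pd.DataFrame:
    return (risk == "high").astype(float).to_frame(name)


def _model_c_with_ci(design: pd.DataFrame, survival: pd.DataFrame,
                     config: EvaluationConfig, rng) -> tuple[CoxModel, float, BootstrapCI]:
    model = cox_fit(design, survival)
    c = concordance(model.linear_predictor(design), survival.loc[design.index])
    pos = np.arange(len(design))

    def stat(idx):
        sub = design.iloc[idx].reset_index(drop=True)
        surv = survival.loc[design.index].iloc[idx].reset_index(drop=True)
        # indicator levels absent from the resample leave constant columns;
        # refit on the remaining columns
        sub = sub.loc[:, sub.nunique() > 1]
        if sub.shape[1] == 0:
            raise ValueError("no non-constant covariates in resample")
        m = cox_fit(sub, surv)
        return concordance(m.linear_predictor(sub), surv)

    ci = bootstrap_ci(stat, len(pos), config, rng)
    return model, c, ci


CLINICAL_PREDICTORS = ("age", "bmi", "pack_years", "sex", "race", "ecog")


def run_univariate(cohort, phenotypes: dict[str, pd.Series],
                   config: EvaluationConfig | None = None,
                   rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Single-predictor Cox models with C-scores and bootstrap CIs.

    ``phenotypes`` maps display names (e.g. ``"Phenotype (ComBat)"``) to
    low/high risk label series.  The report is sorted by C-score.
    """
    config = (config or EvaluationConfig()).validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    rows = []
    designs: dict[str, pd.DataFrame] = {}
    for name in CLINICAL_PREDICTORS:
        if name in cohort.clinical.columns:
            designs[name] = encode_predictor(cohort.clinical, name)
    for label, risk in phenotypes.items():
        designs[label] = _phenotype_design(risk, label)

    for label, design in designs.items():
        design = design.dropna()
        if design.shape[0] < 2 or any(design[c].nunique() <= 1 for c in design.columns):
            warnings.warn(f"predictor {label!r} is constant or empty; excluded")
            continue
        model, c, ci = _model_c_with_ci(design, cohort.survival, config, rng)
        rows.append({
            "model": label, "covariates": "+".join(model.covariate_names),
            "c_score": c, "c_mean_boot": ci.mean,
            "ci_low": ci.ci_low, "ci_high": ci.ci_high,
            "n": model.n, "n_events": model.n_events,
        })
    report = pd.DataFrame(rows).sort_values("c_score", ascending=False)
    return report.reset_index(drop=True)


def run_multivariate(cohort, phenotypes: dict[str, pd.Series],
                     pc_scores: pd.DataFrame | None = None,
                     config: EvaluationConfig | None = None,
                     rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """The four-model comparison against the clinical baseline.

    Models: baseline (ECOG + age); baseline plus each phenotype; baseline
    plus the PCs whose Wald tests (in the joint Cox fit of all retained
    PCs) reject HR = 1 at alpha.  All models are fit complete-case on
    patients with known ECOG so the LRTs compare identical subjects.
    """
    config = (config or EvaluationConfig()).validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)

    ecog = encode_predictor(cohort.clinical, "ecog")["ecog"]
    age = encode_predictor(cohort.clinical, "age")["age"]
    known = ecog.notna()
    base = pd.DataFrame({"ecog": ecog[known], "age": age[known]})
    surv = cohort.survival.loc[base.index]

    candidates: dict[str, tuple[pd.DataFrame, str | None]] = {
        "ECOG + Age (Baseline)": (base, None)}
    for label, risk in phenotypes.items():
        design = pd.concat([_phenotype_design(risk, label).loc[base.index], base],
                           axis=1)
        candidates[f"{label} + ECOG + Age"] = (design, None)

    note = None
    if pc_scores is not None and pc_scores.shape[1] >= 1:
        joint = cox_fit(pc_scores.loc[base.index], surv)
        sig = [name for name, p in zip(joint.covariate_names, joint.p_values)
               if p < config.lrt_alpha]
        if sig:
            design = pd.concat([pc_scores.loc[base.index, sig], base], axis=1)
            candidates[f"{len(sig)} PCs + ECOG + Age"] = (design, None)
        else:
            note = "no PCs passed HR screening; PC model equals the baseline"
            candidates["0 PCs + ECOG + Age"] = (base, note)

    rows = []
    baseline_model = None
    for name, (design, model_note) in candidates.items():
        model, c, ci = _model_c_with_ci(design, surv, config, rng)
        if name.startswith("ECOG + Age"):
            baseline_model = model
        rows.append({"model": name, "covariates": "+".join(model.covariate_names),
                     "c_score": c, "c_mean_boot": ci.mean,
                     "ci_low": ci.ci_low, "ci_high": ci.ci_high,
                     "n": model.n, "n_events": model.n_events,
                     "_model": model, "note": model_note})
    for row in rows:
        if row["model"].startswith("ECOG + Age") or row["covariates"] == "ecog+age":
            row["lrt_p"] = np.nan
        else:
            row["lrt_p"] = likelihood_ratio_test(baseline_model, row.pop("_model")).p_value
        row.pop("_model", None)
    report = pd.DataFrame(rows)
    cols = ["model", "covariates", "c_score", "c_mean_boot", "ci_low", "ci_high",
            "lrt_p", "n", "n_events", "note"]
    return report[cols]
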