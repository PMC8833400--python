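"""ComBat empirical-Bayes harmonization and the nested multi-batch loop.

ComBat models each feature ``g`` for a patient in batch ``i`` as

    x_ig = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ig,

with additive batch location ``gamma`` and multiplicative batch scale
``delta``.  Per-batch estimates are shrunk toward moment-matched parametric
priors (normal for locations, inverse-gamma for scales) by iterated
conditional posterior means, and the fitted batch effects are removed:

    x*_ig = sigma_g * (z_ig - gamma*_ig) / delta*_ig + alpha_g + X beta_g,

where ``z`` is the feature standardized by the pooled model fit.  The
numerical conventions (pooled variance with denominator n, per-batch sample
variances with denominator n-1, relative-change stopping rule) follow the
reference genomics implementations, so output is exchangeable with them.

With several batch variables, the nested loop harmonizes the running matrix
by every remaining candidate variable, counts the features whose
distributions still differ across that variable's levels (two-sample
Kolmogorov–Smirnov tests on every level pair, flagged at ``alpha``), adopts
the candidate with the fewest flags, and repeats until no variables remain.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import HarmonizationConfig

__all__ = [
    "zscore_features",
    "combat_harmonize",
    "ks_flag_count",
    "nested_combat",
    "CombatEstimates",
    "NestedHarmonizationResult",
]


def zscore_features(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise z-score (sample sd, denominator n-1).

    Constant columns cannot be scaled; they are set to all-zero and their
    names returned (and warned about) so the feature-count contract holds.
    """
    if len(features) < 2:
        raise ValueError("z-scoring needs at least 2 patients")
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"constant features zeroed during z-scoring: {constant}")
    safe_sd = sd.replace(0.0, 1.0)
    out = (features - mean) / safe_sd
    out[constant] = 0.0
    return out, constant


@dataclass
class CombatEstimates:
    """Fitted ComBat parameters for one batch variable.

    ``gamma_star`` / ``delta_star_sq`` are the EB-shrunk per-batch
    location/scale estimates (levels x features, on the standardized
    scale); ``grand_mean`` and ``var_pooled`` are the feature-wise
    standardization parameters; the prior hyperparameters are
    moment-matched per batch.
    """

    batch_variable: str
    levels: list[str]
    feature_names: list[str]
    grand_mean: np.ndarray          # (p,)
    var_pooled: np.ndarray          # (p,)
    gamma_hat: np.ndarray           # (L, p) raw batch locations
    delta_hat: np.ndarray           # (L, p) raw batch variances
    gamma_star: np.ndarray          # (L, p)
    delta_star_sq: np.ndarray       # (L, p)
    gamma_bar: np.ndarray           # (L,)
    tau_sq: np.ndarray              # (L,)
    a_prior: np.ndarray             # (L,)
    b_prior: np.ndarray             # (L,)
    n_iter: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "batch_variable": self.batch_variable,
            "levels": self.levels,
            "gamma_star": self.gamma_star.tolist(),
            "delta_star_sq": self.delta_star_sq.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau_sq": self.tau_sq.tolist(),
            "a_prior": self.a_prior.tolist(),
            "b_prior": self.b_prior.tolist(),
            "n_iter": self.n_iter,
        }


def _aprior(delta_hat_row: np.ndarray) -> float:
    m = delta_hat_row.mean()
    s2 = delta_hat_row.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat_row: np.ndarray) -> float:
    m = delta_hat_row.mean()
    s2 = delta_hat_row.var(ddof=1)
    return (m * s2 + m**3) / s2


def _eb_iterate(s_batch, g_hat, d_hat, g_bar, t2, a, b, tol, max_iter):
    """Iterated conditional posterior means for one batch (all features)."""
    n = s_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((s_batch - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_g = np.abs(g_new - g_old) / np.where(g_old != 0, np.abs(g_old), 1.0)
            rel_d = np.abs(d_new - d_old) / np.abs(d_old)
        change = max(rel_g.max(), rel_d.max())
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_new, d_new, it
    raise RuntimeError(
        f"ComBat EB iteration did not converge within {max_iter} iterations "
        f"(last relative change {change:.3e})"
    )


def combat_harmonize(
    features: pd.DataFrame,
    batch: pd.Series,
    config: HarmonizationConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CombatEstimates]:
    """Parametric empirical-Bayes ComBat for one batch variable.

    ``covariates``, when given, is a numeric design matrix of protected
    effects; its fitted contribution is removed before standardization and
    re-added unchanged.  A single observed batch level is a no-op (there is
    no batch contrast to remove).
    """
    config = (config or HarmonizationConfig()).validate()
    if config.prior == "nonparametric":
        raise NotImplementedError("only the parametric EB prior is implemented")
    batch = batch.loc[features.index]
    levels = [str(l) for l in pd.unique(batch.astype(str))]
    codes = pd.Categorical(batch.astype(str), categories=levels).codes
    counts = np.bincount(codes, minlength=len(levels))
    small = [lvl for lvl, c in zip(levels, counts) if c < config.min_batch_size]
    if len(levels) > 1 and small:
        raise ValueError(
            f"batch level(s) {small} of {batch.name!r} have fewer than "
            f"min_batch_size={config.min_batch_size} patients"
        )

    X = features.to_numpy(dtype=float)
    n, p = X.shape
    var_name = str(batch.name) if batch.name is not None else "batch"

    if len(levels) == 1:
        est = CombatEstimates(
            batch_variable=var_name, levels=levels,
            feature_names=list(features.columns),
            grand_mean=X.mean(axis=0), var_pooled=X.var(axis=0),
            gamma_hat=np.zeros((1, p)), delta_hat=np.ones((1, p)),
            gamma_star=np.zeros((1, p)), delta_star_sq=np.ones((1, p)),
            gamma_bar=np.zeros(1), tau_sq=np.ones(1),
            a_prior=np.full(1, np.nan), b_prior=np.full(1, np.nan),
            n_iter={levels[0]: 0},
        )
        return features.copy(), est

    L = len(levels)
    design_cols = [np.eye(L)[codes]]
    q = 0
    if covariates is not None:
        C = covariates.loc[features.index].to_numpy(dtype=float)
        q = C.shape[1]
        design_cols.append(C)
    design = np.hstack(design_cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    B_hat, *_ = np.linalg.lstsq(design, X, rcond=None)
    grand_mean = (counts / n) @ B_hat[:L]
    stand_mean = np.tile(grand_mean, (n, 1))
    if q:
        stand_mean = stand_mean + design[:, L:] @ B_hat[L:]
    resid = X - design @ B_hat
    var_pooled = (resid**2).mean(axis=0)  # denominator n, reference convention

    live = var_pooled > 0  # zero-variance features pass through untouched
    sd_pooled = np.sqrt(var_pooled, where=live, out=np.ones_like(var_pooled))
    s_data = (X - stand_mean) / sd_pooled

    gamma_hat = np.vstack([s_data[codes == i].mean(axis=0) for i in range(L)])
    delta_hat = np.vstack([s_data[codes == i].var(axis=0, ddof=1) for i in range(L)])
    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(delta_hat[i]) for i in range(L)])
    b_prior = np.array([_bprior(delta_hat[i]) for i in range(L)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    n_iter = {}
    for i, lvl in enumerate(levels):
        g, d, it = _eb_iterate(
            s_data[codes == i], gamma_hat[i], delta_hat[i],
            gamma_bar[i], tau_sq[i], a_prior[i], b_prior[i],
            config.eb_tol, config.eb_max_iter,
        )
        gamma_star[i], delta_star[i] = g, d
        n_iter[lvl] = it

    adj = (s_data - gamma_star[codes]) / np.sqrt(delta_star[codes])
    out = adj * sd_pooled + stand_mean
    out[:, ~live] = X[:, ~live]
    gamma_star[:, ~live] = 0.0
    delta_star[:, ~live] = 1.0

    est = CombatEstimates(
        batch_variable=var_name, levels=levels,
        feature_names=list(features.columns),
        grand_mean=grand_mean, var_pooled=var_pooled,
        gamma_hat=gamma_hat, delta_hat=delta_hat,
        gamma_star=gamma_star, delta_star_sq=delta_star,
        gamma_bar=gamma_bar, tau_sq=tau_sq,
        a_prior=a_prior, b_prior=b_prior, n_iter=n_iter,
    )
    harmonized = pd.DataFrame(out, index=features.index, columns=features.columns)
    return harmonized, est


def ks_flag_count(
    features: pd.DataFrame,
    batch: pd.Series,
    alpha: float = 0.05,
    mode: str = "asymp",
) -> tuple[pd.Series, int]:
    """Count features whose distribution differs across batch levels.

    Every unordered pair of levels (with >= 2 patients each) is compared by
    a two-sided two-sample Kolmogorov–Smirnov test per feature; a feature
    is flagged if any pairwise p-value falls below ``alpha``.  No
    multiplicity correction is applied.  Fewer than two usable levels give
    a count of zero.
    """
    batch = batch.loc[features.index].astype(str)
    sizes = batch.value_counts()
    usable = [lvl for lvl in sizes.index if sizes[lvl] >= 2]
    flags = pd.Series(False, index=features.columns)
    if len(usable) < 2:
        return flags, 0
    X = features.to_numpy(dtype=float)
    groups = {lvl: X[(batch == lvl).to_numpy()] for lvl in usable}
    method = "asymp" if mode == "asymp" else "exact"
    for a_lvl, b_lvl in itertools.combinations(usable, 2):
        A, B = groups[a_lvl], groups[b_lvl]
        for g in range(X.shape[1]):
            if flags.iloc[g]:
                continue
            p = stats.ks_2samp(A[:, g], B[:, g], method=method).pvalue
            if p < alpha:
                flags.iloc[g] = True
    return flags, int(flags.sum())


@dataclass
class NestedHarmonizationResult:
    """Audit trail of the nested multi-batch harmonization loop."""

    applied_order: list[str]
    per_iteration: list[dict[str, int]]   # candidate -> KS flag count
    pre_counts: dict[str, int]            # flags on the z-scored input
    post_counts: dict[str, int]           # flags on the final matrix
    final_features: pd.DataFrame
    per_step_estimates: list[CombatEstimates]
    constant_features: list[str]

    def to_dict(self) -> dict:
        return {
            "applied_order": self.applied_order,
            "per_iteration": self.per_iteration,
            "pre_counts": self.pre_counts,
            "post_counts": self.post_counts,
            "constant_features": self.constant_features,
            "estimates": [e.to_dict() for e in self.per_step_estimates],
        }


def nested_combat(
    features: pd.DataFrame,
    batches: pd.DataFrame,
    config: HarmonizationConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> NestedHarmonizationResult:
    """Sequentially harmonize all batch variables, best-first.

    The input is z-scored once.  At each iteration every remaining batch
    variable is used to harmonize the current matrix separately; each
    candidate result is scored by its KS flag count — summed over all batch
    variables by default (``ks_scope="all"``), or with respect to the
    candidate's own variable only (``ks_scope="own"``) — and the lowest
    count wins (ties go to the variable earliest in the input column
    order).  Exactly one iteration per batch variable is performed.
    """
    config = (config or HarmonizationConfig()).validate()
    if batches.shape[1] == 0:
        raise ValueError("at least one batch variable is required")
    batches = batches.loc[features.index]

    current, constant = zscore_features(features)
    order = list(batches.columns)
    pre_counts = {
        var: ks_flag_count(current, batches[var], config.alpha, config.ks_mode)[1]
        for var in order
    }

    applied: list[str] = []
    per_iteration: list[dict[str, int]] = []
    estimates: list[CombatEstimates] = []
    candidates = list(order)
    while candidates:
        results = {}
        counts = {}
        score_vars = order if config.ks_scope == "all" else None
        for var in candidates:
            harm, est = combat_harmonize(current, batches[var], config, covariates)
            counts[var] = sum(
                ks_flag_count(harm, batches[v], config.alpha, config.ks_mode)[1]
                for v in (score_vars or [var])
            )
            results[var] = (harm, est)
        per_iteration.append(counts)
        best = min(candidates, key=lambda v: (counts[v], order.index(v)))
        current, est = results[best]
        estimates.append(est)
        applied.append(best)
        candidates.remove(best)

    post_counts = {
        var: ks_flag_count(current, batches[var], config.alpha, config.ks_mode)[1]
        for var in order
    }
    return NestedHarmonizationResult(
        applied_order=applied,
        per_iteration=per_iteration,
        pre_counts=pre_counts,
        post_counts=post_counts,
        final_features=current,
        per_step_estimates=estimates,
        constant_features=constant,
    )
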