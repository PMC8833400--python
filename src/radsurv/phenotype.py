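"""Binary imaging phenotype: PCA truncation, consensus clustering, labels.

The phenotype is derived unsupervised from the harmonized feature matrix:

1. PCA retains the smallest number of leading components whose cumulative
   explained variance reaches the threshold (default 85%).
2. Consensus clustering over patient subsamples selects the cluster count
   ``k`` as the one minimizing the proportion of ambiguous clustering (PAC)
   of its consensus matrix.
3. Complete-linkage ("maximum distance") hierarchical clustering of the PC
   scores, cut at ``k``, yields the cluster labels.
4. For ``k = 2`` the cluster with the higher observed death fraction is
   oriented as the "high"-risk phenotype.

Association of the phenotype with clinical covariates uses Kruskal–Wallis
tests for continuous covariates and chi-squared contingency tests for
categorical ones, two-sided at alpha = 0.05.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = [
    "pca_reduce",
    "consensus_select_k",
    "cluster_phenotype",
    "orient_risk",
    "associate_covariates",
    "PhenotypeModel",
    "PCAReduction",
    "ConsensusResult",
]


@dataclass
class PCAReduction:
    loadings: pd.DataFrame               # features x m
    explained_variance_ratio: np.ndarray  # full spectrum
    m: int
    variance_threshold: float


def pca_reduce(
    features: pd.DataFrame, variance_threshold: float = 0.85
) -> tuple[pd.DataFrame, PCAReduction]:
    """Project onto the minimal set of leading PCs reaching the threshold.

    Columns are centered before decomposition.  The sign of each component
    is fixed by making its largest-magnitude loading positive, so scores
    are deterministic across runs and libraries.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    if len(features) < 2:
        raise ValueError("PCA needs at least 2 patients")
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    pca = PCA(svd_solver="full")
    scores_full = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    if variance_threshold >= 1.0 - 1e-12:
        m = pca.n_components_
    else:
        m = int(np.searchsorted(cum, variance_threshold) + 1)
        m = min(m, pca.n_components_)
    comps = pca.components_[:m]
    # deterministic sign: largest-magnitude loading element positive
    signs = np.array([np.sign(c[np.argmax(np.abs(c))]) or 1.0 for c in comps])
    comps = comps * signs[:, None]
    scores = scores_full[:, :m] * signs[None, :]
    cols = [f"PC{i + 1}" for i in range(m)]
    scores_df = pd.DataFrame(scores, index=features.index, columns=cols)
    loadings = pd.DataFrame(comps.T, index=features.columns, columns=cols)
    return scores_df, PCAReduction(loadings, evr, m, variance_threshold)


def _complete_linkage_labels(X: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(X, method="complete", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def cluster_phenotype(scores: pd.DataFrame, k: int) -> pd.Series:
    """Complete-linkage hierarchical clustering of PC scores, cut at ``k``."""
    n = len(scores)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} must lie in [2, n={n}]")
    labels = _complete_linkage_labels(scores.to_numpy(dtype=float), k)
    return pd.Series(labels, index=scores.index, name="cluster")


@dataclass
class ConsensusResult:
    k: int
    pac_scores: dict[int, float]
    consensus: dict[int, np.ndarray]      # per-k n x n matrices, NaN = never co-sampled
    k_range: tuple[int, int]
    n_resamples: int
    subsample_fraction: float


def consensus_select_k(
    scores: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | np.random.Generator | None = None,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> ConsensusResult:
    """Select the cluster count by consensus-clustering stability.

    For each candidate ``k``, patients are repeatedly subsampled without
    replacement and clustered; consensus(i, j) is the fraction of
    co-samplings in which i and j landed in the same cluster.  PAC is the
    fraction of defined off-diagonal consensus entries strictly inside
    ``pac_bounds``; the ``k`` with minimal PAC wins, ties going to the
    smaller ``k``.
    """
    n = len(scores)
    lo, hi = int(k_range[0]), int(k_range[1])
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
    if not 0.5 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must lie in (0.5, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = scores.to_numpy(dtype=float)
    n_sub = max(2, int(np.floor(subsample_fraction * n)))

    subsamples = [rng.choice(n, size=n_sub, replace=False) for _ in range(n_resamples)]
    pac_scores: dict[int, float] = {}
    consensus: dict[int, np.ndarray] = {}
    warned = False
    for k in range(lo, hi + 1):
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for idx in subsamples:
            labels = _complete_linkage_labels(X[idx], min(k, len(idx)))
            same = labels[:, None] == labels[None, :]
            cosampled[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(cosampled > 0, together / np.maximum(cosampled, 1), np.nan)
        np.fill_diagonal(M, 1.0)
        iu = np.triu_indices(n, 1)
        vals = M[iu]
        defined = np.isfinite(vals)
        if not defined.all() and not warned:
            warnings.warn("some patient pairs were never co-sampled; "
                          "their consensus entries are undefined and excluded from PAC")
            warned = True
        vals = vals[defined]
        pac = float(((vals > pac_bounds[0]) & (vals < pac_bounds[1])).mean())
        pac_scores[k] = pac
        consensus[k] = M
    best = min(pac_scores, key=lambda k: (pac_scores[k], k))
    return ConsensusResult(best, pac_scores, consensus,
                           (lo, hi), n_resamples, subsample_fraction)


def orient_risk(labels: pd.Series, survival: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Map the two clusters to low/high risk of death.

    The cluster with the higher observed event fraction becomes "high";
    ties break toward the cluster with the shorter median observed time.
    The mapping is returned for the audit trail.
    """
    uniq = sorted(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"risk orientation requires exactly 2 clusters, got {len(uniq)}")
    survival = survival.loc[labels.index]
    stats_by = {}
    for c in uniq:
        mask = labels == c
        stats_by[c] = (
            float(survival.loc[mask, "event"].mean()),
            float(survival.loc[mask, "time"].median()),
        )
    # higher event fraction first; tie -> shorter median time
    high = max(uniq, key=lambda c: (stats_by[c][0], -stats_by[c][1]))
    mapping = {c: ("high" if c == high else "low") for c in uniq}
    risk = labels.map(mapping).rename("risk")
    audit = {
        "cluster_event_fraction": {str(c): stats_by[c][0] for c in uniq},
        "cluster_median_time": {str(c): stats_by[c][1] for c in uniq},
        "mapping": {str(c): mapping[c] for c in uniq},
    }
    return risk, audit


CONTINUOUS_TESTS = ("age", "bmi", "pack_years")
CATEGORICAL_TESTS = ("sex", "race", "ecog")


def associate_covariates(
    risk_labels: pd.Series,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test phenotype-covariate associations.

    Kruskal–Wallis across phenotype groups for continuous covariates;
    chi-squared contingency tests (no continuity correction) for
    categorical covariates and for the event of death.  Degenerate inputs
    (a constant covariate, an all-zero contingency margin) are reported as
    non-significant with a warning rather than failing.
    """
    groups = sorted(pd.unique(risk_labels))
    if len(groups) < 2:
        raise ValueError("both phenotype groups must be non-empty")
    rows = []
    clinical = clinical.loc[risk_labels.index]
    survival = survival.loc[risk_labels.index]

    for cov in CONTINUOUS_TESTS:
        if cov not in clinical.columns:
            continue
        samples = [clinical.loc[risk_labels == g, cov].to_numpy(dtype=float)
                   for g in groups]
        if len(np.unique(np.concatenate(samples))) == 1:
            warnings.warn(f"covariate {cov!r} is constant; association test degenerate")
            rows.append((cov, "kruskal-wallis", np.nan, 1.0, False))
            continue
        stat, p = stats.kruskal(*samples)
        rows.append((cov, "kruskal-wallis", float(stat), float(p), p < alpha))

    categorical = {cov: clinical[cov] for cov in CATEGORICAL_TESTS if cov in clinical.columns}
    categorical["death"] = survival["event"].map({0: "censored", 1: "death"})
    for cov, values in categorical.items():
        table = pd.crosstab(values, risk_labels)
        table = table.loc[(table.sum(axis=1) > 0), (table.sum(axis=0) > 0)]
        if table.shape[0] < 2 or table.shape[1] < 2:
            warnings.warn(f"contingency table for {cov!r} is degenerate; test skipped")
            rows.append((cov, "chi-squared", np.nan, 1.0, False))
            continue
        res = stats.chi2_contingency(table.to_numpy(), correction=False)
        rows.append((cov, "chi-squared", float(res.statistic), float(res.pvalue),
                     res.pvalue < alpha))
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic",
                                       "p_value", "significant"])


@dataclass
class PhenotypeModel:
    """Fitted phenotype: PCA reduction, consensus selection, risk labels."""

    variance_threshold: float = 0.85
    k_range: tuple[int, int] = (2, 6)
    n_resamples: int = 1000
    subsample_fraction: float = 0.8
    fixed_k: int | None = None
    outcome_aware: bool = True
    linkage: str = "complete"
    distance_metric: str = "euclidean"

    scores: pd.DataFrame | None = None
    pca: PCAReduction | None = None
    consensus: ConsensusResult | None = None
    k: int | None = None
    labels: pd.Series | None = None
    binary_labels: pd.Series | None = None
    risk_labels: pd.Series | None = None
    audit: dict = field(default_factory=dict)

    def fit(self, features: pd.DataFrame, survival: pd.DataFrame,
            seed: int | np.random.Generator | None = None) -> "PhenotypeModel":
        self.scores, self.pca = pca_reduce(features, self.variance_threshold)
        if self.fixed_k is not None:
            self.k = int(self.fixed_k)
        else:
            hi = min(self.k_range[1], len(features) - 1)
            self.consensus = consensus_select_k(
                self.scores, (self.k_range[0], hi), self.n_resamples,
                self.subsample_fraction, seed,
            )
            self.k = self.consensus.k
        self.labels = cluster_phenotype(self.scores, self.k)
        # the risk phenotype is binary by contract: when the consensus-optimal
        # k differs from 2, the 2-cluster cut still defines the risk groups
        # and the disagreement is recorded in the audit trail
        self.binary_labels = (self.labels if self.k == 2
                              else cluster_phenotype(self.scores, 2))
        self.audit["binary_cut_forced"] = bool(self.k != 2)
        if self.outcome_aware:
            self.risk_labels, orient_audit = orient_risk(self.binary_labels,
                                                         survival)
        else:
            # outcome-blind alternative: orient by first-PC mean
            mean_pc1 = self.scores.groupby(self.binary_labels)["PC1"].mean()
            high = mean_pc1.idxmax()
            mapping = {c: ("high" if c == high else "low") for c in mean_pc1.index}
            self.risk_labels = self.binary_labels.map(mapping).rename("risk")
            orient_audit = {"mapping": {str(c): v for c, v in mapping.items()},
                            "rule": "first-PC mean"}
        self.audit["orientation"] = orient_audit
        self.audit["n_pcs"] = self.pca.m
        self.audit["k"] = self.k
        if self.consensus is not None:
            self.audit["pac_scores"] = {str(k): v for k, v in
                                        self.consensus.pac_scores.items()}
        return self
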