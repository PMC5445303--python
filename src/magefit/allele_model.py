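"""First-order multiplicative allele-effect model and feature selection.

The model treats each allele as acting multiplicatively on doubling time,
so a linear model on the natural log of doubling time has per-allele
coefficients interpretable as ln fold-change per allele copy (negative =
faster growth).  Fitting minimises the elastic-net penalised squared error

    L(lambda1, lambda2, beta) = |y - X beta|^2 + lambda1 |beta|_1
                              + lambda2 |beta|^2

with hyperparameters chosen by k-fold cross-validation over a grid of
``l1_ratio = lambda1 / (lambda1 + lambda2)`` values concentrated near the
L1-only end (a small number of alleles is expected to carry most of the
effect) and an automatically scaled path of ``alpha = lambda1 + lambda2``
values.

Because the design is undersampled (more candidate alleles than clones),
single fits are unstable: the selection procedure therefore repeats the
cross-validated fit many times, each time holding out a random subset of
clones to score the fitted model, and averages coefficients across
repetitions weighted by the holdout prediction score.  Features with a
negative weighted-mean coefficient advance to a second identical round, and
the round-2 weighted means rank the final selection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io_formats import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    X: np.ndarray  # clones x features, 0/1
    feature_ids: list
    y_log: np.ndarray  # ln(doubling time in minutes)
    clone_ids: list
    non_identifiable: list = field(default_factory=list)  # constant columns

    @property
    def n_clones(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def occurrence_counts(self) -> np.ndarray:
        return self.X.sum(axis=0)


@dataclass
class PenaltyConfig:
    """Elastic-net hyperparameter search space.

    ``alpha = lambda1 + lambda2`` (up to the fitter's sample-size scaling)
    and ``l1_ratio = lambda1 / (lambda1 + lambda2)``; the grid searches
    densely near pure L1.
    """

    l1_ratio_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)
    n_alphas: int = 100
    k_folds: int = 5
    max_iter: int = 5000
    #: alpha-path depth: smallest alpha = eps * alpha_max (the value that
    #: zeroes every coefficient); 1e-3 spans three decades
    path_eps: float = 1e-3
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if not all(0 < r <= 1 for r in self.l1_ratio_grid):
            raise ValueError("l1_ratio values must be in (0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class AlleleEffect:
    feature_id: str
    mean_coefficient: float  # weighted mean over repetitions
    per_rep_coefficients: np.ndarray
    per_rep_weights: np.ndarray
    selection_frequency: float  # fraction of repetitions with nonzero coef
    survived_round: int  # 0, 1 or 2
    occurrence: int = 0


def build_feature_matrix(
    gt: GenotypeTable,
    min_clone_occurrence: int = 2,
    missing_policy: str = "impute_zero",
) -> FeatureMatrix:
    """Genotype table -> numeric design matrix plus log doubling times.

    Features present in fewer than ``min_clone_occurrence`` clones are
    dropped (singletons are uninformative for regression and inflate the
    feature count).  Missing genotype calls are resolved per policy:
    ``impute_zero`` sets them to 0 (conservative: biases toward no effect),
    ``drop_clone`` removes any clone with a missing call.
    """
    geno = gt.genotypes.copy()
    meta = gt.meta
    if missing_policy == "drop_clone":
        keep = ~geno.isna().any(axis=1)
        geno, meta = geno.loc[keep], meta.loc[keep]
    elif missing_policy == "impute_zero":
        n_missing = int(geno.isna().to_numpy().sum())
        if n_missing:
            logger.warning("imputing %d missing genotype calls to 0", n_missing)
        geno = geno.fillna(0.0)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    t = meta["doubling_time_min"].to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("doubling_time_min missing for retained clones")
    if (t <= 0).any():
        raise ValueError("non-positive doubling time")

    occ = geno.sum(axis=0)
    keep_cols = occ[occ >= min_clone_occurrence].index
    if len(keep_cols) == 0:
        raise ValueError(
            f"no features occur in >= {min_clone_occurrence} clones"
        )
    geno = geno[keep_cols]
    constant = [c for c in geno.columns if geno[c].nunique() == 1]
    if constant:
        logger.warning("non-identifiable constant features: %s", constant)
    return FeatureMatrix(
        X=geno.to_numpy(dtype=float),
        feature_ids=list(geno.columns),
        y_log=np.log(t),
        clone_ids=list(geno.index),
        non_identifiable=constant,
    )


def sklearn_penalties_to_quoted_loss(
    alpha: float, l1_ratio: float, n_samples: int
) -> tuple[float, float]:
    """Map the fitter's (alpha, l1_ratio) to (lambda1, lambda2).

    The coordinate-descent objective divides the residual sum of squares by
    2n; multiplying through by 2n gives the unscaled loss
    |y - Xb|^2 + lambda1 |b|_1 + lambda2 |b|^2 with
    lambda1 = 2 n alpha l1_ratio and lambda2 = n alpha (1 - l1_ratio).
    """
    return 2.0 * n_samples * alpha * l1_ratio, n_samples * alpha * (1.0 - l1_ratio)


@dataclass
class PenalizedFit:
    coefficients: np.ndarray
    intercept: float
    alpha: float
    l1_ratio: float


def fit_penalized_cv(
    fm: FeatureMatrix, cfg: PenaltyConfig, seed: int
) -> PenalizedFit:
    """Cross-validation-selected elastic-net fit of y_log on X.

    The binary design is not standardized (features already share a scale,
    and coefficients stay interpretable as ln fold-change per allele); the
    intercept is fitted unpenalized.  Deterministic given ``seed`` (the
    k-fold shuffle is the only randomness).
    """
    if fm.n_clones < cfg.k_folds:
        raise ValueError(
            f"{fm.n_clones} clones but {cfg.k_folds} folds requested"
        )
    cv = KFold(n_splits=cfg.k_folds, shuffle=True, random_state=seed % (2**32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNetCV(
            l1_ratio=list(cfg.l1_ratio_grid),
            alphas=cfg.n_alphas,
            eps=cfg.path_eps,
            cv=cv,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        ).fit(fm.X, fm.y_log)
    return PenalizedFit(
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        l1_ratio=float(model.l1_ratio_),
    )


def fit_penalized(
    fm: FeatureMatrix, alpha: float, l1_ratio: float, max_iter: int = 50000
) -> PenalizedFit:
    """Elastic-net fit at fixed hyperparameters (no cross-validation)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNet(
            alpha=alpha, l1_ratio=l1_ratio, max_iter=max_iter, tol=1e-10
        ).fit(fm.X, fm.y_log)
    return PenalizedFit(
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        alpha=alpha,
        l1_ratio=l1_ratio,
    )


def _holdout_r2(fit: PenalizedFit, X: np.ndarray, y: np.ndarray) -> float:
    pred = X @ fit.coefficients + fit.intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _subset(fm: FeatureMatrix, rows: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        X=fm.X[rows],
        feature_ids=fm.feature_ids,
        y_log=fm.y_log[rows],
        clone_ids=[fm.clone_ids[i] for i in rows],
    )


def repeated_weighted_fit(
    fm: FeatureMatrix,
    cfg: PenaltyConfig | None = None,
    n_reps: int = 100,
    n_holdout: int = 15,
    seed: int = 0,
    survived_round: int = 1,
) -> list[AlleleEffect]:
    """Repeated cross-validated fits with holdout-score weighting.

    Each repetition removes a fresh uniformly random holdout of
    ``n_holdout`` clones, runs the cross-validated elastic-net fit on the
    remainder, and scores the fit by its coefficient of determination on
    the holdout; negative scores are clamped to zero so poorly predicting
    repetitions get no weight.  Per-feature coefficients are averaged
    across repetitions with these weights.  If every repetition scores
    zero, the unweighted mean is used with a warning.
    """
    cfg = cfg or PenaltyConfig()
    if fm.n_clones <= n_holdout + cfg.k_folds:
        raise ValueError(
            f"need more than {n_holdout + cfg.k_folds} clones, have {fm.n_clones}"
        )
    master = np.random.default_rng(seed)
    # independent, reproducible per-repetition seeds below 2**31
    rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    coefs = np.empty((n_reps, fm.n_features))
    weights = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(rep_seeds[r])
        holdout = rng.choice(fm.n_clones, size=n_holdout, replace=False)
        train = np.setdiff1d(np.arange(fm.n_clones), holdout)
        fit = fit_penalized_cv(_subset(fm, train), cfg, seed=int(rep_seeds[r]))
        coefs[r] = fit.coefficients
        weights[r] = max(0.0, _holdout_r2(fit, fm.X[holdout], fm.y_log[holdout]))
    if weights.sum() == 0:
        logger.warning("all holdout scores <= 0; falling back to unweighted mean")
        mean = coefs.mean(axis=0)
    else:
        mean = (weights[:, None] * coefs).sum(axis=0) / weights.sum()
    occ = fm.occurrence_counts()
    return [
        AlleleEffect(
            feature_id=fid,
            mean_coefficient=float(mean[j]),
            per_rep_coefficients=coefs[:, j].copy(),
            per_rep_weights=weights.copy(),
            selection_frequency=float((coefs[:, j] != 0).mean()),
            survived_round=survived_round,
            occurrence=int(occ[j]),
        )
        for j, fid in enumerate(fm.feature_ids)
    ]


def two_round_selection(
    fm: FeatureMatrix,
    cfg: PenaltyConfig | None = None,
    n_reps: int = 100,
    n_holdout: int = 15,
    seed: int = 0,
) -> list[AlleleEffect]:
    """Two rounds of repeated weighted fits with a negative-coefficient gate.

    Round 1 runs over all features; only features whose weighted-mean
    coefficient is negative (putative fitness improvement: shorter doubling
    time) are carried into round 2, which reruns the identical procedure
    restricted to the survivors, re-selecting hyperparameters from scratch.
    The returned list contains every input feature: round-2 survivors first
    (ranked by round-2 weighted-mean coefficient, most beneficial first),
    then the remainder.  Ties break by higher occurrence count, then id.
    """
    cfg = cfg or PenaltyConfig()
    round1 = repeated_weighted_fit(
        fm, cfg, n_reps=n_reps, n_holdout=n_holdout, seed=seed, survived_round=1
    )
    survivors = [e.feature_id for e in round1 if e.mean_coefficient < 0]
    if not survivors:
        logger.warning("no negative round-1 coefficients; empty selection")
        return sorted(round1, key=lambda e: (e.mean_coefficient, -e.occurrence, e.feature_id))
    idx = [fm.feature_ids.index(f) for f in survivors]
    fm2 = FeatureMatrix(
        X=fm.X[:, idx],
        feature_ids=survivors,
        y_log=fm.y_log,
        clone_ids=fm.clone_ids,
    )
    round2 = repeated_weighted_fit(
        fm2, cfg, n_reps=n_reps, n_holdout=n_holdout, seed=seed + 1,
        survived_round=2,
    )
    by_id = {e.feature_id: e for e in round2}
    out = []
    for e in round1:
        if e.feature_id in by_id:
            out.append(by_id[e.feature_id])
        else:
            out.append(e)
            e.survived_round = 0 if e.mean_coefficient >= 0 else 1
    for e in out:
        if e.survived_round == 1 and e.mean_coefficient >= 0:
            e.survived_round = 0
    out.sort(key=lambda e: (-e.survived_round, e.mean_coefficient, -e.occurrence, e.feature_id))
    return out


def selected_features(effects, require_negative: bool = True) -> list:
    """Ids of round-2 survivors (optionally requiring a negative round-2 mean)."""
    return [
        e.feature_id
        for e in effects
        if e.survived_round == 2 and (e.mean_coefficient < 0 or not require_negative)
    ]


def ols_fit(fm: FeatureMatrix) -> pd.DataFrame:
    """Unregularized OLS of y_log on all features, with t-test p-values.

    Intended for small validation designs (ten or fewer alleles against
    ~90 clones); guarded against overparameterised or rank-deficient input.
    """
    if fm.n_features > fm.n_clones / 3:
        raise ValueError(
            f"{fm.n_features} features for {fm.n_clones} clones: OLS guard "
            "requires features <= clones/3"
        )
    X = sm.add_constant(fm.X, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(fm.X, rowvar=False)
        pairs = [
            (fm.feature_ids[i], fm.feature_ids[j])
            for i in range(fm.n_features)
            for j in range(i + 1, fm.n_features)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear features: {pairs}"
        )
    res = sm.OLS(fm.y_log, X).fit()
    return pd.DataFrame(
        {
            "coefficient": res.params[1:],
            "stderr": res.bse[1:],
            "pvalue": res.pvalues[1:],
        },
        index=pd.Index(fm.feature_ids, name="feature_id"),
    )


def univariate_scan(fm: FeatureMatrix) -> pd.DataFrame:
    """One-feature-at-a-time simple regressions of y_log on each allele.

    The GWAS-style comparator for the multivariate model: correlated
    (hitchhiking) alleles receive similarly extreme univariate slopes, which
    is exactly the confounding the joint penalised model addresses.
    Returns a table sorted by p-value.
    """
    if fm.n_clones < 3:
        raise ValueError("need at least 3 clones")
    rows = []
    for j, fid in enumerate(fm.feature_ids):
        x = fm.X[:, j]
        if np.all(x == x[0]):
            rows.append((fid, 0.0, 1.0))
            continue
        slope, _, _, p, _ = stats.linregress(x, fm.y_log)
        rows.append((fid, float(slope), float(p)))
    df = pd.DataFrame(rows, columns=["feature_id", "slope", "pvalue"]).set_index(
        "feature_id"
    )
    return df.sort_values("pvalue")
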