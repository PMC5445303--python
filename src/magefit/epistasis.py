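"""Pairwise interaction analysis among a small set of validated alleles.

Given clones genotyped over n alleles (typically the half-dozen that
survived model selection) with measured doubling times, fit

    ln t = b0 + sum_i b_i x_i + sum_{i<j} g_ij x_i x_j

by OLS and test each interaction term.  Interaction p-values are Bonferroni
controlled at a family-wise error rate over all C(n, 2) pairs; main effects
are reported uncorrected.  A negative g_ij on the log scale means the pair
is more beneficial together than the product of the single effects predicts
(synergy); a positive g_ij means diminishing returns.

The background-recovery analysis asks the complementary question per
allele: grouping clones by their exact genotype at the *other* alleles, how
much of the original fitness defect does adding the focal allele recover,
and how does that compare with the constant-proportion prediction of the
purely multiplicative (no-epistasis) model?
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, exp

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .growth import percent_defect_recovered
from .io_formats import GenotypeTable


def fwer_threshold(alpha: float = 0.05, n_alleles: int = 6) -> float:
    """Bonferroni per-test threshold over all C(n_alleles, 2) pairs."""
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles for pairwise tests")
    return alpha / comb(n_alleles, 2)


@dataclass
class InteractionModel:
    main_effects: pd.DataFrame  # index allele, columns coefficient/stderr/pvalue
    interaction_terms: pd.DataFrame  # index "a:b"
    fwer_alpha: float
    per_test_threshold: float
    significant_pairs: set
    intercept: float
    n_clones: int

    @property
    def n_alleles(self) -> int:
        return len(self.main_effects)


def fit_pairwise_interactions(
    gt: GenotypeTable,
    response: str = "log_doubling_time",
    fwer_alpha: float = 0.05,
) -> InteractionModel:
    """OLS with all main effects and pairwise products; Bonferroni on pairs.

    ``response`` is ``log_doubling_time`` (the multiplicative model,
    default) or ``doubling_time`` (additive).
    """
    if response not in ("log_doubling_time", "doubling_time"):
        raise ValueError(f"unknown response {response!r}")
    alleles = gt.allele_ids
    if len(alleles) < 2:
        raise ValueError("need at least 2 alleles")
    X = gt.genotypes.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing genotype calls; resolve before fitting")
    t = gt.meta["doubling_time_min"].to_numpy(dtype=float)
    y = np.log(t) if response == "log_doubling_time" else t

    pairs = list(combinations(range(len(alleles)), 2))
    names = alleles + [f"{alleles[i]}:{alleles[j]}" for i, j in pairs]
    design = np.column_stack(
        [X] + [X[:, i] * X[:, j] for i, j in pairs]
    )
    n_params = design.shape[1] + 1
    full = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        est = _estimable_columns(full)
        bad = [names[k - 1] for k in range(1, full.shape[1]) if k not in est]
        raise np.linalg.LinAlgError(f"inestimable terms: {bad}")
    if gt.n_clones < 3 * n_params:
        import logging

        logging.getLogger(__name__).warning(
            "only %d clones for %d parameters (<3x)", gt.n_clones, n_params
        )
    res = sm.OLS(y, full).fit()
    table = pd.DataFrame(
        {"coefficient": res.params[1:], "stderr": res.bse[1:], "pvalue": res.pvalues[1:]},
        index=pd.Index(names, name="term"),
    )
    main = table.iloc[: len(alleles)]
    inter = table.iloc[len(alleles):]
    thresh = fwer_threshold(fwer_alpha, len(alleles))
    sig = {
        tuple(term.split(":"))
        for term, row in inter.iterrows()
        if row["pvalue"] < thresh
    }
    return InteractionModel(
        main_effects=main,
        interaction_terms=inter,
        fwer_alpha=fwer_alpha,
        per_test_threshold=thresh,
        significant_pairs=sig,
        intercept=float(res.params[0]),
        n_clones=gt.n_clones,
    )


def _estimable_columns(full: np.ndarray) -> set:
    """Greedy maximal independent column set (for rank-deficiency reporting)."""
    est, cols = set(), []
    for k in range(full.shape[1]):
        trial = cols + [full[:, k]]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial):
            cols = trial
            est.add(k)
    return est


@dataclass
class BackgroundRecoveryPoint:
    focal_allele: str
    background_genotype: tuple
    x_background_defect_pct: float
    y_recovery_pct: float
    x_sd: float
    y_sd: float
    n_without: int
    n_with: int


@dataclass
class BackgroundRecoveryResult:
    focal_allele: str
    points: list
    slope: float
    intercept: float
    r: float
    pvalue: float
    beta_focal: float

    def multiplicative_prediction(self, x_defect_pct):
        """Recovery predicted by the no-epistasis multiplicative model.

        A background at ``x`` percent of the original defect has doubling
        time ``t_bg = t_parent + (x/100)(t_start - t_parent)``; adding the
        focal allele multiplies it by ``exp(beta)``, recovering
        ``100 (1 - exp(beta)) t_bg / (t_start - t_parent)`` percent of the
        original defect.
        """
        x = np.asarray(x_defect_pct, dtype=float)
        span = self._t_start - self._t_parent
        t_bg = self._t_parent + x / 100.0 * span
        return 100.0 * (1.0 - exp(self.beta_focal)) * t_bg / span

    _t_start: float = 0.0
    _t_parent: float = 0.0


def background_recovery_table(
    gt: GenotypeTable,
    focal_allele: str,
    t_start: float,
    t_parent: float,
    beta_focal: float | None = None,
) -> BackgroundRecoveryResult:
    """Per-background fitness recovery attributable to one allele.

    Clones are grouped by their exact genotype over the non-focal alleles;
    within each group having clones both with and without the focal allele,
    x = mean percent of the original defect remaining among focal-absent
    clones and y = mean recovery gained by the focal-present clones, both
    in percent-of-original-defect units.  A least-squares line through the
    (x, y) points summarises the trend; ``beta_focal`` (the allele's
    first-order log-scale coefficient, estimated from the same data by OLS
    when not supplied) parameterises the multiplicative prediction curve.
    """
    if focal_allele not in gt.allele_ids:
        raise KeyError(focal_allele)
    others = [a for a in gt.allele_ids if a != focal_allele]
    geno = gt.genotypes
    if geno.isna().any().any():
        raise ValueError("missing genotype calls; resolve before analysis")
    t = gt.meta["doubling_time_min"].to_numpy(dtype=float)
    pct_remaining = 100.0 - np.array(
        [percent_defect_recovered(ti, t_start, t_parent).percent_recovered for ti in t]
    )
    focal = geno[focal_allele].to_numpy()
    if beta_focal is None:
        X = sm.add_constant(geno.to_numpy(dtype=float), has_constant="add")
        res = sm.OLS(np.log(t), X).fit()
        beta_focal = float(res.params[1 + gt.allele_ids.index(focal_allele)])

    points = []
    if others:
        groups = geno[others].apply(lambda r: tuple(int(v) for v in r), axis=1)
    else:
        groups = pd.Series([()] * gt.n_clones, index=geno.index)
    for bg in sorted(set(groups)):
        in_group = (groups == bg).to_numpy()
        without = in_group & (focal == 0)
        withf = in_group & (focal == 1)
        if not (without.any() and withf.any()):
            continue
        x_vals = pct_remaining[without]
        rec_with = 100.0 - pct_remaining[withf]
        rec_without = 100.0 - x_vals
        diffs = rec_with[:, None] - rec_without[None, :]
        points.append(
            BackgroundRecoveryPoint(
                focal_allele=focal_allele,
                background_genotype=bg,
                x_background_defect_pct=float(x_vals.mean()),
                y_recovery_pct=float(rec_with.mean() - rec_without.mean()),
                x_sd=float(x_vals.std(ddof=1)) if x_vals.size > 1 else 0.0,
                y_sd=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
                n_without=int(without.sum()),
                n_with=int(withf.sum()),
            )
        )
    if not points:
        import logging

        logging.getLogger(__name__).warning(
            "no background has clones both with and without %s", focal_allele
        )
        return BackgroundRecoveryResult(
            focal_allele, [], np.nan, np.nan, np.nan, np.nan, beta_focal,
            _t_start=t_start, _t_parent=t_parent,
        )
    xs = np.array([p.x_background_defect_pct for p in points])
    ys = np.array([p.y_recovery_pct for p in points])
    if len(points) >= 3 and np.ptp(xs) > 0:
        slope, intercept, r, p, _ = stats.linregress(xs, ys)
    else:
        slope = intercept = r = p = np.nan
    return BackgroundRecoveryResult(
        focal_allele=focal_allele,
        points=points,
        slope=float(slope),
        intercept=float(intercept),
        r=float(r),
        pvalue=float(p),
        beta_focal=beta_focal,
        _t_start=t_start,
        _t_parent=t_parent,
    )
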