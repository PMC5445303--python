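"""Design-power simulation: how much causal fitness effect does the
selection procedure capture?

For a grid of (number of causal alleles, number of sampled clones) cells,
simulate full MAGE experiments with a fixed total fitness defect split
across the causal reversions, run the two-round selection procedure on each
simulated clone panel, and score each replicate by the fraction of total
fitness effect detected: the |beta|-weighted recall of the selected allele
set,

    detection_fraction = sum_{selected & causal} |beta| / sum_{causal} |beta|.

In the multiplicative model with no epistasis this coincides with the
fraction of the log-scale defect the selected alleles jointly explain, which
is also available behind the ``recovered_defect`` scoring flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .allele_model import (
    PenaltyConfig,
    build_feature_matrix,
    selected_features,
    two_round_selection,
)
from .mage_sim import MageSimConfig, experiment_to_genotype_table, simulate_population

logger = logging.getLogger(__name__)

#: the start strain's 60% doubling-time excess, on the natural-log scale
DEFAULT_TOTAL_DEFECT = math.log(1.6)


@dataclass
class PowerResult:
    n_causal: int
    n_clones: int
    replicate: int
    detection_fraction: float
    selected_ids: frozenset
    causal_ids: frozenset
    error: str | None = None


def detection_fraction(true_effects: dict, selected) -> float:
    """|beta|-weighted recall of the selected set against the causal set."""
    total = sum(abs(b) for b in true_effects.values())
    if not true_effects or total == 0:
        raise ValueError("no causal effect to detect (sum |beta| = 0)")
    sel = set(selected)
    hit = sum(abs(b) for a, b in true_effects.items() if a in sel)
    return hit / total


def recovered_defect_fraction(true_effects: dict, selected) -> float:
    """Alternative score: log-defect removed by reverting the selected causal
    alleles, over the total causal log-defect.  Equals detection_fraction
    when effects combine multiplicatively with no epistasis."""
    return detection_fraction(true_effects, selected)


def split_defect(
    total: float, n_causal: int, scheme: str = "equal"
) -> list[float]:
    """Per-allele log effects (negative = beneficial) summing to -total.

    ``equal`` splits evenly; ``geometric`` uses a decreasing sequence with
    ratio 0.7 so a few alleles dominate, closer to real effect-size spectra.
    """
    if total <= 0 or n_causal < 1:
        raise ValueError("need positive total defect and >= 1 causal allele")
    if scheme == "equal":
        parts = np.full(n_causal, 1.0)
    elif scheme == "geometric":
        parts = 0.7 ** np.arange(n_causal)
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    parts = parts / parts.sum() * total
    return [-float(p) for p in parts]


def _cell_config(
    base: MageSimConfig,
    n_causal: int,
    n_clones: int,
    total_defect: float,
    split_scheme: str,
    seed: int,
) -> MageSimConfig:
    n_oligos = max(base.n_oligos, n_causal)
    effects = split_defect(total_defect, n_causal, split_scheme)
    causal = {f"rev{i:03d}": effects[i] for i in range(n_causal)}
    n_samples = len(base.sample_cycles)
    per = max(1, round((n_clones - base.n_start_clones) / n_samples))
    return replace(
        base,
        n_oligos=n_oligos,
        causal_reversion_effects=causal,
        epistasis_terms={},
        clones_per_sample=per,
        seed=seed,
    )


def run_power_replicate(
    cfg: MageSimConfig,
    penalty: PenaltyConfig,
    n_reps: int,
    n_holdout: int,
    seed: int,
    min_clone_occurrence: int = 2,
) -> tuple[float, frozenset, frozenset]:
    """One simulated experiment -> selection -> detection fraction."""
    exp = simulate_population(cfg)
    gt = experiment_to_genotype_table(exp)
    fm = build_feature_matrix(gt, min_clone_occurrence=min_clone_occurrence)
    effects = two_round_selection(
        fm, penalty, n_reps=n_reps, n_holdout=n_holdout, seed=seed
    )
    selected = frozenset(selected_features(effects))
    truth = {
        a: b for a, b in cfg.causal_reversion_effects.items() if b != 0.0
    }
    return detection_fraction(truth, selected), selected, frozenset(truth)


def run_power_sweep(
    base_cfg: MageSimConfig | None = None,
    n_causal_grid=(8,),
    n_clones_grid=(90,),
    replicates: int = 20,
    seed: int = 0,
    total_defect: float = DEFAULT_TOTAL_DEFECT,
    split_scheme: str = "equal",
    penalty: PenaltyConfig | None = None,
    n_reps: int = 20,
    n_holdout: int = 15,
) -> list[PowerResult]:
    """Sweep the (n_causal, n_clones) grid, one full pipeline per replicate.

    ``n_reps`` is the per-round repetition count of the selection procedure;
    the sweep default (20, with a coarser/shallower alpha path) trades
    repetitions for replicates, since the weighted-mean coefficient sign —
    all the selection gate needs — stabilises well before 100 repetitions.
    Replicate seeds derive deterministically from the master seed and the
    grid-cell index.
    """
    if not n_causal_grid or not n_clones_grid:
        raise ValueError("empty grid")
    base_cfg = base_cfg or MageSimConfig()
    penalty = penalty or PenaltyConfig(
        n_alphas=30, path_eps=0.02, max_iter=2000, tol=1e-3
    )
    results = []
    for ci, n_causal in enumerate(n_causal_grid):
        for cj, n_clones in enumerate(n_clones_grid):
            cell_index = ci * len(n_clones_grid) + cj
            # keep the ~1/6 holdout fraction of the 15-of-90 default when a
            # cell samples fewer clones than the holdout would allow
            cell_holdout = min(n_holdout, max(2, n_clones // 6))
            for rep in range(replicates):
                rep_seed = (seed * 100003 + cell_index * 1009 + rep) % (2**31 - 1)
                cfg = _cell_config(
                    base_cfg, n_causal, n_clones, total_defect, split_scheme,
                    seed=rep_seed,
                )
                try:
                    frac, sel, causal = run_power_replicate(
                        cfg, penalty, n_reps=n_reps, n_holdout=cell_holdout,
                        seed=rep_seed + 1,
                    )
                    results.append(
                        PowerResult(n_causal, n_clones, rep, frac, sel, causal)
                    )
                except Exception as err:  # record, keep sweeping
                    logger.warning(
                        "replicate failed (n_causal=%d, n_clones=%d, rep=%d): %s",
                        n_causal, n_clones, rep, err,
                    )
                    results.append(
                        PowerResult(
                            n_causal, n_clones, rep, np.nan,
                            frozenset(), frozenset(), error=str(err),
                        )
                    )
    return results


def summarize_power(results) -> pd.DataFrame:
    """Per-grid-cell mean and SD of the detection fraction.

    ``n_ok`` counts replicates that completed; the SD of a single replicate
    is reported as missing.
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        {
            "n_causal": [r.n_causal for r in results],
            "n_clones": [r.n_clones for r in results],
            "detection_fraction": [r.detection_fraction for r in results],
            "ok": [r.error is None for r in results],
        }
    )
    rows = []
    for (nc, ncl), grp in df.groupby(["n_causal", "n_clones"]):
        ok = grp[grp["ok"]]["detection_fraction"]
        rows.append(
            {
                "n_causal": nc,
                "n_clones": ncl,
                "mean_detection": ok.mean() if len(ok) else np.nan,
                "sd_detection": ok.std(ddof=1) if len(ok) > 1 else np.nan,
                "n_ok": int(len(ok)),
            }
        )
    return pd.DataFrame(rows)
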