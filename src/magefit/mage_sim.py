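"""Synthetic MAGE experiment generator with known ground truth.

Simulates a bacterial population carried through cycles of multiplex
oligonucleotide-mediated editing, in the style of a recoded-strain fitness
recovery experiment:

* each cycle every cell independently acquires each targeted reversion with
  per-oligo probability ``q = 1 - (1 - p_any)**(1/n_oligos)``, calibrated so
  the aggregate chance of receiving at least one edit per cycle is ``p_any``
  (10-20% for real MAGE; default 0.15);
* de novo mutations accumulate at about one per clone per cycle (mismatch
  repair is off in MAGE strains), a small fraction of them causal;
* the true doubling time is multiplicative over alleles:
  ``ln t = ln t_start + sum(beta_i x_i) + sum(gamma_ij x_i x_j)`` with
  beneficial effects negative on the log scale;
* between cycles the population is resampled in proportion to the number of
  doublings each cell achieves during the recovery outgrowth
  (``2**(60 h / t_double)`` for ``h`` hours of growth), a minimal
  exponential-growth selection model that can be switched off;
* at chosen cycles, clones are picked (sampled without replacement) and
  their doubling times measured with multiplicative lognormal noise.

Every simulated experiment carries its ground-truth causal-effect maps so
downstream model-selection and power analyses can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, write_genotype_table


@dataclass
class MageSimConfig:
    """Generative parameters for one simulated MAGE experiment.

    Defaults emulate the published experimental regime: 15% of cells get at
    least one edit per cycle, about one de novo mutation per clone per
    cycle, a start strain with a 60% doubling-time excess over its parent
    (40 vs 25 min), 5 h of outgrowth per cycle, and 5% measurement noise on
    doubling times.
    """

    n_oligos: int = 26
    p_any_edit_per_cycle: float = 0.15
    n_cycles: int = 50
    population_size: int = 1000
    de_novo_rate_per_cycle: float = 1.0
    causal_reversion_effects: dict = field(default_factory=dict)  # allele -> beta
    causal_de_novo_fraction: float = 0.05
    de_novo_effect_sd: float = 0.05  # causal de novo beta ~ N(0, sd), truncated
    de_novo_effect_bound: float = 0.2
    epistasis_terms: dict = field(default_factory=dict)  # (allele, allele) -> gamma
    t_start_min: float = 40.0
    t_parent_min: float = 25.0
    measurement_cv: float = 0.05
    selection_hours_per_cycle: float = 5.0
    #: growth saturation: a culture reaches confluence within the outgrowth
    #: window, so no cell contributes more than this many doublings per
    #: cycle however fast it grows (~1:1000-dilution batch regrowth)
    max_doublings_per_cycle: float = 10.0
    sample_cycles: list = field(default_factory=lambda: [5, 10, 15, 20, 25, 30, 35, 40, 45, 50])
    clones_per_sample: int = 9
    #: unedited start-strain clones measured alongside (cycle 0); real panels
    #: include these as the fitness baseline, and they guarantee every allele
    #: that later sweeps to fixation still varies across the panel
    n_start_clones: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_any_edit_per_cycle <= 1.0:
            raise ValueError("p_any_edit_per_cycle must be in [0, 1]")
        if self.t_start_min <= self.t_parent_min:
            raise ValueError("t_start_min must exceed t_parent_min")
        if self.de_novo_rate_per_cycle < 0:
            raise ValueError("de_novo_rate_per_cycle must be non-negative")
        unknown = set(self.causal_reversion_effects) - set(self.reversion_ids)
        if unknown:
            raise ValueError(f"causal effects for unknown targets: {sorted(unknown)}")
        for pair in self.epistasis_terms:
            if len(pair) != 2 or set(pair) - set(self.reversion_ids):
                raise ValueError(f"bad epistasis pair {pair!r}")
        if any(c > self.n_cycles for c in self.sample_cycles):
            raise ValueError("sample cycle beyond n_cycles")

    @property
    def reversion_ids(self) -> list[str]:
        return [f"rev{i:03d}" for i in range(self.n_oligos)]

    @property
    def per_oligo_q(self) -> float:
        """Per-oligo, per-cycle incorporation probability.

        Derived from the aggregate at-least-one-edit rate assuming
        independent incorporation across oligos.
        """
        if self.n_oligos == 0:
            return 0.0
        return 1.0 - (1.0 - self.p_any_edit_per_cycle) ** (1.0 / self.n_oligos)


@dataclass
class SimulatedClone:
    clone_id: str
    cycle: int
    reversions: np.ndarray  # 0/1 over cfg.reversion_ids
    de_novo_ids: tuple
    true_log_doubling_time: float
    measured_doubling_time_min: float


@dataclass
class SimulatedExperiment:
    config: MageSimConfig
    clones: list
    de_novo_effects: dict  # id -> beta (0.0 for neutral), all minted mutations
    final_reversion_frequencies: np.ndarray

    @property
    def causal_reversion_effects(self) -> dict:
        return dict(self.config.causal_reversion_effects)

    @property
    def causal_de_novo_effects(self) -> dict:
        return {k: v for k, v in self.de_novo_effects.items() if v != 0.0}

    @property
    def causal_effects(self) -> dict:
        """All causal alleles (reversions and de novos) with their effects."""
        return {**self.causal_reversion_effects, **self.causal_de_novo_effects}


def _truncated_normal(rng, sd, bound, size):
    draws = rng.normal(0.0, sd, size)
    while True:
        bad = np.abs(draws) > bound
        if not bad.any():
            return draws
        draws[bad] = rng.normal(0.0, sd, int(bad.sum()))


def simulate_population(cfg: MageSimConfig) -> SimulatedExperiment:
    """Run the per-cycle edit / mutate / select / sample loop.

    Deterministic given ``cfg.seed``.  Returns the sampled clones plus the
    ground-truth causal maps.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = cfg.population_size
    n = cfg.n_oligos

    rev = np.zeros((pop, n), dtype=np.uint8)
    beta_rev = np.array(
        [cfg.causal_reversion_effects.get(a, 0.0) for a in cfg.reversion_ids]
    )
    epi = [
        (cfg.reversion_ids.index(a), cfg.reversion_ids.index(b), g)
        for (a, b), g in cfg.epistasis_terms.items()
    ]
    dn_sets = [()] * pop  # per-cell tuple of de novo ids (immutable, shared)
    dn_effect = np.zeros(pop)  # per-cell summed de novo effect
    dn_registry: dict = {}

    log_t_start = math.log(cfg.t_start_min)
    sigma = math.sqrt(math.log(1.0 + cfg.measurement_cv**2))
    sample_at = set(cfg.sample_cycles)
    clones: list[SimulatedClone] = []
    for k in range(cfg.n_start_clones):
        z = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        clones.append(
            SimulatedClone(
                clone_id=f"c000_{k:02d}",
                cycle=0,
                reversions=np.zeros(n, dtype=np.uint8),
                de_novo_ids=(),
                true_log_doubling_time=log_t_start,
                measured_doubling_time_min=float(math.exp(log_t_start + z)),
            )
        )

    def log_t(idx=None):
        r = rev if idx is None else rev[idx]
        d = dn_effect if idx is None else dn_effect[idx]
        lt = log_t_start + r @ beta_rev + d
        for i, j, g in epi:
            lt = lt + g * (r[:, i] * r[:, j])
        return lt

    for cycle in range(1, cfg.n_cycles + 1):
        # targeted edits: each not-yet-edited locus converts with prob q
        if n and cfg.per_oligo_q > 0:
            hits = rng.random((pop, n)) < cfg.per_oligo_q
            rev |= hits.astype(np.uint8)
        # de novo mutations
        if cfg.de_novo_rate_per_cycle > 0:
            counts = rng.poisson(cfg.de_novo_rate_per_cycle, pop)
            total = int(counts.sum())
            if total:
                causal = rng.random(total) < cfg.causal_de_novo_fraction
                effects = np.zeros(total)
                if causal.any():
                    effects[causal] = _truncated_normal(
                        rng, cfg.de_novo_effect_sd, cfg.de_novo_effect_bound,
                        int(causal.sum()),
                    )
                serial = 0
                for cell in np.nonzero(counts)[0]:
                    new = []
                    for _ in range(counts[cell]):
                        mid = f"dn{cycle}_{serial}"
                        dn_registry[mid] = float(effects[serial])
                        new.append(mid)
                        serial += 1
                    dn_sets[cell] = dn_sets[cell] + tuple(new)
                    dn_effect[cell] += effects[serial - len(new): serial].sum()
        # sample clones before selection so late-cycle picks still show
        # within-cycle diversity
        if cycle in sample_at:
            picks = rng.choice(pop, size=min(cfg.clones_per_sample, pop), replace=False)
            lt = log_t(picks)
            noise = rng.normal(0.0, sigma, picks.size) if sigma > 0 else np.zeros(picks.size)
            for k, (cell, l, z) in enumerate(zip(picks, lt, noise)):
                clones.append(
                    SimulatedClone(
                        clone_id=f"c{cycle:03d}_{k:02d}",
                        cycle=cycle,
                        reversions=rev[cell].copy(),
                        de_novo_ids=dn_sets[cell],
                        true_log_doubling_time=float(l),
                        measured_doubling_time_min=float(math.exp(l + z)),
                    )
                )
        # fitness-proportional resampling (selection during outgrowth)
        if cfg.selection_hours_per_cycle > 0:
            doublings = np.minimum(
                60.0 * cfg.selection_hours_per_cycle / np.exp(log_t()),
                cfg.max_doublings_per_cycle,
            )
            w = np.exp2(doublings - doublings.max())
            w /= w.sum()
            idx = rng.choice(pop, size=pop, p=w)
            rev = rev[idx]
            dn_effect = dn_effect[idx]
            dn_sets = [dn_sets[i] for i in idx]

    return SimulatedExperiment(
        config=cfg,
        clones=clones,
        de_novo_effects=dn_registry,
        final_reversion_frequencies=rev.mean(axis=0),
    )


def experiment_to_genotype_table(exp: SimulatedExperiment) -> GenotypeTable:
    """Sampled clones as a GenotypeTable (reversion + observed de novo columns)."""
    cfg = exp.config
    dn_observed: list[str] = []
    seen = set()
    for c in exp.clones:
        for mid in c.de_novo_ids:
            if mid not in seen:
                seen.add(mid)
                dn_observed.append(mid)
    rows = []
    for c in exp.clones:
        row = dict(zip(cfg.reversion_ids, c.reversions.astype(float)))
        present = set(c.de_novo_ids)
        row.update({mid: float(mid in present) for mid in dn_observed})
        rows.append(row)
    geno = pd.DataFrame(rows, index=pd.Index([c.clone_id for c in exp.clones], name="clone_id"))
    meta = pd.DataFrame(
        {
            "lineage": pd.NA,
            "cycle": [c.cycle for c in exp.clones],
            "doubling_time_min": [c.measured_doubling_time_min for c in exp.clones],
        },
        index=geno.index,
    )
    return GenotypeTable(geno, meta)


def export_experiment(exp: SimulatedExperiment, out_dir) -> dict:
    """Write genotype and ground-truth TSVs; returns the paths written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    gt_path = os.path.join(out_dir, "genotypes.tsv")
    truth_path = os.path.join(out_dir, "ground_truth.tsv")
    write_genotype_table(experiment_to_genotype_table(exp), gt_path)
    truth = pd.DataFrame(
        sorted(exp.causal_effects.items()),
        columns=["allele_id", "true_log_effect"],
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"genotypes": gt_path, "ground_truth": truth_path}


def simulate_growth_curve(
    t_double_min: float,
    n_points: int = 97,
    interval_min: float = 5.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    od_init: float = 0.01,
    od_max: float = 1.0,
    lag_min: float = 60.0,
) -> np.ndarray:
    """Piecewise lag / exponential / saturation OD600 series.

    The exponential segment has exact per-point log slope
    ``ln(2) * interval_min / t_double_min``; readings are multiplied by iid
    lognormal noise of coefficient of variation ``noise_cv``.
    """
    if t_double_min <= 0:
        raise ValueError("t_double_min must be positive")
    t = np.arange(n_points) * interval_min
    od = np.where(
        t < lag_min,
        od_init,
        od_init * np.exp2((t - lag_min) / t_double_min),
    )
    od = np.minimum(od, od_max)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        od = od * rng.lognormal(0.0, sigma, n_points)
    return od


def simulate_construction_clones(
    allele_ids,
    effects: dict,
    n_clones: int,
    t_start_min: float = 40.0,
    epistasis_terms: dict | None = None,
    measurement_cv: float = 0.05,
    p_present: float = 0.5,
    seed: int = 0,
) -> GenotypeTable:
    """Clones with random intermediate genotypes over a small allele set.

    Emulates the panel of clones generated while assembling a final strain
    allele-by-allele: each allele is present independently with probability
    ``p_present``, and the measured doubling time follows the multiplicative
    model with optional pairwise epistasis plus lognormal measurement noise.
    Used for pairwise-interaction analyses, where combinatorially mixed
    genotypes (rather than MAGE cycling structure) are what matters.
    """
    rng = np.random.default_rng(seed)
    alleles = list(allele_ids)
    X = (rng.random((n_clones, len(alleles))) < p_present).astype(float)
    lt = math.log(t_start_min) + X @ np.array([effects.get(a, 0.0) for a in alleles])
    for (a, b), g in (epistasis_terms or {}).items():
        lt = lt + g * X[:, alleles.index(a)] * X[:, alleles.index(b)]
    sigma = math.sqrt(math.log(1.0 + measurement_cv**2)) if measurement_cv > 0 else 0.0
    noise = rng.normal(0.0, sigma, n_clones) if sigma > 0 else np.zeros(n_clones)
    t_meas = np.exp(lt + noise)
    ids = pd.Index([f"x{k:04d}" for k in range(n_clones)], name="clone_id")
    geno = pd.DataFrame(X, index=ids, columns=alleles)
    meta = pd.DataFrame(
        {"lineage": pd.NA, "cycle": 0, "doubling_time_min": t_meas}, index=ids
    )
    return GenotypeTable(geno, meta)
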