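"""Recurrent genomic-selection program: the full cycle engine.

One replicate runs: draw the initial crossing parents at random from the
founder panel (cycle 1), fit BayesR marker effects on the whole panel's
BLUE-like phenotypes, then repeat per cycle — cross the current parents per
the cross plan, keep 10 F1 per cross, bulk 200 F2, advance to F4 by
single-seed descent, predict GEBVs on the candidates (F4 pool plus the
current parents), and let the strategy pick the next parent set and cross
plan.  Cycle k's record summarizes the parents *of* cycle k, so cycle 1 is
the random baseline and a program with n_cycles parent sets performs
n_cycles - 1 rounds of selection (matching the convention that gain "c1" is
the transition from the random parents into the first selected set).

Marker effects are estimated once per replicate from the founder panel and
reused in every cycle (two-step genomic selection); set
``retrain_each_cycle`` to re-fit on the panel plus nothing new — retraining
data beyond the panel is out of scope.  Inbreeding is tracked against the
founder allele frequencies, which are held fixed across cycles so that F
measures loss of the initial diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesr import BayesRConfig, MarkerEffects, fit_marker_effects, predict_gebv
from .founders import Population, TraitArchitecture, simulate_phenotypes, TRAITS
from .genome import GeneticMap, Individual, cross, advance_ssd, dosage_matrix
from .kinship import compute_grm, inbreeding_coefficient
from .selection import CrossPlan, StrategyConfig, random_cross_plan, select_parents

__all__ = [
    "ProgramConfig",
    "CycleRecord",
    "SimulationResult",
    "run_cycle",
    "run_program",
    "compare_strategies",
    "desk_scale",
]


@dataclass
class ProgramConfig:
    """Scheme dimensions.  ``n_cycles`` counts parent sets including the
    initial random one, so the default 5 performs 4 selection rounds."""

    n_cycles: int = 5
    n_replicates: int = 50
    n_initial_parents: int = 50
    n_crosses: int = 30
    n_f1_per_cross: int = 10
    n_f2_bulk: int = 200
    n_f4_per_cross: int = 100
    strategy: StrategyConfig = field(default_factory=StrategyConfig)
    bayesr: BayesRConfig = field(default_factory=BayesRConfig)
    retrain_each_cycle: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_cycles", "n_replicates", "n_initial_parents", "n_crosses",
            "n_f1_per_cross", "n_f2_bulk", "n_f4_per_cross",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class CycleRecord:
    replicate: int
    cycle: int
    mean_gebv: dict  # trait -> mean GEBV over this cycle's parents
    sd_gebv: dict  # trait -> SD of GEBVs over this cycle's parents
    F: float  # inbreeding coefficient of this cycle's parents
    selected_ids: list


@dataclass
class SimulationResult:
    records: list  # CycleRecord, complete replicate x cycle grid
    config: ProgramConfig
    replicate_seeds: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"replicate": r.replicate, "cycle": r.cycle, "F": r.F}
            for t in TRAITS:
                row[f"mean_gebv_{t}"] = r.mean_gebv[t]
                row[f"sd_gebv_{t}"] = r.sd_gebv[t]
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["replicate", "cycle"]).reset_index(drop=True)

    def to_csv(self, path, strategy: str | None = None) -> None:
        df = self.to_frame()
        df.insert(0, "strategy", strategy or self.config.strategy.strategy)
        df.to_csv(path, index=False)


def _record_parents(
    parents: list[Individual],
    effects: MarkerEffects,
    base_freqs: np.ndarray,
    replicate: int,
    cycle: int,
) -> CycleRecord:
    dos = dosage_matrix(parents)
    mean_g, sd_g = {}, {}
    for t in TRAITS:
        g = predict_gebv(dos, effects, t)
        mean_g[t], sd_g[t] = float(g.mean()), float(g.std())
    grm = compute_grm(dos, base_freqs, [p.id for p in parents])
    return CycleRecord(
        replicate, cycle, mean_g, sd_g, inbreeding_coefficient(grm),
        [p.id for p in parents],
    )


def run_cycle(
    parents: list[Individual],
    plan: CrossPlan,
    effects: MarkerEffects,
    config: ProgramConfig,
    gmap: GeneticMap,
    base_freqs: np.ndarray,
    rng: np.random.Generator,
    cycle_tag: str = "c",
    replicate: int = 0,
    cycle: int = 0,
):
    """One breeding round: crosses -> F1 -> F2 bulk -> SSD F4 -> GEBV ->
    selection.  Returns (new_parents, new_plan, CycleRecord of new parents)."""
    if len(parents) < 2:
        raise ValueError("need at least 2 parents")
    by_id = {p.id: p for p in parents}
    f1_families = [
        cross(
            by_id[a], by_id[b], config.n_f1_per_cross, gmap, rng,
            generation="F1", id_prefix=f"{cycle_tag}_x{ci}",
        )
        for ci, (a, b) in enumerate(plan.crosses)
    ]
    f4s = advance_ssd(
        f1_families, gmap, rng,
        n_f2_bulk=config.n_f2_bulk,
        n_f4_per_cross=config.n_f4_per_cross,
        id_prefix=cycle_tag,
    )
    candidates = f4s + parents
    cand_ids = [c.id for c in candidates]
    dos = dosage_matrix(candidates)
    gebv = pd.DataFrame(
        {t: predict_gebv(dos, effects, t) for t in TRAITS}, index=cand_ids
    )
    grm = None
    if config.strategy.strategy == "GY_plus_OL_Rel":
        grm = compute_grm(dos, base_freqs, cand_ids)
    selected_ids, new_plan = select_parents(
        config.strategy, gebv, grm, cand_ids, rng
    )
    by_cand = {c.id: c for c in candidates}
    new_parents = [by_cand[i] for i in selected_ids]
    record = _record_parents(new_parents, effects, base_freqs, replicate, cycle)
    return new_parents, new_plan, record


def _replicate_seeds(master_seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_program(
    founders: Population,
    arch: TraitArchitecture,
    config: ProgramConfig,
    phenotypes: pd.DataFrame | None = None,
    effects_by_replicate: dict | None = None,
) -> SimulationResult:
    """Run the full recurrent scheme over all replicates.

    Per replicate: sample the initial parents uniformly without replacement
    from the founder panel, fit marker effects on the whole panel (unless a
    pre-fitted ``effects_by_replicate`` mapping is supplied — used to share
    training across strategy arms under common random numbers), then run the
    cycles.  Replicate seeds derive deterministically from ``config.seed``.
    """
    if founders.n_individuals < config.n_initial_parents:
        raise ValueError("founder pool smaller than n_initial_parents")
    if phenotypes is None:
        phenotypes = simulate_phenotypes(founders, arch, seed=config.seed)
    base_freqs = founders.dosages().mean(axis=0) / 2.0
    seeds = _replicate_seeds(config.seed, config.n_replicates)

    records: list[CycleRecord] = []
    for rep, rep_seed in enumerate(seeds):
        rng = np.random.default_rng(rep_seed)
        if effects_by_replicate is not None and rep in effects_by_replicate:
            effects = effects_by_replicate[rep]
        else:
            bcfg = BayesRConfig(
                config.bayesr.n_iter, config.bayesr.burn_in, config.bayesr.thin,
                config.bayesr.mixture_variance_fractions,
                config.bayesr.dirichlet_prior, rep_seed,
            )
            effects = fit_marker_effects(
                founders.dosages(), phenotypes, bcfg,
                marker_ids=founders.marker_ids,
            )
            if effects_by_replicate is not None:
                effects_by_replicate[rep] = effects
        picks = rng.choice(
            founders.n_individuals, size=config.n_initial_parents, replace=False
        )
        parents = [founders.individuals[i] for i in picks]
        plan = random_cross_plan([p.id for p in parents], config.n_crosses, rng)
        records.append(_record_parents(parents, effects, base_freqs, rep, 1))
        for cyc in range(2, config.n_cycles + 1):
            parents, plan, record = run_cycle(
                parents, plan, effects, config, founders.gmap, base_freqs, rng,
                cycle_tag=f"r{rep}c{cyc}", replicate=rep, cycle=cyc,
            )
            records.append(record)
    return SimulationResult(records, config, seeds)


def compare_strategies(
    founders: Population,
    arch: TraitArchitecture,
    config: ProgramConfig,
    strategies=("GY", "OL", "GY_plus_OL", "GY_plus_OL_Rel"),
    phenotypes: pd.DataFrame | None = None,
) -> dict:
    """Run every strategy arm under common random numbers.

    All arms share the master seed, hence the same initial parents and the
    same per-replicate marker effects (fitted once and cached), so strategy
    contrasts are paired within replicate.
    """
    if phenotypes is None:
        phenotypes = simulate_phenotypes(founders, arch, seed=config.seed)
    cache: dict = {}
    results = {}
    for strat in strategies:
        scfg = StrategyConfig(
            strategy=strat,
            n_parents=config.strategy.n_parents,
            n_crosses=config.strategy.n_crosses,
            index_weights=config.strategy.index_weights,
            lam=config.strategy.lam,
            usage_cap=config.strategy.usage_cap,
            ga=config.strategy.ga,
        )
        cfg = ProgramConfig(
            n_cycles=config.n_cycles,
            n_replicates=config.n_replicates,
            n_initial_parents=config.n_initial_parents,
            n_crosses=config.n_crosses,
            n_f1_per_cross=config.n_f1_per_cross,
            n_f2_bulk=config.n_f2_bulk,
            n_f4_per_cross=config.n_f4_per_cross,
            strategy=scfg,
            bayesr=config.bayesr,
            seed=config.seed,
        )
        results[strat] = run_program(
            founders, arch, cfg, phenotypes=phenotypes, effects_by_replicate=cache
        )
    return results


def desk_scale(seed: int | None = None) -> ProgramConfig:
    """Reduced-scale preset for laptop-time experiments: 600 F4 candidates
    per cycle (30 crosses x 20), 10 replicates, a shortened BayesR chain and
    a modest GA budget.  Pair with a 1000-marker, 200-QTL founder panel."""
    from .selection import GAConfig

    return ProgramConfig(
        n_cycles=5,
        n_replicates=10,
        n_initial_parents=50,
        n_crosses=30,
        n_f1_per_cross=10,
        n_f2_bulk=60,
        n_f4_per_cross=20,
        strategy=StrategyConfig(
            ga=GAConfig(pop_size=120, n_generations=200, seed=seed)
        ),
        bayesr=BayesRConfig(n_iter=800, burn_in=200, thin=5, seed=seed),
        seed=seed,
    )
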