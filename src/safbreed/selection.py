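"""Parent selection strategies: truncation, equal-weight index, and
GA-optimized mate allocation with a genomic co-ancestry penalty.

Four strategies are supported, mirroring common practice in recurrent
genomic selection:

* ``GY`` / ``OL`` — single-trait truncation (independent culling): the top
  n candidates by that trait's GEBV become parents, and crosses among them
  are drawn at random.
* ``GY_plus_OL`` — an equal-weight index of the two traits' standardized
  GEBVs; truncation on the index, random crossing.
* ``GY_plus_OL_Rel`` — parent selection and mate allocation are optimized
  jointly: a pairwise fitness matrix holds the mid-parent index minus
  lambda times the genomic co-ancestry (the off-diagonal GRM entry), and a
  genetic algorithm searches for the set of crosses maximizing total
  fitness subject to a parent-set cap.
* ``random`` — a null strategy (random parents, random crosses) used to
  verify that gains vanish without a selection differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import GRMatrix

__all__ = [
    "GAConfig",
    "StrategyConfig",
    "FitnessMatrix",
    "CrossPlan",
    "select_truncation",
    "build_index",
    "build_fitness_matrix",
    "ga_optimize_crosses",
    "random_cross_plan",
    "select_parents",
]

STRATEGIES = ("GY", "OL", "GY_plus_OL", "GY_plus_OL_Rel", "random")


@dataclass
class GAConfig:
    pop_size: int = 200
    n_generations: int = 300
    mutation_rate: float = 0.02
    crossover_rate: float = 0.8
    elitism: int = 2
    tournament_k: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for r in (self.mutation_rate, self.crossover_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if not (0 <= self.elitism < self.pop_size):
            raise ValueError("elitism must be in [0, pop_size)")


@dataclass
class StrategyConfig:
    strategy: str = "GY_plus_OL"
    n_parents: int = 50
    n_crosses: int = 30
    index_weights: tuple = (1.0, 1.0)
    lam: float = 0.5  # co-ancestry penalty weight
    usage_cap: int = 2  # max crosses per parent in the GA plan
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if self.n_parents < 2:
            raise ValueError("n_parents must be >= 2")
        if self.n_crosses < 1:
            raise ValueError("n_crosses must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class FitnessMatrix:
    """Pairwise cross fitness: mid-parent index minus lambda * co-ancestry."""

    values: np.ndarray
    candidate_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.candidate_ids)
        if self.values.shape != (n, n):
            raise ValueError("fitness matrix shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fitness matrix must be finite")


@dataclass
class CrossPlan:
    """A list of parent-id pairs; no self-crosses, bounded distinct parents."""

    crosses: list  # [(parent_id, parent_id), ...]
    parent_set: list  # distinct ids, in order of first use

    def __post_init__(self) -> None:
        for a, b in self.crosses:
            if a == b:
                raise ValueError("self-crosses are not allowed")


def select_truncation(gebvs, candidate_ids, n: int) -> list:
    """Ids of the n largest GEBVs; ties broken by stable input order."""
    g = np.asarray(gebvs, dtype=float)
    if n > g.shape[0]:
        raise ValueError("cannot select more candidates than available")
    order = np.argsort(-g, kind="stable")[:n]
    return [candidate_ids[i] for i in order]


def build_index(gebv_gy, gebv_ol, weights=(1.0, 1.0)) -> np.ndarray:
    """w1 * z(GEBV_GY) + w2 * z(GEBV_OL), standardized over the candidate set."""
    g1 = np.asarray(gebv_gy, dtype=float)
    g2 = np.asarray(gebv_ol, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("GEBV vectors must have equal length")
    s1, s2 = g1.std(), g2.std()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("degenerate candidate set: zero GEBV variance")
    return weights[0] * (g1 - g1.mean()) / s1 + weights[1] * (g2 - g2.mean()) / s2


def build_fitness_matrix(index, grm: GRMatrix, lam: float) -> FitnessMatrix:
    """fitness(i, j) = (index_i + index_j) / 2 - lam * GRM(i, j).

    The diagonal is filled by the same formula but is never used: plans
    exclude self-crosses by construction.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape[0] != len(grm.individual_ids):
        raise ValueError("index and GRM must cover the same candidates")
    mid = (idx[:, None] + idx[None, :]) / 2.0
    return FitnessMatrix(mid - lam * grm.values, list(grm.individual_ids))


def plan_objective(plan_idx: np.ndarray, fitness: np.ndarray) -> float:
    """Total fitness of a plan given as an (n_crosses, 2) index array."""
    return float(fitness[plan_idx[:, 0], plan_idx[:, 1]].sum())


def _repair(plan, n_cand, n_crosses, n_parents, cap, rng, spread_to=None):
    """Make a plan feasible: no self pairs, no duplicate pairs, per-parent
    usage <= cap, distinct parents <= n_parents (hard).  Infeasible genes are
    resampled; if the sampler gets cornered near the caps, a deterministic
    fallback picks the least-used unseen pair within the parent set (the
    usage cap may then exceed by one — the parent-set bound never does).

    With ``spread_to`` set, crosses are additionally re-spread after repair
    so the plan uses exactly min(spread_to, 2*n_crosses, n_cand) distinct
    parents: slots of multiply-used parents are reassigned to unused
    candidates until the parent count is met."""
    usage: dict[int, int] = {}
    seen: set[tuple[int, int]] = set()
    out = plan.copy()

    def ok_pair(a: int, b: int) -> bool:
        return (
            a != b
            and (min(a, b), max(a, b)) not in seen
            and usage.get(a, 0) < cap
            and usage.get(b, 0) < cap
            and (len(usage) + (a not in usage) + (b not in usage)) <= n_parents
        )

    for i in range(n_crosses):
        a, b = int(out[i, 0]), int(out[i, 1])
        if not ok_pair(a, b):
            for _attempt in range(60):
                if len(usage) >= n_parents:
                    pool = [p for p, u in usage.items() if u < cap]
                    if len(pool) < 2:
                        break
                    a, b = (int(x) for x in rng.choice(pool, size=2, replace=False))
                else:
                    a, b = int(rng.integers(n_cand)), int(rng.integers(n_cand))
                if ok_pair(a, b):
                    break
            else:
                a = b = -1
            if not ok_pair(a, b):
                # deterministic fallback within the current parent set
                keys = sorted(usage, key=lambda p: (usage[p], p))
                found = False
                for x in range(len(keys)):
                    for y in range(x + 1, len(keys)):
                        a, b = keys[x], keys[y]
                        if (min(a, b), max(a, b)) not in seen:
                            found = True
                            break
                    if found:
                        break
                if not found:  # pragma: no cover - needs n_crosses > C(n_parents, 2)
                    raise RuntimeError("repair failed; constraints too tight")
        out[i] = (a, b)
        seen.add((min(a, b), max(a, b)))
        usage[a] = usage.get(a, 0) + 1
        usage[b] = usage.get(b, 0) + 1

    if spread_to is not None:
        target = min(spread_to, 2 * n_crosses, n_cand)
        unused = [p for p in range(n_cand) if p not in usage]
        rng.shuffle(unused)
        # replace one slot of a multiply-used parent with an unused candidate
        # until exactly `target` distinct parents participate
        while len(usage) < target and unused:
            multi = [p for p, u in usage.items() if u > 1]
            if not multi:
                break
            p = multi[int(rng.integers(len(multi)))]
            slots = [
                (i, s) for i in range(n_crosses) for s in (0, 1) if out[i, s] == p
            ]
            i, s = slots[int(rng.integers(len(slots)))]
            new = unused.pop()
            old_key = (min(out[i, 0], out[i, 1]), max(out[i, 0], out[i, 1]))
            seen.discard(old_key)
            out[i, s] = new
            seen.add((min(out[i, 0], out[i, 1]), max(out[i, 0], out[i, 1])))
            usage[p] -= 1
            if usage[p] == 0:
                del usage[p]
            usage[new] = 1
    return out


def ga_optimize_crosses(
    fitness: FitnessMatrix,
    n_crosses: int,
    n_parents: int,
    ga: GAConfig | None = None,
    usage_cap: int = 2,
    rng: np.random.Generator | None = None,
    min_parents: int | None = None,
) -> CrossPlan:
    """Genetic-algorithm search for the cross set maximizing total fitness.

    Chromosomes are fixed-length lists of ``n_crosses`` parent pairs over the
    candidate indices; a repair operator enforces feasibility (no selfs or
    duplicate pairs, per-parent usage cap, parent-set size cap).  With
    ``min_parents`` set, plans are re-spread to use exactly that many
    distinct parents (bounded by 2*n_crosses and the candidate count), which
    keeps the crosses distributed over the whole selected parent set instead
    of concentrating on a few elite individuals.  Tournament
    selection, one-point crossover at pair boundaries, per-gene mutation, and
    elitism.  Initial plans are biased toward candidates with high row-mean
    fitness, which speeds convergence without changing the objective.
    """
    cfg = ga if ga is not None else GAConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    F = fitness.values
    n_cand = F.shape[0]
    eff_parents = min(n_parents, n_cand)
    if usage_cap * eff_parents < 2 * n_crosses or n_cand < 2:
        raise ValueError("infeasible: not enough parent slots for the requested crosses")
    if n_crosses > n_cand * (n_cand - 1) // 2:
        raise ValueError("infeasible: not enough distinct pairs")

    score = F.mean(axis=1)
    top_pool = np.argsort(-score)[: max(2 * eff_parents, 4)]

    def random_plan(biased: bool) -> np.ndarray:
        src = top_pool if biased else np.arange(n_cand)
        raw = rng.choice(src, size=(n_crosses, 2))
        return _repair(raw, n_cand, n_crosses, eff_parents, usage_cap, rng,
                       spread_to=min_parents)

    pop = [random_plan(i < cfg.pop_size // 2) for i in range(cfg.pop_size)]
    obj = np.array([plan_objective(p, F) for p in pop])

    for _gen in range(cfg.n_generations):
        order = np.argsort(-obj)
        elite = [pop[i].copy() for i in order[: cfg.elitism]]
        # tournament selection
        draws = rng.integers(0, cfg.pop_size, size=(cfg.pop_size, cfg.tournament_k))
        winners = draws[np.arange(cfg.pop_size), np.argmax(obj[draws], axis=1)]
        children = []
        for i in range(0, cfg.pop_size - cfg.elitism, 2):
            pa = pop[winners[i]].copy()
            pb = pop[winners[(i + 1) % cfg.pop_size]].copy()
            if rng.random() < cfg.crossover_rate and n_crosses > 1:
                cut = int(rng.integers(1, n_crosses))
                pa[cut:], pb[cut:] = pb[cut:].copy(), pa[cut:].copy()
            for child in (pa, pb):
                mut = rng.random(child.shape) < cfg.mutation_rate
                if mut.any():
                    repl = np.where(
                        rng.random(int(mut.sum())) < 0.5,
                        rng.choice(top_pool, size=int(mut.sum())),
                        rng.integers(0, n_cand, size=int(mut.sum())),
                    )
                    child[mut] = repl
                children.append(
                    _repair(child, n_cand, n_crosses, eff_parents, usage_cap, rng,
                            spread_to=min_parents)
                )
        pop = elite + children[: cfg.pop_size - cfg.elitism]
        obj = np.array([plan_objective(p, F) for p in pop])

    best = pop[int(np.argmax(obj))]
    ids = fitness.candidate_ids
    crosses = [(ids[int(a)], ids[int(b)]) for a, b in best]
    parent_set = list(dict.fromkeys([p for pair in crosses for p in pair]))
    return CrossPlan(crosses, parent_set)


def random_cross_plan(
    parent_ids, n_crosses: int, rng: np.random.Generator
) -> CrossPlan:
    """n_crosses distinct unordered pairs drawn uniformly among the parents."""
    ids = list(parent_ids)
    n = len(ids)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if n_crosses > len(all_pairs):
        raise ValueError("not enough distinct pairs among the parents")
    picks = rng.choice(len(all_pairs), size=n_crosses, replace=False)
    crosses = [(ids[all_pairs[k][0]], ids[all_pairs[k][1]]) for k in picks]
    parent_set = list(dict.fromkeys([p for pair in crosses for p in pair]))
    return CrossPlan(crosses, parent_set)


def select_parents(
    strategy: StrategyConfig,
    gebv_table,
    grm: GRMatrix | None,
    candidate_ids,
    rng: np.random.Generator,
):
    """Dispatch the four strategies; returns (selected ids, CrossPlan).

    ``gebv_table`` is a DataFrame with columns GY and OL indexed like
    ``candidate_ids``.  Truncation/index strategies pick exactly n_parents
    and cross them at random; the Rel strategy returns the (<= n_parents)
    parent set and cross plan found jointly by the GA.
    """
    ids = list(candidate_ids)
    gy = gebv_table["GY"].to_numpy()
    ol = gebv_table["OL"].to_numpy()
    s = strategy.strategy
    if s == "GY" or s == "OL":
        selected = select_truncation(gy if s == "GY" else ol, ids, strategy.n_parents)
    elif s == "GY_plus_OL":
        idx = build_index(gy, ol, strategy.index_weights)
        selected = select_truncation(idx, ids, strategy.n_parents)
    elif s == "random":
        selected = [ids[i] for i in rng.choice(len(ids), strategy.n_parents, replace=False)]
    elif s == "GY_plus_OL_Rel":
        if grm is None:
            raise ValueError("the Rel strategy requires a GRM over the candidates")
        idx = build_index(gy, ol, strategy.index_weights)
        fit = build_fitness_matrix(idx, grm, strategy.lam)
        plan = ga_optimize_crosses(
            fit, strategy.n_crosses, strategy.n_parents, strategy.ga,
            usage_cap=strategy.usage_cap, rng=rng,
            min_parents=strategy.n_parents,
        )
        return plan.parent_set, plan
    else:  # pragma: no cover - guarded by StrategyConfig
        raise ValueError(f"unknown strategy {s!r}")
    plan = random_cross_plan(selected, strategy.n_crosses, rng)
    return selected, plan
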