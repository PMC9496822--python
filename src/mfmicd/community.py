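"""Memetic immunogenetic community detection (MFMICD).

The detector maximizes modularity Q in two stages.  The global stage is a
genetic algorithm over community-label chromosomes with

* ID-passing initialization (every node copies a random neighbor's id),
* fitness calibration ``Fit = Q - min(Q)`` so roulette selection sees
  non-negative weights,
* dynamic crossover/mutation rates driven by the population's convergence
  rate ``phi = f_avg / (f_max - f_min)`` through the power law
  ``pm = 1/(phi + 1)``, ``pc = 1 - pm``,
* "Strongest First" pairing with circular two-cut crossover,
* neighbor-constrained mutation, and
* an immune operator that extracts the labels of high-degree nodes from the
  current best member as a vaccine, injects it into a random subset of the
  population, and keeps only non-degrading results.

The local stage refines the best chromosome by tabu search over single-node
moves, scoring candidates with a penalized objective
``F = Q - lambda * (#internally disconnected communities)`` and allowing
tabu moves only when they beat the best F seen (aspiration).

All randomness flows through one ``numpy.random.Generator`` seeded from
``GAParams.seed``, so a run is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .metrics import modularity, modularity_from_labels, pairwise_stability
from .network import BinaryNetwork, Partition

__all__ = [
    "Chromosome",
    "Population",
    "GAParams",
    "DivisionResult",
    "initialize_population",
    "decode_partition",
    "calibrated_fitness",
    "convergence_rate",
    "dynamic_rates",
    "roulette_select",
    "strongest_first_crossover",
    "mutate",
    "immune_operator",
    "tabu_local_search",
    "run_mfmicd",
    "run_mfmicd_repeated",
]

CONVERGED = math.inf  # sentinel convergence rate when f_max == f_min


@dataclass
class Chromosome:
    """Community-label string: ``labels[i]`` is node i's community label."""

    labels: np.ndarray

    def copy(self) -> "Chromosome":
        return Chromosome(self.labels.copy())


@dataclass
class Population:
    members: list[Chromosome]
    raw_q: np.ndarray  # modularity per member
    fitness: np.ndarray  # calibrated, non-negative


@dataclass(frozen=True)
class GAParams:
    """Tunables of the two-stage search.

    Defaults follow the reference configuration for 32-node functional
    brain networks: population 100, 50 global generations, 20 tabu rounds
    with tenure 10.
    """

    pop_size: int = 100
    max_gen_global: int = 50
    max_gen_tabu: int = 20
    tabu_tenure: int = 10
    runs_per_setting: int = 1
    lambda_penalty: float = 0.1
    pm_bounds: tuple[float, float] = (0.01, 0.5)
    pc_bounds: tuple[float, float] = (0.5, 0.99)
    seed: int = 0

    def __post_init__(self):
        for name in ("pop_size", "max_gen_global", "max_gen_tabu", "tabu_tenure", "runs_per_setting"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")
        for lo, hi in (self.pm_bounds, self.pc_bounds):
            if not (0.0 < lo <= hi < 1.0):
                raise InvalidParameterError("rate bounds must satisfy 0 < lo <= hi < 1")
        if self.lambda_penalty < 0:
            raise InvalidParameterError("lambda_penalty must be non-negative")


@dataclass(frozen=True)
class DivisionResult:
    """Outcome of one detection run (plus optional restart stability)."""

    best_partition: Partition
    best_q: float
    trace: list[dict]  # per generation: best_q, mean_q, pc, pm
    stability_nmi: float | None
    seed: int


def initialize_population(
    network: BinaryNetwork, pop_size: int, rng: np.random.Generator
) -> Population:
    """ID-passing initialization.

    Each chromosome starts as the identity labeling (node i -> label i);
    every node then adopts the id of one uniformly chosen graph neighbor.
    Isolated nodes keep their own id.  Labels therefore never leave a
    node's connected component.
    """
    if pop_size < 2:
        raise InvalidParameterError("pop_size must be at least 2")
    adj = network.adjacency_lists()
    n = network.n_nodes
    members = []
    for _ in range(pop_size):
        labels = np.arange(n, dtype=np.int64)
        new = labels.copy()
        for i in range(n):
            if adj[i]:
                new[i] = adj[i][rng.integers(len(adj[i]))]
        members.append(Chromosome(new))
    return Population(members=members, raw_q=np.zeros(pop_size), fitness=np.zeros(pop_size))


def decode_partition(chrom: Chromosome) -> Partition:
    """Nodes sharing a label form a group; groups numbered by smallest member."""
    return Partition.from_labels(chrom.labels)


def calibrated_fitness(raw_q: np.ndarray) -> np.ndarray:
    """Shift raw modularity to non-negative fitness: ``Fit = Q - min(Q)``.

    A fully converged population yields all-zero fitness; selection then
    falls back to uniform probabilities.
    """
    raw_q = np.asarray(raw_q, dtype=float)
    if raw_q.size == 0:
        raise InvalidInputError("empty objective vector")
    if not np.all(np.isfinite(raw_q)):
        raise InvalidInputError("objective values must be finite")
    return raw_q - raw_q.min()


def convergence_rate(fitness_stats: tuple[float, float, float]) -> float:
    """``phi = f_avg / (f_max - f_min)``; +inf when the population converged."""
    f_avg, f_max, f_min = fitness_stats
    if f_max < f_min:
        raise InvalidInputError("f_max must be >= f_min")
    if f_max == f_min:
        return CONVERGED
    return f_avg / (f_max - f_min)


def dynamic_rates(phi: float, params: GAParams) -> tuple[float, float]:
    """Map convergence rate to (pc, pm) via ``pm = 1/(phi+1)``, ``pc = 1-pm``.

    Early on phi is small, so mutation is high (population diversity);
    as the population converges phi grows and mutation shrinks toward its
    lower bound.  Both rates are clamped to their configured bounds.
    """
    pm_lo, pm_hi = params.pm_bounds
    pc_lo, pc_hi = params.pc_bounds
    pm = pm_lo if math.isinf(phi) else 1.0 / (phi + 1.0)
    pm = min(max(pm, pm_lo), pm_hi)
    pc = min(max(1.0 - pm, pc_lo), pc_hi)
    return pc, pm


def roulette_select(fitness: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional sampling of member indices (with replacement)."""
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness < 0):
        raise InvalidInputError("fitness must be non-negative")
    total = fitness.sum()
    if total == 0:
        probs = np.full(fitness.size, 1.0 / fitness.size)
    else:
        probs = fitness / total
    return rng.choice(fitness.size, size=n_draws, p=probs)


def _circular_segment(n: int, c1: int, c2: int) -> np.ndarray:
    """Positions [c1, c2) walking forward with wrap-around; empty if c1 == c2."""
    length = (c2 - c1) % n
    return (c1 + np.arange(length)) % n


def strongest_first_crossover(
    pop: Population, pc: float, rng: np.random.Generator
) -> list[Chromosome]:
    """Pair members in descending-fitness order and apply circular crossover.

    The fittest mates with the second fittest, the third with the fourth,
    and so on (fitness ties broken by member index).  Each pair crosses
    with probability ``pc``: two cut points are drawn and the circular
    segment between them (which may wrap past the end of the string) is
    swapped between the parents.  Non-crossing pairs copy through; an odd
    trailing member is copied unchanged.
    """
    order = sorted(range(len(pop.members)), key=lambda i: (-pop.fitness[i], i))
    n = pop.members[0].labels.size if pop.members else 0
    offspring: list[Chromosome] = []
    for a_pos in range(0, len(order) - 1, 2):
        pa = pop.members[order[a_pos]].labels
        pb = pop.members[order[a_pos + 1]].labels
        if rng.random() < pc and n > 0:
            c1 = int(rng.integers(n))
            c2 = int(rng.integers(n))
            seg = _circular_segment(n, c1, c2)
            ca, cb = pa.copy(), pb.copy()
            ca[seg] = pb[seg]
            cb[seg] = pa[seg]
            offspring.append(Chromosome(ca))
            offspring.append(Chromosome(cb))
        else:
            offspring.append(Chromosome(pa.copy()))
            offspring.append(Chromosome(pb.copy()))
    if len(order) % 2 == 1:
        offspring.append(pop.members[order[-1]].copy())
    return offspring


def mutate(
    chrom: Chromosome, pm: float, network: BinaryNetwork, rng: np.random.Generator
) -> Chromosome:
    """Neighbor-constrained mutation.

    Each locus independently, with probability ``pm``, takes the current
    label of a uniformly chosen graph neighbor (labels read from the
    pre-mutation chromosome).  Isolated nodes never change.
    """
    if not (0.0 <= pm <= 1.0):
        raise InvalidParameterError("pm must lie in [0, 1]")
    adj = network.adjacency_lists()
    old = chrom.labels
    new = old.copy()
    hits = np.nonzero(rng.random(old.size) < pm)[0]
    for i in hits:
        if adj[i]:
            new[i] = old[adj[i][rng.integers(len(adj[i]))]]
    return Chromosome(new)


def _eval_q(labels: np.ndarray, ctx: tuple) -> float:
    u, v, deg, m = ctx
    return modularity_from_labels(labels, u, v, deg, m)


def immune_operator(
    pop: Population, network: BinaryNetwork, rng: np.random.Generator
) -> Population:
    """Vaccination + immune selection.

    The vaccine is the set of (node, label) assignments of the
    top-decile-degree nodes in the current best member.  It is injected
    into a random 20% of the non-best members; each vaccinated member is
    kept only if its modularity does not decrease, otherwise it reverts.
    The best member itself is never touched, so the population's best Q
    cannot drop.
    """
    u, v = network.edge_arrays()
    ctx = (u, v, network.degrees(), network.n_edges)
    best_idx = int(np.argmax(pop.raw_q))
    deg = network.degrees()
    n = network.n_nodes
    n_vac_nodes = max(1, math.ceil(n / 10))
    # highest-degree nodes, ties by node index
    vaccine_nodes = np.argsort(-deg, kind="stable")[:n_vac_nodes]
    vaccine_labels = pop.members[best_idx].labels[vaccine_nodes]

    others = [i for i in range(len(pop.members)) if i != best_idx]
    n_inject = max(1, math.ceil(0.2 * len(others))) if others else 0
    targets = rng.choice(len(others), size=n_inject, replace=False) if n_inject else []
    new_members = [m.copy() for m in pop.members]
    new_q = pop.raw_q.copy()
    for t in targets:
        i = others[int(t)]
        trial = new_members[i].labels.copy()
        trial[vaccine_nodes] = vaccine_labels
        q_trial = _eval_q(trial, ctx)
        if q_trial >= pop.raw_q[i]:
            new_members[i] = Chromosome(trial)
            new_q[i] = q_trial
    return Population(members=new_members, raw_q=new_q, fitness=calibrated_fitness(new_q))


# ---------------------------------------------------------------------------
# tabu local search


def _disconnected_communities(labels: np.ndarray, adj: list[list[int]]) -> int:
    """Count communities whose induced subgraph is not connected."""
    groups: dict[int, list[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(node)
    bad = 0
    for members in groups.values():
        if len(members) == 1:
            continue
        member_set = set(members)
        seen = {members[0]}
        stack = [members[0]]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y in member_set and y not in seen:
                    seen.add(y)
                    stack.append(y)
        if len(seen) != len(members):
            bad += 1
    return bad


def tabu_local_search(
    network: BinaryNetwork, start: Partition, params: GAParams
) -> Partition:
    """Refine a partition by tabu search over single-node moves.

    The neighborhood of the current labeling is every move of one node to
    a community that contains at least one of its graph neighbors, plus a
    split of the node into a fresh singleton.  Candidates are scored with
    ``F = Q - lambda * (#disconnected communities)``; the best admissible
    move is taken each round even if it worsens F (that is what lets the
    search leave local optima).  Reassigning a node back to a recently
    abandoned label is tabu for ``tabu_tenure`` rounds, unless doing so
    beats the best F found so far (aspiration).  Returns the best-scoring
    labeling encountered, which is never worse in Q than a feasible start.
    """
    if start.n_nodes != network.n_nodes:
        raise InvalidInputError("partition does not match network")
    u, v = network.edge_arrays()
    deg = network.degrees()
    m = network.n_edges
    adj = network.adjacency_lists()
    n = network.n_nodes

    labels = start.labels().copy()

    def score(lab: np.ndarray) -> float:
        q = modularity_from_labels(lab, u, v, deg, m)
        pen = _disconnected_communities(lab, adj)
        return q - params.lambda_penalty * pen

    best_labels = labels.copy()
    best_f = score(labels)
    cur_f = best_f
    tabu_until: dict[tuple[int, int], int] = {}

    for rnd in range(params.max_gen_tabu):
        best_move = None  # (f, node, new_label)
        for i in range(n):
            own = int(labels[i])
            cand_labels = {int(labels[j]) for j in adj[i]} - {own}
            # split to fresh singleton, unless already a singleton
            if int(np.count_nonzero(labels == own)) > 1:
                cand_labels.add(int(labels.max()) + 1)
            for new_lab in sorted(cand_labels):
                labels[i] = new_lab
                f = score(labels)
                labels[i] = own
                is_tabu = tabu_until.get((i, new_lab), -1) >= rnd
                if is_tabu and f <= best_f:
                    continue
                key = (f, -i, -new_lab)
                if best_move is None or key > best_move[0]:
                    best_move = (key, i, new_lab, f)
        if best_move is None:
            break
        _, i, new_lab, f = best_move
        tabu_until[(i, int(labels[i]))] = rnd + params.tabu_tenure
        labels[i] = new_lab
        cur_f = f
        if f > best_f:
            best_f = f
            best_labels = labels.copy()
    return Partition.from_labels(best_labels)


# ---------------------------------------------------------------------------
# full loop


def run_mfmicd(network: BinaryNetwork, params: GAParams | None = None) -> DivisionResult:
    """Run the full two-stage detection on a binary network.

    Global immunogenetic search for ``max_gen_global`` generations with
    elitist (mu+lambda) survivor replacement, then tabu refinement of the
    global best.  Fully reproducible from ``params.seed``.
    """
    params = params or GAParams()
    if network.n_nodes < 1:
        raise InvalidInputError("network must be nonempty")
    rng = np.random.default_rng(params.seed)
    u, v = network.edge_arrays()
    ctx = (u, v, network.degrees(), network.n_edges)

    pop = initialize_population(network, params.pop_size, rng)
    pop.raw_q = np.array([_eval_q(c.labels, ctx) for c in pop.members])
    pop.fitness = calibrated_fitness(pop.raw_q)

    trace: list[dict] = []
    for _gen in range(params.max_gen_global):
        phi = convergence_rate(
            (float(pop.fitness.mean()), float(pop.fitness.max()), float(pop.fitness.min()))
        )
        pc, pm = dynamic_rates(phi, params)

        parent_idx = roulette_select(pop.fitness, len(pop.members), rng)
        parents = Population(
            members=[pop.members[i] for i in parent_idx],
            raw_q=pop.raw_q[parent_idx],
            fitness=pop.fitness[parent_idx],
        )
        offspring = strongest_first_crossover(parents, pc, rng)
        offspring = [mutate(c, pm, network, rng) for c in offspring]
        off_q = np.array([_eval_q(c.labels, ctx) for c in offspring])
        off_pop = Population(
            members=offspring, raw_q=off_q, fitness=calibrated_fitness(off_q)
        )
        off_pop = immune_operator(off_pop, network, rng)

        # elitist (mu+lambda) replacement: best of parents ∪ offspring survive
        all_members = pop.members + off_pop.members
        all_q = np.concatenate([pop.raw_q, off_pop.raw_q])
        keep = np.argsort(-all_q, kind="stable")[: params.pop_size]
        pop = Population(
            members=[all_members[i] for i in keep],
            raw_q=all_q[keep],
            fitness=calibrated_fitness(all_q[keep]),
        )
        trace.append(
            {
                "generation": _gen,
                "best_q": float(pop.raw_q.max()),
                "mean_q": float(pop.raw_q.mean()),
                "pc": pc,
                "pm": pm,
            }
        )

    best_idx = int(np.argmax(pop.raw_q))
    best_part = decode_partition(pop.members[best_idx])
    refined = tabu_local_search(network, best_part, params)
    best_q = modularity(network, refined)
    return DivisionResult(
        best_partition=refined,
        best_q=best_q,
        trace=trace,
        stability_nmi=None,
        seed=params.seed,
    )


def run_mfmicd_repeated(
    network: BinaryNetwork, params: GAParams | None = None
) -> DivisionResult:
    """Independent restarts; returns the best run with cross-run stability.

    Runs the detector ``runs_per_setting`` times with seeds derived from
    ``params.seed``, keeps the highest-Q result, and (when more than one
    run was made) attaches the mean pairwise NMI across the runs' final
    partitions as ``stability_nmi``.
    """
    params = params or GAParams()
    n_runs = params.runs_per_setting
    results = [
        run_mfmicd(network, replace(params, seed=(params.seed + 9973 * r) % (2**31 - 1), runs_per_setting=1))
        for r in range(n_runs)
    ]
    best = max(results, key=lambda r: r.best_q)
    stability = (
        pairwise_stability([r.best_partition for r in results]) if n_runs > 1 else None
    )
    return replace(best, stability_nmi=stability, seed=params.seed)
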