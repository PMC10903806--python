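"""Genetic-algorithm layer: fitness, selection, mutation, lineages, cloning.

Fitness of an individual is the number of distinct cell types present in its
terminal expression pattern, where a cell type is the ON/OFF combination of
the four marker genes (up to 2**4 = 16 types).  Selection is
fitness-proportional through a softmax, ``p_i = exp(f_i) / sum_j exp(f_j)``,
which amplifies the advantage of a single extra cell type.  Mutation
resamples four entries of the interaction matrix and adds small Gaussian
noise to every continuous parameter.  The two-stage "population cloning"
protocol restarts evolution from a stored ancestral population with fresh
random numbers, producing species diverged from a common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .model import Genome, SimulationParams, develop_population

__all__ = [
    "EvolutionParams",
    "GenerationSnapshot",
    "Lineage",
    "call_cell_types",
    "fitness",
    "selection_probabilities",
    "random_genome",
    "mutate",
    "evolve",
    "clone_and_rerun",
    "UNDEFINED_CELL_TYPE",
]

#: Code assigned to cells whose marker states are not all decided.
UNDEFINED_CELL_TYPE = -1

#: Lower bound kept on gamma after mutation (a gene's timescale stays finite).
GAMMA_FLOOR = 1e-4

# Priors for freshly generated random genomes.  The interaction probabilities
# are part of the study conditions; the continuous priors are package
# defaults (documented in docs/methods.md) chosen so that dt*(gamma + 2 D)
# stays within the explicit-Euler contraction bound.
J_PRIOR_PROBS = {1: 1 / 16, 0: 7 / 8, -1: 1 / 16}
GAMMA_PRIOR = (0.05, 1.0)
THETA_PRIOR = (-1.0, 1.0)
DIFFUSION_PRIOR = (0.0, 0.2)


@dataclass(frozen=True)
class EvolutionParams:
    """Genetic-algorithm parameters.

    ``j_mutation_probs`` is the (to +1, to -1, to 0) resampling distribution
    applied independently to each of ``n_j_mutation_sites`` randomly chosen
    interaction-matrix positions per offspring.  ``param_mutation_sd`` is the
    s.d. of the Gaussian perturbation added to every continuous parameter.
    ``fitness_accept_min`` is the threshold on the fittest individual of the
    final generation above which a run counts as "fit" for downstream
    analysis.
    """

    pop_size: int = 100
    n_generations: int = 1000
    n_j_mutation_sites: int = 4
    j_mutation_probs: tuple[float, float, float] = (1 / 8, 1 / 8, 3 / 4)
    param_mutation_sd: float = 0.01
    fitness_accept_min: int = 15
    #: lower bound kept on gamma under mutation; scaled-down studies with a
    #: shorter developmental window raise it so the slowest mutable
    #: timescale keeps the same fraction of the window
    gamma_floor: float = GAMMA_FLOOR

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "j_mutation_probs", tuple(self.j_mutation_probs)
        )
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if abs(sum(self.j_mutation_probs) - 1.0) > 1e-12:
            raise ValueError("j_mutation_probs must sum to 1")
        if self.n_j_mutation_sites < 0:
            raise ValueError("n_j_mutation_sites must be non-negative")


@dataclass(eq=False)
class GenerationSnapshot:
    """Recorded state of one generation of a lineage.

    ``deltas[k]`` is the initial-condition perturbation under which
    individual ``k``'s fitness was evaluated, so any recorded fitness can be
    replayed exactly.  ``parents[k]`` indexes individual ``k``'s parent in
    the previous generation (-1 in generation 0).
    """

    genomes: list[Genome]
    fitness: np.ndarray
    parents: np.ndarray
    deltas: np.ndarray


@dataclass(eq=False)
class Lineage:
    """Per-generation record of an evolutionary run.

    ``snapshots[g]`` holds generation ``g``; there are
    ``n_generations + 1`` snapshots.  A lineage produced by
    :func:`clone_and_rerun` carries ``branch_generation`` and shares all
    snapshots up to the branch with its parent.
    """

    sim_params: SimulationParams
    evo_params: EvolutionParams
    seed: Optional[int]
    snapshots: list[GenerationSnapshot] = field(default_factory=list)
    branch_generation: Optional[int] = None
    parent_seed: Optional[int] = None

    @property
    def n_generations(self) -> int:
        return len(self.snapshots) - 1

    def max_fitness(self, generation: int = -1) -> int:
        return int(self.snapshots[generation].fitness.max())

    def mean_fitness(self, generation: int = -1) -> float:
        return float(self.snapshots[generation].fitness.mean())

    @property
    def is_fit(self) -> bool:
        """Whether the fittest final individual clears the acceptance bar."""
        return self.max_fitness() >= self.evo_params.fitness_accept_min

    def representative(self, generation: int = -1) -> tuple[Genome, int]:
        """Fittest individual of a generation (ties -> lowest index)."""
        snap = self.snapshots[generation]
        k = int(np.argmax(snap.fitness))
        return snap.genomes[k], k

    def top_individuals(self, m: int, generation: int = -1) -> list[Genome]:
        """The ``m`` fittest individuals of a generation (stable order)."""
        snap = self.snapshots[generation]
        order = np.argsort(-snap.fitness, kind="stable")[:m]
        return [snap.genomes[int(k)] for k in order]


def call_cell_types(
    terminal_field: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Per-cell 4-bit cell-type codes from the terminal marker pattern.

    A marker gene is ON in a cell if its expression exceeds
    ``on_threshold`` (0.99) and OFF below ``off_threshold`` (0.01); the
    lowest-index marker is the most significant bit.  A cell with any
    undecided marker gets :data:`UNDEFINED_CELL_TYPE` and contributes no
    type.
    """
    terminal_field = np.asarray(terminal_field, dtype=float)
    markers = terminal_field[list(params.marker_indices)]
    on = markers > params.on_threshold
    off = markers < params.off_threshold
    defined = (on | off).all(axis=0)
    n_mark = len(params.marker_indices)
    weights = 1 << np.arange(n_mark - 1, -1, -1)
    codes = weights @ on.astype(int)
    codes = np.where(defined, codes, UNDEFINED_CELL_TYPE)
    return codes.astype(int)


def fitness(terminal_field: np.ndarray, params: SimulationParams) -> int:
    """Number of distinct defined cell types in the terminal pattern."""
    codes = call_cell_types(terminal_field, params)
    return int(len(set(codes[codes != UNDEFINED_CELL_TYPE].tolist())))


def selection_probabilities(fitnesses: Sequence[float]) -> np.ndarray:
    """Softmax selection probabilities ``exp(f_i) / sum_j exp(f_j)``.

    Computed shift-stably; strictly increasing in fitness, summing to 1.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("empty population")
    if not np.isfinite(f).all():
        raise ValueError("fitnesses must be finite")
    z = np.exp(f - f.max())
    return z / z.sum()


def random_genome(
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    gamma_range: tuple[float, float] = GAMMA_PRIOR,
    theta_range: tuple[float, float] = THETA_PRIOR,
    diffusion_range: tuple[float, float] = DIFFUSION_PRIOR,
) -> Genome:
    """Random genome per the stated interaction-density prior.

    Interaction entries are i.i.d. with P(+1) = P(-1) = 1/16 and
    P(0) = 7/8 (expected density N/8 connections per gene); morphogen rows
    are zeroed since their expression is clamped.  Continuous parameters are
    drawn from the documented uniform priors; scaled-down studies that
    shorten the developmental window should raise the gamma floor in
    proportion so the slowest prior timescale keeps the same fraction of
    the window.
    """
    N = params.n_genes
    vals = np.array([1, 0, -1], dtype=np.int8)
    probs = [J_PRIOR_PROBS[1], J_PRIOR_PROBS[0], J_PRIOR_PROBS[-1]]
    J = rng.choice(vals, size=(N, N), p=probs)
    J[list(params.morphogen_indices), :] = 0
    genome = Genome(
        interactions=J,
        gamma=rng.uniform(*gamma_range, size=N),
        theta=rng.uniform(*theta_range, size=N),
        diffusion=rng.uniform(*diffusion_range, size=N),
        x_init=rng.uniform(0.0, 1.0, size=N),
    )
    genome.validate()
    return genome


def mutate(
    genome: Genome,
    sim_params: SimulationParams,
    evo_params: EvolutionParams,
    rng: np.random.Generator,
) -> Genome:
    """One offspring genome.

    Four distinct interaction-matrix positions (rows restricted to
    non-morphogen genes, whose expression is actually dynamic) are each
    independently resampled to +1 / -1 / 0 with the configured
    probabilities; Gaussian(0, sd) noise is added to every gamma, theta,
    diffusion and x_init entry, after which gamma is floored at 1e-4,
    diffusion at 0, and x_init clipped to [0, 1].
    """
    N = genome.n_genes
    out = genome.copy()
    rows = sim_params.non_morphogen_indices
    n_sites = min(evo_params.n_j_mutation_sites, rows.size * N)
    if n_sites > 0:
        flat = rng.choice(rows.size * N, size=n_sites, replace=False)
        p_plus, p_minus, p_zero = evo_params.j_mutation_probs
        new_vals = rng.choice(
            np.array([1, -1, 0], dtype=np.int8),
            size=n_sites,
            p=[p_plus, p_minus, p_zero],
        )
        out.interactions[rows[flat // N], flat % N] = new_vals
    sd = evo_params.param_mutation_sd
    if sd > 0:
        out.gamma = out.gamma + rng.normal(0.0, sd, size=N)
        out.theta = out.theta + rng.normal(0.0, sd, size=N)
        out.diffusion = out.diffusion + rng.normal(0.0, sd, size=N)
        out.x_init = out.x_init + rng.normal(0.0, sd, size=N)
    np.maximum(out.gamma, evo_params.gamma_floor, out=out.gamma)
    np.maximum(out.diffusion, 0.0, out=out.diffusion)
    np.clip(out.x_init, 0.0, 1.0, out=out.x_init)
    return out


def _as_rng(
    rng_or_seed: Union[int, np.random.Generator, None]
) -> tuple[np.random.Generator, Optional[int]]:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed, None
    return np.random.default_rng(rng_or_seed), rng_or_seed


def _draw_deltas(
    rng: np.random.Generator, P: int, params: SimulationParams
) -> np.ndarray:
    deltas = rng.normal(0.0, params.init_noise_sd, size=(P, params.n_genes))
    deltas[:, list(params.morphogen_indices)] = 0.0
    return deltas


def evolve(
    initial_population: Sequence[Genome],
    sim_params: SimulationParams,
    evo_params: EvolutionParams,
    rng_or_seed: Union[int, np.random.Generator, None] = None,
    *,
    n_generations: Optional[int] = None,
    on_generation: Optional[Callable[[int, np.ndarray], None]] = None,
) -> Lineage:
    """Run the genetic algorithm and record the full lineage.

    Per generation every individual is developed under a fresh
    initial-condition perturbation, fitness is recorded, parents are drawn
    with replacement from the softmax selection probabilities, and each
    offspring is mutated.  ``on_generation(g, fitness)`` is invoked after
    each generation's evaluation (for progress logging).
    """
    rng, seed = _as_rng(rng_or_seed)
    G = evo_params.n_generations if n_generations is None else n_generations
    P = len(initial_population)
    if P < 1:
        raise ValueError("population must be non-empty")
    lineage = Lineage(sim_params, evo_params, seed)
    pop = [g.copy() for g in initial_population]
    parents = np.full(P, -1, dtype=int)
    for g in range(G + 1):
        deltas = _draw_deltas(rng, P, sim_params)
        try:
            terminal = develop_population(pop, sim_params, deltas)
        except FloatingPointError as err:
            raise FloatingPointError(f"generation {g}: {err}") from err
        fits = np.array(
            [fitness(terminal[k], sim_params) for k in range(P)], dtype=int
        )
        lineage.snapshots.append(
            GenerationSnapshot([gm.copy() for gm in pop], fits, parents, deltas)
        )
        if on_generation is not None:
            on_generation(g, fits)
        if g == G:
            break
        probs = selection_probabilities(fits)
        parents = rng.choice(P, size=P, p=probs)
        pop = [
            mutate(pop[int(p)], sim_params, evo_params, rng) for p in parents
        ]
    return lineage


def clone_and_rerun(
    lineage: Lineage,
    branch_generation: int,
    rng_or_seed: Union[int, np.random.Generator, None],
    *,
    n_extra_generations: Optional[int] = None,
) -> Lineage:
    """Restart evolution from a stored ancestral population.

    The cloned lineage shares all snapshots up to ``branch_generation`` with
    its parent and then evolves for ``n_extra_generations`` (default:
    enough to match the parent's total length) under a fresh random-number
    stream, yielding a species diverged from the common ancestor.
    """
    if not 0 <= branch_generation <= lineage.n_generations:
        raise LookupError(
            f"no snapshot at generation {branch_generation} "
            f"(lineage has {lineage.n_generations})"
        )
    rng, seed = _as_rng(rng_or_seed)
    if n_extra_generations is None:
        n_extra_generations = lineage.n_generations - branch_generation
    branch_pop = lineage.snapshots[branch_generation].genomes
    rerun = evolve(
        branch_pop,
        lineage.sim_params,
        lineage.evo_params,
        rng,
        n_generations=n_extra_generations,
    )
    out = Lineage(
        lineage.sim_params,
        lineage.evo_params,
        seed,
        snapshots=[
            GenerationSnapshot(
                [gm.copy() for gm in s.genomes],
                s.fitness.copy(),
                s.parents.copy(),
                s.deltas.copy(),
            )
            for s in lineage.snapshots[:branch_generation]
        ]
        + rerun.snapshots,
        branch_generation=branch_generation,
        parent_seed=lineage.seed,
    )
    return out
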