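"""Configuration, serialization, fixtures and the experiment orchestrator.

The top-level workflow mirrors the two-stage evolutionary protocol: evolve a
root lineage under the cell-type-count fitness, clone ancestral populations
at scheduled branch generations and re-evolve them into diverged species,
then measure branch-depth similarity curves, bottleneck statistics,
pleiotropy and clone-variance profiles, and classify each replicate as
hourglass-positive or not.

File formats are deliberately plain: genomes and reports as JSON, lineages
as a directory of JSON snapshots plus a fitness CSV, trajectories as NPZ,
configs as YAML mirroring the standard parameter names (N, L, beta, P,
t_term, G_term, sigma).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from .evolution import (
    EvolutionParams,
    GenerationSnapshot,
    Lineage,
    clone_and_rerun,
    evolve,
    random_genome,
)
from .model import Genome, SimulationParams, Trajectory, develop

__all__ = [
    "ExperimentConfig",
    "desk_scale_config",
    "run_hourglass_experiment",
    "make_fixture",
    "FixtureBundle",
    "genome_to_dict",
    "genome_from_dict",
    "save_genome",
    "load_genome",
    "save_trajectory",
    "load_trajectory",
    "save_lineage",
    "load_lineage",
    "load_config",
    "save_config",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

logger = logging.getLogger("devhourglass")

# YAML keys follow the conventional parameter names of the model.
_SIM_KEYS = {
    "N": "n_genes",
    "L": "n_cells",
    "beta": "beta",
    "dt": "dt",
    "t_term": "n_steps",
    "sigma": "init_noise_sd",
    "morphogen_indices": "morphogen_indices",
    "marker_indices": "marker_indices",
    "on_threshold": "on_threshold",
    "off_threshold": "off_threshold",
}
_EVO_KEYS = {
    "P": "pop_size",
    "G_term": "n_generations",
    "n_J_mutation_sites": "n_j_mutation_sites",
    "J_mutation_probs": "j_mutation_probs",
    "param_mutation_sd": "param_mutation_sd",
    "fitness_accept_min": "fitness_accept_min",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of a branch-and-compare hourglass experiment."""

    sim: SimulationParams = field(default_factory=SimulationParams)
    evo: EvolutionParams = field(default_factory=EvolutionParams)
    n_replicates: int = 1
    branch_every: int = 100
    branch_generations: Optional[tuple[int, ...]] = None
    clones_per_branch: int = 1
    n_compare_individuals: int = 3
    n_variance_clones: int = 100
    variance_noise_sd: float = 0.01
    similarity_indicator: str = "delta"
    analyze_rejected: bool = False
    gamma_prior: tuple[float, float] = (0.05, 1.0)

    def __post_init__(self) -> None:
        if self.branch_generations is not None:
            object.__setattr__(
                self, "branch_generations", tuple(self.branch_generations)
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.branch_every <= self.evo.n_generations:
            raise ValueError("branch_every must lie in (0, G_term]")
        for g in self.branch_schedule:
            if not 0 <= g <= self.evo.n_generations:
                raise ValueError(f"branch generation {g} outside [0, G_term]")

    @property
    def branch_schedule(self) -> list[int]:
        """Branch generations: explicit list if given, otherwise every
        ``branch_every``-th generation."""
        if self.branch_generations is not None:
            return sorted(self.branch_generations)
        return list(
            range(self.branch_every, self.evo.n_generations, self.branch_every)
        )


def desk_scale_config(
    *,
    n_replicates: int = 1,
    init_noise_sd: float = 0.316,
    analyze_rejected: bool = False,
) -> ExperimentConfig:
    """Scaled-down study conditions for a single workstation.

    A 16-gene, 32-cell model developed for 400 steps, evolved for 650
    generations in populations of 50, with species cloned 150-300
    generations before the end — ancestors are taken after the fitness
    plateau, as in the full-scale protocol, and the divergence depths span
    the range where interior similarity peaks are most prominent.  The
    developmental window is 2.5x shorter than at full scale, so the gamma
    prior floor is raised in proportion (0.05 -> 0.125) to keep the slowest
    prior timescale at 1/5 of the window, and the cell-type acceptance bar
    is set to 6 of 16, the level that pilot evolutions at this lattice size
    reliably exceed (the 32-cell lattice saturates around 8-9 types).
    ``init_noise_sd`` defaults to sqrt(0.1): the epigenetic perturbation
    with variance 0.1.
    """
    return ExperimentConfig(
        sim=SimulationParams(
            n_genes=16,
            n_cells=32,
            n_steps=400,
            init_noise_sd=init_noise_sd,
        ),
        evo=EvolutionParams(
            pop_size=50,
            n_generations=650,
            fitness_accept_min=6,
        ),
        n_replicates=n_replicates,
        branch_every=50,
        branch_generations=(350, 400, 450, 500),
        n_compare_individuals=3,
        n_variance_clones=100,
        gamma_prior=(0.125, 1.0),
        analyze_rejected=analyze_rejected,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def genome_to_dict(genome: Genome, **metadata) -> dict:
    d = {
        "schema_version": SCHEMA_VERSION,
        "J": genome.interactions.astype(int).tolist(),
        "gamma": genome.gamma.tolist(),
        "theta": genome.theta.tolist(),
        "D": genome.diffusion.tolist(),
        "x_init": genome.x_init.tolist(),
        "N": genome.n_genes,
    }
    d.update(metadata)
    return d


def genome_from_dict(d: dict) -> Genome:
    _check_schema(d)
    g = Genome(
        interactions=np.array(d["J"], dtype=np.int8),
        gamma=np.array(d["gamma"], dtype=float),
        theta=np.array(d["theta"], dtype=float),
        diffusion=np.array(d["D"], dtype=float),
        x_init=np.array(d["x_init"], dtype=float),
    )
    g.validate()
    return g


def _check_schema(d: dict) -> None:
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {version!r}; expected {SCHEMA_VERSION}"
        )


def save_genome(genome: Genome, path: Union[str, Path], **metadata) -> None:
    Path(path).write_text(json.dumps(genome_to_dict(genome, **metadata), indent=1))


def load_genome(path: Union[str, Path]) -> Genome:
    return genome_from_dict(json.loads(Path(path).read_text()))


def save_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    np.savez_compressed(
        path,
        x=traj.values,
        dt=traj.dt,
        delta=traj.delta,
        step_stride=traj.step_stride,
        stationary=traj.stationary,
        oscillating=traj.oscillating,
        schema_version=SCHEMA_VERSION,
    )


def load_trajectory(path: Union[str, Path]) -> Trajectory:
    with np.load(path) as npz:
        _check_schema({"schema_version": int(npz["schema_version"])})
        return Trajectory(
            values=npz["x"],
            dt=float(npz["dt"]),
            delta=npz["delta"],
            step_stride=int(npz["step_stride"]),
            stationary=bool(npz["stationary"]),
            oscillating=bool(npz["oscillating"]),
        )


def _params_to_dict(sim: SimulationParams, evo: EvolutionParams) -> dict:
    out = {}
    for key, attr in _SIM_KEYS.items():
        val = getattr(sim, attr)
        out[key] = list(val) if isinstance(val, tuple) else val
    for key, attr in _EVO_KEYS.items():
        val = getattr(evo, attr)
        out[key] = list(val) if isinstance(val, tuple) else val
    return out


def _params_from_dict(d: dict) -> tuple[SimulationParams, EvolutionParams]:
    sim_kwargs = {
        attr: d[key] for key, attr in _SIM_KEYS.items() if key in d
    }
    evo_kwargs = {
        attr: d[key] for key, attr in _EVO_KEYS.items() if key in d
    }
    for name in ("morphogen_indices", "marker_indices"):
        if name in sim_kwargs:
            sim_kwargs[name] = tuple(sim_kwargs[name])
    if "j_mutation_probs" in evo_kwargs:
        evo_kwargs["j_mutation_probs"] = tuple(evo_kwargs["j_mutation_probs"])
    return SimulationParams(**sim_kwargs), EvolutionParams(**evo_kwargs)


def save_config(config: ExperimentConfig, path: Union[str, Path]) -> None:
    d = _params_to_dict(config.sim, config.evo)
    d.update(
        n_replicates=config.n_replicates,
        branch_every=config.branch_every,
        branch_generations=(
            None
            if config.branch_generations is None
            else list(config.branch_generations)
        ),
        clones_per_branch=config.clones_per_branch,
        n_compare_individuals=config.n_compare_individuals,
        n_variance_clones=config.n_variance_clones,
        variance_noise_sd=config.variance_noise_sd,
        similarity_indicator=config.similarity_indicator,
        analyze_rejected=config.analyze_rejected,
        gamma_prior=list(config.gamma_prior),
    )
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    sim, evo = _params_from_dict(d)
    extra = {
        k: d[k]
        for k in (
            "n_replicates",
            "branch_every",
            "branch_generations",
            "clones_per_branch",
            "n_compare_individuals",
            "n_variance_clones",
            "variance_noise_sd",
            "similarity_indicator",
            "analyze_rejected",
            "gamma_prior",
        )
        if k in d and d[k] is not None
    }
    if "gamma_prior" in extra:
        extra["gamma_prior"] = tuple(extra["gamma_prior"])
    return ExperimentConfig(sim=sim, evo=evo, **extra)


def save_lineage(lineage: Lineage, out_dir: Union[str, Path]) -> None:
    """One directory per run: metadata JSON, fitness CSV, snapshot JSONs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": lineage.seed,
        "branch_generation": lineage.branch_generation,
        "parent_seed": lineage.parent_seed,
        "n_generations": lineage.n_generations,
        "params": _params_to_dict(lineage.sim_params, lineage.evo_params),
    }
    (out / "lineage.json").write_text(json.dumps(meta, indent=1))
    rows = []
    for g, snap in enumerate(lineage.snapshots):
        for k in range(len(snap.genomes)):
            rows.append(
                {
                    "generation": g,
                    "individual": k,
                    "fitness": int(snap.fitness[k]),
                    "parent": int(snap.parents[k]),
                }
            )
        payload = {
            "schema_version": SCHEMA_VERSION,
            "genomes": [genome_to_dict(gm) for gm in snap.genomes],
            "deltas": snap.deltas.tolist(),
            "parents": snap.parents.tolist(),
            "fitness": snap.fitness.tolist(),
        }
        (out / f"generation_{g:05d}.json").write_text(json.dumps(payload))
    pd.DataFrame(rows).to_csv(out / "fitness.csv", index=False)


def load_lineage(in_dir: Union[str, Path]) -> Lineage:
    src = Path(in_dir)
    meta = json.loads((src / "lineage.json").read_text())
    _check_schema(meta)
    sim, evo = _params_from_dict(meta["params"])
    lineage = Lineage(
        sim,
        evo,
        meta["seed"],
        branch_generation=meta["branch_generation"],
        parent_seed=meta["parent_seed"],
    )
    for g in range(meta["n_generations"] + 1):
        payload = json.loads((src / f"generation_{g:05d}.json").read_text())
        _check_schema(payload)
        lineage.snapshots.append(
            GenerationSnapshot(
                genomes=[genome_from_dict(d) for d in payload["genomes"]],
                fitness=np.array(payload["fitness"], dtype=int),
                parents=np.array(payload["parents"], dtype=int),
                deltas=np.array(payload["deltas"], dtype=float),
            )
        )
    return lineage


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class FixtureBundle:
    """A fixture genome with its simulation parameters and, where the
    construction pins them down, expected analysis results."""

    kind: str
    genome: Genome
    sim_params: SimulationParams
    expected: dict


def make_fixture(kind: str, seed: int = 0) -> FixtureBundle:
    """Deterministic test genomes.

    ``random``: a genome from the stated interaction-density prior at small
    size.  ``chain``: a morphogen -> relay -> relay -> marker cascade with a
    decoy gene, whose essential network is the planted chain.
    ``bistable-switch``: two mutually inhibiting genes with two stable fixed
    points selected by the sign of the initial perturbation.
    ``evolved-small``: a pre-evolved small genome shipped with recorded
    fitness, bottleneck range and slow gene.
    """
    if kind == "random":
        sim = SimulationParams(
            n_genes=8, n_cells=16, n_steps=200, init_noise_sd=0.1
        )
        rng = np.random.default_rng(seed)
        return FixtureBundle("random", random_genome(sim, rng), sim, {})
    if kind == "chain":
        return _chain_fixture()
    if kind == "bistable-switch":
        return _bistable_fixture()
    if kind == "evolved-small":
        return _evolved_small_fixture()
    raise ValueError(f"unknown fixture kind {kind!r}")


def _chain_fixture() -> FixtureBundle:
    # morphogen 0 -> relay 6 (slow) -> relay 7 -> marker 5; gene 8 is a
    # decoy fed by morphogen 1 with no route to any marker.
    N = 9
    sim = SimulationParams(n_genes=N, n_cells=16, n_steps=400)
    J = np.zeros((N, N), dtype=np.int8)
    J[6, 0] = 1
    J[7, 6] = 1
    J[5, 7] = 1
    J[8, 1] = 1
    gamma = np.ones(N)
    gamma[6] = 0.1  # slow relay keeps the upstream signal moving during
    gamma[7] = 0.3  # the marker's switch period
    theta = np.full(N, 1.0)  # unused genes stay silent
    for g in (5, 6, 7, 8):
        theta[g] = 0.5
    genome = Genome(
        interactions=J,
        gamma=gamma,
        theta=theta,
        diffusion=np.zeros(N),
        x_init=np.zeros(N),
    )
    expected = {
        "essential_edges": {(0, 6), (6, 7), (7, 5)},
        "analysis_cell": 4,
        "decoy_gene": 8,
    }
    return FixtureBundle("chain", genome, sim, expected)


def _bistable_fixture() -> FixtureBundle:
    sim = SimulationParams(
        n_genes=2,
        n_cells=4,
        n_steps=600,
        morphogen_indices=(),
        marker_indices=(),
        init_noise_sd=0.1,
    )
    genome = Genome(
        interactions=np.array([[0, -1], [-1, 0]], dtype=np.int8),
        gamma=np.ones(2),
        theta=np.full(2, -0.5),
        diffusion=np.zeros(2),
        x_init=np.full(2, 0.5),
    )
    expected = {"fixed_points": [(1.0, 0.0), (0.0, 1.0)]}
    return FixtureBundle("bistable-switch", genome, sim, expected)


def _evolved_small_fixture() -> FixtureBundle:
    ref = resources.files("devhourglass") / "fixtures" / "evolved_small.json"
    d = json.loads(ref.read_text())
    _check_schema(d)
    genome = genome_from_dict(d)
    sim, _evo = _params_from_dict(d["params"])
    return FixtureBundle("evolved-small", genome, sim, d["expected"])


# ---------------------------------------------------------------------------
# experiment orchestrator
# ---------------------------------------------------------------------------

def run_hourglass_experiment(
    config: ExperimentConfig,
    seed: int,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Run the full branch-and-compare workflow and return a report.

    Per replicate: evolve a root lineage from random genomes; apply the
    fitness acceptance filter; clone the ancestral population at every
    scheduled branch generation and re-evolve; compute branch-depth
    similarity curves and bottleneck statistics; compute pleiotropy,
    clone-variance and timescale summaries for the representative
    individual; classify the replicate hourglass-positive when the
    shallowest-branch mean similarity profile has an interior peak.

    Replicate failures are recorded in the report and the run continues.
    When ``out_dir`` is given, per-replicate reports are written as JSON and
    previously completed replicates are reloaded instead of recomputed.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(config.n_replicates) >> 1]
    replicates = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for r, rep_seed in enumerate(rep_seeds):
        cache = (
            out_path / f"replicate_{r:03d}.json" if out_path is not None else None
        )
        if cache is not None and cache.exists():
            replicates.append(json.loads(cache.read_text()))
            continue
        try:
            rep = _run_replicate(config, rep_seed)
        except Exception as err:  # partial failures must not kill the run
            logger.exception("replicate %d failed", r)
            rep = {"seed": rep_seed, "failed": True, "error": repr(err)}
        rep["replicate"] = r
        replicates.append(rep)
        if cache is not None:
            cache.write_text(json.dumps(rep, indent=1))
    accepted = [r for r in replicates if r.get("accepted")]
    analyzed = [r for r in accepted if "hourglass_positive" in r]
    n_positive = sum(bool(r["hourglass_positive"]) for r in analyzed)
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "n_replicates": config.n_replicates,
        "n_accepted": len(accepted),
        "n_hourglass_positive": n_positive,
        "hourglass_positive_fraction": (
            n_positive / len(analyzed) if analyzed else None
        ),
        "branch_schedule": config.branch_schedule,
        "replicates": replicates,
    }
    if out_path is not None:
        (out_path / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _run_replicate(config: ExperimentConfig, rep_seed: int) -> dict:
    sim, evo = config.sim, config.evo
    ss = np.random.SeedSequence(rep_seed)
    rng = np.random.default_rng(ss)
    pop = [
        random_genome(sim, rng, gamma_range=config.gamma_prior)
        for _ in range(evo.pop_size)
    ]

    def log_gen(g: int, fits: np.ndarray) -> None:
        if g % 50 == 0 or g == evo.n_generations:
            logger.info(
                json.dumps(
                    {
                        "event": "generation",
                        "seed": rep_seed,
                        "generation": g,
                        "max_fitness": int(fits.max()),
                        "mean_fitness": round(float(fits.mean()), 3),
                    }
                )
            )

    root = evolve(pop, sim, evo, rng, on_generation=log_gen)
    root.seed = rep_seed
    rep: dict = {
        "seed": rep_seed,
        "max_fitness": root.max_fitness(),
        "mean_fitness": root.mean_fitness(),
        "accepted": bool(root.is_fit),
        "failed": False,
    }
    if not rep["accepted"] and not config.analyze_rejected:
        return rep

    clone_seeds = np.random.SeedSequence(rep_seed + 1).generate_state(
        len(config.branch_schedule) * config.clones_per_branch
    )
    clones = []
    k = 0
    for gen in config.branch_schedule:
        for _ in range(config.clones_per_branch):
            clone = clone_and_rerun(root, gen, int(clone_seeds[k] >> 1))
            clone.parent_seed = root.seed
            clones.append(clone)
            k += 1

    depth_sims = an.branch_depth_similarity(
        root,
        clones,
        rng,
        indicator=config.similarity_indicator,
        n_individuals=config.n_compare_individuals,
    )
    # a replicate shows the hourglass when some compared branch depth has an
    # interior similarity peak; the positive depths are the recent ones
    positive_depths = [d for d in depth_sims if d.hourglass_positive]
    rep["hourglass_positive"] = bool(positive_depths)
    best = positive_depths[-1] if positive_depths else depth_sims[-1]
    rep["bottleneck_mean"] = best.bottleneck_mean
    rep["bottleneck_sd"] = best.bottleneck_sd
    rep["depths"] = [
        {
            "branch_generation": d.branch_generation,
            "bottleneck_mean": d.bottleneck_mean,
            "bottleneck_sd": d.bottleneck_sd,
            "hourglass_positive": bool(d.hourglass_positive),
            "n_pairs": d.n_pairs,
        }
        for d in depth_sims
    ]

    rep_genome, _ = root.representative()
    traj = develop(rep_genome, sim, rng)
    rep["stationary"] = bool(traj.stationary)
    rep["oscillating"] = bool(traj.oscillating)

    stages, frac = an.pleiotropy_fraction(traj)
    rep["pleiotropy_peak_step"] = int(stages[int(np.argmax(frac))])
    rep["pleiotropy_max_fraction"] = float(frac.max())

    var = an.clone_variance(
        rep_genome,
        sim,
        config.n_variance_clones,
        rng,
        noise_sd=config.variance_noise_sd,
    )
    rep["clone_variance_argmin_step"] = var.argmin_step

    ts = an.gene_timescales(traj)
    slow = an.slow_genes(ts)
    rep["slow_genes"] = [int(g) for g in slow]
    rep["slowest_timescale_steps"] = float(ts.mean[ts.rank_order[0]])
    return rep
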