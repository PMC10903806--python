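"""Deterministic developmental dynamics on a one-dimensional cell lattice.

An individual is a row of ``L`` cells, each carrying the same gene-regulatory
network (GRN) over ``N`` genes.  Expression levels ``x_i(l, t)`` evolve by an
explicit-Euler, discrete-space reaction-diffusion update

    x_i(l) <- x_i(l) + dt * [ gamma_i * (F(i, x(l)) - x_i(l))
                              + D_i * (x_i(l+1) - 2 x_i(l) + x_i(l-1)) ]

where the synthesis term is a steep sigmoid of the summed regulatory input,

    F(i, x) = 1 / (1 + exp(-beta * (sum_j J_ij x_j - theta_i)))

with interactions ``J_ij`` restricted to {-1, 0, +1}.  Two designated
morphogen genes carry fixed, complementary linear spatial gradients that are
clamped at every step and provide positional information; zero-flux (Neumann)
boundaries are applied at both lattice ends via ghost copies of the edge
cells.  Initial conditions are spatially uniform per gene, with a heritable
level plus a single Gaussian "epigenetic" perturbation per gene shared by all
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "SimulationParams",
    "Genome",
    "Trajectory",
    "synthesis_rate",
    "morphogen_profile",
    "initial_field",
    "step",
    "develop",
    "develop_population",
    "STATIONARITY_TOL",
    "OSCILLATION_WINDOW",
]

#: Tolerance on max |dx| per step below which dynamics count as stationary.
#: Chosen well below the 0.01 margin used for calling cells ON/OFF.
STATIONARITY_TOL = 1e-6

#: Number of trailing steps inspected for sign-alternating updates.
OSCILLATION_WINDOW = 50

#: Number of trailing steps over which stationarity is assessed.
STATIONARITY_WINDOW = 10


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of a single developmental run.

    Defaults follow the full-scale study conditions: 24 genes, 128 cells,
    sigmoid sensitivity ``beta = 40`` (a very high effective Hill
    coefficient), Euler increment ``dt = 0.1``, 1000 developmental steps,
    morphogens on genes 0-1, cell-type markers on genes 2-5, and initial
    perturbation ``sigma = 0.1``.
    """

    n_genes: int = 24
    n_cells: int = 128
    beta: float = 40.0
    dt: float = 0.1
    n_steps: int = 1000
    morphogen_indices: tuple[int, ...] = (0, 1)
    marker_indices: tuple[int, ...] = (2, 3, 4, 5)
    init_noise_sd: float = 0.1
    on_threshold: float = 0.99
    off_threshold: float = 0.01

    def __post_init__(self) -> None:
        morph = tuple(self.morphogen_indices)
        mark = tuple(self.marker_indices)
        object.__setattr__(self, "morphogen_indices", morph)
        object.__setattr__(self, "marker_indices", mark)
        if self.n_genes < len(morph) + len(mark):
            raise ValueError(
                "n_genes must accommodate morphogen and marker genes"
            )
        if set(morph) & set(mark):
            raise ValueError("morphogen and marker index sets must be disjoint")
        for idx in morph + mark:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"gene index {idx} out of range")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0 <= self.off_threshold < self.on_threshold <= 1:
            raise ValueError("require 0 <= off_threshold < on_threshold <= 1")

    @property
    def non_morphogen_indices(self) -> np.ndarray:
        mask = np.ones(self.n_genes, dtype=bool)
        mask[list(self.morphogen_indices)] = False
        return np.flatnonzero(mask)


@dataclass(eq=False)
class Genome:
    """Heritable state of one species.

    ``interactions[i, j]`` is the signed regulatory effect of gene ``j`` on
    gene ``i`` (+1 activation, -1 inhibition, 0 none).  ``gamma`` sets each
    gene's reaction rate (its timescale is ``1/gamma`` in model time units),
    ``theta`` the expression threshold, ``diffusion`` the cell-to-cell
    diffusion constant of the gene product, and ``x_init`` the inherited
    spatially uniform initial expression level.
    """

    interactions: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    diffusion: np.ndarray
    x_init: np.ndarray

    def __post_init__(self) -> None:
        self.interactions = np.asarray(self.interactions, dtype=np.int8)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.diffusion = np.asarray(self.diffusion, dtype=float)
        self.x_init = np.asarray(self.x_init, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.interactions.shape[0]

    def validate(self) -> None:
        n = self.n_genes
        if self.interactions.shape != (n, n):
            raise ValueError("interaction matrix must be square")
        if not np.isin(self.interactions, (-1, 0, 1)).all():
            raise ValueError("interaction entries must be -1, 0 or +1")
        for name in ("gamma", "theta", "diffusion", "x_init"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
        if not (self.gamma > 0).all():
            raise ValueError("gamma must be positive")
        if not (self.diffusion >= 0).all():
            raise ValueError("diffusion constants must be non-negative")
        if ((self.x_init < 0) | (self.x_init > 1)).any():
            raise ValueError("x_init must lie in [0, 1]")

    def copy(self) -> "Genome":
        return Genome(
            self.interactions.copy(),
            self.gamma.copy(),
            self.theta.copy(),
            self.diffusion.copy(),
            self.x_init.copy(),
        )

    def equals(self, other: "Genome") -> bool:
        return (
            np.array_equal(self.interactions, other.interactions)
            and np.array_equal(self.gamma, other.gamma)
            and np.array_equal(self.theta, other.theta)
            and np.array_equal(self.diffusion, other.diffusion)
            and np.array_equal(self.x_init, other.x_init)
        )

    def with_gamma_scaled(self, gene_index: int, factor: float) -> "Genome":
        """Return a copy with gene ``gene_index``'s rate multiplied by
        ``factor`` (> 1 makes the gene faster, < 1 slower)."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        out = self.copy()
        out.gamma[gene_index] *= factor
        return out


@dataclass(eq=False)
class Trajectory:
    """One developmental run: a gene x cell x frame tensor plus metadata.

    ``values[:, :, k]`` is the expression field after ``k * step_stride``
    update steps (frame 0 is the initial condition).  ``delta`` records the
    per-gene initial perturbation actually applied.  Analyses that count
    individual steps (timescales, switch periods) require an unthinned run
    (``step_stride == 1``).
    """

    values: np.ndarray
    dt: float
    delta: np.ndarray
    step_stride: int = 1
    stationary: bool = False
    oscillating: bool = False
    genome: Optional[Genome] = None
    params: Optional[SimulationParams] = None
    stored_steps: Optional[np.ndarray] = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    @property
    def steps(self) -> np.ndarray:
        """Step index of every stored frame."""
        if self.stored_steps is not None:
            return self.stored_steps
        return np.arange(self.n_frames) * self.step_stride

    def frame(self, k: int) -> np.ndarray:
        return self.values[:, :, k]

    @property
    def terminal(self) -> np.ndarray:
        return self.values[:, :, -1]


def _sigmoid(z: np.ndarray | float, beta: float) -> np.ndarray | float:
    return expit(beta * np.asarray(z, dtype=float))


def synthesis_rate(
    gene_index: int,
    x_cell: np.ndarray,
    genome: Genome,
    params: SimulationParams,
) -> float:
    """Sigmoidal synthesis term F(i, x) for one gene in one cell.

    Returns ``f(sum_j J_ij x_j - theta_i)`` with
    ``f(z) = 1 / (1 + exp(-beta z))``; strictly increasing in the summed
    regulatory input.
    """
    x_cell = np.asarray(x_cell, dtype=float)
    if not np.isfinite(x_cell).all():
        raise ValueError("expression vector contains non-finite values")
    if not 0 <= gene_index < genome.n_genes:
        raise IndexError(f"gene index {gene_index} out of range")
    z = float(genome.interactions[gene_index] @ x_cell - genome.theta[gene_index])
    return float(_sigmoid(z, params.beta))


def morphogen_profile(params: SimulationParams) -> tuple[np.ndarray, np.ndarray]:
    """Fixed complementary linear morphogen gradients.

    With cells indexed ``l = 1..L``, the first morphogen gene carries
    ``(L - l) / (L - 1)`` (maximal at the left end) and the second
    ``(l - 1) / (L - 1)`` (maximal at the right end).  Both are clamped at
    every developmental step.
    """
    L = params.n_cells
    if L < 2:
        raise ValueError("morphogen gradients need at least 2 cells")
    if len(params.morphogen_indices) != 2:
        raise ValueError("morphogen profile is defined for exactly 2 morphogens")
    l = np.arange(1, L + 1, dtype=float)
    return (L - l) / (L - 1), (l - 1) / (L - 1)


def initial_field(
    genome: Genome,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    *,
    delta: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial expression field and the per-gene perturbation applied.

    Non-morphogen genes start spatially uniform at ``x_init_i + delta_i``
    with ``delta_i ~ N(0, sigma)`` drawn once per gene and shared by all
    cells; morphogen rows are set from :func:`morphogen_profile`.  Values are
    deliberately not clipped to [0, 1]; boundedness holds for in-range
    starts.
    """
    N, L = params.n_genes, params.n_cells
    if delta is None:
        if rng is None or params.init_noise_sd == 0:
            delta = np.zeros(N)
        else:
            delta = rng.normal(0.0, params.init_noise_sd, size=N)
    delta = np.asarray(delta, dtype=float).copy()
    delta[list(params.morphogen_indices)] = 0.0
    x = np.repeat((genome.x_init + delta)[:, None], L, axis=1)
    _clamp_morphogens(x, params)
    return x, delta


def _clamp_morphogens(x: np.ndarray, params: SimulationParams) -> None:
    """Overwrite morphogen rows with their fixed gradients (in place).

    Works on both single fields (N, L) and population stacks (P, N, L).
    """
    if not params.morphogen_indices:
        return
    g0, g1 = morphogen_profile(params)
    i0, i1 = params.morphogen_indices
    x[..., i0, :] = g0
    x[..., i1, :] = g1


def _laplacian(x: np.ndarray) -> np.ndarray:
    """Discrete 1-D Laplacian along the last axis with zero-flux ends.

    Neumann boundaries are realised with ghost copies of the edge cells,
    so the edge terms reduce to ``x[1] - x[0]`` and ``x[-2] - x[-1]``.
    """
    lap = np.empty_like(x)
    lap[..., 1:-1] = x[..., 2:] - 2.0 * x[..., 1:-1] + x[..., :-2]
    lap[..., 0] = x[..., 1] - x[..., 0]
    lap[..., -1] = x[..., -2] - x[..., -1]
    return lap


def _check_stability(genome: Genome, params: SimulationParams) -> None:
    margin = params.dt * (genome.gamma.max() + 2.0 * genome.diffusion.max())
    if margin > 1.0:
        warnings.warn(
            f"dt * (max gamma + 2 max D) = {margin:.3f} > 1; the explicit "
            "Euler update may lose its contraction property",
            RuntimeWarning,
            stacklevel=3,
        )


def step(field: np.ndarray, genome: Genome, params: SimulationParams) -> np.ndarray:
    """Advance one expression field by a single Euler step.

    Morphogen rows are excluded from the reaction-diffusion update and
    re-clamped to their gradients afterwards; their rows of the interaction
    matrix are inert (outgoing columns act normally).
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (params.n_genes, params.n_cells):
        raise ValueError(
            f"field must be (n_genes, n_cells) = "
            f"({params.n_genes}, {params.n_cells}), got {field.shape}"
        )
    if not np.isfinite(field).all():
        raise FloatingPointError("non-finite expression field")
    J = genome.interactions.astype(float)
    F = _sigmoid(J @ field - genome.theta[:, None], params.beta)
    new = field + params.dt * (
        genome.gamma[:, None] * (F - field)
        + genome.diffusion[:, None] * _laplacian(field)
    )
    if params.morphogen_indices:
        idx = list(params.morphogen_indices)
        new[idx] = field[idx]
    return new


def develop(
    genome: Genome,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
    *,
    initial: Optional[np.ndarray] = None,
    delta: Optional[np.ndarray] = None,
    store_every: int = 1,
) -> Trajectory:
    """Run the full developmental dynamics and return the trajectory.

    The initial field is drawn via :func:`initial_field` unless ``initial``
    (a caller-supplied (N, L) matrix) or ``delta`` is given.  All
    ``n_steps + 1`` frames are stored unless ``store_every`` thins them (the
    initial and final frames are always kept).  The returned trajectory
    carries a stationarity flag (max |dx| over the last 10 steps below
    tolerance) and an oscillation flag (persistent sign-alternating updates
    above tolerance within the last 50 steps).
    """
    genome.validate()
    _check_stability(genome, params)
    if store_every < 1:
        raise ValueError("store_every must be >= 1")
    N, L, T = params.n_genes, params.n_cells, params.n_steps
    if initial is not None:
        x = np.array(initial, dtype=float)
        if x.shape != (N, L):
            raise ValueError("initial field has wrong shape")
        rec_delta = np.zeros(N) if delta is None else np.asarray(delta, float)
    else:
        x, rec_delta = initial_field(genome, params, rng, delta=delta)

    stored_steps = list(range(0, T + 1, store_every))
    if stored_steps[-1] != T:
        stored_steps.append(T)
    values = np.empty((N, L, len(stored_steps)))
    values[:, :, 0] = x
    frame_pos = 1

    osc_start = max(1, T - OSCILLATION_WINDOW + 1)
    stat_start = max(1, T - STATIONARITY_WINDOW + 1)
    max_dx_tail = 0.0
    flips = np.zeros((N, L), dtype=np.int32)
    tail_amp = np.zeros((N, L))
    prev_dx: Optional[np.ndarray] = None

    J = genome.interactions.astype(float)
    gam = genome.gamma[:, None]
    dif = genome.diffusion[:, None]
    theta = genome.theta[:, None]
    morph = list(params.morphogen_indices)

    for t in range(1, T + 1):
        F = _sigmoid(J @ x - theta, params.beta)
        dx = params.dt * (gam * (F - x) + dif * _laplacian(x))
        if morph:
            dx[morph] = 0.0
        x = x + dx
        if t % 32 == 0 or t == T:
            if not np.isfinite(x).all():
                raise FloatingPointError(
                    f"non-finite expression field at step {t}"
                )
        if t >= osc_start:
            if prev_dx is not None:
                alternating = (dx * prev_dx < 0) & (
                    np.minimum(np.abs(dx), np.abs(prev_dx)) > STATIONARITY_TOL
                )
                flips += alternating
            tail_amp = np.maximum(tail_amp, np.abs(dx))
            prev_dx = dx
        if t >= stat_start:
            max_dx_tail = max(max_dx_tail, float(np.abs(dx).max()))
        if t % store_every == 0 or t == T:
            values[:, :, frame_pos] = x
            frame_pos += 1

    stationary = max_dx_tail < STATIONARITY_TOL
    window = min(OSCILLATION_WINDOW, T) - 1
    oscillating = bool(
        not stationary
        and window > 0
        and ((flips >= max(1, window // 2)) & (tail_amp > STATIONARITY_TOL)).any()
    )
    return Trajectory(
        values=values[:, :, :frame_pos],
        dt=params.dt,
        delta=rec_delta,
        step_stride=store_every,
        stationary=stationary,
        oscillating=oscillating,
        genome=genome,
        params=params,
        stored_steps=np.asarray(stored_steps[:frame_pos]),
    )


def develop_population(
    genomes: Sequence[Genome],
    params: SimulationParams,
    deltas: np.ndarray,
) -> np.ndarray:
    """Terminal expression fields of a whole population, stepped in lockstep.

    ``deltas`` is a (P, N) array of per-individual initial perturbations
    (morphogen columns are ignored).  Returns a (P, N, L) array of terminal
    fields.  Uses the compiled kernel when numba is available; otherwise a
    vectorized numpy update with identical semantics.
    """
    from . import _kernels

    P = len(genomes)
    N, L, T = params.n_genes, params.n_cells, params.n_steps
    J = np.stack([g.interactions for g in genomes])
    gam = np.stack([g.gamma for g in genomes])
    dif = np.stack([g.diffusion for g in genomes])
    theta = np.stack([g.theta for g in genomes])
    xi = np.stack([g.x_init for g in genomes])
    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (P, N):
        raise ValueError("deltas must be (P, n_genes)")

    x = np.repeat((xi + deltas)[:, :, None], L, axis=2)
    _clamp_morphogens(x, params)
    morph_mask = np.zeros(N, dtype=bool)
    morph_mask[list(params.morphogen_indices)] = True

    if _kernels.HAVE_NUMBA:
        _kernels.population_steps(
            J, gam, theta, dif, x, morph_mask, params.beta, params.dt, T
        )
        if not np.isfinite(x).all():
            raise FloatingPointError("non-finite population field")
        return x

    Jf = J.astype(float)
    gam3, dif3, theta3 = gam[:, :, None], dif[:, :, None], theta[:, :, None]
    morph = list(params.morphogen_indices)
    for t in range(1, T + 1):
        F = expit(params.beta * (np.matmul(Jf, x) - theta3))
        dx = params.dt * (gam3 * (F - x) + dif3 * _laplacian(x))
        if morph:
            dx[:, morph] = 0.0
        x += dx
        if t % 50 == 0 and not np.isfinite(x).all():
            raise FloatingPointError(f"non-finite population field at step {t}")
    if not np.isfinite(x).all():
        raise FloatingPointError("non-finite population field")
    return x
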