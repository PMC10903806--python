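"""Hourglass analytics on developmental trajectories.

Two inter-species similarity indicators are provided: the inverse of the
total gene-expression difference,

    Delta(t1, t2) = 1 / (eps + sum_i sum_l |x_i^A(l, t1) - x_i^B(l, t2)|),

which keeps spatially local information, and Pearson's correlation between
the spatially summed expression vectors ``X_i = sum_l x_i(l, t)`` of the two
individuals.  A similarity matrix over pairs of developmental time points is
summarised by its ridge (the best-matching partner time for every step of
the first individual), a projected profile along the ridge, and the
bottleneck step where the profile peaks.  A developmental hourglass shows as
an interior bottleneck: the projected similarity peaks at a middle stage,
not at either end of development.

Also here: the fraction of expressed pleiotropic genes per stage, the
variance of the pattern dynamics over clones, per-gene expression-change
timescales with slow-gene identification, and the correlation between the
slowest gene's timescale and the bottleneck timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .model import Genome, SimulationParams, Trajectory

__all__ = [
    "SimilarityMatrix",
    "TimescaleReport",
    "DepthSimilarity",
    "CloneVarianceResult",
    "similarity_delta",
    "similarity_pearson",
    "similarity_matrix",
    "branch_depth_similarity",
    "pleiotropy_fraction",
    "clone_variance",
    "gene_timescales",
    "slow_genes",
    "timescale_bottleneck_correlation",
    "DELTA_EPSILON",
]

#: Regulariser added to the summed absolute difference so that the inverse
#: difference indicator is finite for identical frames.
DELTA_EPSILON = 1e-8

#: Bottlenecks within this central fraction of the compared step range count
#: as interior.
INTERIOR_RANGE = (0.05, 0.95)

#: Relative margin by which an interior peak must exceed both endpoint
#: values for a profile to count as hourglass-positive.
PEAK_MARGIN = 0.05

Indicator = Literal["delta", "pearson"]


def _check_pair(a: Trajectory, b: Trajectory) -> None:
    if a.n_genes != b.n_genes or a.n_cells != b.n_cells:
        raise ValueError(
            "trajectories must agree in gene and cell counts: "
            f"({a.n_genes}, {a.n_cells}) vs ({b.n_genes}, {b.n_cells})"
        )


def similarity_delta(
    traj_a: Trajectory,
    traj_b: Trajectory,
    t1: int,
    t2: int,
    *,
    eps: float = DELTA_EPSILON,
) -> float:
    """Inverse total expression difference between two frames.

    Symmetric under swapping (A, t1) and (B, t2); capped at ``1/eps`` for
    identical frames.  Frame indices refer to stored frames.
    """
    _check_pair(traj_a, traj_b)
    diff = np.abs(traj_a.frame(t1) - traj_b.frame(t2)).sum()
    return float(1.0 / (eps + diff))


def _spatial_sums(traj: Trajectory) -> np.ndarray:
    """(n_frames, n_genes) matrix of spatially summed expression."""
    return traj.values.sum(axis=1).T


def similarity_pearson(
    traj_a: Trajectory, traj_b: Trajectory, t1: int, t2: int
) -> tuple[float, bool]:
    """Pearson correlation of spatially summed expression vectors.

    Returns ``(rho, defined)``; ``defined`` is False when either vector has
    zero variance across genes, in which case ``rho`` is 0 rather than NaN.
    """
    _check_pair(traj_a, traj_b)
    xa = traj_a.frame(t1).sum(axis=1)
    xb = traj_b.frame(t2).sum(axis=1)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return 0.0, False
    rho = pearsonr(xa, xb).statistic
    return float(rho), True


@dataclass(eq=False)
class SimilarityMatrix:
    """Similarity over pairs of developmental time points of two runs.

    ``values[i, j]`` compares step ``steps_a[i]`` of the first trajectory
    with step ``steps_b[j]`` of the second.  ``ridge[i]`` is the best
    partner step for ``steps_a[i]`` (ties toward the smaller step), the
    projected ``profile`` is the value along the ridge, and
    ``bottleneck_step`` is the step of the first trajectory where the
    profile peaks.
    """

    values: np.ndarray
    steps_a: np.ndarray
    steps_b: np.ndarray
    indicator: Indicator

    @property
    def ridge(self) -> np.ndarray:
        return self.steps_b[np.argmax(self.values, axis=1)]

    @property
    def profile(self) -> np.ndarray:
        return self.values.max(axis=1)

    @property
    def bottleneck_index(self) -> int:
        return int(np.argmax(self.profile))

    @property
    def bottleneck_step(self) -> int:
        return int(self.steps_a[self.bottleneck_index])

    @property
    def bottleneck_is_interior(self) -> bool:
        return _is_interior(self.bottleneck_step, self.steps_a)

    @property
    def hourglass_positive(self) -> bool:
        return profile_is_hourglass(self.profile, self.steps_a)


def _is_interior(step: int, steps: np.ndarray) -> bool:
    lo = steps[0] + INTERIOR_RANGE[0] * (steps[-1] - steps[0])
    hi = steps[0] + INTERIOR_RANGE[1] * (steps[-1] - steps[0])
    return bool(lo <= step <= hi)


def profile_is_hourglass(profile: np.ndarray, steps: np.ndarray) -> bool:
    """Interior peak exceeding both endpoint values by a relative margin."""
    k = int(np.argmax(profile))
    if not _is_interior(int(steps[k]), steps):
        return False
    peak = profile[k]
    return bool(
        peak >= (1.0 + PEAK_MARGIN) * profile[0]
        and peak >= (1.0 + PEAK_MARGIN) * profile[-1]
    )


def similarity_matrix(
    traj_a: Trajectory,
    traj_b: Trajectory,
    indicator: Indicator = "delta",
    step_grid: Optional[Sequence[int]] = None,
    *,
    eps: float = DELTA_EPSILON,
) -> SimilarityMatrix:
    """Similarity indicator over a grid of developmental time-point pairs.

    ``step_grid`` gives frame indices applied to both trajectories (default:
    every stored frame).  For the inverse-difference indicator the grid of
    pairwise L1 distances is computed in one pass; for Pearson the spatially
    summed vectors are correlated.
    """
    _check_pair(traj_a, traj_b)
    if step_grid is None:
        grid_a = np.arange(traj_a.n_frames)
        grid_b = np.arange(traj_b.n_frames)
    else:
        grid_a = grid_b = np.asarray(list(step_grid), dtype=int)
        if grid_a.size == 0:
            raise ValueError("empty step grid")
        if grid_a.max() >= min(traj_a.n_frames, traj_b.n_frames):
            raise ValueError("step grid exceeds trajectory length")

    if indicator == "delta":
        fa = traj_a.values[:, :, grid_a].reshape(-1, grid_a.size).T
        fb = traj_b.values[:, :, grid_b].reshape(-1, grid_b.size).T
        dist = cdist(fa, fb, metric="cityblock")
        values = 1.0 / (eps + dist)
    elif indicator == "pearson":
        xa = _spatial_sums(traj_a)[grid_a]
        xb = _spatial_sums(traj_b)[grid_b]
        za = xa - xa.mean(axis=1, keepdims=True)
        zb = xb - xb.mean(axis=1, keepdims=True)
        sa = za.std(axis=1)
        sb = zb.std(axis=1)
        n = xa.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            values = (za @ zb.T / n) / np.outer(sa, sb)
        values = np.nan_to_num(values, nan=0.0)
    else:
        raise ValueError(f"unknown indicator {indicator!r}")

    return SimilarityMatrix(
        values=values,
        steps_a=grid_a * traj_a.step_stride,
        steps_b=grid_b * traj_b.step_stride,
        indicator=indicator,
    )


@dataclass(eq=False)
class DepthSimilarity:
    """Averaged projected similarity for one branch depth.

    ``branch_generation`` is the generation at which the compared species
    diverged; ``profile`` is the mean projected similarity over all compared
    pairs, against developmental ``steps`` of the reference species.
    ``bottleneck_mean``/``sd`` summarise the per-pair bottleneck steps.
    """

    branch_generation: int
    steps: np.ndarray
    profile: np.ndarray
    pair_bottlenecks: np.ndarray
    n_pairs: int

    @property
    def bottleneck_mean(self) -> float:
        return float(self.pair_bottlenecks.mean())

    @property
    def bottleneck_sd(self) -> float:
        return float(self.pair_bottlenecks.std())

    @property
    def bottleneck_range(self) -> tuple[float, float]:
        return (
            self.bottleneck_mean - self.bottleneck_sd,
            self.bottleneck_mean + self.bottleneck_sd,
        )

    @property
    def hourglass_positive(self) -> bool:
        return profile_is_hourglass(self.profile, self.steps)


def branch_depth_similarity(
    root_lineage,
    branch_lineages: Iterable,
    rng: np.random.Generator,
    *,
    indicator: Indicator = "delta",
    n_individuals: int = 3,
    step_grid: Optional[Sequence[int]] = None,
) -> list[DepthSimilarity]:
    """Similarity-vs-developmental-step curves, one per branch depth.

    For every branch generation present among ``branch_lineages``, the top
    ``n_individuals`` of the final generation of the root lineage and of
    each branched lineage are developed under fresh initial-condition noise
    and compared pairwise (root x branch cross-pairs); projected similarity
    profiles are averaged over pairs and per-pair bottleneck steps are
    summarised as mean +/- sd.  Results are sorted by branch generation,
    deepest divergence first.
    """
    branches = list(branch_lineages)
    if not branches:
        raise ValueError("need at least one branched lineage")
    for b in branches:
        if b.branch_generation is None:
            raise ValueError("branched lineages must carry branch metadata")
        if b.parent_seed != root_lineage.seed:
            raise ValueError("branched lineage does not share the root lineage")

    sim = root_lineage.sim_params
    root_trajs = _develop_top(root_lineage, n_individuals, sim, rng)

    by_gen: dict[int, list] = {}
    for b in branches:
        by_gen.setdefault(int(b.branch_generation), []).append(b)

    out: list[DepthSimilarity] = []
    for gen in sorted(by_gen):
        profiles = []
        bottlenecks = []
        steps = None
        for b in by_gen[gen]:
            branch_trajs = _develop_top(b, n_individuals, sim, rng)
            for ta in root_trajs:
                for tb in branch_trajs:
                    sm = similarity_matrix(ta, tb, indicator, step_grid)
                    profiles.append(sm.profile)
                    bottlenecks.append(sm.bottleneck_step)
                    steps = sm.steps_a
        out.append(
            DepthSimilarity(
                branch_generation=gen,
                steps=steps,
                profile=np.mean(profiles, axis=0),
                pair_bottlenecks=np.asarray(bottlenecks, dtype=float),
                n_pairs=len(profiles),
            )
        )
    return out


def _develop_top(lineage, m: int, sim: SimulationParams, rng) -> list[Trajectory]:
    from .model import develop  # local import to avoid cycle at module load

    return [develop(g, sim, rng) for g in lineage.top_individuals(m)]


def pleiotropy_fraction(
    traj: Trajectory,
    n_stages: int = 16,
    stage_window: Optional[tuple[int, int]] = None,
    spacing: Literal["linear", "log"] = "linear",
    expr_threshold: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of expressed genes that are pleiotropic, per stage.

    Developmental time is split into ``n_stages`` evenly spaced time points
    (arithmetically or logarithmically) through ``stage_window`` (default
    [10, last step]).  A gene counts as expressed at a stage when its
    spatial mean exceeds ``expr_threshold`` and as pleiotropic when it is
    expressed at strictly more than half of all stages.  Returns
    ``(stage_steps, fractions)`` with 0/0 treated as 0.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    last = int(traj.steps[-1])
    lo, hi = stage_window if stage_window is not None else (min(10, last), last)
    if not 0 <= lo <= hi <= last:
        raise ValueError("stage window outside trajectory")
    if spacing == "linear":
        stage_steps = np.unique(np.linspace(lo, hi, n_stages).round().astype(int))
    elif spacing == "log":
        stage_steps = np.unique(
            np.geomspace(max(lo, 1), hi, n_stages).round().astype(int)
        )
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    frame_idx = stage_steps // traj.step_stride
    means = traj.values[:, :, frame_idx].mean(axis=1)  # (genes, stages)
    expressed = means > expr_threshold
    pleiotropic = expressed.sum(axis=1) > stage_steps.size / 2
    n_expr = expressed.sum(axis=0).astype(float)
    n_pleio = (expressed & pleiotropic[:, None]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_expr > 0, n_pleio / np.maximum(n_expr, 1), 0.0)
    return stage_steps, frac


@dataclass(eq=False)
class CloneVarianceResult:
    """Variance of the pattern dynamics over clones, per developmental step.

    ``variance[t] = (1/K) sum_k sum_l sum_i (x_i^k(l,t) - xbar_i(l,t))^2``
    over ``K`` clones of one genome developed under independent noise.
    """

    steps: np.ndarray
    variance: np.ndarray

    @property
    def argmin_step(self) -> int:
        return int(self.steps[np.argmin(self.variance)])


def clone_variance(
    genome: Genome,
    sim_params: SimulationParams,
    n_clones: int,
    rng: np.random.Generator,
    *,
    noise_sd: float = 0.01,
    noise_mode: Literal["initial", "ongoing"] = "initial",
) -> CloneVarianceResult:
    """Develop clones under i.i.d. noise and track their pattern variance.

    ``initial`` mode perturbs only the initial condition (one Gaussian draw
    per gene per clone, sd ``noise_sd``); ``ongoing`` adds Gaussian noise to
    every gene and cell at every step.  Clones are stepped in lockstep and
    per-step sums are accumulated, so memory stays flat in the number of
    clones.
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    genome.validate()
    N, L, T = sim_params.n_genes, sim_params.n_cells, sim_params.n_steps
    from .model import _clamp_morphogens, _laplacian  # shared kernels
    from scipy.special import expit

    if noise_mode not in ("initial", "ongoing"):
        raise ValueError(f"unknown noise mode {noise_mode!r}")
    init_sd = noise_sd if noise_mode == "initial" else 0.0
    deltas = rng.normal(0.0, init_sd, size=(n_clones, N)) if init_sd > 0 else np.zeros((n_clones, N))
    deltas[:, list(sim_params.morphogen_indices)] = 0.0

    x = np.repeat((genome.x_init[None, :] + deltas)[:, :, None], L, axis=2)
    _clamp_morphogens(x, sim_params)
    morph = list(sim_params.morphogen_indices)
    non_morph = sim_params.non_morphogen_indices

    J = genome.interactions.astype(float)[None, :, :]
    gam = genome.gamma[None, :, None]
    dif = genome.diffusion[None, :, None]
    theta = genome.theta[None, :, None]
    beta, dt = sim_params.beta, sim_params.dt

    variance = np.empty(T + 1)
    variance[0] = _pattern_variance(x)
    for t in range(1, T + 1):
        F = expit(beta * (np.matmul(J, x) - theta))
        dx = dt * (gam * (F - x) + dif * _laplacian(x))
        if morph:
            dx[:, morph] = 0.0
        x += dx
        if noise_mode == "ongoing":
            x[:, non_morph] += rng.normal(
                0.0, noise_sd, size=(n_clones, non_morph.size, L)
            )
        variance[t] = _pattern_variance(x)
    return CloneVarianceResult(steps=np.arange(T + 1), variance=variance)


def _pattern_variance(x: np.ndarray) -> float:
    """(1/K) sum over clones, genes and cells of squared deviation."""
    mean = x.mean(axis=0, keepdims=True)
    return float(((x - mean) ** 2).sum() / x.shape[0])


@dataclass(eq=False)
class TimescaleReport:
    """Per-gene expression-change timescales (units: developmental steps).

    ``mean``/``sd`` aggregate over cells the longest run of steps during
    which a gene's expression keeps changing monotonically above the
    derivative threshold.  ``rank_order`` sorts genes by mean timescale,
    slowest first.
    """

    mean: np.ndarray
    sd: np.ndarray

    @property
    def rank_order(self) -> np.ndarray:
        return np.argsort(-self.mean, kind="stable")

    @property
    def n_genes(self) -> int:
        return self.mean.size


def gene_timescales(
    traj: Trajectory, derivative_threshold: float = 0.001
) -> TimescaleReport:
    """Estimate each gene's expression-change timescale in every cell.

    Discrete derivatives ``(x(t_k) - x(t_{k-1})) / dt`` are scanned for the
    longest consecutive run of steps in which the derivative keeps its sign
    and its magnitude exceeds ``derivative_threshold`` (condition one
    discards oscillatory flicker, condition two discards the saturated
    tail).  The run length in steps is the timescale; mean and sd are taken
    over cells, counting cells where the gene never crosses the threshold
    as 0.
    """
    if traj.step_stride != 1:
        raise ValueError("timescale estimation requires an unthinned trajectory")
    if traj.n_frames < 3:
        raise ValueError("trajectory too short to estimate derivatives")
    d = np.diff(traj.values, axis=2) / traj.dt  # (N, L, T)
    valid = np.abs(d) > derivative_threshold
    sign = np.sign(d)
    N, L, T = d.shape
    best = np.zeros((N, L), dtype=int)
    cur = np.zeros((N, L), dtype=int)
    prev_sign = np.zeros((N, L))
    for t in range(T):
        v = valid[:, :, t]
        s = sign[:, :, t]
        cont = v & (cur > 0) & (s == prev_sign)
        cur = np.where(cont, cur + 1, np.where(v, 1, 0))
        prev_sign = np.where(v, s, 0.0)
        np.maximum(best, cur, out=best)
    return TimescaleReport(
        mean=best.mean(axis=1).astype(float), sd=best.std(axis=1).astype(float)
    )


def slow_genes(
    report: TimescaleReport,
    n_slow: Optional[int] = None,
) -> np.ndarray:
    """Indices of the slow genes, slowest first.

    With ``n_slow`` given, simply the top-``n_slow`` genes by mean
    timescale.  Otherwise the mean timescales are sorted descending and cut
    at the largest multiplicative gap within the top half of the ranking; if
    no gap exists (all timescales equal) an empty selection is returned.
    """
    if report.n_genes == 0:
        raise ValueError("empty timescale report")
    order = report.rank_order
    if n_slow is not None:
        return order[: max(0, n_slow)]
    means = report.mean[order]
    if report.n_genes == 1:
        return order
    half = max(1, report.n_genes // 2)
    ratios = np.full(half, -np.inf)
    for k in range(half):
        a, b = means[k], means[k + 1]
        if a <= 0:
            break
        ratios[k] = np.inf if b == 0 else a / b
    if not (ratios > 1.0).any():
        return order[:0]
    cut = int(np.argmax(ratios))
    return order[: cut + 1]


def timescale_bottleneck_correlation(
    samples: Sequence[tuple[float, float]],
) -> tuple[float, float, bool]:
    """Pearson correlation and least-squares slope between the slowest
    gene's timescale and the bottleneck step, over samples.

    Returns ``(correlation, slope, defined)``; ``defined`` is False when
    either coordinate has zero variance.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (timescale, bottleneck) samples")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, False
    rho = float(pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return rho, slope, True
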