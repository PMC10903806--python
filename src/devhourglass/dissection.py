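"""Extraction of the essential gene-network structure for one cell.

The full interaction matrix is shared by every cell, but the morphogen
gradients activate different sub-circuits at different positions, so the
whole network carries many "decoy" edges that do nothing in a given cell.
The essential subnetwork responsible for marker-gene switching in a chosen
cell is extracted in stages: (1) detect the switch periods during which at
least one marker gene's summed input lies within the sigmoid's dynamic
range ``[-2/beta, 2/beta]``; (2) drop edges touching genes never expressed
during those periods, and outgoing edges of genes whose expression stays
constant (a constant regulator only shifts the target's effective
threshold); (3) score every remaining edge by its share of the target's
total input change over each period and drop edges whose contribution never
exceeds a threshold; (4) finally keep only genes lying on a directed route
from a morphogen to a marker gene.

Edges whose source is a morphogen gene are exempt from the constancy and
contribution filters: morphogen expression is constant by construction, yet
its static positional input is exactly what roots the retained paths, so
removing those edges would disconnect every network from its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .model import Genome, SimulationParams, Trajectory

__all__ = [
    "SwitchPeriod",
    "EssentialNetwork",
    "detect_switch_periods",
    "prune_inactive",
    "edge_contribution",
    "extract_essential_network",
    "CONTRIBUTION_THRESHOLD",
    "EXPRESSION_FLOOR",
]

#: Minimum |contribution| for an edge to be retained in some period.
CONTRIBUTION_THRESHOLD = 0.01

#: Expression floor below which a gene counts as not expressed, and
#: constancy tolerance on its range; aligned with the cell-typing OFF margin.
EXPRESSION_FLOOR = 0.01


@dataclass(frozen=True)
class SwitchPeriod:
    """Maximal step interval during which some marker input is in the
    sigmoid's dynamic range at the analysed cell."""

    start: int
    end: int
    markers: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("period start must not exceed end")

    @property
    def steps(self) -> slice:
        return slice(self.start, self.end + 1)


@dataclass(eq=False)
class EssentialNetwork:
    """Pruned subgraph judged causally responsible for marker switching.

    ``edges`` maps ``(source, target)`` to the interaction sign; the edge
    set is a subset of the nonzero entries of the genome's interaction
    matrix.  ``contributions[(j, i)]`` lists the per-period contribution
    scores (None for periods where the denominator was indeterminate).
    """

    edges: dict[tuple[int, int], int]
    contributions: dict[tuple[int, int], list[Optional[float]]]
    periods: list[SwitchPeriod]
    cell_index: int
    morphogen_genes: tuple[int, ...]
    marker_genes: tuple[int, ...]
    slow_genes: tuple[int, ...] = ()

    @property
    def nodes(self) -> set[int]:
        return {g for e in self.edges for g in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.DiGraph:
        """networkx digraph with node role annotations, for GraphML export."""
        g = nx.DiGraph()
        for node in sorted(self.nodes):
            g.add_node(
                node,
                morphogen=node in self.morphogen_genes,
                marker=node in self.marker_genes,
                slow=node in self.slow_genes,
            )
        for (j, i), sign in sorted(self.edges.items()):
            scores = [s for s in self.contributions.get((j, i), []) if s is not None]
            g.add_edge(
                j,
                i,
                sign=int(sign),
                max_abs_contribution=float(
                    max((abs(s) for s in scores), default=0.0)
                ),
            )
        return g


def _marker_inputs(
    traj: Trajectory, genome: Genome, cell_index: int, params: SimulationParams
) -> np.ndarray:
    """(n_markers, n_frames) summed inputs to each marker at the cell."""
    x = traj.values[:, cell_index, :]  # (genes, frames)
    markers = list(params.marker_indices)
    J = genome.interactions[markers].astype(float)
    theta = genome.theta[markers]
    return J @ x - theta[:, None]


def detect_switch_periods(
    traj: Trajectory,
    genome: Genome,
    cell_index: int,
    params: SimulationParams,
) -> list[SwitchPeriod]:
    """Maximal step intervals where a marker input is within ``2/beta`` of
    its threshold at the given cell.

    Overlapping windows of different markers are merged; each period records
    which markers were in their dynamic range during it.
    """
    if not 0 <= cell_index < traj.n_cells:
        raise IndexError(f"cell index {cell_index} out of range")
    if traj.step_stride != 1:
        raise ValueError("switch detection requires an unthinned trajectory")
    inputs = _marker_inputs(traj, genome, cell_index, params)
    band = 2.0 / params.beta
    in_band = np.abs(inputs) <= band  # (markers, frames)
    any_band = in_band.any(axis=0)
    periods: list[SwitchPeriod] = []
    t = 0
    n = any_band.size
    markers = list(params.marker_indices)
    while t < n:
        if any_band[t]:
            start = t
            while t + 1 < n and any_band[t + 1]:
                t += 1
            active = tuple(
                markers[m]
                for m in range(len(markers))
                if in_band[m, start : t + 1].any()
            )
            periods.append(SwitchPeriod(start, t, active))
        t += 1
    return periods


def prune_inactive(
    genome: Genome,
    traj: Trajectory,
    periods: Sequence[SwitchPeriod],
    cell_index: int,
    params: SimulationParams,
    *,
    floor: float = EXPRESSION_FLOOR,
) -> np.ndarray:
    """Boolean edge mask after removing inactive and constant genes.

    An edge mask entry ``[i, j]`` is True when the edge ``j -> i`` survives.
    Genes whose expression at the cell never exceeds ``floor`` during the
    switch periods lose all edges; genes whose expression range stays below
    ``floor`` lose their outgoing edges (their input is a constant bias).
    Morphogen sources are exempt from the constancy rule.
    """
    if not periods:
        raise ValueError("no switch periods to analyse")
    x = traj.values[:, cell_index, :]
    steps = np.concatenate([np.arange(p.start, p.end + 1) for p in periods])
    xs = x[:, steps]
    silent = xs.max(axis=1) < floor
    constant = np.ptp(xs, axis=1) < floor
    morph = np.zeros(genome.n_genes, dtype=bool)
    morph[list(params.morphogen_indices)] = True

    mask = genome.interactions != 0
    mask[silent, :] = False  # incoming edges of silent genes
    dead_source = (silent | constant) & ~morph
    mask[:, dead_source] = False  # outgoing edges of silent/constant genes
    mask[:, silent & morph] = False  # a silent morphogen is still no input
    return mask


def edge_contribution(
    genome: Genome,
    traj: Trajectory,
    edge: tuple[int, int],
    period: SwitchPeriod,
    cell_index: int,
    *,
    mask: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Contribution of edge ``j -> i`` to the target's input change.

    With ``dx_k`` the expression change of gene ``k`` over the period at the
    analysed cell, the score is ``J_ij dx_j / sum_k J_ik dx_k`` where the
    denominator runs over the currently retained incoming edges of ``i``
    (all nonzero entries when ``mask`` is None).  Returns None when the
    denominator is indeterminate (|sum| < 1e-12); such edges are retained
    conservatively.
    """
    j, i = edge
    if mask is None:
        mask = genome.interactions != 0
    if not mask[i, j]:
        raise ValueError(f"edge {j} -> {i} is not in the retained set")
    x = traj.values[:, cell_index, :]
    dx = x[:, period.end] - x[:, period.start]
    row = genome.interactions[i].astype(float) * mask[i]
    denom = float(row @ dx)
    if abs(denom) < 1e-12:
        return None
    return float(genome.interactions[i, j] * dx[j] / denom)


def extract_essential_network(
    genome: Genome,
    traj: Trajectory,
    cell_index: int,
    params: SimulationParams,
    *,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD,
    slow_gene_indices: Sequence[int] = (),
) -> EssentialNetwork:
    """Run the full dissection pipeline for one cell.

    Applies, in order: switch-period detection, inactive/constant-gene
    pruning, per-edge contribution filtering (an edge survives if its
    |score| exceeds the threshold in at least one period, or if a period was
    indeterminate), and finally route filtering to a fixed point — a gene
    keeps its edges only while it lies on a directed path from a morphogen
    to a marker within the retained subgraph.  Returns an empty network with
    empty period list when no switch periods exist.
    """
    genome.validate()
    periods = detect_switch_periods(traj, genome, cell_index, params)
    morph = tuple(params.morphogen_indices)
    mark = tuple(params.marker_indices)
    if not periods:
        return EssentialNetwork(
            {}, {}, [], cell_index, morph, mark, tuple(slow_gene_indices)
        )
    mask = prune_inactive(genome, traj, periods, cell_index, params)

    contributions: dict[tuple[int, int], list[Optional[float]]] = {}
    keep = np.zeros_like(mask)
    morph_set = set(morph)
    for i, j in zip(*np.nonzero(mask)):
        i, j = int(i), int(j)
        scores = [
            edge_contribution(genome, traj, (j, i), p, cell_index, mask=mask)
            for p in periods
        ]
        contributions[(j, i)] = scores
        if j in morph_set:
            keep[i, j] = True  # static positional input, exempt from scoring
        else:
            keep[i, j] = any(
                s is None or abs(s) > contribution_threshold for s in scores
            )

    keep = _route_filter(keep, morph, mark)
    edges = {
        (int(j), int(i)): int(genome.interactions[i, j])
        for i, j in zip(*np.nonzero(keep))
    }
    contributions = {e: contributions[e] for e in edges}
    return EssentialNetwork(
        edges, contributions, periods, cell_index, morph, mark,
        tuple(slow_gene_indices),
    )


def _route_filter(
    mask: np.ndarray,
    morphogens: Sequence[int],
    markers: Sequence[int],
) -> np.ndarray:
    """Keep only genes with a path from a morphogen AND to a marker.

    Morphogen genes trivially satisfy the first condition and markers the
    second.  Removing a gene's edges can break other genes' routes, so the
    filter is iterated to a fixed point (which also makes the overall
    extraction idempotent).
    """
    mask = mask.copy()
    morph_set, mark_set = set(morphogens), set(markers)
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(range(mask.shape[0]))
        g.add_edges_from((int(j), int(i)) for i, j in zip(*np.nonzero(mask)))
        from_morph = set(morph_set)
        for m in morph_set:
            from_morph |= nx.descendants(g, m)
        to_mark = set(mark_set)
        for m in mark_set:
            to_mark |= nx.ancestors(g, m)
        ok = from_morph & to_mark
        bad = [n for n in g.nodes if n not in ok and (g.degree(n) > 0)]
        if not bad:
            return mask
        for n in bad:
            mask[n, :] = False
            mask[:, n] = False
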