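# Methods

## Model

An individual is a row of `L` cells without proliferation; every cell
carries the same gene-regulatory network over `N` genes.  Expression levels
`x_i(l, t) ∈ [0, 1]` follow an explicit-Euler, discrete-space
reaction-diffusion update

    x_i(l) ← x_i(l) + Δt · [ γ_i (F(i, x(l)) − x_i(l))
                             + D_i (x_i(l+1) − 2 x_i(l) + x_i(l−1)) ]

with sigmoidal synthesis

    F(i, x) = 1 / (1 + exp(−β (Σ_j J_ij x_j − θ_i))),

interactions `J_ij ∈ {−1, 0, +1}` (activation / none / inhibition of gene
`i` by gene `j`), reaction rate `γ_i` (the gene's timescale is `1/γ_i` in
model time units, `1/(γ_i Δt)` in steps), threshold `θ_i`, and diffusion
constant `D_i` for the gene product.  β = 40 makes the sigmoid nearly a
step function (a very high effective Hill coefficient): its dynamic range
is `|input − θ| ≲ 2/β = 0.05`.

Genes 0 and 1 are morphogens: their rows are excluded from the update and
clamped every step to the complementary linear gradients `(L−l)/(L−1)` and
`(l−1)/(L−1)` (cells `l = 1..L`), providing time-invariant positional
input.  Lattice ends are zero-flux (Neumann) via ghost copies of the edge
cells.  Initial conditions are spatially uniform per gene: the heritable
level `x_init_i` plus one Gaussian "epigenetic" perturbation `δ_i` per
gene, shared by all cells of the individual.

On the perturbation scale: the source description calls σ = 0.1 the
*variance* of δ, which we take literally — the study-level default standard
deviation is √0.1 ≈ 0.316.  The parameter (`init_noise_sd`) is an sd and is
freely configurable; our pilot evolutions found the hourglass emerges under
the variance reading and not under sd = 0.1, where initial states of close
species are so alike that early similarity dominates every profile.

With `Δt (γ_i + 2 D_i) ≤ 1` the update is a convex combination of values in
[0, 1] plus a contraction toward `F ∈ (0, 1)`, so in-range initial
conditions stay in range; a warning is issued when parameters leave this
regime.  Initial values are not clipped, so out-of-range starts (large δ)
are legal and simply relax into the unit interval.

## Fitness, selection, mutation

A cell's type is the ON/OFF combination of the four marker genes (2–5):
ON above 0.99, OFF below 0.01, anything between leaves the cell untyped.
Fitness is the number of distinct types present in the terminal pattern
(max 2⁴ = 16).  Selection is softmax on fitness,
`p_i = e^{f_i} / Σ_j e^{f_j}`, which keeps a one-type advantage selectively
visible.  Each offspring resamples 4 distinct interaction-matrix entries
(rows restricted to non-morphogen genes, whose expression is actually
dynamic) to +1 / −1 / 0 with probabilities 1/8, 1/8, 3/4, and adds
N(0, 0.01) to every `γ_i`, `θ_i`, `D_i`, `x_init_i`, flooring `γ` at 1e−4,
`D` at 0, and clipping `x_init` to [0, 1].  Fresh δ noise is drawn per
individual per generation, so fitness is evaluated under initial-condition
noise — this is what makes developmental noise robustness selectable.

Random founding genomes draw `J` entries i.i.d. with P(±1) = 1/16 each
(expected `N/8` regulators per gene) and morphogen rows zeroed.  The
continuous priors are a package choice (the source is silent):
`γ ~ U(0.05, 1]`, `θ ~ U(−1, 1)`, `D ~ U[0, 0.2]`, `x_init ~ U[0, 1]`,
keeping `Δt (γ + 2D) ≤ 0.14` well inside the contraction regime.

## Lineages and population cloning

`evolve` records every generation: genomes, fitnesses, parent indices and
the δ each individual was evaluated under, so any recorded fitness can be
replayed exactly.  One sequential RNG per lineage drives noise, selection
and mutation; `clone_and_rerun` restarts from the stored population at a
branch generation under a fresh generator, producing species diverged from
a common ancestor while sharing all pre-branch snapshots.  (Independent
named streams per concern would allow swapping only post-branch streams;
since cloning restarts from a snapshot anyway, a single stream is
equivalent and simpler.)

## Hourglass analytics

*Similarity.*  `Δ(t1, t2) = 1 / (ε + Σ_i Σ_l |x_i^A(l,t1) − x_i^B(l,t2)|)`
with ε = 1e−8 regularising the identical-frame case, and Pearson's ρ
between spatially summed expression vectors.  A similarity matrix over all
frame pairs is summarised by its ridge (argmax over t2 per t1, ties toward
the smaller step), the projected profile along the ridge, and the
bottleneck step where the profile peaks.  A profile is *hourglass-positive*
when its peak lies within the central 5–95 % of the step range and exceeds
both endpoint values by ≥ 5 % (the source judges peaks visually; the margin
makes the call deterministic).

*Branch-depth similarity.*  For each branch generation, the three fittest
final individuals of the root and of each cloned lineage are developed
under fresh δ and compared pairwise (9 cross pairs); profiles are averaged
over pairs and per-pair bottleneck steps summarised as mean ± sd (the
"bottleneck range").  A replicate is classified hourglass-positive when
some compared branch depth has an hourglass-positive mean profile.

*Pleiotropy.*  16 stage time points, evenly spaced (linear or log) through
[10, t_term]; a gene is expressed at a stage when its spatial mean exceeds
0.1 and pleiotropic when expressed at strictly more than half of all
stages; the per-stage fraction is pleiotropic-expressed over expressed,
0/0 → 0.  (The source's figure caption says 12 stages where its methods
text says 16; we follow the methods text, and the stage count is a
parameter.)

*Clone variance.*  `Var(t) = (1/K) Σ_k Σ_l Σ_i (x_i^k(l,t) − x̄_i(l,t))²`
over K clones of one genome under i.i.d. δ with sd 0.01 (the "ongoing"
mode instead adds per-step Gaussian noise to every gene and cell).  Clones
are stepped in lockstep with streaming accumulation, so memory is flat in
K.  The source states sd 0.01 in its methods and σ = 0.1 in a figure
caption; both are supported, 0.01 is the default.

*Timescales.*  Per gene and cell, the longest consecutive run of steps
whose discrete derivative keeps its sign and exceeds 0.001 in magnitude;
the run length in steps is the timescale, averaged over cells (cells never
crossing the threshold count 0).  Slow genes are cut at the largest
multiplicative gap within the top half of the descending mean-timescale
ranking; with no gap (all equal) the cut is empty unless an explicit count
is given.

## Essential-network extraction

For one cell: (1) *switch periods* — maximal step intervals where some
marker's summed input is within 2/β of threshold; overlapping windows of
different markers merge.  (2) *inactivity pruning* — genes never expressed
(max < 0.01) during the periods lose all edges; genes with constant
expression (range < 0.01) lose outgoing edges, since a constant regulator
only shifts the target's effective threshold.  (3) *contribution filter* —
edge j→i scores `J_ij Δx_j / Σ_k J_ik Δx_k` over retained inputs per
period; edges whose |score| never exceeds 0.01 are dropped; an
indeterminate denominator (< 1e−12) retains the edge conservatively.
(4) *route filter* — iterated to a fixed point, a gene keeps edges only
while it lies on a directed path from a morphogen to a marker.

Edges *from morphogen genes* are exempt from the constancy and
contribution rules: morphogen expression is constant by construction, so a
literal reading would remove every morphogen out-edge and the route filter
would then empty every network; their static positional input is exactly
what roots the retained paths.

## Desk-scale study conditions

The full-scale conditions (N = 24, L = 128, P = 100, 1000 steps, 1000
generations, 21 replicates) are far beyond a single-workstation budget, so
the packaged study (`desk_scale_config`) runs N = 16, L = 32, P = 50,
t_term = 400 steps, G_term = 650 generations, branch points 350–500 in
steps of 50 (divergence depths 150–300 generations), 3 compared
individuals per species and 100 variance clones.  Scaling choices, fixed
from pilot runs before the acceptance checks were evaluated:

- *t_term = 400 with γ prior floor 0.125* — the floor is raised 2.5× as the
  window shrinks 2.5×, keeping the slowest prior timescale at 1/5 of
  development, as at full scale.
- *Branch points after the fitness plateau* — fitness at this lattice size
  plateaus around generation 300–400 at 6–9 of 16 types (32 cells cannot
  support the full 16); ancestors are cloned from generation 350 onward,
  echoing the full-scale 800-of-1000 protocol.  Divergence depths of
  150–300 generations at this genome size correspond to the source's
  "recent 100–300 generations" once the ~2.4× higher per-entry mutation
  rate of the smaller interaction matrix is accounted for; which depth in
  that range peaks varies run to run, so several depths are sampled and a
  replicate is positive when any of them is.
- *Acceptance bar 6 of 16* — the analogue of the full-scale "fittest above
  15" filter, set from the pilot attainable-fitness distribution.
- *Replicate counts* — each replicate is a full evolution plus four cloned
  re-evolutions (~1650 generations); the packaged study runs a handful of
  replicates per noise level (four high-noise and two low-noise in the test
  suite, three and two in the reproduction script), which is enough to
  exhibit the phenomenology but leaves the prevalence fractions with wide
  sampling error compared to the source's 21 runs.

The shipped pre-evolved exemplar genome (`make_fixture("evolved-small")`)
is generated separately at *fixture scale*: the same 16-gene, 32-cell
lattice but with the full 1000-step window and the full-scale γ prior
floor 0.05, because under the shortened 400-step window evolved slowness
is carried by poised network modes rather than by small-γ genes, and the
single-gene rate manipulation then has nothing to act on.  The fixture
records its own parameters, the replay perturbation, the bottleneck band
measured against a stored partner species (an individual of a lineage
cloned 300 generations before the end), the slow genes, and the analysis
cell.  The rate manipulation of the slowest gene is assessed as the shift
of the similarity bottleneck against that partner — the bottleneck of the
detected hourglass, which is the object the manipulation is about.

What passing at desk scale does and does not show: the qualitative
phenomenology (interior similarity peaks for recently diverged species,
their loss at low noise, the pleiotropy peak near the bottleneck at stage
resolution, slow genes scheduling the bottleneck via heterochrony) is
reproduced, but quantitative values — prevalence fractions, bottleneck
steps, timescales — are specific to the scaled conditions and noisier than
the full-scale figures: with 32 cells and 6–9 cell types, terminal
patterns of close species can nearly coincide, which thins the margin by
which an interior peak beats the profile's endpoint and makes
classification more conservative than the source's visual calls.  One
full-scale coincidence does not survive the scaling at all: the
clone-variance minimum sits near the end of development rather than at the
bottleneck, because a 32-cell lattice offers clones few alternative fates
to diverge into after the bottleneck; the corresponding check is expected
to fail at this scale and is retained unchanged as a record of that
limitation.

## Numerical choices

- Stationarity: max |Δx| over the last 10 steps below 1e−6; oscillation:
  sign-alternating updates above 1e−6 over at least half of the last
  50 steps.  Both well below the 0.01 cell-typing margin.
- The compiled population stepper exploits `J ∈ {−1, 0, +1}` (signed sums,
  no general matmul) and short-circuits the sigmoid where it saturates: in
  double precision `1/(1+e^{−z})` rounds to exactly 1.0 for z ≥ 40, so the
  cutoff changes no representable value.  No fastmath, so operation order
  and results are reproducible.  The reference stepper (`step`) is plain
  numpy; the two agree to floating-point roundoff and the test suite pins
  the reference against an independent per-cell loop at 1e−12.
- Ridge and bottleneck ties break toward the smaller step; all outputs are
  deterministic for a fixed seed.
- Trajectory thinning (`store_every`) is for storage only; step-counting
  analyses (timescales, switch periods) require unthinned runs and raise
  otherwise.

## Limitations

- No cell proliferation, mechanics, or 2-D/3-D geometry; morphogens are
  linear ramps only (exponential gradients are out of scope).
- The desk-scale lattice cannot realize all 16 cell types, so absolute
  fitness levels are not comparable with full-scale runs.
- Classification uses a fixed 5 % peak margin; profiles whose interior
  peak beats the endpoints by less are counted negative even when a human
  would call them hourglass-shaped.
- The Spearman rank similarity indicator and morphological staging are not
  implemented.
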