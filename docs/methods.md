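# Methods

## Model

A gene regulatory network is a signed directed graph over N genes. The
expression level x_i of gene i obeys additive Hill kinetics:

    dx_i/dt = -k x_i
              + Σ_{j ∈ activators(i)} a_ji x_j^n / (S^n + x_j^n)
              + Σ_{j ∈ repressors(i)}  b_ji S^n / (S^n + x_j^n)

The first term is linear self-degradation, the second saturating
activation, the third "repression as derepression": a repressed gene is
produced at rate b when its repressor is absent and not at all when the
repressor saturates. There is no basal production term and no AND/product
logic — regulators combine additively. Self-edges use the gene's own
level. Per-edge strengths a_ji, b_ji default to the global constants a and
b; only the sensitivity analysis sets them individually.

One consequence of the derepression form that matters for interpretation:
*strengthening* a repressive edge j ⊣ i deepens the attractor in which i
is high and j is low, because the edge's production term is largest
exactly there. Sensitivity results must be read with this arithmetic in
mind.

Default constants: k = 1, S = 0.5, n = 4 (the classic bistable-switch
regime for this kinetics; bistability requires roughly S in 0.5–1.5 and
n in 4–8). Time and concentration are dimensionless throughout; the
potential U is dimensionless by construction.

Noise convention (used consistently in every module): the Langevin force
has autocorrelation ⟨η_i(t) η_j(t')⟩ = 2 D δ_ij δ(t−t'), so the
Euler–Maruyama update is x ← x + F dt + sqrt(2 D dt) ξ and a linear
1-gene system has stationary variance D/k. Expression levels are clamped
at 0 from below (concentrations cannot be negative).

## Attractors and basin weights

`find_attractors` integrates the rate equations from uniform random
initial states in a box (default [0, 3]^N, covering Hill saturation for
S = 0.5), polishes endpoints by Newton root-finding with the analytic
Jacobian, verifies stability through Jacobian eigenvalues, deduplicates
within 0.05 in max-norm, and weights each attractor by the fraction of
starts that reached it. Weights therefore form a probability vector and
are bit-reproducible for a fixed seed.

## Gaussian mean-field landscape

Per basin, the mean follows the deterministic equations and the diagonal
variances follow dσ_i/dt = 2 A_ii(x̄) σ_i + 2D with A the Jacobian
(mean-field factorisation of the joint probability; cross-covariances are
dropped — the full matrix equation σA^T + Aσ + 2D would track them, but
the factorised closure keeps the landscape construction O(N)). At a
stable fixed point σ_i = −D/A_ii. The steady-state probability is the
basin-weight mixture of the per-basin Gaussians, and because covariances
are diagonal, projecting onto any two genes is exact (dropping
coordinates drops factors). U = −ln max(P, floor) with floor = 1e−12 of
the grid maximum.

Limitations of the closure, deliberately accepted: it is a weak-noise
approximation, and it says nothing useful for genes pinned near zero
expression, where the 0-clamp truncates the distribution (the Langevin
variance of such a gene is boundary-dominated and smaller than D/k).
Variance validation against sampling is therefore done in a basin whose
levels are far from zero. What mean-field/Langevin agreement tests show
is that the two routes rank cell states consistently (rank correlation of
P over populated cells ≥ 0.7), not that the Gaussian tails are right.

## Flux

On a 2-D projection, J = F₂P − D∇P with central differences; at a true
steady state ∇·J = 0. For a gradient system with Boltzmann P the flux
vanishes to discretisation order (verified at second-order convergence
under grid refinement); for the fate-decision motif it does not — the
residual curl flux is what bends kinetic paths away from steepest
descent. The flux module also reports the decomposition residual
F − (J/P − D∇U) as a diagnostic; it vanishes in the continuum limit.

## Barriers and MFPT

Barrier heights are read from a 2-D grid of U: the two minima are located
(or supplied), and the saddle is the minimax cell — over all 8-connected
grid paths between the minima, the path minimising its maximum U. This is
computed by watershed flooding (cells activated in increasing U order,
union-find connectivity), which is exactly equivalent and O(M log M); an
independent sublevel-set-connectivity oracle cross-checks it in the
tests. Barriers are U_saddle − U_min ≥ 0.

MFPT is estimated by independent Langevin restarts from the source
attractor state; a passage ends on first entry into the max-norm ball
(default radius 0.1 of the attractor separation; 0.2 in the motif
studies) around the target state — or around *any* target state when the
question is first exit to any competing fate. Means come with a standard
error over passages. Restarting from the attractor point (rather than a
basin-equilibrated ensemble) matches the definition of the transition
experiment and adds only a short intra-basin relaxation to each passage.

## Dominant paths

The Onsager–Machlup weight of a path is exp(−S) with
S = ∫ Σ_i (ẋ_i − F_i(x))² / 4D dt. The leading-order functional is used;
the ∇·F/2 correction is omitted (at small D it re-ranks nothing) and the
choice is recorded in each result's metadata. Discretisation: midpoint
rule per segment — velocity (x_{k+1}−x_k)/Δt against the force at the
segment midpoint. Minimisation is L-BFGS-B over the interior points with
the analytic action gradient (finite-difference-verified in tests),
multi-start from the straight line plus seeded noise, ties broken by
action then lexicographic first interior point. Path duration is fixed
(default T = 30; the geometric comparisons in the tests use T = 10 and 80
points, which converges the transit segment tightly) with an optional
bounded search over T.

Irreversibility is quantified as the discrete Fréchet distance between
the forward path and the reversed backward path, normalised by the
endpoint separation. For a symmetric-well gradient field this index
converges to zero (the two minimisers coincide — detailed balance); for
the fate-decision motif it stays an order of magnitude above the
gradient-case convergence floor.

## Discretised state graphs

Each gene's trace is binarised at (max − min)/2 + min of its own
trajectory; ties code high; constant genes code 0 with a warning.
Projection keeps the ordered marker genes (the packaged network's 22
markers; the pluripotent state reads eleven 1s then eleven 0s, the
differentiated state the complement). State probability is occupancy
fraction; transition probability is the joint fraction of consecutive
snapshot pairs with different codes (self-pairs excluded; a per-source
conditional variant is available by flag). States and transitions below
the probability cutoff (default 2e−4) are dropped. Exports: GraphML with
probability and Hamming-distance annotations (lossless), SIF and TSV.

## Sensitivity analysis and annealing

A scan perturbs each target — a single link strength (×(1+δp), default
δp = ±0.2), a global constant, or a gene knockdown (all incoming
production removed, so the gene decays to zero; outgoing edges still
transmit the decayed level) — and recomputes barriers and MFPTs **at the
perturbed system's own relocated attractors**, paired with the baseline
attractors by proximity. All stochastic stages reuse the baseline seeds,
so a zero perturbation yields exactly zero deltas. Links are ranked by
|Δbarrier_stem| + |Δbarrier_diff|, ties by name.

Annealing scales the whole activation matrix by a(t)/a along a linear (or
exponential) schedule of rate |da/dt| inside a single Langevin run. The
fate jump is detected when the thresholded marker code (per-gene cutoffs
defaulting to the Hill threshold S — the natural on/off boundary) matches
a destination code for 10 consecutive recorded samples. Downward sweeps
yield the differentiation threshold a_c1, upward sweeps the reprogramming
threshold a_c2; a_c1 < a_c2 is the hysteresis loop of the bistable
switch.

## The two-gene motif and its two readings

The packaged GATA1/PU1-style motif (mutual repression b = 1, self-
activation a, k = 1, S = 0.5, n = 4, D = 0.05) has two distinct regimes,
and the study suites use each where it is the right instrument:

* **a ≈ 1 and above — tristable.** A central progenitor state (both genes
  co-expressed at intermediate level) coexists with two committed side
  states. The central basin is the stem-like state; falling to a side
  basin is differentiation. This regime carries the kinetic trend suite:
  raising a deepens the progenitor basin (barrier and MFPT of
  differentiation rise) while flattening the committed basins (barrier
  and MFPT of reprogramming fall); raising b deepens everything; raising
  D flattens everything. Sweeps used: a ∈ {0.9, 1.0, 1.1},
  b ∈ {0.9, 1.0, 1.1}, D ∈ {0.03, 0.05, 0.08}.
* **a ≈ 0.5 — bistable.** Only the two mirror lineage states exist; one
  gene is read as the stem marker, the other as the differentiation
  marker. This regime carries the irreversibility and sensitivity
  studies. In the tristable regime, per-link barrier changes are small
  enough that Kramers prefactors decouple barrier and MFPT shifts; in the
  bistable regime the two metrics agree in sign for every scanned link
  perturbation (each link strengthened by 20%, the cross-repressions also
  weakened by 20%), which is the consistency property the scan is designed
  to exhibit. Perturbations of the global constants are deliberately not
  part of this suite: the global activation constant moves the two MFPTs
  by only about a percent here, below any practical sampling resolution.

Hysteresis study conditions: sweep a from 1.8 to 0.3 and back, linear
rate 5e−4 per unit time, D = 0.008, dt = 0.01, jump detection as above.
The noise level is deliberately below the trend-suite value: at D = 0.05
both basins equilibrate faster than the ramp and the loop closes.

## The 52-gene fixture

The packaged stem-cell network is a *reconstruction*, not a transcription
of a published table: the 22 marker genes with their order numbers, the
named repression links (CDX2⊣OCT4, OCT4⊣GATA6, NANOG⊣GATA6, GATA4⊣GATA6,
LMCD1⊣GATA6, PRDM14⊣GATA6), the fourteen named activation links among
OCT4/SOX2/NANOG/OCT4SOX2/KLF4/ZIC3/PBX1, the two antagonistic marker
pairs and the three self-activations are exact; the remaining 99 edges
(28 placeholder genes G25–G52 among them) are synthetic filler engineered
to the same architecture — mutual activation inside the stem-marker
block, stem-activated downstream genes, a differentiation cascade under
GATA6/CDX2/GATA4, and stem↔differentiation cross-repression — while
keeping every non-core gene cycle-free so the attractor structure is
carried by the core toggle. Every edge carries a provenance tag (text |
synthetic) in the packaged TSV, and the edge list is checksummed. The
OCT4SOX2 complex is an ordinary node activated by OCT4 and SOX2.

Balanced operating point: a = 0.35, b = 0.4. The global constants were
chosen, by the model's own selection criteria (existence of steady
states, bistability, two comparably visible basins), via multi-start
attractor counting over a grid of (a, b); at a = b = 0.5 this
reconstruction is monostable-stem, and the bistable window in a is
roughly 0.35–0.40 at b = 0.4. At the chosen point the stem basin
captures ~95% of uniform random starts — the landscape shows a deep stem
valley and a shallower differentiated valley. GATA6 sits near 0.9 (not
zero) in the stem state: its GATA4 repressor is low there, and
derepression sustains an intermediate level. Binarisation still separates
the states cleanly (0.9 vs 2.4).

What the synthetic fixture does and does not show: tests on it
demonstrate that the pipeline recovers the designed two-state structure,
marker codes and knockdown directions from a realistic-scale network; the
specific gene-level rankings on the synthetic half of the wiring carry no
biological claim.

## Problem sizes and reproducibility

Study-scale settings used in the test suite and acceptance script:
attractor censuses use 150–500 random starts; histogram landscapes 2–4
million Euler–Maruyama steps at dt = 0.01 on 40–60 bins; MFPTs 60–400
passages; path optimisation 80 points and ≤ 8000 L-BFGS iterations;
annealing sweeps 3000 time units each. All stochastic kernels are
numba-compiled and seeded (identical seed ⇒ bit-identical output); the
full acceptance run completes in a few minutes on one CPU.

## Known limitations

* Diagonal Gaussian closure: no cross-covariances, no validity near the
  zero-expression boundary, weak-noise assumption.
* Histogram barriers inherit sampling noise ~1/sqrt(occupancy); deltas
  below ~0.05 in U need long runs or common random numbers.
* The leading-order Onsager–Machlup functional fixes path duration
  effects only up to the optional scalar-T search.
* Knockdowns of core toggle genes typically make the network monostable;
  the scan flags such records rather than reporting barriers.
* Cell division, transdifferentiation targets, and topology inference
  are out of scope.
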