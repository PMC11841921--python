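# Methods

## Model structure and assumptions

`notchsim` treats each endothelial cell as a well-mixed compartment whose
protein copy numbers follow deterministic mass-action kinetics, in units of
molecules/cell and hours. Two networks are implemented.

The **ligand-competition model** (model 1) tracks free DLL4 (D), free JAG1
(J), the DLL4 homodimer (C), free Notch1 (N) and Notch activity (S). Its
biological content is three asymmetries between the ligands:

1. only DLL4 homodimerizes, and only the homodimer cis-inhibits Notch
   (rate `kci`);
2. DLL4 and JAG1 heterodimerize into an inert complex, so each ligand acts
   as a sink for the other;
3. trans-JAG1 activates Notch1 much more weakly than trans-DLL4 (affinity
   ratio `alpha`, 1e-4 at baseline; `alpha = 0` makes trans-JAG1 inert,
   `alpha = 1` makes the ligands equivalent).

All binding reactions are irreversible, following the modelling tradition
for this pathway; a variant with an explicit reversible DLL4–JAG1 complex
(`rhs_reversible`, rates k+ and k−) is provided, and its steady states
coincide with the irreversible model at the effective rate
`khe = beta*k+/(beta + k−)` (`reversible_equivalent_khe`). This equivalence
is exercised by the test suite over random (k+, k−) draws.

The **VEGF-coupled model** (model 2) embeds the same ligand network in the
tip/stalk selection circuit: free VEGF binds VEGFR2 (R) to produce VEGFR2
activity (V), V upregulates DLL4 production (Hill function with fold change
`lam_D = 10`), DLL4 trans-activates Notch in neighbours, and Notch activity
S shuts down VEGFR2 production (fold change `lam_R = 0`, i.e. complete
suppression at saturation). This intercellular negative feedback is what
amplifies small initial differences into alternating cell fates.

Both models decay S (and V) at `betaS` rather than `beta`; where printed
sources differ on the decay species in the S-equation, the implementation
uses −betaS·S for the intracellular-domain balance in both models, keeping
the two models consistent with each other and with the interpretation of S
as a fast-decaying cleaved signal.

## Parameters

Baseline values (`SignallingParams.table1()`):

| symbol | meaning | value | units |
|---|---|---|---|
| bD, bJ | DLL4/JAG1 production | 100 | molec/h |
| bN | Notch1 production | 500 | molec/h |
| bR | VEGFR2 production | 800 | molec/h |
| beta | generic protein degradation | 0.1 | 1/h |
| betaS | S and V degradation | 0.5 | 1/h |
| kho | DLL4 homodimerization | 1e-4 | 1/(molec·h) |
| khe | DLL4–JAG1 heterodimerization | 1e-3 | 1/(molec·h) |
| kt | trans-activation | 5e-5 | 1/(molec·h) |
| kci | cis-inhibition | 6e-4 | 1/(molec·h) |
| kv | VEGF–VEGFR2 binding | 5e-5 | 1/(molec·h) |
| alpha | trans JAG1:DLL4 affinity ratio | 1e-4 | — |
| θD, λD, nD | V → DLL4 production Hill | 200, 10, 2 | molec, —, — |
| θR, λR, nR | S → VEGFR2 production Hill | 30, 0, 2 | molec, —, — |
| Vext | free VEGF at the front | 2500 | molec |

Production rates put protein levels in the thousands-of-molecules range at
`beta = 0.1`/h (a ~7 h half-life); `betaS = 0.5`/h reflects the fast decay
of cleaved signalling domains. `khe > kho` encodes the stronger
JAG1–DLL4 affinity relative to DLL4 self-association.

## Steady-state analysis

At steady state the (D, J) subsystem closes on itself. Eliminating J gives
a monic cubic in D with composites `A1 = (beta+kt*Next)/(2kho)`,
`B1 = (beta+alpha*kt*Next)/khe`, `A2 = (beta+kt*Next)/khe`,
`B2 = 2kho/khe²`; an equivalent cubic holds for J. `ligand_cubic` builds
both; `solve_ligand_steady_state` finds the roots by companion-matrix
eigenvalues (`numpy.roots`), Newton-polishes them, recovers J from the
JAG1 balance and accepts the pair that zeroes both balances to
1e-6·max(bD, bJ, 1) molecules/h. Closed-form cubic formulas were avoided
because the coefficients span ~6 orders of magnitude at realistic rates.
When more than one nonnegative root is consistent, the root reached by the
ODE from zero initial conditions is returned (in extensive random sampling
a single consistent root was always observed; the tie-break is a
safeguard). `khe = 0` decouples the ligands, the cubic degenerates, and
the solver switches to the quadratic/linear closed forms; `ligand_cubic`
raises `DecoupledRegimeError` to force callers onto that path.

Implicit differentiation of the D-cubic yields the sign pattern
(∂D̄/∂bD, ∂D̄/∂bJ, ∂J̄/∂bD, ∂J̄/∂bJ) = (+, −, −, +): each ligand's
steady level rises with its own production and falls with the other's.
`ligand_monotonicity` verifies this numerically with central differences
(relative step 1e-3) and reports 0 rather than a sign when a difference is
below 1e-9 relative noise — e.g. the exactly-zero cross-derivatives at
`khe = 0`.

In the strong-heterodimerization limit (khe much larger than beta+kt·Next
and kho) the cubics collapse to the mutual-inactivation law implemented in
`strong_het_limit`. Note the limit is asymptotic: at `khe = 0.1` with
(bD, bJ) = (100, 50), khe·D̄ ≈ 31 ≫ beta so DLL4 sits within 0.25% of its
limit value 309.0, but the depleted JAG1 settles at
J̄ = bJ/(beta + khe·D̄) ≈ 1.61 molecules rather than exactly 0. The
acceptance benchmarks report these computed values, not the limits.

## Numerics

**Integration** is classical fixed-step RK4 (`integrate`), h = 0.01 h by
default with t_end = 1000 h: the fastest baseline relaxation rates are a
few per hour (e.g. kci·N and khe·D at high copy number), so h = 0.01
resolves all timescales with ~1e-10 relative step error, and the slowest
(beta = 0.1/h) equilibrates well before t_end. Integration stops early
when max |dx/dt| over free (unclamped) entries falls below `steady_tol`
(1e-6 molecules/h by default). States are clipped to zero when they dip
below 0 by at most 1e-9 (floating-point noise); a larger negative
excursion or a non-finite value raises `IntegrationError` with the failure
time — positivity is a property of the dynamics, so its violation signals
a genuinely unstable step size.

**Clamping** (`ClampSpec`-style mappings, used by the sender/receiver
scenarios) holds selected species at fixed values: their derivatives are
zeroed inside every RK4 stage and the values re-asserted after each step.
Zeroing inside the stages matters: resetting only after the step lets a
strongly-driven clamped species drift by O(h) within the step, which
biases the species coupled to it and leaves a spurious O(h·|dx/dt|)
residual floor.

**Cell coupling.** The trans input of a cell is the average of the
corresponding species over its neighbour positions, recomputed at every
RK4 stage from the stage state so the coupled system is integrated fully
consistently at O(h⁴). Off-lattice neighbour positions contribute zero
ligand, and by default the average divides by the full slot count (6 for
hexagons, 2 on a line): a boundary cell genuinely faces empty space. The
alternative convention — dividing by the realized neighbour count — is
available as `boundary="truncate"`. Trans Notch (Next) is averaged the
same way, since the D and J balances contain ligand consumption by
neighbouring receptors. Two-cell systems (bifurcation analysis, the
sender/receiver assays) use pure pairwise exchange: each cell's trans
input is the other cell's level.

**Lattice geometry** is pointy-top hexagons of side 1 in odd-row-offset
layout (rows 1.5 apart, columns √3 apart, odd rows shifted √3/2), which
realizes a regular hexagonal packing; the VEGF field
`V(y) = Vext·exp(−a(y−y0))` depends only on the row depth y, with the
front row at y0 receiving exactly Vext. On a line of cells (the model of
the vascular front itself) VEGF is uniform at Vext. `a` is in units of
inverse hexagon side; `a = 1` drops VEGF by e^1.5 ≈ 4.5× per row.

**Tissue initial conditions** are uniform on [0, 100] molecules per
species per cell from `numpy.random.default_rng(seed)`; the random
heterogeneity seeds the lateral-inhibition instability, and all outputs
are bit-reproducible given (configuration, seed).

**Tip/stalk classification** thresholds VEGFR2 activity at the population
midpoint (min+max)/2; when the population spread is under 5% of
max(V_max, 1) no fates are assigned ("uniform"). The front alternation
index is the fraction of adjacent front-row pairs with differing labels:
1.0 for a perfect salt-and-pepper front, ~0.5 for random labels, 0 for a
homogeneous front. For model-1 tissues (no V), free DLL4 serves as the
fate marker since tip cells are the DLL4-high cells.

**Equilibrium finding** (two cells) refines Newton (scipy's hybrid Powell)
from a multistart set: the symmetric steady state obtained by stiff-safe
relaxation (LSODA) from rest, symmetry-broken perturbations of it, the
attractors of a few random states, and seeded random starts scaled to
rough per-species magnitudes. Accepted roots must have residual below
1e-8× the largest production rate and nonnegative components; duplicates
merge at 1e-4 relative distance, and every heterogeneous equilibrium's
cell-swap partner is added explicitly (the coupled system is
exchange-symmetric). Stability comes from the eigenvalues of a
central-difference Jacobian (step 1e-6·max(|x|,1)); real parts within
±1e-6/h of zero are classified "marginal". Equilibria whose two cell
blocks agree to 1e-6 relative are "homogeneous", the rest "heterogeneous"
— the latter, when stable, are the tip/stalk states.

**Continuation** is natural-parameter: a grid sweep with Newton
warm-started from the previous grid point's equilibria plus fresh
multistarts to catch branch births. This suffices because the analysed
branches are single-valued in the swept parameter over the ranges of
interest; fold-following (pseudo-arclength) is out of scope and noted as a
limitation for steeply folded problems. Parameter intervals where the
stable-equilibrium count changes are bisected to 1% of the sweep range.
The patterning phase diagram marks a parameter point as "patterning" iff a
stable heterogeneous equilibrium exists there.

## Scenarios: what the in-silico experiments emulate

The sender/receiver scenarios (`fig4*`) emulate co-culture reporter
assays: a sender cell with clamped surface DLL4 (cis-inhibition assays) or
a receiver with clamped Notch and no own ligand (trans-activation assays),
with the partner's production rate swept. Clamp levels and sweep ranges
are read from figure axes of the source experiments and are exposed as
configuration values (`options.sender_D_clamp`, etc.) rather than being
hard-coded.

The mutant-group scenario (`fig6_line_mutants`) applies production-rate
multipliers {0.5, 1, 4} for loss-of-function, wild-type and
inducible-overexpression groups; the original presentation ramps the rates
continuously and labels regions, so the multipliers are package defaults,
configurable per run. The stripe scenario (`fig7_stripes`) adds external
trans-ligand to two contiguous stripes of a cell line at levels ramping
0→200 molecules. The shallower-gradient scenario (`s6_gradient_sharpness`)
uses a ∈ {1, 0.5, 0.2, 1/35}.

## What the synthetic setups do and do not capture

All inputs are generated in-package; there is no external data. The tissue
model omits cell migration, division and rearrangement, VEGF diffusion
dynamics (the field is static), receptor oligomerization,
ligand-intracellular-domain signalling, stochastic gene expression, and
delays. Passing tests therefore demonstrate properties of the
deterministic reaction network on a fixed lattice — pattern selection by
lateral inhibition, ligand mutual inactivation, parameter monotonicity —
not quantitative agreement with in-vivo sprouting, where those omitted
processes reshape both timescales and geometry.

## Problem sizes and known limitations

The test and benchmark workloads use a 10×10 hexagonal lattice (10 seeds
per condition), 100-sample random-parameter oracle checks, 20-point
continuation grids over bD ∈ [100, 2000], and two-cell phase-diagram grids
of order 6×6 — sizes chosen so the full suite runs on a laptop-class
single core in minutes while still exercising every code path at the
scale the analyses require. Natural-parameter continuation can in
principle miss an attractor with a very small basin if every Newton start
lands elsewhere; the multistart count (and `n_starts`) trades robustness
against runtime, and the suite cross-checks the branch structure against
long-time integration from random states at representative points.
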