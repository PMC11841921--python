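# notchsim

A simulator for DLL4/JAG1–Notch signalling in sprouting angiogenesis, built
around the observation that the two Notch ligands form an inactive
DLL4–JAG1 heterodimer. During angiogenesis, endothelial cells at the
vascular front differentiate into migratory *tip* cells (high VEGFR2
activity, high DLL4, low JAG1) and trailing *stalk* cells (the converse).
DLL4 and JAG1 exert opposing control over this choice, and `notchsim`
provides the modelling machinery to study why: single-cell and multicellular
ODE simulation, closed-form steady-state analysis of the ligand competition,
and bifurcation analysis of two coupled cells. It is aimed at systems
biologists studying lateral inhibition, ligand competition and tip/stalk
selection.

## The models

**Ligand-competition model (model 1).** Per cell, with free DLL4 monomer
*D*, free JAG1 monomer *J*, cis-inhibitory DLL4 homodimer *C*, free Notch1
receptor *N* and Notch activity (free intracellular domain) *S*:

```
dD/dt = b_D − βD − 2k_ho D² − k_he JD − k_t N_ext D
dJ/dt = b_J − βJ − k_he DJ − αk_t N_ext J
dC/dt = k_ho D² − βC − k_ci NC
dN/dt = b_N − βN − k_ci CN − k_t D_ext N − αk_t J_ext N
dS/dt = k_t D_ext N + αk_t J_ext N − β_S S
```

DLL4 homodimerizes (rate `k_ho`) into the cis-inhibitory species *C*;
DLL4 and JAG1 heterodimerize (rate `k_he`) into an inert complex that
sequesters both monomers; trans ligand on neighbouring cells
(`D_ext`, `J_ext`) activates Notch, with JAG1 handicapped by the affinity
ratio `α ∈ [0, 1]`; trans Notch (`N_ext`) consumes the cell's own ligand.

**VEGF-coupled model (model 2)** adds free VEGFR2 *R* and VEGFR2 activity
*V*: local free VEGF binds VEGFR2 (rate `k_v`), VEGFR2 activity upregulates
DLL4 production through a Hill function `H(V; θ_D, λ_D, n_D)`, and Notch
activity shuts VEGFR2 production down through `H(S; θ_R, λ_R=0, n_R)` —
the lateral-inhibition feedback that makes neighbouring cells adopt
opposite fates.

At steady state, the free-ligand levels of model 1 satisfy a monic cubic
whose coefficients expose a mutual-inactivation law: when heterodimerization
is strong, whichever ligand is produced faster survives (DLL4 at
`√((β+k_t N_ext)²/(16k_ho²) + (b_D−b_J)/(2k_ho)) − (β+k_t N_ext)/(4k_ho)`
when `b_D > b_J`; JAG1 at `(b_J−b_D)/(β+αk_t N_ext)` when `b_J > b_D`) and
the other is driven toward zero. `notchsim.steady_state` implements the
cubic, its positive-root selection, this limit, and the monotonicity of the
steady state in the production rates.

## Worked example

Mutual inactivation of the two ligands under strong heterodimerization
(`k_he = 0.1`): fix DLL4 production at 100 molecules/h and sweep JAG1
production from 0 to 200.

```sh
$ notchsim run s3_mutual_inactivation --out out/s3 --set sweep.n=11 --seed 1
{
  "scenario": "s3_mutual_inactivation",
  "seed": 1,
  "max_Jbar_below_crossing": 5.087258547070181,
  "max_Dbar_above_crossing": 4.856412979764729,
  "crossing_at": 100.0
}
```

Below the crossing (`b_J < b_D = 100`) free JAG1 never exceeds ~5 molecules
— heterodimerization with the more abundant DLL4 consumes it almost
entirely; above the crossing the roles flip and free DLL4 collapses instead.
The full steady-state table (numeric solution next to the analytic limit)
is written to `out/s3/steady_states.csv`.

The same machinery drives the tissue-scale experiments, e.g. tip/stalk
patterning on a 10×10 hexagonal lattice under an exponential VEGF gradient:

```python
import notchsim as ns

lat = ns.build_lattice("hex", 10, 10)
traj, pattern = ns.simulate_tissue(
    lat, ns.SignallingParams.table1(), model=2,
    vegf=ns.VegfFieldSpec(Vext=2500.0, a=1.0), seed=0,
)
print(pattern.front_alternation_index)   # 0.889: alternating tip/stalk front
```

`notchsim list` shows all registered scenarios (cis/trans sender–receiver
assays, lattice patterning, line-of-cells mutants and stripe experiments,
two-cell bifurcation sweeps, and the patterning phase diagram).

## Layout

- `notchsim.model_core` — parameter/state types, Hill function, the two
  model right-hand sides, a reversible-heterodimerization variant, and a
  fixed-step RK4 integrator with clamping and steady-state detection.
- `notchsim.steady_state` — ligand steady-state cubics, strong-limit
  formulas, monotonicity checks, reversible↔irreversible rate mapping.
- `notchsim.multicell` — hexagonal/line lattices, VEGF fields,
  neighbour-averaged coupling, tissue simulation, tip/stalk metrics.
- `notchsim.bifurcation` — two-cell equilibria, stability, branch
  continuation, patterning phase diagrams.
- `notchsim.scenarios` / `notchsim.cli` — registered experiments,
  CSV/JSON serialization, `notchsim` command.

See `docs/methods.md` for the modelling assumptions, parameter meanings and
numerical choices.
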