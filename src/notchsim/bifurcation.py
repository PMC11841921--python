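"""Steady states and stability of the two-cell coupled system.

Two identical cells exchange trans inputs pairwise (each cell's trans
DLL4/JAG1/Notch is the other cell's level), the standard mutual-coupling
arrangement for lateral-inhibition analysis.  Equilibria of the coupled
vector field are located by Newton refinement (via `scipy.optimize.root`)
from a multistart set -- the symmetric steady state, symmetry-broken
perturbations of it, and seeded random states -- and classified by the
eigenvalues of a finite-difference Jacobian and by their symmetry:
*homogeneous* (both cells identical; the unpatterned state) or
*heterogeneous* (cells differ; a tip/stalk pair).  Branches are traced by
natural-parameter continuation with warm starts, which suffices because
the plotted branches are single-valued in the swept parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .model_core import (
    SignallingParams,
    _Trans,
    integrate,
    species_for_model,
    _rhs1_core,
    _rhs2_core,
)

__all__ = [
    "Equilibrium",
    "BifurcationBranch",
    "pair_rhs",
    "find_equilibria",
    "jacobian_fd",
    "classify_stability",
    "continue_branch",
    "phase_diagram",
]

STABILITY_TOL = 1e-6  # 1/hour; eigenvalue real parts within +-tol are marginal


@dataclass
class Equilibrium:
    """A steady state of the coupled two-cell system.

    ``state`` concatenates the two cells' species vectors; ``sym_class``
    is "homogeneous" when the blocks agree to 1e-6 relative.
    """

    state: np.ndarray
    residual: float
    stability: str
    sym_class: str
    leading_eig: float

    @property
    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.state.size // 2
        return self.state[:k], self.state[k:]

    def swapped(self) -> np.ndarray:
        a, b = self.cells
        return np.concatenate([b, a])


@dataclass
class BifurcationBranch:
    """Equilibria along a one-parameter sweep.

    ``events`` lists (lo, hi, count_before, count_after) intervals where
    the number of stable equilibria changes, refined by bisection.
    """

    param_name: str
    param_values: np.ndarray
    equilibria: list[list[Equilibrium]]
    events: list[tuple[float, float, int, int]]

    def stable_counts(self) -> np.ndarray:
        return np.array(
            [sum(e.stability == "stable" for e in eqs) for eqs in self.equilibria]
        )


def pair_rhs(params: SignallingParams, model: int = 2,
             extra_trans: tuple[float, float] = (0.0, 0.0),
             V_local: float | None = None) -> Callable[[np.ndarray], np.ndarray]:
    """Vector field of two pairwise-coupled cells as a flat state of length 2*k.

    ``extra_trans`` adds engineered external (Dext, Jext) to both cells;
    ``V_local`` is the free-VEGF level (defaults to params.Vext_base).
    """
    species = species_for_model(model)
    k = len(species)
    iD, iJ, iN = species.index("D"), species.index("J"), species.index("N")
    Dadd, Jadd = extra_trans
    if V_local is None:
        V_local = params.Vext_base

    def f(x: np.ndarray) -> np.ndarray:
        y = x.reshape(2, k)
        trans = _Trans(
            Dext=y[::-1, iD] + Dadd, Jext=y[::-1, iJ] + Jadd, Next=y[::-1, iN]
        )
        if model == 2:
            dy = _rhs2_core(y, params, V_local, trans)
        else:
            dy = _rhs1_core(y, params, trans)
        return dy.ravel()

    return f


def jacobian_fd(rhs: Callable[[np.ndarray], np.ndarray], state: np.ndarray,
                eps: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of ``rhs`` at ``state``.

    The step for component i is eps * max(|state_i|, 1).
    """
    x = np.asarray(state, dtype=float)
    n = x.size
    J = np.empty((n, n))
    for i in range(n):
        hstep = eps * max(abs(x[i]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[i] += hstep
        xm[i] -= hstep
        J[:, i] = (rhs(xp) - rhs(xm)) / (2.0 * hstep)
    return J


def classify_stability(jacobian: np.ndarray, tol: float = STABILITY_TOL) -> str:
    """'stable' if all eigenvalue real parts < -tol, 'unstable' if any > +tol,
    'marginal' otherwise."""
    re = np.linalg.eigvals(jacobian).real
    if np.all(re < -tol):
        return "stable"
    if np.any(re > tol):
        return "unstable"
    return "marginal"


def _species_scales(params: SignallingParams, model: int) -> np.ndarray:
    """Rough per-species magnitudes used for random starts and dedup scaling."""
    p = params
    bD = float(np.max(np.asarray(p.bD)))
    bJ = float(np.max(np.asarray(p.bJ)))
    bN = float(np.max(np.asarray(p.bN)))
    bR = float(np.max(np.asarray(p.bR)))
    D = p.hill_D.lam * max(bD, 1.0) / p.beta if model == 2 else max(bD, 1.0) / p.beta
    J = max(bJ, 1.0) / p.beta
    N = max(bN, 1.0) / p.beta
    C = p.kho * D * D / p.beta + 1.0
    S = p.kt * D * N / p.betaS + 1.0
    if model == 1:
        return np.array([D, J, C, N, S])
    R = max(bR, 1.0) / p.beta
    V = p.kv * p.Vext_base * R / p.betaS + 1.0
    return np.array([D, J, C, N, S, R, V])


def _dedupe(cands: list[np.ndarray], scale: np.ndarray,
            rtol: float = 1e-4) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for x in cands:
        if not any(np.max(np.abs(x - y) / scale) < rtol for y in out):
            out.append(x)
    return out


def find_equilibria(
    params: SignallingParams,
    model: int = 2,
    n_starts: int = 16,
    seed: int = 0,
    extra_trans: tuple[float, float] = (0.0, 0.0),
    V_local: float | None = None,
    warm_starts: Sequence[np.ndarray] = (),
    residual_tol_scale: float = 1e-8,
    relax_start: bool = True,
) -> list[Equilibrium]:
    """Locate the equilibria of the pairwise-coupled two-cell system.

    Newton (scipy ``root``, hybrid Powell) is launched from (a) the
    symmetric steady state obtained by integration, (b) symmetry-broken
    perturbations of it, (c) ``n_starts`` seeded random states, and any
    caller-supplied warm starts.  Converged points are accepted when the
    residual is below ``residual_tol_scale``x the production scale,
    deduplicated at 1e-4 relative distance, completed with their cell-swap
    partners, and classified by Jacobian eigenvalues and symmetry.
    """
    if n_starts < 8:
        raise ValueError("n_starts must be >= 8")
    species = species_for_model(model)
    k = len(species)
    f = pair_rhs(params, model, extra_trans, V_local)
    scales = _species_scales(params, model)
    pair_scale = np.concatenate([scales, scales])
    res_scale = max(float(np.max(np.asarray(params.bD))),
                    float(np.max(np.asarray(params.bJ))),
                    float(np.max(np.asarray(params.bN))),
                    float(np.max(np.asarray(params.bR))) if model == 2 else 0.0,
                    1.0)
    tol = residual_tol_scale * res_scale

    def _relax(x0: np.ndarray) -> np.ndarray | None:
        # Stiff-safe relaxation toward an attractor; used only to seed
        # Newton, so a loose tolerance suffices.
        sol = solve_ivp(lambda t, x: f(x), (0.0, 500.0), x0,
                        method="LSODA", rtol=1e-8, atol=1e-8)
        return sol.y[:, -1] if sol.success else None

    starts: list[np.ndarray] = [np.asarray(w, dtype=float) for w in warm_starts]
    rng = np.random.default_rng(seed)
    if relax_start:
        # (a) symmetric steady state by relaxation from rest, plus the
        # attractors reached from a few random states
        sym = _relax(np.zeros(2 * k))
        if sym is not None:
            starts.append(sym)
            # (b) symmetry-broken perturbations of the symmetric state
            for fac in (0.2, 0.5):
                up = sym.copy()
                up[:k] *= 1.0 + fac
                up[k:] *= 1.0 - fac
                starts.append(up)
                starts.append(np.concatenate([up[k:], up[:k]]))
        for _ in range(3):
            x0 = np.concatenate([rng.uniform(0.0, 1.0, size=k) * scales,
                                 rng.uniform(0.0, 1.0, size=k) * scales])
            relaxed = _relax(x0)
            if relaxed is not None:
                starts.append(relaxed)
    # (c) seeded random starts
    for _ in range(n_starts):
        cell1 = rng.uniform(0.0, 1.0, size=k) * scales
        cell2 = rng.uniform(0.0, 1.0, size=k) * scales
        starts.append(np.concatenate([cell1, cell2]))

    found: list[np.ndarray] = []
    for x0 in starts:
        sol = _scipy_root(f, np.maximum(x0, 0.0), method="hybr", tol=1e-13)
        x = sol.x
        if np.max(np.abs(f(x))) < tol and np.min(x) > -1e-9:
            found.append(np.clip(x, 0.0, None))
    found = _dedupe(found, pair_scale)
    # complete swap pairs (the coupled system is exchange-symmetric)
    for x in list(found):
        swapped = np.concatenate([x[k:], x[:k]])
        if not any(np.max(np.abs(swapped - y) / pair_scale) < 1e-4 for y in found):
            sol = _scipy_root(f, swapped, method="hybr", tol=1e-13)
            if np.max(np.abs(f(sol.x))) < tol and np.min(sol.x) > -1e-9:
                found.append(np.clip(sol.x, 0.0, None))
    found = _dedupe(found, pair_scale)

    out = []
    for x in found:
        Jm = jacobian_fd(f, x)
        eigs = np.linalg.eigvals(Jm).real
        a, b = x[:k], x[k:]
        homog = np.max(np.abs(a - b) / np.maximum(np.maximum(np.abs(a), np.abs(b)), 1.0)) < 1e-6
        out.append(Equilibrium(
            state=x,
            residual=float(np.max(np.abs(f(x)))),
            stability=classify_stability(Jm),
            sym_class="homogeneous" if homog else "heterogeneous",
            leading_eig=float(np.max(eigs)),
        ))
    out.sort(key=lambda e: (e.sym_class, tuple(np.round(e.state, 6))))
    return out


def _count_stable(eqs: list[Equilibrium]) -> int:
    return sum(e.stability == "stable" for e in eqs)


def _equilibria_at(value, params, model, param_name, extra_trans, V_local,
                   n_starts, seed, warm):
    if param_name in ("Dext", "Jext"):
        extra = (value, extra_trans[1]) if param_name == "Dext" else (extra_trans[0], value)
        p = params
    else:
        extra = extra_trans
        p = params.with_(**{param_name: value})
    return find_equilibria(p, model, n_starts=n_starts, seed=seed,
                           extra_trans=extra, V_local=V_local, warm_starts=warm)


def continue_branch(
    params: SignallingParams,
    model: int,
    param_name: str,
    prange: tuple[float, float],
    n_points: int = 41,
    n_starts: int = 12,
    seed: int = 0,
    extra_trans: tuple[float, float] = (0.0, 0.0),
    V_local: float | None = None,
    refine: bool = True,
) -> BifurcationBranch:
    """Natural-parameter continuation of the two-cell equilibria.

    ``param_name`` is a SignallingParams field, or "Dext"/"Jext" to sweep
    an engineered external trans-ligand level.  At each grid value Newton
    is warm-started from the previous value's equilibria plus fresh
    multistarts (to catch branch births).  Parameter intervals where the
    stable-equilibrium count changes are recorded and, if ``refine`` is
    set, bisected down to 1% of the sweep range.
    """
    lo, hi = prange
    values = np.linspace(lo, hi, n_points)
    all_eqs: list[list[Equilibrium]] = []
    warm: list[np.ndarray] = []
    for v in values:
        eqs = _equilibria_at(v, params, model, param_name, extra_trans, V_local,
                             n_starts, seed, warm)
        all_eqs.append(eqs)
        warm = [e.state for e in eqs]

    events: list[tuple[float, float, int, int]] = []
    min_width = 1e-2 * (hi - lo)
    for i in range(len(values) - 1):
        c0, c1 = _count_stable(all_eqs[i]), _count_stable(all_eqs[i + 1])
        if c0 == c1:
            continue
        a, b = float(values[i]), float(values[i + 1])
        ca, warm_a = c0, [e.state for e in all_eqs[i]]
        while refine and (b - a) > min_width:
            m = 0.5 * (a + b)
            eqs_m = _equilibria_at(m, params, model, param_name, extra_trans,
                                   V_local, n_starts, seed, warm_a)
            cm = _count_stable(eqs_m)
            if cm == ca:
                a, warm_a = m, [e.state for e in eqs_m]
            else:
                b = m
        events.append((a, b, c0, c1))
    return BifurcationBranch(param_name, values, all_eqs, events)


def phase_diagram(
    params: SignallingParams,
    jext_grid: Sequence[float],
    alpha_grid: Sequence[float],
    model: int = 2,
    n_starts: int = 12,
    seed: int = 0,
    V_local: float | None = None,
) -> np.ndarray:
    """Patterning map over (external trans-JAG1 level, JAG1-Notch affinity).

    Entry [i, j] is True iff a stable heterogeneous equilibrium (alternating
    tip/stalk fate) exists at Jext = jext_grid[i], alpha = alpha_grid[j].
    """
    out = np.zeros((len(jext_grid), len(alpha_grid)), dtype=bool)
    for j, alpha in enumerate(alpha_grid):
        p = params.with_(alpha=float(alpha))
        warm: list[np.ndarray] = []
        for i, jext in enumerate(jext_grid):
            eqs = find_equilibria(p, model, n_starts=n_starts, seed=seed,
                                  extra_trans=(0.0, float(jext)),
                                  V_local=V_local, warm_starts=warm)
            out[i, j] = any(
                e.stability == "stable" and e.sym_class == "heterogeneous" for e in eqs
            )
            warm = [e.state for e in eqs]
    return out
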