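"""Closed-form and semi-analytic steady states of the ligand subsystem.

At steady state, the free-DLL4 and free-JAG1 levels of the
DLL4/JAG1-Notch model decouple from the receptor variables and satisfy a
pair of coupled balance equations,

    bD - (beta + kt*Next)*D - 2*kho*D^2 - khe*J*D = 0
    bJ - (beta + alpha*kt*Next)*J - khe*D*J       = 0,

which reduce to a monic cubic in D (and an equivalent cubic in J) with
composite coefficients

    A1 = (beta + kt*Next)/(2*kho),     B1 = (beta + alpha*kt*Next)/khe,
    A2 = (beta + kt*Next)/khe,         B2 = 2*kho/khe^2.

When heterodimerization is strong (khe much larger than beta + kt*Next and
kho), the cubics degenerate to a mutual-inactivation rule: whichever ligand
is produced faster wins and the other is driven to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import ReversibleBindingParams, SignallingParams

__all__ = [
    "DecoupledRegimeError",
    "SteadyStateCubic",
    "LigandSteadyState",
    "ligand_cubic",
    "solve_ligand_steady_state",
    "strong_het_limit",
    "ligand_monotonicity",
    "reversible_equivalent_khe",
]


class DecoupledRegimeError(ValueError):
    """khe = 0: the ligands decouple and the cubic formulation is undefined."""


@dataclass(frozen=True)
class SteadyStateCubic:
    """Composite coefficients and the monic ligand cubics.

    ``cubic_D`` and ``cubic_J`` list the coefficients highest power first,
    [1, c2, c1, c0], of the cubics satisfied by steady free DLL4 and free
    JAG1 respectively.
    """

    A1: float
    B1: float
    A2: float
    B2: float
    cubic_D: tuple[float, float, float, float]
    cubic_J: tuple[float, float, float, float]

    def evaluate(self, D) -> float | np.ndarray:
        """Evaluate F(D; bD, bJ), the monic D-cubic, at a point."""
        return np.polyval(self.cubic_D, D)


def ligand_cubic(params: SignallingParams, Next: float = 0.0) -> SteadyStateCubic:
    """Build the steady-state cubics of the ligand subsystem.

    Requires khe > 0 and kho > 0 (the composites divide by both); with
    khe = 0 a :class:`DecoupledRegimeError` signals that the decoupled
    quadratic/linear path must be used instead.
    """
    if Next < 0:
        raise ValueError("Next must be >= 0")
    p = params
    if p.khe == 0:
        raise DecoupledRegimeError(
            "khe = 0 decouples the ligands; use solve_ligand_steady_state, "
            "which handles this regime directly"
        )
    if p.kho == 0:
        raise ValueError("ligand_cubic requires kho > 0")
    g = p.beta + p.kt * Next            # effective DLL4 removal rate
    ga = p.beta + p.alpha * p.kt * Next  # effective JAG1 removal rate
    A1 = g / (2.0 * p.kho)
    B1 = ga / p.khe
    A2 = g / p.khe
    B2 = 2.0 * p.kho / p.khe**2
    cubic_D = (
        1.0,
        A1 + B1,
        (p.bJ - p.bD) / (2.0 * p.kho) + A1 * B1,
        -p.bD / (2.0 * p.kho) * B1,
    )
    cubic_J = (
        1.0,
        (p.bD - p.bJ) / ga + A2 - ga * B2,
        2.0 * p.bJ * B2 - p.bJ * A2 / ga,
        -p.bJ**2 * B2 / ga,
    )
    return SteadyStateCubic(A1=A1, B1=B1, A2=A2, B2=B2, cubic_D=cubic_D, cubic_J=cubic_J)


@dataclass(frozen=True)
class LigandSteadyState:
    """Steady free-ligand levels and the residuals of the balance equations."""

    Dbar: float
    Jbar: float
    residual_D: float
    residual_J: float


def _balance_residuals(D, J, p: SignallingParams, Next: float) -> tuple[float, float]:
    g = p.beta + p.kt * Next
    ga = p.beta + p.alpha * p.kt * Next
    rD = p.bD - g * D - 2.0 * p.kho * D * D - p.khe * J * D
    rJ = p.bJ - ga * J - p.khe * D * J
    return float(rD), float(rJ)


def _polish_root(coeffs, x0: float, iters: int = 30) -> float:
    """Newton-polish a cubic root; fall back to the input on stagnation."""
    c = np.asarray(coeffs, dtype=float)
    dc = np.polyder(c)
    x = float(x0)
    for _ in range(iters):
        f = np.polyval(c, x)
        fp = np.polyval(dc, x)
        if fp == 0:
            break
        step = f / fp
        x_new = x - step
        if not np.isfinite(x_new):
            return float(x0)
        if abs(step) <= 1e-15 * max(abs(x), 1.0):
            x = x_new
            break
        x = x_new
    return x


def solve_ligand_steady_state(params: SignallingParams, Next: float = 0.0,
                              residual_tol: float | None = None) -> LigandSteadyState:
    """Steady free DLL4 and free JAG1 for a single cell facing trans Notch ``Next``.

    Solves the ligand cubic via companion-matrix eigenvalues (`numpy.roots`),
    Newton-polishes the real nonnegative roots, recovers Jbar from the JAG1
    balance, and returns the pair that zeroes both balance equations.  If
    several nonnegative roots qualify, the one reached by the ODE from zero
    initial conditions (smallest positive root; the ligand subsystem's
    attractor from below) is returned.  With khe = 0 the decoupled
    quadratic/linear solution is used.
    """
    p = params
    if Next < 0:
        raise ValueError("Next must be >= 0")
    g = p.beta + p.kt * Next
    ga = p.beta + p.alpha * p.kt * Next
    scale = max(p.bD, p.bJ, 1.0)
    if residual_tol is None:
        residual_tol = 1e-6 * scale

    if p.khe == 0:
        # Decoupled regime: quadratic in D, linear in J.
        if p.kho > 0:
            D = (-g + np.sqrt(g * g + 8.0 * p.kho * p.bD)) / (4.0 * p.kho)
        else:
            D = p.bD / g
        J = p.bJ / ga
        rD, rJ = _balance_residuals(D, J, p, Next)
        return LigandSteadyState(float(D), float(J), abs(rD), abs(rJ))

    if p.kho == 0:
        # No homodimerization: the D-balance is quadratic in D once J is
        # eliminated; solve the 2x2 system by substitution.
        # bD - g*D - khe*D*bJ/(ga + khe*D) = 0  ->  quadratic in D.
        a = -g * p.khe
        b = p.bD * p.khe - g * ga - p.khe * p.bJ
        c = p.bD * ga
        disc = b * b - 4.0 * a * c
        roots = [r for r in np.roots([a, b, c]) if np.isreal(r) and r.real >= 0] if disc >= 0 else []
        candidates = sorted(float(r.real) for r in roots)
    else:
        cubic = ligand_cubic(p, Next)
        roots = np.roots(cubic.cubic_D)
        real = roots[np.abs(roots.imag) < 1e-8 * max(1.0, np.abs(roots).max())].real
        candidates = sorted(
            _polish_root(cubic.cubic_D, r) for r in real if r >= -1e-9
        )
        candidates = [max(r, 0.0) for r in candidates]

    consistent = []
    for D in candidates:
        J = p.bJ / (ga + p.khe * D)
        rD, rJ = _balance_residuals(D, J, p, Next)
        if abs(rD) < residual_tol and abs(rJ) < residual_tol and J >= 0:
            consistent.append(LigandSteadyState(float(D), float(J), abs(rD), abs(rJ)))
    if not consistent:
        raise RuntimeError(
            "no nonnegative root consistent with both balance equations; "
            f"candidate roots: {candidates}"
        )
    if len(consistent) > 1:
        # Multiple consistent roots: pick the attractor reached by the ODE
        # from zero initial conditions.
        from .model_core import integrate

        traj = integrate(
            lambda y: _rhs_dj(y, p, g, ga),
            np.zeros(2), h=0.01, t_end=2000.0, steady_tol=1e-9,
            species=("D", "J"),
        )
        D_ode = float(traj.final_state[0, 0])
        consistent.sort(key=lambda ss: abs(ss.Dbar - D_ode))
    return consistent[0]


def _rhs_dj(y, p: SignallingParams, g: float, ga: float) -> np.ndarray:
    """Closed (D, J) ligand subsystem used for the multiple-root tie-break."""
    D, J = y[:, 0], y[:, 1]
    out = np.empty_like(y)
    out[:, 0] = p.bD - g * D - 2.0 * p.kho * D * D - p.khe * J * D
    out[:, 1] = p.bJ - ga * J - p.khe * D * J
    return out


def strong_het_limit(params: SignallingParams, Next: float = 0.0) -> LigandSteadyState:
    """Mutual-inactivation limit of very strong DLL4-JAG1 heterodimerization.

    When khe dominates both beta + kt*Next and kho, the ligand produced
    faster survives and the other vanishes: for bD > bJ,
    Dbar = sqrt(((beta+kt*Next)/(4*kho))^2 + (bD-bJ)/(2*kho)) - (beta+kt*Next)/(4*kho)
    with Jbar = 0; for bJ > bD, Dbar = 0 and
    Jbar = (bJ-bD)/(beta + alpha*kt*Next); equal rates annihilate both.
    """
    p = params
    if Next < 0:
        raise ValueError("Next must be >= 0")
    g = p.beta + p.kt * Next
    ga = p.beta + p.alpha * p.kt * Next
    bD = float(np.asarray(p.bD))
    bJ = float(np.asarray(p.bJ))
    if bD > bJ:
        if p.kho == 0:
            raise ZeroDivisionError("the bD > bJ limit requires kho > 0")
        q = g / (4.0 * p.kho)
        D = float(np.sqrt(q * q + (bD - bJ) / (2.0 * p.kho)) - q)
        J = 0.0
    elif bJ > bD:
        D = 0.0
        J = float((bJ - bD) / ga)
    else:
        D = J = 0.0
    rD, rJ = _balance_residuals(D, J, p, Next)
    return LigandSteadyState(D, J, abs(rD), abs(rJ))


def ligand_monotonicity(params: SignallingParams, Next: float = 0.0,
                        delta: float = 1e-3) -> tuple[int, int, int, int]:
    """Signs of (dDbar/dbD, dDbar/dbJ, dJbar/dbD, dJbar/dbJ).

    Central differences with a relative step ``delta``; +1 / -1 for a sign
    resolved beyond numerical noise, 0 when the derivative is indeterminate
    at the working precision (e.g. exactly zero coupling with khe = 0).
    For valid positive parameters the pattern is (+, -, -, +): raising one
    ligand's production depletes the other through heterodimerization.
    """
    p = params

    def solve(bD, bJ):
        ss = solve_ligand_steady_state(p.with_(bD=bD, bJ=bJ), Next)
        return ss.Dbar, ss.Jbar

    bD0 = float(np.asarray(p.bD))
    bJ0 = float(np.asarray(p.bJ))
    out = []
    for which in ("bD", "bJ"):
        b0 = bD0 if which == "bD" else bJ0
        db = delta * max(abs(b0), 1.0)
        lo = solve(b0 - db, bJ0) if which == "bD" else solve(bD0, b0 - db)
        hi = solve(b0 + db, bJ0) if which == "bD" else solve(bD0, b0 + db)
        for comp in (0, 1):  # D then J
            diff = hi[comp] - lo[comp]
            noise = 1e-9 * max(abs(hi[comp]), abs(lo[comp]), 1.0)
            out.append(0 if abs(diff) <= noise else (1 if diff > 0 else -1))
    # out is ordered (dD/dbD, dJ/dbD, dD/dbJ, dJ/dbJ); reorder to spec.
    return (out[0], out[2], out[1], out[3])


def reversible_equivalent_khe(rev: ReversibleBindingParams, beta: float) -> float:
    """Effective irreversible heterodimerization rate of the reversible model.

    A reversible DJ complex with association k+, dissociation k- and
    degradation beta removes ligand monomers at the same steady-state rate
    as an irreversible reaction with khe = beta*k+ / (beta + k-).
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return beta * rev.kplus / (beta + rev.kminus)
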