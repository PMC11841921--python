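"""Core types and dynamics of the DLL4/JAG1-Notch signalling models.

Two endothelial signalling networks are implemented as mass-action ODE
systems in units of molecules/cell and hours:

* model 1 -- DLL4/JAG1-Notch: free DLL4 monomer (D), free JAG1 monomer (J),
  cis-inhibitory DLL4 homodimer (C), free Notch1 receptor (N) and Notch
  activity / free intracellular domain (S).  DLL4 homodimerizes (rate kho)
  into the cis-inhibitory species C, DLL4 and JAG1 heterodimerize (rate khe)
  into an inert complex that sequesters both monomers, trans ligand on
  neighbouring cells (Dext, Jext) activates Notch with an affinity ratio
  alpha for JAG1 relative to DLL4, and trans Notch (Next) consumes ligand.
* model 2 -- DLL4/JAG1-Notch-VEGF: adds free VEGFR2 (R) and VEGFR2
  activity (V).  Local free VEGF binds VEGFR2 (rate kv) producing V, V
  upregulates DLL4 production through a Hill function, and Notch activity S
  downregulates VEGFR2 production through a second Hill function -- the
  lateral-inhibition feedback that selects tip and stalk cells.

A variant of model 1 with reversible DLL4-JAG1 heterodimerization (explicit
DJ complex with association/dissociation rates k+/k-) is also provided; its
steady states map onto model 1 with an effective khe = beta*k+/(beta+k-).

All right-hand sides are vectorized over a leading cell axis, so a tissue of
n cells integrates as a single (n, n_species) array.  Parameters may be
scalars or per-cell arrays of matching length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "MODEL1_SPECIES",
    "MODEL2_SPECIES",
    "REVERSIBLE_SPECIES",
    "HillSpec",
    "SignallingParams",
    "ReversibleBindingParams",
    "CellState",
    "TransInput",
    "Trajectory",
    "IntegrationError",
    "hill",
    "rhs_model1",
    "rhs_model2",
    "rhs_reversible",
    "integrate",
    "species_for_model",
]

MODEL1_SPECIES: tuple[str, ...] = ("D", "J", "C", "N", "S")
MODEL2_SPECIES: tuple[str, ...] = ("D", "J", "C", "N", "S", "R", "V")
REVERSIBLE_SPECIES: tuple[str, ...] = ("D", "J", "C", "N", "S", "DJ")


def species_for_model(model: int) -> tuple[str, ...]:
    """Species order for model 1 or model 2 state arrays."""
    if model == 1:
        return MODEL1_SPECIES
    if model == 2:
        return MODEL2_SPECIES
    raise ValueError(f"model must be 1 or 2, got {model!r}")


def _all_nonneg(x) -> bool:
    return bool(np.all(np.asarray(x) >= 0))


@dataclass(frozen=True)
class HillSpec:
    """Shape of a Hill regulatory function H(x) = (lam*x^n + theta^n)/(x^n + theta^n).

    theta is the half-saturation constant (molecules), lam the fold change
    (lam > 1 upregulates, lam < 1 downregulates, lam = 0 switches production
    off at saturation) and n the Hill exponent.
    """

    theta: float
    lam: float
    n: float

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not self.lam >= 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")


def hill(x, spec: HillSpec):
    """Hill regulatory function H(x; theta, lam, n).

    Returns (lam*x^n + theta^n) / (x^n + theta^n); the value always lies
    between min(1, lam) and max(1, lam).  ``x`` may be a scalar or array and
    must be nonnegative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill() requires x >= 0")
    xn = x**spec.n
    tn = spec.theta**spec.n
    out = (spec.lam * xn + tn) / (xn + tn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SignallingParams:
    """Rate constants and production rates of models 1 and 2 (Table-1 symbols).

    Production rates in molecules/hour, first-order rates in 1/hour,
    bimolecular rates in 1/(molecule*hour).  Every numeric field may be a
    scalar or a per-cell array (broadcast against the cell axis of the
    state).  ``alpha`` is the trans JAG1-Notch1 : DLL4-Notch1 affinity
    ratio; ``Vext_base`` the free-VEGF level at the angiogenic front.
    """

    bD: float | np.ndarray = 100.0
    bJ: float | np.ndarray = 100.0
    bN: float | np.ndarray = 500.0
    bR: float | np.ndarray = 800.0
    beta: float = 0.1
    betaS: float = 0.5
    kho: float = 1e-4
    khe: float | np.ndarray = 1e-3
    kt: float = 5e-5
    kci: float = 6e-4
    kv: float = 5e-5
    alpha: float = 1e-4
    hill_D: HillSpec = field(default_factory=lambda: HillSpec(200.0, 10.0, 2.0))
    hill_R: HillSpec = field(default_factory=lambda: HillSpec(30.0, 0.0, 2.0))
    Vext_base: float = 2500.0

    def __post_init__(self):
        if not np.all(np.asarray(self.beta) > 0):
            raise ValueError("beta must be > 0")
        if not np.all(np.asarray(self.betaS) > 0):
            raise ValueError("betaS must be > 0")
        for name in ("bD", "bJ", "bN", "bR", "kho", "khe", "kt", "kci", "kv", "Vext_base"):
            if not _all_nonneg(getattr(self, name)):
                raise ValueError(f"{name} must be >= 0")
        if not (np.all(np.asarray(self.alpha) >= 0) and np.all(np.asarray(self.alpha) <= 1)):
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def table1(cls) -> "SignallingParams":
        """Baseline parameter set used throughout the simulations."""
        return cls()

    def with_(self, **overrides) -> "SignallingParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class ReversibleBindingParams:
    """Association (k+) and dissociation (k-) rates of the explicit DJ complex.

    Scalars, or per-cell arrays for batched integration.
    """

    kplus: float | np.ndarray
    kminus: float | np.ndarray

    def __post_init__(self):
        if not (_all_nonneg(self.kplus) and _all_nonneg(self.kminus)):
            raise ValueError("kplus and kminus must be >= 0")


@dataclass(frozen=True)
class TransInput:
    """Trans species presented to a cell by its neighbours.

    Dext/Jext are the trans DLL4/JAG1 levels driving Notch activation;
    Next is the trans Notch level that consumes the cell's own ligand.
    Scalars for a single cell, per-cell arrays for a tissue.
    """

    Dext: float | np.ndarray = 0.0
    Jext: float | np.ndarray = 0.0
    Next: float | np.ndarray = 0.0

    def __post_init__(self):
        for name in ("Dext", "Jext", "Next"):
            if not _all_nonneg(getattr(self, name)):
                raise ValueError(f"{name} must be >= 0")


class _Trans:
    """Non-validating trans-input holder for inner loops (RK4 stages, Newton
    iterates), where intermediate states may dip infinitesimally negative."""

    __slots__ = ("Dext", "Jext", "Next")

    def __init__(self, Dext=0.0, Jext=0.0, Next=0.0):
        self.Dext = Dext
        self.Jext = Jext
        self.Next = Next


def _hill_core(x, spec: HillSpec):
    """Hill function tolerant of tiny negative excursions (clipped to 0)."""
    xn = np.maximum(x, 0.0) ** spec.n
    tn = spec.theta**spec.n
    return (spec.lam * xn + tn) / (xn + tn)


@dataclass
class CellState:
    """Per-cell species levels (molecules). R/V exist only for model 2, DJ only
    for the reversible-binding variant."""

    D: float = 0.0
    J: float = 0.0
    C: float = 0.0
    N: float = 0.0
    S: float = 0.0
    R: float | None = None
    V: float | None = None
    DJ: float | None = None

    def to_array(self, species: Sequence[str] = MODEL1_SPECIES) -> np.ndarray:
        vals = []
        for name in species:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"CellState is missing required species {name!r}")
            vals.append(float(v))
        return np.array(vals)

    @classmethod
    def from_array(cls, arr, species: Sequence[str] = MODEL1_SPECIES) -> "CellState":
        arr = np.asarray(arr, dtype=float).ravel()
        if arr.size != len(species):
            raise ValueError(f"array length {arr.size} != {len(species)} species")
        return cls(**dict(zip(species, arr.tolist())))


def _state_2d(y, species) -> tuple[np.ndarray, bool]:
    """Coerce CellState / 1-D / 2-D input to (n_cells, n_species); report if 1-D."""
    if isinstance(y, CellState):
        return y.to_array(species)[None, :], True
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim != 2 or arr.shape[1] != len(species):
        raise ValueError(f"state must have {len(species)} species on the last axis")
    return arr, False


def rhs_model1(state, params: SignallingParams, trans: TransInput | None = None):
    """Time derivative of the DLL4/JAG1-Notch model (no VEGF module).

    ``state`` may be a CellState, a length-5 vector (D, J, C, N, S) or an
    (n_cells, 5) array; the result has the same shape/type.
    """
    trans = trans or TransInput()
    y, squeeze = _state_2d(state, MODEL1_SPECIES)
    out = _rhs1_core(y, params, trans)
    if isinstance(state, CellState):
        return CellState.from_array(out[0], MODEL1_SPECIES)
    return out[0] if squeeze else out


def _rhs1_core(y, p: SignallingParams, t: TransInput) -> np.ndarray:
    D, J, C, N, S = (y[:, i] for i in range(5))
    akt = p.alpha * p.kt
    out = np.empty_like(y)
    out[:, 0] = p.bD - p.beta * D - 2.0 * p.kho * D * D - p.khe * J * D - p.kt * t.Next * D
    out[:, 1] = p.bJ - p.beta * J - p.khe * D * J - akt * t.Next * J
    out[:, 2] = p.kho * D * D - p.beta * C - p.kci * N * C
    out[:, 3] = p.bN - p.beta * N - p.kci * C * N - p.kt * t.Dext * N - akt * t.Jext * N
    out[:, 4] = p.kt * t.Dext * N + akt * t.Jext * N - p.betaS * S
    return out


def rhs_model2(state, params: SignallingParams, V_local, trans: TransInput | None = None):
    """Time derivative of the DLL4/JAG1-Notch-VEGF model.

    ``V_local`` is the free-VEGF level at the cell (scalar or per-cell).
    DLL4 production is modulated by H(V; hill_D) where V is the cell's
    VEGFR2 activity; VEGFR2 production by H(S; hill_R).
    """
    trans = trans or TransInput()
    if isinstance(state, CellState) and (state.R is None or state.V is None):
        raise ValueError("model 2 requires R and V in the state")
    y, squeeze = _state_2d(state, MODEL2_SPECIES)
    out = _rhs2_core(y, params, np.asarray(V_local, dtype=float), trans)
    if isinstance(state, CellState):
        return CellState.from_array(out[0], MODEL2_SPECIES)
    return out[0] if squeeze else out


def _rhs2_core(y, p: SignallingParams, V_local, t: TransInput) -> np.ndarray:
    D, J, C, N, S, R, V = (y[:, i] for i in range(7))
    akt = p.alpha * p.kt
    out = np.empty_like(y)
    out[:, 0] = (
        _hill_core(V, p.hill_D) * p.bD
        - p.beta * D - 2.0 * p.kho * D * D - p.khe * J * D - p.kt * t.Next * D
    )
    out[:, 1] = p.bJ - p.beta * J - p.khe * D * J - akt * t.Next * J
    out[:, 2] = p.kho * D * D - p.beta * C - p.kci * N * C
    out[:, 3] = p.bN - p.beta * N - p.kci * C * N - p.kt * t.Dext * N - akt * t.Jext * N
    out[:, 4] = p.kt * t.Dext * N + akt * t.Jext * N - p.betaS * S
    out[:, 5] = _hill_core(S, p.hill_R) * p.bR - p.beta * R - p.kv * V_local * R
    out[:, 6] = p.kv * V_local * R - p.betaS * V
    return out


def rhs_reversible(state, params: SignallingParams, rev: ReversibleBindingParams,
                   trans: TransInput | None = None):
    """Model 1 with an explicit, reversible DLL4-JAG1 complex DJ.

    D and J associate at rate k+ and the complex dissociates at rate k-
    (and degrades at beta); ``params.khe`` is ignored.  Species order
    (D, J, C, N, S, DJ).
    """
    trans = trans or TransInput()
    y, squeeze = _state_2d(state, REVERSIBLE_SPECIES)
    out = _rhs_rev_core(y, params, rev, trans)
    if isinstance(state, CellState):
        return CellState.from_array(out[0], REVERSIBLE_SPECIES)
    return out[0] if squeeze else out


def _rhs_rev_core(y, p: SignallingParams, rev: ReversibleBindingParams,
                  t: TransInput) -> np.ndarray:
    D, J, C, N, S, DJ = (y[:, i] for i in range(6))
    akt = p.alpha * p.kt
    assoc = rev.kplus * D * J
    out = np.empty_like(y)
    out[:, 0] = p.bD - p.beta * D - 2.0 * p.kho * D * D - assoc + rev.kminus * DJ - p.kt * t.Next * D
    out[:, 1] = p.bJ - p.beta * J - assoc + rev.kminus * DJ - akt * t.Next * J
    out[:, 2] = p.kho * D * D - p.beta * C - p.kci * N * C
    out[:, 3] = p.bN - p.beta * N - p.kci * C * N - p.kt * t.Dext * N - akt * t.Jext * N
    out[:, 4] = p.kt * t.Dext * N + akt * t.Jext * N - p.betaS * S
    out[:, 5] = assoc - rev.kminus * DJ - p.beta * DJ
    return out


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters NaN/Inf or a genuine negative state."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} at t = {t:.6g} h")
        self.t = t


@dataclass
class Trajectory:
    """Recorded output of a fixed-step integration.

    ``states`` has shape (n_times, n_cells, n_species) in the order given by
    ``species``; ``converged`` is True when the maximum absolute time
    derivative fell below the steady tolerance before t_end, and
    ``final_residual`` is that maximum at the last step (molecules/hour).
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple[str, ...]
    converged: bool
    final_residual: float

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def series(self, name: str, cell: int = 0) -> np.ndarray:
        """Time series of one species in one cell."""
        return self.states[:, cell, self.species.index(name)]


# Values in [-NEG_CLIP, 0) are floating-point noise and are clipped to zero;
# anything below -NEG_CLIP is treated as a genuine violation of positivity.
NEG_CLIP = 1e-9


def _resolve_clamps(clamps, species, n_cells):
    """Turn {species: value} into (index, value-array-or-scalar, mask) triples.

    A scalar value clamps every cell; an array of length n_cells clamps
    per-cell, with NaN entries meaning 'leave this cell free'.
    """
    resolved = []
    for name, value in (clamps or {}).items():
        if name not in species:
            raise ValueError(f"cannot clamp unknown species {name!r}; have {species}")
        idx = species.index(name)
        val = np.asarray(value, dtype=float)
        if val.ndim == 0:
            resolved.append((idx, float(val), None))
        else:
            if val.size != n_cells:
                raise ValueError(f"clamp for {name!r} has length {val.size}, expected {n_cells}")
            mask = ~np.isnan(val)
            resolved.append((idx, val, mask))
    return resolved


def _apply_clamps(y, resolved):
    for idx, val, mask in resolved:
        if mask is None:
            y[:, idx] = val
        else:
            y[mask, idx] = val[mask]


def integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    init,
    h: float = 0.01,
    t_end: float = 1000.0,
    clamps: Mapping[str, float | np.ndarray] | None = None,
    steady_tol: float = 1e-6,
    species: Sequence[str] = MODEL1_SPECIES,
    record_every: int | None = None,
) -> Trajectory:
    """Classical fixed-step fourth-order Runge-Kutta integration.

    ``rhs`` maps an (n_cells, n_species) state array to its derivative (it
    is responsible for any cell coupling, so trans inputs are re-evaluated
    at every RK4 stage).  Clamped species are reset to their clamp value
    after every step.  Integration stops early, with ``converged`` set,
    once the maximum |dy/dt| over free entries drops below ``steady_tol``.

    ``record_every`` controls output thinning (in steps); by default at most
    ~1000 frames are kept.  The final state is always recorded.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    if t_end < h:
        raise ValueError("t_end must be >= h")
    species = tuple(species)
    y, _ = _state_2d(init, species)
    y = y.copy()
    if np.any(y < 0):
        raise ValueError("initial state must be nonnegative")
    n_cells = y.shape[0]
    resolved = _resolve_clamps(clamps, species, n_cells)
    _apply_clamps(y, resolved)

    free = np.ones_like(y, dtype=bool)
    for idx, _, mask in resolved:
        if mask is None:
            free[:, idx] = False
        else:
            free[mask, idx] = False

    if resolved:
        # Hold clamped entries exactly: zero their derivatives inside the
        # RK4 stages (a post-step reset alone would let them drift within a
        # step, biasing coupled species by O(h)).
        raw_rhs = rhs

        def rhs(y):
            d = raw_rhs(y)
            for idx, _, mask in resolved:
                if mask is None:
                    d[:, idx] = 0.0
                else:
                    d[mask, idx] = 0.0
            return d

    n_steps = int(round(t_end / h))
    if record_every is None:
        record_every = max(1, n_steps // 1000)

    times = [0.0]
    frames = [y.copy()]
    converged = False
    resid = float("inf")
    t = 0.0
    h2 = 0.5 * h
    h6 = h / 6.0
    for step in range(1, n_steps + 1):
        k1 = rhs(y)
        resid = float(np.max(np.abs(k1[free]))) if free.any() else 0.0
        if resid < steady_tol:
            converged = True
            break
        k2 = rhs(y + h2 * k1)
        k3 = rhs(y + h2 * k2)
        k4 = rhs(y + h * k3)
        y = y + h6 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = step * h
        if not np.isfinite(y).all():
            raise IntegrationError("non-finite state encountered", t)
        ymin = y.min()
        if ymin < 0.0:
            if ymin < -NEG_CLIP:
                raise IntegrationError(
                    f"state went negative ({ymin:.3e}), below the noise threshold", t
                )
            np.clip(y, 0.0, None, out=y)
        _apply_clamps(y, resolved)
        if step % record_every == 0:
            times.append(t)
            frames.append(y.copy())

    if times[-1] != t:
        times.append(t)
        frames.append(y.copy())
    if converged:
        final_resid = resid
    else:
        k = rhs(y)
        final_resid = float(np.max(np.abs(k[free]))) if free.any() else 0.0
        converged = final_resid < steady_tol
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(frames),
        species=species,
        converged=converged,
        final_residual=final_resid,
    )
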