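"""Community state, the three dynamical models, and the stiff ODE integrator.

Three variants of the replicator dynamics are implemented:

* **Mass-regulated** (the main model): resource concentration fixed at ``r``;
  the per-capita outflow phi is dynamically adjusted to
  ``phi = (r/m) * sum_j c_j x_j`` (the normalized production), which drives the
  total strand concentration ``mu = sum_i (x_i + 2 y_i)`` logistically toward
  the target ``m``.
* **Chemostat**: constant dilution rate phi, with the resource concentration an
  explicit dynamical variable fed at inflow concentration rho.
* **Phenomenological**: one power-law equation per species,
  ``dz/dt = k z^p - phi z`` with ``phi = (sum_j k_j z_j^{p_j}) / m``; no
  strand structure.

``integrate`` drives any of the three with SciPy's BDF method, detects steady
state early, clips harmless negative round-off, and refuses to return partial
output silently on solver failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    ChemostatEnvironment,
    MassEnvironment,
    PhenomenologicalSpecies,
    SpeciesKinetics,
)

__all__ = [
    "CommunityState",
    "Trajectory",
    "IntegrationError",
    "normalized_production",
    "total_concentrations",
    "mass_regulated_rhs",
    "chemostat_rhs",
    "phenomenological_rhs",
    "MassRegulatedModel",
    "ChemostatModel",
    "PhenomenologicalModel",
    "integrate",
]

#: default integration horizon (time units); equilibrium is virtually always
#: reached much earlier and detected by the steady-state criterion
DEFAULT_T_END = 1.0e6
DEFAULT_RTOL = 1.0e-10
DEFAULT_ATOL = 1.0e-12
#: relative steady-state criterion on max_i |d mu_i / dt| / max(mu, 1e-12);
#: tight enough that species persisting at ~1e-5 of the total mass are fully
#: relaxed when the run stops early
STEADY_TOL = 1.0e-12
#: entries in (-CLIP_TOL, 0) are round-off and clipped to zero; anything more
#: negative signals a misconfigured solver and aborts
CLIP_TOL = 1.0e-9


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the solver's diagnostics."""


@dataclass
class CommunityState:
    """Concentrations of single- (x) and double-stranded (y) replicators.

    ``rvar`` carries the current resource concentration in the chemostat
    model and is None otherwise.
    """

    x: np.ndarray
    y: np.ndarray
    rvar: Optional[float] = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError(
                f"x and y must have equal length, got {self.x.shape} and {self.y.shape}"
            )
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("concentrations must be non-negative")
        if self.rvar is not None:
            self.rvar = float(self.rvar)
            if self.rvar < 0:
                raise ValueError("resource concentration must be non-negative")

    @property
    def n_species(self) -> int:
        return self.x.size

    @property
    def mu(self) -> np.ndarray:
        """Per-species total strand concentration mu_i = x_i + 2 y_i."""
        return self.x + 2.0 * self.y

    @property
    def mu_total(self) -> float:
        return float(np.sum(self.mu))


def total_concentrations(state: CommunityState) -> tuple[np.ndarray, float]:
    """Per-species totals mu_i = x_i + 2 y_i and the community total mu."""
    mu = state.mu
    return mu, float(np.sum(mu))


def normalized_production(
    x: np.ndarray, kins: Sequence[SpeciesKinetics], env: MassEnvironment
) -> float:
    """Normalized production phi = (r/m) * sum_j c_j x_j."""
    x = np.asarray(x, dtype=float)
    if x.size != len(kins):
        raise ValueError(
            f"state has {x.size} species but {len(kins)} kinetic parameter sets given"
        )
    c = np.array([k.c for k in kins], dtype=float)
    return float(env.r / env.m * np.dot(c, x))


class _KineticsArrays:
    """Vectorised view of a list of SpeciesKinetics."""

    def __init__(self, kins: Sequence[SpeciesKinetics]):
        self.kins = list(kins)
        self.a = np.array([k.a for k in kins], dtype=float)
        self.b = np.array([k.b for k in kins], dtype=float)
        self.c = np.array([k.c for k in kins], dtype=float)
        self.labels = [k.label or str(i + 1) for i, k in enumerate(kins)]
        self.n = len(self.kins)


def _strand_rhs(x, y, a, b, c, r, phi):
    """Common strand kinetics: association, dissociation, replication, outflow."""
    assoc = a * x * x
    dx = -2.0 * assoc + 2.0 * b * y - r * c * x - phi * x
    dy = assoc - b * y + r * c * x - phi * y
    return dx, dy


def mass_regulated_rhs(
    state: CommunityState, kins: Sequence[SpeciesKinetics], env: MassEnvironment
) -> CommunityState:
    """Time derivative of the mass-regulated dynamics.

    phi is computed internally from the current state.  The aggregate identity
    d mu / dt = phi (m - mu) follows by summation and is exercised by the
    property tests.
    """
    if state.n_species != len(kins):
        raise ValueError("state and kinetics dimension mismatch")
    ka = _KineticsArrays(kins)
    phi = normalized_production(state.x, kins, env)
    dx, dy = _strand_rhs(state.x, state.y, ka.a, ka.b, ka.c, env.r, phi)
    return _derivative_state(dx, dy)


def _derivative_state(dx, dy, dr: Optional[float] = None) -> CommunityState:
    # bypass the non-negativity check: derivatives may legitimately be negative
    st = CommunityState.__new__(CommunityState)
    st.x = np.asarray(dx, dtype=float)
    st.y = np.asarray(dy, dtype=float)
    st.rvar = dr
    return st


def chemostat_rhs(
    state: CommunityState, kins: Sequence[SpeciesKinetics], env: ChemostatEnvironment
) -> CommunityState:
    """Time derivative of the chemostat dynamics (state carries the resource)."""
    if state.rvar is None:
        raise ValueError("chemostat state must carry a resource concentration (rvar)")
    if state.n_species != len(kins):
        raise ValueError("state and kinetics dimension mismatch")
    ka = _KineticsArrays(kins)
    r = state.rvar
    dx, dy = _strand_rhs(state.x, state.y, ka.a, ka.b, ka.c, r, env.phi)
    dr = -r * float(np.dot(ka.c, state.x)) + (env.rho - r) * env.phi
    return _derivative_state(dx, dy, dr)


def phenomenological_rhs(
    z: np.ndarray, species: Sequence[PhenomenologicalSpecies], m: float
) -> np.ndarray:
    """Time derivative dz_i/dt = k_i z_i^{p_i} - phi z_i of the power-law model."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("concentrations must be non-negative")
    if z.size != len(species):
        raise ValueError("state and species dimension mismatch")
    k = np.array([s.k for s in species], dtype=float)
    p = np.array([s.p for s in species], dtype=float)
    production = k * np.power(z, p)
    phi = float(np.sum(production)) / m
    return production - phi * z


# ---------------------------------------------------------------------------
# flat-vector model wrappers for the integrator


class MassRegulatedModel:
    """Flat-vector form of the mass-regulated dynamics: state = [x..., y...]."""

    has_resource = False

    def __init__(self, kins: Sequence[SpeciesKinetics], env: MassEnvironment):
        self.ka = _KineticsArrays(kins)
        self.env = env

    @property
    def labels(self):
        return self.ka.labels

    def pack(self, state: CommunityState) -> np.ndarray:
        return np.concatenate([state.x, state.y])

    def unpack(self, v: np.ndarray) -> CommunityState:
        n = self.ka.n
        return CommunityState(np.maximum(v[:n], 0.0), np.maximum(v[n : 2 * n], 0.0))

    def __call__(self, t: float, v: np.ndarray) -> np.ndarray:
        n = self.ka.n
        x, y = v[:n], v[n : 2 * n]
        phi = self.env.r / self.env.m * float(np.dot(self.ka.c, x))
        dx, dy = _strand_rhs(x, y, self.ka.a, self.ka.b, self.ka.c, self.env.r, phi)
        return np.concatenate([dx, dy])

    def phi(self, v: np.ndarray) -> float:
        return self.env.r / self.env.m * float(np.dot(self.ka.c, v[: self.ka.n]))

    def steady_residual(self, v: np.ndarray) -> float:
        """max_i |d mu_i/dt| relative to the current total concentration."""
        n = self.ka.n
        dv = self(0.0, v)
        dmu = dv[:n] + 2.0 * dv[n : 2 * n]
        mu = float(np.sum(v[:n] + 2.0 * v[n : 2 * n]))
        return float(np.max(np.abs(dmu), initial=0.0) / max(mu, 1.0e-12))


class ChemostatModel:
    """Flat-vector chemostat dynamics: state = [x..., y..., r]."""

    has_resource = True

    def __init__(self, kins: Sequence[SpeciesKinetics], env: ChemostatEnvironment):
        self.ka = _KineticsArrays(kins)
        self.env = env

    @property
    def labels(self):
        return self.ka.labels

    def pack(self, state: CommunityState) -> np.ndarray:
        if state.rvar is None:
            raise ValueError("chemostat state needs a resource concentration")
        return np.concatenate([state.x, state.y, [state.rvar]])

    def unpack(self, v: np.ndarray) -> CommunityState:
        n = self.ka.n
        return CommunityState(
            np.maximum(v[:n], 0.0), np.maximum(v[n : 2 * n], 0.0), max(float(v[2 * n]), 0.0)
        )

    def __call__(self, t: float, v: np.ndarray) -> np.ndarray:
        n = self.ka.n
        x, y, r = v[:n], v[n : 2 * n], v[2 * n]
        dx, dy = _strand_rhs(x, y, self.ka.a, self.ka.b, self.ka.c, r, self.env.phi)
        dr = -r * float(np.dot(self.ka.c, x)) + (self.env.rho - r) * self.env.phi
        return np.concatenate([dx, dy, [dr]])

    def phi(self, v: np.ndarray) -> float:
        return self.env.phi

    def steady_residual(self, v: np.ndarray) -> float:
        n = self.ka.n
        dv = self(0.0, v)
        dmu = np.append(dv[:n] + 2.0 * dv[n : 2 * n], dv[2 * n])
        mu = float(np.sum(v[:n] + 2.0 * v[n : 2 * n]) + v[2 * n])
        return float(np.max(np.abs(dmu), initial=0.0) / max(mu, 1.0e-12))


class PhenomenologicalModel:
    """Flat-vector power-law dynamics: state = z."""

    has_resource = False

    def __init__(self, species: Sequence[PhenomenologicalSpecies], m: float):
        if m <= 0:
            raise ValueError("target concentration m must be > 0")
        self.species = list(species)
        self.k = np.array([s.k for s in species], dtype=float)
        self.p = np.array([s.p for s in species], dtype=float)
        self.m = float(m)
        self.labels = [s.label or str(i + 1) for i, s in enumerate(species)]

    def pack(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float).copy()

    def unpack(self, v: np.ndarray) -> np.ndarray:
        return np.maximum(v, 0.0)

    def __call__(self, t: float, v: np.ndarray) -> np.ndarray:
        z = np.maximum(v, 0.0)
        production = self.k * np.power(z, self.p)
        phi = float(np.sum(production)) / self.m
        return production - phi * z

    def phi(self, v: np.ndarray) -> float:
        z = np.maximum(v, 0.0)
        return float(np.sum(self.k * np.power(z, self.p))) / self.m

    def steady_residual(self, v: np.ndarray) -> float:
        dv = self(0.0, v)
        mu = float(np.sum(np.maximum(v, 0.0)))
        return float(np.max(np.abs(dv), initial=0.0) / max(mu, 1.0e-12))


@dataclass
class Trajectory:
    """Time series of a community integration plus derived observables.

    For the phenomenological model ``y`` is None and ``x`` holds the single
    concentration variable z of each species.
    """

    times: np.ndarray
    x: np.ndarray
    y: Optional[np.ndarray]
    labels: list
    phi: np.ndarray
    rvar: Optional[np.ndarray] = None
    converged: bool = False
    t_converged: Optional[float] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def mu(self) -> np.ndarray:
        return self.x + 2.0 * self.y if self.y is not None else self.x

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu.sum(axis=1)

    def final_state(self) -> CommunityState:
        if self.y is None:
            raise ValueError("phenomenological trajectory has no strand structure")
        r = float(self.rvar[-1]) if self.rvar is not None else None
        return CommunityState(self.x[-1], self.y[-1], r)

    def species_count(self, threshold: float = 1.0e-7) -> int:
        """Number of species with final total concentration above threshold."""
        return int(np.sum(self.mu[-1] >= threshold))

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide table: time, x_<label>, y_<label>, mu_<label>, mu_total, phi."""
        data: dict = {"time": self.times}
        for j, lab in enumerate(self.labels):
            data[f"x_{lab}"] = self.x[:, j]
        if self.y is not None:
            for j, lab in enumerate(self.labels):
                data[f"y_{lab}"] = self.y[:, j]
        for j, lab in enumerate(self.labels):
            data[f"mu_{lab}"] = self.mu[:, j]
        data["mu_total"] = self.mu_total
        data["phi"] = self.phi
        if self.rvar is not None:
            data["r"] = self.rvar
        return pd.DataFrame(data)


def _save_grid(t0: float, t_end: float, n_save: int) -> np.ndarray:
    """Log-spaced checkpoints from t0 (or a small positive time) to t_end."""
    start = max(t0, t_end * 1.0e-8, 1.0e-3)
    if start >= t_end:
        return np.array([t_end])
    return np.unique(np.concatenate([np.geomspace(start, t_end, n_save), [t_end]]))


def _clip_negatives(v: np.ndarray, clip_tol: float) -> np.ndarray:
    worst = float(v.min(initial=0.0))
    if worst < -clip_tol:
        raise IntegrationError(
            f"state went negative beyond the clipping tolerance ({worst:.3e} < "
            f"-{clip_tol:.1e}); the solver is likely misconfigured"
        )
    return np.maximum(v, 0.0)


def integrate(
    model,
    state0,
    t_end: float = DEFAULT_T_END,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    steady_tol: float = STEADY_TOL,
    clip_tol: float = CLIP_TOL,
    n_save: int = 200,
    method: str = "BDF",
) -> Trajectory:
    """Integrate one of the three models to ``t_end`` or to steady state.

    The run stops early (with ``converged=True``) when the relative residual
    ``max_i |d mu_i/dt| / max(mu, 1e-12)`` drops below ``steady_tol``.  States
    are recorded on a log-spaced grid of ``n_save`` checkpoints.

    Raises
    ------
    IntegrationError
        If the underlying solver reports failure or the state leaves the
        admissible region by more than the clipping tolerance.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    v = np.asarray(model.pack(state0), dtype=float).copy()
    checkpoints = _save_grid(0.0, t_end, n_save)

    times = [0.0]
    states = [v.copy()]
    converged = model.steady_residual(v) < steady_tol
    t_converged = 0.0 if converged else None

    t_prev = 0.0
    if not converged:
        for t_next in checkpoints:
            sol = solve_ivp(
                model,
                (t_prev, t_next),
                v,
                method=method,
                rtol=rtol,
                atol=atol,
                dense_output=False,
            )
            if not sol.success:
                raise IntegrationError(
                    f"ODE solver failed on [{t_prev:g}, {t_next:g}]: {sol.message}"
                )
            v = _clip_negatives(sol.y[:, -1], clip_tol)
            times.append(t_next)
            states.append(v.copy())
            t_prev = t_next
            if model.steady_residual(v) < steady_tol:
                converged = True
                t_converged = t_next
                break

    states = np.asarray(states)
    times = np.asarray(times)
    phi = np.array([model.phi(s) for s in states])

    if isinstance(model, PhenomenologicalModel):
        return Trajectory(times, states, None, model.labels, phi, None, converged, t_converged)
    n = model.ka.n
    rvar = states[:, 2 * n] if model.has_resource else None
    return Trajectory(
        times, states[:, :n], states[:, n : 2 * n], model.labels, phi, rvar,
        converged, t_converged,
    )
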