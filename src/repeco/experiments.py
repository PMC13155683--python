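"""Computational experiments: parameter sweeps, the fluctuating-environment
protocol, and the three-model comparison.

Sweeps solve the analytic equilibrium on log-spaced grids of the target
replicator concentration ``m`` and/or the resource concentration ``r``.
Increasing ``m`` lowers the equilibrium normalized production and so raises
diversity; increasing ``r`` raises production and typically lowers diversity
(not necessarily monotonically, because the intrinsic growth rates shift
with ``r`` as well).

The fluctuating-environment protocol introduces a new random species at a
fixed cadence into a community whose common association rate a(t) and
resource level r(t) oscillate periodically, r(t) ten times faster than a(t);
species that fail to establish are culled.  The community's diversity tracks
a(t) and peaks near resource scarcity.

The model comparison contrasts the mechanistic strand model with (i) the
phenomenological power-law model, whose diverging per-capita growth at zero
density lets any sub-exponential species invade anything ("survival of
everybody"), and (ii) the chemostat model, whose inflow concentration rho and
dilution rate act analogously to m and r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import (
    ChemostatModel,
    CommunityState,
    IntegrationError,
    MassRegulatedModel,
    PhenomenologicalModel,
    integrate,
)
from .equilibrium import equilibrium_state
from .kinetics import (
    ChemostatEnvironment,
    MassEnvironment,
    PhenomenologicalSpecies,
    SpeciesKinetics,
    intrinsic_growth_rate,
)
from .fixtures import methods_bc_grid

__all__ = [
    "SweepResult",
    "FluctuationConfig",
    "FluctuationResult",
    "sweep_m",
    "sweep_r",
    "sweep_grid",
    "fluctuating_run",
    "model_comparison",
]


@dataclass
class SweepResult:
    """Equilibria across a parameter grid.

    ``summary`` has one row per grid cell (m, r, phi_hat, n_survivors);
    ``species`` has one row per cell per species with its intrinsic growth
    rate and equilibrium concentrations.
    """

    summary: pd.DataFrame
    species: pd.DataFrame

    def cell(self, m: float, r: float) -> pd.Series:
        s = self.summary
        match = s[(np.isclose(s["m"], m)) & (np.isclose(s["r"], r))]
        if match.empty:
            raise KeyError(f"no sweep cell at m={m}, r={r}")
        return match.iloc[0]


def _sweep(kins: Sequence[SpeciesKinetics], cells) -> SweepResult:
    summary_rows = []
    species_rows = []
    for m, r in cells:
        env = MassEnvironment(m=m, r=r)
        sol = equilibrium_state(kins, env)
        summary_rows.append(
            {"m": m, "r": r, "phi_hat": sol.phi_hat, "n_survivors": sol.n_survivors}
        )
        for i, lab in enumerate(sol.labels):
            species_rows.append(
                {
                    "m": m,
                    "r": r,
                    "label": lab,
                    "lambda": float(sol.lambdas[i]),
                    "x_hat": float(sol.x_hat[i]),
                    "y_hat": float(sol.y_hat[i]),
                    "mu_hat": float(sol.mu_hat[i]),
                    "survived": lab in sol.survivors,
                }
            )
    return SweepResult(pd.DataFrame(summary_rows), pd.DataFrame(species_rows))


def sweep_m(
    kins: Sequence[SpeciesKinetics], r: float, m_grid: Optional[np.ndarray] = None
) -> SweepResult:
    """Equilibria along a (log-spaced by default) grid of target concentrations."""
    if m_grid is None:
        m_grid = np.logspace(-2, 2, 81)
    return _sweep(kins, [(float(m), float(r)) for m in np.asarray(m_grid)])


def sweep_r(
    kins: Sequence[SpeciesKinetics], m: float, r_grid: Optional[np.ndarray] = None
) -> SweepResult:
    """Equilibria along a grid of resource concentrations.

    The per-species table includes lambda at each r, so reordering of the
    intrinsic growth rates with the resource level is visible.
    """
    if r_grid is None:
        r_grid = np.logspace(-1, 1.5, 81)
    return _sweep(kins, [(float(m), float(r)) for r in np.asarray(r_grid)])


def sweep_grid(
    kins: Sequence[SpeciesKinetics],
    m_grid: Optional[np.ndarray] = None,
    r_grid: Optional[np.ndarray] = None,
) -> SweepResult:
    """Full factorial m x r sweep (diversity and production surfaces)."""
    if m_grid is None:
        m_grid = np.logspace(-2, 2, 81)
    if r_grid is None:
        r_grid = np.logspace(-1, 1.5, 81)
    cells = [(float(m), float(r)) for m in np.asarray(m_grid) for r in np.asarray(r_grid)]
    return _sweep(kins, cells)


# ---------------------------------------------------------------------------
# fluctuating environment


def _sinusoid(lo: float, hi: float, period: float) -> Callable[[float], float]:
    mid, amp = 0.5 * (hi + lo), 0.5 * (hi - lo)
    if period <= 0:
        raise ValueError("period must be positive")
    return lambda t: mid + amp * math.sin(2.0 * math.pi * t / period)


def _log_sinusoid(lo: float, hi: float, period: float) -> Callable[[float], float]:
    mid, amp = 0.5 * (math.log(hi) + math.log(lo)), 0.5 * (math.log(hi) - math.log(lo))
    if period <= 0:
        raise ValueError("period must be positive")
    return lambda t: math.exp(mid + amp * math.sin(2.0 * math.pi * t / period))


@dataclass
class FluctuationConfig:
    """Protocol of the fluctuating-environment run.

    The common association rate a(t) oscillates sinusoidally between ``a_min``
    and ``a_max`` on the slow period; the resource r(t) oscillates
    log-sinusoidally between ``r_min`` and ``r_max`` on a period one tenth as
    long.  Every ``mutant_interval`` time units a species with (b, c) drawn
    uniformly from the discrete rate grids enters at single-strand
    concentration ``intro_x``; at each introduction, species below the
    establishment threshold are removed (``removal_mode="all"``) or only a
    below-threshold newest species is (``removal_mode="newest"``).
    """

    a_min: float = 50.0
    a_max: float = 100.0
    a_period: float = 10_000.0
    r_min: float = 0.25
    r_max: float = 4.0
    r_period: float = 1_000.0
    m: float = 2.0
    mutant_interval: float = 100.0
    intro_x: float = 1.0e-5
    establishment_threshold: float = 3.0e-5
    t_total: float = 30_000.0
    removal_mode: str = "all"
    seed: int = 0
    rtol: float = 1.0e-8
    atol: float = 1.0e-10
    b_set: tuple = tuple(np.linspace(5.0, 10.0, 21))
    c_set: tuple = tuple(np.linspace(1.0, 5.0, 21))

    def __post_init__(self) -> None:
        if self.mutant_interval <= 0 or self.t_total <= 0:
            raise ValueError("intervals must be positive")
        if self.intro_x <= 0 or self.establishment_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.a_min <= self.a_max and 0 < self.r_min <= self.r_max):
            raise ValueError("waveform bounds must be positive and ordered")
        if self.removal_mode not in ("all", "newest"):
            raise ValueError(f"unknown removal_mode {self.removal_mode!r}")

    def a_of(self, t: float) -> float:
        if self.a_min == self.a_max:
            return self.a_min
        return _sinusoid(self.a_min, self.a_max, self.a_period)(t)

    def r_of(self, t: float) -> float:
        if self.r_min == self.r_max:
            return self.r_min
        return _log_sinusoid(self.r_min, self.r_max, self.r_period)(t)


def association_phase_contrast(series: pd.DataFrame, cfg: "FluctuationConfig",
                               window: float = 1000.0) -> float:
    """Mean species count near maxima of a(t) minus the mean near minima.

    Positive when diversity follows the association rate.  Maxima of the
    sinusoid sit at a quarter period, minima at three quarters; all full slow
    periods in the series are used.
    """
    t_end = float(series["t"].iloc[-1])
    peaks = np.arange(0.25 * cfg.a_period, t_end, cfg.a_period)
    troughs = np.arange(0.75 * cfg.a_period, t_end, cfg.a_period)

    def mean_near(centres):
        mask = np.zeros(len(series), dtype=bool)
        for c in centres:
            mask |= (series["t"] - c).abs().to_numpy() <= window
        return float(series.loc[mask, "n_established"].mean())

    return mean_near(peaks) - mean_near(troughs)


def resource_phase_contrast(series: pd.DataFrame, cfg: "FluctuationConfig") -> float:
    """Mean paired difference of species counts at r(t) minima vs maxima.

    Each fast resource period contributes one pair (scarcity sample minus
    abundance sample), so the slowly varying a(t) is controlled for; positive
    when diversity peaks under resource scarcity.
    """
    t_end = float(series["t"].iloc[-1])
    t_arr = series["t"].to_numpy()
    n_arr = series["n_established"].to_numpy()

    def at(t):
        return n_arr[np.argmin(np.abs(t_arr - t))]

    diffs = [
        at(0.75 * cfg.r_period + k * cfg.r_period) - at(0.25 * cfg.r_period + k * cfg.r_period)
        for k in range(int(t_end / cfg.r_period))
    ]
    return float(np.mean(diffs))


@dataclass
class FluctuationResult:
    """Time series and event log of a fluctuating-environment run."""

    series: pd.DataFrame  # t, a, r, n_established, n_present
    events: list  # dicts: {t, event, label, b, c}
    final_species: list  # (label, b, c) of species present at the end
    final_mu: np.ndarray


def fluctuating_run(cfg: FluctuationConfig) -> FluctuationResult:
    """Run the fluctuating-environment introduction/culling protocol.

    Deterministic for a fixed config (the seed drives the only RNG).
    """
    rng = np.random.default_rng(cfg.seed)
    b_set = np.asarray(cfg.b_set, dtype=float)
    c_set = np.asarray(cfg.c_set, dtype=float)

    # community bookkeeping: parallel lists of (label, b, c) and state arrays
    labels: list[str] = []
    b_arr = np.empty(0)
    c_arr = np.empty(0)
    x = np.empty(0)
    y = np.empty(0)
    events: list[dict] = []
    rows = []
    counter = 0

    def record(t: float) -> None:
        mu = x + 2.0 * y
        rows.append(
            {
                "t": t,
                "a": cfg.a_of(t),
                "r": cfg.r_of(t),
                "n_established": int(np.sum(mu >= cfg.establishment_threshold)),
                "n_present": len(labels),
            }
        )

    def rhs(t: float, v: np.ndarray) -> np.ndarray:
        n = b_arr.size
        xv, yv = v[:n], v[n:]
        a = cfg.a_of(t)
        r = cfg.r_of(t)
        phi = r / cfg.m * float(np.dot(c_arr, xv))
        assoc = a * xv * xv
        dx = -2.0 * assoc + 2.0 * b_arr * yv - r * c_arr * xv - phi * xv
        dy = assoc - b_arr * yv + r * c_arr * xv - phi * yv
        return np.concatenate([dx, dy])

    n_steps = int(round(cfg.t_total / cfg.mutant_interval))
    t = 0.0
    record(t)
    for step in range(n_steps):
        # removal of non-established species happens when the next mutant enters
        mu = x + 2.0 * y
        if cfg.removal_mode == "all":
            keep = mu >= cfg.establishment_threshold
        else:  # "newest": only the most recent introduction is at risk
            keep = np.ones(len(labels), dtype=bool)
            if len(labels) and mu[-1] < cfg.establishment_threshold:
                keep[-1] = False
        if not keep.all():
            for i in np.flatnonzero(~keep):
                events.append(
                    {"t": t, "event": "removed", "label": labels[i],
                     "b": float(b_arr[i]), "c": float(c_arr[i])}
                )
            labels = [lab for lab, k in zip(labels, keep) if k]
            b_arr, c_arr, x, y = b_arr[keep], c_arr[keep], x[keep], y[keep]

        counter += 1
        b_new = float(rng.choice(b_set))
        c_new = float(rng.choice(c_set))
        lab = f"mut{counter}"
        labels.append(lab)
        b_arr = np.append(b_arr, b_new)
        c_arr = np.append(c_arr, c_new)
        x = np.append(x, cfg.intro_x)
        y = np.append(y, 0.0)
        events.append({"t": t, "event": "introduced", "label": lab, "b": b_new, "c": c_new})

        t_next = (step + 1) * cfg.mutant_interval
        sol = solve_ivp(
            rhs, (t, t_next), np.concatenate([x, y]),
            method="BDF", rtol=cfg.rtol, atol=cfg.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"fluctuating run failed on [{t:g}, {t_next:g}]: {sol.message}"
            )
        v = np.maximum(sol.y[:, -1], 0.0)
        n = b_arr.size
        x, y = v[:n], v[n:]
        t = t_next
        record(t)

    return FluctuationResult(
        series=pd.DataFrame(rows),
        events=events,
        final_species=[(lab, float(b), float(c)) for lab, b, c in zip(labels, b_arr, c_arr)],
        final_mu=x + 2.0 * y,
    )


# ---------------------------------------------------------------------------
# model comparison


def phenomenological_invasion(
    residents: Sequence[PhenomenologicalSpecies],
    invader: PhenomenologicalSpecies,
    m: float,
    *,
    z0_invader: float = 1.0e-8,
    t_end: float = 1.0e4,
) -> dict:
    """Trajectory-based invasion test in the power-law model.

    Residents start at their single-community equilibrium (total mass m,
    partitioned by integrating the residents alone), the invader at a tiny
    concentration.  Because per-capita growth k z^{p-1} diverges as z -> 0
    for p < 1, any sub-exponential invader grows in: the hallmark artifact of
    the phenomenological framework.
    """
    species = list(residents)
    model_res = PhenomenologicalModel(species, m)
    res0 = np.full(len(species), m / max(len(species), 1))
    traj = integrate(model_res, res0, t_end=1.0e5, rtol=1.0e-9, atol=1.0e-12)
    z_res = traj.x[-1]

    full = PhenomenologicalModel(species + [invader], m)
    z0 = np.append(z_res, z0_invader)
    traj2 = integrate(full, z0, t_end=t_end, rtol=1.0e-9, atol=1.0e-12)
    z_inv_final = float(traj2.x[-1, -1])
    return {
        "invader_final": z_inv_final,
        "invaded": z_inv_final > 100.0 * z0_invader,
        "trajectory": traj2,
    }


def chemostat_equilibrium(
    kins: Sequence[SpeciesKinetics],
    env: ChemostatEnvironment,
    *,
    x0: float = 1.0e-3,
    t_end: float = 1.0e6,
    rtol: float = 1.0e-10,
    atol: float = 1.0e-12,
):
    """Integrate the chemostat model to steady state from a dilute start."""
    n = len(kins)
    model = ChemostatModel(kins, env)
    state0 = CommunityState(np.full(n, x0), np.zeros(n), env.rho)
    return integrate(model, state0, t_end=t_end, rtol=rtol, atol=atol)


def chemostat_rho_sweep(
    kins: Sequence[SpeciesKinetics],
    dilution: float,
    rho_grid: Sequence[float],
    *,
    extinction_threshold: float = 1.0e-7,
) -> pd.DataFrame:
    """Survivor counts of the chemostat model across inflow concentrations.

    Increasing rho acts like increasing the target concentration m of the
    mass-regulated model: diversity is non-decreasing along the sweep.
    """
    rows = []
    for rho in rho_grid:
        env = ChemostatEnvironment(rho=float(rho), phi=float(dilution))
        traj = chemostat_equilibrium(kins, env)
        mu = traj.mu[-1]
        rows.append(
            {
                "rho": float(rho),
                "dilution": float(dilution),
                "r_hat": float(traj.rvar[-1]),
                "mu_total": float(mu.sum()),
                "n_survivors": int(np.sum(mu >= extinction_threshold)),
            }
        )
    return pd.DataFrame(rows)


def model_comparison(
    kins: Sequence[SpeciesKinetics],
    env: MassEnvironment,
    *,
    rho_grid: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0),
    dilution: float = 1.0,
) -> dict:
    """Contrast the mechanistic model with the two comparison frameworks.

    (i) Invasion gating: in the mechanistic model an S-invader with intrinsic
    growth rate below the resident production is repelled; the matching
    phenomenological scenario (resident E-species, weak power-law invader)
    admits the invader regardless.  (ii) Regulation analogy: the chemostat's
    inflow concentration rho scales diversity like the target concentration m.
    """
    kins = list(kins)
    e_kins = [k for k in kins if k.is_exponential]
    if not e_kins:
        raise ValueError("model_comparison expects a community containing an E-species")
    sol = equilibrium_state(kins, env)
    lam0 = intrinsic_growth_rate(e_kins[0], env.r)

    # mechanistic: weak S-invader (lambda' < phi_hat_res) is repelled
    from .assembly import can_invade

    weak = SpeciesKinetics(a=77.5, b=9.75, c=1.6, label="weak-S")
    mech_blocked = not can_invade(weak, sol.phi_hat, env.r)

    # phenomenological analogue: E-resident (p=1, k=lambda0), weak S-invader
    resident = PhenomenologicalSpecies(k=lam0, p=1.0, label="E")
    invader = PhenomenologicalSpecies(k=0.1, p=0.5, label="weak-S")
    phen = phenomenological_invasion([resident], invader, env.m)

    rho_sweep = chemostat_rho_sweep(
        [k for k in kins if not k.is_exponential], dilution, rho_grid
    )
    m_counts = [
        equilibrium_state([k for k in kins if not k.is_exponential],
                          MassEnvironment(m=float(m), r=env.r)).n_survivors
        for m in rho_grid
    ]
    return {
        "mechanistic_weak_invader_blocked": mech_blocked,
        "phenomenological_weak_invader_succeeds": bool(phen["invaded"]),
        "phenomenological_invader_final": phen["invader_final"],
        "chemostat_rho_sweep": rho_sweep,
        "mass_m_sweep_counts": m_counts,
    }
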