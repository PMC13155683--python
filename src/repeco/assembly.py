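"""Invasion analysis and community assembly.

A rare invader grows at its intrinsic growth rate lambda', so it can enter a
resident community at equilibrium exactly when lambda' exceeds the resident
normalized production phi_hat_res — independently of the invader's association
rate.  A successful invasion never decreases the equilibrium production
(phi_hat_new >= phi_hat_res); residents whose intrinsic growth rate falls in
the half-open "zone of exclusion" (phi_hat_res, phi_hat_new] are extirpated,
and a displaced resident E-species (whose lambda sits exactly at phi_hat_res)
is lost as well.  The width of the zone measures the invader's
competitiveness; its lambda' measures its invasiveness.

Because every successful invasion (weakly) raises phi_hat, sequentially
invading species from a pool converges to the unique assembly that maximizes
phi_hat — independent of the order of introductions, and identical to solving
the equilibrium of the whole pool at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .equilibrium import EquilibriumSolution, equilibrium_state
from .kinetics import MassEnvironment, SpeciesKinetics, intrinsic_growth_rate

__all__ = [
    "InvasionOutcome",
    "AssemblyResult",
    "can_invade",
    "invade",
    "exclusion_zone",
    "assemble",
]

#: relative tolerance used when cross-checking the lambda-in-zone rule
#: against the zero-mass outcome of the new equilibrium
_ZONE_RTOL = 1.0e-9


@dataclass
class InvasionOutcome:
    """Result of introducing one invader into a resolved resident community."""

    invader_label: str
    lambda_invader: float
    phi_res: float
    phi_new: float
    can_invade: bool
    extinct: list
    survivors: list
    resident_solution: EquilibriumSolution
    new_solution: Optional[EquilibriumSolution] = None

    @property
    def zone(self) -> tuple[float, float]:
        """Zone of exclusion (phi_res, phi_new]; zero width on failure."""
        return (self.phi_res, self.phi_new)

    @property
    def zone_width(self) -> float:
        return self.phi_new - self.phi_res

    def to_report(self) -> dict:
        return {
            "invader": self.invader_label,
            "lambda": self.lambda_invader,
            "phi_res": self.phi_res,
            "phi_new": self.phi_new,
            "can_invade": self.can_invade,
            "extinct": list(self.extinct),
            "survivors": list(self.survivors),
        }


def can_invade(invader: SpeciesKinetics, phi_res: float, r: float) -> bool:
    """Invasion criterion: the invader's intrinsic growth rate must strictly
    exceed the resident normalized production.  Independent of the invader's
    association rate."""
    if phi_res < 0:
        raise ValueError("resident production must be non-negative")
    return intrinsic_growth_rate(invader, r) > phi_res


def invade(
    residents: Sequence[SpeciesKinetics],
    invader: SpeciesKinetics,
    env: MassEnvironment,
    resident_solution: Optional[EquilibriumSolution] = None,
) -> InvasionOutcome:
    """Adiabatic invasion: resolve the resident equilibrium, test the invasion
    criterion, and on success re-solve the equilibrium of residents + invader.

    ``extinct`` lists the resident survivors lost in the transition; the list
    is cross-checked against the lambda-in-zone characterization (plus the
    displaced-E rule) on every call.
    """
    residents = list(residents)
    sol_res = resident_solution or equilibrium_state(residents, env)
    lam = intrinsic_growth_rate(invader, env.r)
    label = invader.label or "invader"

    if lam <= sol_res.phi_hat:
        return InvasionOutcome(
            invader_label=label,
            lambda_invader=lam,
            phi_res=sol_res.phi_hat,
            phi_new=sol_res.phi_hat,
            can_invade=False,
            extinct=[],
            survivors=list(sol_res.survivors),
            resident_solution=sol_res,
        )

    sol_new = equilibrium_state(residents + [invader], env)
    extinct = [s for s in sol_res.survivors if s not in sol_new.survivors]
    _cross_check_extinct(residents, sol_res, sol_new, extinct, env)
    return InvasionOutcome(
        invader_label=label,
        lambda_invader=lam,
        phi_res=sol_res.phi_hat,
        phi_new=sol_new.phi_hat,
        can_invade=True,
        extinct=extinct,
        survivors=list(sol_new.survivors),
        resident_solution=sol_res,
        new_solution=sol_new,
    )


def _cross_check_extinct(residents, sol_res, sol_new, extinct, env) -> None:
    """Verify extinct == {residents with lambda in (phi_res, phi_new]} plus a
    displaced resident E-species, modulo marginal (round-off) cases."""
    lo, hi = sol_res.phi_hat, sol_new.phi_hat
    tol = _ZONE_RTOL * max(hi, 1.0)
    expected = set()
    for kin in residents:
        lab = kin.label or ""
        if lab not in sol_res.survivors:
            continue
        lam = intrinsic_growth_rate(kin, env.r)
        if lab == sol_res.resident_E:
            if lab not in sol_new.survivors:
                expected.add(lab)
        elif lo + tol < lam <= hi + tol:
            expected.add(lab)
    marginal = set(sol_new.marginal) | set(sol_res.marginal)
    if (set(extinct) ^ expected) - marginal:
        raise RuntimeError(
            "zone-of-exclusion rule and equilibrium zero-mass outcome disagree: "
            f"zone predicts {sorted(expected)}, equilibrium gives {sorted(extinct)}"
        )


def exclusion_zone(outcome: InvasionOutcome) -> dict:
    """Zone of exclusion (phi_res, phi_new] of a resolved invasion.

    Returns the interval, its width (the invader's competitiveness), and the
    labels extirpated by it.  A failed invasion has a zero-width (empty) zone.
    """
    return {
        "interval": outcome.zone,
        "width": outcome.zone_width,
        "extinct": list(outcome.extinct),
        "empty": not outcome.can_invade or outcome.zone_width == 0.0,
    }


def invade_by_trajectory(
    residents: Sequence[SpeciesKinetics],
    invader: SpeciesKinetics,
    env: MassEnvironment,
    *,
    x0: float = 1.0e-5,
    t_end: float = 1.0e6,
    extinction_threshold: float = 1.0e-7,
) -> dict:
    """Dynamical cross-check of the adiabatic invasion analysis.

    The residents start at their analytic equilibrium, the invader at a small
    single-strand concentration; the full dynamics are integrated to steady
    state and species below the extinction threshold are declared extinct.
    Slower than :func:`invade` but assumption-free about the outcome.
    """
    from .dynamics import CommunityState, MassRegulatedModel, integrate

    residents = list(residents)
    sol = equilibrium_state(residents, env)
    kins = residents + [invader]
    x_init = np.append(sol.x_hat, x0)
    y_init = np.append(sol.y_hat, 0.0)
    model = MassRegulatedModel(kins, env)
    traj = integrate(model, CommunityState(x_init, y_init), t_end=t_end)
    mu = traj.mu[-1]
    labels = [k.label for k in kins]
    survivors = [lab for lab, m in zip(labels, mu) if m >= extinction_threshold]
    return {
        "survivors": survivors,
        "invader_established": labels[-1] in survivors,
        "mu_final": mu,
        "phi_final": float(traj.phi[-1]),
        "trajectory": traj,
    }


@dataclass
class AssemblyResult:
    """Final community reached from a species pool."""

    survivors: list
    phi_hat: float
    solution: EquilibriumSolution
    n_invasions: int = 0
    events: list = field(default_factory=list)


def assemble(
    pool: Sequence[SpeciesKinetics],
    env: MassEnvironment,
    order: Sequence[int] | str = "all-at-once",
) -> AssemblyResult:
    """Maximal coexisting assembly from a species pool.

    With ``order="all-at-once"`` the equilibrium of the whole pool is solved
    directly (species that cannot persist drop out with zero mass).  With an
    explicit introduction order, species are invaded one at a time and passes
    over the pool repeat until no member can invade; the final survivor set
    and phi_hat are order-independent and coincide with the all-at-once
    solution.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("species pool must not be empty")

    if isinstance(order, str):
        if order != "all-at-once":
            raise ValueError(f"unknown assembly order {order!r}")
        sol = equilibrium_state(pool, env)
        return AssemblyResult(list(sol.survivors), sol.phi_hat, sol)

    order = list(order)
    if sorted(order) != list(range(len(pool))):
        raise ValueError("order must be a permutation of the pool indices")

    current: list[SpeciesKinetics] = []
    sol: Optional[EquilibriumSolution] = None
    events = []
    n_invasions = 0
    by_label = {k.label: k for k in pool}
    for _ in range(len(pool) + 1):
        changed = False
        for idx in order:
            kin = pool[idx]
            if sol is not None and kin.label in sol.survivors:
                continue
            if sol is None:
                current = [kin]
                sol = equilibrium_state(current, env)
                n_invasions += 1
                events.append({"invader": kin.label, "phi_hat": sol.phi_hat, "extinct": []})
                changed = True
                continue
            outcome = invade(current, kin, env, resident_solution=sol)
            if not outcome.can_invade:
                continue
            n_invasions += 1
            changed = True
            sol = outcome.new_solution
            current = [by_label[lab] for lab in sol.survivors]
            sol = equilibrium_state(current, env)
            events.append(
                {"invader": kin.label, "phi_hat": sol.phi_hat, "extinct": outcome.extinct}
            )
        if not changed:
            break
    assert sol is not None
    return AssemblyResult(list(sol.survivors), sol.phi_hat, sol, n_invasions, events)
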