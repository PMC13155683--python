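"""Analytic equilibria of the mass-regulated replicator community.

At equilibrium every surviving species grows exactly at the system's
normalized production phi_hat (the common per-capita outflow).  For an
S-species (a > 0) the growth rate Lambda(x) is strictly decreasing in its own
single-strand concentration, so Lambda(x_hat) = phi_hat can be inverted in
closed form; its equilibrium total then follows from the strand-ratio
identities

    x_hat / mu_hat = phi_hat / (r c),        y_hat / x_hat = (c r - phi_hat) / (2 phi_hat).

Summing the per-species masses over all S-species gives a continuous, strictly
decreasing function of phi on (0, max_i lambda_i) that diverges as phi -> 0
and vanishes at the largest intrinsic growth rate, so the mass-balance
condition sum_i mu_hat_i(phi) = m has a unique root: that root is phi_hat, and
the survivors are exactly the species with lambda_i > phi_hat.

An E-species (a = 0) can only be stationary when phi_hat equals its own
intrinsic growth rate, so a persisting E-species pins phi_hat = lambda_0 and
absorbs whatever mass the S-species do not claim at that production level.  At
most one E-species can persist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .kinetics import MassEnvironment, SpeciesKinetics, growth_rate, intrinsic_growth_rate

__all__ = [
    "EquilibriumSolution",
    "DegenerateCommunityError",
    "invert_growth_rate",
    "species_equilibrium_mass",
    "equilibrium_phi",
    "equilibrium_state",
    "critical_target_concentration",
]

#: relative half-width of the band around phi_hat inside which a species'
#: survivor/excluded classification is reported as "marginal"
MARGINAL_RTOL = 1.0e-9
#: absolute tolerance on the E-species residual-mass test
RESIDUAL_ATOL = 1.0e-12


class DegenerateCommunityError(ValueError):
    """Input community admits no well-defined equilibrium decision (e.g. tied
    E-species growth rates, or a tied first-extinction threshold)."""


@dataclass
class EquilibriumSolution:
    """Equilibrium of a replicator community.

    Arrays are aligned with the input species order; excluded species carry
    zeros.  ``resident_E`` names the single persisting E-species, if any.
    ``marginal`` lists species whose intrinsic growth rate is within round-off
    of phi_hat, where the survivor classification is not numerically reliable.
    """

    phi_hat: float
    labels: list
    lambdas: np.ndarray
    x_hat: np.ndarray
    y_hat: np.ndarray
    mu_hat: np.ndarray
    survivors: list
    resident_E: Optional[str] = None
    marginal: list = field(default_factory=list)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    def to_report(self) -> dict:
        """JSON-serialisable equilibrium report."""
        return {
            "phi_hat": self.phi_hat,
            "survivors": list(self.survivors),
            "species": {
                lab: {
                    "x_hat": float(self.x_hat[i]),
                    "y_hat": float(self.y_hat[i]),
                    "mu_hat": float(self.mu_hat[i]),
                    "lambda": float(self.lambdas[i]),
                }
                for i, lab in enumerate(self.labels)
            },
            "flags": {"resident_E": self.resident_E, "marginal": list(self.marginal)},
        }


def invert_growth_rate(kin: SpeciesKinetics, r: float, phi: float) -> float:
    """Single-strand concentration x_hat at which Lambda(x_hat) = phi.

    Defined for an S-species (a > 0) and 0 < phi < lambda.  Evaluated in the
    factored form x_hat = (lambda - phi)(phi - lambda_minus) / (2 a phi), where
    lambda and lambda_minus are the two roots of the defining quadratic
    phi^2 + (b + c r) phi - b c r = 0; this avoids the cancellation the raw
    numerator b c r - (b + c r) phi - phi^2 suffers as phi -> lambda.
    """
    if kin.a <= 0:
        raise ValueError("invert_growth_rate requires an S-species (a > 0)")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    lam = intrinsic_growth_rate(kin, r)
    if phi == lam:
        # Lambda(0) = lambda: the defining quadratic makes the numerator vanish
        return 0.0
    if phi > lam:
        raise ValueError(
            f"phi={phi} > lambda={lam}: no positive equilibrium concentration "
            "(species excluded at this production level)"
        )
    s = kin.b + kin.c * r
    lam_minus = -0.5 * (s + np.sqrt(s * s + 4.0 * kin.b * kin.c * r))
    return float((lam - phi) * (phi - lam_minus) / (2.0 * kin.a * phi))


def species_equilibrium_mass(kin: SpeciesKinetics, r: float, phi: float) -> float:
    """Equilibrium total concentration mu_hat of an S-species at production phi.

    mu_hat = r c x_hat / phi, strictly decreasing in phi on (0, lambda);
    returns 0 for phi >= lambda (the species is excluded), so the function is
    continuous across the exclusion boundary and safe for root-finding.
    """
    if kin.a <= 0:
        raise ValueError("species_equilibrium_mass requires an S-species (a > 0)")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    lam = intrinsic_growth_rate(kin, r)
    if phi >= lam:
        return 0.0
    return r * kin.c * invert_growth_rate(kin, r, phi) / phi


def _total_s_mass(s_kins: Sequence[SpeciesKinetics], r: float, phi: float) -> float:
    return sum(species_equilibrium_mass(k, r, phi) for k in s_kins)


def _labels(kins: Sequence[SpeciesKinetics]) -> list:
    return [k.label or str(i + 1) for i, k in enumerate(kins)]


def _fill_solution(
    kins: Sequence[SpeciesKinetics],
    env: MassEnvironment,
    phi_hat: float,
    resident_E: Optional[int],
    mu_E: float,
) -> EquilibriumSolution:
    labels = _labels(kins)
    lambdas = np.array([intrinsic_growth_rate(k, env.r) for k in kins])
    n = len(kins)
    x_hat = np.zeros(n)
    y_hat = np.zeros(n)
    mu_hat = np.zeros(n)
    survivors: list = []
    marginal: list = []
    for i, kin in enumerate(kins):
        lam = lambdas[i]
        if abs(lam - phi_hat) <= MARGINAL_RTOL * phi_hat and i != resident_E:
            marginal.append(labels[i])
        if i == resident_E:
            mu_hat[i] = mu_E
            x_hat[i] = mu_E * phi_hat / (env.r * kin.c)
        elif kin.a > 0 and lam > phi_hat:
            x_hat[i] = invert_growth_rate(kin, env.r, phi_hat)
            mu_hat[i] = env.r * kin.c * x_hat[i] / phi_hat
        else:
            continue
        y_hat[i] = x_hat[i] * (kin.c * env.r - phi_hat) / (2.0 * phi_hat)
        survivors.append(labels[i])
    return EquilibriumSolution(
        phi_hat=float(phi_hat),
        labels=labels,
        lambdas=lambdas,
        x_hat=x_hat,
        y_hat=y_hat,
        mu_hat=mu_hat,
        survivors=survivors,
        resident_E=labels[resident_E] if resident_E is not None else None,
        marginal=marginal,
    )


def _pure_s_phi(s_kins: Sequence[SpeciesKinetics], env: MassEnvironment) -> float:
    lambdas = [intrinsic_growth_rate(k, env.r) for k in s_kins]
    lam_max = max(lambdas)
    eps = 1.0e-12 * lam_max
    lo, hi = eps, lam_max - eps
    f = lambda phi: _total_s_mass(s_kins, env.r, phi) - env.m
    f_lo, f_hi = f(lo), f(hi)
    if f_lo < 0:  # total S mass below m even at phi -> 0: cannot happen for a > 0
        raise RuntimeError("mass balance not bracketed at the lower end")
    if f_hi > 0:
        raise RuntimeError("mass balance not bracketed at the upper end")
    return float(brentq(f, lo, hi, xtol=1.0e-15, rtol=1.0e-13))


def equilibrium_phi(
    kins: Sequence[SpeciesKinetics], env: MassEnvironment
) -> EquilibriumSolution:
    """Equilibrium normalized production and community composition.

    Pure-S communities: phi_hat is the unique root of the mass balance
    sum_i mu_hat_i(phi) = m.  With E-species present, only the one with the
    largest intrinsic growth rate lambda_0 can persist; it does so exactly
    when the S-species leave positive residual mass at phi = lambda_0, in
    which case phi_hat = lambda_0 and the E-species absorbs the residual.
    Otherwise the E-species is excluded and the pure-S branch applies.
    """
    kins = list(kins)
    if not kins:
        raise ValueError("community must contain at least one species")
    if env.r <= 0:
        raise ValueError("equilibrium requires a positive resource concentration")

    e_idx = [i for i, k in enumerate(kins) if k.is_exponential]
    s_kins = [k for k in kins if not k.is_exponential]

    resident_E: Optional[int] = None
    if e_idx:
        e_lams = [intrinsic_growth_rate(kins[i], env.r) for i in e_idx]
        order = np.argsort(e_lams)[::-1]
        if len(e_idx) > 1 and e_lams[order[0]] == e_lams[order[1]]:
            raise DegenerateCommunityError(
                "two E-species share the maximal intrinsic growth rate; "
                "no tie-breaking rule exists (E-species cannot coexist)"
            )
        best_e = e_idx[int(order[0])]
        lam0 = e_lams[int(order[0])]
        residual = env.m - _total_s_mass(s_kins, env.r, lam0)
        if residual > RESIDUAL_ATOL:
            return _fill_solution(kins, env, lam0, best_e, residual)
        # E-species cannot claim positive mass: falls back to the pure-S branch

    if not s_kins:
        raise ValueError(
            "community of E-species only admits no positive-mass equilibrium "
            "when the E-species residual test fails"
        )
    phi_hat = _pure_s_phi(s_kins, env)
    return _fill_solution(kins, env, phi_hat, None, 0.0)


def equilibrium_state(
    kins: Sequence[SpeciesKinetics], env: MassEnvironment
) -> EquilibriumSolution:
    """Full equilibrium with per-species strand concentrations filled in.

    ``equilibrium_phi`` already resolves the complete state; this alias names
    the operation that consumers needing x_hat / y_hat should call.
    """
    return equilibrium_phi(kins, env)


def critical_target_concentration(
    kins: Sequence[SpeciesKinetics], r: float
) -> float:
    """Critical target concentration m* at which the first extinction occurs.

    For a pure-S community, phi_hat decreases with m, so as m shrinks the
    production rises until it reaches the smallest intrinsic growth rate
    lambda_min; at that boundary the lowest-lambda species holds zero mass and
    m* equals the mass of all remaining species at phi = lambda_min.
    """
    kins = list(kins)
    if any(k.is_exponential for k in kins):
        raise ValueError("critical_target_concentration is defined for pure-S communities")
    if len(kins) < 2:
        raise ValueError("a single-species community has no first-extinction threshold")
    lambdas = np.array([intrinsic_growth_rate(k, r) for k in kins])
    lam_min = float(lambdas.min())
    if np.sum(np.isclose(lambdas, lam_min, rtol=1.0e-12, atol=0.0)) > 1:
        raise DegenerateCommunityError(
            "two or more species share the smallest intrinsic growth rate; the "
            "first-extinction threshold is degenerate"
        )
    others = [k for k, lam in zip(kins, lambdas) if lam > lam_min]
    return float(sum(species_equilibrium_mass(k, r, lam_min) for k in others))
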