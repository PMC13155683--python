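"""Kinetic parameter sets, environments, and the replicator growth-rate laws.

A replicator species is described by three mass-action rate constants: the
association rate ``a`` at which two single strands of the same species pair
into a replication-inert duplex, the dissociation rate ``b`` of such duplexes,
and the template-directed replication rate ``c``.  A species with ``a > 0``
self-inhibits through duplex formation and grows sub-exponentially (an
"S-species"); a species with ``a = 0`` grows exponentially (an "E-species").

Once the single-/double-strand ratio of a species has equilibrated, its
population grows at the fitness

    Lambda(x) = [ -(2 a x + b + c r) + sqrt((2 a x + b + c r)^2 + 4 b c r) ] / 2,

a strictly decreasing function of the species' own single-strand concentration
``x`` whenever ``a > 0``.  Its value at vanishing concentration,

    lambda = Lambda(0),

is the intrinsic growth rate: the largest growth rate the species can attain,
and the rate at which a rare species (or an E-species at any concentration)
grows.  ``lambda`` does not depend on ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesKinetics",
    "PhenomenologicalSpecies",
    "MassEnvironment",
    "ChemostatEnvironment",
    "intrinsic_growth_rate",
    "growth_rate",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SpeciesKinetics:
    """Rate constants of one replicator species.

    Parameters
    ----------
    a:
        Association rate of two single strands into a duplex
        (concentration^-1 time^-1, >= 0).  ``a == 0`` marks an
        exponentially-growing E-species.
    b:
        Duplex dissociation rate (time^-1, > 0).
    c:
        Replication rate on the common resource (concentration^-1 time^-1, > 0).
    label:
        Identifier used in reports and trajectory columns.
    """

    a: float
    b: float
    c: float
    label: str = ""

    def __post_init__(self) -> None:
        a = _require_finite("a", self.a)
        b = _require_finite("b", self.b)
        c = _require_finite("c", self.c)
        if a < 0:
            raise ValueError(f"association rate a must be >= 0, got {a}")
        if b <= 0:
            raise ValueError(f"dissociation rate b must be > 0, got {b}")
        if c <= 0:
            raise ValueError(f"replication rate c must be > 0, got {c}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def is_exponential(self) -> bool:
        """True for an E-species (zero association rate)."""
        return self.a == 0.0


@dataclass(frozen=True)
class PhenomenologicalSpecies:
    """One species of the single-equation power-law growth model.

    Growth follows dz/dt = k z^p - phi z; ``0 < p < 1`` approximates a
    sub-exponential replicator at high concentration, ``p == 1`` is an
    exponential species.
    """

    k: float
    p: float
    label: str = ""

    def __post_init__(self) -> None:
        k = _require_finite("k", self.k)
        p = _require_finite("p", self.p)
        if k <= 0:
            raise ValueError(f"rate constant k must be > 0, got {k}")
        if not 0.0 < p <= 1.0:
            raise ValueError(f"growth exponent p must be in (0, 1], got {p}")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "p", p)

    @property
    def is_exponential(self) -> bool:
        return self.p == 1.0


@dataclass(frozen=True)
class MassEnvironment:
    """Mass-regulated setting: fixed resource, outflow tuned to a target mass.

    ``m`` is the target replicator concentration (the carrying capacity of the
    total strand concentration); ``r`` is the constant resource concentration.
    """

    m: float
    r: float

    def __post_init__(self) -> None:
        m = _require_finite("m", self.m)
        r = _require_finite("r", self.r)
        if m <= 0:
            raise ValueError(f"target replicator concentration m must be > 0, got {m}")
        if r < 0:
            raise ValueError(f"resource concentration r must be >= 0, got {r}")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "r", r)


@dataclass(frozen=True)
class ChemostatEnvironment:
    """Chemostat setting: constant dilution rate, dynamically tracked resource.

    ``rho`` is the inflowing resource concentration and ``phi`` the dilution
    rate (relative outflow per unit time).  At equilibrium the total replicator
    concentration equals ``rho - r_hat``.
    """

    rho: float
    phi: float

    def __post_init__(self) -> None:
        rho = _require_finite("rho", self.rho)
        phi = _require_finite("phi", self.phi)
        if rho <= 0:
            raise ValueError(f"inflow concentration rho must be > 0, got {rho}")
        if phi <= 0:
            raise ValueError(f"dilution rate phi must be > 0, got {phi}")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "phi", phi)


def _growth_rate_stable(s, bcr):
    """Evaluate [-s + sqrt(s^2 + 4 bcr)] / 2 without cancellation.

    Multiplying by the conjugate gives 2 bcr / (s + sqrt(s^2 + 4 bcr)), exact
    when bcr << s^2 where the direct form loses all significant digits.
    """
    s = np.asarray(s, dtype=float)
    bcr = np.asarray(bcr, dtype=float)
    return 2.0 * bcr / (s + np.sqrt(s * s + 4.0 * bcr))


def intrinsic_growth_rate(kin: SpeciesKinetics, r: float) -> float:
    """Intrinsic growth rate lambda of a species at resource concentration r.

    lambda = [-(b + c r) + sqrt((b + c r)^2 + 4 b c r)] / 2.  Independent of
    the association rate ``a``; equals 0 when r = 0 (no resource, no growth).
    """
    r = _require_finite("r", r)
    if r < 0:
        raise ValueError(f"resource concentration r must be >= 0, got {r}")
    s = kin.b + kin.c * r
    return float(_growth_rate_stable(s, kin.b * kin.c * r))


def growth_rate(kin: SpeciesKinetics, r: float, x: float) -> float:
    """Concentration-dependent growth rate Lambda(x) of a species.

    Strictly decreasing in the species' own single-strand concentration ``x``
    when ``a > 0``; Lambda(0) recovers the intrinsic growth rate.
    """
    r = _require_finite("r", r)
    x = _require_finite("x", x)
    if r < 0:
        raise ValueError(f"resource concentration r must be >= 0, got {r}")
    if x < 0:
        raise ValueError(f"concentration x must be >= 0, got {x}")
    s = 2.0 * kin.a * x + kin.b + kin.c * r
    return float(_growth_rate_stable(s, kin.b * kin.c * r))


def lambda_vector(kins, r: float) -> np.ndarray:
    """Intrinsic growth rates of a list of species at resource level r."""
    b = np.array([k.b for k in kins], dtype=float)
    c = np.array([k.c for k in kins], dtype=float)
    s = b + c * r
    return np.asarray(_growth_rate_stable(s, b * c * r), dtype=float)
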